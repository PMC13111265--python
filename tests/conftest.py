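import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qtltriad import simulate_locus

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


MA_HEADER = "SNP\tCHR\tPOS\tA1\tA2\tfreq\tb\tse\tp\tN\n"


def ma_line(snp, chrom, pos, a1, a2, freq, b, se, p, n):
    return f"{snp}\t{chrom}\t{pos}\t{a1}\t{a2}\t{freq}\t{b}\t{se}\t{p}\t{n}\n"


@pytest.fixture
def write_ma(tmp_path):
    """Write a COJO-style summary-statistics file and return its path."""

    def _write(rows, header=MA_HEADER, name="sumstats.tsv"):
        path = tmp_path / name
        path.write_text(header + "".join(rows))
        return path

    return _write


@pytest.fixture(scope="session")
def mediated_locus():
    """One mediated-scenario locus at the default study conditions."""
    return simulate_locus("mediated", 100, seed=20260927)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
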