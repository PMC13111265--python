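"""Bayesian colocalization of two traits from summary statistics.

Per-variant Wakefield approximate Bayes factors are combined by
enumeration over the five mutually exclusive causal configurations of a
locus (H0: no association; H1/H2: one trait only; H3: both traits,
distinct causal variants; H4: both traits, one shared causal variant),
yielding posterior probabilities PP.H0..PP.H4.  All evidence is
accumulated in log space, so arbitrarily strong signals do not overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sumstats import Dataset, harmonize_datasets

__all__ = ["ColocResult", "wakefield_labf", "coloc_abf", "ColocAnalysis"]

_HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities over the five colocalization hypotheses."""

    pp: dict[str, float]
    n_snps: int
    p1: float
    p2: float
    p12: float
    log_evidence: dict[str, float]

    @property
    def pph4(self) -> float:
        return self.pp["H4"]

    def summary(self) -> str:
        pp = "  ".join(f"PP.{h}={self.pp[h]:.3f}" for h in _HYPOTHESES)
        return (
            f"Colocalization over {self.n_snps} SNPs "
            f"(p1={self.p1:g}, p2={self.p2:g}, p12={self.p12:g})\n  {pp}"
        )


def wakefield_labf(z, se, prior_sd: float = 0.2):
    """Log approximate Bayes factor for one variant (Wakefield).

    With ``V = se^2``, ``W = prior_sd^2`` and shrinkage ``r = W/(V+W)``::

        lABF = 0.5 * (log(1 - r) + r * z^2)
    """
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    z = np.asarray(z, dtype=float)
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    return 0.5 * (np.log1p(-r) + r * z**2)


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)); tiny negative differences clamp to -inf."""
    if b >= a:
        if b > a + 1e-9:
            warnings.warn(
                "colocalization H3 evidence numerically negative; clamped to zero",
                RuntimeWarning,
                stacklevel=2,
            )
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    z1,
    se1,
    z2,
    se2,
    *,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.2,
    prior_sd2: float = 0.15,
) -> ColocResult:
    """Enumeration colocalization from aligned z/se vectors of two traits.

    The panels must be identical and in the same allele orientation.
    Priors are per-SNP probabilities of being causal for trait 1 only
    (``p1``), trait 2 only (``p2``), or both (``p12``); effect-size
    prior SDs default to 0.2 (molecular trait) and 0.15 (case-control).
    """
    z1, se1, z2, se2 = (np.atleast_1d(np.asarray(x, float)) for x in (z1, se1, z2, se2))
    if not (z1.shape == se1.shape == z2.shape == se2.shape):
        raise ValueError("trait panels must be identical in length")
    m = z1.size
    if m < 1:
        raise ValueError("at least one SNP required")
    labf1 = wakefield_labf(z1, se1, prior_sd1)
    labf2 = wakefield_labf(z2, se2, prior_sd2)
    l1 = float(logsumexp(labf1))
    l2 = float(logsumexp(labf2))
    l12 = float(logsumexp(labf1 + labf2))

    with np.errstate(divide="ignore"):
        lp1, lp2, lp12 = np.log(p1), np.log(p2), np.log(p12)
    log_ev = {
        "H0": 0.0,
        "H1": lp1 + l1,
        "H2": lp2 + l2,
        "H3": (lp1 + lp2 + _logdiff(l1 + l2, l12)) if m > 1 else -np.inf,
        "H4": lp12 + l12,
    }
    ev = np.array([log_ev[h] for h in _HYPOTHESES])
    pp = np.exp(ev - logsumexp(ev))
    return ColocResult(
        pp=dict(zip(_HYPOTHESES, map(float, pp))),
        n_snps=m,
        p1=p1,
        p2=p2,
        p12=p12,
        log_evidence=log_ev,
    )


class ColocAnalysis:
    """Colocalization of two summary-statistic datasets at a locus.

    Aligns the shared variant panel, harmonises trait 2 to trait 1's
    allele orientation, and runs :func:`coloc_abf`.  Effect-size prior
    SDs are chosen from each dataset's ``trait_kind`` (0.2 for molecular
    traits, 0.15 for disease) unless given explicitly.
    """

    def __init__(
        self,
        trait1: Dataset,
        trait2: Dataset,
        *,
        p1: float = 1e-4,
        p2: float = 1e-4,
        p12: float = 1e-5,
        prior_sd1: float | None = None,
        prior_sd2: float | None = None,
        variant_ids: list[str] | None = None,
    ):
        self.trait1 = trait1
        self.trait2 = trait2
        self.p1, self.p2, self.p12 = p1, p2, p12
        self.prior_sd1 = prior_sd1 if prior_sd1 is not None else self._default_sd(trait1)
        self.prior_sd2 = prior_sd2 if prior_sd2 is not None else self._default_sd(trait2)
        self.variant_ids = variant_ids

    @staticmethod
    def _default_sd(ds: Dataset) -> float:
        return 0.15 if ds.trait_kind == "disease" else 0.2

    def fit(self) -> ColocResult:
        t1, t2 = self.trait1, self.trait2
        if self.variant_ids is not None:
            t1 = t1.subset(self.variant_ids)
            t2 = t2.subset(self.variant_ids)
        merged, _ = harmonize_datasets(t1, t2)
        if merged.empty:
            raise ValueError("no shared variants between the two traits")
        return coloc_abf(
            merged["beta_exp"] / merged["se_exp"],
            merged["se_exp"],
            merged["beta_out"] / merged["se_out"],
            merged["se_out"],
            p1=self.p1,
            p2=self.p2,
            p12=self.p12,
            prior_sd1=self.prior_sd1,
            prior_sd2=self.prior_sd2,
        )
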