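"""Synthetic coupled mQTL → eQTL → GWAS summary statistics with known truth.

One simulated locus is an LD block of ``m`` variants carrying three
layers of marginal associations — methylation (mQTL), expression (eQTL)
and disease (GWAS) — generated directly on the standardized summary
scale:

    z_layer ~ MVN( sqrt(n_layer) * R @ b_layer,  R )

where ``R`` is the LD correlation matrix (AR(1), ``r_jk = rho^|j-k|``,
by default) and ``b_layer`` the per-SNP *causal* effects implied by the
scenario's structural chain

    SNP --alpha--> methylation --gamma--> expression --c--> disease

with an optional direct (pleiotropic) SNP -> disease effect ``pi`` and a
direct SNP -> expression effect ``delta``.  Observed effects are
``beta = z/sqrt(n)`` with ``se = 1/sqrt(n)``.  Layers are sampled
independently (non-overlapping cohorts).

Scenarios
---------
``mediated``    one causal SNP, full chain alpha, gamma, c; pi = 0.
``pleiotropy``  one causal SNP affecting expression and disease through
                separate paths (c = 0, pi != 0).
``linkage``     distinct causal SNPs for the molecular layers and for
                disease, in LD with each other.
``null``        no effects anywhere.
``reverse``     disease drives expression: a strong direct disease
                effect whose echo in expression is attenuated, so the
                variant explains more outcome than exposure variance.

Default effect sizes and sample sizes are the generator's study
conditions (alpha = 0.15, gamma = 0.5, c = 0.3; n = 20k/20k/200k);
explicit keyword overrides are allowed for calibration designs such as
a strong-eQTL / null-outcome locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .smr import LdMatrix
from .sumstats import Annotation, Dataset, wald_p

__all__ = [
    "LocusTruth",
    "SimulatedLocus",
    "simulate_locus",
    "evaluate_recovery",
    "GENE_ID",
    "PROBE_ID",
]

GENE_ID = "GENE1"
PROBE_ID = "cg00000001"

SCENARIOS = ("mediated", "pleiotropy", "linkage", "null", "reverse")

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class LocusTruth:
    """Ground truth of one simulated locus."""

    scenario: str
    m_snps: int
    causal_indices: Mapping[str, tuple[int, ...]]
    alpha: float
    gamma: float
    c: float
    pi: float
    delta: float
    rho: float
    n_m: int
    n_e: int
    n_g: int
    seed: int


@dataclass
class SimulatedLocus:
    """Three coupled summary-statistic layers plus LD, annotation, truth."""

    mqtl: Dataset
    eqtl: Dataset
    gwas: Dataset
    ld: LdMatrix
    annotation: Annotation
    truth: LocusTruth


def _resolve_effects(
    scenario: str,
    alpha: float,
    gamma: float,
    c: float,
    pi: float | None,
    delta: float | None,
    reverse_frac: float,
) -> tuple[float, float, float, float, float]:
    """Scenario defaults for which structural effects are active."""
    if scenario == "mediated":
        return alpha, gamma, c, 0.0 if pi is None else pi, 0.0 if delta is None else delta
    if scenario == "pleiotropy":
        # direct disease effect sized like the mediated marginal effect
        pi = alpha * gamma * 0.3 if pi is None else pi
        return alpha, gamma, 0.0, pi, 0.0 if delta is None else delta
    if scenario == "linkage":
        pi = alpha * gamma * 0.3 if pi is None else pi
        delta = alpha * gamma if delta is None else delta
        return alpha, gamma, 0.0, pi, delta
    if scenario == "null":
        return 0.0, 0.0, 0.0, 0.0, 0.0
    if scenario == "reverse":
        pi = alpha if pi is None else pi
        return 0.0, 0.0, 0.0, pi, 0.0
    raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")


def simulate_locus(
    scenario: str = "mediated",
    m_snps: int = 100,
    *,
    rho: float = 0.6,
    alpha: float = 0.15,
    gamma: float = 0.5,
    c: float = 0.3,
    pi: float | None = None,
    delta: float | None = None,
    n_m: int = 20_000,
    n_e: int = 20_000,
    n_g: int = 200_000,
    seed: int = 0,
    causal_index: int | None = None,
    linkage_lag: int = 1,
    reverse_frac: float = 0.5,
    ld: LdMatrix | None = None,
    panel_seed: int = 0,
) -> SimulatedLocus:
    """Draw one locus.  Deterministic under (seed, configuration).

    ``causal_index`` defaults to the block centre; under ``linkage`` the
    disease causal SNP sits ``linkage_lag`` positions away (AR(1) LD
    ``r = rho^linkage_lag``).  A user-supplied PSD ``ld`` overrides the
    AR(1) structure.
    """
    if m_snps < 2:
        raise ValueError("m_snps must be >= 2")
    if min(n_m, n_e, n_g) < 50:
        raise ValueError("sample sizes must be >= 50")
    if ld is None and abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")

    alpha_, gamma_, c_, pi_, delta_ = _resolve_effects(
        scenario, alpha, gamma, c, pi, delta, reverse_frac
    )
    j = m_snps // 2 if causal_index is None else causal_index
    j_dis = min(j + linkage_lag, m_snps - 1) if scenario == "linkage" else j

    variant_ids = [f"rs{100000 + i}" for i in range(m_snps)]
    if ld is None:
        ld = LdMatrix.ar1(variant_ids, rho)
    elif ld.variant_ids != variant_ids:
        ld = LdMatrix(variant_ids, ld.r)
    R = ld.r

    e_j = np.zeros(m_snps)
    e_j[j] = 1.0
    e_dis = np.zeros(m_snps)
    e_dis[j_dis] = 1.0

    b_m = alpha_ * e_j
    b_e = gamma_ * b_m + delta_ * e_j
    b_g = c_ * b_e + pi_ * e_dis
    if scenario == "reverse":
        # the disease signal echoes into expression, attenuated
        b_e = reverse_frac * b_g

    ss = np.random.SeedSequence(seed)
    child_m, child_e, child_g = ss.spawn(3)
    # panel metadata (alleles, frequencies) belongs to the reference panel,
    # not the sampling noise: replicate draws share it
    rng_panel = np.random.default_rng(np.random.SeedSequence([panel_seed, 9201]))
    eaf = rng_panel.uniform(0.05, 0.5, size=m_snps)
    allele_idx = rng_panel.integers(0, len(_NONPALINDROMIC), size=m_snps)
    pos = 1_000_000 + 1_000 * np.arange(m_snps)

    chol = np.linalg.cholesky(R + 1e-12 * np.eye(m_snps))
    layers = {}
    for name, b, n, child in (
        ("mqtl", b_m, n_m, child_m),
        ("eqtl", b_e, n_e, child_e),
        ("gwas", b_g, n_g, child_g),
    ):
        rng = np.random.default_rng(child)
        z = np.sqrt(n) * (R @ b) + chol @ rng.standard_normal(m_snps)
        beta = z / np.sqrt(n)
        se = np.full(m_snps, 1.0 / np.sqrt(n))
        layers[name] = pd.DataFrame(
            {
                "snp": variant_ids,
                "chrom": "1",
                "pos": pos,
                "a1": [_NONPALINDROMIC[i][0] for i in allele_idx],
                "a2": [_NONPALINDROMIC[i][1] for i in allele_idx],
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "p": wald_p(beta, se),
                "n": float(n),
            }
        )

    truth = LocusTruth(
        scenario=scenario,
        m_snps=m_snps,
        causal_indices={
            "methylation": (j,) if alpha_ != 0 else (),
            "expression": (j,) if (gamma_ * alpha_ != 0 or delta_ != 0 or scenario == "reverse") else (),
            "disease": tuple(
                sorted({idx for idx, active in ((j, c_ * (gamma_ * alpha_ + delta_) != 0), (j_dis, pi_ != 0)) if active})
            ),
        },
        alpha=alpha_,
        gamma=gamma_,
        c=c_,
        pi=pi_,
        delta=delta_,
        rho=rho,
        n_m=n_m,
        n_e=n_e,
        n_g=n_g,
        seed=seed,
    )
    annotation = Annotation(
        pd.DataFrame(
            {
                "feature_id": [GENE_ID, PROBE_ID],
                "chrom": ["1", "1"],
                "tss": [int(pos[j]), int(pos[j]) - 5_000],
                "kind": ["gene", "probe"],
            }
        )
    )
    return SimulatedLocus(
        mqtl=Dataset("sim_mqtl", "methylation", layers["mqtl"]),
        eqtl=Dataset("sim_eqtl", "expression", layers["eqtl"]),
        gwas=Dataset("sim_gwas", "disease", layers["gwas"]),
        ld=ld,
        annotation=annotation,
        truth=truth,
    )


def evaluate_recovery(batch: Sequence[SimulatedLocus], results: Sequence) -> pd.DataFrame:
    """Recovery/calibration metrics per scenario.

    ``results[i]`` is the chain list (or a fitted three-step results
    object exposing ``.chains``) produced on ``batch[i]``.  Reported per
    scenario: detection rate (truth pair among candidates), false-
    candidate rate (any non-truth candidate, or any candidate under
    null), median relative bias of the step-1 (c) and step-3 (gamma)
    ratio estimates, HEIDI rejection rate at 0.05, and median coloc
    PP.H4 / PP.H3.
    """
    if len(batch) != len(results):
        raise ValueError("batch and results must have matching lengths")
    rows = []
    for locus, res in zip(batch, results):
        chains = getattr(res, "chains", res)
        truth = locus.truth
        cand = [ch for ch in chains if all(ch.gates.values())]
        truth_detected = any(
            ch.gene_id == GENE_ID and ch.probe_id == PROBE_ID for ch in cand
        )
        false_cand = any(
            not (ch.gene_id == GENE_ID and ch.probe_id == PROBE_ID) for ch in cand
        )
        c_hat = gamma_hat = np.nan
        heidi_reject = np.nan
        pph4 = pph3 = np.nan
        if chains:
            ch = next(
                (x for x in chains if x.gene_id == GENE_ID and x.probe_id == PROBE_ID),
                chains[0],
            )
            c_hat = ch.step1.b_smr
            gamma_hat = ch.step3.b_smr
            heidi_ps = [
                p for p in (ch.step1.p_heidi, ch.step2.p_heidi, ch.step3.p_heidi)
                if p is not None and np.isfinite(p)
            ]
            heidi_reject = float(any(p <= 0.05 for p in heidi_ps)) if heidi_ps else np.nan
            if ch.coloc is not None:
                pph4 = ch.coloc.pp["H4"]
                pph3 = ch.coloc.pp["H3"]
        rows.append(
            {
                "scenario": truth.scenario,
                "detected": float(truth_detected),
                "false_candidate": float(false_cand),
                "c_rel_bias": (c_hat - truth.c) / truth.c if truth.c else np.nan,
                "gamma_rel_bias": (gamma_hat - truth.gamma) / truth.gamma
                if truth.gamma
                else np.nan,
                "heidi_reject": heidi_reject,
                "pph4": pph4,
                "pph3": pph3,
            }
        )
    per = pd.DataFrame(rows)
    out = per.groupby("scenario").agg(
        n_loci=("detected", "size"),
        detection_rate=("detected", "mean"),
        false_candidate_rate=("false_candidate", "mean"),
        c_median_rel_bias=("c_rel_bias", "median"),
        gamma_median_rel_bias=("gamma_rel_bias", "median"),
        heidi_rejection_rate=("heidi_reject", "mean"),
        pph4_median=("pph4", "median"),
        pph3_median=("pph3", "median"),
    )
    return out.reset_index()


def write_locus(locus: SimulatedLocus, out_dir: str | Path) -> None:
    """Write a simulated locus as the pipeline's on-disk inputs."""
    from .sumstats import write_sumstats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sumstats(locus.mqtl, out / "mqtl.tsv")
    write_sumstats(locus.eqtl, out / "eqtl.tsv")
    write_sumstats(locus.gwas, out / "gwas.tsv")
    locus.ld.to_tsv(out / "ld.tsv")
    locus.annotation.df.to_csv(out / "annotation.tsv", sep="\t", index=False)
    t = locus.truth
    with open(out / "truth.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for key in ("scenario", "m_snps", "alpha", "gamma", "c", "pi", "delta",
                    "rho", "n_m", "n_e", "n_g", "seed"):
            fh.write(f"{key}\t{getattr(t, key)}\n")
        for layer, idx in t.causal_indices.items():
            fh.write(f"causal_{layer}\t{','.join(map(str, idx)) or '-'}\n")
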