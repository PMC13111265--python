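"""Gene-level two-sample Mendelian randomization from summary statistics.

Cis-instrument selection (significance + LD pruning), Wald-ratio / IVW
estimation on the disease outcome, Steiger directionality filtering, and
instrument-strength (F-statistic) reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .sumstats import Annotation, Dataset, bh_fdr, harmonize_datasets, wald_p

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids a cycle
    from .smr import LdMatrix

__all__ = [
    "Instrument",
    "MrResult",
    "variance_explained",
    "f_statistic",
    "select_instruments",
    "ivw_mr",
    "steiger_filter",
    "TwoSampleMR",
    "MRResults",
]


@dataclass(frozen=True)
class Instrument:
    """One harmonised instrument: exposure and outcome marginal effects."""

    variant_id: str
    beta_exp: float
    se_exp: float
    p_exp: float
    beta_out: float = np.nan
    se_out: float = np.nan
    p_out: float = np.nan
    n_exp: float | None = None
    n_out: float | None = None
    r2_exp: float | None = None
    r2_out: float | None = None
    f_stat: float | None = None


@dataclass(frozen=True)
class MrResult:
    """Per-feature MR estimate on the log-odds scale, with OR translation."""

    feature_id: str
    method: str  # "wald_ratio" or "ivw"
    beta: float
    se: float
    p: float
    n_instruments: int
    steiger_pass: bool
    q: float = np.nan

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - 1.96 * self.se)),
            float(np.exp(self.beta + 1.96 * self.se)),
        )


def variance_explained(z: float, n: float) -> float:
    """Approximate variance explained by one variant: ``z^2/(z^2+n-2)``."""
    return z * z / (z * z + n - 2.0)


def f_statistic(r2: float, n: float) -> float:
    """Single-instrument F-statistic ``(n-2) r^2 / (1-r^2)``."""
    return (n - 2.0) * r2 / (1.0 - r2)


def steiger_filter(inst: Instrument) -> bool:
    """Directionality check: instrument explains more variance in the
    exposure than in the outcome.  Equality fails (conservative); missing
    sample sizes make the check untestable, treated as fail."""
    if inst.n_exp is None or inst.n_out is None:
        return False
    r2_exp = (
        inst.r2_exp
        if inst.r2_exp is not None
        else variance_explained(inst.beta_exp / inst.se_exp, inst.n_exp)
    )
    r2_out = (
        inst.r2_out
        if inst.r2_out is not None
        else variance_explained(inst.beta_out / inst.se_out, inst.n_out)
    )
    return r2_exp > r2_out


def select_instruments(
    exposure: Dataset,
    annotation: Annotation,
    ld: "LdMatrix | None",
    *,
    features: Sequence[str] | None = None,
    cis_window: int = 1_000_000,
    instr_p: float = 1e-5,
    instr_fdr: float = 0.05,
    prune_r2: float = 0.1,
    fallback_window: int = 250_000,
) -> dict[str, list[Instrument]]:
    """Select independent cis instruments per feature.

    Candidates lie within ``cis_window`` of the feature TSS, pass BH-FDR
    (computed once across the exposure dataset) below ``instr_fdr`` and
    ``p < instr_p``, and are greedily LD-pruned strongest-p-first at
    ``r^2 < prune_r2``.  Without an LD panel, pruning falls back to
    distance (drop candidates within ``fallback_window`` bp of a kept
    instrument).  Features absent from the annotation are skipped.
    """
    feats = list(features) if features is not None else annotation.features()
    df = exposure.df.copy()
    df["q_exp"] = bh_fdr(df["p"].to_numpy())
    out: dict[str, list[Instrument]] = {}
    for feat in feats:
        try:
            chrom, tss = annotation.locate(feat)
        except KeyError:
            continue
        cis = df[
            (df["chrom"].astype(str) == chrom)
            & (np.abs(df["pos"] - tss) <= cis_window)
            & (df["q_exp"] < instr_fdr)
            & (df["p"] < instr_p)
        ].sort_values("p", kind="mergesort")
        kept: list[pd.Series] = []
        for _, row in cis.iterrows():
            independent = True
            for k in kept:
                if ld is not None and row["snp"] in ld and k["snp"] in ld:
                    if ld.r2(row["snp"], k["snp"]) >= prune_r2:
                        independent = False
                        break
                elif abs(row["pos"] - k["pos"]) <= fallback_window:
                    independent = False
                    break
            if independent:
                kept.append(row)
        insts = []
        for row in kept:
            n = float(row["n"]) if pd.notna(row["n"]) else None
            z = row["beta"] / row["se"]
            r2 = variance_explained(z, n) if n else None
            insts.append(
                Instrument(
                    variant_id=str(row["snp"]),
                    beta_exp=float(row["beta"]),
                    se_exp=float(row["se"]),
                    p_exp=float(row["p"]),
                    n_exp=n,
                    r2_exp=r2,
                    f_stat=f_statistic(r2, n) if r2 is not None else None,
                )
            )
        out[feat] = insts
    return out


def ivw_mr(instruments: Sequence[Instrument], feature_id: str = "") -> MrResult:
    """Wald-ratio (single instrument) or fixed-effect IVW MR estimate.

    A single instrument gives the ratio ``beta_out/beta_exp`` with the
    first-order delta-method SE
    ``sqrt(se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4)``;
    two or more give a fixed-effect IVW of per-instrument ratios with
    weights ``beta_exp^2 / se_out^2``.  Instruments with zero exposure
    effect are dropped.
    """
    usable = [i for i in instruments if i.beta_exp != 0]
    if not usable:
        raise ValueError("no usable instruments")
    if len(usable) == 1:
        inst = usable[0]
        b = inst.beta_out / inst.beta_exp
        se = np.sqrt(
            inst.se_out**2 / inst.beta_exp**2
            + inst.beta_out**2 * inst.se_exp**2 / inst.beta_exp**4
        )
        method = "wald_ratio"
    else:
        ratios = np.array([i.beta_out / i.beta_exp for i in usable])
        w = np.array([i.beta_exp**2 / i.se_out**2 for i in usable])
        b = float(np.sum(w * ratios) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        method = "ivw"
    return MrResult(
        feature_id=feature_id,
        method=method,
        beta=float(b),
        se=float(se),
        p=float(wald_p(b, se)),
        n_instruments=len(usable),
        steiger_pass=all(steiger_filter(i) for i in usable),
    )


class TwoSampleMR:
    """Two-sample MR of a molecular exposure on a disease outcome.

    Selects independent cis instruments per feature, harmonises outcome
    effects to the exposure orientation, applies Steiger directionality
    filtering, and estimates per-feature causal effects by Wald ratio /
    IVW; ``fit()`` returns an :class:`MRResults` with BH q-values across
    features.
    """

    def __init__(
        self,
        exposure: Dataset,
        outcome: Dataset,
        annotation: Annotation,
        ld: "LdMatrix | None" = None,
        *,
        features: Sequence[str] | None = None,
        cis_window: int = 1_000_000,
        instr_p: float = 1e-5,
        instr_fdr: float = 0.05,
        prune_r2: float = 0.1,
        drop_steiger_failures: bool = True,
        palindromic_eaf_band: float = 0.08,
    ):
        self.exposure = exposure
        self.outcome = outcome
        self.annotation = annotation
        self.ld = ld
        self.features = features
        self.cis_window = cis_window
        self.instr_p = instr_p
        self.instr_fdr = instr_fdr
        self.prune_r2 = prune_r2
        self.drop_steiger_failures = drop_steiger_failures
        self.palindromic_eaf_band = palindromic_eaf_band

    def fit(self) -> "MRResults":
        selected = select_instruments(
            self.exposure,
            self.annotation,
            self.ld,
            features=self.features,
            cis_window=self.cis_window,
            instr_p=self.instr_p,
            instr_fdr=self.instr_fdr,
            prune_r2=self.prune_r2,
        )
        merged, _ = harmonize_datasets(
            self.exposure, self.outcome, self.palindromic_eaf_band
        )
        out_by_snp = merged.set_index("snp")
        results: list[MrResult] = []
        instruments: dict[str, list[Instrument]] = {}
        for feat, insts in selected.items():
            filled = []
            for inst in insts:
                if inst.variant_id not in out_by_snp.index:
                    continue
                row = out_by_snp.loc[inst.variant_id]
                n_out = float(row["n_out"]) if pd.notna(row["n_out"]) else None
                inst = replace(
                    inst,
                    beta_out=float(row["beta_out"]),
                    se_out=float(row["se_out"]),
                    p_out=float(row["p_out"]),
                    n_out=n_out,
                    r2_out=(
                        variance_explained(row["beta_out"] / row["se_out"], n_out)
                        if n_out
                        else None
                    ),
                )
                filled.append(inst)
            steiger_ok = [i for i in filled if steiger_filter(i)]
            used = steiger_ok if self.drop_steiger_failures else filled
            instruments[feat] = filled
            if not used:
                continue
            res = ivw_mr(used, feature_id=feat)
            res = replace(res, steiger_pass=len(steiger_ok) == len(filled))
            results.append(res)
        return MRResults(self, results, instruments)


class MRResults:
    """Per-feature MR estimates with FDR, OR scale, and instrument metadata."""

    def __init__(
        self,
        model: TwoSampleMR,
        results: list[MrResult],
        instruments: dict[str, list[Instrument]],
    ):
        if results:
            q = bh_fdr([r.p for r in results])
            results = [replace(r, q=qi) for r, qi in zip(results, q)]
        self.model = model
        self.results = results
        self.instruments = instruments

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            lo, hi = r.or_ci95
            f_stats = [
                i.f_stat for i in self.instruments.get(r.feature_id, []) if i.f_stat
            ]
            rows.append(
                {
                    "feature_id": r.feature_id,
                    "method": r.method,
                    "n_instruments": r.n_instruments,
                    "beta": r.beta,
                    "se": r.se,
                    "p": r.p,
                    "q": r.q,
                    "or": r.or_point,
                    "or_l95": lo,
                    "or_u95": hi,
                    "steiger_pass": r.steiger_pass,
                    "mean_f": float(np.mean(f_stats)) if f_stats else np.nan,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "feature_id", "method", "n_instruments", "beta", "se", "p",
                "q", "or", "or_l95", "or_u95", "steiger_pass", "mean_f",
            ],
        )

    def summary(self) -> str:
        t = self.table
        lines = [
            "Two-sample Mendelian randomization",
            f"  exposure: {self.model.exposure.label} -> outcome: {self.model.outcome.label}",
            f"  features with estimates: {len(t)}",
        ]
        for _, r in t.iterrows():
            lines.append(
                f"    {r['feature_id']:>12}  {r['method']:<10} k={int(r['n_instruments'])}  "
                f"OR={r['or']:.3f} [{r['or_l95']:.3f}-{r['or_u95']:.3f}]  "
                f"q={r['q']:.3g}  steiger={'pass' if r['steiger_pass'] else 'FAIL'}"
            )
        return "\n".join(lines)
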