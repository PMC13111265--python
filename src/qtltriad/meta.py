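"""Fixed-effects inverse-variance-weighted GWAS meta-analysis.

Pools harmonised per-variant effects across input studies (METAL-style
effect/SE scheme), defines genome-wide-significant loci by greedy
distance clumping, and checks directional concordance against a
replication dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import Dataset, VariantAssociation, harmonize_pair, wald_p

__all__ = [
    "MetaResult",
    "Locus",
    "ivw_meta",
    "define_loci",
    "replication_concordance",
    "MetaAnalysis",
    "MetaResults",
]


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effects estimate for one variant."""

    pooled_beta: float
    pooled_se: float
    z: float
    p: float
    k_studies: int
    direction: str
    q_het: float
    i2: float

    variant_id: str = ""


@dataclass(frozen=True)
class Locus:
    """A clumped genome-wide-significant region around an index variant."""

    index_variant: str
    chrom: str
    pos: int
    window_start: int
    window_end: int
    member_variants: tuple[str, ...]


def ivw_meta(per_study: Sequence[tuple[float, float]], variant_id: str = "") -> MetaResult:
    """Fixed-effects IVW pooling of per-study (beta, se) for one variant.

    Weights are ``1/se^2``; ``pooled_se = (sum w)^-1/2``; heterogeneity
    is Cochran's Q with ``I^2 = max(0, (Q-(k-1))/Q)``.
    """
    if len(per_study) == 0:
        raise ValueError("ivw_meta requires at least one study")
    beta = np.array([b for b, _ in per_study], dtype=float)
    se = np.array([s for _, s in per_study], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / se**2
    pooled_beta = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    z = pooled_beta / pooled_se
    q = float(np.sum(w * (beta - pooled_beta) ** 2))
    k = len(per_study)
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    direction = "".join("+" if b > 0 else "-" if b < 0 else "?" for b in beta)
    return MetaResult(
        pooled_beta=pooled_beta,
        pooled_se=pooled_se,
        z=float(z),
        p=float(wald_p(pooled_beta, pooled_se)),
        k_studies=k,
        direction=direction,
        q_het=q,
        i2=i2,
        variant_id=variant_id,
    )


def define_loci(
    results: pd.DataFrame,
    p_sig: float = 5e-8,
    window: int = 500_000,
) -> list[Locus]:
    """Greedy distance clumping of significant variants into loci.

    Repeatedly takes the smallest-p unassigned significant variant as an
    index and absorbs all significant variants on the same chromosome
    within ``+/- window`` bp.  Ties in minimum p break by (chrom, pos).
    ``results`` needs columns ``snp, chrom, pos, p``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    sig = results[results["p"] < p_sig].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    assigned = np.zeros(len(sig), dtype=bool)
    loci: list[Locus] = []
    for i in range(len(sig)):
        if assigned[i]:
            continue
        idx = sig.iloc[i]
        near = (
            ~assigned
            & (sig["chrom"].to_numpy() == idx["chrom"])
            & (np.abs(sig["pos"].to_numpy() - int(idx["pos"])) <= window)
        )
        members = sig.loc[near]
        assigned |= near
        loci.append(
            Locus(
                index_variant=str(idx["snp"]),
                chrom=str(idx["chrom"]),
                pos=int(idx["pos"]),
                window_start=int(members["pos"].min()),
                window_end=int(members["pos"].max()),
                member_variants=tuple(members["snp"]),
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.pos))
    return loci


def replication_concordance(
    discovery: Dataset,
    replication: Dataset,
    index_variants: Sequence[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Directional-concordance check of index variants in a replication GWAS.

    Replication records are harmonised to the discovery orientation
    first; a variant is *consistent* when the harmonised signs agree
    (an exactly zero replication beta is inconsistent and flagged
    ambiguous) and *nominal* when its replication p < ``alpha``.
    """
    rows = []
    for vid in index_variants:
        try:
            disc = discovery.get(vid)
        except KeyError:
            rows.append((vid, False, np.nan, False, "absent_discovery"))
            continue
        try:
            rep = replication.get(vid)
        except KeyError:
            rows.append((vid, False, np.nan, False, "absent_replication"))
            continue
        harm, flag = harmonize_pair(disc, rep)
        if flag.startswith("drop"):
            rows.append((vid, False, np.nan, False, flag))
            continue
        if harm.beta == 0:
            rows.append((vid, False, harm.p, harm.p < alpha, "ambiguous_zero"))
            continue
        consistent = np.sign(disc.beta) == np.sign(harm.beta)
        rows.append((vid, bool(consistent), harm.p, harm.p < alpha, flag))
    table = pd.DataFrame(
        rows,
        columns=["variant_id", "direction_consistent", "p_replication", "nominal", "flag"],
    )
    tested = ~table["flag"].str.startswith(("absent", "drop"))
    summary = {
        "n_total": int(len(table)),
        "n_tested": int(tested.sum()),
        "n_consistent": int(table.loc[tested, "direction_consistent"].sum()),
        "n_nominal": int(table.loc[tested, "nominal"].sum()),
    }
    return table, summary


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class MetaAnalysis:
    """Fixed-effects IVW meta-analysis across GWAS datasets.

    Variants are matched by id and harmonised to the orientation of the
    first study in which they appear; variants present in a single study
    pass through with k = 1.

    Parameters
    ----------
    studies
        Disease GWAS datasets sharing (a subset of) a variant panel.
    palindromic_eaf_band
        Frequency band around 0.5 inside which palindromic variants are
        dropped during harmonisation.
    """

    def __init__(self, studies: Sequence[Dataset], palindromic_eaf_band: float = 0.08):
        if not studies:
            raise ValueError("MetaAnalysis requires at least one study")
        self.studies = list(studies)
        self.palindromic_eaf_band = palindromic_eaf_band

    def fit(self) -> "MetaResults":
        # reference orientation: first study carrying the variant
        panels: dict[str, list[tuple[int, VariantAssociation]]] = {}
        for si, ds in enumerate(self.studies):
            for rec in ds.records():
                panels.setdefault(rec.variant_id, []).append((si, rec))
        rows = []
        for vid, entries in panels.items():
            _, ref = entries[0]
            per_study: list[tuple[float, float]] = []
            ns, eafs = [], []
            for _, rec in entries:
                harm, flag = harmonize_pair(ref, rec, self.palindromic_eaf_band)
                if flag.startswith("drop"):
                    continue
                per_study.append((harm.beta, harm.se))
                if harm.n is not None:
                    ns.append(harm.n)
                if harm.eaf is not None:
                    eafs.append((harm.eaf, harm.n or 1.0))
            if not per_study:
                continue
            res = ivw_meta(per_study, variant_id=vid)
            eaf = (
                sum(e * w for e, w in eafs) / sum(w for _, w in eafs) if eafs else np.nan
            )
            rows.append(
                {
                    "snp": vid,
                    "chrom": ref.chrom,
                    "pos": ref.pos,
                    "a1": ref.effect_allele,
                    "a2": ref.other_allele,
                    "eaf": eaf,
                    "beta": res.pooled_beta,
                    "se": res.pooled_se,
                    "z": res.z,
                    "p": res.p,
                    "n": sum(ns) if ns else np.nan,
                    "k_studies": res.k_studies,
                    "direction": res.direction,
                    "q_het": res.q_het,
                    "i2": res.i2,
                }
            )
        table = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
        return MetaResults(self, table)


class MetaResults:
    """Pooled per-variant table plus locus utilities."""

    def __init__(self, model: MetaAnalysis, table: pd.DataFrame):
        self.model = model
        self.table = table

    def define_loci(self, p_sig: float = 5e-8, window: int = 500_000) -> list[Locus]:
        return define_loci(self.table, p_sig=p_sig, window=window)

    def to_dataset(self, label: str = "meta") -> Dataset:
        df = self.table[
            ["snp", "chrom", "pos", "a1", "a2", "eaf", "beta", "se", "p", "n"]
        ].copy()
        return Dataset(label=label, trait_kind="disease", df=df)

    def summary(self, p_sig: float = 5e-8, window: int = 500_000) -> str:
        loci = self.define_loci(p_sig, window)
        lines = [
            "Fixed-effects IVW meta-analysis",
            f"  studies: {len(self.model.studies)}   variants pooled: {len(self.table)}",
            f"  genome-wide significant (p < {p_sig:g}): "
            f"{int((self.table['p'] < p_sig).sum())} variants in {len(loci)} loci",
        ]
        for loc in loci:
            row = self.table[self.table["snp"] == loc.index_variant].iloc[0]
            lines.append(
                f"    {loc.index_variant}  chr{loc.chrom}:{loc.pos}  "
                f"beta={row['beta']:+.4f}  se={row['se']:.4f}  p={row['p']:.3g}  "
                f"members={len(loc.member_variants)}"
            )
        return "\n".join(lines)
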