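"""Per-variant association summary statistics.

Containers, I/O, allele harmonisation, MAF filtering, and the p-value /
FDR utilities shared by every downstream stage.  All coordinates are
1-based inclusive; chromosome labels are normalised by stripping any
``chr`` prefix.  The on-disk format is tab- or whitespace-delimited text
with a header row in the GCTA-COJO ``.ma`` style (``SNP A1 A2 freq b se
p N``) plus ``CHR``/``POS``; other headers are mapped via a *dialect*
dictionary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "VariantAssociation",
    "Dataset",
    "Annotation",
    "read_sumstats",
    "write_sumstats",
    "read_annotation",
    "harmonize_pair",
    "harmonize_datasets",
    "filter_by_maf",
    "wald_p",
    "log_wald_p",
    "bh_fdr",
]

#: canonical in-memory column order for summary-statistic frames
CANONICAL_COLUMNS = ("snp", "chrom", "pos", "a1", "a2", "eaf", "beta", "se", "p", "n")

#: default on-disk header (GCTA-COJO .ma style plus coordinates)
DEFAULT_DIALECT: dict[str, str] = {
    "SNP": "snp",
    "CHR": "chrom",
    "POS": "pos",
    "A1": "a1",
    "A2": "a2",
    "freq": "eaf",
    "b": "beta",
    "se": "se",
    "p": "p",
    "N": "n",
}

_REQUIRED = ("snp", "a1", "a2", "beta", "se", "p")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: relative tolerance on P for the beta/se/p internal-concordance check,
#: reflecting inputs rounded to 4-5 significant figures
P_CONCORDANCE_RTOL = 0.05


# ---------------------------------------------------------------------------
# p-value / FDR utilities
# ---------------------------------------------------------------------------

def log_wald_p(beta, se):
    """Natural log of the two-sided Wald p-value, accurate far into the tail.

    ``log p = log 2 + log Phi(-|beta/se|)`` evaluated with
    :func:`scipy.special.log_ndtr`, so the result is finite for |z| of
    several hundred where the linear-scale p underflows.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise ValueError("se must be finite and > 0")
    z = np.abs(beta / se)
    return np.log(2.0) + special.log_ndtr(-z)


def wald_p(beta, se):
    """Two-sided Wald p-value ``2*Phi(-|beta/se|)``.

    Evaluated on the log scale and exponentiated, so there is no
    catastrophic loss of accuracy in the deep tail; results below the
    smallest positive double are floored there to keep p in (0, 1].
    """
    p = np.exp(log_wald_p(beta, se))
    tiny = np.nextafter(0.0, 1.0)
    return np.maximum(p, tiny) if np.ndim(p) else max(float(p), tiny)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q(i) = min_{j: rank(j) >= rank(i)} m * p(j) / rank(j)``, capped at 1.
    """
    p = np.atleast_1d(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("bh_fdr requires a non-empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association in one dataset."""

    variant_id: str
    chrom: str = ""
    pos: int = 0
    effect_allele: str = ""
    other_allele: str = ""
    eaf: float | None = None
    beta: float = 0.0
    se: float = 1.0
    p: float = 1.0
    n: float | None = None

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if self.eaf is not None and not np.isnan(self.eaf):
            if not 0.0 <= self.eaf <= 1.0:
                raise ValueError(f"{self.variant_id}: eaf outside [0, 1]")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class Dataset:
    """A labelled collection of per-variant associations for one trait.

    ``df`` holds one row per variant in canonical column order
    (:data:`CANONICAL_COLUMNS`); ``variant_id`` is unique within a
    dataset.  ``trait_kind`` is one of ``disease``, ``expression``,
    ``methylation``.
    """

    label: str
    trait_kind: str
    df: pd.DataFrame
    n_cases: int | None = None
    n_controls: int | None = None
    qc_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "action"])
    )

    def __post_init__(self):
        if self.trait_kind not in {"disease", "expression", "methylation"}:
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        if self.df["snp"].duplicated().any():
            dups = self.df.loc[self.df["snp"].duplicated(), "snp"].head().tolist()
            raise ValueError(f"duplicate variant ids in {self.label}: {dups}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def variant_ids(self) -> list[str]:
        return self.df["snp"].tolist()

    def get(self, variant_id: str) -> VariantAssociation:
        sub = self.df[self.df["snp"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        return _row_to_record(sub.iloc[0])

    def records(self) -> Iterator[VariantAssociation]:
        for _, row in self.df.iterrows():
            yield _row_to_record(row)

    def subset(self, variant_ids: Iterable[str]) -> "Dataset":
        ids = set(variant_ids)
        return dataclasses.replace(
            self, df=self.df[self.df["snp"].isin(ids)].reset_index(drop=True)
        )


@dataclass
class Annotation:
    """Feature (gene or CpG probe) positions: id, chromosome, TSS, optional end.

    An optional ``kind`` column ("gene"/"probe") disambiguates feature
    classes where both live in one table.
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = {"feature_id", "chrom", "tss"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.df["feature_id"].duplicated().any():
            raise ValueError("feature_id must be unique in annotation")
        if (self.df["tss"] < 1).any():
            raise ValueError("tss must be >= 1 (1-based coordinates)")
        self.df = self.df.reset_index(drop=True)
        self.df["chrom"] = self.df["chrom"].astype(str).str.replace(
            "^chr", "", regex=True
        )

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in set(self.df["feature_id"])

    def locate(self, feature_id: str) -> tuple[str, int]:
        sub = self.df[self.df["feature_id"] == feature_id]
        if sub.empty:
            raise KeyError(feature_id)
        row = sub.iloc[0]
        return str(row["chrom"]), int(row["tss"])

    def features(self, kind: str | None = None) -> list[str]:
        if kind is None or "kind" not in self.df.columns:
            return self.df["feature_id"].tolist()
        return self.df.loc[self.df["kind"] == kind, "feature_id"].tolist()


def _row_to_record(row: pd.Series) -> VariantAssociation:
    eaf = row.get("eaf")
    return VariantAssociation(
        variant_id=str(row["snp"]),
        chrom=str(row.get("chrom", "")),
        pos=int(row["pos"]) if pd.notna(row.get("pos")) else 0,
        effect_allele=str(row["a1"]),
        other_allele=str(row["a2"]),
        eaf=float(eaf) if pd.notna(eaf) else None,
        beta=float(row["beta"]),
        se=float(row["se"]),
        p=float(row["p"]),
        n=float(row["n"]) if pd.notna(row.get("n")) else None,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    label: str | None = None,
    trait_kind: str = "disease",
) -> Dataset:
    """Read a tab/whitespace-delimited summary-statistics file.

    ``dialect`` maps file column names to canonical names (defaults to
    the COJO ``.ma`` header).  Rows failing type checks (unparsable or
    non-positive ``se``, p outside (0,1], unparsable beta) are dropped
    and counted in the returned dataset's ``qc_log``.  Rows whose printed
    P disagrees with ``2*Phi(-|beta/se|)`` by more than 5% relative are
    kept with P recomputed and the printed value stored as
    ``p_reported`` (action ``p_recomputed`` in the QC log).

    Raises a hard error when a required column is missing or the file is
    empty.
    """
    path = Path(path)
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    try:
        raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty summary-statistics file") from None
    if raw.empty:
        raise ValueError(f"{path}: no data rows")
    raw = raw.rename(columns=dialect)
    for col in _REQUIRED:
        if col not in raw.columns:
            raise ValueError(f"{path}: required column {col!r} not resolvable")
    for col in CANONICAL_COLUMNS:
        if col not in raw.columns:
            raw[col] = np.nan

    df = pd.DataFrame({"snp": raw["snp"].astype(str)})
    df["chrom"] = raw["chrom"].astype(str).str.replace("^chr", "", regex=True)
    df["pos"] = pd.to_numeric(raw["pos"], errors="coerce")
    df["a1"] = raw["a1"].astype(str).str.upper()
    df["a2"] = raw["a2"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "p", "n"):
        df[col] = pd.to_numeric(raw[col], errors="coerce")

    qc: list[tuple[str, str]] = []
    bad = (
        df["beta"].isna()
        | df["se"].isna()
        | (df["se"] <= 0)
        | df["p"].isna()
        | (df["p"] <= 0)
        | (df["p"] > 1)
        | ~df["a1"].str.fullmatch(r"[ACGT]+|[ID]")
        | ~df["a2"].str.fullmatch(r"[ACGT]+|[ID]")
    )
    for vid in df.loc[bad, "snp"]:
        qc.append((vid, "dropped_invalid"))
    df = df[~bad].reset_index(drop=True)

    bad_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    df.loc[bad_eaf, "eaf"] = np.nan
    for vid in df.loc[bad_eaf, "snp"]:
        qc.append((vid, "eaf_cleared"))

    # internal beta/se/p concordance; discordant rows are repaired
    p_calc = wald_p(df["beta"].to_numpy(), df["se"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(df["p"].to_numpy() / p_calc - 1.0)
    discordant = rel > P_CONCORDANCE_RTOL
    df["p_reported"] = np.nan
    if discordant.any():
        df.loc[discordant, "p_reported"] = df.loc[discordant, "p"]
        df.loc[discordant, "p"] = p_calc[discordant]
        for vid in df.loc[discordant, "snp"]:
            qc.append((vid, "p_recomputed"))

    if df["snp"].duplicated().any():
        dup = df["snp"].duplicated(keep="first")
        for vid in df.loc[dup, "snp"]:
            qc.append((vid, "dropped_duplicate"))
        df = df[~dup].reset_index(drop=True)

    return Dataset(
        label=label or path.stem,
        trait_kind=trait_kind,
        df=df,
        qc_log=pd.DataFrame(qc, columns=["variant_id", "action"]),
    )


def write_sumstats(ds: Dataset, path: str | Path) -> None:
    """Write a dataset back in the default on-disk header."""
    inv = {v: k for k, v in DEFAULT_DIALECT.items()}
    out = ds.df[list(CANONICAL_COLUMNS)].rename(columns=inv)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_annotation(path: str | Path) -> Annotation:
    """Read a feature annotation table (feature_id, chrom, tss[, end, kind])."""
    df = pd.read_csv(path, sep=r"\s+")
    return Annotation(df)


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _flip(rec: VariantAssociation) -> VariantAssociation:
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def harmonize_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindromic_eaf_band: float = 0.08,
) -> tuple[VariantAssociation, str]:
    """Orient an outcome record to the exposure's effect allele.

    Returns the (possibly modified) outcome record and an action flag:
    ``same``, ``flip`` (alleles swapped: beta sign flipped, eaf
    complemented), ``strand`` (strand complement resolved the pair, with
    a flip applied when also swapped), ``drop_palindromic`` (A/T or C/G
    variant whose allele frequency is within ``palindromic_eaf_band`` of
    0.5, or missing), or ``drop_mismatch`` (irreconcilable alleles).
    Dropped records are returned unchanged.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError("harmonize_pair requires matching variant ids")
    e1, e2 = exposure.effect_allele.upper(), exposure.other_allele.upper()
    o1, o2 = outcome.effect_allele.upper(), outcome.other_allele.upper()
    if not (e1 and e2 and o1 and o2):
        raise ValueError("alleles must be non-missing")

    if _is_palindromic(e1, e2):
        if not _is_palindromic(o1, o2) or {o1, o2} != {e1, e2}:
            return outcome, "drop_mismatch"
        for eaf in (exposure.eaf, outcome.eaf):
            if eaf is None or np.isnan(eaf) or abs(eaf - 0.5) <= palindromic_eaf_band:
                return outcome, "drop_palindromic"
        # letters orient first; a side-of-0.5 frequency disagreement then
        # implies the strands differ, which for palindromes is a flip
        flipped = o1 == e2
        cand = _flip(outcome) if flipped else outcome
        if (cand.eaf - 0.5) * (exposure.eaf - 0.5) < 0:
            # strands differ: complementing a palindrome swaps its letters,
            # so the correct orientation is the opposite of the letter match
            cand = outcome if flipped else _flip(outcome)
            return cand, "strand"
        return cand, ("flip" if flipped else "same")

    if (o1, o2) == (e1, e2):
        return outcome, "same"
    if (o1, o2) == (e2, e1):
        return _flip(outcome), "flip"
    c1, c2 = _COMPLEMENT.get(o1), _COMPLEMENT.get(o2)
    if (c1, c2) == (e1, e2):
        return replace(outcome, effect_allele=e1, other_allele=e2), "strand"
    if (c1, c2) == (e2, e1):
        flipped = _flip(outcome)
        return replace(flipped, effect_allele=e1, other_allele=e2), "strand"
    return outcome, "drop_mismatch"


def harmonize_datasets(
    exposure: Dataset,
    outcome: Dataset,
    palindromic_eaf_band: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonise all shared variants of two datasets to the exposure orientation.

    Returns ``(merged, actions)`` where ``merged`` has exposure columns
    suffixed ``_exp`` and harmonised outcome columns suffixed ``_out``
    (dropped variants removed) and ``actions`` logs one flag per shared
    variant.
    """
    merged = exposure.df.merge(
        outcome.df, on="snp", suffixes=("_exp", "_out"), how="inner"
    )
    keep_rows = []
    actions = []
    for _, row in merged.iterrows():
        exp = VariantAssociation(
            variant_id=row["snp"],
            effect_allele=row["a1_exp"],
            other_allele=row["a2_exp"],
            eaf=None if pd.isna(row["eaf_exp"]) else float(row["eaf_exp"]),
            beta=float(row["beta_exp"]),
            se=float(row["se_exp"]),
            p=float(row["p_exp"]),
        )
        out = VariantAssociation(
            variant_id=row["snp"],
            effect_allele=row["a1_out"],
            other_allele=row["a2_out"],
            eaf=None if pd.isna(row["eaf_out"]) else float(row["eaf_out"]),
            beta=float(row["beta_out"]),
            se=float(row["se_out"]),
            p=float(row["p_out"]),
        )
        harm, flag = harmonize_pair(exp, out, palindromic_eaf_band)
        actions.append((row["snp"], flag))
        if flag.startswith("drop"):
            continue
        row = row.copy()
        row["beta_out"] = harm.beta
        row["eaf_out"] = np.nan if harm.eaf is None else harm.eaf
        row["a1_out"], row["a2_out"] = harm.effect_allele, harm.other_allele
        keep_rows.append(row)
    out_df = pd.DataFrame(keep_rows).reset_index(drop=True) if keep_rows else merged.iloc[0:0]
    return out_df, pd.DataFrame(actions, columns=["variant_id", "action"])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_by_maf(ds: Dataset, maf_min: float = 0.005) -> Dataset:
    """Drop variants with minor-allele frequency below ``maf_min``.

    MAF is folded: ``min(eaf, 1-eaf)``.  Records with missing EAF are
    retained and flagged ``maf_unknown`` in the QC log.  Idempotent; the
    output is always a subset of the input.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    eaf = ds.df["eaf"]
    maf = np.minimum(eaf, 1.0 - eaf)
    keep = eaf.isna() | (maf >= maf_min)
    qc_new = [(vid, "dropped_maf") for vid in ds.df.loc[~keep, "snp"]]
    qc_new += [(vid, "maf_unknown") for vid in ds.df.loc[eaf.isna(), "snp"]]
    qc = pd.concat(
        [ds.qc_log, pd.DataFrame(qc_new, columns=["variant_id", "action"])],
        ignore_index=True,
    )
    return dataclasses.replace(
        ds, df=ds.df[keep].reset_index(drop=True), qc_log=qc
    )
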