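"""Three-step SMR orchestration with gating, colocalization and sign chains.

Step 1 tests expression -> disease for each gene in the supplied gene
filter; step 2 tests methylation -> disease for each CpG probe; step 3
tests methylation -> expression, run only for (probe, gene) pairs that
were significant in steps 1 and 2 and lie within each other's cis
window.  A pair becomes a *candidate causal chain* when it passes:

1. BH-FDR < 0.05 within each of the three steps;
2. instrument significance p < 1e-5 in the eQTL, mQTL and GWAS data;
3. every computable HEIDI p > 0.05 (no evidence of linkage);
4. (optional) colocalization PP.H4 > 0.5 between eQTL and GWAS.

The sign chain interprets a candidate: the methylation -> disease
direction must equal the product of the methylation -> expression and
expression -> disease directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coloc import ColocAnalysis, ColocResult
from .config import PipelineConfig
from .smr import LdMatrix, SmrAnalysis, SmrResults
from .sumstats import Annotation, Dataset

__all__ = ["StepResult", "CausalChain", "ThreeStepSmr", "ThreeStepResults",
           "run_three_step", "infer_sign_chain"]


@dataclass(frozen=True)
class StepResult:
    """One SMR step of a chain (a row of an :class:`SmrResults` table)."""

    feature_id: str
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    q_smr: float
    p_heidi: float | None
    n_heidi_snps: int
    p_exp_top: float
    p_out_top: float

    @property
    def or_point(self) -> float:
        return float(np.exp(self.b_smr))

    @property
    def or_ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.b_smr - 1.96 * self.se_smr)),
            float(np.exp(self.b_smr + 1.96 * self.se_smr)),
        )


@dataclass
class CausalChain:
    """A (probe, gene) pair with its three SMR steps and gate verdicts."""

    probe_id: str
    gene_id: str
    step1: StepResult  # expression -> disease
    step2: StepResult  # methylation -> disease
    step3: StepResult  # methylation -> expression
    gates: dict[str, bool]
    sign_consistent: bool
    coloc: ColocResult | None = None
    heidi_untestable: bool = False

    @property
    def coloc_pph4(self) -> float:
        return np.nan if self.coloc is None else self.coloc.pp["H4"]

    @property
    def is_candidate(self) -> bool:
        return all(self.gates.values())


def infer_sign_chain(chain: CausalChain) -> tuple[str, bool]:
    """Readable direction statement plus the sign-consistency verdict.

    Per-edge direction is the sign of ``b_smr`` (OR > 1 <=> b > 0);
    consistency requires sign(step2) = sign(step1) * sign(step3).
    """
    s1 = np.sign(chain.step1.b_smr)
    s2 = np.sign(chain.step2.b_smr)
    s3 = np.sign(chain.step3.b_smr)
    consistent = s2 == s1 * s3
    e3 = "→" if s3 > 0 else "⊣"
    e1 = "→" if s1 > 0 else "⊣"
    verdict = "risk-increasing" if s2 > 0 else "protective"
    text = (
        f"methylation {e3} expression {e1} disease "
        f"⇒ methylation {verdict}"
        + ("" if consistent else " [SIGN-INCONSISTENT]")
    )
    return text, bool(consistent)


def _step_result(row: pd.Series) -> StepResult:
    return StepResult(
        feature_id=str(row.get("feature_id", row.name)),
        top_snp=str(row["top_snp"]),
        b_smr=float(row["b_smr"]),
        se_smr=float(row["se_smr"]),
        p_smr=float(row["p_smr"]),
        q_smr=float(row["q_smr"]),
        p_heidi=None if pd.isna(row["p_heidi"]) else float(row["p_heidi"]),
        n_heidi_snps=int(row["nsnp_heidi"]),
        p_exp_top=float(row["p_exp_top"]),
        p_out_top=float(row["p_out_top"]),
    )


class ThreeStepSmr:
    """Three-step SMR of methylation, expression and disease layers.

    Parameters
    ----------
    eqtl, mqtl, gwas : Dataset
        cis-eQTL, cis-mQTL and disease GWAS summary statistics on a
        shared variant panel orientation.
    ld : LdMatrix or None
        LD panel; HEIDI is untestable without it.
    annotation : Annotation
        Gene and probe positions.  Probes are the features marked
        ``kind == "probe"`` when the column exists, otherwise every
        feature not in ``gene_filter``.
    gene_filter : sequence of str
        The gene universe entering step 1 (the role the immune-response
        differential-gene list plays in the source analysis).
    """

    def __init__(
        self,
        eqtl: Dataset,
        mqtl: Dataset,
        gwas: Dataset,
        ld: LdMatrix | None,
        annotation: Annotation,
        gene_filter: Sequence[str],
        config: PipelineConfig | None = None,
    ):
        if not list(gene_filter):
            raise ValueError("gene_filter must be non-empty")
        self.eqtl = eqtl
        self.mqtl = mqtl
        self.gwas = gwas
        self.ld = ld
        self.annotation = annotation
        self.gene_filter = list(gene_filter)
        self.config = config or PipelineConfig()

    def _smr(self, exposure: Dataset, outcome: Dataset) -> SmrAnalysis:
        cfg = self.config
        return SmrAnalysis(
            exposure,
            outcome,
            self.ld,
            self.annotation,
            cis_window=cfg.cis_window,
            instr_p=cfg.instr_p,
            heidi_kwargs=cfg.heidi_kwargs(),
            palindromic_eaf_band=cfg.palindromic_eaf_band,
        )

    def fit(self) -> "ThreeStepResults":
        cfg = self.config
        genes = [g for g in self.gene_filter if g in self.annotation]
        probe_universe = self.annotation.features("probe")
        if set(probe_universe) == set(self.annotation.features()):
            probe_universe = [f for f in probe_universe if f not in set(self.gene_filter)]

        step1 = self._smr(self.eqtl, self.gwas).fit(genes)
        step2 = self._smr(self.mqtl, self.gwas).fit(probe_universe)

        sig1 = step1.table[step1.table["q_smr"] < cfg.step_fdr]
        sig2 = step2.table[step2.table["q_smr"] < cfg.step_fdr]

        # pair each significant probe with each significant gene whose cis
        # window contains it
        pairs: list[tuple[str, str]] = []
        for gene in sig1["feature_id"]:
            g_chrom, g_tss = self.annotation.locate(gene)
            for probe in sig2["feature_id"]:
                p_chrom, p_tss = self.annotation.locate(probe)
                if p_chrom == g_chrom and abs(p_tss - g_tss) <= cfg.cis_window:
                    pairs.append((probe, gene))

        step3 = self._smr(self.mqtl, self.eqtl).fit(
            sorted({p for p, _ in pairs})
        )
        s1 = step1.table.set_index("feature_id")
        s2 = step2.table.set_index("feature_id")
        s3 = step3.table.set_index("feature_id")

        chains: list[CausalChain] = []
        coloc_cache: dict[str, ColocResult | None] = {}
        for probe, gene in pairs:
            if probe not in s3.index:
                continue
            r1, r2, r3 = s1.loc[gene], s2.loc[probe], s3.loc[probe]
            st1, st2, st3 = _step_result(r1), _step_result(r2), _step_result(r3)

            heidi_ps = [st.p_heidi for st in (st1, st2, st3)]
            computable = [p for p in heidi_ps if p is not None]
            untestable = len(computable) < 3
            heidi_pass = all(p > cfg.heidi_alpha for p in computable)
            if untestable and not cfg.keep_heidi_untestable:
                heidi_pass = False

            if gene not in coloc_cache:
                coloc_cache[gene] = self._coloc_gene(gene)
            coloc = coloc_cache[gene]

            gates = {
                "fdr_all3": bool(
                    (st1.q_smr < cfg.step_fdr)
                    and (st2.q_smr < cfg.step_fdr)
                    and (st3.q_smr < cfg.step_fdr)
                ),
                "p_all_datasets": bool(
                    (st1.p_exp_top < cfg.instr_p)
                    and (st2.p_exp_top < cfg.instr_p)
                    and (st1.p_out_top < cfg.instr_p)
                ),
                "heidi_all3": bool(heidi_pass),
            }
            if cfg.coloc_gate_enabled:
                gates["coloc"] = bool(
                    coloc is not None and coloc.pp["H4"] > cfg.pph4_gate
                )
            sign_ok = np.sign(st2.b_smr) == np.sign(st1.b_smr) * np.sign(st3.b_smr)
            chains.append(
                CausalChain(
                    probe_id=probe,
                    gene_id=gene,
                    step1=st1,
                    step2=st2,
                    step3=st3,
                    gates=gates,
                    sign_consistent=bool(sign_ok),
                    coloc=coloc,
                    heidi_untestable=untestable,
                )
            )
        return ThreeStepResults(self, chains, step1, step2, step3)

    def _coloc_gene(self, gene: str) -> ColocResult | None:
        """eQTL-vs-GWAS colocalization over the gene's cis panel."""
        cfg = self.config
        chrom, tss = self.annotation.locate(gene)
        cis_ids = self.eqtl.df.loc[
            (self.eqtl.df["chrom"].astype(str) == chrom)
            & (np.abs(self.eqtl.df["pos"] - tss) <= cfg.cis_window),
            "snp",
        ].tolist()
        if not cis_ids:
            return None
        try:
            return ColocAnalysis(
                self.eqtl,
                self.gwas,
                p1=cfg.coloc_p1,
                p2=cfg.coloc_p2,
                p12=cfg.coloc_p12,
                prior_sd1=cfg.coloc_sd_molecular,
                prior_sd2=cfg.coloc_sd_disease,
                variant_ids=cis_ids,
            ).fit()
        except ValueError:
            return None


class ThreeStepResults:
    """Chains, per-step tables and candidate extraction."""

    def __init__(
        self,
        model: ThreeStepSmr,
        chains: list[CausalChain],
        step1: SmrResults,
        step2: SmrResults,
        step3: SmrResults,
    ):
        self.model = model
        self.chains = chains
        self.step1 = step1
        self.step2 = step2
        self.step3 = step3

    @property
    def candidates(self) -> list[CausalChain]:
        return [ch for ch in self.chains if ch.is_candidate]

    def chain_table(self) -> pd.DataFrame:
        rows = []
        for ch in self.chains:
            text, _ = infer_sign_chain(ch)
            row = {
                "probe_id": ch.probe_id,
                "gene_id": ch.gene_id,
                "b_step1": ch.step1.b_smr,
                "b_step2": ch.step2.b_smr,
                "b_step3": ch.step3.b_smr,
                "q_step1": ch.step1.q_smr,
                "q_step2": ch.step2.q_smr,
                "q_step3": ch.step3.q_smr,
                "coloc_pph4": ch.coloc_pph4,
                "sign_consistent": ch.sign_consistent,
                "sign_chain": text,
                "is_candidate": ch.is_candidate,
                "heidi_untestable": ch.heidi_untestable,
            }
            row.update({f"gate_{k}": v for k, v in ch.gates.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Three-step SMR",
            f"  step 1 (expression→disease): {len(self.step1.table)} genes tested",
            f"  step 2 (methylation→disease): {len(self.step2.table)} probes tested",
            f"  step 3 (methylation→expression): {len(self.step3.table)} probes tested",
            f"  chains assembled: {len(self.chains)}   candidates: {len(self.candidates)}",
        ]
        for ch in self.candidates:
            text, _ = infer_sign_chain(ch)
            lo1, hi1 = ch.step1.or_ci95
            lines.append(
                f"    {ch.probe_id} × {ch.gene_id}: "
                f"step1 OR={ch.step1.or_point:.2f} [{lo1:.2f}-{hi1:.2f}]  "
                f"PP.H4={ch.coloc_pph4:.3f}  {text}"
            )
        return "\n".join(lines)


def run_three_step(
    eqtl: Dataset,
    mqtl: Dataset,
    gwas: Dataset,
    ld: LdMatrix | None,
    annotation: Annotation,
    gene_filter: Sequence[str],
    config: PipelineConfig | None = None,
) -> list[CausalChain]:
    """Functional wrapper: fit the three-step model and return its chains."""
    return ThreeStepSmr(eqtl, mqtl, gwas, ld, annotation, gene_filter, config).fit().chains
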