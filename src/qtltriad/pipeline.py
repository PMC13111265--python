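"""End-to-end pipeline: (optional) GWAS meta-analysis → three-step SMR
with colocalization → report, with a provenance run log."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .meta import MetaAnalysis, MetaResults
from .report import write_report
from .smr import LdMatrix
from .sumstats import Dataset, filter_by_maf, read_annotation, read_sumstats
from .triad import ThreeStepResults, ThreeStepSmr

__all__ = ["InputError", "PipelineInputs", "run_pipeline"]

log = logging.getLogger("qtltriad")


class InputError(ValueError):
    """Missing or unparsable input file (exit code 3 at the CLI)."""


@dataclass
class PipelineInputs:
    gwas_paths: list[str]
    eqtl_path: str | None = None
    mqtl_path: str | None = None
    ld_path: str | None = None
    annotation_path: str | None = None
    gene_list_path: str | None = None


def _read(path: str, trait_kind: str) -> Dataset:
    if not Path(path).exists():
        raise InputError(f"input file not found: {path}")
    try:
        return read_sumstats(path, trait_kind=trait_kind)
    except ValueError as exc:
        raise InputError(str(exc)) from None


def run_pipeline(
    config: PipelineConfig,
    inputs: PipelineInputs,
    out_dir: str | Path,
    *,
    skip_triad: bool = False,
) -> dict:
    """Execute the configured pipeline and write per-stage TSVs.

    Returns a dict with the fitted stage results (``meta``, ``triad``)
    and output paths.  Every gate decision and dropped record is logged
    with the threshold that triggered it; the full configuration is
    written into the run log for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    try:
        log.info("configuration: %s", config.to_dict())

        gwas_sets = [
            filter_by_maf(_read(p, "disease"), config.maf_min)
            for p in inputs.gwas_paths
        ]
        for ds in gwas_sets:
            dropped = (ds.qc_log["action"] == "dropped_maf").sum()
            log.info(
                "%s: %d variants after MAF >= %g filter (%d dropped)",
                ds.label, len(ds), config.maf_min, dropped,
            )
        if len(gwas_sets) > 1:
            meta_res: MetaResults = MetaAnalysis(
                gwas_sets, config.palindromic_eaf_band
            ).fit()
            meta_res.table.to_csv(out / "meta.tsv", sep="\t", index=False)
            loci = meta_res.define_loci(config.p_sig, config.locus_window)
            pd.DataFrame(
                [
                    {
                        "index_variant": l.index_variant,
                        "chrom": l.chrom,
                        "pos": l.pos,
                        "window_start": l.window_start,
                        "window_end": l.window_end,
                        "n_members": len(l.member_variants),
                    }
                    for l in loci
                ]
            ).to_csv(out / "loci.tsv", sep="\t", index=False)
            log.info("meta-analysis: %d loci at p < %g", len(loci), config.p_sig)
            gwas = meta_res.to_dataset()
            results["meta"] = meta_res
        else:
            gwas = gwas_sets[0]

        if skip_triad:
            return results

        for name, path in (
            ("eqtl", inputs.eqtl_path),
            ("mqtl", inputs.mqtl_path),
            ("annotation", inputs.annotation_path),
            ("gene_list", inputs.gene_list_path),
        ):
            if path is None:
                raise InputError(f"--{name} is required unless --skip-triad is set")

        eqtl = _read(inputs.eqtl_path, "expression")
        mqtl = _read(inputs.mqtl_path, "methylation")
        annotation = read_annotation(inputs.annotation_path)
        gene_filter = [
            g for g in Path(inputs.gene_list_path).read_text().split() if g
        ]
        ld = LdMatrix.from_tsv(inputs.ld_path) if inputs.ld_path else None
        if ld is None:
            log.warning("no LD matrix supplied: HEIDI untestable throughout")

        triad_res: ThreeStepResults = ThreeStepSmr(
            eqtl, mqtl, gwas, ld, annotation, gene_filter, config
        ).fit()
        triad_res.step1.table.to_csv(out / "step1.tsv", sep="\t", index=False)
        triad_res.step2.table.to_csv(out / "step2.tsv", sep="\t", index=False)
        triad_res.step3.table.to_csv(out / "step3.tsv", sep="\t", index=False)
        triad_res.chain_table().to_csv(out / "candidates.tsv", sep="\t", index=False)
        for ch in triad_res.chains:
            log.info(
                "chain %s x %s gates=%s (fdr<%g, p<%g, heidi>%g, pph4>%g)",
                ch.probe_id, ch.gene_id, ch.gates, config.step_fdr,
                config.instr_p, config.heidi_alpha, config.pph4_gate,
            )
        write_report(triad_res.chains, out / "report")
        log.info(
            "triad: %d chains, %d candidates",
            len(triad_res.chains), len(triad_res.candidates),
        )
        results["triad"] = triad_res
        return results
    finally:
        log.removeHandler(handler)
        handler.close()
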