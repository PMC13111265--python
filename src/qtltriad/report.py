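"""Forest-table output and human-readable run summaries."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .triad import CausalChain, infer_sign_chain

__all__ = ["forest_table", "write_report"]

_STEP_LABELS = {
    "step1": "expression→disease",
    "step2": "methylation→disease",
    "step3": "methylation→expression",
}


def forest_table(chains: list[CausalChain]) -> pd.DataFrame:
    """One row per chain per step: OR with 95% CI, q, HEIDI p, PP.H4."""
    rows = []
    for ch in chains:
        text, consistent = infer_sign_chain(ch)
        for step_name in ("step1", "step2", "step3"):
            st = getattr(ch, step_name)
            lo, hi = st.or_ci95
            rows.append(
                {
                    "probe_id": ch.probe_id,
                    "gene_id": ch.gene_id,
                    "step": step_name,
                    "edge": _STEP_LABELS[step_name],
                    "top_snp": st.top_snp,
                    "b_smr": st.b_smr,
                    "se_smr": st.se_smr,
                    "or": st.or_point,
                    "or_l95": lo,
                    "or_u95": hi,
                    "p_smr": st.p_smr,
                    "q_smr": st.q_smr,
                    "p_heidi": np.nan if st.p_heidi is None else st.p_heidi,
                    "coloc_pph4": ch.coloc_pph4,
                    "sign_chain": text,
                    "sign_consistent": consistent,
                    "is_candidate": ch.is_candidate,
                }
            )
    columns = [
        "probe_id", "gene_id", "step", "edge", "top_snp", "b_smr", "se_smr",
        "or", "or_l95", "or_u95", "p_smr", "q_smr", "p_heidi", "coloc_pph4",
        "sign_chain", "sign_consistent", "is_candidate",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_report(
    chains: list[CausalChain],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the forest TSV plus a text summary; returns the two paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = out_prefix.with_suffix(".forest.tsv")
    txt = out_prefix.with_suffix(".summary.txt")
    table = forest_table(chains)
    table.to_csv(tsv, sep="\t", index=False, float_format="%.6g")

    lines = []
    candidates = [ch for ch in chains if ch.is_candidate]
    if not chains:
        lines.append("no candidates")
    else:
        lines.append(f"{len(chains)} chain(s) assembled, {len(candidates)} candidate(s)")
        for ch in chains:
            text, _ = infer_sign_chain(ch)
            lines.append(f"\n{ch.probe_id} × {ch.gene_id}"
                         + ("  [candidate]" if ch.is_candidate else ""))
            for step_name in ("step1", "step2", "step3"):
                st = getattr(ch, step_name)
                lo, hi = st.or_ci95
                ph = "NA" if st.p_heidi is None else f"{st.p_heidi:.3f}"
                lines.append(
                    f"  {_STEP_LABELS[step_name]:<24} OR = {st.or_point:.2f} "
                    f"[95% CI: {lo:.2f}-{hi:.2f}]  q = {st.q_smr:.3g}  p_HEIDI = {ph}"
                )
            pph4 = "NA" if np.isnan(ch.coloc_pph4) else f"{ch.coloc_pph4:.3f}"
            lines.append(f"  PP.H4 = {pph4}")
            lines.append(f"  {text}")
    txt.write_text("\n".join(lines) + "\n")
    return tsv, txt
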