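"""End-to-end orchestration: PSI -> differential -> calls -> enrichments ->
motif proximity -> dose-response, with TSV outputs and a JSON run summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .dose import DoseResponseResult, correlate_dose, sample_dysregulation
from .enrich import enrichment_table
from .events import GeneSet, SpliceEvent, events_to_frame, validate_design
from .motifs import (
    MBNL_GAPPED,
    MBNL_YGCY,
    RBFOX_GCAYG,
    assign_window,
    assignments_frame,
    compile_pattern,
    scan,
)
from .psi import call_missplicing, differential_table, psi_matrix

logger = logging.getLogger("misplice")

DEFAULT_PATTERNS = (MBNL_YGCY, MBNL_GAPPED, RBFOX_GCAYG)


@dataclass
class PipelineResult:
    differential: pd.DataFrame
    psi: pd.DataFrame
    enrichment_event: pd.DataFrame
    enrichment_gene: pd.DataFrame
    enrichment_mie: pd.DataFrame
    motif_assignments: pd.DataFrame
    motif_enrichment: pd.DataFrame
    dose: Optional[DoseResponseResult]
    summary: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    events: Sequence[SpliceEvent],
    counts: pd.DataFrame,
    design: pd.DataFrame,
    sequences: Optional[dict[str, str]] = None,
    regions: Optional[dict[str, tuple[int, int]]] = None,
    gene_sets: Sequence[GeneSet] = (),
    patterns: Sequence[str] = DEFAULT_PATTERNS,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run every analysis stage on validated inputs.

    Deterministic given the inputs and config; when ``out_dir`` is set the
    result tables are written as TSV plus a machine-readable summary.json.
    """
    stage = "validate"
    try:
        validate_design(design, config.min_samples_per_group)
        events_frame = events_to_frame(events)

        stage = "psi"
        logger.info("stage psi: %d events x %d samples", len(events), len(design))
        psi = psi_matrix(counts, config.min_coverage)

        stage = "differential"
        diff = differential_table(counts, design, events_frame, config)
        diff = call_missplicing(diff, config)
        logger.info(
            "stage differential: %d tested, %d called",
            len(diff),
            int(diff["is_missplicing"].sum()) if len(diff) else 0,
        )

        stage = "enrichment"
        gene_sets = list(gene_sets)
        enr_event = enrichment_table(diff, gene_sets, mode="event") if gene_sets else pd.DataFrame()
        enr_gene = enrichment_table(diff, gene_sets, mode="gene") if gene_sets else pd.DataFrame()
        enr_mie = (
            enrichment_table(diff, gene_sets, mode="mie")
            if gene_sets and (diff["event_type"] == "SE").any()
            else pd.DataFrame()
        )

        stage = "motif"
        assignments = pd.DataFrame()
        motif_enr = pd.DataFrame()
        if sequences is not None and regions is not None:
            compiled = [compile_pattern(p) for p in patterns]
            assign = []
            by_id = {e.event_id: e for e in events}
            for event_id in sorted(sequences):
                ev = by_id.get(event_id)
                if ev is None:
                    continue
                hits = []
                for pat in compiled:
                    hits.extend(scan(sequences[event_id], pat))
                assign.append(assign_window(ev, hits, config.motif_window, regions[event_id]))
            assignments = assignments_frame(assign)
            se_called_any = bool(
                ((diff["event_type"] == "SE") & diff["is_missplicing"]).any()
            ) if len(diff) else False
            if gene_sets and se_called_any:
                from .motifs import motif_enrichment as _me

                rows = []
                for gs in gene_sets:
                    r = _me(diff, assignments, gs, mode="event")
                    rows.append(
                        {
                            "set_name": r.set_name,
                            "a": r.table.a,
                            "b": r.table.b,
                            "c": r.table.c,
                            "d": r.table.d,
                            "odds_ratio": r.odds_ratio,
                            "ci_low": r.ci_low,
                            "ci_high": r.ci_high,
                            "p": r.p,
                        }
                    )
                motif_enr = pd.DataFrame(rows)

        stage = "dose"
        dose = None
        rl = design.set_index("sample_id")["repeat_length"] if "repeat_length" in design.columns else None
        called_ids = diff.loc[diff["is_missplicing"].astype(bool), "event_id"].tolist() if len(diff) else []
        if rl is not None and rl.notna().sum() >= 3 and len(called_ids) >= 1:
            try:
                scores = sample_dysregulation(psi, called_ids, design)
                dose = correlate_dose(scores, rl)
            except ValueError as exc:
                logger.warning("stage dose skipped: %s", exc)

        stage = "summary"
        summary = {
            "version": __version__,
            "config": config.to_dict(),
            "n_events": len(events),
            "n_samples": int(len(design)),
            "n_events_tested": int(len(diff)),
            "n_events_skipped": len(diff.attrs.get("skipped", {})),
            "n_missplice_called": int(diff["is_missplicing"].sum()) if len(diff) else 0,
            "per_type": diff.attrs.get("summary", {}),
            "dose": None
            if dose is None
            else {"pearson_r": dose.pearson_r, "p": dose.p, "slope": dose.slope, "n": dose.n},
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        differential=diff,
        psi=psi,
        enrichment_event=enr_event,
        enrichment_gene=enr_gene,
        enrichment_mie=enr_mie,
        motif_assignments=assignments,
        motif_enrichment=motif_enr,
        dose=dose,
        summary=summary,
    )
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.differential.to_csv(out / "differential.tsv", sep="\t", index=False)
    result.psi.to_csv(out / "psi.tsv", sep="\t")
    for name, df in (
        ("enrichment_event.tsv", result.enrichment_event),
        ("enrichment_gene.tsv", result.enrichment_gene),
        ("enrichment_mie.tsv", result.enrichment_mie),
        ("motif_assignments.tsv", result.motif_assignments),
        ("motif_enrichment.tsv", result.motif_enrichment),
    ):
        if len(df):
            df.to_csv(out / name, sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
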