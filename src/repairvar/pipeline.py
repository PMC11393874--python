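"""Pipeline orchestration: merge -> classify -> summarize, with a manifest.

The manifest records, per filtering stage, how many variants were still
alive, mirroring the flow-chart view of the screen; counts must be
non-increasing along each round and reconcile with the final retained set.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__
from .annotation_io import variant_to_row, TABLE_COLUMNS
from .cohort_stats import PatientRecord, summarize_cohort
from .gene_panel import PanelGene, PanelIndex
from .prioritization import (AfClass, FilterConfig, PriorityCall, af_class,
                             cadd_pass, classify, NON_TRANSCRIPT_TERMS)
from .variants import AnnotatedVariant

import pandas as pd


@dataclass
class RunManifest:
    inputs: list[str]
    config: dict
    tool_version: str = __version__
    timestamp: str = ""
    panel_size: int = 0
    stage_counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def stage_counts(variants: Sequence[AnnotatedVariant],
                 calls: Sequence[PriorityCall],
                 panel: PanelIndex,
                 config: FilterConfig) -> dict:
    """Survivor counts along the strict round's filter sequence, then the
    per-round retained totals."""
    alive = list(variants)
    counts = {"input": len(alive)}
    alive = [v for v in alive
             if panel.lookup(v.gene, v.annotation.gene_id) is not None]
    counts["after_panel"] = len(alive)
    alive = [v for v in alive if cadd_pass(v.cadd_phred, config)]
    counts["after_cadd"] = len(alive)
    alive = [v for v in alive if v.annotation.is_canonical
             or v.annotation.consequence_terms <= NON_TRANSCRIPT_TERMS]
    counts["after_canonical"] = len(alive)
    alive = [v for v in alive
             if af_class(v, config.af_strict) is not AfClass.EXCLUDED]
    counts["after_af_strict"] = len(alive)
    strict_n = sum(1 for c in calls if c.round == "strict")
    counts["strict_retained"] = strict_n
    counts["relaxed_retained"] = sum(1 for c in calls if c.retained) - strict_n
    counts["final_retained"] = sum(1 for c in calls if c.retained)
    return counts


def write_priority_table(variants: Sequence[AnnotatedVariant],
                         calls: Sequence[PriorityCall], dest) -> None:
    """Prioritized-variant TSV: the curated dialect plus verdict columns."""
    by_kg = {(c.key, c.gene): c for c in calls}
    rows = []
    for v in variants:
        c = by_kg.get((v.key, v.gene))
        if c is None:
            continue
        row = variant_to_row(v)
        row.update(retained=int(c.retained), group=c.group.value,
                   call_subcategory=c.subcategory.value,
                   af_class=c.af_class.value, rule_trace=c.trace_text())
        rows.append(row)
    cols = list(TABLE_COLUMNS) + ["retained", "group", "call_subcategory",
                                  "af_class", "rule_trace"]
    pd.DataFrame(rows, columns=cols).to_csv(dest, sep="\t", index=False)


def run_pipeline(
    variants: Sequence[AnnotatedVariant],
    panel: set[PanelGene],
    config: FilterConfig,
    out_dir,
    patients: Optional[Sequence[PatientRecord]] = None,
    inputs: Sequence[str] = (),
) -> tuple[Sequence[PriorityCall], RunManifest]:
    """Classify a merged cohort and write the three standard outputs:
    ``prioritized.tsv``, ``summary.txt`` (when a patient table is given)
    and ``manifest.json``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = PanelIndex(panel)
    calls = classify(variants, index, config)

    manifest = RunManifest(
        inputs=list(inputs),
        config=config.to_dict(),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        panel_size=len(panel),
        stage_counts=stage_counts(variants, calls, index, config),
    )
    write_priority_table(variants, calls, out / "prioritized.tsv")
    (out / "manifest.json").write_text(manifest.to_json() + "\n")

    if patients is not None:
        summary = summarize_cohort(patients, calls, variants)
        (out / "summary.txt").write_text(summary.as_text() + "\n")
    return calls, manifest
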