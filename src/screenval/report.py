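"""Rendering of model outputs as text, CSV and JSON artifacts.

The renderer never re-rounds: every number shown is taken from the module
outputs (rounded cells, one-decimal percentage strings, summary frames),
so reports are byte-stable for fixed inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .analytic_validity import ConfusionCounts, TestPerformance
from .clinical_validity import ClinicalOutcome, scenario_report
from .sensitivity_analysis import MCResult

__all__ = [
    "confusion_text",
    "confusion_frame",
    "metrics_frame",
    "main_model_text",
    "main_model_json",
    "scenario_text",
    "scenario_frame",
    "write_outputs",
]


def confusion_text(gene_name: str, counts: ConfusionCounts) -> str:
    """Render one gene's rounded 2x2 table as aligned text."""
    r = counts.rounded()
    tp, fp, fn, tn = r.tp_rounded, r.fp_rounded, r.fn_rounded, r.tn_rounded
    rows = [
        (f"{gene_name} main model", "Has variant", "No variant", "Total"),
        ("Detected: yes", f"{tp}", f"{fp}", f"{tp + fp}"),
        ("Detected: no", f"{fn}", f"{tn}", f"{fn + tn}"),
        ("Total", f"{tp + fn}", f"{fp + tn}", f"{tp + fp + fn + tn}"),
    ]
    widths = [max(len(row[i]) for row in rows) for i in range(4)]
    return "\n".join(
        "  ".join(cell.rjust(w) if i else cell.ljust(w)
                  for i, (cell, w) in enumerate(zip(row, widths)))
        for row in rows
    )


def confusion_frame(counts: Mapping[str, ConfusionCounts]) -> pd.DataFrame:
    """Per-gene cells, continuous and rounded, one gene per row."""
    rows = []
    for name, c in counts.items():
        rows.append({
            "gene": name,
            "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
            "tp_rounded": c.tp_rounded, "fp_rounded": c.fp_rounded,
            "fn_rounded": c.fn_rounded, "tn_rounded": c.tn_rounded,
        })
    return pd.DataFrame(rows).set_index("gene")


def metrics_frame(metrics: Mapping[str, TestPerformance]) -> pd.DataFrame:
    rows = []
    for name, m in metrics.items():
        rows.append({
            "gene": name,
            "sensitivity": m.sensitivity, "specificity": m.specificity,
            "ppv": m.ppv, "npv": m.npv,
        })
    return pd.DataFrame(rows).set_index("gene")


def main_model_text(
    counts: Mapping[str, ConfusionCounts],
    metrics: Mapping[str, TestPerformance],
) -> str:
    """The 2x2 tables plus one-decimal percentage metrics, per gene."""
    blocks = []
    for name, c in counts.items():
        pct = metrics[name].as_percent_strings()
        blocks.append(confusion_text(name, c))
        blocks.append(
            "  ".join(f"{k}: {v}" for k, v in pct.items())
        )
    return "\n\n".join(blocks) + "\n"


def main_model_json(
    counts: Mapping[str, ConfusionCounts],
    metrics: Mapping[str, TestPerformance],
) -> str:
    """JSON with both raw proportions and the formatted percentages."""
    doc = {}
    for name, c in counts.items():
        m = metrics[name]
        doc[name] = {
            "cells": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
            "cells_rounded": {
                "tp": c.tp_rounded, "fp": c.fp_rounded,
                "fn": c.fn_rounded, "tn": c.tn_rounded,
            },
            "metrics": {
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "ppv": m.ppv, "npv": m.npv,
            },
            "metrics_percent": m.as_percent_strings(),
        }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def scenario_frame(outcome: ClinicalOutcome) -> pd.DataFrame:
    return pd.DataFrame(scenario_report(outcome)).set_index("scenario")


def scenario_text(outcome: ClinicalOutcome) -> str:
    """Flowchart-style text tree of the outcome scenarios."""
    lines = [f"Population screened: {outcome.population_size}"]
    for rec in scenario_report(outcome):
        label = rec["outcome"].replace("_", " ")
        lines.append(
            f"├─ Scenario {rec['scenario']} ({label}): {rec['n_women']} women"
        )
        rng = ""
        if rec["cancers_low"] != rec["cancers_high"]:
            rng = f" (range {rec['cancers_low']}-{rec['cancers_high']})"
        lines.append(f"│    expected breast cancers: {rec['expected_cancers']}{rng}")
        if "predicted_no_cancer" in rec:
            lines.append(
                f"│    predicted not to develop cancer: {rec['predicted_no_cancer']}"
            )
    last_branch = max(i for i, ln in enumerate(lines) if ln.startswith("├─"))
    lines[last_branch] = lines[last_branch].replace("├─", "└─", 1)
    for i in range(last_branch + 1, len(lines)):
        lines[i] = lines[i].replace("│ ", "  ", 1)
    return "\n".join(lines) + "\n"


def mc_summary_frame(result: MCResult, rounded: bool = True) -> pd.DataFrame:
    return result.summary(rounded=rounded)


def write_outputs(
    out_prefix: str,
    text: Optional[str] = None,
    frames: Optional[Mapping[str, pd.DataFrame]] = None,
    json_text: Optional[str] = None,
) -> list[Path]:
    """Write the rendered artifacts next to ``out_prefix``; returns paths."""
    prefix = Path(out_prefix)
    if prefix.parent and not prefix.parent.exists():
        raise IOError(f"output directory does not exist: {prefix.parent}")
    written = []
    if text is not None:
        p = prefix.with_name(prefix.name + ".txt")
        p.write_text(text)
        written.append(p)
    if json_text is not None:
        p = prefix.with_name(prefix.name + ".json")
        p.write_text(json_text)
        written.append(p)
    for suffix, frame in (frames or {}).items():
        p = prefix.with_name(f"{prefix.name}_{suffix}.csv")
        frame.to_csv(p)
        written.append(p)
    return written
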