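"""Markdown and CSV rendering of analysis outputs.

Every number is rendered through the single rounding policy of
:func:`resectability.metrics.round_half_up` (one decimal for percentages,
three for AUC); the renderers never re-round intermediate values.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .metrics import DiagnosticAccuracyResults, round_half_up


def _md_table(headers: Sequence[str], rows: Iterable[Sequence[str]]) -> str:
    lines = ["| " + " | ".join(headers) + " |",
             "| " + " | ".join("---" for _ in headers) + " |"]
    for row in rows:
        lines.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(lines)


def _pct(value: Optional[float]) -> str:
    return "--" if value is None else f"{round_half_up(100 * value, 1):.1f}"


def _pct_ci(value: Optional[float], ci: Optional[tuple]) -> str:
    if value is None:
        return "--"
    if ci is None:
        return _pct(value)
    return f"{_pct(value)} ({_pct(ci[0])}-{_pct(ci[1])})"


def _auc_ci(value: Optional[float], ci: Optional[tuple]) -> str:
    if value is None:
        return "--"
    point = f"{round_half_up(value, 3):.3f}"
    if ci is None:
        return point
    return f"{point} ({round_half_up(ci[0], 3):.3f}-{round_half_up(ci[1], 3):.3f})"


METRIC_COLUMNS = [
    "Procedure", "AUC (95% CI)", "TN (n (%))", "FN (n (%))", "FP (n (%))",
    "TP (n (%))", "Sens (%) (95% CI)", "Spec (%) (95% CI)", "PPV (%) (95% CI)",
    "NPV (%) (95% CI)", "Accuracy (%) (95% CI)", "F1 (%) (95% CI)",
    "F0.5 (%) (95% CI)",
]


def metric_table_frame(results: Sequence[DiagnosticAccuracyResults]) -> pd.DataFrame:
    """One row per assessor in the published column layout.

    AUC intervals are method-dependent (the structural-component default is
    one of several defensible choices for a binary read), so reports flag
    them with a trailing footnote marker.
    """
    rows = []
    for res in results:
        counts, metrics = res.counts, res.metrics
        total = counts.total

        def count_cell(k):
            return f"{k} ({round_half_up(100 * k / total, 1):.1f})"

        rows.append({
            "Procedure": res.label,
            "AUC (95% CI)": _auc_ci(metrics.auc, metrics.ci.get("auc")) + " [a]",
            "TN (n (%))": count_cell(counts.tn),
            "FN (n (%))": count_cell(counts.fn),
            "FP (n (%))": count_cell(counts.fp),
            "TP (n (%))": count_cell(counts.tp),
            "Sens (%) (95% CI)": _pct_ci(metrics.sensitivity, metrics.ci.get("sensitivity")),
            "Spec (%) (95% CI)": _pct_ci(metrics.specificity, metrics.ci.get("specificity")),
            "PPV (%) (95% CI)": _pct_ci(metrics.ppv, metrics.ci.get("ppv")),
            "NPV (%) (95% CI)": _pct_ci(metrics.npv, metrics.ci.get("npv")),
            "Accuracy (%) (95% CI)": _pct_ci(metrics.accuracy, metrics.ci.get("accuracy")),
            "F1 (%) (95% CI)": _pct(metrics.fbeta.get(1.0)),
            "F0.5 (%) (95% CI)": _pct(metrics.fbeta.get(0.5)),
        })
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def render_metric_table(results: Sequence[DiagnosticAccuracyResults]) -> str:
    frame = metric_table_frame(results)
    table = _md_table(frame.columns, frame.itertuples(index=False))
    return table + "\n\n[a] AUC interval method-dependent (structural-component normal interval)."


def render_frequency_table(frame: pd.DataFrame, title: str = "") -> str:
    rows = [
        (row["site"], f"{int(row['count'])} ({row['percent']:.1f})")
        for _, row in frame.iterrows()
    ]
    header = f"### {title}\n\n" if title else ""
    n = int(frame["n_assessed"].iloc[0])
    return header + _md_table(["Anatomical site involvement", f"n = {n} (n (%))"], rows)


def render_agreement_table(frame: pd.DataFrame) -> str:
    rows = [
        (r.modality, r.site, r.a, r.b, r.c, r.d,
         _pct(r.OPA), _pct(r.PPA), _pct(r.NPA))
        for r in frame.itertuples(index=False)
    ]
    return _md_table(
        ["Modality", "Site", "a", "b", "c", "d", "OPA (%)", "PPA (%)", "NPA (%)"], rows
    )
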