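"""Five-metric evaluation and benchmark aggregation.

Class 1 is "splice site".  Accuracy, precision, sensitivity (recall),
specificity and F1 are reported as percentages.  Ratios with a zero
denominator are reported as NaN with a warning rather than silently as 0,
so they drop out of averages visibly instead of corrupting them.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import encode_batch
from .model import SpliceCNNResults, adapt_length, classify

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """The five evaluation metrics (percent) plus optional raw counts."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    counts: ConfusionCounts | None = None
    dataset_name: str = ""
    site_type: str = "donor"

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def display(self) -> dict[str, float]:
        """Metrics rounded to 2 decimals, the conventional table format."""
        return {k: round(v, 2) for k, v in self.as_dict().items()}

    def __str__(self) -> str:
        vals = "  ".join(f"{k}={v:.2f}%" for k, v in self.as_dict().items())
        return f"[{self.dataset_name or 'unnamed'} / {self.site_type}] {vals}"


def confusion_counts(predicted_labels: Sequence[int],
                     true_labels: Sequence[int]) -> ConfusionCounts:
    """Standard 2x2 tally with class 1 = splice site."""
    pred = np.asarray(predicted_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise EvaluationError(f"length mismatch: {pred.shape} vs {true.shape}")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise EvaluationError("labels must be 0 or 1")
    return ConfusionCounts(
        tp=int(((pred == 1) & (true == 1)).sum()),
        fp=int(((pred == 1) & (true == 0)).sum()),
        tn=int(((pred == 0) & (true == 0)).sum()),
        fn=int(((pred == 0) & (true == 1)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den * 100.0


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (all in percent)."""
    if np.isnan(precision) or np.isnan(sensitivity):
        return float("nan")
    if precision + sensitivity == 0:
        warnings.warn("F1 undefined (precision + sensitivity = 0); reporting NaN",
                      stacklevel=2)
        return float("nan")
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def compute_metrics(c: ConfusionCounts, dataset_name: str = "",
                    site_type: str = "donor") -> MetricsReport:
    """Accuracy, precision, sensitivity, specificity and F1 from counts."""
    if c.total == 0:
        raise EvaluationError("cannot compute metrics over zero examples")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total, "accuracy"),
        precision=precision,
        sensitivity=sensitivity,
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        f1=f1_score(precision, sensitivity),
        counts=c,
        dataset_name=dataset_name,
        site_type=site_type,
    )


def evaluate(results: SpliceCNNResults, windows: Sequence[str],
             labels: Sequence[int], dataset_name: str = "",
             threshold: float = 0.5) -> MetricsReport:
    """Predict on labeled windows and compute the five metrics.

    Windows are adapted (center-crop / N-pad) to the model's input length.
    """
    if len(windows) == 0:
        raise EvaluationError("benchmark is empty")
    W = results.config.input_length
    adapted = [adapt_length(w, W) for w in windows]
    batch = encode_batch(adapted, labels)
    pred = classify(results.predict_proba(batch), threshold=threshold)
    counts = confusion_counts(pred, batch.labels)
    return compute_metrics(counts, dataset_name=dataset_name,
                           site_type=results.site_type)


def aggregate_reports(reports: Sequence[MetricsReport],
                      rounded: bool = False) -> MetricsReport:
    """Unweighted arithmetic mean of each metric across benchmark reports.

    With ``rounded=True`` the per-report display values (2 decimals) are
    averaged, matching how published benchmark tables are aggregated from
    their printed per-benchmark rows.
    """
    if not reports:
        raise EvaluationError("need at least one report")
    site_types = {r.site_type for r in reports}
    if len(site_types) > 1:
        raise EvaluationError(f"cannot aggregate mixed site types {site_types}")
    values = {}
    for name in METRIC_NAMES:
        per = [r.display()[name] if rounded else getattr(r, name) for r in reports]
        values[name] = float(np.mean(per))
    return MetricsReport(**values, counts=None,
                         dataset_name=f"average({len(reports)})",
                         site_type=reports[0].site_type)


# ---------------------------------------------------------------------------
# Report I/O: one row per benchmark plus an average row.

def reports_to_frame(reports: Sequence[MetricsReport],
                     include_average: bool = True) -> pd.DataFrame:
    rows = list(reports)
    if include_average and len(reports) > 1:
        rows.append(aggregate_reports(reports))
    return pd.DataFrame([
        {"dataset": r.dataset_name, "site_type": r.site_type, **r.display()}
        for r in rows
    ])


def write_reports(reports: Sequence[MetricsReport], tsv_path: str | Path | None = None,
                  json_path: str | Path | None = None) -> None:
    frame = reports_to_frame(reports)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = []
        for r in reports:
            d = {"dataset": r.dataset_name, "site_type": r.site_type, **r.as_dict()}
            if r.counts is not None:
                d["counts"] = dataclasses.asdict(r.counts)
            payload.append(d)
        Path(json_path).write_text(json.dumps(payload, indent=2))


def read_benchmark_fasta(path: str | Path) -> tuple[list[str], list[int]]:
    """Read labeled benchmark windows from FASTA whose headers carry
    ``label=0|1`` (and optionally ``site=donor|acceptor``)."""
    from Bio.SeqIO import parse
    windows, labels = [], []
    for rec in parse(str(path), "fasta"):
        fields = dict(kv.split("=", 1) for kv in rec.description.split()
                      if "=" in kv)
        if "label" not in fields:
            raise EvaluationError(f"record {rec.id} lacks a label= header field")
        windows.append(str(rec.seq).upper())
        labels.append(int(fields["label"]))
    return windows, labels
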