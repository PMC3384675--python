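"""Scoring, threshold calibration and report writing.

Detection outcomes are scored against ground truth as a binary
classification per decision: TP when the object is in the scene and the
detector says present, TN when both say absent, FP/FN otherwise.  Four
statistical indexes summarize the confusion counts, in percent:

    Se = 100 * TP / (TP + FN)        sensitivity
    Sp = 100 * TN / (TN + FP)        specificity
    Ex = 100 * (TP + TN) / n         exactitude (accuracy)
    Er = 100 * (FP + FN) / n         error rate  (Ex + Er = 100)

The decision threshold on the correlation-peak intensity is calibrated by
exhaustive scan: candidate thresholds at the midpoints between consecutive
distinct observed intensities (plus the two all-present / all-absent
extremes), choosing the candidate that maximizes exactitude, with ties
broken toward higher specificity and then toward the higher threshold.
Absolute peak intensities depend on the FFT normalization convention, so a
threshold is only meaningful for the pipeline that calibrated it.

Localization is reported separately from detection: an estimated start is
"exact" when it equals the true start, a "one-row shift" when it is off by
exactly one image row (= scene width in bases), and "wrong" otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "IndexReport",
    "score",
    "indexes",
    "calibrate_threshold",
    "locate_report",
    "write_index_table",
    "write_locate_table",
    "write_hits_table",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class IndexReport:
    """Se/Sp/Ex/Er percentages for one noise level (NaN when undefined)."""

    se: float
    sp: float
    ex: float
    er: float
    noise_level: float | None = None


def score(
    decisions: Iterable[tuple[Hashable, Hashable, bool]],
    truth: Mapping[tuple[Hashable, Hashable], bool],
) -> ConfusionCounts:
    """Count TP/TN/FP/FN over ``(query_id, scene_id, present)`` decisions.

    Every decision must have a truth entry; an unmatched key raises.
    """
    c = ConfusionCounts()
    for query_id, scene_id, present in decisions:
        key = (query_id, scene_id)
        if key not in truth:
            raise ValueError(f"no ground-truth entry for decision {key}")
        expected = truth[key]
        if expected and present:
            c.tp += 1
        elif expected:
            c.fn += 1
        elif present:
            c.fp += 1
        else:
            c.tn += 1
    return c


def indexes(c: ConfusionCounts, noise_level: float | None = None) -> IndexReport:
    """Se/Sp/Ex/Er in percent; Se or Sp is NaN when its class is absent."""
    if c.n == 0:
        raise ValueError("cannot compute indexes over zero decisions")
    se = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    sp = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    ex = 100.0 * (c.tp + c.tn) / c.n
    er = 100.0 * (c.fp + c.fn) / c.n
    return IndexReport(se=se, sp=sp, ex=ex, er=er, noise_level=noise_level)


def calibrate_threshold(
    examples: Sequence[tuple[float, bool]],
    objective: str = "exactitude",
) -> float:
    """Exactitude-maximizing decision threshold over labelled intensities.

    ``examples`` are ``(peak_intensity, truth_present)`` pairs; a decision
    is "present" iff intensity > threshold.  Candidates are the midpoints
    between consecutive sorted distinct intensities plus -inf and +inf;
    ties break toward higher specificity, then the higher threshold.
    Requires at least one positive and one negative example.
    """
    if objective != "exactitude":
        raise ValueError(f"unknown calibration objective {objective!r}")
    intens = np.asarray([e[0] for e in examples], dtype=float)
    labels = np.asarray([bool(e[1]) for e in examples])
    if labels.all() or not labels.any():
        raise ValueError("calibration needs at least one positive and one negative example")
    uniq = np.unique(intens)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    pos = np.sort(intens[labels])
    neg = np.sort(intens[~labels])
    tp = pos.size - np.searchsorted(pos, candidates, side="right")
    fp = neg.size - np.searchsorted(neg, candidates, side="right")
    tn = neg.size - fp
    ex = (tp + tn) / intens.size
    sp = tn / neg.size
    best = int(np.lexsort((candidates, sp, ex))[-1])
    return float(candidates[best])


def locate_report(
    locations: Iterable[tuple[int, int]],
    width: int = 100,
) -> dict[str, int]:
    """Classify estimated vs true start positions of confirmed detections.

    ``locations`` are ``(est_start_base, true_start)`` pairs for detections
    that are both claimed and truly present.  Returns counts for the three
    categories, which partition the input: ``exact`` (equal), ``shift``
    (off by exactly ``width`` bases, the one-pixel vertical shift) and
    ``wrong`` (anything else).
    """
    out = {"exact": 0, "shift": 0, "wrong": 0}
    for est, true in locations:
        if est == true:
            out["exact"] += 1
        elif abs(est - true) == width:
            out["shift"] += 1
        else:
            out["wrong"] += 1
    return out


def _fmt(value: float, decimal: str) -> str:
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    return f"{value:.2f}".replace(".", decimal)


def write_index_table(
    reports: Sequence[IndexReport],
    path: str | Path,
    decimal: str = ".",
) -> None:
    """Write a per-noise-level Se/Sp/Ex/Er table (levels as columns)."""
    cols = {
        f"{int(round((r.noise_level or 0.0) * 100))}%": [
            _fmt(r.se, decimal),
            _fmt(r.sp, decimal),
            _fmt(r.ex, decimal),
            _fmt(r.er, decimal),
        ]
        for r in reports
    }
    frame = pd.DataFrame(cols, index=["Se", "Sp", "Ex", "Er"])
    frame.to_csv(path, sep="\t", index_label="Noise")


def write_locate_table(counts: Mapping[str, int], path: str | Path, decimal: str = ".") -> None:
    """Write the localization table (exact / one-row shift / wrong)."""
    total = sum(counts.values())
    rows = []
    for label, key in [
        ("Exact location", "exact"),
        ("Vertical one pixel shift", "shift"),
        ("Wrong location", "wrong"),
    ]:
        n = counts.get(key, 0)
        pct = 100.0 * n / total if total else math.nan
        rows.append({"Category": label, "N": n, "Percentage": _fmt(pct, decimal)})
    rows.append({"Category": "Total", "N": total, "Percentage": _fmt(100.0 if total else math.nan, decimal)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_hits_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Write the per-detection hits table as TSV.

    Expected columns: query_id, scene_index, peak_intensity, present,
    est_start_base, shift_flag (extra columns pass through).
    """
    hits.to_csv(path, sep="\t", index=False)
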