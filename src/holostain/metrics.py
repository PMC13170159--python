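"""Confusion-matrix metrics for slide-interpretation studies.

Percentages use half-up rounding at an explicit number of decimals so
published-style figures are reproduced at their printed precision.  An
optional *abstain* column (indeterminate calls) is excluded from accuracy
denominators but drives the call rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

GRAM_CLASS_MAP = {
    "GNB": "negative",
    "GPC_clusters": "positive",
    "GPC_pairs_chains": "positive",
}


class UndefinedMetricError(ZeroDivisionError):
    """A requested metric has an empty denominator."""


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero at the given decimal place."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer counts of true (rows) × predicted (columns) labels.

    ``abstain_label`` names a predicted column holding abstentions
    (e.g. "Indeterminate"); it is excluded from accuracy denominators.
    """

    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]
    counts: np.ndarray
    abstain_label: str | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match the label lists")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.row_labels)) != len(self.row_labels) or \
                len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("labels must be unique")
        if self.abstain_label is not None and \
                self.abstain_label not in self.col_labels:
            raise ValueError("abstain_label must be one of the column labels")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, truths: Sequence[str], predictions: Sequence[str],
                     labels: Sequence[str], abstain_label: str | None = None
                     ) -> "ConfusionMatrix":
        cols = list(labels) + ([abstain_label] if abstain_label and
                               abstain_label not in labels else [])
        counts = np.zeros((len(labels), len(cols)), dtype=int)
        li = {lab: i for i, lab in enumerate(labels)}
        ci = {lab: i for i, lab in enumerate(cols)}
        for t, p in zip(truths, predictions):
            counts[li[t], ci[p]] += 1
        return cls(tuple(labels), tuple(cols), counts, abstain_label)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, abstain_label: str | None = None
                       ) -> "ConfusionMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(),
                   abstain_label)

    @classmethod
    def from_csv(cls, path: str | Path, abstain_label: str | None = None
                 ) -> "ConfusionMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0), abstain_label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    # -- helpers -----------------------------------------------------------
    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _non_abstain_cols(self) -> list[int]:
        return [i for i, lab in enumerate(self.col_labels)
                if lab != self.abstain_label]

    def collapse(self, mapping: Dict[str, str]) -> "ConfusionMatrix":
        """Merge classes by a label map (totals preserved); the abstain
        column, if any, is carried through unchanged."""
        for lab in self.row_labels:
            if lab not in mapping:
                raise KeyError(f"class {lab!r} missing from the collapse map")
        new_rows = list(dict.fromkeys(mapping[r] for r in self.row_labels))
        new_cols = list(dict.fromkeys(
            mapping.get(c, c) if c != self.abstain_label else c
            for c in self.col_labels))
        counts = np.zeros((len(new_rows), len(new_cols)), dtype=int)
        for i, r in enumerate(self.row_labels):
            for j, c in enumerate(self.col_labels):
                cj = c if c == self.abstain_label else mapping.get(c, c)
                counts[new_rows.index(mapping[r]), new_cols.index(cj)] += \
                    self.counts[i, j]
        return ConfusionMatrix(tuple(new_rows), tuple(new_cols), counts,
                               self.abstain_label)


def overall_accuracy(cm: ConfusionMatrix, round_to: int = 1) -> float:
    """100 × trace / total over the non-abstain columns."""
    cols = cm._non_abstain_cols()
    if tuple(cm.col_labels[j] for j in cols) != cm.row_labels:
        raise ValueError("matrix must be square over shared class labels")
    sub = cm.counts[:, cols]
    total = sub.sum()
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return round_half_up(100.0 * np.trace(sub) / total, round_to)


def per_class_accuracy(cm: ConfusionMatrix, cls: str, round_to: int = 1) -> float:
    """100 × diagonal cell / row total (non-abstain columns)."""
    if cls not in cm.row_labels:
        raise KeyError(f"class {cls!r} not in matrix rows")
    i = cm.row_labels.index(cls)
    cols = cm._non_abstain_cols()
    row_total = cm.counts[i, cols].sum()
    if row_total == 0:
        raise UndefinedMetricError(f"no non-abstain calls for class {cls!r}")
    j = cm.col_labels.index(cls)
    return round_half_up(100.0 * cm.counts[i, j] / row_total, round_to)


def binary_gram_accuracy(cm: ConfusionMatrix,
                         gram_map: Dict[str, str] = GRAM_CLASS_MAP,
                         round_to: int = 1) -> Tuple[float, float]:
    """Per-group accuracy after collapsing classes to Gram reaction.

    Returns ``(gram_negative_pct, gram_positive_pct)``.
    """
    for lab in cm.row_labels:
        if lab not in gram_map:
            raise KeyError(f"class {lab!r} missing from gram_map")
    collapsed = cm.collapse(gram_map)
    return (per_class_accuracy(collapsed, "negative", round_to),
            per_class_accuracy(collapsed, "positive", round_to))


def call_rate_and_called_accuracy(cm: ConfusionMatrix, round_to: int = 1
                                  ) -> Tuple[float, float]:
    """Share of non-abstain interpretations, and accuracy among them."""
    if cm.abstain_label is None:
        raise ValueError("matrix has no abstain column")
    total = cm.total
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    cols = cm._non_abstain_cols()
    called = cm.counts[:, cols].sum()
    call_rate = round_half_up(100.0 * called / total, round_to)
    if called == 0:
        raise UndefinedMetricError("no non-abstain calls")
    correct = sum(cm.counts[i, cm.col_labels.index(lab)]
                  for i, lab in enumerate(cm.row_labels)
                  if lab in cm.col_labels)
    return call_rate, round_half_up(100.0 * correct / called, round_to)


# -- bundled reference matrices -------------------------------------------

def _load_fixture(name: str, abstain_label: str | None) -> ConfusionMatrix:
    with resources.as_file(resources.files("holostain.data") / name) as p:
        return ConfusionMatrix.from_csv(p, abstain_label)


def automated_interpretation_matrix() -> ConfusionMatrix:
    """3×3 validation matrix of the automated whole-slide interpreter
    (65 accepted slides)."""
    return _load_fixture("table1.csv", None)


def human_reader_matrix() -> ConfusionMatrix:
    """Reader-study matrix (96 interpretations, Indeterminate allowed)."""
    return _load_fixture("table2.csv", "Indeterminate")
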