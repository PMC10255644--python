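"""Metrics from confusion matrices: per-class and macro P/R/F1, IIR, delta-M.

Per-class precision is Ncorrect_k / Npredicted_k (column sum) and recall is
Ncorrect_k / Ntested_k (row sum); F1 is their harmonic mean and the macro
average is the unweighted mean over the twelve classes, so rare behaviors
weigh as much as frequent ones. The individual-independence ratio (IIR)
divides a metric under leave-one-hen-out CV by the same metric under
10-fold CV: values below 1 quantify how much performance rests on having
seen the test individual during training. Confusion-matrix differences
localize which class confusions a condition changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from henrec.models import FoldResult
from henrec.signals_io import BEHAVIORS


@dataclass
class ConfusionMatrix:
    """Square count (or averaged-count) matrix: rows true, columns predicted."""

    counts: np.ndarray
    class_order: tuple[str, ...] = BEHAVIORS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{k} classes"
            )
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_tested(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_predicted(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_correct(self) -> np.ndarray:
        return np.diag(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_order), columns=list(self.class_order)
        )


@dataclass
class MetricsReport:
    """Per-class and macro precision/recall/F1 for one CV scheme."""

    class_order: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    scheme: str = ""

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"precision": self.precision, "recall": self.recall, "f1": self.f1},
            index=list(self.class_order),
        )
        df.loc["macro"] = [self.macro_precision, self.macro_recall, self.macro_f1]
        return df


@dataclass(frozen=True)
class IIRValue:
    """A LOHO/10-fold metric ratio; undefined when the denominator is 0."""

    value: float
    defined: bool = True


def average_confusion(folds: Sequence[FoldResult]) -> ConfusionMatrix:
    """Element-wise mean of per-fold count matrices (the paper-style summary).

    Metrics are scale-invariant, so averaging vs. summing across folds
    yields identical precision/recall/F1; the averaged matrix is the
    canonical display form.
    """
    if not folds:
        raise ValueError("need at least one fold")
    order = folds[0].class_order
    for f in folds:
        if f.class_order != order:
            raise ValueError("fold class orders differ")
    mean = np.mean([f.confusion for f in folds], axis=0)
    return ConfusionMatrix(mean, tuple(order))


def compute_metrics(cm: ConfusionMatrix, scheme: str = "") -> MetricsReport:
    """Per-class precision/recall/F1 and their macro averages.

    Zero-denominator cases (a class never predicted, or absent from the
    test data) yield 0 for that metric and still enter the macro mean, so
    the macro average always spans the full class list.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(cm.n_predicted > 0, cm.n_correct / np.where(cm.n_predicted > 0, cm.n_predicted, 1), 0.0)
        rec = np.where(cm.n_tested > 0, cm.n_correct / np.where(cm.n_tested > 0, cm.n_tested, 1), 0.0)
    denom = prec + rec
    f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)
    return MetricsReport(
        class_order=tuple(cm.class_order),
        precision=prec, recall=rec, f1=f1, scheme=scheme,
    )


def compute_iir(metric_loho: float, metric_10fold: float) -> IIRValue:
    """Individual-independence ratio: metric(LOHO) / metric(10-fold)."""
    if metric_10fold == 0:
        return IIRValue(value=float("nan"), defined=False)
    return IIRValue(value=metric_loho / metric_10fold)


@dataclass
class DeltaMatrix:
    """Element-wise difference of two confusion matrices (condition a - b).

    A positive diagonal entry means condition a classified that class
    correctly more often; a positive off-diagonal entry means condition a
    increased that particular confusion.
    """

    delta: np.ndarray
    class_order: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.delta, index=list(self.class_order), columns=list(self.class_order)
        )


def delta_confusion(ma: ConfusionMatrix, mb: ConfusionMatrix) -> DeltaMatrix:
    if tuple(ma.class_order) != tuple(mb.class_order):
        raise ValueError("class orders differ between the two matrices")
    return DeltaMatrix(ma.counts - mb.counts, tuple(ma.class_order))


def f1_correlation(report_a: MetricsReport, report_b: MetricsReport) -> float:
    """Pearson correlation of per-class F1 between two schemes (utility)."""
    a, b = report_a.f1, report_b.f1
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def build_report(
    results: Mapping[str, Mapping[str, dict]],
    metric: str = "f1",
    decimals: int = 3,
) -> dict[str, pd.DataFrame]:
    """Tabulate macro metrics and IIR across conditions and classifiers.

    ``results[condition][family]`` is a dict with keys ``"10-fold"`` and/or
    ``"loho"`` mapping to :class:`MetricsReport`. Returns a table per
    scheme (rows = conditions plus an unweighted ``Mean`` row, columns =
    classifier families) and an ``iir`` table where both schemes exist,
    rounded to the conventional 3 decimals.
    """
    conditions = list(results)
    families = list(dict.fromkeys(fam for cond in results.values() for fam in cond))

    def macro(rep: MetricsReport) -> float:
        return {"f1": rep.macro_f1, "precision": rep.macro_precision,
                "recall": rep.macro_recall}[metric]

    tables: dict[str, pd.DataFrame] = {}
    for scheme in ("10-fold", "loho"):
        rows = {}
        for cond in conditions:
            row = {}
            for fam in families:
                rep = results[cond].get(fam, {}).get(scheme)
                row[fam] = macro(rep) if rep is not None else np.nan
            rows[cond] = row
        df = pd.DataFrame.from_dict(rows, orient="index", columns=families)
        if df.notna().any().any():
            df.loc["Mean"] = df.mean(axis=0)
            tables[scheme] = df.round(decimals)
    if "10-fold" in tables and "loho" in tables:
        iir = tables["loho"].drop(index="Mean") / tables["10-fold"].drop(index="Mean")
        iir.loc["Mean"] = iir.mean(axis=0)
        tables["iir"] = iir.round(decimals)
    return tables
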