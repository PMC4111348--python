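"""Prescreening decisions and screening-performance evaluation.

A per-sample Raman result is turned into a three-way decision: ``unusable``
(fluorescence swamped every scan, no ratio), ``viable`` (ratio above a
threshold, or prominent C-H bands), or ``suspect``.  Against wet-chemistry
truth (collagen yield above a floor), the ratio threshold is evaluated as a
binary classifier via its confusion matrix and Youden's J, and an operating
threshold can be chosen by exhaustive sweep over the observed ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .band_analysis import SampleRamanResult
from .spectra_io import PairedDataset

__all__ = [
    "ScreeningDecision",
    "ScreenEvaluation",
    "DegenerateTruthError",
    "classify_sample",
    "evaluate_screen",
    "choose_threshold",
]


class DegenerateTruthError(ValueError):
    """All evaluable samples fall in one truth class; J is undefined."""


@dataclass(frozen=True)
class ScreeningDecision:
    sample_id: str
    decision: str  # viable | suspect | unusable
    basis: str  # ratio_threshold | ch_presence | fluorescence

    def __post_init__(self) -> None:
        if (self.decision == "unusable") != (self.basis == "fluorescence"):
            raise ValueError("unusable decisions must rest on fluorescence basis")


@dataclass(frozen=True)
class ScreenEvaluation:
    """Confusion matrix and derived rates for one (ratio, collagen) cut.

    Truth is strict (`pct_collagen > collagen_threshold`); prediction is
    inclusive (`raman_ratio >= ratio_threshold`), so confusion counts are
    reproducible at tied values.
    """

    ratio_threshold: float
    collagen_threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int  # records missing ratio or collagen, reported separately

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def classify_sample(
    result: SampleRamanResult, ratio_threshold: float
) -> ScreeningDecision:
    """Three-way prescreening decision for one sample.

    Fluorescence failure takes precedence (no ratio exists); otherwise the
    sample is viable when its mean ratio reaches the threshold or its C-H
    bands are prominent, and suspect otherwise.
    """
    if result.fluorescence_failed or result.ratio_mean is None:
        return ScreeningDecision(result.sample_id, "unusable", "fluorescence")
    if result.ratio_mean >= ratio_threshold:
        return ScreeningDecision(result.sample_id, "viable", "ratio_threshold")
    if result.ch_presence == "prominent":
        return ScreeningDecision(result.sample_id, "viable", "ch_presence")
    return ScreeningDecision(result.sample_id, "suspect", "ratio_threshold")


def _evaluable(dataset: PairedDataset) -> tuple[np.ndarray, np.ndarray, int]:
    df = dataset.records
    ok = df["raman_ratio"].notna() & df["pct_collagen"].notna()
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("no evaluable records (need both ratio and collagen)")
    return (
        df.loc[ok, "raman_ratio"].to_numpy(float),
        df.loc[ok, "pct_collagen"].to_numpy(float),
        n_excluded,
    )


def evaluate_screen(
    dataset: PairedDataset,
    ratio_threshold: float,
    collagen_threshold: float = 1.0,
) -> ScreenEvaluation:
    """Confusion matrix of ratio >= threshold against collagen > floor."""
    ratio, collagen, n_excluded = _evaluable(dataset)
    truth = collagen > collagen_threshold
    pred = ratio >= ratio_threshold
    return ScreenEvaluation(
        ratio_threshold=float(ratio_threshold),
        collagen_threshold=float(collagen_threshold),
        tp=int(np.sum(truth & pred)),
        fp=int(np.sum(~truth & pred)),
        tn=int(np.sum(~truth & ~pred)),
        fn=int(np.sum(truth & ~pred)),
        n_excluded=n_excluded,
    )


def choose_threshold(
    dataset: PairedDataset, collagen_threshold: float = 1.0
) -> tuple[float, ScreenEvaluation]:
    """Youden-optimal ratio threshold by exhaustive sweep.

    Every observed ratio is a candidate cut (prediction is ratio >= cut).
    Ties in J break toward higher sensitivity (the lower cut).  The returned
    threshold is the midpoint between the chosen cut and the next observed
    ratio below it — the natural operating point between the two classes —
    and the evaluation at that midpoint.  Raises
    :class:`DegenerateTruthError` when all evaluable samples share one truth
    class.
    """
    ratio, collagen, _ = _evaluable(dataset)
    truth = collagen > collagen_threshold
    if truth.all() or not truth.any():
        raise DegenerateTruthError(
            "all evaluable samples in one truth class; Youden's J undefined"
        )
    candidates = np.unique(ratio)
    best_j, best_cut = -np.inf, None
    for cut in candidates:  # ascending: lower cuts (higher sensitivity) win ties
        pred = ratio >= cut
        tp = np.sum(truth & pred)
        fp = np.sum(~truth & pred)
        tn = np.sum(~truth & ~pred)
        fn = np.sum(truth & ~pred)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j:
            best_j, best_cut = j, cut
    below = candidates[candidates < best_cut]
    threshold = float((best_cut + below[-1]) / 2.0) if below.size else float(best_cut)
    return threshold, evaluate_screen(dataset, threshold, collagen_threshold)
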