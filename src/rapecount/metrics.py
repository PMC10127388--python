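"""Count-evaluation statistics over paired manual and inferred counts.

Seven regression-counting metrics are computed from per-image pairs
(M_i = manual count, I_i = inferred count):

    Acc   = 1 - (1/n) sum |M_i - I_i| / M_i
    MAE   = (1/n) sum |M_i - I_i|
    rMAE  = sqrt(MAE)
    rMSE  = sqrt((1/n) sum (M_i - I_i)^2)
    rrMSE = 100 * rMSE / mean(M)
    R^2   = 1 - sum (M_i - I_i)^2 / sum (I_i - mean(I))^2

Note the R^2 convention: the denominator is the *inferred* counts' spread,
which differs from the textbook coefficient of determination (denominator
= manual spread). Both are available via ``r2_denominator``; the inferred
form is the default for comparability with the counting literature this
follows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["EvaluationSet", "CountMetrics", "evaluate_counts", "write_report"]


@dataclass(frozen=True)
class EvaluationSet:
    """Paired counts across a test set; one item per image."""

    items: tuple[tuple[str, float, float], ...]  # (image_id, manual, inferred)

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("evaluation set needs at least one item")
        for image_id, m, i in self.items:
            if not (math.isfinite(m) and math.isfinite(i)) or m < 0 or i < 0:
                raise ValueError(f"invalid counts for {image_id!r}: M={m}, I={i}")

    @property
    def n(self) -> int:
        return len(self.items)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        m = np.array([it[1] for it in self.items], dtype=float)
        i = np.array([it[2] for it in self.items], dtype=float)
        return m, i

    @staticmethod
    def from_pairs(manual, inferred, ids=None) -> "EvaluationSet":
        manual = list(manual)
        inferred = list(inferred)
        if ids is None:
            ids = [f"img{k:04d}" for k in range(len(manual))]
        return EvaluationSet(tuple(zip(ids, map(float, manual), map(float, inferred))))


@dataclass(frozen=True)
class CountMetrics:
    acc: float
    mae: float
    rmae: float
    rmse: float
    rrmse: float
    r2: float  # may be nan when undefined (all inferred counts identical)

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc, "mae": self.mae, "rmae": self.rmae,
            "rmse": self.rmse, "rrmse": self.rrmse, "r2": self.r2,
        }


def evaluate_counts(
    ev: EvaluationSet,
    *,
    r2_denominator: str = "inferred",
    round_counts: bool = False,
) -> CountMetrics:
    """Compute the seven count metrics for one evaluation set.

    Items with M_i = 0 are excluded from the Acc average only (the accuracy
    term divides by M_i) and kept for everything else. ``round_counts``
    rounds inferred counts to the nearest integer first — density sums are
    real-valued, and both conventions are found in practice.
    """
    if r2_denominator not in ("inferred", "manual"):
        raise ValueError("r2_denominator must be 'inferred' or 'manual'")
    m, i = ev.arrays()
    if round_counts:
        i = np.round(i)
    err = m - i
    abs_err = np.abs(err)

    pos = m > 0
    if not pos.all():
        logger.warning(
            "Acc: excluding %d image(s) with zero manual count", int((~pos).sum())
        )
    if pos.any():
        acc = float(1.0 - np.mean(abs_err[pos] / m[pos]))
    else:
        acc = math.nan

    mae = float(abs_err.mean())
    rmae = math.sqrt(mae)
    rmse = float(np.sqrt(np.mean(err**2)))
    m_bar = float(m.mean())
    if m_bar == 0:
        raise ZeroDivisionError("rrMSE undefined: mean manual count is zero")
    rrmse = 100.0 * rmse / m_bar

    ref = i if r2_denominator == "inferred" else m
    ss_ref = float(((ref - ref.mean()) ** 2).sum())
    if ss_ref == 0.0:
        logger.warning("R^2 undefined: zero spread in %s counts", r2_denominator)
        r2 = math.nan
    else:
        r2 = 1.0 - float((err**2).sum()) / ss_ref
    return CountMetrics(acc, mae, rmae, rmse, rrmse, r2)


def write_report(ev: EvaluationSet, metrics: CountMetrics, path: str | Path) -> None:
    """Per-image CSV (image_id, manual, inferred) plus a summary row."""
    rows = [
        {"image_id": iid, "manual": m, "inferred": i} for iid, m, i in ev.items
    ]
    df = pd.DataFrame(rows)
    summary = {"image_id": "SUMMARY", "manual": df["manual"].mean(),
               "inferred": df["inferred"].mean()}
    summary.update(metrics.as_dict())
    df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    df.to_csv(path, index=False)
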