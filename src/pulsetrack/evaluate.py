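"""Accuracy evaluation against a reference HR series.

The headline metric is the mean absolute error (MAE) in bpm between the
pipeline output and a reference series (e.g. ECG-derived HR), after
matching reference points to output grid points by nearest timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EvaluationError
from .tracking import HrEstimate, HrTrace

__all__ = ["EvaluationResult", "align_and_mae"]


@dataclass
class EvaluationResult:
    """MAE with the spread of the absolute errors, in bpm."""

    mae: float
    sd_abs_err: float
    per_point_abs_err: np.ndarray
    n_points: int

    def __str__(self) -> str:
        return f"MAE {self.mae:.2f} ± {self.sd_abs_err:.2f} bpm (n={self.n_points})"


def align_and_mae(
    estimate: HrTrace,
    reference: list[HrEstimate] | HrTrace,
    tolerance_s: float = 1.0,
) -> EvaluationResult:
    """Match reference points to the estimate grid and compute the MAE.

    Each present reference point is paired with the nearest estimate grid
    point within ``tolerance_s`` (default 1 s, half the 2 s shift);
    unmatched points are ignored.
    """
    if isinstance(reference, HrTrace):
        ref_t, ref_hr = reference.t, reference.hr
    else:
        present = [e for e in reference if e.present]
        ref_t = np.array([e.t for e in present])
        ref_hr = np.array([e.hr for e in present])
    if estimate.t.size == 0 or ref_t.size == 0:
        raise EvaluationError("empty estimate or reference series")

    if estimate.t.size == 1:
        nearest = np.zeros(ref_t.size, dtype=int)
    else:
        idx = np.clip(np.searchsorted(estimate.t, ref_t), 1, estimate.t.size - 1)
        left_closer = np.abs(ref_t - estimate.t[idx - 1]) <= np.abs(estimate.t[idx] - ref_t)
        nearest = np.where(left_closer, idx - 1, idx)
    matched = np.abs(estimate.t[nearest] - ref_t) <= tolerance_s
    if not matched.any():
        raise EvaluationError("no reference point within tolerance of the estimate grid")

    err = np.abs(estimate.hr[nearest[matched]] - ref_hr[matched])
    return EvaluationResult(
        mae=float(err.mean()),
        sd_abs_err=float(err.std(ddof=0)),
        per_point_abs_err=err,
        n_points=int(err.size),
    )
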