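"""Threshold sweep, error metrics, RE regression and its inversion.

The relative identification error RE = FP/(TP+FP) is computed at a grid of
distance thresholds equally spaced between 0 and the largest query–best-match
distance.  An ordinary least-squares polynomial (linear by default) is fitted
to the (threshold, RE) points and inverted to find the *ad hoc* threshold at
which the fitted RE equals a user-chosen target (5% by default).  When no
real root lies within the swept domain the target error is unreachable for
the library and a warning result is returned instead of an extrapolated
threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P

from .identify import BestMatchResult, Outcome, classify_best_close_match

__all__ = [
    "AMBIGUITY_MODES",
    "ThresholdMetrics",
    "REModel",
    "AdhocResult",
    "FittingError",
    "threshold_grid",
    "metrics_at_threshold",
    "sweep",
    "sweep_table",
    "fit_re_curve",
    "solve_adhoc_threshold",
]

AMBIGUITY_MODES = ("incorrect", "ignored", "correct")

UNREACHABLE_MESSAGE = (
    "cannot find an ad hoc distance threshold for the chosen error probability"
)


class FittingError(ValueError):
    """Raised when too few defined RE points are available for the regression."""


@dataclass(frozen=True)
class ThresholdMetrics:
    """Counts and error metrics of best close match at one threshold.

    Counts are raw outcome tallies; the metrics have the chosen ambiguity
    mode already applied.  Undefined metrics (empty denominator) are NaN.
    """

    t: float
    tp: int
    fp: int
    fp_ambiguous: int
    tn: int
    fn: int
    undefined: int
    mode: str
    re: float
    oe: float
    accuracy: float
    precision: float

    @property
    def n_queries(self) -> int:
        return self.tp + self.fp + self.fp_ambiguous + self.tn + self.fn + self.undefined


def threshold_grid(t_max: float, n_points: int = 30) -> np.ndarray:
    """Equally spaced thresholds from 0 to t_max inclusive."""
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if t_max == 0:
        warnings.warn(
            "largest query-best-match distance is 0; degenerate single-point grid"
        )
        return np.array([0.0])
    return np.linspace(0.0, t_max, n_points)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan

def metrics_at_threshold(
    results: list[BestMatchResult], t: float, mode: str = "incorrect"
) -> ThresholdMetrics:
    """Outcome counts and RE/OE/accuracy/precision at one threshold.

    Ambiguity modes: ``incorrect`` folds FP_ambiguous into FP, ``correct``
    folds it into TP, ``ignored`` drops ambiguous queries from numerators and
    denominators.  Queries with no defined distance are excluded from all
    denominators and reported in the ``undefined`` count.
    """
    if mode not in AMBIGUITY_MODES:
        raise ValueError(f"unknown ambiguity mode {mode!r}; choose from {AMBIGUITY_MODES}")
    tally = {o: 0 for o in Outcome}
    for r in results:
        tally[classify_best_close_match(r, t)] += 1
    tp, fp, fpa = tally[Outcome.TP], tally[Outcome.FP], tally[Outcome.FP_AMBIGUOUS]
    tn, fn, und = tally[Outcome.TN], tally[Outcome.FN], tally[Outcome.UNDEFINED]
    if mode == "incorrect":
        tp_eff, fp_eff, n_eff = tp, fp + fpa, tp + fp + fpa + tn + fn
    elif mode == "correct":
        tp_eff, fp_eff, n_eff = tp + fpa, fp, tp + fp + fpa + tn + fn
    else:  # ignored
        tp_eff, fp_eff, n_eff = tp, fp, tp + fp + tn + fn
    return ThresholdMetrics(
        t=float(t),
        tp=tp,
        fp=fp,
        fp_ambiguous=fpa,
        tn=tn,
        fn=fn,
        undefined=und,
        mode=mode,
        re=_safe_div(fp_eff, tp_eff + fp_eff),
        oe=_safe_div(fp_eff + fn, n_eff),
        accuracy=_safe_div(tp_eff + tn, n_eff),
        precision=_safe_div(tp_eff, tp_eff + fp_eff),
    )


def sweep(
    results: list[BestMatchResult],
    grid: np.ndarray,
    mode: str = "incorrect",
) -> list[ThresholdMetrics]:
    """Metrics at every grid threshold, in grid order."""
    if len(grid) == 0:
        raise ValueError("empty threshold grid")
    return [metrics_at_threshold(results, t, mode) for t in grid]


def sweep_table(metrics: list[ThresholdMetrics]) -> pd.DataFrame:
    """Sweep results as a flat table (one row per threshold)."""
    return pd.DataFrame(
        {
            "t": [m.t for m in metrics],
            "TP": [m.tp for m in metrics],
            "FP": [m.fp for m in metrics],
            "FP_ambiguous": [m.fp_ambiguous for m in metrics],
            "TN": [m.tn for m in metrics],
            "FN": [m.fn for m in metrics],
            "undefined": [m.undefined for m in metrics],
            "RE": [m.re for m in metrics],
            "OE": [m.oe for m in metrics],
            "accuracy": [m.accuracy for m in metrics],
            "precision": [m.precision for m in metrics],
        }
    )


@dataclass
class REModel:
    """OLS polynomial fit of RE against threshold.

    ``coefficients`` are in ascending order (constant first).  ``fit_points``
    holds the (t, RE) pairs actually used; thresholds with undefined RE are
    excluded before fitting.  ``domain`` is the swept interval [0, t_max];
    root finding never extrapolates beyond it.
    """

    fit_kind: str
    degree: int
    coefficients: np.ndarray
    fit_points: pd.DataFrame
    domain: tuple[float, float]

    def predict(self, t) -> np.ndarray:
        return P.polyval(np.asarray(t, dtype=float), self.coefficients)


@dataclass
class AdhocResult:
    """Solved *ad hoc* threshold (or unreachable marker) for a target RE."""

    target_re: float
    threshold: float | None
    model: REModel
    message: str

    @property
    def reachable(self) -> bool:
        return self.threshold is not None

    def to_dict(self) -> dict:
        return {
            "target_re": self.target_re,
            "threshold": self.threshold,
            "fit_kind": self.model.fit_kind,
            "degree": self.model.degree,
            "coefficients": [float(c) for c in self.model.coefficients],
            "message": self.message,
        }


def fit_re_curve(
    ts: np.ndarray,
    res: np.ndarray,
    fit_kind: str = "linear",
    degree: int | None = None,
) -> REModel:
    """Fit RE against threshold by ordinary least squares.

    ``fit_kind`` is ``linear`` (degree forced to 1) or ``polynomial``
    (degree 2 unless given).  Points with undefined (NaN) RE are dropped; at
    least degree + 1 defined points are required.
    """
    ts = np.asarray(ts, dtype=float)
    res = np.asarray(res, dtype=float)
    if fit_kind == "linear":
        degree = 1
    elif fit_kind == "polynomial":
        degree = 2 if degree is None else int(degree)
        if degree < 1:
            raise ValueError("degree must be >= 1")
    else:
        raise ValueError(f"unknown fit kind {fit_kind!r}")
    ok = ~np.isnan(res)
    if ok.sum() < degree + 1:
        raise FittingError(
            f"only {int(ok.sum())} thresholds have a defined RE; "
            f"a degree-{degree} fit needs at least {degree + 1} "
            "(try a denser threshold grid)"
        )
    coeffs = P.polyfit(ts[ok], res[ok], degree)
    return REModel(
        fit_kind=fit_kind,
        degree=degree,
        coefficients=coeffs,
        fit_points=pd.DataFrame({"t": ts[ok], "RE": res[ok]}),
        domain=(float(ts.min()), float(ts.max())),
    )


def solve_adhoc_threshold(model: REModel, target_re: float = 0.05) -> AdhocResult:
    """Invert the fitted RE curve at a target error rate.

    Returns the smallest real root of fitted_RE(t) = target_re inside the
    swept domain.  If no such root exists the target is unreachable for this
    library and the result carries a warning message instead of a threshold;
    the curve is never extrapolated beyond the domain.
    """
    if not 0 <= target_re < 1:
        raise ValueError("target_re must be in [0, 1)")
    lo, hi = model.domain
    shifted = model.coefficients.copy()
    shifted[0] -= target_re
    if np.allclose(shifted, 0.0):
        roots = np.array([lo])
    else:
        roots = P.polyroots(shifted)
    eps = 1e-9 * max(1.0, hi)
    real = [
        min(max(float(r.real), lo), hi)
        for r in np.atleast_1d(roots)
        if abs(r.imag) < 1e-9 and lo - eps <= r.real <= hi + eps
    ]
    if real:
        t_star = min(real)
        return AdhocResult(
            target_re=target_re,
            threshold=t_star,
            model=model,
            message=f"for a RE of {target_re:g} use a threshold of {t_star:.4f}",
        )
    return AdhocResult(
        target_re=target_re,
        threshold=None,
        model=model,
        message=f"{UNREACHABLE_MESSAGE} (target RE = {target_re:g})",
    )
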