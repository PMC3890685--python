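"""Estimator front-ends for threshold calibration and identification.

`AdHocThreshold` is the calibration step: given a reference library it runs
leave-one-out best-close-match identification over a threshold sweep, fits
the RE-vs-threshold regression and inverts it at the target error rate.
`BestCloseMatchClassifier` applies the method to new queries: nearest
reference within the threshold wins, otherwise the query is left
unidentified.  Both follow scikit-learn conventions (``get_params`` /
``set_params``, fitted attributes with a trailing underscore) and accept
either a :class:`~closematch.library.BarcodeLibrary` or parallel sequence /
label arrays.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import distance as dist
from . import identify as ident
from . import threshold as thr
from .library import BarcodeLibrary

__all__ = ["AdHocThreshold", "BestCloseMatchClassifier"]


def _as_library(X, y) -> BarcodeLibrary:
    if isinstance(X, BarcodeLibrary):
        if y is not None:
            raise ValueError("y must be None when X is a BarcodeLibrary")
        return X
    if y is None:
        raise ValueError("species labels y are required when X is raw sequences")
    seqs = [str(s) for s in X]
    labels = [str(s) for s in y]
    if len(seqs) != len(labels):
        raise ValueError("X and y have different lengths")
    ids = [f"q{i}_{lab}" for i, lab in enumerate(labels)]
    return BarcodeLibrary.from_sequences(ids, labels, seqs)


class AdHocThreshold(BaseEstimator):
    """Calibrate the distance threshold that yields a target relative error.

    Parameters
    ----------
    metric : {"p", "jc69", "k2p"}, default="k2p"
        Pairwise distance model; K2P is the conventional barcoding choice.
    target_re : float, default=0.05
        Desired relative identification error among accepted identifications.
    n_thresholds : int, default=30
        Number of sweep points between 0 and the largest query–best-match
        distance; more points sharpen the regression.
    fit_kind : {"linear", "polynomial"}, default="linear"
    degree : int, default=2
        Polynomial degree when ``fit_kind="polynomial"``.
    ambiguity : {"incorrect", "ignored", "correct"}, default="incorrect"
        How tied best-match sets mixing species enter the error metrics.

    Attributes
    ----------
    threshold_ : float or None
        The solved *ad hoc* threshold; None when the target RE is
        unreachable for the library.
    reachable_ : bool
    message_ : str
        Human-readable summary ("for a RE of ... use a threshold of ...",
        or the unreachable warning).
    re_model_ : closematch.threshold.REModel
    sweep_ : pandas.DataFrame
        Counts and metrics at every swept threshold.
    loo_results_ : list of BestMatchResult
    best_match_metrics_ : closematch.threshold.ThresholdMetrics
        Metrics of plain best match (no threshold), i.e. the sweep endpoint.
    """

    def __init__(
        self,
        metric: str = "k2p",
        target_re: float = 0.05,
        n_thresholds: int = 30,
        fit_kind: str = "linear",
        degree: int = 2,
        ambiguity: str = "incorrect",
    ):
        self.metric = metric
        self.target_re = target_re
        self.n_thresholds = n_thresholds
        self.fit_kind = fit_kind
        self.degree = degree
        self.ambiguity = ambiguity

    def fit(self, X, y=None):
        """Run the full calibration on a reference library."""
        lib = _as_library(X, y)
        matrix = dist.pairwise_matrix(lib, self.metric)
        results = ident.leave_one_out(lib, matrix)
        bm = [r.bm_distance for r in results if r.defined]
        if not bm:
            raise ValueError("no defined query-best-match distance in the library")
        grid = thr.threshold_grid(max(bm), self.n_thresholds)
        metrics = thr.sweep(results, grid, self.ambiguity)
        model = thr.fit_re_curve(
            grid, np.array([m.re for m in metrics]), self.fit_kind, self.degree
        )
        solution = thr.solve_adhoc_threshold(model, self.target_re)

        self.library_ = lib
        self.distance_matrix_ = matrix
        self.loo_results_ = results
        self.grid_ = grid
        self.metrics_ = metrics
        self.sweep_ = thr.sweep_table(metrics)
        self.re_model_ = model
        self.result_ = solution
        self.threshold_ = solution.threshold
        self.reachable_ = solution.reachable
        self.message_ = solution.message
        self.best_match_metrics_ = metrics[-1]
        self.red_flags_ = ident.red_flags(lib, results)
        return self

    def fitted_re(self, t):
        """Evaluate the fitted RE curve at thresholds ``t``."""
        check_is_fitted(self, "re_model_")
        return self.re_model_.predict(t)


class BestCloseMatchClassifier(BaseEstimator, ClassifierMixin):
    """Assign species to queries by best close match against a reference.

    A query takes the species of its nearest reference sequence(s) when that
    minimum distance is within ``threshold``; queries beyond the threshold,
    with no defined distance, or with a tied best-match set mixing species
    are labelled ``unidentified_label``.  With ``threshold=None`` the
    threshold is calibrated at fit time by :class:`AdHocThreshold`.

    Attributes
    ----------
    classes_ : ndarray of reference species names.
    threshold_ : float
        The acceptance threshold actually used.
    calibrator_ : AdHocThreshold, only when calibration ran at fit time.
    """

    def __init__(
        self,
        metric: str = "k2p",
        threshold: float | None = None,
        target_re: float = 0.05,
        unidentified_label: str = "unidentified",
    ):
        self.metric = metric
        self.threshold = threshold
        self.target_re = target_re
        self.unidentified_label = unidentified_label

    def fit(self, X, y=None):
        lib = _as_library(X, y)
        self.library_ = lib
        self.classes_ = np.unique(lib.species)
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
        else:
            cal = AdHocThreshold(metric=self.metric, target_re=self.target_re).fit(lib)
            self.calibrator_ = cal
            if not cal.reachable_:
                raise ValueError(
                    f"threshold calibration failed: {cal.message_}; "
                    "pass an explicit threshold instead"
                )
            self.threshold_ = float(cal.threshold_)
        return self

    def _best_match(self, seq: str):
        counts = [
            dist.site_pair_counts(seq, rec.residues) for rec in self.library_.records
        ]
        d = np.array(
            [dist.distance_from_counts(c, self.metric) for c in counts]
        )
        if np.all(np.isnan(d)):
            return math.nan, frozenset()
        dmin = np.nanmin(d)
        ties = np.nonzero(d <= dmin + ident.TIE_TOL)[0]
        species = frozenset(self.library_.species[j] for j in ties)
        return float(dmin), species

    def predict(self, X):
        """Species name per query, or the unidentified label."""
        check_is_fitted(self, "threshold_")
        out = []
        for seq in X:
            dmin, species = self._best_match(str(seq))
            if (
                math.isnan(dmin)
                or dmin > self.threshold_
                or len(species) != 1
            ):
                out.append(self.unidentified_label)
            else:
                out.append(next(iter(species)))
        return np.array(out, dtype=object)

    def predict_detail(self, X) -> pd.DataFrame:
        """Per-query best-match distance, tied species and assignment."""
        check_is_fitted(self, "threshold_")
        rows = []
        for seq in X:
            dmin, species = self._best_match(str(seq))
            accepted = not math.isnan(dmin) and dmin <= self.threshold_
            rows.append(
                {
                    "bm_distance": dmin,
                    "match_species": ",".join(sorted(species)),
                    "accepted": accepted,
                    "assignment": next(iter(species))
                    if accepted and len(species) == 1
                    else self.unidentified_label,
                }
            )
        return pd.DataFrame(rows)

    def score(self, X, y):
        """Fraction of queries assigned their true species name."""
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))
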