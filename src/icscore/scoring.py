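"""Immune cell score (ICS) construction with ROC-derived density cutoffs.

The ICS combines four density components — CD3⁺ and CD8⁺ cells in the
tumour core and the invasive margin — each binarized high/low at a
cutoff.  Cutoffs are derived per component from a receiver operating
characteristic against three-year disease-specific mortality, taking the
threshold that maximises Youden's J (sensitivity + specificity − 1), with
low density oriented as the positive test for death since high
infiltration is protective.  The score is the number of "high" calls
(0–4) and is grouped low (0–1), moderate (2), high (3–4).

Patients censored before 36 months have an undefined three-year status
and are by default excluded from cutoff fitting (they are still scored
and enter the survival analysis); a flag can instead treat them as
survivors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "COMPONENTS",
    "CutoffSet",
    "FIXED_CUTOFFS",
    "NoCutoffError",
    "three_year_status",
    "fit_cutoff",
    "binarize",
    "compute_ics",
    "score_to_group",
    "ICSScorer",
]

#: the four ICS components, in canonical column order.
COMPONENTS = ("CD3_core", "CD3_margin", "CD8_core", "CD8_margin")

#: months defining the mortality window for cutoff derivation.
THREE_YEARS = 36.0

GROUPS = ("low", "moderate", "high")


class NoCutoffError(RuntimeError):
    """ROC cutoff undefined: all usable outcomes identical."""


@dataclass(frozen=True)
class CutoffSet:
    """Four density cutoffs (cells/mm²) for one technique."""

    technique: str
    cutoffs: dict  # component name -> cells/mm²
    derivation: str  # "fitted" | "fixed"

    def as_array(self) -> np.ndarray:
        return np.array([self.cutoffs[c] for c in COMPONENTS], dtype=float)


#: previously published cutoffs (cells/mm²), usable as a fixed CutoffSet.
#: They did not transfer between cohorts in the original report, so the
#: default pipeline refits; these ship for reference and comparison runs.
FIXED_CUTOFFS = {
    "hotspot": CutoffSet(
        "hotspot",
        dict(zip(COMPONENTS, (1116.0, 1314.0, 1185.0, 998.0))),
        "fixed",
    ),
    "whole_section": CutoffSet(
        "whole_section",
        dict(zip(COMPONENTS, (396.0, 370.0, 120.0, 157.0))),
        "fixed",
    ),
}


def three_year_status(time_months: float, event_dss: int) -> str:
    """Three-year disease-specific mortality status.

    Returns ``"dead_of_disease"`` for a disease death at ≤ 36 months,
    ``"survivor"`` for follow-up reaching 36 months without disease
    death, and ``"excluded_censored"`` for censoring before 36 months.
    """
    if time_months <= 0 or not np.isfinite(time_months):
        raise ValueError("time_months must be positive and finite")
    if event_dss == 1 and time_months <= THREE_YEARS:
        return "dead_of_disease"
    if time_months >= THREE_YEARS:
        return "survivor"
    return "excluded_censored"


def _statuses(time, event_dss) -> np.ndarray:
    return np.array(
        [three_year_status(t, e) for t, e in zip(np.asarray(time, float),
                                                 np.asarray(event_dss, int))],
        dtype=object,
    )


def fit_cutoff(densities, dead: np.ndarray) -> float:
    """ROC-optimal cutoff for one component by Youden's J.

    ``dead`` is a boolean vector (True = dead of disease within three
    years) aligned with ``densities``; excluded patients must already be
    removed.  "Test positive" is density < c.  Candidate thresholds are
    the midpoints between consecutive sorted unique densities; among
    maximisers of J the smallest threshold is returned.
    """
    d = np.asarray(densities, dtype=float)
    dead = np.asarray(dead, dtype=bool)
    if len(d) != len(dead):
        raise ValueError("densities and outcomes must align")
    n_dead = dead.sum()
    n_surv = (~dead).sum()
    if n_dead == 0 or n_surv == 0:
        raise NoCutoffError("need at least one death and one survivor")
    uniq = np.unique(d)
    if len(uniq) < 2:
        raise NoCutoffError("all densities identical: no threshold exists")
    cands = (uniq[:-1] + uniq[1:]) / 2
    # sens = P(d < c | dead), spec = P(d >= c | survivor)
    sens = np.array([(d[dead] < c).mean() for c in cands])
    spec = np.array([(d[~dead] >= c).mean() for c in cands])
    j = sens + spec - 1.0
    best = np.nonzero(j == j.max())[0][0]  # ties -> smallest c (cands sorted)
    return float(cands[best])


def binarize(density: float, cutoff: float) -> str:
    """Call a component high/low; the cutoff itself counts as high."""
    if density < 0 or cutoff < 0:
        raise ValueError("density and cutoff must be nonnegative")
    return "high" if density >= cutoff else "low"


def score_to_group(score: int) -> str:
    if score in (0, 1):
        return "low"
    if score == 2:
        return "moderate"
    if score in (3, 4):
        return "high"
    raise ValueError(f"score must be 0..4, got {score}")


def compute_ics(component_calls: dict) -> tuple[int, str]:
    """Score and group from the four high/low calls.

    Raises ``ValueError`` when a component is missing (such a patient is
    unscorable for the technique and must be flagged by the caller).
    """
    missing = [c for c in COMPONENTS if component_calls.get(c) not in ("low", "high")]
    if missing or set(component_calls) - set(COMPONENTS):
        raise ValueError(f"need exactly the four components; missing/invalid: {missing}")
    score = sum(component_calls[c] == "high" for c in COMPONENTS)
    return score, score_to_group(score)


class ICSScorer:
    """Immune cell score classifier, scikit-learn style.

    ``fit(X, y)`` derives the four ROC cutoffs; ``transform(X)`` returns
    scores 0–4; ``predict(X)`` returns the low/moderate/high group.

    Parameters
    ----------
    cutoffs : CutoffSet, optional
        Fixed cutoffs; when given, ``fit`` only validates and stores them
        (``y`` may be None).
    censored_as_survivors : bool
        Treat patients censored before 36 months as three-year survivors
        in cutoff fitting instead of excluding them.

    Attributes
    ----------
    cutoffs_ : ndarray of shape (4,)
        Fitted (or fixed) cutoffs in :data:`COMPONENTS` order.
    n_excluded_ : int
        Patients dropped from cutoff fitting as censored before 36 months.

    Notes
    -----
    ``X`` is an (n, 4) array or DataFrame of densities in cells/mm²,
    columns in :data:`COMPONENTS` order; ``y`` is an (n, 2) array of
    (time_months, event_dss).  Rows of ``X`` with NaN components yield
    NaN scores (unscorable patients); all four cutoffs are fitted on the
    per-component non-missing subsets.
    """

    def __init__(self, cutoffs: CutoffSet | None = None,
                 censored_as_survivors: bool = False):
        self.cutoffs = cutoffs
        self.censored_as_survivors = censored_as_survivors

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"cutoffs": self.cutoffs,
                "censored_as_survivors": self.censored_as_survivors}

    def set_params(self, **params) -> "ICSScorer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(COMPONENTS)]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(COMPONENTS):
            raise ValueError(f"X must have {len(COMPONENTS)} columns "
                             f"({', '.join(COMPONENTS)})")
        return X

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y=None) -> "ICSScorer":
        X = self._as_matrix(X)
        if self.cutoffs is not None:
            self.cutoffs_ = self.cutoffs.as_array()
            self.derivation_ = "fixed"
            self.n_excluded_ = 0
            return self
        if y is None:
            raise ValueError("y (time, event_dss) required to fit cutoffs")
        y = np.asarray(y, dtype=float)
        status = _statuses(y[:, 0], y[:, 1])
        if self.censored_as_survivors:
            usable = np.ones(len(status), dtype=bool)
            dead_all = status == "dead_of_disease"
        else:
            usable = status != "excluded_censored"
            dead_all = status == "dead_of_disease"
        self.n_excluded_ = int((~usable).sum())
        cuts = []
        for idx in range(len(COMPONENTS)):
            col = X[:, idx]
            keep = usable & ~np.isnan(col)
            cuts.append(fit_cutoff(col[keep], dead_all[keep]))
        self.cutoffs_ = np.array(cuts)
        self.derivation_ = "fitted"
        return self

    def transform(self, X) -> np.ndarray:
        """ICS 0–4 per patient; NaN where any component is missing."""
        X = self._as_matrix(X)
        calls = X >= self.cutoffs_
        score = calls.sum(axis=1).astype(float)
        score[np.isnan(X).any(axis=1)] = np.nan
        return score

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def predict(self, X) -> np.ndarray:
        """Group labels low / moderate / high; None where unscorable."""
        score = self.transform(X)
        return np.array(
            [None if np.isnan(s) else score_to_group(int(s)) for s in score],
            dtype=object,
        )

    def component_calls(self, X) -> pd.DataFrame:
        """Per-component high/low calls as a DataFrame."""
        X = self._as_matrix(X)
        calls = np.where(np.isnan(X), None,
                         np.where(X >= self.cutoffs_, "high", "low"))
        return pd.DataFrame(calls, columns=list(COMPONENTS))

    def cutoff_set(self, technique: str) -> CutoffSet:
        """Fitted cutoffs packaged with their derivation tag."""
        return CutoffSet(technique, dict(zip(COMPONENTS, map(float, self.cutoffs_))),
                         self.derivation_)
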