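"""Component-level summaries of a fitted GFA posterior.

A component is one latent dimension together with its per-view loading
columns.  It is *active* in a view when the posterior inclusion
probability of the corresponding indicator exceeds a threshold, and
*empty* when active in no view — empty components are the evidence that
the chosen K was large enough.

The model is identifiable only up to a joint permutation and sign flip
of components, so comparisons against ground truth (or between runs) go
through an exact one-to-one assignment on absolute score correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .gfa_model import LatentState, ViewData
from .gibbs_sampler import PosteriorSummary

__all__ = [
    "component_activity",
    "prune_empty_components",
    "variance_explained",
    "match_components",
    "ComponentMatch",
    "MatchResult",
]


def component_activity(
    posterior: PosteriorSummary, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior inclusion probabilities and their thresholded booleans.

    Returns ``(probs, active)``, both views x components; ``active`` is
    ``probs > threshold``.
    """
    probs = posterior.activity
    return probs, probs > threshold


def prune_empty_components(
    posterior: PosteriorSummary, threshold: float = 0.5
) -> np.ndarray:
    """Indices of components active in at least one view."""
    _, active = component_activity(posterior, threshold)
    return np.flatnonzero(active.any(axis=0))


def variance_explained(
    posterior: PosteriorSummary, views: list[ViewData] | None = None
) -> np.ndarray:
    """Fraction of each view's model variance attributed to each component.

    Computed from posterior means: for component k and view m the
    numerator is ``sum_d wbar_dk^2`` and the denominator is the total
    ``sum_k' sum_d wbar_dk'^2 + sum_d 1/taubar_d`` (signal plus noise
    under unit-variance latent scores).  Fractions lie in [0, 1] and sum
    to at most 1 per view.
    """
    M = len(posterior.w_mean)
    K = posterior.w_mean[0].shape[1]
    out = np.zeros((K, M))
    for m in range(M):
        num = np.sum(posterior.w_mean[m] ** 2, axis=0)          # per component
        denom = num.sum() + np.sum(1.0 / posterior.tau_mean[m])
        out[:, m] = num / denom
    return out


@dataclass
class ComponentMatch:
    est_index: int
    ref_index: int
    r: float
    sign: int


@dataclass
class MatchResult:
    """Outcome of the exact assignment between two sets of components."""

    matches: list[ComponentMatch]
    activity_agreement: float | None = None

    @property
    def abs_r(self) -> np.ndarray:
        return np.array([abs(m.r) for m in self.matches])

    def n_matched(self, min_abs_r: float = 0.8) -> int:
        return int(np.sum(self.abs_r >= min_abs_r))


def _score_matrix(obj: PosteriorSummary | LatentState | np.ndarray) -> np.ndarray:
    if isinstance(obj, PosteriorSummary):
        return obj.z_mean
    if isinstance(obj, LatentState):
        return obj.Z
    return np.asarray(obj, dtype=float)


def _activity_matrix(obj) -> np.ndarray | None:
    if isinstance(obj, PosteriorSummary):
        return (obj.activity > 0.5).astype(int)
    if isinstance(obj, LatentState):
        return np.asarray(obj.H, dtype=int)
    return None


def match_components(
    est: PosteriorSummary | LatentState | np.ndarray,
    ref: PosteriorSummary | LatentState | np.ndarray,
    activity_threshold: float = 0.5,
) -> MatchResult:
    """Optimal one-to-one component matching on |Pearson r| of scores.

    Solves the assignment exactly (Hungarian algorithm) to maximize the
    summed absolute correlation between latent score columns; a
    constant score column correlates 0 with everything, which pushes it
    to the end of the assignment.  When both sides carry activity
    information, also reports the fraction of view x component entries
    on which the matched (sign-insensitive) activity patterns agree.
    """
    Ze = _score_matrix(est)
    Zr = _score_matrix(ref)
    if Ze.shape[0] != Zr.shape[0]:
        raise ValueError("score matrices must share the sample dimension")
    Ke, Kr = Ze.shape[1], Zr.shape[1]
    corr = np.zeros((Ke, Kr))
    se = Ze.std(axis=0)
    sr = Zr.std(axis=0)
    ok_e, ok_r = se > 0, sr > 0
    if ok_e.any() and ok_r.any():
        Zen = (Ze[:, ok_e] - Ze[:, ok_e].mean(axis=0)) / se[ok_e]
        Zrn = (Zr[:, ok_r] - Zr[:, ok_r].mean(axis=0)) / sr[ok_r]
        sub = (Zen.T @ Zrn) / Ze.shape[0]
        corr[np.ix_(ok_e, ok_r)] = np.clip(sub, -1.0, 1.0)
    rows, cols = linear_sum_assignment(-np.abs(corr))
    matches = [
        ComponentMatch(
            est_index=int(i),
            ref_index=int(j),
            r=float(corr[i, j]),
            sign=int(np.sign(corr[i, j])) or 1,
        )
        for i, j in zip(rows, cols)
    ]
    matches.sort(key=lambda m: m.ref_index)

    agreement = None
    He, Hr = _activity_matrix(est), _activity_matrix(ref)
    if He is not None and Hr is not None:
        if isinstance(est, PosteriorSummary):
            He = (est.activity > activity_threshold).astype(int)
        cols_e = [m.est_index for m in matches]
        cols_r = [m.ref_index for m in matches]
        agreement = float(np.mean(He[:, cols_e] == Hr[:, cols_r]))
    return MatchResult(matches=matches, activity_agreement=agreement)
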