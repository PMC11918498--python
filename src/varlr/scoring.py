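"""Composite scoring: weighted LR combination, posterior calibration, weight learning.

The three evidence channels are combined on the log10 scale under learned
exponents (the phenotype exponent is fixed at 1):

    composite = log10(LR_pheno) + c1*log10(LR_geno) + c2*log10(LR_seg)

Because the exponents break the plain likelihood-ratio interpretation, the
composite is recalibrated against diagnostic / nondiagnostic score
distributions (one Gaussian per class) to recover a posterior probability.
The exponents themselves are learned by a greedy PR-AUC hill-climb from the
origin, averaged over cross-validation folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm
from sklearn.metrics import average_precision_score

from .errors import CalibrationError

__all__ = [
    "WeightConfig",
    "LikelihoodBundle",
    "CaseScores",
    "GaussianCalibration",
    "composite_score",
    "odds_posterior",
    "calibrate_posterior",
    "optimize_weights",
    "rank_bundles",
]

# defaults learned on the reference training cohort
DEFAULT_C1 = 2.29
DEFAULT_C2 = 3.69
DEFAULT_PRIOR = 0.3


@dataclass(frozen=True)
class WeightConfig:
    """Exponents and prior for the composite score.

    ``c1`` scales the genotype LR, ``c2`` the segregation LR; the phenotype
    exponent is fixed at 1.
    """

    c1: float = DEFAULT_C1
    c2: float = DEFAULT_C2
    prior: float = DEFAULT_PRIOR
    subset_max: int = 10

    def __post_init__(self):
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("exponents must be non-negative")
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must be in (0, 1)")
        if self.subset_max < 1:
            raise ValueError("subset_max must be >= 1")


@dataclass
class LikelihoodBundle:
    """All evidence for one (case, disease, gene) triple."""

    case_id: str
    disease: str
    gene: str
    lr_pheno: float
    lr_geno: float
    lr_seg: float
    composite: float  # log10 scale
    posterior: float = float("nan")
    rank: int = 0


@dataclass(frozen=True)
class CaseScores:
    """Per-case training rows for weight optimization.

    ``log_lrs`` has shape (n_candidates, 3): log10 of (pheno, geno, seg).
    ``labels`` marks the diagnostic gene rows.
    """

    case_id: str
    log_lrs: np.ndarray
    labels: np.ndarray

    @property
    def diagnostic(self) -> bool:
        return bool(self.labels.any())


def composite_score(lrs: Tuple, w: WeightConfig) -> float:
    """Weighted log10 combination of (LR_pheno, LR_geno, LR_seg)."""
    lp, lg, ls = lrs
    if lp <= 0 or lg <= 0 or ls <= 0:
        raise ValueError(f"likelihood ratios must be positive, got {lrs!r}")
    return math.log10(lp) + w.c1 * math.log10(lg) + w.c2 * math.log10(ls)


def odds_posterior(composite: float, prior: float) -> float:
    """Posterior treating 10**composite as a plain LR with the given prior.

    With c1 = c2 = 1 this is the classical likelihood-ratio posterior; it is
    the fallback when no calibration has been fit.
    """
    odds = prior / (1.0 - prior) * 10.0**composite
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class GaussianCalibration:
    """Two-Gaussian class-conditional calibration of composite scores."""

    mu_diagnostic: float
    sd_diagnostic: float
    mu_nondiagnostic: float
    sd_nondiagnostic: float
    prior: float

    def __call__(self, t):
        g_d = norm.pdf(t, self.mu_diagnostic, self.sd_diagnostic)
        g_n = norm.pdf(t, self.mu_nondiagnostic, self.sd_nondiagnostic)
        num = self.prior * g_d
        den = num + (1.0 - self.prior) * g_n
        with np.errstate(invalid="ignore"):
            post = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
        # far in the tails both densities underflow; decide by proximity
        if np.ndim(post) == 0:
            if not np.isfinite(post):
                return 1.0 if abs(t - self.mu_diagnostic) < abs(t - self.mu_nondiagnostic) else 0.0
            return float(post)
        bad = ~np.isfinite(post)
        if bad.any():
            t_arr = np.asarray(t, dtype=float)
            post = np.where(
                bad,
                (np.abs(t_arr - self.mu_diagnostic) < np.abs(t_arr - self.mu_nondiagnostic)).astype(float),
                post,
            )
        return post


def calibrate_posterior(
    train_scores: Sequence,
    labels: Sequence,
    prior: float,
) -> GaussianCalibration:
    """Fit per-class Gaussians to composite scores and return the posterior map.

    Raises :class:`CalibrationError` naming the offending class when it has
    fewer than two points or zero variance.
    """
    scores = np.asarray(train_scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must align")
    params = {}
    for name, mask in (("diagnostic", y), ("nondiagnostic", ~y)):
        pts = scores[mask]
        if pts.size < 2:
            raise CalibrationError(
                f"{name} class has {pts.size} point(s); need at least 2"
            )
        sd = float(pts.std(ddof=1))
        if sd == 0.0:
            raise CalibrationError(f"{name} class has zero variance")
        params[name] = (float(pts.mean()), sd)
    return GaussianCalibration(
        mu_diagnostic=params["diagnostic"][0],
        sd_diagnostic=params["diagnostic"][1],
        mu_nondiagnostic=params["nondiagnostic"][0],
        sd_nondiagnostic=params["nondiagnostic"][1],
        prior=prior,
    )


def _pooled_pr_auc(cases: Sequence, c1: float, c2: float) -> float:
    scores = np.concatenate(
        [c.log_lrs[:, 0] + c1 * c.log_lrs[:, 1] + c2 * c.log_lrs[:, 2] for c in cases]
    )
    labels = np.concatenate([c.labels for c in cases])
    return float(average_precision_score(labels, scores))


def _hill_climb(cases: Sequence, step: float, bounds: Tuple) -> Tuple:
    """Greedy axis-step search from the origin, maximizing pooled PR AUC.

    Coordinates are tracked in integer step units to avoid float drift.
    Neighbor order (tie-break): +c1, -c1, +c2, -c2; movement requires a
    strict improvement, so the AUC trajectory is non-decreasing.
    """
    lo, hi = bounds
    max_units = int(round((hi - lo) / step))
    pos = (0, 0)  # units above lo
    current = _pooled_pr_auc(cases, lo, lo)
    while True:
        best = None
        for du, dv in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            u, v = pos[0] + du, pos[1] + dv
            if not (0 <= u <= max_units and 0 <= v <= max_units):
                continue
            auc = _pooled_pr_auc(cases, lo + u * step, lo + v * step)
            if auc > current and (best is None or auc > best[0]):
                best = (auc, (u, v))
        if best is None:
            return lo + pos[0] * step, lo + pos[1] * step
        current, pos = best


def _stratified_folds(cases: Sequence, folds: int):
    """Round-robin assignment within each class, deterministic in input order."""
    assignment = [[] for _ in range(folds)]
    for label in (True, False):
        i = 0
        for c in cases:
            if c.diagnostic is label:
                assignment[i % folds].append(c)
                i += 1
    return [f for f in assignment if f]


def optimize_weights(
    cases: Sequence,
    folds: int = 5,
    step: float = 0.1,
    bounds: Tuple = (0.0, 10.0),
    prior: float = DEFAULT_PRIOR,
    subset_max: int = 10,
) -> WeightConfig:
    """Learn (c1, c2) by per-fold greedy PR-AUC search, averaging fold optima."""
    if folds < 1:
        raise ValueError("folds must be >= 1")
    n_diag = sum(1 for c in cases if c.diagnostic)
    if n_diag < folds:
        raise ValueError(
            f"need at least {folds} diagnostic cases for {folds} folds, got {n_diag}"
        )
    optima = [_hill_climb(fold, step, bounds) for fold in _stratified_folds(cases, folds)]
    c1 = float(np.mean([o[0] for o in optima]))
    c2 = float(np.mean([o[1] for o in optima]))
    return WeightConfig(c1=c1, c2=c2, prior=prior, subset_max=subset_max)


def rank_bundles(bundles: Sequence) -> None:
    """Assign 1..n ranks in place by posterior descending, gene ID on ties."""
    order = sorted(bundles, key=lambda b: (-b.posterior, b.gene))
    for i, b in enumerate(order, start=1):
        b.rank = i
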