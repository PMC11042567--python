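"""Channel-activation analysis: per-subject GLM betas, one-sample
activation t-tests, and the between-group activation contrast.

The GLM design has two regressors per channel — an intercept and the task
boxcar convolved with the canonical HRF — and the activation amplitude is
the task-regressor coefficient.  Group comparison uses a two-sample Welch
t-test (the groups are independent and of unequal size), with the sign
convention mild − severe.  Raw p < α is thresholded by default; an
optional Bonferroni correction over channels is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .io import HemoRecording
from .simulate import TaskParadigm, task_regressor

__all__ = [
    "ActivationResult",
    "glm_beta",
    "channel_activation_test",
    "group_activation_contrast",
]


@dataclass
class ActivationResult:
    """Per-channel statistics of an activation analysis."""

    beta: np.ndarray      # mean activation amplitude per channel
    t_value: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if np.any((self.p_value < 0) | (self.p_value > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def glm_beta(rec: HemoRecording, paradigm: TaskParadigm | None = None,
             species: int = 0) -> np.ndarray:
    """Task-regressor coefficient per channel from an [intercept, HRF
    regressor] least-squares fit (ΔHbO by default)."""
    paradigm = paradigm or rec.paradigm
    if paradigm is None:
        raise ValueError("no paradigm available")
    reg = task_regressor(paradigm)
    if reg.size != rec.n_samples:
        raise ValueError("paradigm length does not match recording")
    X = np.column_stack([np.ones_like(reg), reg])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("design matrix is collinear")
    Y = rec.data[:, :, species]
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef[1]


def channel_activation_test(betas: np.ndarray,
                            alpha: float = 0.05,
                            bonferroni: bool = False) -> ActivationResult:
    """One-sample t-test of per-channel betas against zero.

    ``betas`` is subjects × channels.  Zero-variance channels get t = 0,
    p = 1 (flagged by NaN-free sentinels rather than raising).
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    if betas.shape[0] < 2:
        raise ValueError("need at least two subjects")
    t, p = sstats.ttest_1samp(betas, 0.0, axis=0)
    bad = ~np.isfinite(t)
    t = np.where(bad, 0.0, t)
    p = np.where(bad, 1.0, p)
    thresh = alpha / betas.shape[1] if bonferroni else alpha
    return ActivationResult(
        beta=betas.mean(axis=0),
        t_value=np.asarray(t),
        p_value=np.asarray(p),
        significant=np.asarray(p) < thresh,
        alpha=alpha,
    )


def group_activation_contrast(betas_mild: np.ndarray,
                              betas_severe: np.ndarray,
                              alpha: float = 0.05,
                              bonferroni: bool = False) -> ActivationResult:
    """Welch two-sample t contrast of activation, mild − severe."""
    bm = np.atleast_2d(np.asarray(betas_mild, dtype=float))
    bs = np.atleast_2d(np.asarray(betas_severe, dtype=float))
    if bm.shape[0] < 2 or bs.shape[0] < 2:
        raise ValueError("need at least two subjects per group")
    if bm.shape[1] != bs.shape[1]:
        raise ValueError("channel counts differ between groups")
    t, p = sstats.ttest_ind(bm, bs, axis=0, equal_var=False)
    bad = ~np.isfinite(t)
    t = np.where(bad, 0.0, t)
    p = np.where(bad, 1.0, p)
    thresh = alpha / bm.shape[1] if bonferroni else alpha
    return ActivationResult(
        beta=bm.mean(axis=0) - bs.mean(axis=0),
        t_value=np.asarray(t),
        p_value=np.asarray(p),
        significant=np.asarray(p) < thresh,
        alpha=alpha,
    )
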