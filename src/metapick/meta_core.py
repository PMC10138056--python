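"""Inverse-variance meta-analysis primitives.

Implements the standard fixed-effect and random-effects machinery on which
the rest of the package is built: study weights, the pooled estimate

.. math::

    \\hat\\theta = \\frac{\\sum_i w_i y_i}{\\sum_i w_i},
    \\qquad w_i = \\frac{1}{\\sigma_i^2 + \\tau^2},

its normal-theory confidence interval, one-sided p-values, the
DerSimonian-Laird moment estimator of the between-study variance
:math:`\\tau^2`, and a typical-variance form of the :math:`I^2`
heterogeneity fraction.

Within-study variances :math:`\\sigma_i^2` are treated as known constants
throughout, which is the convention in analytic work on meta-analytic
hypothesis testing: the pooled one-sided p-value
:math:`\\Phi(-\\hat\\theta\\sqrt{\\sum_i w_i})` is then exactly standard
normal under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import isfinite
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from ._errors import InputError

__all__ = [
    "Study",
    "StudySet",
    "MetaResult",
    "compute_weights",
    "pool",
    "study_p_value",
    "pooled_p_value",
    "dersimonian_laird_tau2",
    "i_squared_typical",
]

logger = logging.getLogger(__name__)

_MODELS = ("fixed", "random")
_SIDES = ("right", "left", "two")


@dataclass(frozen=True)
class Study:
    """One trial's reported effect and within-study variance.

    Parameters
    ----------
    label
        Unique, nonempty identifier.
    effect
        Point estimate on the pooling scale (e.g. a log odds ratio).
    variance
        Known within-study variance, strictly positive and finite.
    """

    label: str
    effect: float
    variance: float

    def __post_init__(self) -> None:
        if not self.label:
            raise InputError("study label must be nonempty")
        if not isfinite(self.effect):
            raise InputError(f"study {self.label!r}: effect must be finite")
        if not isfinite(self.variance) or self.variance <= 0:
            raise InputError(
                f"study {self.label!r}: variance must be positive and finite"
            )


class StudySet:
    """Ordered, label-unique collection of studies.

    Stored columnar (label tuple plus float64 effect/variance arrays) so
    that simulation-scale ensembles stay vectorised; ``Study`` objects are
    materialised on access. Input order is preserved and is the documented
    tie-break for selection operations.
    """

    __slots__ = ("_effects", "_variances", "_labels")

    def __init__(self, studies: Iterable[Study]):
        studies = list(studies)
        effects = np.array([s.effect for s in studies], dtype=np.float64)
        variances = np.array([s.variance for s in studies], dtype=np.float64)
        labels = tuple(s.label for s in studies)
        self._init_from(effects, variances, labels)

    @classmethod
    def from_arrays(
        cls,
        effects: Sequence[float] | np.ndarray,
        variances: Sequence[float] | np.ndarray,
        labels: Sequence[str] | None = None,
    ) -> "StudySet":
        """Build a set from parallel arrays.

        When ``labels`` is omitted, positional labels ``s1, s2, ...`` are
        generated lazily on first access (large simulated ensembles never
        need them).
        """
        obj = cls.__new__(cls)
        obj._init_from(
            np.asarray(effects, dtype=np.float64).copy(),
            np.asarray(variances, dtype=np.float64).copy(),
            tuple(labels) if labels is not None else None,
        )
        return obj

    def _init_from(self, effects, variances, labels) -> None:
        if effects.ndim != 1 or effects.shape != variances.shape:
            raise InputError("effects and variances must be 1-d and same length")
        if effects.size == 0:
            raise InputError("a study set must contain at least one study")
        if labels is not None:
            if len(labels) != effects.size:
                raise InputError("labels length does not match effects")
            if len(set(labels)) != len(labels):
                seen: set = set()
                dup = next(l for l in labels if l in seen or seen.add(l))
                raise InputError(f"duplicate study label {dup!r}")
        if not np.all(np.isfinite(effects)):
            i = int(np.flatnonzero(~np.isfinite(effects))[0])
            raise InputError(f"study {self._name(labels, i)!r}: effect must be finite")
        bad = ~(np.isfinite(variances) & (variances > 0))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise InputError(
                f"study {self._name(labels, i)!r}: variance must be positive and finite"
            )
        self._effects = effects
        self._variances = variances
        self._labels = labels

    @staticmethod
    def _name(labels, i: int) -> str:
        return labels[i] if labels is not None else f"s{i + 1}"

    @property
    def effects(self) -> np.ndarray:
        return self._effects

    @property
    def variances(self) -> np.ndarray:
        return self._variances

    @property
    def labels(self) -> tuple[str, ...]:
        if self._labels is None:
            self._labels = tuple(f"s{i + 1}" for i in range(self._effects.size))
        return self._labels

    def __len__(self) -> int:
        return self._effects.size

    def __iter__(self) -> Iterator[Study]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Study:
        return Study(self.labels[i], float(self._effects[i]), float(self._variances[i]))

    def subset(self, indices: Sequence[int] | np.ndarray) -> "StudySet":
        """New StudySet restricted to ``indices`` (in the given order)."""
        idx = np.asarray(indices, dtype=np.intp)
        labels = tuple(self.labels[i] for i in idx)
        return StudySet.from_arrays(self._effects[idx], self._variances[idx], labels)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StudySet(K={len(self)})"


@dataclass(frozen=True)
class MetaResult:
    """Pooled analysis of a study set under one model.

    ``se`` is :math:`(\\sum_i w_i)^{-1/2}`; the confidence interval is the
    two-sided normal interval at level ``1 - alpha``; ``p_one_sided`` is the
    right-tailed :math:`\\Phi(-\\hat\\theta/\\mathrm{se})` used for the
    directional hypothesis :math:`H_1: \\theta > 0`.
    """

    model: str
    alpha: float
    theta_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_one_sided: float
    tau2: float
    weights: Mapping[str, float]


# ---------------------------------------------------------------------------
# array layer: everything simulation-critical works on raw float64 arrays
# ---------------------------------------------------------------------------

def _weights_arr(variances: np.ndarray, tau2: float) -> np.ndarray:
    return 1.0 / (variances + tau2)


def _pool_arr(effects: np.ndarray, variances: np.ndarray, tau2: float):
    """Return (theta_hat, sum_of_weights)."""
    w = _weights_arr(variances, tau2)
    sw = float(w.sum())
    return float((w * effects).sum()) / sw, sw


def _p_right(theta_hat: float, sum_w: float) -> float:
    return float(norm.cdf(-theta_hat * np.sqrt(sum_w)))


def _dl_tau2_arr(effects: np.ndarray, variances: np.ndarray) -> float:
    k = effects.size
    if k == 1:
        logger.warning(
            "DerSimonian-Laird tau^2 requested for a single study; "
            "returning 0 (no between-study information)"
        )
        return 0.0
    w0 = 1.0 / variances
    sw0 = w0.sum()
    y0 = (w0 * effects).sum() / sw0
    q = float((w0 * (effects - y0) ** 2).sum())
    denom = float(sw0 - (w0**2).sum() / sw0)
    return max(0.0, (q - (k - 1)) / denom)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def compute_weights(studies: StudySet, tau2: float = 0.0) -> dict[str, float]:
    """Inverse-variance weights ``1 / (sigma_i^2 + tau2)`` keyed by label.

    ``tau2 = 0`` gives the fixed-effect weights exactly.
    """
    if tau2 < 0 or not isfinite(tau2):
        raise InputError("tau2 must be nonnegative and finite")
    w = _weights_arr(studies.variances, tau2)
    return dict(zip(studies.labels, (float(x) for x in w)))


def pool(
    studies: StudySet,
    model: str = "fixed",
    alpha: float = 0.05,
    tau2_override: float | None = None,
) -> MetaResult:
    """Pool a study set by inverse-variance weighting.

    Parameters
    ----------
    model
        ``"fixed"`` uses weights :math:`1/\\sigma_i^2`; ``"random"`` uses
        :math:`1/(\\sigma_i^2+\\hat\\tau^2)` with the DerSimonian-Laird
        estimate unless ``tau2_override`` supplies a fixed value.
    alpha
        Two-sided level for the confidence interval (and the significance
        threshold downstream consumers apply to the one-sided p).
    tau2_override
        Hold :math:`\\tau^2` fixed at this value instead of estimating it;
        only meaningful under the random-effects model.
    """
    if model not in _MODELS:
        raise InputError(f"model must be one of {_MODELS}, got {model!r}")
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")
    if model == "fixed":
        if tau2_override is not None:
            raise InputError("tau2_override is only valid for the random model")
        tau2 = 0.0
    else:
        if tau2_override is not None:
            if tau2_override < 0 or not isfinite(tau2_override):
                raise InputError("tau2_override must be nonnegative and finite")
            tau2 = float(tau2_override)
        else:
            tau2 = dersimonian_laird_tau2(studies)

    theta_hat, sw = _pool_arr(studies.effects, studies.variances, tau2)
    se = sw ** -0.5
    z = float(norm.ppf(1 - alpha / 2))
    return MetaResult(
        model=model,
        alpha=alpha,
        theta_hat=theta_hat,
        se=se,
        ci_low=theta_hat - z * se,
        ci_high=theta_hat + z * se,
        p_one_sided=_p_right(theta_hat, sw),
        tau2=tau2,
        weights=compute_weights(studies, tau2),
    )


def study_p_value(study: Study, weight: float) -> float:
    """One-sided p-value of a single study, :math:`\\Phi(-\\sqrt{w_i}\\,y_i)`."""
    if weight <= 0 or not isfinite(weight):
        raise InputError("weight must be positive and finite")
    return float(norm.cdf(-np.sqrt(weight) * study.effect))


def pooled_p_value(result: MetaResult, sided: str = "right") -> float:
    """P-value of the pooled estimate.

    ``right`` (default) is :math:`\\Phi(-\\hat\\theta\\sqrt{\\sum w_i})` for
    :math:`H_1:\\theta>0`; ``left`` is its mirror; ``two`` is
    :math:`2\\Phi(-|\\hat\\theta|\\sqrt{\\sum w_i})`.
    """
    if sided not in _SIDES:
        raise InputError(f"sided must be one of {_SIDES}, got {sided!r}")
    z = result.theta_hat / result.se
    if sided == "right":
        return float(norm.cdf(-z))
    if sided == "left":
        return float(norm.cdf(z))
    return float(2 * norm.cdf(-abs(z)))


def dersimonian_laird_tau2(studies: StudySet) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance.

    .. math::

        \\hat\\tau^2 = \\max\\!\\left(0,\\;
        \\frac{Q - (S-1)}{\\sum_i w_i^0 - \\sum_i (w_i^0)^2 / \\sum_i w_i^0}
        \\right),

    with fixed-effect weights :math:`w_i^0 = 1/\\sigma_i^2` and
    :math:`Q = \\sum_i w_i^0 (y_i - \\bar y^0)^2` around the fixed-effect
    pooled mean. A single study returns 0 with a logged warning (the
    estimator's denominator is degenerate and one study carries no
    between-study information).
    """
    return _dl_tau2_arr(studies.effects, studies.variances)


def i_squared_typical(tau2: float, typical_within_var: float) -> float:
    """Heterogeneity fraction :math:`\\tau^2 / (\\tau^2 + s^2)`.

    ``typical_within_var`` (:math:`s^2`) is a representative within-study
    variance; with :math:`s^2 = 0.17` (the mean of the simulation's
    truncated variance distribution) a between-study variance of 0.70 gives
    :math:`I^2 \\approx 80\\%`.
    """
    if typical_within_var <= 0 or not isfinite(typical_within_var):
        raise InputError("typical_within_var must be positive and finite")
    if tau2 < 0 or not isfinite(tau2):
        raise InputError("tau2 must be nonnegative and finite")
    return tau2 / (tau2 + typical_within_var)
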