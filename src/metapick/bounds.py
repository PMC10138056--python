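"""Cherry-pickability conditions and their Monte Carlo validation.

Two analytic conditions state when an adversarial meta-analyst has enough
room to force a desired conclusion by retaining ``S`` of ``K`` studies.
Both are stated in terms of a significance level :math:`\\alpha`, a failure
probability :math:`\\delta`, a retention-fraction parameter
:math:`\\epsilon`, and the weight imbalance
:math:`\\eta = w_{max}/w_{min} \\ge 1` of the included studies.

*Condition 1 (force significance).* For :math:`\\alpha \\in (0, 1/2)`,
:math:`\\delta \\in (0,1)`, :math:`\\epsilon \\in (0, 1/3)`: if
:math:`S/K \\le \\epsilon` and

.. math::

    S \\ \\ge\\ \\max\\!\\left\\{
        \\frac{\\eta\\,\\Phi^{-1}(\\alpha)}
             {\\Phi^{-1}\\!\\big(\\tfrac12 - \\tfrac{\\epsilon^2}{2}\\big)},\\;
        \\frac{\\epsilon \\log(1/\\delta)}
             {2\\big(\\tfrac12 - \\tfrac{3\\epsilon^2}{2}\\big)^2} - 2
    \\right\\},

then greedy top-``S`` selection achieves
:math:`p_{meta}(D_S) \\le \\alpha` with probability at least
:math:`1 - \\delta` even when the true effect is zero.

*Condition 2 (force non-significance).* For :math:`\\epsilon \\in (0,1)`:
if :math:`1 - \\epsilon \\le S/K \\le 1` and

.. math::

    \\frac{\\eta\\,\\Phi^{-1}(\\alpha)}
         {\\Phi^{-1}\\!\\big(1 - \\tfrac{\\epsilon^2}{2}\\big)}
    \\ \\le\\ S\\ <\\
    \\frac{(1-\\epsilon)\\log(1/\\delta)}{2(1 - \\epsilon/2)^2} - 2,

then the analyst can achieve :math:`p_{meta}(D_S) \\ge \\alpha` with
probability at least :math:`\\delta` (note the asymmetry: :math:`\\delta`,
not :math:`1-\\delta`).

Both displays are conservative sufficient conditions, not tight
thresholds; ``empirical_guarantee_check`` validates them by direct
simulation, and the property tests keep the transcriptions honest.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, isfinite, log

import numpy as np
from scipy.stats import norm

from ._errors import InputError
from .cherrypick import Direction, Tau2Policy, _rank_indices, _subset_pmeta
from .meta_core import StudySet
from .simulation import _generate_arrays

__all__ = [
    "BoundInputs",
    "TheoremReport",
    "weight_ratio",
    "theorem1_min_studies",
    "theorem1_holds",
    "theorem2_bounds",
    "theorem2_holds",
    "empirical_guarantee_check",
]


@dataclass(frozen=True)
class BoundInputs:
    """Parameters of the cherry-pickability conditions.

    ``epsilon`` must lie in (0, 1/3) for condition 1 and (0, 1) for
    condition 2; the range is enforced by the operation that consumes it.
    ``eta`` is the weight ratio :math:`w_{max}/w_{min} \\ge 1`.
    """

    alpha: float
    delta: float
    epsilon: float
    eta: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise InputError("alpha must lie in (0, 1/2)")
        if not 0 < self.delta < 1:
            raise InputError("delta must lie in (0, 1)")
        if not 0 < self.epsilon < 1:
            raise InputError("epsilon must lie in (0, 1)")
        if self.eta < 1 or not isfinite(self.eta):
            raise InputError("eta must be finite and >= 1")


@dataclass(frozen=True)
class TheoremReport:
    """Auditable verdict on one (S, K) configuration.

    ``s_min`` is populated for condition 1, ``s_low``/``s_high`` for
    condition 2; ``ratio_ok`` reports the S/K gate on its own so a reader
    can see which clause failed.
    """

    theorem: int
    satisfied: bool
    inputs: BoundInputs
    ratio_ok: bool
    notes: str
    s_min: float | None = None
    s_low: float | None = None
    s_high: float | None = None


def weight_ratio(studies: StudySet, tau2: float = 0.0) -> float:
    """Weight imbalance eta = w_max / w_min under a given tau^2.

    Equals ``(max sigma^2 + tau2) / (min sigma^2 + tau2)``; 1 for
    homoscedastic studies and tending to 1 as tau2 dominates.
    """
    if tau2 < 0 or not isfinite(tau2):
        raise InputError("tau2 must be nonnegative and finite")
    v = studies.variances
    return float((v.max() + tau2) / (v.min() + tau2))


def theorem1_min_studies(inputs: BoundInputs) -> float:
    """Minimum subset size in the force-significance condition.

    The larger of a weight-ratio/quantile term (divergent as
    :math:`\\epsilon \\to 0^+`, where :math:`\\Phi^{-1}(1/2-\\epsilon^2/2)`
    approaches zero from below) and a concentration term in
    :math:`\\epsilon \\log(1/\\delta)`. Monotone nondecreasing in ``eta``
    and in ``1/delta``.
    """
    if not 0 < inputs.epsilon < 1 / 3:
        raise InputError("epsilon must lie in (0, 1/3) for condition 1")
    a, d, e, eta = inputs.alpha, inputs.delta, inputs.epsilon, inputs.eta
    quantile_term = eta * norm.ppf(a) / norm.ppf(0.5 - e**2 / 2)
    concentration_term = e * log(1 / d) / (2 * (0.5 - 1.5 * e**2) ** 2) - 2
    return float(max(quantile_term, concentration_term))


def theorem1_holds(S: int, K: int, inputs: BoundInputs) -> TheoremReport:
    """Does (S, K) satisfy the force-significance condition?

    Requires ``S/K <= epsilon`` and ``S >= ceil(s_min)`` (the analytic
    bound is real-valued; S is an integer count of studies).
    """
    if not 1 <= S <= K:
        raise InputError("need 1 <= S <= K")
    s_min = theorem1_min_studies(inputs)
    ratio_ok = S / K <= inputs.epsilon
    satisfied = ratio_ok and S >= ceil(s_min)
    return TheoremReport(
        theorem=1,
        satisfied=satisfied,
        inputs=inputs,
        ratio_ok=ratio_ok,
        s_min=s_min,
        notes=(
            f"requires S/K <= {inputs.epsilon} (got {S / K:.4g}) and "
            f"S >= ceil({s_min:.4g}); guarantee is "
            f"P[p_meta(D_S) <= alpha] >= 1 - delta at theta = 0"
        ),
    )


def theorem2_bounds(inputs: BoundInputs) -> tuple[float, float]:
    """Lower and upper S expressions of the force-non-significance condition.

    Returns ``(s_low, s_high)`` as printed; the interval may be empty
    (``s_low >= s_high``), which is reported rather than raised. Since
    :math:`\\Phi^{-1}(\\alpha) < 0`, ``s_low`` is negative and decreases
    (the admissible interval widens) as ``eta`` grows.
    """
    a, d, e, eta = inputs.alpha, inputs.delta, inputs.epsilon, inputs.eta
    s_low = eta * norm.ppf(a) / norm.ppf(1 - e**2 / 2)
    s_high = (1 - e) * log(1 / d) / (2 * (1 - e / 2) ** 2) - 2
    return float(s_low), float(s_high)


def theorem2_holds(S: int, K: int, inputs: BoundInputs) -> TheoremReport:
    """Does (S, K) satisfy the force-non-significance condition?

    Requires ``1 - epsilon <= S/K <= 1`` and ``s_low <= S < s_high``. The
    attached guarantee is weak by construction: success probability at
    least :math:`\\delta` (not :math:`1-\\delta`).
    """
    if not 1 <= S <= K:
        raise InputError("need 1 <= S <= K")
    s_low, s_high = theorem2_bounds(inputs)
    ratio_ok = 1 - inputs.epsilon <= S / K <= 1
    satisfied = ratio_ok and s_low <= S < s_high
    return TheoremReport(
        theorem=2,
        satisfied=satisfied,
        inputs=inputs,
        ratio_ok=ratio_ok,
        s_low=s_low,
        s_high=s_high,
        notes=(
            f"requires {1 - inputs.epsilon:.4g} <= S/K <= 1 (got {S / K:.4g}) "
            f"and {s_low:.4g} <= S < {s_high:.4g}"
            + ("; interval is empty" if s_low >= s_high else "")
            + "; guarantee is P[p_meta(D_S) >= alpha] >= delta (not 1 - delta)"
        ),
    )


def subset_weight_ratio(studies: StudySet, selected_labels, tau2: float = 0.0) -> float:
    """Post-hoc eta over a selected subset (for re-evaluating a report).

    The conditions define eta over the retained subset, which is unknown
    before selection; the package default is the conservative full-set
    ratio, and this helper recomputes eta once a subset is in hand.
    """
    wanted = set(selected_labels)
    idx = [i for i, lab in enumerate(studies.labels) if lab in wanted]
    if not idx:
        raise InputError("no selected labels found in the study set")
    return weight_ratio(studies.subset(idx), tau2)


def empirical_guarantee_check(
    theorem: int,
    S: int,
    K: int,
    inputs: BoundInputs,
    theta: float,
    reps: int,
    seed: int,
    tau2: float = 0.0,
) -> float:
    """Monte Carlo frequency with which greedy selection meets the target.

    Simulates ``reps`` ensembles of ``K`` studies from the package's study
    generator at the given true effect (``theta = 0`` for condition 1,
    ``theta > 0`` for condition 2) with known between-study variance
    ``tau2`` held fixed in the weights, applies greedy top-``S`` selection
    in the condition's direction, and returns the fraction of replicates
    achieving :math:`p_{meta}(D_S) \\le \\alpha` (condition 1) or
    :math:`\\ge \\alpha` (condition 2). Deterministic for a fixed seed.
    """
    if theorem not in (1, 2):
        raise InputError("theorem must be 1 or 2")
    if reps < 100:
        raise InputError("reps must be at least 100")
    if not 1 <= S <= K:
        raise InputError("need 1 <= S <= K")
    direction = Direction.OVERSTATE if theorem == 1 else Direction.UNDERSTATE
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        eff, var = _generate_arrays(K, theta, tau2, rng)
        order = _rank_indices(eff, var, tau2, direction)
        idx = order[:S]
        model = "fixed" if tau2 == 0 else "random"
        p_sel, _ = _subset_pmeta(eff, var, idx, model, Tau2Policy.FULL_SET, tau2)
        if theorem == 1:
            hits += p_sel <= inputs.alpha
        else:
            hits += p_sel >= inputs.alpha
    return hits / reps
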