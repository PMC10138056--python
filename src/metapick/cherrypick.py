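"""Adversarial subset selection for meta-analyses.

A meta-analyst who controls the inclusion/exclusion criteria can retain an
arbitrary size-``S`` subset :math:`D_S` of the ``K`` available studies. The
greedy rule implemented here keeps the studies with the top-``S`` smallest
one-sided p-values :math:`\\Phi(-\\sqrt{w_i}\\,y_i)` to force significance
(*overstate*), or the top-``S`` largest to force non-significance
(*understate*), and recomputes the pooled p-value on the retained subset.
An exhaustive enumerator over all :math:`\\binom{K}{S}` subsets serves as an
optimality oracle for the greedy rule; it is an auditing aid of this
package, not part of the selection model itself.

With equal weights the greedy choice is provably optimal for the pooled
p-value (it is monotone in the subset sum of effects at fixed ``S``); with
unequal weights it may be slightly suboptimal, which is why both routes are
exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm

from ._errors import InputError
from .meta_core import StudySet, _dl_tau2_arr, _p_right, _pool_arr

__all__ = [
    "Direction",
    "Tau2Policy",
    "CherryPickResult",
    "select_top_s",
    "exhaustive_best_subset",
    "can_flip",
]


class Direction(str, Enum):
    """Which false conclusion the selection aims for.

    ``OVERSTATE`` seeks :math:`p_{meta}(D_S) \\le \\alpha` (claim an effect);
    ``UNDERSTATE`` seeks :math:`p_{meta}(D_S) \\ge \\alpha` (hide one).
    """

    OVERSTATE = "overstate"
    UNDERSTATE = "understate"


class Tau2Policy(str, Enum):
    """Where the between-study variance entering the subset analysis comes from.

    ``FULL_SET`` (default) estimates :math:`\\tau^2` once on all K studies
    and holds it fixed, which keeps the vulnerability bounds applicable;
    ``SUBSET`` re-estimates it on each candidate subset.
    """

    SUBSET = "subset"
    FULL_SET = "full_set"


@dataclass(frozen=True)
class CherryPickResult:
    """Outcome of one subset-selection attempt."""

    selected: tuple[str, ...]
    S: int
    direction: Direction
    strategy: str
    pmeta_selected: float
    pmeta_full: float
    flipped: bool
    alpha: float
    model: str
    policy: Tau2Policy
    tau2_full: float
    tau2_selected: float


def _coerce(direction, policy) -> tuple[Direction, Tau2Policy]:
    try:
        return Direction(direction), Tau2Policy(policy)
    except ValueError as exc:
        raise InputError(str(exc)) from None


def _context(studies: StudySet, model: str) -> float:
    """Full-set tau^2 used for ranking weights and the full-set analysis."""
    if model == "fixed":
        return 0.0
    if model != "random":
        raise InputError(f"model must be 'fixed' or 'random', got {model!r}")
    return _dl_tau2_arr(studies.effects, studies.variances)


def _rank_indices(
    effects: np.ndarray,
    variances: np.ndarray,
    tau2_rank: float,
    direction: Direction,
) -> np.ndarray:
    """All study indices ordered by the greedy preference.

    Per-study one-sided p is monotone decreasing in
    :math:`z_i = \\sqrt{w_i}\\,y_i`, so OVERSTATE ranks by descending z and
    UNDERSTATE by ascending z. The sort is stable: ties keep input order.
    """
    z = effects / np.sqrt(variances + tau2_rank)
    key = -z if direction is Direction.OVERSTATE else z
    return np.argsort(key, kind="stable")


def _subset_pmeta(
    effects: np.ndarray,
    variances: np.ndarray,
    idx: np.ndarray,
    model: str,
    policy: Tau2Policy,
    tau2_full: float,
) -> tuple[float, float]:
    """Pooled one-sided p on the subset ``idx`` and the tau^2 it used."""
    if model == "fixed":
        tau2 = 0.0
    elif policy is Tau2Policy.FULL_SET:
        tau2 = tau2_full
    else:
        tau2 = _dl_tau2_arr(effects[idx], variances[idx])
    theta, sw = _pool_arr(effects[idx], variances[idx], tau2)
    return _p_right(theta, sw), tau2


def select_top_s(
    studies: StudySet,
    S: int,
    direction: Direction | str,
    model: str = "fixed",
    alpha: float = 0.05,
    policy: Tau2Policy | str = Tau2Policy.FULL_SET,
) -> CherryPickResult:
    """Greedy top-``S`` selection by per-study one-sided p-value.

    OVERSTATE keeps the ``S`` smallest p-values, UNDERSTATE the ``S``
    largest; ties are broken by input order. The pooled p-value is then
    recomputed on the retained subset (with :math:`\\tau^2` per ``policy``
    under the random-effects model).
    """
    direction, policy = _coerce(direction, policy)
    K = len(studies)
    if not 1 <= S <= K:
        raise InputError(f"S must satisfy 1 <= S <= K={K}, got {S}")
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")

    eff, var = studies.effects, studies.variances
    tau2_full = _context(studies, model)
    order = _rank_indices(eff, var, tau2_full, direction)
    idx = np.sort(order[:S])  # report the subset in input order

    p_sel, tau2_sel = _subset_pmeta(eff, var, idx, model, policy, tau2_full)
    theta_full, sw_full = _pool_arr(eff, var, tau2_full)
    p_full = _p_right(theta_full, sw_full)

    return CherryPickResult(
        selected=tuple(studies.labels[i] for i in idx),
        S=S,
        direction=direction,
        strategy="greedy_top_s",
        pmeta_selected=p_sel,
        pmeta_full=p_full,
        flipped=(p_sel <= alpha) != (p_full <= alpha),
        alpha=alpha,
        model=model,
        policy=policy,
        tau2_full=tau2_full,
        tau2_selected=tau2_sel,
    )


def exhaustive_best_subset(
    studies: StudySet,
    S: int,
    direction: Direction | str,
    model: str = "fixed",
    alpha: float = 0.05,
    policy: Tau2Policy | str = Tau2Policy.FULL_SET,
    budget: int = 200_000,
) -> CherryPickResult:
    """Enumerate every size-``S`` subset and return the extremal one.

    Minimises (OVERSTATE) or maximises (UNDERSTATE) the pooled one-sided
    p-value; exact ties are resolved toward the lexicographically smallest
    sorted label tuple. Refuses to run when :math:`\\binom{K}{S}` exceeds
    ``budget``. Under ``policy=SUBSET`` with the random-effects model,
    :math:`\\tau^2` is re-estimated for every candidate subset (expensive).
    """
    direction, policy = _coerce(direction, policy)
    K = len(studies)
    if not 1 <= S <= K:
        raise InputError(f"S must satisfy 1 <= S <= K={K}, got {S}")
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")
    n_subsets = comb(K, S)
    if n_subsets > budget:
        raise InputError(
            f"C({K},{S}) = {n_subsets} subsets exceeds the enumeration "
            f"budget of {budget}"
        )

    eff, var = studies.effects, studies.variances
    tau2_full = _context(studies, model)
    combos = np.array(list(combinations(range(K), S)), dtype=np.intp)

    if model == "fixed" or policy is Tau2Policy.FULL_SET:
        tau2_pool = 0.0 if model == "fixed" else tau2_full
        w = 1.0 / (var + tau2_pool)
        sw = w[combos].sum(axis=1)
        theta = (w * eff)[combos].sum(axis=1) / sw
        tau2_cols = np.full(n_subsets, tau2_pool)
    else:
        w0 = 1.0 / var
        sw0 = w0[combos].sum(axis=1)
        y0 = (w0 * eff)[combos].sum(axis=1) / sw0
        q = (w0[combos] * (eff[combos] - y0[:, None]) ** 2).sum(axis=1)
        if S == 1:
            tau2_cols = np.zeros(n_subsets)
        else:
            denom = sw0 - (w0**2)[combos].sum(axis=1) / sw0
            tau2_cols = np.maximum(0.0, (q - (S - 1)) / denom)
        w = 1.0 / (var[combos] + tau2_cols[:, None])
        sw = w.sum(axis=1)
        theta = (w * eff[combos]).sum(axis=1) / sw
    # compare on the pooled z scale: p = Phi(-z) underflows to exact ties
    # for strongly significant subsets, z does not
    zstat = theta * np.sqrt(sw)
    best_z = zstat.max() if direction is Direction.OVERSTATE else zstat.min()
    ties = np.flatnonzero(zstat == best_z)
    if ties.size > 1:
        labels = studies.labels
        best = min(ties, key=lambda i: tuple(sorted(labels[j] for j in combos[i])))
    else:
        best = int(ties[0])
    idx = combos[best]

    theta_full, sw_full = _pool_arr(eff, var, tau2_full)
    p_full = _p_right(theta_full, sw_full)
    p_sel = float(norm.cdf(-zstat[best]))

    return CherryPickResult(
        selected=tuple(studies.labels[i] for i in idx),
        S=S,
        direction=direction,
        strategy="exhaustive",
        pmeta_selected=p_sel,
        pmeta_full=p_full,
        flipped=(p_sel <= alpha) != (p_full <= alpha),
        alpha=alpha,
        model=model,
        policy=policy,
        tau2_full=tau2_full,
        tau2_selected=float(tau2_cols[best]),
    )


def can_flip(
    studies: StudySet,
    S: int,
    alpha: float = 0.05,
    direction: Direction | str = Direction.OVERSTATE,
    model: str = "fixed",
    policy: Tau2Policy | str = Tau2Policy.FULL_SET,
    exhaustive: bool = False,
) -> tuple[bool, CherryPickResult]:
    """Can a size-``S`` selection flip the full-set conclusion?

    True iff the chosen strategy's subset achieves the direction's
    significance target while the full set does not: for OVERSTATE,
    :math:`p_{meta}(D_S) \\le \\alpha < p_{meta}(D_K)`; for UNDERSTATE the
    reverse inequalities.
    """
    strategy = exhaustive_best_subset if exhaustive else select_top_s
    res = strategy(studies, S, direction, model=model, alpha=alpha, policy=policy)
    if res.direction is Direction.OVERSTATE:
        achieved = res.pmeta_selected <= alpha
    else:
        achieved = res.pmeta_selected >= alpha
    return achieved and res.flipped, res
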