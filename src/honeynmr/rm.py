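"""Replacement Method (RM) variable selection around PLS-DA cross-validation.

RM is a deterministic local search for the d-variable subset minimising
RMSECV: start from a random d-subset and repeatedly try replacing one member
at a time with every non-member, keeping the swap that most reduces RMSECV,
until the subset is stable.  A regression with d variables has d possible
paths (the slot where replacement starts); the search runs every path from
every random start and keeps the best subset found.  Ties keep the incumbent
variable; among improving challengers the lowest column index wins.

An exhaustive enumerator over all d-subsets serves as the global-optimum
oracle on small problems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .chemometrics import _as_array, cv_pls


@dataclass
class RMResult:
    selected: tuple[int, ...]                 # sorted column indices
    rmsecv: float
    trajectory: list[tuple[int, int, tuple[int, ...], float]] = field(default_factory=list)
    # (start, path, subset, rmsecv) per accepted replacement
    n_starts: int = 0
    seed: int | None = None
    converged: bool = True
    selected_names: tuple | None = None
    n_evaluations: int = 0


def _make_scorer(Xa, y, n_blocks, max_lv, center):
    cache: dict[tuple[int, ...], float] = {}

    def score(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            res = cv_pls(Xa[:, subset], y, n_blocks=n_blocks,
                         max_lv=min(len(subset), max_lv), center=center)
            cache[subset] = float(res.rmsecv.min())
        return cache[subset]

    return score, cache


def rm_select(
    X,
    y,
    d: int,
    cv_spec: tuple[int, int] = (7, 3),
    seed: int = 0,
    n_starts: int = 10,
    center: bool = True,
) -> RMResult:
    """Select d variables by the Replacement Method.

    ``cv_spec = (n_blocks, max_lv)``; the latent-variable count inside each
    candidate evaluation is re-selected by the RMSECV argmin rule, capped at
    ``min(d, max_lv)``.
    """
    Xa, cols = _as_array(X)
    p = Xa.shape[1]
    if not 1 <= d <= p:
        raise ValueError(f"d must be in [1, {p}], got {d}")
    n_blocks, max_lv = cv_spec
    score, cache = _make_scorer(Xa, np.asarray(y, dtype=float).ravel(), n_blocks, max_lv, center)

    if d == p:
        full = tuple(range(p))
        s = score(full)
        return RMResult(full, s, [], n_starts=0, seed=seed, converged=True,
                        selected_names=tuple(cols) if cols else None, n_evaluations=1)

    rng = np.random.default_rng(seed)
    best_set: tuple[int, ...] | None = None
    best_score = np.inf
    trajectory: list[tuple[int, int, tuple[int, ...], float]] = []
    for start in range(n_starts):
        init = sorted(int(i) for i in rng.choice(p, size=d, replace=False))
        for path in range(d):
            cur = list(init)
            cur_score = score(tuple(sorted(cur)))
            changed = True
            while changed:
                changed = False
                for off in range(d):
                    slot = (path + off) % d
                    members = set(cur)
                    cand_best, cand_score = cur[slot], cur_score
                    for cand in range(p):
                        if cand in members:
                            continue
                        trial = list(cur)
                        trial[slot] = cand
                        s = score(tuple(sorted(trial)))
                        if s < cand_score:  # strict: ties keep incumbent / lowest index
                            cand_best, cand_score = cand, s
                    if cand_best != cur[slot]:
                        cur[slot] = cand_best
                        cur_score = cand_score
                        changed = True
                        trajectory.append((start, path, tuple(sorted(cur)), cur_score))
            final = tuple(sorted(cur))
            if cur_score < best_score or (cur_score == best_score and final < (best_set or final)):
                best_set, best_score = final, cur_score

    names = tuple(cols[i] for i in best_set) if cols else None
    return RMResult(best_set, best_score, trajectory, n_starts=n_starts, seed=seed,
                    converged=True, selected_names=names, n_evaluations=len(cache))


def exhaustive_select(
    X,
    y,
    d: int,
    cv_spec: tuple[int, int] = (7, 3),
    budget: int = 10_000,
    center: bool = True,
) -> RMResult:
    """Global minimum over every d-subset (ties -> lexicographically smallest)."""
    Xa, cols = _as_array(X)
    p = Xa.shape[1]
    if not 1 <= d <= p:
        raise ValueError(f"d must be in [1, {p}], got {d}")
    n_subsets = comb(p, d)
    if n_subsets > budget:
        raise ValueError(
            f"C({p},{d}) = {n_subsets} exceeds the budget of {budget}; "
            "lower p or d (or raise the budget)"
        )
    n_blocks, max_lv = cv_spec
    score, cache = _make_scorer(Xa, np.asarray(y, dtype=float).ravel(), n_blocks, max_lv, center)
    best_set, best_score = None, np.inf
    for subset in itertools.combinations(range(p), d):
        s = score(subset)
        if s < best_score:  # strict: first (lexicographically smallest) minimum kept
            best_set, best_score = subset, s
    names = tuple(cols[i] for i in best_set) if cols else None
    return RMResult(best_set, best_score, [], n_starts=0, seed=None, converged=True,
                    selected_names=names, n_evaluations=len(cache))
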