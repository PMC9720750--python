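"""LMG relative-importance decomposition and one-way ANOVA helpers.

The LMG metric attributes the full-model R^2 of a linear regression to its
predictor groups by averaging, over orderings of the groups, the increase in
R^2 contributed by each group when it enters the model. With interaction
terms included as their own groups, orderings in which an interaction would
enter before one of its parent main effects are statistically incoherent;
with ``marginality=True`` (the default) such orderings are excluded and the
average is taken over the admissible orderings only.

Two equivalent evaluation routes are provided: explicit enumeration of the
admissible orderings (used for <= 6 groups) and a subset-based route that
weights each subset by the number of admissible orderings passing through it,
counted by dynamic programming over down-sets of the marginality partial
order (used for larger problems). Shares always sum to the full-model R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

from ._lm import term_parents

__all__ = ["VariancePartition", "lmg_shares", "anova_oneway", "OneWayAnova"]


@dataclass(frozen=True)
class VariancePartition:
    """LMG shares of response variance by predictor group.

    ``shares`` are fractions of *total* response variance (they sum to the
    full-model R^2); ``shares_pct`` and ``shares_of_explained_pct`` are the
    two percentage normalisations.
    """

    shares: dict[str, float]
    r2_full: float
    method: str
    marginality: bool

    @property
    def shares_pct(self) -> dict[str, float]:
        """Percent of total response variance (sums to 100 * R^2)."""
        return {k: 100.0 * v for k, v in self.shares.items()}

    @property
    def shares_of_explained_pct(self) -> dict[str, float]:
        """Percent of the explained variance (sums to 100)."""
        if self.r2_full == 0:
            return {k: 0.0 for k in self.shares}
        return {k: 100.0 * v / self.r2_full for k, v in self.shares.items()}

    def summary(self) -> str:
        lines = [f"LMG decomposition ({self.method}, "
                 f"{'marginality-restricted' if self.marginality else 'all orderings'})",
                 f"full-model R2 = {self.r2_full:.4f}"]
        for k, v in self.shares.items():
            lines.append(
                f"  {k}: {100 * v:.2f}% of total "
                f"({self.shares_of_explained_pct[k]:.2f}% of explained)"
            )
        return "\n".join(lines)


def _r2_cache(y: np.ndarray, groups: dict[str, np.ndarray]):
    """Return a memoised R^2(subset) evaluator over group subsets."""
    names = list(groups)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        raise ValueError("response has zero variance")
    mats = {}
    for k in names:
        m = np.asarray(groups[k], dtype=float)
        mats[k] = m[:, None] if m.ndim == 1 else m
    cache: dict[frozenset, float] = {frozenset(): 0.0}

    def r2(subset: frozenset) -> float:
        if subset in cache:
            return cache[subset]
        X = np.hstack([np.ones((y.size, 1))] + [mats[k] for k in names if k in subset])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        val = 1.0 - float(resid @ resid) / sst
        cache[subset] = val
        return val

    return names, r2


def _admissible(order: tuple[str, ...], parents: dict[str, set[str]]) -> bool:
    seen: set[str] = set()
    for g in order:
        if parents[g] - seen:
            return False
        seen.add(g)
    return True


def _parents_within(names: list[str]) -> dict[str, set[str]]:
    name_set = set(names)
    return {g: term_parents(g) & name_set for g in names}


def _count_extensions(remaining: frozenset, parents: dict[str, set[str]],
                      done: frozenset, memo: dict) -> int:
    """Number of admissible orderings of ``remaining`` given ``done`` placed."""
    if not remaining:
        return 1
    key = remaining
    if key in memo:
        return memo[key]
    total = 0
    for g in remaining:
        if parents[g] <= done:
            total += _count_extensions(remaining - frozenset([g]), parents, done | {g}, memo)
    memo[key] = total
    return total


def _lmg_enumeration(y, groups, marginality: bool) -> tuple[dict[str, float], float]:
    names, r2 = _r2_cache(y, groups)
    parents = _parents_within(names) if marginality else {g: set() for g in names}
    orders = [o for o in permutations(names) if _admissible(o, parents)]
    if not orders:
        raise ValueError("no admissible orderings; check marginality structure")
    shares = {g: 0.0 for g in names}
    for order in orders:
        run: frozenset = frozenset()
        for g in order:
            nxt = run | {g}
            shares[g] += r2(frozenset(nxt)) - r2(run)
            run = nxt
    shares = {g: v / len(orders) for g, v in shares.items()}
    return shares, r2(frozenset(names))


def _lmg_subsets(y, groups, marginality: bool) -> tuple[dict[str, float], float]:
    """Subset-weighted (Shapley-style) evaluation over admissible orderings.

    For each group g and each admissible prefix set S (a down-set of the
    marginality order containing all parents of g), the weight is
    N(S) * M(S + g) / N(all), where N counts admissible orderings of a
    down-set and M counts admissible completions.
    """
    names, r2 = _r2_cache(y, groups)
    parents = _parents_within(names) if marginality else {g: set() for g in names}
    all_set = frozenset(names)

    n_memo: dict[frozenset, int] = {frozenset(): 1}

    def n_orderings(s: frozenset) -> int:
        """Admissible orderings of the down-set s (parents of members in s)."""
        if s in n_memo:
            return n_memo[s]
        total = 0
        for g in s:
            # g can be last iff no member of s\{g} requires g... i.e. g is not
            # a parent of any other member of s
            if any(g in parents[h] for h in s if h != g):
                continue
            total += n_orderings(s - frozenset([g]))
        n_memo[s] = total
        return total

    def completions(placed: frozenset) -> int:
        """Admissible orderings of the remaining groups after ``placed``."""
        rem = all_set - placed
        memo: dict = {}
        return _count_extensions(frozenset(rem), parents, placed, memo)

    # enumerate down-sets (antichains closed under parents) via BFS
    downsets: set[frozenset] = {frozenset()}
    frontier = [frozenset()]
    while frontier:
        s = frontier.pop()
        for g in all_set - s:
            if parents[g] <= s:
                t = s | {g}
                if t not in downsets:
                    downsets.add(t)
                    frontier.append(t)

    total_orders = n_orderings(all_set)
    shares = {g: 0.0 for g in names}
    for s in downsets:
        ns = n_orderings(s)
        if ns == 0 and s:
            continue
        for g in all_set - s:
            if not parents[g] <= s:
                continue
            w = ns * completions(s | {g})
            if w == 0:
                continue
            shares[g] += w * (r2(s | {g}) - r2(s))
    shares = {g: v / total_orders for g, v in shares.items()}
    return shares, r2(all_set)


def lmg_shares(
    response,
    predictor_groups: dict[str, np.ndarray],
    marginality: bool = True,
    method: str = "auto",
) -> VariancePartition:
    """LMG decomposition of linear-model R^2 over predictor groups.

    Parameters
    ----------
    response : array-like, length n
    predictor_groups : mapping of group name -> (n,) or (n, k) design block.
        Interaction groups are named with colons (``"lnM:T"``); with
        ``marginality=True`` they may only enter after all their parent
        groups present in the mapping.
    method : {"auto", "exact_permutations", "shapley_subsets"}
        ``auto`` enumerates orderings for <= 6 groups and uses the subset
        route otherwise.

    Raises on rank-deficient full designs.
    """
    if not predictor_groups:
        raise ValueError("at least one predictor group required")
    y = np.asarray(response, dtype=float)
    X_full = np.hstack(
        [np.ones((y.size, 1))]
        + [np.asarray(m, float).reshape(y.size, -1) for m in predictor_groups.values()]
    )
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient full design")
    if method == "auto":
        method = "exact_permutations" if len(predictor_groups) <= 6 else "shapley_subsets"
    if method == "exact_permutations":
        shares, r2_full = _lmg_enumeration(y, predictor_groups, marginality)
    elif method == "shapley_subsets":
        shares, r2_full = _lmg_subsets(y, predictor_groups, marginality)
    else:
        raise ValueError(f"unknown method {method!r}")
    return VariancePartition(
        shares=shares, r2_full=r2_full, method=method, marginality=marginality
    )


@dataclass(frozen=True)
class OneWayAnova:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict


def anova_oneway(values, groups) -> OneWayAnova:
    """Classical one-way ANOVA of ``values`` across the levels of ``groups``."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs >= 2 values")
    f, p = stats.f_oneway(*samples)
    return OneWayAnova(
        f_stat=float(f),
        df_between=int(levels.size - 1),
        df_within=int(values.size - levels.size),
        p_value=float(p),
        group_means={g: float(s.mean()) for g, s in zip(levels, samples)},
    )
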