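"""Term-structured linear models: named term groups, marginality, F-tests.

The statistical modules fit ANCOVA-style models whose design matrices are
organised in *terms* (e.g. ``"lnM"``, ``"site"``, ``"lnM:T:site"``). A term is
a colon-joined product of factors; a categorical factor expands to drop-first
dummy columns. Keeping the term structure explicit makes marginality-aware
stepwise elimination and grouped variance decomposition straightforward,
while the actual fitting is delegated to statsmodels OLS.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


def term_factors(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


def term_order(term: str) -> int:
    return len(term_factors(term))


def term_parents(term: str) -> set[str]:
    """All lower-order marginal terms of an interaction term."""
    f = term_factors(term)
    out: set[str] = set()
    for r in range(1, len(f)):
        for combo in combinations(f, r):
            out.add(":".join(combo))
    return out


@dataclass
class TermModel:
    """A response plus a dictionary of named term column-blocks.

    ``blocks[term]`` is an (n, k) array; the intercept is implicit and always
    included. Categorical factors are dummy-coded against their first level.
    """

    y: np.ndarray
    blocks: dict[str, np.ndarray]
    colnames: dict[str, list[str]]

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        response: str,
        terms: Sequence[str],
        categorical: dict[str, Sequence] | None = None,
    ) -> "TermModel":
        """Build term blocks from a data frame.

        ``categorical`` maps factor names to their ordered levels (first level
        is the reference); factors not listed are treated as continuous
        columns of ``df``.
        """
        categorical = categorical or {}
        factor_cols: dict[str, tuple[np.ndarray, list[str]]] = {}
        for name in {f for t in terms for f in term_factors(t)}:
            if name in categorical:
                levels = list(categorical[name])
                cols = np.column_stack(
                    [(df[name].to_numpy() == lev).astype(float) for lev in levels[1:]]
                ) if len(levels) > 1 else np.empty((len(df), 0))
                labels = [f"{name}[{lev}]" for lev in levels[1:]]
            else:
                cols = df[name].to_numpy(dtype=float)[:, None]
                labels = [name]
            factor_cols[name] = (cols, labels)
        blocks: dict[str, np.ndarray] = {}
        colnames: dict[str, list[str]] = {}
        for term in terms:
            mats, labs = zip(*(factor_cols[f] for f in term_factors(term)))
            cur = mats[0]
            cur_labs = list(labs[0])
            for m, lb in zip(mats[1:], labs[1:]):
                cur = np.einsum("ni,nj->nij", cur, m).reshape(len(df), -1)
                cur_labs = [f"{a}:{b}" for a in cur_labs for b in lb]
            blocks[term] = cur
            colnames[term] = cur_labs
        return cls(
            y=df[response].to_numpy(dtype=float), blocks=blocks, colnames=colnames
        )

    def design(self, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
        X = [np.ones((self.y.size, 1))]
        names = ["Intercept"]
        for t in terms:
            X.append(self.blocks[t])
            names.extend(self.colnames[t])
        return np.hstack(X), names

    def fit(self, terms: Sequence[str]):
        """OLS fit of the listed terms (plus intercept)."""
        X, names = self.design(terms)
        res = sm.OLS(self.y, X).fit()
        res.model.exog_names[:] = names  # readable coefficient labels
        return res

    def check_full_rank(self, terms: Sequence[str]) -> None:
        """Raise naming aliased terms when the full design is rank-deficient."""
        X, _ = self.design(terms)
        if np.linalg.matrix_rank(X) == X.shape[1]:
            return
        aliased = []
        base = np.ones((self.y.size, 1))
        cur = base
        for t in terms:
            cand = np.hstack([cur, self.blocks[t]])
            if np.linalg.matrix_rank(cand) < cur.shape[1] + self.blocks[t].shape[1]:
                aliased.append(t)
            cur = cand
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def nested_f_test(model: TermModel, terms: Sequence[str], drop: str):
    """F-test of the nested model without ``drop`` against the full model.

    Returns (F, df_num, df_den, p).
    """
    full = model.fit(terms)
    restricted = model.fit([t for t in terms if t != drop])
    f, p, df_num = full.compare_f_test(restricted)
    return float(f), int(df_num), int(full.df_resid), float(p)


def removable_terms(terms: Sequence[str]) -> list[str]:
    """Terms not marginal to any other retained term (stepwise candidates)."""
    term_set = set(terms)
    return [t for t in terms if not any(t in term_parents(o) for o in term_set if o != t)]


def stepwise_eliminate(
    model: TermModel, terms: Sequence[str], alpha: float = 0.05
) -> tuple[list[str], list[dict]]:
    """Backward elimination by nested F-tests, respecting marginality.

    At each step the highest-order removable term with the largest p-value is
    dropped if p > alpha; stops when every removable term is significant.
    Returns the retained terms and the elimination trace.
    """
    retained = list(terms)
    trace: list[dict] = []
    while True:
        candidates = removable_terms(retained)
        if not candidates:
            break
        tests = []
        for t in candidates:
            f, dfn, dfd, p = nested_f_test(model, retained, t)
            tests.append({"term": t, "p": p, "F": f, "df_num": dfn, "df_den": dfd})
        nonsig = [x for x in tests if x["p"] > alpha]
        if not nonsig:
            break
        pick = max(nonsig, key=lambda x: (term_order(x["term"]), x["p"]))
        retained.remove(pick["term"])
        trace.append(pick)
    return retained, trace
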