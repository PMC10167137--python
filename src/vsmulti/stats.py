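"""Rank-based factorial inference and robust correlation estimators.

* :func:`ats` — the ANOVA-type statistic for fully crossed between-subjects
  factorial designs: the response is pooled-ranked, relative treatment
  effects are computed per cell, and each main effect / interaction is
  tested with a Box-approximated F statistic (possibly non-integer
  numerator df, finite denominator df).
* :func:`percentage_bend_cor` — Wilcox's percentage bend correlation,
  down-weighting a fixed fraction ``beta`` of extreme deviations from the
  median before forming the normalised cross-product.
* :func:`kendall_tau` — Kendall's tau-b (tie-corrected).

Thin nonparametric utilities for demographics checks (Mann-Whitney,
chi-square on a contingency table) are included for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "ATSResult",
    "ats",
    "percentage_bend_cor",
    "kendall_tau",
    "mann_whitney",
    "chi_square",
]


@dataclass
class ATSResult:
    table: pd.DataFrame          # effect, statistic, df1, df2, p
    n: int
    factors: tuple

    def to_dict(self) -> dict:
        return {"n": int(self.n), "factors": list(self.factors),
                "table": self.table.to_dict(orient="records")}

    def effect(self, name: str) -> dict:
        row = self.table.loc[self.table["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0].to_dict()


def _centering(levels: int) -> np.ndarray:
    return np.eye(levels) - np.ones((levels, levels)) / levels


def _averaging(levels: int) -> np.ndarray:
    return np.ones((levels, levels)) / levels


def ats(data: pd.DataFrame, factors, response: str,
        denominator: str = "finite") -> ATSResult:
    """ANOVA-type statistic for a crossed factorial design.

    Every combination of factor levels must be a nonempty cell with at
    least two observations.  ``denominator="finite"`` uses the standard
    finite denominator-df approximation; ``denominator="inf"`` refers the
    statistic to F(df1, inf).
    """
    factors = list(factors)
    y = data[response].to_numpy(dtype=float)
    n_total = y.size
    ranks = sp_stats.rankdata(y)

    level_lists = [sorted(data[f].unique(), key=str) for f in factors]
    cells = list(product(*level_lists))
    d = len(cells)

    cell_index = {}
    keys = list(zip(*[data[f] for f in factors]))
    for i, key in enumerate(keys):
        cell_index.setdefault(key, []).append(i)
    empty = [c for c in cells if c not in cell_index]
    if empty:
        raise ValueError(f"empty design cells: {empty}")
    small = [c for c in cells if len(cell_index[c]) < 2]
    if small:
        raise ValueError(f"cells with fewer than two observations: {small}")

    n_i = np.array([len(cell_index[c]) for c in cells], dtype=float)
    rbar = np.array([np.mean(ranks[cell_index[c]]) for c in cells])
    s2 = np.array([np.var(ranks[cell_index[c]], ddof=1) for c in cells])

    p_hat = (rbar - 0.5) / n_total                      # relative effects
    v = n_total * (s2 / (n_total ** 2)) / n_i           # diag of V_N
    V = np.diag(v)

    rows = []
    sizes = [len(ls) for ls in level_lists]
    for order in range(1, len(factors) + 1):
        for subset in combinations(range(len(factors)), order):
            M = np.ones((1, 1))
            for j, a in enumerate(sizes):
                part = _centering(a) if j in subset else _averaging(a)
                M = np.kron(M, part)
            T = M      # symmetric idempotent hypothesis projection
            tv = T @ V
            tr_tv = np.trace(tv)
            stat = n_total * (p_hat @ T @ p_hat) / tr_tv
            df1 = tr_tv ** 2 / np.trace(tv @ tv)
            t_ii = np.diag(T)
            df2_den = np.sum((t_ii * v) ** 2 / (n_i - 1.0))
            df2 = tr_tv ** 2 / df2_den if df2_den > 0 else np.inf
            if denominator == "inf":
                df2 = np.inf
            p = float(sp_stats.f.sf(stat, df1, df2)) if np.isfinite(df2) \
                else float(sp_stats.chi2.sf(stat * df1, df1))
            rows.append({"effect": ":".join(factors[i] for i in subset),
                         "statistic": float(stat), "df1": float(df1),
                         "df2": float(df2), "p": p})
    return ATSResult(table=pd.DataFrame(rows), n=n_total, factors=tuple(factors))


def percentage_bend_cor(x, y, beta: float = 0.2) -> float:
    """Wilcox's percentage bend correlation.

    The bend constant for each variable is the ``(1 - beta)`` empirical
    quantile of absolute deviations from the median; deviations are passed
    through the clipping psi function before the normalised cross-product.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least five observations")

    def psi_scores(v):
        med = np.median(v)
        w = np.sort(np.abs(v - med))
        m = int(np.floor((1.0 - beta) * n + 0.5))
        omega = w[m - 1]
        if omega <= 0:
            raise ValueError("zero bend scale (constant input)")
        z = (v - med) / omega
        i1 = int(np.sum(z < -1.0))
        i2 = int(np.sum(z > 1.0))
        sx = np.sum(v[(z >= -1.0) & (z <= 1.0)])
        phi = (omega * (i2 - i1) + sx) / (n - i1 - i2)
        return np.clip((v - phi) / omega, -1.0, 1.0)

    a = psi_scores(x)
    b = psi_scores(y)
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected concordance coefficient)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau undefined for an all-tied vector")
    tau, _ = sp_stats.kendalltau(x, y)
    return float(tau)


def mann_whitney(x, y) -> dict:
    res = sp_stats.mannwhitneyu(x, y, alternative="two-sided")
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def chi_square(table) -> dict:
    res = sp_stats.chi2_contingency(np.asarray(table))
    return {"statistic": float(res.statistic), "df": int(res.dof),
            "p": float(res.pvalue)}
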