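"""Variable-importance screening: Boruta shadow features and One Rule.

Boruta decides, for every candidate covariate, whether it carries *any*
information about the response: each iteration appends a permuted "shadow"
copy of every covariate, fits a random forest on the augmented table, and
scores a covariate a *hit* when its permutation importance exceeds the most
important shadow.  Two-sided binomial tests on the accumulated hit counts
(level 0.01, Bonferroni-corrected over iterations) drive the
confirmed / rejected decisions; covariates still undecided after
``max_iter`` iterations remain tentative.

One Rule is the classical single-variable baseline: discretize, map each
level of one covariate to its majority class, and rank covariates by the
training accuracy of that one rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = ["ImportanceResult", "boruta", "one_rule"]


@dataclass
class ImportanceResult:
    decisions: dict                       # name -> confirmed | tentative | rejected
    importance_history: pd.DataFrame      # iterations x variables
    shadow_max_history: np.ndarray
    hits: dict
    n_iterations: int
    one_rule_accuracy: dict = field(default_factory=dict)

    @property
    def confirmed(self):
        return sorted(k for k, v in self.decisions.items() if v == "confirmed")

    def to_dict(self) -> dict:
        return {
            "decisions": self.decisions,
            "hits": {k: int(v) for k, v in self.hits.items()},
            "n_iterations": int(self.n_iterations),
            "shadow_max_history": [float(v) for v in self.shadow_max_history],
            "importance_history": {
                c: [float(v) for v in self.importance_history[c]]
                for c in self.importance_history.columns
            },
            "one_rule_accuracy": {k: float(v) for k, v in self.one_rule_accuracy.items()},
        }


def _encode(X: pd.DataFrame) -> np.ndarray:
    cols = []
    for c in X.columns:
        col = X[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            cols.append(pd.Categorical(col).codes.astype(float))
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def _permutation_importance(model, Z, y, rng, n_repeats=3):
    """Mean increase in MSE when one column of ``Z`` is permuted.

    ``Z``/``y`` should be data the model was *not* fit on: evaluating the
    permutation loss on the training rows systematically inflates the
    importance of high-cardinality or weakly confounded covariates, because
    permuting them also destroys memorised noise.  All permuted copies are
    stacked into a single ``predict`` call, which is far cheaper than one
    forest traversal per column and repeat.
    """
    n, k = Z.shape
    base = np.mean((model.predict(Z) - y) ** 2)
    blocks = []
    for j in range(k):
        for _ in range(n_repeats):
            zp = Z.copy()
            zp[:, j] = zp[rng.permutation(n), j]
            blocks.append(zp)
    preds = model.predict(np.vstack(blocks)).reshape(k, n_repeats, n)
    mses = np.mean((preds - y[None, None, :]) ** 2, axis=2)
    return mses.mean(axis=1) - base


def _holdout_split(rng, n, holdout, groups):
    """Train/held-out row indices; group-wise when ``groups`` is given.

    Rows sharing a group label (e.g. repeated observations of one
    participant) stay on the same side of the split, so memorising a
    cluster during fitting cannot pay off at evaluation time.
    """
    if holdout <= 0:
        idx = rng.permutation(n)
        return idx, idx
    if groups is None:
        perm = rng.permutation(n)
        n_hold = max(int(round(holdout * n)), 10)
        return perm[n_hold:], perm[:n_hold]
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    k_hold = max(int(round(holdout * uniq.size)), 2)
    hold_groups = rng.choice(uniq, size=k_hold, replace=False)
    hold_mask = np.isin(labels, hold_groups)
    return np.flatnonzero(~hold_mask), np.flatnonzero(hold_mask)


def boruta(X: pd.DataFrame, y, max_iter: int = 30, seed: int | None = None,
           n_estimators: int = 150, n_repeats: int = 5,
           alpha: float = 0.01, holdout: float = 0.25, groups=None,
           classification: bool = False) -> ImportanceResult:
    """All-relevant screening of the columns of ``X`` against ``y``.

    Permutation importance (not impurity) is used throughout, since the
    comparison against permuted shadows requires an importance measure that
    is itself permutation-based; each iteration refits the forest on a
    fresh ``1 - holdout`` split and measures importances on the held-out
    rows (the out-of-sample analogue of out-of-bag importance).  With
    ``groups`` (e.g. participant ids) the split keeps whole groups
    together, which stops covariates that merely identify a group — a
    participant's exact age across their repeated rows — from scoring
    memorisation as importance.  Deterministic for a fixed ``seed``.
    """
    if max_iter < 10:
        raise ValueError("max_iter must be at least 10")
    if X.isna().any().any():
        raise ValueError("covariate table contains missing values")
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    k = len(names)
    n = len(y)
    Xe = _encode(X)
    rng = np.random.default_rng(seed)

    hits = dict.fromkeys(names, 0)
    decisions = dict.fromkeys(names, "tentative")
    hist = []
    shadow_hist = []
    Forest = RandomForestClassifier if classification else RandomForestRegressor

    it = 0
    for it in range(1, max_iter + 1):
        shadows = Xe.copy()
        for j in range(k):
            shadows[:, j] = shadows[rng.permutation(n), j]
        Z = np.hstack([Xe, shadows])
        train, hold = _holdout_split(rng, n, holdout, groups)
        forest = Forest(n_estimators=n_estimators,
                        random_state=int(rng.integers(2**31 - 1)),
                        n_jobs=1)
        forest.fit(Z[train], y[train])
        imp = _permutation_importance(forest, Z[hold], y[hold], rng,
                                      n_repeats=n_repeats)
        real, shadow = imp[:k], imp[k:]
        shadow_max = float(shadow.max())
        hist.append(real)
        shadow_hist.append(shadow_max)
        for j, name in enumerate(names):
            if real[j] > shadow_max:
                hits[name] += 1
        # two-sided binomial decision, Bonferroni over the iteration budget
        thr = alpha / max_iter
        for name in names:
            if decisions[name] != "tentative":
                continue
            h = hits[name]
            if sp_stats.binom.sf(h - 1, it, 0.5) < thr / 2:
                decisions[name] = "confirmed"
            elif sp_stats.binom.cdf(h, it, 0.5) < thr / 2:
                decisions[name] = "rejected"
        if all(v != "tentative" for v in decisions.values()):
            break

    history = pd.DataFrame(hist, columns=names)
    return ImportanceResult(decisions=decisions, importance_history=history,
                            shadow_max_history=np.asarray(shadow_hist),
                            hits=hits, n_iterations=it)


def _discretize(col: pd.Series, n_bins: int = 4) -> np.ndarray:
    vals = col.to_numpy()
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        return pd.Categorical(col).codes
    uniq = np.unique(vals)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, vals)
    ranks = pd.qcut(vals, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(ranks)


def one_rule(X: pd.DataFrame, y, n_bins: int = 4) -> dict:
    """Training accuracy of the best single-variable majority rule.

    Numeric responses and covariates are discretized by quartiles.  The
    accuracy of every variable is at least the majority-class baseline.
    """
    y_binned = _discretize(pd.Series(y), n_bins=n_bins)
    out = {}
    for c in X.columns:
        levels = _discretize(X[c], n_bins=n_bins)
        correct = 0
        for lv in np.unique(levels):
            sub = y_binned[levels == lv]
            _, counts = np.unique(sub, return_counts=True)
            correct += int(counts.max())
        out[c] = correct / len(y_binned)
    return out
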