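"""Distributional regression trees.

Recursive partitioning in which every node fits a full parametric
distribution (Ex-Gaussian for reaction times, generalized beta type 1 for
accuracy rates) by maximum likelihood, and splits wherever the
per-observation score contributions show significant parameter instability
along a covariate — the model-based recursive-partitioning scheme built on
M-fluctuation tests.

The node model is intercept-only: covariates act exclusively through
splits, so each node of the fitted tree is a plain distribution, exactly
the object displayed in the usual tree figures (n, median, approximate 95%
CI of the median per node).

Covariate handling:

* nominal (group, gender, target): a chi-square fluctuation statistic over
  level-wise score sums; splits consider every level bipartition;
* ordinal (set size): the same chi-square statistic, but admissible splits
  are restricted to contiguous-level bipartitions;
* numeric (age): a supLM statistic over ordered cutpoints within a trimmed
  range, with its asymptotic p-value (supremum of a squared, tied-down
  Bessel process, evaluated by a cached simulation of the limit process).

P-values are Bonferroni-adjusted across the covariates showing variation
(the supLM already accounts for scanning cutpoints, so no correction over
cutpoints is applied); a node splits only when the adjusted p-value falls
below ``alpha``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .distributions import DistributionSpec, FittedNodeModel, fit_mle

__all__ = [
    "TreeConfig",
    "TreeNode",
    "instability_test",
    "select_split",
    "find_partition",
    "grow",
    "median_ci",
    "to_dot",
]

COVARIATE_KINDS = ("numeric", "ordinal", "nominal")


@dataclass
class TreeConfig:
    """Tuning parameters of the tree grower."""

    family: DistributionSpec
    covariates: dict                      # name -> kind
    alpha: float = 0.05
    min_node: int = 20
    max_depth: int = 5
    trim: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_node < 5 * self.family.n_params:
            raise ValueError("min_node must be at least 5x the parameter count")
        for name, kind in self.covariates.items():
            if kind not in COVARIATE_KINDS:
                raise ValueError(f"covariate {name!r} has unknown kind {kind!r}")


@dataclass
class TreeNode:
    node_id: int
    depth: int
    model: FittedNodeModel
    summary: dict
    data_index: np.ndarray = field(repr=False)
    split: dict | None = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def leaves(self):
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "depth": self.depth,
            "n": self.summary["n"],
            "median": self.summary["median"],
            "ci": [self.summary["ci_lo"], self.summary["ci_hi"]],
            "family": self.model.spec.family,
            "theta_hat": dict(zip(self.model.spec.parameter_names,
                                  np.asarray(self.model.theta_hat).tolist())),
            "loglik": self.model.loglik,
        }
        if self.split is not None:
            s = dict(self.split)
            if "left_levels" in s:
                s["left_levels"] = list(s["left_levels"])
                s["right_levels"] = list(s["right_levels"])
            d["split"] = s
            d["children"] = [c.to_dict() for c in self.children]
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=_json_default, **kw)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


# --------------------------------------------------------------------------
# median with approximate 95% CI (binomial order-statistic method)
# --------------------------------------------------------------------------

def median_ci(sample, z: float = 1.96) -> dict:
    """Median and approximate 95% CI from order statistics.

    Uses the binomial rank method: the interval runs from order statistic
    ``floor((n - z sqrt(n)) / 2)`` to its symmetric counterpart
    ``ceil((n + z sqrt(n)) / 2)``, clamped to the sample range.  For fewer
    than six observations the sample range is reported (with a width
    warning flag) since the ranks degenerate.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("median_ci needs at least one observation")
    med = float(np.median(x))
    if n < 6:
        return {"median": med, "lo": float(x[0]), "hi": float(x[-1]),
                "wide": True}
    lo_rank = int(np.floor((n - z * np.sqrt(n)) / 2.0))
    hi_rank = int(np.ceil((n + z * np.sqrt(n)) / 2.0))
    lo_rank = min(max(lo_rank, 1), n)
    hi_rank = min(max(hi_rank, 1), n)
    return {"median": med, "lo": float(x[lo_rank - 1]),
            "hi": float(x[hi_rank - 1]), "wide": False}


# --------------------------------------------------------------------------
# parameter-instability tests
# --------------------------------------------------------------------------

_SUPLM_NULL_CACHE: dict = {}
_SUPLM_PATHS = 20000
_SUPLM_GRID = 1000
_SUPLM_SEED = 202306  # fixed: the asymptotic null table is not data-dependent


def _suplm_null(p: int, trim: float) -> np.ndarray:
    """Simulated null distribution of the supLM statistic.

    The limit of the supLM scan is ``sup_{t in [trim, 1-trim]}
    ||B(t)||^2 / (t (1-t))`` for a p-dimensional Brownian bridge B; the
    distribution is simulated once per (p, trim) on a fine grid and cached.
    """
    key = (p, round(trim, 6))
    tab = _SUPLM_NULL_CACHE.get(key)
    if tab is not None:
        return tab
    rng = np.random.default_rng(_SUPLM_SEED + 1000 * p)
    m = _SUPLM_GRID
    t = np.arange(1, m) / m
    mask = (t >= trim) & (t <= 1.0 - trim)
    tsel = t[mask]
    denom = tsel * (1.0 - tsel)
    stats_out = np.empty(_SUPLM_PATHS)
    chunk = 2000
    for start in range(0, _SUPLM_PATHS, chunk):
        k = min(chunk, _SUPLM_PATHS - start)
        incr = rng.standard_normal((k, m, p)) / np.sqrt(m)
        w = np.cumsum(incr, axis=1)
        total = w[:, -1:, :]
        b = w[:, :-1, :] - t[None, :, None] * total
        lm = np.sum(b[:, mask, :] ** 2, axis=2) / denom[None, :]
        stats_out[start:start + k] = lm.max(axis=1)
    tab = np.sort(stats_out)
    _SUPLM_NULL_CACHE[key] = tab
    return tab


def _decorrelate(score_matrix: np.ndarray) -> np.ndarray:
    """Whiten the (centered) scores with the inverse square root of their
    empirical covariance."""
    s = score_matrix - score_matrix.mean(axis=0, keepdims=True)
    n = s.shape[0]
    j = s.T @ s / n
    # guard against numerically singular information (boundary-ish fits)
    eps = 1e-10 * np.trace(j) / max(j.shape[0], 1)
    j = j + eps * np.eye(j.shape[0])
    vals, vecs = np.linalg.eigh(j)
    vals = np.maximum(vals, 1e-12 * vals.max())
    j_inv_sqrt = vecs @ np.diag(vals ** -0.5) @ vecs.T
    return s @ j_inv_sqrt


def instability_test(score_matrix, covariate, kind: str, trim: float = 0.1) -> dict:
    """Test parameter instability of a node fit along one covariate.

    Returns ``{"statistic", "p"}``.  Nominal/ordinal covariates use a
    chi-square fluctuation statistic over level-wise score sums (df =
    (k - 1) p); numeric covariates use the supLM scan over ordered
    cutpoints in the trimmed range with its asymptotic p-value.  A constant
    covariate yields p = 1 by convention.
    """
    s = np.asarray(score_matrix, dtype=float)
    cov = np.asarray(covariate)
    n, p = s.shape
    if cov.shape[0] != n:
        raise ValueError("covariate length must match the score matrix")

    if kind in ("nominal", "ordinal"):
        levels, inv = np.unique(cov, return_inverse=True)
        k = levels.size
        if k < 2:
            return {"statistic": 0.0, "p": 1.0}
        u = _decorrelate(s)
        stat = 0.0
        for li in range(k):
            m = inv == li
            n_l = int(m.sum())
            s_l = u[m].sum(axis=0)
            stat += float(s_l @ s_l) / n_l
        df = (k - 1) * p
        return {"statistic": stat, "p": float(sp_stats.chi2.sf(stat, df))}

    if kind == "numeric":
        cov = cov.astype(float)
        if np.ptp(cov) == 0.0:
            return {"statistic": 0.0, "p": 1.0}
        order = np.argsort(cov, kind="mergesort")
        u = _decorrelate(s)[order]
        c_sorted = cov[order]
        w = np.cumsum(u, axis=0) / np.sqrt(n)
        j = np.arange(1, n)                       # cut after position j
        t = j / n
        valid = (t >= trim) & (t <= 1.0 - trim) & (c_sorted[1:] > c_sorted[:-1])
        if not valid.any():
            return {"statistic": 0.0, "p": 1.0}
        lm = np.sum(w[:-1] ** 2, axis=1) / (t * (1.0 - t))
        stat = float(lm[valid].max())
        tab = _suplm_null(p, trim)
        p_val = (np.searchsorted(tab, stat, side="left"), tab.size)
        pv = 1.0 - p_val[0] / p_val[1]
        pv = max(pv, 1.0 / tab.size)
        return {"statistic": stat, "p": float(pv)}

    raise ValueError(f"unknown covariate kind {kind!r}")


# --------------------------------------------------------------------------
# split selection and partition search
# --------------------------------------------------------------------------

def select_split(model: FittedNodeModel, data, config: TreeConfig) -> dict | None:
    """Pick the covariate with the most significant instability.

    P-values are Bonferroni-multiplied by the number of covariates showing
    variation; the minimising covariate is returned iff its adjusted
    p-value is below ``config.alpha``.
    """
    tests = {}
    for name, kind in config.covariates.items():
        col = data[name].to_numpy()
        if np.unique(col).size < 2:
            continue
        tests[name] = instability_test(model.score_matrix, col, kind,
                                       trim=config.trim)
    if not tests:
        return None
    m = len(tests)
    best_name = min(tests, key=lambda k: (tests[k]["p"], list(config.covariates).index(k)))
    adj = min(1.0, tests[best_name]["p"] * m)
    if adj >= config.alpha:
        return None
    return {"covariate": best_name, "adjusted_p": adj,
            "statistic": tests[best_name]["statistic"]}


def _ordinal_partitions(levels):
    # contiguous bipartitions of the sorted levels
    levels = sorted(levels)
    return [(tuple(levels[:i]), tuple(levels[i:]))
            for i in range(1, len(levels))]


def _nominal_partitions(levels):
    levels = sorted(levels, key=str)
    k = len(levels)
    out = []
    # enumerate 2^(k-1) - 1 bipartitions: first level stays on the left
    for mask in range(1, 2 ** (k - 1)):
        left = [levels[0]]
        right = []
        for i in range(1, k):
            (right if (mask >> (i - 1)) & 1 else left).append(levels[i])
        if right:
            out.append((tuple(left), tuple(right)))
    return out


def find_partition(y, covariate, kind: str, config: TreeConfig,
                   init=None, max_numeric_cutpoints: int = 40) -> dict | None:
    """Best binary partition of ``covariate`` by summed child log-likelihoods.

    Numeric covariates scan thresholds midway between adjacent observed
    values (every boundary when there are at most ``max_numeric_cutpoints``
    of them, an evenly spaced subset otherwise); ordinal covariates try
    contiguous-level bipartitions only; nominal covariates try all level
    bipartitions.  Returns ``None`` when no admissible partition leaves
    both children with at least ``min_node`` observations and usable fits.
    """
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate)
    best = None

    def try_masks(left_mask, desc):
        nonlocal best
        n_l, n_r = int(left_mask.sum()), int((~left_mask).sum())
        if n_l < config.min_node or n_r < config.min_node:
            return
        fl = fit_mle(y[left_mask], config.family, init=init, n_restarts=0,
                     polish=False, max_iter=150)
        fr = fit_mle(y[~left_mask], config.family, init=init, n_restarts=0,
                     polish=False, max_iter=150)
        if not (np.isfinite(fl.loglik) and np.isfinite(fr.loglik)):
            return
        total = fl.loglik + fr.loglik
        if best is None or total > best["loglik"]:
            best = {"loglik": total, **desc}

    if kind == "numeric":
        vals = np.unique(cov.astype(float))
        bounds = np.arange(vals.size - 1)
        if bounds.size > max_numeric_cutpoints:
            pick = np.linspace(0, bounds.size - 1,
                               max_numeric_cutpoints).round().astype(int)
            bounds = np.unique(bounds[pick])
        for i in bounds:
            thr = 0.5 * (vals[i] + vals[i + 1])
            try_masks(cov.astype(float) <= thr, {"threshold": float(thr)})
    elif kind == "ordinal":
        for left, right in _ordinal_partitions(np.unique(cov)):
            try_masks(np.isin(cov, left),
                      {"left_levels": left, "right_levels": right})
    elif kind == "nominal":
        for left, right in _nominal_partitions(np.unique(cov)):
            try_masks(np.isin(cov, left),
                      {"left_levels": left, "right_levels": right})
    else:
        raise ValueError(f"unknown covariate kind {kind!r}")
    return best


def _partition_mask(split: dict, cov: np.ndarray) -> np.ndarray:
    if "threshold" in split:
        return cov.astype(float) <= split["threshold"]
    return np.isin(cov, split["left_levels"])


# --------------------------------------------------------------------------
# growing
# --------------------------------------------------------------------------

def grow(data, response: str, config: TreeConfig) -> TreeNode:
    """Grow a distributional regression tree on ``data[response]``.

    Recursion: fit the family at the node, test instability of each
    covariate, split on the Bonferroni-significant minimiser (searching the
    best log-likelihood partition), and stop at ``min_node``, ``max_depth``
    or when no covariate is significantly unstable.  Node ids are assigned
    depth-first in reporting order (left before right).
    """
    df = data.reset_index(drop=True)
    missing = [c for c in config.covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates missing from data: {missing}")
    for c in list(config.covariates) + [response]:
        if df[c].isna().any():
            raise ValueError(f"missing values in column {c!r}")

    y_all = df[response].to_numpy(dtype=float)
    root_index = np.arange(len(df))

    def build(index: np.ndarray, depth: int, parent_theta=None) -> TreeNode:
        y = y_all[index]
        model = fit_mle(y, config.family, init=parent_theta)
        ci = median_ci(y)
        summary = {"n": int(index.size), "median": ci["median"],
                   "ci_lo": ci["lo"], "ci_hi": ci["hi"]}
        node = TreeNode(node_id=-1, depth=depth, model=model,
                        summary=summary, data_index=index)
        # a boundary fit (likelihood maximised on the link-scale box, e.g.
        # GB1 chasing an atom of identical rates) is still a usable,
        # deterministic node model; only an outright optimiser failure stops
        # the recursion
        usable = model.converged or model.boundary
        if not usable:
            if depth == 0:
                raise RuntimeError("root node fit failed to converge")
            return node
        if depth >= config.max_depth or index.size < 2 * config.min_node:
            return node
        sub = df.iloc[index]
        sel = select_split(model, sub, config)
        if sel is None:
            return node
        kind = config.covariates[sel["covariate"]]
        part = find_partition(y, sub[sel["covariate"]].to_numpy(), kind,
                              config, init=model.theta_hat)
        if part is None:
            return node
        mask = _partition_mask(part, sub[sel["covariate"]].to_numpy())
        split = {"covariate": sel["covariate"],
                 "adjusted_p": sel["adjusted_p"],
                 "statistic": sel["statistic"]}
        split.update({k: v for k, v in part.items() if k != "loglik"})
        node.split = split
        node.children = [
            build(index[mask], depth + 1, model.theta_hat),
            build(index[~mask], depth + 1, model.theta_hat),
        ]
        return node

    root = build(root_index, 0)

    counter = [0]

    def number(node: TreeNode):
        counter[0] += 1
        node.node_id = counter[0]
        for ch in node.children:
            number(ch)

    number(root)
    return root


# --------------------------------------------------------------------------
# Graphviz export
# --------------------------------------------------------------------------

def _glyph(p: float) -> str:
    if p < 0.001:
        return " ♦"   # diamond, p < .001
    if p < 0.05:
        return " ●"   # filled circle, p < .05
    return ""


def _edge_labels(split: dict):
    if "threshold" in split:
        thr = split["threshold"]
        return f"<= {thr:g}", f"> {thr:g}"
    left = ", ".join(str(v) for v in split["left_levels"])
    right = ", ".join(str(v) for v in split["right_levels"])
    return left, right


def to_dot(root: TreeNode, title: str = "") -> str:
    """Render the tree as Graphviz DOT with node labels
    ``n = xx, median [lo, hi]``."""
    lines = ["digraph tree {", '  node [shape=box, fontname="Helvetica"];']
    if title:
        lines.append(f'  label="{title}"; labelloc=t;')

    def visit(node: TreeNode):
        s = node.summary
        label = f"n = {s['n']}, {s['median']:.2f} [{s['ci_lo']:.2f}, {s['ci_hi']:.2f}]"
        if node.split is not None:
            label = (f"{node.node_id}: {node.split['covariate']}"
                     f"{_glyph(node.split['adjusted_p'])}\\n" + label)
        else:
            label = f"{node.node_id}\\n" + label
        lines.append(f'  n{node.node_id} [label="{label}"];')
        if node.split is not None:
            el, er = _edge_labels(node.split)
            for ch, lab in zip(node.children, (el, er)):
                visit(ch)
                lines.append(f'  n{node.node_id} -> n{ch.node_id} [label="{lab}"];')

    visit(root)
    lines.append("}")
    return "\n".join(lines)
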