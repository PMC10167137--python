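"""The multiverse of regression lenses and the reduced-model rule.

The full substantive model for both responses is

    DV ~ G x S x T + n + a + g

(a full-factorial block in group, set size and target, plus main effects of
nystagmus, age and gender), fit under three defensible analytic universes:

* quantile regression at the median (check-loss minimisation),
* robust linear regression (Huber M-estimation, tuning constant 1.345),
* distributional regression (joint ML over linear predictors for the
  location *and* scale parameters of a parametric family through their
  links — the regression form of GAMLSS).

All universes consume a byte-identical design matrix with treatment coding
and fixed reference levels (control group, set size 4, target absent,
female, no nystagmus).

The reduced explainable model retains a covariate when it is either
confirmed by the Boruta screen or appears in a design column that is
significant with a consistent sign in at least two universes.  That OR rule
is this package's operationalisation of "patterns found across lenses";
the threshold and universe count are configurable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .distributions import DistributionSpec, _LOGPDFS, fit_mle

__all__ = [
    "ModelFormula",
    "MultiverseResult",
    "build_design",
    "fit_quantile",
    "fit_robust",
    "fit_distributional",
    "fit_multiverse",
    "reduce_model",
]

SYMBOLS = {"group": "G", "set_size": "S", "target": "T",
           "nystagmus": "n", "age": "a", "gender": "g"}
REFERENCE_LEVELS = {"group": "c", "set_size": 4, "target": "ab",
                    "gender": "f", "nystagmus": 0}
NUMERIC_VARS = {"age", "acuity_logmar"}


def _var_columns(data: pd.DataFrame, var: str):
    """Treatment-coded columns for one variable: [(name, values, level)]."""
    if var in NUMERIC_VARS:
        return [(SYMBOLS.get(var, var), data[var].to_numpy(dtype=float), None)]
    ref = REFERENCE_LEVELS.get(var)
    levels = sorted(data[var].unique(), key=str)
    if ref is None:
        ref = levels[0]
    cols = []
    for lv in levels:
        if lv == ref:
            continue
        name = f"{SYMBOLS.get(var, var)}[{lv}]"
        cols.append((name, (data[var] == lv).to_numpy(dtype=float), lv))
    return cols


def build_design(data: pd.DataFrame, factorial_vars, main_vars=()):
    """Design matrix with a full interaction block over ``factorial_vars``
    plus main effects of ``main_vars``.

    Returns ``(X, colmap)`` where ``colmap`` maps each column name to the
    set of variables it involves (the intercept maps to the empty set).
    """
    cols = {"Intercept": np.ones(len(data))}
    colmap = {"Intercept": frozenset()}
    per_var = {v: _var_columns(data, v) for v in factorial_vars}
    fv = list(factorial_vars)
    for order in range(1, len(fv) + 1):
        for subset in combinations(fv, order):
            parts = [per_var[v] for v in subset]
            idx = [0] * len(parts)
            # cartesian product of the non-reference columns of each variable
            def rec(i, name_parts, values):
                if i == len(parts):
                    name = ":".join(name_parts)
                    cols[name] = values
                    colmap[name] = frozenset(subset)
                    return
                for nm, vals, _ in parts[i]:
                    rec(i + 1, name_parts + [nm], values * vals)
            rec(0, [], np.ones(len(data)))
    for v in main_vars:
        for nm, vals, _ in _var_columns(data, v):
            cols[nm] = vals
            colmap[nm] = frozenset([v])
    X = pd.DataFrame(cols, index=data.index)
    return X, colmap


@dataclass
class ModelFormula:
    """A declared model: response plus factorial and main-effect variables."""

    response: str
    factorial_vars: tuple
    main_vars: tuple = ()

    def design(self, data: pd.DataFrame):
        X, colmap = build_design(data, self.factorial_vars, self.main_vars)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            aliased = _aliased_columns(X)
            raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
        return X, colmap

    def describe(self) -> str:
        fact = " x ".join(SYMBOLS.get(v, v) for v in self.factorial_vars)
        mains = " + ".join(SYMBOLS.get(v, v) for v in self.main_vars)
        rhs = fact if not mains else f"{fact} + {mains}"
        return f"{self.response} ~ {rhs}"


def _aliased_columns(X: pd.DataFrame):
    arr = X.to_numpy()
    q, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-10
    return [c for c, d in zip(X.columns, diag) if d < tol]


def design_hash(X: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(",".join(X.columns).encode())
    h.update(np.ascontiguousarray(X.to_numpy(dtype=float)).tobytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# universes
# --------------------------------------------------------------------------

def fit_quantile(X: pd.DataFrame, y, tau: float = 0.5) -> pd.DataFrame:
    """Median (or ``tau``-quantile) regression coefficient table."""
    model = sm.QuantReg(np.asarray(y, dtype=float), X)
    res = model.fit(q=tau)
    tab = pd.DataFrame({"estimate": res.params, "se": res.bse,
                        "p": res.pvalues})
    tab.attrs["inference"] = "asymptotic (kernel density at the quantile)"
    tab.attrs["tau"] = tau
    return tab


def fit_robust(X: pd.DataFrame, y) -> pd.DataFrame:
    """Huber M-estimation (c = 1.345) coefficient table."""
    model = sm.RLM(np.asarray(y, dtype=float), X,
                   M=sm.robust.norms.HuberT(t=1.345))
    res = model.fit()
    tab = pd.DataFrame({"estimate": res.params, "se": res.bse,
                        "p": res.pvalues})
    tab.attrs["inference"] = "asymptotic normal (IRLS)"
    tab.attrs["converged"] = bool(getattr(res, "converged", True))
    return tab


def _param_scores_fd(spec, y, theta_cols, rel_h=1e-5):
    """Per-observation d logpdf / d theta_j at observation-specific theta.

    Step sizes shrink near a parameter-domain boundary so the perturbed
    values stay admissible (e.g. a logit-linked mean arbitrarily close
    to 1).
    """
    logpdf = _LOGPDFS[spec.family]
    n = y.shape[0]
    p = spec.n_params
    doms = spec.parameter_supports()
    out = np.empty((n, p))
    for j in range(p):
        th = np.asarray(theta_cols[j], dtype=float)
        h = np.maximum(np.abs(th) * rel_h, 1e-8)
        lo, hi = doms[j]
        if np.isfinite(hi):
            h = np.minimum(h, 0.5 * (hi - th))
        if np.isfinite(lo):
            h = np.minimum(h, 0.5 * (th - lo))
        h = np.maximum(h, 1e-300)
        tp = [np.asarray(c, dtype=float).copy() for c in theta_cols]
        tm = [np.asarray(c, dtype=float).copy() for c in theta_cols]
        tp[j] = tp[j] + h
        tm[j] = tm[j] - h
        out[:, j] = (logpdf(y, *tp) - logpdf(y, *tm)) / (2 * h)
    return out


def fit_distributional(X: pd.DataFrame, y, family: DistributionSpec,
                       scale_design: bool = True, max_iter: int = 5000) -> dict:
    """Distributional (GAMLSS-type) regression: joint ML over per-parameter
    linear predictors.

    The full design matrix enters the location (``mu``) and — when
    ``scale_design`` — the scale (``sigma``) predictor; remaining shape
    parameters get intercepts.  Standard errors come from the observed
    information (numerical Hessian of the joint log-likelihood).

    Returns ``{"tables": {param: DataFrame}, "loglik", "converged"}``.
    """
    from scipy import optimize
    from statsmodels.tools.numdiff import approx_hess

    y = np.asarray(y, dtype=float)
    family.check_support(y)
    Xa = X.to_numpy(dtype=float)
    n, k = Xa.shape
    links = family.link_objs()
    p = family.n_params
    designs = []
    for j in range(p):
        if j == 0 or (j == 1 and scale_design):
            designs.append(Xa)
        else:
            designs.append(np.ones((n, 1)))
    sizes = [d.shape[1] for d in designs]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    base = fit_mle(y, family)
    beta0 = np.zeros(offsets[-1])
    for j in range(p):
        eta_j = links[j].to_eta(base.theta_hat[j])
        beta0[offsets[j]] = eta_j
    # warm-start the location slopes from least squares on the link scale,
    # but only if that actually improves on the intercept-only start
    try:
        mu_target = links[0].to_eta(np.clip(y, *_safe_bounds(family)))
        ls, *_ = np.linalg.lstsq(Xa, mu_target, rcond=None)
        cand = beta0.copy()
        cand[offsets[0]:offsets[1]] = ls
        if _negll_at(family, links, designs, offsets, y, cand) < \
                _negll_at(family, links, designs, offsets, y, beta0):
            beta0 = cand
    except Exception:
        pass

    def unpack(beta):
        etas = [designs[j] @ beta[offsets[j]:offsets[j + 1]] for j in range(p)]
        thetas = [links[j].to_theta(etas[j]) for j in range(p)]
        return etas, thetas

    def negll(beta):
        _, thetas = unpack(beta)
        try:
            lp = _LOGPDFS[family.family](y, *thetas)
        except (ValueError, FloatingPointError):
            return np.inf
        if not np.all(np.isfinite(lp)):
            return np.inf
        return -float(lp.sum())

    def negll_grad(beta):
        etas, thetas = unpack(beta)
        try:
            sc = family.scores(y, thetas)
        except (ValueError, FloatingPointError):
            return np.zeros_like(beta)
        g = np.empty_like(beta)
        with np.errstate(all="ignore"):
            for j in range(p):
                d = links[j].dtheta_deta(etas[j])
                g[offsets[j]:offsets[j + 1]] = -(designs[j].T @ (sc[:, j] * d))
        return np.nan_to_num(g, nan=0.0, posinf=1e10, neginf=-1e10)

    def _optimize(beta_init, free):
        idx = np.flatnonzero(free)
        fixed = beta_init.copy()

        def f(b):
            full = fixed.copy()
            full[idx] = b
            return negll(full)

        def gf(b):
            full = fixed.copy()
            full[idx] = b
            return negll_grad(full)[idx]

        res = optimize.minimize(f, beta_init[idx], jac=gf, method="L-BFGS-B",
                                options={"maxiter": max_iter, "ftol": 1e-12,
                                         "maxcor": 30})
        out = fixed.copy()
        out[idx] = res.x
        return out, res

    # stage 1: location slopes with intercept-only scale/shape predictors,
    # then the full parameter vector from that warm start
    free1 = np.zeros(offsets[-1], dtype=bool)
    free1[offsets[0]:offsets[1]] = True
    for j in range(1, p):
        free1[offsets[j]] = True
    with np.errstate(all="ignore"):
        beta1, _ = _optimize(beta0, free1)
        beta_hat, res = _optimize(beta1, np.ones(offsets[-1], dtype=bool))
    converged = bool(res.success) and np.isfinite(res.fun)
    with np.errstate(all="ignore"):
        grad_norm = float(np.max(np.abs(negll_grad(beta_hat))))
    # line searches stall on near-degenerate ridges (GB1 shape parameters
    # fitting discretised rates) while the identified directions sit at
    # their optimum; accept the point for inference when the gradient is
    # small relative to the objective's scale
    near_opt = grad_norm < 1e-3 * max(1.0, abs(float(res.fun)))

    se = np.full_like(beta_hat, np.nan)
    if np.isfinite(res.fun) and (converged or near_opt):
        try:
            with np.errstate(all="ignore"):
                H = approx_hess(beta_hat, negll)
            H = 0.5 * (H + H.T)
            vals, vecs = np.linalg.eigh(H)
            vmax = float(vals.max())
            if vmax > 0:
                # floor the curvature spectrum (condition cap 1e6): flat or
                # negative directions get a large, conservative variance
                # instead of a spuriously small or undefined one
                vals_f = np.maximum(vals, vmax * 1e-6)
                cov = (vecs / vals_f) @ vecs.T
                diag = np.diag(cov).copy()
                diag[diag <= 0] = np.inf
                se = np.sqrt(diag)
        except np.linalg.LinAlgError:
            pass

    from scipy import stats as sp_stats
    tables = {}
    for j in range(p):
        names = list(X.columns) if sizes[j] == k else ["Intercept"]
        est = beta_hat[offsets[j]:offsets[j + 1]]
        sej = se[offsets[j]:offsets[j + 1]]
        zz = est / sej
        tables[family.parameter_names[j]] = pd.DataFrame(
            {"estimate": est, "se": sej,
             "p": 2 * sp_stats.norm.sf(np.abs(zz))}, index=names)
    return {"tables": tables, "loglik": -float(res.fun), "converged": converged}


def _negll_at(family, links, designs, offsets, y, beta):
    p = family.n_params
    thetas = [links[j].to_theta(designs[j] @ beta[offsets[j]:offsets[j + 1]])
              for j in range(p)]
    try:
        lp = _LOGPDFS[family.family](y, *thetas)
    except (ValueError, FloatingPointError):
        return np.inf
    return -float(lp.sum()) if np.all(np.isfinite(lp)) else np.inf


def _safe_bounds(family: DistributionSpec):
    lo, hi = family.support
    if np.isfinite(lo) and np.isfinite(hi):
        span = hi - lo
        return lo + 1e-3 * span, hi - 1e-3 * span
    return -np.inf, np.inf


# --------------------------------------------------------------------------
# the multiverse
# --------------------------------------------------------------------------

@dataclass
class MultiverseResult:
    formula: ModelFormula
    tables: dict                       # universe -> coefficient DataFrame
    colmap: dict
    design_sha256: str
    agreement: pd.DataFrame = field(default=None)
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula.describe(),
            "design_sha256": self.design_sha256,
            "tables": {u: t.reset_index().rename(columns={"index": "term"})
                        .to_dict(orient="records")
                       for u, t in self.tables.items()},
            "agreement": (self.agreement.reset_index()
                          .rename(columns={"index": "term"})
                          .to_dict(orient="records")
                          if self.agreement is not None else None),
            "notes": self.notes,
        }


def _agreement(tables: dict, alpha: float) -> pd.DataFrame:
    terms = next(iter(tables.values())).index
    rows = []
    for term in terms:
        signs = [np.sign(t.loc[term, "estimate"]) for t in tables.values()]
        sig = [t.loc[term, "p"] < alpha for t in tables.values()]
        sig_signs = {s for s, is_sig in zip(signs, sig) if is_sig}
        rows.append({
            "n_significant": int(sum(sig)),
            "sign_consistent": len(set(signs)) == 1,
            "sig_sign_consistent": len(sig_signs) <= 1,
        })
    return pd.DataFrame(rows, index=terms)


def fit_multiverse(formula: ModelFormula, data: pd.DataFrame,
                   family: DistributionSpec = None,
                   universes=("quantile", "robust", "distributional"),
                   alpha: float = 0.05) -> MultiverseResult:
    """Fit the declared model under every requested universe."""
    X, colmap = formula.design(data)
    y = data[formula.response].to_numpy(dtype=float)
    sha = design_hash(X)
    tables = {}
    notes = {}
    if "quantile" in universes:
        tables["quantile"] = fit_quantile(X, y)
    if "robust" in universes:
        tables["robust"] = fit_robust(X, y)
    if "distributional" in universes:
        if family is None:
            raise ValueError("the distributional universe needs a family")
        fit = fit_distributional(X, y, family)
        # agreement works on the location submodel; full tables kept in notes
        tables["distributional"] = fit["tables"][family.parameter_names[0]]
        notes["distributional"] = {
            "family": family.family,
            "loglik": fit["loglik"],
            "converged": fit["converged"],
            "submodels": {k: v.to_dict(orient="index")
                          for k, v in fit["tables"].items()},
        }
    result = MultiverseResult(formula=formula, tables=tables, colmap=colmap,
                              design_sha256=sha, notes=notes)
    result.agreement = _agreement(tables, alpha)
    return result


def reduce_model(multiverse: MultiverseResult, importance=None,
                 alpha: float = 0.05, min_universes: int = 2,
                 p_adjust: str = "bonferroni") -> dict:
    """Derive the reduced explainable model.

    A variable is retained when it is confirmed by the importance screen,
    OR when some design column involving it is significant with a
    consistent estimate sign in at least ``min_universes`` universes.
    The vote stage makes one inclusion decision per candidate variable and
    each variable gets a vote from each of its design columns, so its
    familywise error is Bonferroni-controlled at ``alpha`` overall: the
    vote for variable ``v`` uses the per-column threshold
    ``alpha / (n_vars * m_v)`` with ``n_vars`` the number of candidate
    variables and ``m_v`` the number of non-intercept columns involving
    ``v`` (``p_adjust="none"`` uses plain ``alpha``).  Correlated universes
    make "two of three" barely stricter than a single test, so the
    correction carries the burden of keeping null covariates out.

    The two arms rectify each other: a variable the screen *actively
    rejected* (importance consistently below the best shadow) is not
    resurrected by a marginal regression vote — rejection is an
    all-relevant decision, whereas a lone sub-threshold p-value among many
    correlated universes is weak evidence.  Tentative variables remain
    eligible for the vote.  With fewer than ``min_universes`` universes
    available the rule degrades to "significant in all available universes"
    and this is recorded in the audit trail.
    """
    tables = multiverse.tables
    n_univ = len(tables)
    need = min(min_universes, n_univ)
    terms = next(iter(tables.values())).index
    m_var = {}
    for term in terms:
        for v in multiverse.colmap.get(term, frozenset()):
            m_var[v] = m_var.get(v, 0) + 1
    audit = {"rule": f"confirmed OR >= {need} consistent-sign universes at "
                     f"p < alpha/(n_vars*m_v) per column (alpha={alpha})",
             "universes": sorted(tables), "columns": {}}
    if n_univ < min_universes:
        audit["degraded"] = True

    confirmed = set(importance.confirmed) if importance is not None else set()
    rejected = set() if importance is None else \
        {k for k, v in importance.decisions.items() if v == "rejected"}
    all_vars = sorted({v for vs in multiverse.colmap.values() for v in vs})

    voted = set()
    for term in terms:
        vars_in = multiverse.colmap.get(term, frozenset())
        if not vars_in:
            continue
        pvals = np.array([t.loc[term, "p"] for t in tables.values()])
        signs = np.array([np.sign(t.loc[term, "estimate"]) for t in tables.values()])
        qual_vars = []
        for v in vars_in:
            thr = alpha / (len(m_var) * m_var[v]) if p_adjust == "bonferroni" \
                else alpha
            sig = pvals < thr
            if int(sig.sum()) >= need and len(set(signs[sig])) == 1:
                qual_vars.append(v)
        audit["columns"][term] = {
            "p": [float(p) for p in pvals],
            "qualifies_for": sorted(qual_vars),
        }
        voted.update(qual_vars)

    retained = sorted((confirmed | (voted - rejected)) & set(all_vars))
    audit["confirmed"] = sorted(confirmed)
    audit["voted"] = sorted(voted)
    audit["rejected_veto"] = sorted(voted & rejected)
    if not retained:
        audit["warning"] = "empty retained set; falling back to intercept-only"
    return {"retained": retained, "audit": audit}
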