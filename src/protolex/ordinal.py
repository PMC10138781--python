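"""Cumulative-link (proportional-odds) ordinal regression.

Ratings Y ∈ {1..K} are modeled through cumulative logits

    P(Y ≤ k) = logistic(θ_k − η),   η = x'β (+ z'u for mixed models),

with strictly increasing thresholds θ_1 < … < θ_{K−1}.  Fixed-effects
models are fit by Newton's method on the (log-concave) likelihood with
analytic gradient and Hessian.  Mixed models with crossed random effects
(e.g. by-participant and by-item intercepts, optional by-item slopes) are
fit by a Laplace approximation: for candidate variance parameters the
joint penalized likelihood is maximized over (θ, β, u) by Newton, and the
marginal likelihood is corrected by the log-determinant of the penalized
Hessian over u; the variance parameters are optimized in an outer
Nelder-Mead loop.  Profiling the fixed effects at the joint mode makes
the fit exact in the σ → 0 limit, where it reduces to the fixed-effects
fit.

Predictors are standardized internally for optimization; thresholds,
coefficients and their covariance are reported on the original scale.

A formula mini-language covers the analyses here:
``rating ~ score + accent + wordhood:bin + (1|participant) + (1|item)``
with ``a:b`` products, ``a*b`` expansion, and random terms ``(1|g)``,
``(0+x|g)``, ``(1+x|g)`` (independent variances).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse as sp

_BIG = 30.0  # pseudo-infinite threshold for the extreme categories


# ---------------------------------------------------------------------------
# formula handling

def _split_top(s: str, sep: str = "+") -> list[str]:
    parts, depth, cur = [], 0, []
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return [p.strip() for p in parts if p.strip()]


@dataclass(frozen=True)
class RandomTerm:
    group: str
    slope: str | None  # None = intercept
    name: str


def parse_formula(formula: str) -> tuple[str, list[str], list[RandomTerm]]:
    lhs, rhs = formula.split("~")
    response = lhs.strip()
    fixed: list[str] = []
    random: list[RandomTerm] = []
    for term in _split_top(rhs):
        if term.startswith("(") and "|" in term:
            inner = term.strip("() ")
            spec, group = (x.strip() for x in inner.split("|"))
            for piece in (x.strip() for x in spec.split("+")):
                if piece == "0":
                    continue
                if piece == "1":
                    random.append(RandomTerm(group, None, f"(1|{group})"))
                else:
                    random.append(RandomTerm(group, piece, f"(0+{piece}|{group})"))
        elif term == "1":
            continue
        elif "*" in term:
            a, b = (x.strip() for x in term.split("*"))
            for t in (a, b, f"{a}:{b}"):
                if t not in fixed:
                    fixed.append(t)
        else:
            if term not in fixed:
                fixed.append(term)
    return response, fixed, random


def _encode(data: pd.DataFrame, name: str) -> pd.DataFrame:
    if name not in data.columns:
        raise KeyError(f"variable {name!r} not in data")
    col = data[name]
    if col.dtype == bool:
        return pd.DataFrame({name: col.astype(float)})
    if isinstance(col.dtype, pd.CategoricalDtype):
        levels = [lev for lev in col.cat.categories if (col == lev).any()]
        return pd.DataFrame(
            {f"{name}[{lev}]": (col == lev).astype(float) for lev in levels[1:]}
        )
    if col.dtype == object:
        levels = sorted(col.dropna().unique())
        return pd.DataFrame(
            {f"{name}[{lev}]": (col == lev).astype(float) for lev in levels[1:]}
        )
    return pd.DataFrame({name: col.astype(float)})


def build_design(data: pd.DataFrame, fixed_terms: Sequence[str]
                 ) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Design matrix and a map from column name to its factor components."""
    cols: dict[str, np.ndarray] = {}
    components: dict[str, tuple[str, ...]] = {}
    for term in fixed_terms:
        factors = [f.strip() for f in term.split(":")]
        encoded = [_encode(data, f) for f in factors]
        # cross all encoded columns of the factors
        names_vals = [("", np.ones(len(data)))]
        for enc in encoded:
            names_vals = [
                (f"{n}:{c}" if n else c, v * enc[c].to_numpy())
                for n, v in names_vals for c in enc.columns
            ]
        for n, v in names_vals:
            cols[n] = v
            components[n] = tuple(n.split(":"))
    X = pd.DataFrame(cols, index=data.index)
    return X, components


# ---------------------------------------------------------------------------
# results container

@dataclass
class OrdinalFit:
    thresholds: np.ndarray                # θ_1 < … < θ_{K−1}, original scale
    coef: pd.Series                       # named β, original scale
    loglike: float
    aic: float
    nparams: int
    cov: pd.DataFrame                     # over [θ names + coef names]
    converged: bool
    levels: np.ndarray                    # the observed rating levels, sorted
    re_sd: dict[str, float] = field(default_factory=dict)
    singular: bool = False
    components: dict[str, tuple[str, ...]] = field(default_factory=dict)
    col_means: dict[str, float] = field(default_factory=dict)
    formula: str = ""

    def __post_init__(self):
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def se(self) -> pd.Series:
        d = np.sqrt(np.diag(self.cov.to_numpy()))
        return pd.Series(d, index=self.cov.index)

    def coef_table(self) -> pd.DataFrame:
        names = list(self.coef.index)
        se = self.se.loc[names]
        z = self.coef / se
        from scipy.stats import norm
        p = 2 * norm.sf(np.abs(z))
        return pd.DataFrame({"estimate": self.coef, "se": se, "z": z,
                             "p": p}, index=names)

    def to_json(self, path=None) -> str:
        payload = {
            "thresholds": self.thresholds.tolist(),
            "coef": self.coef.to_dict(),
            "loglike": self.loglike,
            "aic": self.aic,
            "nparams": self.nparams,
            "re_sd": self.re_sd,
            "converged": self.converged,
            "singular": self.singular,
            "formula": self.formula,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# core likelihood machinery

def _logistic(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _row_quantities(theta, eta, ycode, K):
    """Per-row P, and first/second derivatives wrt (s1, s0)."""
    th = np.concatenate(([-_BIG], theta, [_BIG]))
    s1 = th[ycode + 1] - eta
    s0 = th[ycode] - eta
    F1, F0 = _logistic(s1), _logistic(s0)
    f1, f0 = F1 * (1 - F1), F0 * (1 - F0)
    f1p, f0p = f1 * (1 - 2 * F1), f0 * (1 - 2 * F0)
    P = np.clip(F1 - F0, 1e-300, None)
    g1 = f1 / P
    g0 = -f0 / P
    H11 = f1p / P - g1 ** 2
    H00 = -f0p / P - (f0 / P) ** 2
    H10 = f1 * f0 / P ** 2
    return P, g1, g0, H11, H00, H10


class _POProblem:
    """Joint Newton solver for the penalized proportional-odds likelihood."""

    def __init__(self, ycode, K, X, w, re_terms=None):
        # re_terms: list of (group_codes, values, n_levels, name)
        self.ycode = ycode
        self.K = K
        self.X = np.asarray(X, float)
        self.w = np.asarray(w, float)
        self.n, self.p = self.X.shape
        self.re = re_terms or []
        self.q_sizes = [t[2] for t in self.re]
        self.q = sum(self.q_sizes)
        self.d = (K - 1) + self.p + self.q
        self._build_A()

    def _build_A(self):
        n, K, p = self.n, self.K, self.p
        rows, cols, vals = [], [], []
        r = np.arange(n)
        # threshold indicator for s1 (rating k uses θ_{k+1} unless top)
        m1 = self.ycode < K - 1
        rows.append(r[m1]); cols.append(self.ycode[m1]); vals.append(np.ones(m1.sum()))
        T1 = sp.csr_matrix((np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                           shape=(n, self.d))
        rows, cols, vals = [], [], []
        m0 = self.ycode > 0
        rows.append(r[m0]); cols.append(self.ycode[m0] - 1); vals.append(np.ones(m0.sum()))
        T0 = sp.csr_matrix((np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                           shape=(n, self.d))
        # −η part: X then Z blocks
        rows, cols, vals = [r.repeat(p)], [np.tile(np.arange(K - 1, K - 1 + p), n)], \
            [(-self.X).ravel()]
        off = K - 1 + p
        for codes, zvals, nlev, _ in self.re:
            rows.append(r); cols.append(off + codes); vals.append(-np.asarray(zvals, float))
            off += nlev
        M = sp.csr_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(n, self.d))
        self.A1 = (T1 + M).tocsr()
        self.A0 = (T0 + M).tocsr()
        self.A1T = self.A1.T.tocsr()
        self.A0T = self.A0.T.tocsr()
        self._rows1 = np.diff(self.A1.indptr)
        self._rows0 = np.diff(self.A0.indptr)

    def unpack(self, v):
        K, p = self.K, self.p
        return v[:K - 1], v[K - 1:K - 1 + p], v[K - 1 + p:]

    def penalty_diag(self, sigmas):
        d = np.zeros(self.d)
        off = self.K - 1 + self.p
        for (codes, zv, nlev, name), s in zip(self.re, sigmas):
            d[off:off + nlev] = 1.0 / s ** 2
            off += nlev
        return d

    def pen_ll(self, v, pdiag):
        theta, beta, u = self.unpack(v)
        if np.any(np.diff(theta) <= 0):
            return -np.inf
        eta = self.X @ beta
        off = 0
        for codes, zv, nlev, _ in self.re:
            eta = eta + zv * u[off:off + nlev][codes]
            off += nlev
        P, *_ = _row_quantities(theta, eta, self.ycode, self.K)
        return float(self.w @ np.log(P)) - 0.5 * float(v @ (pdiag * v))

    def grad_hess(self, v, pdiag):
        theta, beta, u = self.unpack(v)
        eta = self.X @ beta
        off = 0
        for codes, zv, nlev, _ in self.re:
            eta = eta + zv * u[off:off + nlev][codes]
            off += nlev
        P, g1, g0, H11, H00, H10 = _row_quantities(theta, eta, self.ycode, self.K)
        w = self.w
        grad = self.A1T @ (w * g1) + self.A0T @ (w * g0) - pdiag * v

        def _scaled(A, rows, d):
            B = A.copy()
            B.data = B.data * np.repeat(d, rows)
            return B
        # H = A1'(W1 A1 + W10 A0) + A0'(W10 A1 + W0 A0); two products suffice
        B1 = _scaled(self.A1, self._rows1, w * H11) + \
            _scaled(self.A0, self._rows0, w * H10)
        B0 = _scaled(self.A1, self._rows1, w * H10) + \
            _scaled(self.A0, self._rows0, w * H00)
        H = (self.A1T @ B1 + self.A0T @ B0).toarray()
        H[np.diag_indices_from(H)] -= pdiag
        ll = float(w @ np.log(P)) - 0.5 * float(v @ (pdiag * v))
        return ll, grad, H

    def newton(self, v0, sigmas=(), tol=1e-7, max_iter=60):
        pdiag = self.penalty_diag(list(sigmas))
        v = v0.copy()
        ll = self.pen_ll(v, pdiag)
        if not np.isfinite(ll):
            raise ConvergenceError("invalid starting values")
        gnorm = np.inf
        scale = 1.0 + np.sum(self.w)
        for _ in range(max_iter):
            ll, grad, H = self.grad_hess(v, pdiag)
            gnorm = np.max(np.abs(grad))
            if gnorm < tol * scale:
                break
            try:
                cf = scipy.linalg.cho_factor(-H + 1e-10 * np.eye(self.d))
                step = scipy.linalg.cho_solve(cf, grad)
            except scipy.linalg.LinAlgError:
                step = np.linalg.lstsq(-H + 1e-6 * np.eye(self.d), grad,
                                       rcond=None)[0]
            t = 1.0
            for _ in range(40):
                vn = v + t * step
                lln = self.pen_ll(vn, pdiag)
                if lln >= ll - 1e-12:
                    break
                t *= 0.5
            else:
                break
            improved = lln - ll
            v = vn
            ll = lln
            if improved < 1e-12 * (1 + abs(ll)):
                _, grad, _ = self.grad_hess(v, pdiag)
                gnorm = np.max(np.abs(grad))
                break
        converged = gnorm < 1e-4 * scale
        return v, ll, converged

    def start_values(self):
        # empirical cumulative logits of the marginal rating distribution
        counts = np.bincount(self.ycode, weights=self.w, minlength=self.K)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        cum = np.clip(cum, 1e-4, 1 - 1e-4)
        theta = np.log(cum / (1 - cum))
        theta = np.maximum.accumulate(theta + 1e-6 * np.arange(self.K - 1))
        v = np.zeros(self.d)
        v[:self.K - 1] = theta
        return v


def _standardize(X: np.ndarray):
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    const = sds < 1e-12
    sds[const] = 1.0
    means[const] = 0.0
    return (X - means) / sds, means, sds


def _destandardize(theta_s, beta_s, cov_s, means, sds, K):
    # η_std = Σ β'_j (x_j − m_j)/s_j, so on the original scale
    # θ = θ' + Σ β'_j m_j/s_j and β = β'/s
    beta = beta_s / sds
    shift = float(beta_s @ (means / sds))
    theta = theta_s + shift
    d = len(theta_s) + len(beta_s)
    L = np.zeros((d, d))
    for k in range(K - 1):
        L[k, k] = 1.0
        L[k, K - 1:] = means / sds
    for j in range(len(beta_s)):
        L[K - 1 + j, K - 1 + j] = 1.0 / sds[j]
    cov = L @ cov_s @ L.T
    return theta, beta, cov


def _prepare(data: pd.DataFrame, formula: str, weights):
    response, fixed, random = parse_formula(formula)
    y = data[response].to_numpy()
    if not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("ratings must be integers")
    levels = np.sort(np.unique(y))
    if len(levels) < 2:
        raise ValueError("need at least 2 distinct rating levels")
    ycode = np.searchsorted(levels, y)
    X, components = build_design(data, fixed)
    Xv = X.to_numpy(float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    if weights is None:
        w = np.ones(len(data))
    elif isinstance(weights, str):
        w = data[weights].to_numpy(float)
    else:
        w = np.asarray(weights, float)
    return levels, ycode, X, components, w, random


def fit_clm(data: pd.DataFrame, formula: str,
            weights=None) -> OrdinalFit:
    """Fixed-effects cumulative-logit fit by Newton's method.

    `weights` (optional column name or array) allows aggregated
    (response-pattern-weighted) data; the log-likelihood and AIC are those
    of the weighted sample.
    """
    levels, ycode, X, components, w, random = _prepare(data, formula, weights)
    if random:
        raise ValueError("random terms present: use fit_clmm")
    K = len(levels)
    Xs, means, sds = _standardize(X.to_numpy(float))
    prob = _POProblem(ycode, K, Xs, w)
    v, ll, converged = prob.newton(prob.start_values())
    if not converged:
        raise ConvergenceError("fixed-effects fit did not converge "
                               "(possible separation)")
    theta_s, beta_s, _ = prob.unpack(v)
    _, _, H = prob.grad_hess(v, np.zeros(prob.d))
    cov_s = np.linalg.inv(-H)
    theta, beta, cov = _destandardize(theta_s, beta_s, cov_s, means, sds, K)
    p = (K - 1) + len(beta)
    names = [f"theta[{i+1}]" for i in range(K - 1)] + list(X.columns)
    col_means = {c: float(m) for c, m in zip(X.columns, X.to_numpy().mean(axis=0))}
    return OrdinalFit(
        thresholds=theta,
        coef=pd.Series(beta, index=list(X.columns)),
        loglike=ll, aic=2 * p - 2 * ll, nparams=p,
        cov=pd.DataFrame(cov, index=names, columns=names),
        converged=converged, levels=levels,
        components=components, col_means=col_means, formula=formula,
    )


def fit_clmm(data: pd.DataFrame, formula: str, weights=None,
             sigma_bounds: tuple[float, float] = (1e-4, 25.0),
             outer_tol: float = 2e-3) -> OrdinalFit:
    """Mixed-effects cumulative-logit fit via Laplace approximation.

    Random-effect variances are optimized by Nelder-Mead on the Laplace
    marginal likelihood with fixed effects profiled at the joint penalized
    mode; reduces to `fit_clm` as the variances shrink to zero.
    """
    levels, ycode, X, components, w, random = _prepare(data, formula, weights)
    if not random:
        raise ValueError("no random terms: use fit_clm")
    K = len(levels)
    re_terms = []
    for rt in random:
        g = data[rt.group]
        glevels, codes = np.unique(g, return_inverse=True)
        if len(glevels) < 2:
            raise ValueError(f"grouping factor {rt.group!r} needs ≥ 2 levels")
        zv = np.ones(len(data)) if rt.slope is None \
            else data[rt.slope].to_numpy(float)
        re_terms.append((codes, zv, len(glevels), rt.name))
    Xs, means, sds = _standardize(X.to_numpy(float))
    prob = _POProblem(ycode, K, Xs, w, re_terms)
    lo, hi = sigma_bounds
    state = {"v": prob.start_values()}

    def neg_marginal(log_sigmas):
        sigmas = np.exp(np.clip(log_sigmas, math.log(lo), math.log(hi)))
        v, ll_pen, _ = prob.newton(state["v"], sigmas)
        state["v"] = v
        _, _, H = prob.grad_hess(v, prob.penalty_diag(sigmas))
        off = K - 1 + prob.p
        Huu = -H[off:, off:]
        sign, logdet_H = np.linalg.slogdet(Huu)
        if sign <= 0:
            return np.inf
        logdet_D = 2.0 * sum(q * math.log(s)
                             for q, s in zip(prob.q_sizes, sigmas))
        marg = ll_pen - 0.5 * (logdet_D + logdet_H)
        return -marg

    x0 = np.full(len(re_terms), math.log(0.3))
    res = scipy.optimize.minimize(neg_marginal, x0, method="Nelder-Mead",
                                  options={"xatol": outer_tol,
                                           "fatol": outer_tol, "maxiter": 200})
    sigmas = np.exp(np.clip(res.x, math.log(lo), math.log(hi)))
    v, ll_pen, inner_conv = prob.newton(state["v"], sigmas)
    pdiag = prob.penalty_diag(sigmas)
    _, _, H = prob.grad_hess(v, pdiag)
    marg_ll = -neg_marginal(np.log(sigmas))
    theta_s, beta_s, u = prob.unpack(v)
    cov_full = np.linalg.inv(-H)
    nfix = (K - 1) + prob.p
    cov_s = cov_full[:nfix, :nfix]
    theta, beta, cov = _destandardize(theta_s, beta_s, cov_s, means, sds, K)
    singular = bool(np.any(sigmas <= lo * 1.01))
    p = nfix + len(re_terms)
    names = [f"theta[{i+1}]" for i in range(K - 1)] + list(X.columns)
    col_means = {c: float(m) for c, m in zip(X.columns, X.to_numpy().mean(axis=0))}
    return OrdinalFit(
        thresholds=theta,
        coef=pd.Series(beta, index=list(X.columns)),
        loglike=marg_ll, aic=2 * p - 2 * marg_ll, nparams=p,
        cov=pd.DataFrame(cov, index=names, columns=names),
        converged=bool(res.success and inner_conv), levels=levels,
        re_sd={t[3]: float(s) for t, s in zip(re_terms, sigmas)},
        singular=singular,
        components=components, col_means=col_means, formula=formula,
    )


# ---------------------------------------------------------------------------
# contrasts, bootstrap, model comparison

def marginal_contrast(fit: OrdinalFit, factor: str,
                      at: Mapping[str, float] | None = None,
                      level: float = 0.95):
    """Contrast of linear predictors for a unit change in `factor`.

    Interacting terms are set to the values in `at` (by design-column
    name) or averaged over the reference grid (observed column means).
    Returns (estimate, z, (lo, hi)); SE by the delta method from the
    coefficient covariance.
    """
    at = dict(at or {})
    for k in at:
        if k not in fit.col_means:
            raise KeyError(f"no design column {k!r} in the model")
    c = pd.Series(0.0, index=fit.coef.index)
    found = False
    for col, comps in fit.components.items():
        if factor not in comps:
            continue
        found = True
        others = [x for x in comps if x != factor]
        val = 1.0
        for o in others:
            val *= at.get(o, fit.col_means[o])
        c[col] += val
    if not found:
        raise KeyError(f"factor {factor!r} not in the model")
    est = float(c @ fit.coef)
    cov_bb = fit.cov.loc[fit.coef.index, fit.coef.index].to_numpy()
    se = math.sqrt(float(c.to_numpy() @ cov_bb @ c.to_numpy()))
    z = est / se
    from scipy.stats import norm
    h = norm.ppf(0.5 + level / 2) * se
    return est, z, (est - h, est + h)


def bootstrap_ci(values: Sequence[float], B: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile interval of the mean over B seeded resamples."""
    vals = np.asarray(values, float)
    if len(vals) < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(B, len(vals)))
    means = vals[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(lo), float(hi)


def lr_test(full: OrdinalFit, reduced: OrdinalFit) -> float:
    """Likelihood-ratio p-value for nested fits."""
    from scipy.stats import chi2
    df = full.nparams - reduced.nparams
    if df <= 0:
        raise ValueError("models are not nested in the right order")
    stat = 2 * (full.loglike - reduced.loglike)
    return float(chi2.sf(max(stat, 0.0), df))


def select_model(data: pd.DataFrame, formula: str, alpha: float = 0.05,
                 fitter=fit_clm, **kwargs) -> OrdinalFit:
    """Backward elimination of interaction terms.

    An interaction is removed when its coefficients neither differ from
    zero at `alpha` (Wald) nor improve fit by likelihood-ratio test.
    """
    response, fixed, random = parse_formula(formula)
    re_str = "".join(f" + ({'1' if rt.slope is None else '0+' + rt.slope}|{rt.group})"
                     for rt in random)

    def mk(terms):
        return f"{response} ~ {' + '.join(terms)}{re_str}"

    terms = list(fixed)
    fit = fitter(data, mk(terms), **kwargs)
    while True:
        inters = [t for t in terms if ":" in t]
        removed = False
        for t in inters:
            cols = [c for c in fit.coef.index if _term_of(c, t)]
            tab = fit.coef_table().loc[cols]
            if (tab["p"] > alpha).all():
                reduced_terms = [x for x in terms if x != t]
                red = fitter(data, mk(reduced_terms), **kwargs)
                if lr_test(fit, red) > alpha:
                    terms = reduced_terms
                    fit = red
                    removed = True
                    break
        if not removed:
            return fit


def _term_of(col: str, term: str) -> bool:
    base = sorted(f.split("[")[0] for f in col.split(":"))
    return base == sorted(term.split(":"))
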