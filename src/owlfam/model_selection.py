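"""Likelihood fitting of GLM families and AICc multimodel inference.

Plain fixed-effect fits delegate to statsmodels (GLM, NegativeBinomial,
ZeroInflatedPoisson, ZeroInflatedNegativeBinomialP). Random-intercept
models use an in-package Laplace-approximated marginal maximum
likelihood that supports one grouping factor or a crossed pair, for all
of the binomial / Poisson / negative-binomial / Gaussian families plus
an intercept-only zero-inflation component on the count families.

Model comparison uses AICc = -2*loglik + 2k + 2k(k+1)/(n-k-1), Akaike
weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2), and full-model
(zero-substitution) averaging with unconditional variances: a term
absent from a model contributes an estimate of 0 with zero variance at
that model's weight, and the between-model spread enters the averaged
variance.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ConvergenceError",
    "FittedModel",
    "ModelSet",
    "AveragedEstimate",
    "fit_glm",
    "fit_random_intercept",
    "fit_formula",
    "aicc",
    "build_model_set",
    "model_average",
]


class ConvergenceError(RuntimeError):
    """Raised when a likelihood fit diverges or the design is degenerate."""


@dataclass
class FittedModel:
    name: str
    family: str
    link: str
    zero_inflated: bool
    random_intercept: tuple[str, ...]
    loglik: float
    k: int
    n: int
    estimates: pd.Series
    vcov: pd.DataFrame
    extra: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    def estimate(self, term: str) -> float:
        return float(self.estimates[term])

    def se(self, term: str) -> float:
        return float(np.sqrt(self.vcov.loc[term, term]))


@dataclass
class ModelSet:
    table: pd.DataFrame          # model, k, loglik, aicc, delta, weight
    models: dict[str, FittedModel]

    def best(self) -> FittedModel:
        return self.models[self.table["model"].iloc[0]]


@dataclass
class AveragedEstimate:
    term: str
    estimate: float
    ci_low: float
    ci_high: float


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# family objects: conditional loglik and derivatives w.r.t. the linear
# predictor, for the Laplace mixed-model engine

_LINKS = {"binomial": "logit", "poisson": "log", "negative_binomial": "log",
          "gaussian": "identity"}


def _binomial_d(y, eta, _):
    p = special.expit(eta)
    ll = y * eta - np.log1p(np.exp(-np.abs(eta))) - np.maximum(eta, 0.0)
    return ll, y - p, -p * (1 - p)


def _poisson_d(y, eta, _):
    mu = np.exp(eta)
    ll = y * eta - mu - special.gammaln(y + 1)
    return ll, y - mu, -mu


def _gaussian_d(y, eta, extra):
    s2 = extra["sigma_resid"] ** 2
    r = y - eta
    ll = -0.5 * np.log(2 * np.pi * s2) - r**2 / (2 * s2)
    return ll, r / s2, np.full_like(eta, -1.0 / s2)


def _negbin_d(y, eta, extra):
    a = extra["alpha"]
    mu = np.exp(eta)
    ll = (special.gammaln(y + 1 / a) - special.gammaln(1 / a) - special.gammaln(y + 1)
          - (y + 1 / a) * np.log1p(a * mu) + y * np.log(a) + y * eta)
    d1 = (y - mu) / (1 + a * mu)
    d2 = -mu * (1 + a * y) / (1 + a * mu) ** 2
    return ll, d1, d2


def _zip_d(y, eta, extra):
    pi = special.expit(extra["psi"])
    mu = np.exp(eta)
    ll, d1, d2 = _poisson_d(y, eta, extra)
    ll = ll + np.log1p(-pi)
    zero = y == 0
    if np.any(zero):
        m0 = mu[zero]
        A = pi + (1 - pi) * np.exp(-m0)
        A1 = -(1 - pi) * np.exp(-m0) * m0
        A2 = -(1 - pi) * np.exp(-m0) * m0 * (1 - m0)
        ll = ll.copy(); d1 = d1.copy(); d2 = d2.copy()
        ll[zero] = np.log(A)
        d1[zero] = A1 / A
        d2[zero] = (A2 * A - A1**2) / A**2
    return ll, d1, d2


_FAMILY_D = {
    ("binomial", False): _binomial_d,
    ("poisson", False): _poisson_d,
    ("gaussian", False): _gaussian_d,
    ("negative_binomial", False): _negbin_d,
    ("poisson", True): _zip_d,
}


# ---------------------------------------------------------------------------
# plain GLM fits (statsmodels)

def _as_design(design) -> pd.DataFrame:
    X = pd.DataFrame(design).astype(float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ConvergenceError("rank-deficient design matrix")
    return X


def fit_glm(response, design, family: str, link: str | None = None,
            zero_inflated: bool = False, name: str = "model") -> FittedModel:
    """Maximum-likelihood GLM fit.

    ``design`` must already contain its intercept column. ``k`` counts
    regression coefficients plus any dispersion (Gaussian residual
    variance, negative-binomial alpha) and zero-inflation parameters.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    X = _as_design(design)
    link = link or _LINKS[family]
    if link != _LINKS[family]:
        raise ValueError(f"{family} is fitted with its canonical {_LINKS[family]} link")
    names = list(X.columns)
    extra: dict = {}

    if zero_inflated:
        if family not in ("poisson", "negative_binomial"):
            raise ValueError("zero inflation applies to count families only")
        if np.all(y == 0):
            # degenerate boundary: all mass on the structural zero; loglik -> 0
            est = pd.Series(np.zeros(len(names)), index=names)
            vc = pd.DataFrame(np.full((len(names), len(names)), np.nan),
                              index=names, columns=names)
            k = len(names) + 1 + (1 if family == "negative_binomial" else 0)
            return FittedModel(name, family, link, True, (), 0.0, k, len(y), est, vc,
                               {"zero_inflation_prob": 1.0, "boundary": True})
        cls = (sm.ZeroInflatedPoisson if family == "poisson"
               else sm.ZeroInflatedNegativeBinomialP)
        mod = cls(y, X.to_numpy(), exog_infl=np.ones((len(y), 1)))
        res = mod.fit(method="bfgs", maxiter=500, disp=0)
        if not res.mle_retvals.get("converged", True):
            res = mod.fit(method="nm", maxiter=5000, disp=0)
        full = np.asarray(res.params, dtype=float)
        # params: [inflate_const, beta..., (alpha)]
        beta = full[1:1 + len(names)]
        extra["zero_inflation_prob"] = float(special.expit(full[0]))
        if family == "negative_binomial":
            extra["alpha"] = float(full[-1])
        k = len(full)
        vc_full = np.asarray(res.cov_params(), dtype=float)
        vc = vc_full[1:1 + len(names), 1:1 + len(names)]
        ll = float(res.llf)
    elif family == "negative_binomial":
        mod = sm.NegativeBinomial(y, X.to_numpy())
        res = mod.fit(method="bfgs", maxiter=500, disp=0)
        if not res.mle_retvals.get("converged", True):
            res = mod.fit(method="nm", maxiter=5000, disp=0)
        full = np.asarray(res.params, dtype=float)
        beta = full[:-1]
        extra["alpha"] = float(full[-1])
        k = len(full)
        vc = np.asarray(res.cov_params(), dtype=float)[:-1, :-1]
        ll = float(res.llf)
    else:
        fams = {"binomial": sm.families.Binomial(), "poisson": sm.families.Poisson(),
                "gaussian": sm.families.Gaussian()}
        res = sm.GLM(y, X.to_numpy(), family=fams[family]).fit()
        beta = np.asarray(res.params, dtype=float)
        k = len(beta) + (1 if family == "gaussian" else 0)  # +residual variance
        vc = np.asarray(res.cov_params(), dtype=float)
        ll = float(res.llf)
        if family == "gaussian":
            extra["sigma_resid"] = float(np.sqrt(res.scale))
    if not np.all(np.isfinite(beta)) or (family == "binomial" and np.max(np.abs(beta)) > 30):
        raise ConvergenceError(
            f"fit diverged (max |coef| = {np.max(np.abs(beta)):.3g}); "
            "possible separation or degenerate response")
    est = pd.Series(beta, index=names)
    vcov = pd.DataFrame(vc, index=names, columns=names)
    return FittedModel(name, family, link, zero_inflated, (), ll, k, len(y), est, vcov, extra)


# ---------------------------------------------------------------------------
# Laplace random-intercept engine

class _LaplaceProblem:
    def __init__(self, y, X, groups: dict, family: str, zero_inflated: bool):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.factors = list(groups)
        self.codes = []
        self.sizes = []
        for f in self.factors:
            codes, uniq = pd.factorize(np.asarray(groups[f]))
            self.codes.append(codes)
            self.sizes.append(len(uniq))
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)])[:-1]
        self.q = int(sum(self.sizes))
        key = (family, zero_inflated)
        if key not in _FAMILY_D:
            raise NotImplementedError(
                f"random-intercept fits not implemented for {family} "
                f"(zero_inflated={zero_inflated})")
        self.dfun = _FAMILY_D[key]
        self.u_warm = np.zeros(self.q)

    def eta(self, beta, u):
        eta = self.X @ beta
        for codes, off in zip(self.codes, self.offsets):
            eta = eta + u[off + codes]
        return eta

    def _newton(self, beta, prec, extra):
        """Inner mode of the penalized conditional loglik; returns (u, H, f(u))."""
        u = self.u_warm.copy()
        f_old = None
        for _ in range(100):
            ll, d1, d2 = self.dfun(self.y, self.eta(beta, u), extra)
            f = ll.sum() - 0.5 * np.sum(prec * u**2)
            g = -prec * u
            H = np.diag(prec.copy())
            for codes, off in zip(self.codes, self.offsets):
                np.add.at(g, off + codes, d1)
            w = -d2
            for ci, oi in zip(self.codes, self.offsets):
                for cj, oj in zip(self.codes, self.offsets):
                    np.add.at(H, (oi + ci, oj + cj), w)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = g / np.diag(H)
            # step-halving line search on the penalized objective
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                ll_n, _, _ = self.dfun(self.y, self.eta(beta, u_new), extra)
                f_new = ll_n.sum() - 0.5 * np.sum(prec * u_new**2)
                if np.isfinite(f_new) and f_new >= f - 1e-12:
                    break
                t *= 0.5
            if np.max(np.abs(t * step)) < 1e-9 or (f_old is not None and
                                                   abs(f_new - f_old) < 1e-10):
                u = u_new
                break
            u, f_old = u_new, f_new
        ll, d1, d2 = self.dfun(self.y, self.eta(beta, u), extra)
        f = ll.sum() - 0.5 * np.sum(prec * u**2)
        H = np.diag(prec.copy())
        w = -d2
        for ci, oi in zip(self.codes, self.offsets):
            for cj, oj in zip(self.codes, self.offsets):
                np.add.at(H, (oi + ci, oj + cj), w)
        self.u_warm = u
        return u, H, f

    def marginal_loglik(self, beta, log_sigmas, extra):
        sig = np.exp(log_sigmas)
        prec = np.zeros(self.q)
        for s, size, off in zip(sig, self.sizes, self.offsets):
            prec[off:off + size] = 1.0 / s**2
        u, H, f = self._newton(beta, prec, extra)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf
        log_prior_norm = -0.5 * self.q * np.log(2 * np.pi) - np.sum(
            np.array(self.sizes) * log_sigmas)
        return f + log_prior_norm + 0.5 * self.q * np.log(2 * np.pi) - 0.5 * logdet


def _fd_hessian(fun, x, h=1e-4):
    x = np.asarray(x, dtype=float)
    p = len(x)
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (fun(x + ei + ej) - fun(x + ei - ej)
                                     - fun(x - ei + ej) + fun(x - ei - ej)) / (4 * h**2)
    return H


def fit_random_intercept(response, design, family: str, groups,
                         zero_inflated: bool = False, link: str | None = None,
                         name: str = "model") -> FittedModel:
    """Marginal-ML GLMM with Gaussian random intercepts (Laplace approximation).

    ``groups`` maps factor name -> per-observation labels; one factor or a
    crossed pair. When every variance estimate collapses to the boundary
    the fixed effects coincide with :func:`fit_glm`. ``k`` counts fixed
    effects + one variance component per factor + dispersion/zero-inflation.
    """
    y = np.asarray(response, dtype=float)
    X = _as_design(design)
    names = list(X.columns)
    if isinstance(groups, (pd.Series, np.ndarray, list)):
        groups = {"group": np.asarray(groups)}
    if not 1 <= len(groups) <= 2:
        raise ValueError("one grouping factor or a crossed pair required")
    for f, lab in groups.items():
        if len(pd.unique(np.asarray(lab))) < 2:
            raise ValueError(f"grouping factor {f!r} has a single level")
    prob = _LaplaceProblem(y, X, groups, family, zero_inflated)

    # extra dispersion parameters appended to the outer vector
    extra_names = []
    if family == "gaussian":
        extra_names.append("log_sigma_resid")
    if family == "negative_binomial":
        extra_names.append("log_alpha")
    if zero_inflated:
        extra_names.append("psi")

    try:
        start_fm = fit_glm(y, X, family, zero_inflated=zero_inflated, name="start")
        beta0 = start_fm.estimates.to_numpy()
    except ConvergenceError:
        beta0 = np.zeros(len(names))
        start_fm = None
    x0 = np.concatenate([beta0, np.full(len(groups), np.log(0.3)),
                         np.zeros(len(extra_names))])
    if start_fm is not None:
        for i, en in enumerate(extra_names):
            if en == "log_sigma_resid" and "sigma_resid" in start_fm.extra:
                x0[len(names) + len(groups) + i] = np.log(start_fm.extra["sigma_resid"])
            if en == "log_alpha" and "alpha" in start_fm.extra:
                x0[len(names) + len(groups) + i] = np.log(max(start_fm.extra["alpha"], 1e-3))
            if en == "psi" and "zero_inflation_prob" in start_fm.extra:
                pz = np.clip(start_fm.extra["zero_inflation_prob"], 1e-4, 1 - 1e-4)
                x0[len(names) + len(groups) + i] = special.logit(pz)

    nb, ng = len(names), len(groups)

    def unpack(x):
        beta = x[:nb]
        log_sig = np.clip(x[nb:nb + ng], np.log(1e-4), np.log(50.0))
        extra = {}
        for i, en in enumerate(extra_names):
            v = x[nb + ng + i]
            if en == "log_sigma_resid":
                extra["sigma_resid"] = float(np.exp(np.clip(v, -10, 5)))
            elif en == "log_alpha":
                extra["alpha"] = float(np.exp(np.clip(v, -10, 5)))
            else:
                extra["psi"] = float(np.clip(v, -20, 20))
        return beta, log_sig, extra

    def nll(x):
        beta, log_sig, extra = unpack(x)
        v = prob.marginal_loglik(beta, log_sig, extra)
        return 1e10 if not np.isfinite(v) else -v

    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    res = optimize.minimize(nll, res.x, method="BFGS",
                            options={"maxiter": 200, "gtol": 1e-5})
    if not np.all(np.isfinite(res.x)):
        raise ConvergenceError("mixed-model fit diverged")
    beta, log_sig, extra_p = unpack(res.x)
    ll = -nll(res.x)

    H = _fd_hessian(nll, res.x)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    vc = cov_all[:nb, :nb]
    # guard against FD noise producing tiny negative variances
    d = np.diag(vc).copy()
    if np.any(d < 0):
        vc = vc.copy()
        np.fill_diagonal(vc, np.abs(d))

    k = nb + ng + len(extra_names)
    extra = {"sigma_" + f: float(np.exp(s)) for f, s in zip(groups, log_sig)}
    extra.update(extra_p)
    if zero_inflated and "psi" in extra:
        extra["zero_inflation_prob"] = float(special.expit(extra.pop("psi")))
    est = pd.Series(beta, index=names)
    vcov = pd.DataFrame(vc, index=names, columns=names)
    return FittedModel(name, family, link or _LINKS[family], zero_inflated,
                       tuple(groups), float(ll), k, len(y), est, vcov, extra)


# ---------------------------------------------------------------------------
# formula interface

_RANDOM_RE = re.compile(r"\+?\s*\(\s*1\s*\|\s*([A-Za-z_][A-Za-z0-9_]*)\s*\)")


def fit_formula(data: pd.DataFrame, formula: str, family: str,
                zero_inflated: bool = False, name: str | None = None) -> FittedModel:
    """Fit from a formula such as ``"family_unit ~ habitat * density + (1|year)"``.

    ``(1|factor)`` terms are random intercepts; the rest is patsy syntax.
    """
    from patsy import dmatrices

    rand = _RANDOM_RE.findall(formula)
    fixed = _RANDOM_RE.sub("", formula).strip()
    fixed = re.sub(r"~\s*\+", "~ ", fixed)
    if fixed.endswith("~"):
        fixed += " 1"
    ydm, xdm = dmatrices(fixed, data, return_type="dataframe")
    y = ydm.to_numpy().ravel()
    name = name or formula
    if rand:
        groups = {g: data[g].to_numpy() for g in rand}
        return fit_random_intercept(y, xdm, family, groups,
                                    zero_inflated=zero_inflated, name=name)
    return fit_glm(y, xdm, family, zero_inflated=zero_inflated, name=name)


# ---------------------------------------------------------------------------
# model-set machinery

def build_model_set(models: list[FittedModel]) -> ModelSet:
    """AICc table with deltas and Akaike weights, sorted best-first.

    All models must be fits to the same data (identical n). Ties are
    broken by model name for a stable ordering.
    """
    if not models:
        raise ValueError("empty model list")
    ns = {m.n for m in models}
    if len(ns) > 1:
        raise ValueError(f"models fitted to different data (n = {sorted(ns)})")
    rows = [{"model": m.name, "k": m.k, "loglik": m.loglik, "aicc": m.aicc}
            for m in models]
    tab = pd.DataFrame(rows).sort_values(["aicc", "model"], kind="mergesort")
    tab["delta"] = tab["aicc"] - tab["aicc"].min()
    rel = np.exp(-0.5 * tab["delta"].to_numpy())
    tab["weight"] = rel / rel.sum()
    tab = tab.reset_index(drop=True)
    return ModelSet(table=tab, models={m.name: m for m in models})


def model_average(model_set: ModelSet, terms: list[str],
                  delta_max: float | None = None) -> list[AveragedEstimate]:
    """Full-model (zero-substitution) averaging with unconditional 95% CIs.

    A term absent from a model contributes estimate 0 with variance 0 at
    that model's weight. The unconditional variance is
    ``sum_m w_m * (var_m + (beta_m - beta_bar)^2)``. ``delta_max``
    optionally restricts the averaging set (weights renormalised).
    """
    if not terms:
        raise ValueError("empty term list")
    tab = model_set.table
    if delta_max is not None:
        tab = tab[tab["delta"] <= delta_max]
    w = tab["weight"].to_numpy()
    w = w / w.sum()
    out = []
    z = stats.norm.ppf(0.975)
    for term in terms:
        present = [term in model_set.models[mn].estimates.index for mn in tab["model"]]
        if not any(present):
            raise ValueError(f"term {term!r} appears in no model")
        est = np.array([model_set.models[mn].estimate(term) if p else 0.0
                        for mn, p in zip(tab["model"], present)])
        var = np.array([model_set.models[mn].se(term) ** 2 if p else 0.0
                        for mn, p in zip(tab["model"], present)])
        bbar = float(np.sum(w * est))
        vbar = float(np.sum(w * (var + (est - bbar) ** 2)))
        se = math.sqrt(max(vbar, 0.0))
        out.append(AveragedEstimate(term, bbar, bbar - z * se, bbar + z * se))
    return out
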