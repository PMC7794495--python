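"""Cormack–Jolly–Seber apparent-survival engine.

Open-population CJS model conditioning on first capture, with a
two-age-class structure (juvenile survival over the first interval
after marking, adult survival thereafter), habitat groups at marking
(urban / rural juveniles), additive time variation on the logit scale,
a family-unit flag and an individual body-condition covariate entering
survival per age class, and recapture structured by time, habitat and
field effort.

The likelihood is individual-based (so individual covariates are
supported): for a bird first captured at occasion *f* and last seen at
*l*, the history probability is the product of survival terms over
intervals f..l-1, detection/non-detection terms over occasions f+1..l,
and the absorbing "never seen again" probability

    chi_t = (1 - phi_t) + phi_t * (1 - p_{t+1}) * chi_{t+1},

computed by backward recursion. All parameters live on the logit scale;
confidence intervals are delta-method on the logit, back-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .model_selection import _fd_hessian, aicc

__all__ = [
    "EncounterHistory",
    "CJSDesign",
    "CJSFit",
    "cjs_loglik",
    "fit_cjs",
    "m_array",
    "cjs_model_average",
    "chisq_gof_p",
    "bootstrap_gof",
]

AGE_CLASSES = ("JuvU", "JuvR", "Ad")


@dataclass
class EncounterHistory:
    individual_id: str
    history: np.ndarray
    group: str                      # "JuvU" or "JuvR" at marking
    born_in_family_unit: bool = False
    body_condition: float | None = None

    def __post_init__(self):
        self.history = np.asarray(self.history, dtype=int)
        if self.history.max() > 1 or self.history.min() < 0:
            raise ValueError("history must be binary")
        if not self.history.any():
            raise ValueError("history has no captures")

    @property
    def first_capture(self) -> int:
        return int(np.argmax(self.history))

    @property
    def last_capture(self) -> int:
        return int(len(self.history) - 1 - np.argmax(self.history[::-1]))


def _norm_effect(spec):
    """Normalise a per-age-class effect spec.

    None, 'additive' (one shared slope over all classes), or a tuple of
    groups, each group being an age class or a tuple of age classes that
    share one slope — e.g. ``(("JuvU", "JuvR"),)`` gives a single slope
    applied to both juvenile classes and none to adults.
    """
    if spec is None:
        return None
    if spec == "additive":
        return ("additive",)
    if isinstance(spec, str):
        spec = (spec,)
    groups = []
    for g in spec:
        g = (g,) if isinstance(g, str) else tuple(g)
        bad = set(g) - set(AGE_CLASSES)
        if bad:
            raise ValueError(f"unknown age classes {sorted(bad)}")
        groups.append(g)
    return tuple(groups)


def _effect_name(group) -> str:
    return "+".join(group)


@dataclass(frozen=True)
class CJSDesign:
    """Structure of the survival (phi) and recapture (p) predictors.

    ``phi_family`` / ``phi_condition``: None, "additive" (one shared
    slope), or a tuple of age classes each getting its own slope —
    mirroring notations like (JuvU*body condition)/JuvR/Ad.
    """

    age_classes: bool = True
    phi_time: bool = False
    phi_family: object = None
    phi_condition: object = None
    p_effort: bool = False
    p_time: bool = False
    p_habitat: bool = False
    name: str = "cjs"

    def phi_columns(self, T: int) -> list[str]:
        cols = list("phi_" + a for a in AGE_CLASSES) if self.age_classes else ["phi"]
        if self.phi_time:
            cols += [f"phi_t{t}" for t in range(1, T - 1)]
        for label, spec in (("family", _norm_effect(self.phi_family)),
                            ("cond", _norm_effect(self.phi_condition))):
            if spec == ("additive",):
                cols.append(f"phi_{label}")
            elif spec:
                cols += [f"phi_{label}:{_effect_name(g)}" for g in spec]
        return cols

    def p_columns(self, T: int) -> list[str]:
        cols = ["p_int"]
        if self.p_effort:
            cols.append("p_effort_high")
        if self.p_habitat:
            cols.append("p_urban")
        if self.p_time:
            cols += [f"p_t{t}" for t in range(2, T)]
        return cols

    def n_params(self, T: int) -> int:
        return len(self.phi_columns(T)) + len(self.p_columns(T))


class _Compiled:
    """Design matrices and masks for a set of histories."""

    def __init__(self, histories: list[EncounterHistory], design: CJSDesign,
                 effort: np.ndarray | None):
        self.design = design
        self.n = len(histories)
        if self.n == 0:
            raise ValueError("no encounter histories")
        T = len(histories[0].history)
        if T < 2:
            raise ValueError("need at least 2 occasions")
        if any(len(h.history) != T for h in histories):
            raise ValueError("ragged encounter histories")
        self.T = T
        if effort is None:
            effort = np.array(["high"] * T)
        effort = np.asarray(effort)
        if len(effort) != T:
            raise ValueError("one effort level per occasion required")
        self.effort = effort

        self.histories = histories
        self.Y = np.array([h.history for h in histories])
        self.f = np.array([h.first_capture for h in histories])
        self.l = np.array([h.last_capture for h in histories])
        urban = np.array([h.group == "JuvU" for h in histories], dtype=float)
        fam = np.array([h.born_in_family_unit for h in histories], dtype=float)
        spec_c = _norm_effect(design.phi_condition)
        cond = np.array([0.0 if h.body_condition is None else h.body_condition
                         for h in histories], dtype=float)
        if spec_c and any(h.body_condition is None for h in histories):
            raise ValueError("body_condition required by the design but missing")

        phi_cols = design.phi_columns(T)
        p_cols = design.p_columns(T)
        self.phi_cols, self.p_cols = phi_cols, p_cols
        n, K = self.n, len(phi_cols)
        # interval t covers occasion t -> t+1; juvenile iff t == first capture
        tgrid = np.arange(T - 1)[None, :]
        juv = tgrid == self.f[:, None]
        Xphi = np.zeros((n, T - 1, K))
        ci = 0
        if design.age_classes:
            Xphi[:, :, 0] = juv * urban[:, None]
            Xphi[:, :, 1] = juv * (1 - urban[:, None])
            Xphi[:, :, 2] = ~juv
            ci = 3
        else:
            Xphi[:, :, 0] = 1.0
            ci = 1
        if design.phi_time:
            for t in range(1, T - 1):
                Xphi[:, t, ci] = 1.0
                ci += 1
        ind = {"JuvU": juv * urban[:, None], "JuvR": juv * (1 - urban[:, None]),
               "Ad": (~juv).astype(float)}
        for spec, vec in ((_norm_effect(design.phi_family), fam),
                          (spec_c, cond)):
            if spec == ("additive",):
                Xphi[:, :, ci] = vec[:, None]
                ci += 1
            elif spec:
                for g in spec:
                    Xphi[:, :, ci] = vec[:, None] * sum(ind[a] for a in g)
                    ci += 1
        self.Xphi = Xphi

        Kp = len(p_cols)
        Xp = np.zeros((n, T, Kp))
        Xp[:, :, 0] = 1.0
        ci = 1
        if design.p_effort:
            Xp[:, :, ci] = (effort == "high").astype(float)[None, :]
            ci += 1
        if design.p_habitat:
            Xp[:, :, ci] = urban[:, None]
            ci += 1
        if design.p_time:
            for t in range(2, T):
                Xp[:, t, ci] = 1.0
                ci += 1
        self.Xp = Xp

        occ = np.arange(T)[None, :]
        self.interval_mask = (tgrid >= self.f[:, None]) & (tgrid <= self.l[:, None] - 1)
        self.occ_mask = (occ >= self.f[:, None] + 1) & (occ <= self.l[:, None])

    def loglik(self, params: np.ndarray) -> float:
        K = len(self.phi_cols)
        bphi, bp = params[:K], params[K:]
        eps = 1e-12
        phi = np.clip(special.expit(self.Xphi @ bphi), eps, 1 - eps)
        p = np.clip(special.expit(self.Xp @ bp), eps, 1 - eps)
        # observed stretch: survival over intervals, detection at occasions
        ll = (np.log(phi) * self.interval_mask).sum(axis=1)
        det = np.where(self.Y == 1, np.log(p), np.log1p(-p))
        ll += (det * self.occ_mask).sum(axis=1)
        # chi: never seen after last capture
        chi = np.ones((self.n, self.T))
        for t in range(self.T - 2, -1, -1):
            chi[:, t] = (1 - phi[:, t]) + phi[:, t] * (1 - p[:, t + 1]) * chi[:, t + 1]
        ll += np.log(np.clip(chi[np.arange(self.n), self.l], eps, 1.0))
        return float(ll.sum())


def cjs_loglik(histories, design: CJSDesign, params, effort=None) -> float:
    """CJS log-likelihood of the histories at logit-scale ``params``.

    ``params`` concatenates the phi and p coefficients in the order of
    ``design.phi_columns(T) + design.p_columns(T)``.
    """
    comp = _Compiled(list(histories), design, effort)
    params = np.asarray(params, dtype=float)
    if len(params) != design.n_params(comp.T):
        raise ValueError(f"expected {design.n_params(comp.T)} parameters, "
                         f"got {len(params)}")
    return comp.loglik(params)


@dataclass
class CJSFit:
    design: CJSDesign
    params: pd.Series
    vcov: pd.DataFrame
    loglik: float
    k: int
    n: int
    T: int
    converged: bool
    boundary: bool
    confounded_last: bool
    _compiled: _Compiled = field(repr=False, default=None)

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)

    def _real(self, row: np.ndarray, cols) -> tuple[float, float, float]:
        beta = self.params[cols].to_numpy()
        V = self.vcov.loc[cols, cols].to_numpy()
        eta = float(row @ beta)
        se = float(np.sqrt(max(row @ V @ row, 0.0)))
        z = stats.norm.ppf(0.975)
        return (special.expit(eta), special.expit(eta - z * se),
                special.expit(eta + z * se))

    def survival(self, age_class: str = "Ad", interval: int = 0,
                 family: bool = False, condition: float = 0.0):
        """Real-scale apparent survival (est, lo, hi) for one age class.

        ``interval`` indexes the time deviation (0 = reference) when the
        design is time varying; family/condition set the covariates.
        """
        cols = self.design.phi_columns(self.T)
        row = np.zeros(len(cols))
        name = f"phi_{age_class}" if self.design.age_classes else "phi"
        row[cols.index(name)] = 1.0
        if self.design.phi_time and interval >= 1:
            row[cols.index(f"phi_t{interval}")] = 1.0
        for label, val, spec in (("family", float(family), _norm_effect(self.design.phi_family)),
                                 ("cond", condition, _norm_effect(self.design.phi_condition))):
            if spec == ("additive",):
                row[cols.index(f"phi_{label}")] = val
            elif spec:
                for g in spec:
                    if age_class in g:
                        row[cols.index(f"phi_{label}:{_effect_name(g)}")] = val
        idx = [self.params.index.get_loc(c) for c in cols]
        full_row = np.zeros(len(self.params))
        full_row[idx] = row
        return self._real(full_row, list(self.params.index))

    def recapture(self, effort: str = "high", urban: bool = False, occasion: int = 1):
        cols = self.design.p_columns(self.T)
        row = np.zeros(len(self.params))
        off = len(self.design.phi_columns(self.T))
        row[off + cols.index("p_int")] = 1.0
        if self.design.p_effort:
            row[off + cols.index("p_effort_high")] = float(effort == "high")
        if self.design.p_habitat:
            row[off + cols.index("p_urban")] = float(urban)
        if self.design.p_time and occasion >= 2:
            row[off + cols.index(f"p_t{occasion}")] = 1.0
        return self._real(row, list(self.params.index))

    def mean_survival(self, age_class: str = "Ad", **kw):
        """Across-interval mean real-scale survival; drops the terminal
        interval when it is confounded with recapture."""
        if not self.design.phi_time:
            return self.survival(age_class, **kw)
        last = self.T - 2 - (1 if self.confounded_last else 0)
        vals = [self.survival(age_class, interval=t, **kw) for t in range(0, last + 1)]
        arr = np.array(vals)
        return tuple(arr.mean(axis=0))


def fit_cjs(histories, design: CJSDesign, effort=None, start=None) -> CJSFit:
    """Maximum-likelihood CJS fit on the logit scale.

    AICc uses the number of marked individuals as the effective sample
    size. Logits are bounded at +/-15; estimates on that bound are
    flagged as boundary (real-scale 0 or 1).
    """
    histories = list(histories)
    comp = _Compiled(histories, design, effort)
    npar = design.n_params(comp.T)
    x0 = np.zeros(npar) if start is None else np.asarray(start, dtype=float)

    def nll(x):
        return -comp.loglik(x)

    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            bounds=[(-15, 15)] * npar,
                            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8})
    xhat = res.x
    boundary = bool(np.any(np.abs(xhat) > 14.5))
    H = _fd_hessian(nll, xhat)
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.linalg.pinv(H)
    d = np.diag(V).copy()
    if np.any(d < 0):
        V = V.copy()
        np.fill_diagonal(V, np.abs(d))
    cols = design.phi_columns(comp.T) + design.p_columns(comp.T)
    fit = CJSFit(design=design, params=pd.Series(xhat, index=cols),
                 vcov=pd.DataFrame(V, index=cols, columns=cols),
                 loglik=-res.fun, k=npar, n=comp.n, T=comp.T,
                 converged=bool(res.success or res.fun < np.inf),
                 boundary=boundary,
                 confounded_last=bool(design.phi_time and design.p_time),
                 _compiled=comp)
    return fit


def m_array(histories) -> pd.DataFrame:
    """Release/first-recapture summary: per release occasion, the number
    released, first recaptured at each later occasion, and never seen."""
    histories = list(histories)
    if not histories:
        raise ValueError("no histories")
    T = len(histories[0].history)
    released = np.zeros(T - 1, dtype=int)
    m = np.zeros((T - 1, T), dtype=int)
    for h in histories:
        seen = np.flatnonzero(h.history)
        for a, b in zip(seen[:-1], seen[1:]):
            released[a] += 1
            m[a, b] += 1
        if seen[-1] < T - 1:
            released[seen[-1]] += 1
    rows = []
    for i in range(T - 1):
        row = {"occasion": i + 1, "released": int(released[i])}
        for j in range(i + 1, T):
            row[f"recaptured_at_{j + 1}"] = int(m[i, j])
        row["never_seen"] = int(released[i] - m[i].sum())
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


def cjs_model_average(fits: list[CJSFit], targets: list[dict]) -> pd.DataFrame:
    """Akaike-weight averaging of real-scale survival across CJS fits.

    Each target is a kwargs dict for :meth:`CJSFit.survival` (plus a
    'label'); unconditional variances combine the within-fit delta-method
    variance and the between-fit spread of the real-scale estimates.
    """
    if not fits:
        raise ValueError("no fits")
    if len({f.n for f in fits}) > 1:
        raise ValueError("fits on different data")
    a = np.array([f.aicc for f in fits])
    delta = a - a.min()
    w = np.exp(-delta / 2)
    w /= w.sum()
    z = stats.norm.ppf(0.975)
    rows = []
    for tg in targets:
        tg = dict(tg)
        label = tg.pop("label", str(tg))
        ests, ses = [], []
        for f in fits:
            e, lo, hi = f.survival(**tg)
            ests.append(e)
            ses.append((hi - lo) / (2 * z) if hi > lo else 0.0)
        ests = np.array(ests)
        var = np.array(ses) ** 2
        ebar = float(np.sum(w * ests))
        vbar = float(np.sum(w * (var + (ests - ebar) ** 2)))
        se = np.sqrt(vbar)
        rows.append({"target": label, "estimate": ebar,
                     "ci_low": max(ebar - z * se, 0.0),
                     "ci_high": min(ebar + z * se, 1.0)})
    return pd.DataFrame(rows)


def chisq_gof_p(chi2: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(chi2, df))


def simulate_from_fit(fit: CJSFit, rng: np.random.Generator) -> list[EncounterHistory]:
    """Parametric resample: new histories from the fitted phi/p, keeping
    each individual's first capture, group and covariates."""
    comp = fit._compiled
    K = len(comp.phi_cols)
    x = fit.params.to_numpy()
    phi = special.expit(comp.Xphi @ x[:K])
    p = special.expit(comp.Xp @ x[K:])
    out = []
    for i, orig in enumerate(comp.histories):
        T = comp.T
        hist = np.zeros(T, dtype=int)
        f = comp.f[i]
        hist[f] = 1
        alive = True
        for t in range(f, T - 1):
            alive = alive and (rng.random() < phi[i, t])
            if not alive:
                break
            if rng.random() < p[i, t + 1]:
                hist[t + 1] = 1
        out.append(EncounterHistory(
            individual_id=f"sim_{i}", history=hist, group=orig.group,
            born_in_family_unit=orig.born_in_family_unit,
            body_condition=orig.body_condition))
    return out


def bootstrap_gof(fit: CJSFit, n_rep: int = 100, seed: int = 0,
                  effort=None) -> dict:
    """Parametric-bootstrap goodness of fit.

    Simulates ``n_rep`` datasets from the fitted model, refits each, and
    compares the observed deviance (-2 loglik at the MLE) with the
    bootstrap distribution: p = fraction of simulated deviances >= the
    observed one. Also returns the dispersion ratio c-hat =
    observed / mean simulated deviance.
    """
    import warnings

    if n_rep < 50:
        warnings.warn("bootstrap_gof with n_rep < 50 is imprecise", stacklevel=2)
    rng = np.random.default_rng(seed)
    if effort is None:
        effort = fit._compiled.effort
    obs_dev = -2 * fit.loglik
    devs = []
    for _ in range(n_rep):
        sim = simulate_from_fit(fit, rng)
        refit = fit_cjs(sim, fit.design, effort=effort,
                        start=fit.params.to_numpy())
        devs.append(-2 * refit.loglik)
    devs = np.asarray(devs)
    return {"observed_deviance": obs_dev,
            "p": float(np.mean(devs >= obs_dev)),
            "c_hat": float(obs_dev / devs.mean()),
            "simulated_deviances": devs}
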