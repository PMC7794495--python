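"""End-to-end analyses on simulated or user data.

Each ``run_*`` function fits one of the study's named analyses — the
monthly attendance GLM, the family-unit occurrence GLMM, the
productivity and body-condition GLMMs, the lifetime-reproductive-
success GLM and the CJS survival model sets — with its candidate model
set hard-coded so that reports are comparable line by line with the
published tables. Joining logic (events x indices x chicks) lives here;
the statistical modules consume tidy arrays only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model_selection as ms
from .cmr import CJSDesign, cjs_model_average, fit_cjs
from .metrics import body_condition, center_covariates

__all__ = [
    "AnalysisError",
    "AnalysisReport",
    "run_attendance_analysis",
    "run_family_unit_analysis",
    "run_productivity_analyses",
    "run_condition_analyses",
    "run_lrs_analysis",
    "run_survival_analyses",
]


class AnalysisError(RuntimeError):
    """A degenerate input made an analysis unfittable."""


@dataclass
class AnalysisReport:
    name: str
    model_table: pd.DataFrame | None
    averaged: pd.DataFrame | None
    extras: dict = field(default_factory=dict)


def _avg_frame(model_set: ms.ModelSet, terms: list[str]) -> pd.DataFrame:
    rows = [{"term": a.term, "estimate": a.estimate,
             "ci_low": a.ci_low, "ci_high": a.ci_high}
            for a in ms.model_average(model_set, terms)]
    return pd.DataFrame(rows)


def run_attendance_analysis(attendance: pd.DataFrame) -> AnalysisReport:
    """Binomial GLM of monthly natal-nest presence: time x habitat."""
    if len(attendance) == 0:
        raise AnalysisError("empty attendance table")
    data = attendance.copy()
    data["urban"] = (data["habitat"] == "urban").astype(float)
    fm = ms.fit_formula(data, "present ~ month * urban", "binomial",
                        name="month * habitat")
    z = 1.959963984540054
    rows = []
    for term in fm.estimates.index:
        est, se = fm.estimate(term), fm.se(term)
        rows.append({"term": term, "estimate": est,
                     "ci_low": est - z * se, "ci_high": est + z * se})
    return AnalysisReport("attendance", None, pd.DataFrame(rows),
                          {"model": fm})


_FAMILY_SET = [
    ("habitat + productivity + density", "family ~ urban + presid + dens"),
    ("habitat*productivity + density", "family ~ urban * presid + dens"),
    ("habitat*density + productivity", "family ~ urban * dens + presid"),
    ("habitat + density", "family ~ urban + dens"),
    ("habitat*density", "family ~ urban * dens"),
    ("habitat*productivity", "family ~ urban * presid"),
    ("habitat + productivity", "family ~ urban + presid"),
    ("habitat", "family ~ urban"),
    ("density", "family ~ dens"),
    ("productivity", "family ~ presid"),
    ("null", "family ~ 1"),
]


def run_family_unit_analysis(events: pd.DataFrame,
                             indices: pd.DataFrame | None = None
                             ) -> AnalysisReport:
    """Family-unit occurrence: binomial GLMMs with a year random intercept.

    Candidate set: habitat, conspecific density (aggregation index) and
    conspecific productivity residual with their pairwise interactions,
    down to the null model. Covariates are centred and scaled to unit
    variance before fitting.
    """
    data = events.copy()
    if indices is not None:
        data = data.merge(indices, on=["nest_id", "year"], how="left",
                          suffixes=("", "_idx"))
    for col in ("S", "P_resid"):
        if col not in data.columns:
            raise AnalysisError(f"events lack the {col!r} index column; "
                                "join the metrics output first")
    y = (data["unit_type"] == "family").astype(float)
    if y.nunique() < 2:
        raise AnalysisError("response is constant (no family units or no "
                            "pairs); the occurrence model is degenerate")
    data["family"] = y
    data["urban"] = (data["habitat"] == "urban").astype(float)
    for raw, col in (("S", "dens"), ("P_resid", "presid")):
        c, _ = center_covariates(data[raw].to_numpy())
        sd = c.std()
        data[col] = c / sd if sd > 0 else c
    fits = [ms.fit_formula(data, f + " + (1|year)", "binomial", name=nm)
            for nm, f in _FAMILY_SET]
    mset = ms.build_model_set(fits)
    terms = ["urban", "dens", "presid", "urban:presid", "urban:dens"]
    return AnalysisReport("family_unit", mset.table, _avg_frame(mset, terms),
                          {"model_set": mset})


_UNIT_SET = [
    ("habitat*family", "y ~ urban * family"),
    ("habitat + family", "y ~ urban + family"),
    ("habitat", "y ~ urban"),
    ("family", "y ~ family"),
    ("null", "y ~ 1"),
]


def _unit_effects_set(data: pd.DataFrame, family: str, random_terms: str,
                      zero_inflated: bool) -> ms.ModelSet:
    fits = [ms.fit_formula(data, f + random_terms, family,
                           zero_inflated=zero_inflated, name=nm)
            for nm, f in _UNIT_SET]
    return ms.build_model_set(fits)


def run_productivity_analyses(events: pd.DataFrame) -> AnalysisReport:
    """Zero-inflated Poisson GLMMs of annual productivity.

    Two model sets: all monitored nests (year random term) and only
    nests occupied at least once by a family unit (year and nest random
    terms).
    """
    if len(events) == 0:
        raise AnalysisError("no breeding events")
    data = events.copy()
    data["y"] = data["productivity"].astype(float)
    data["urban"] = (data["habitat"] == "urban").astype(float)
    data["family"] = (data["unit_type"] == "family").astype(float)
    all_zero = bool((data["y"] == 0).all())
    set_all = _unit_effects_set(data, "poisson", " + (1|year)",
                                zero_inflated=True)
    ever_family = data.groupby("nest_id")["family"].transform("max") == 1
    sub = data[ever_family]
    extras = {"model_set_all": set_all}
    tables = {"all_nests": set_all.table}
    averaged = {"all_nests": _avg_frame(set_all, ["urban", "family",
                                                  "urban:family"])}
    if not all_zero and len(sub) and sub["nest_id"].nunique() >= 2 \
            and sub["year"].nunique() >= 2:
        set_fam = _unit_effects_set(sub, "poisson", " + (1|year) + (1|nest_id)",
                                    zero_inflated=True)
        extras["model_set_family_nests"] = set_fam
        tables["family_nests"] = set_fam.table
        averaged["family_nests"] = _avg_frame(set_fam, ["urban", "family"])
    table = pd.concat(tables, names=["model_set"]).reset_index(level=0)
    avg = pd.concat(averaged, names=["model_set"]).reset_index(level=0)
    return AnalysisReport("productivity", table, avg, extras)


def run_condition_analyses(chicks: pd.DataFrame) -> AnalysisReport:
    """Gaussian GLMMs of chick body condition (nest and year random terms)."""
    if len(chicks) == 0:
        raise AnalysisError("no chicks")
    data = chicks.copy()
    data["y"] = body_condition(data["mass_g"].to_numpy(),
                               data["wing_mm"].to_numpy())
    data["urban"] = (data["habitat"] == "urban").astype(float)
    data["family"] = data["born_in_family_unit"].astype(float)
    data = data.rename(columns={"natal_nest": "nest_id"})
    rand = " + (1|year) + (1|nest_id)"
    if data["nest_id"].nunique() < 2 or data["year"].nunique() < 2:
        rand = " + (1|year)" if data["year"].nunique() >= 2 else ""
    if rand:
        fits = [ms.fit_formula(data, f + rand, "gaussian", name=nm)
                for nm, f in _UNIT_SET]
    else:
        fits = [ms.fit_formula(data, f, "gaussian", name=nm)
                for nm, f in _UNIT_SET]
    mset = ms.build_model_set(fits)
    ever_family = data.groupby("nest_id")["family"].transform("max") == 1
    extras = {"model_set_all": mset, "random_terms": rand.strip(" +")}
    tables = {"all_nests": mset.table}
    averaged = {"all_nests": _avg_frame(mset, ["urban", "family",
                                               "urban:family"])}
    sub = data[ever_family]
    if len(sub) and sub["family"].nunique() > 1 and sub["nest_id"].nunique() >= 2 \
            and sub["year"].nunique() >= 2:
        mset_f = ms.build_model_set(
            [ms.fit_formula(sub, f + " + (1|year) + (1|nest_id)", "gaussian",
                            name=nm) for nm, f in _UNIT_SET])
        extras["model_set_family_nests"] = mset_f
        tables["family_nests"] = mset_f.table
        averaged["family_nests"] = _avg_frame(mset_f, ["urban", "family"])
    table = pd.concat(tables, names=["model_set"]).reset_index(level=0)
    avg = pd.concat(averaged, names=["model_set"]).reset_index(level=0)
    return AnalysisReport("condition", table, avg, extras)


def run_lrs_analysis(individuals: pd.DataFrame) -> AnalysisReport:
    """Lifetime reproductive success: negative-binomial GLM, null vs
    dispersal strategy, with an intercept-only zero-inflation component.

    ``individuals`` needs a 'strategy' column ('delayed' or 'dispersed')
    and an 'lrs' count. For delayers the LRS is expected to already
    include the natal-year brood credited under the first-degree
    relatedness-equivalence rule.
    """
    if len(individuals) == 0:
        raise AnalysisError("no individuals")
    data = individuals.copy()
    data["y"] = data["lrs"].astype(float)
    data["delayed"] = (data["strategy"] == "delayed").astype(float)
    zero_inflated = True
    family = "negative_binomial"
    if (data["y"] == 0).all():
        family = "poisson"  # NB dispersion unidentifiable on all zeros
    fits = [
        ms.fit_formula(data, "y ~ 1", family, zero_inflated=zero_inflated,
                       name="null"),
        ms.fit_formula(data, "y ~ delayed", family, zero_inflated=zero_inflated,
                       name="delayed dispersal"),
    ]
    mset = ms.build_model_set(fits)
    return AnalysisReport("lrs", mset.table, _avg_frame(mset, ["delayed"]),
                          {"model_set": mset})


def _survival_family_set(T: int) -> list[CJSDesign]:
    time = T >= 3
    return [
        CJSDesign(phi_time=time, p_effort=True, name="(JuvU/JuvR/Ad) + time"),
        CJSDesign(phi_time=time, phi_family="additive", p_effort=True,
                  name="(JuvU/JuvR/Ad) + family unit + time"),
        CJSDesign(phi_time=time, phi_family=(("JuvR",),), p_effort=True,
                  name="(JuvU/(JuvR*family unit)/Ad) + time"),
        CJSDesign(phi_time=time, phi_family=(("Ad",),), p_effort=True,
                  name="(JuvU/JuvR/(Ad*family unit)) + time"),
        CJSDesign(phi_time=time, phi_family=(("JuvU",),), p_effort=True,
                  name="((JuvU*family unit)/JuvR/Ad) + time"),
        CJSDesign(phi_time=time, phi_family=(("JuvU", "JuvR"),), p_effort=True,
                  name="(((JuvU/JuvR)*family unit)/Ad) + time"),
        CJSDesign(phi_time=time, phi_family=(("JuvU",), ("JuvR",), ("Ad",)),
                  p_effort=True, name="((JuvU/JuvR/Ad)*family unit) + time"),
    ]


def _survival_condition_set(T: int) -> list[CJSDesign]:
    time = T >= 3
    return [
        CJSDesign(phi_time=time, phi_condition="additive", p_effort=True,
                  name="((JuvU/JuvR/Ad) + body condition) + time"),
        CJSDesign(phi_time=time, phi_condition=(("JuvU", "JuvR"),),
                  p_effort=True,
                  name="(((JuvU/JuvR) + body condition)/Ad) + time"),
        CJSDesign(phi_time=time, phi_condition=(("JuvU",),), p_effort=True,
                  name="((JuvU*body condition)/JuvR/Ad) + time"),
        CJSDesign(phi_time=time, phi_condition=(("JuvR",),), p_effort=True,
                  name="(JuvU/(JuvR*body condition)/Ad) + time"),
        CJSDesign(phi_time=time, phi_condition=(("Ad",),), p_effort=True,
                  name="(JuvU/JuvR/(Ad*body condition)) + time"),
        CJSDesign(phi_time=time, p_effort=True, name="(JuvU/JuvR/Ad) + time"),
    ]


def run_survival_analyses(histories, effort=None) -> AnalysisReport:
    """CJS model sets: family-structure effects and body-condition effects.

    Fits the published candidate structures (all with effort on
    recapture), model-averages real-scale survival by age class over the
    family-structure set, and reports the body-condition slope from the
    best condition model. With two occasions, time effects collapse to
    constant survival and are flagged.
    """
    histories = list(histories)
    if not histories:
        raise AnalysisError("no encounter histories")
    T = len(histories[0].history)
    extras: dict = {"time_collapsed": T < 3}

    fam_fits = [fit_cjs(histories, d, effort=effort)
                for d in _survival_family_set(T)]
    fam_tab = _cjs_table(fam_fits)
    targets = [{"label": f"phi_{a}_{grp}", "age_class": a, "family": fam}
               for a in ("JuvU", "JuvR", "Ad")
               for grp, fam in (("family", True), ("pair", False))]
    averaged_surv = cjs_model_average(fam_fits, targets)

    has_cond = all(h.body_condition is not None for h in histories)
    cond_tab = None
    if has_cond:
        cond_fits = [fit_cjs(histories, d, effort=effort)
                     for d in _survival_condition_set(T)]
        cond_tab = _cjs_table(cond_fits)
        # best-supported model that carries a condition slope
        with_slope = [f for f in cond_fits
                      if any(c.startswith("phi_cond") for c in f.params.index)]
        best = min(with_slope, key=lambda f: f.aicc) if with_slope else None
        if best is not None:
            slope_cols = [c for c in best.params.index if c.startswith("phi_cond")]
            c0 = slope_cols[0]
            est, se = float(best.params[c0]), float(np.sqrt(best.vcov.loc[c0, c0]))
            z = 1.959963984540054
            extras["condition_slope"] = {"estimate": est, "ci_low": est - z * se,
                                         "ci_high": est + z * se, "model": best.design.name}
        extras["condition_fits"] = cond_fits
    extras["family_fits"] = fam_fits
    tables = {"family_structure": fam_tab}
    if cond_tab is not None:
        tables["body_condition"] = cond_tab
    table = pd.concat(tables, names=["model_set"]).reset_index(level=0)
    return AnalysisReport("survival", table, averaged_surv, extras)


def _cjs_table(fits) -> pd.DataFrame:
    a = np.array([f.aicc for f in fits])
    delta = a - a.min()
    w = np.exp(-delta / 2)
    w /= w.sum()
    tab = pd.DataFrame({"model": [f.design.name for f in fits],
                        "k": [f.k for f in fits], "aicc": a,
                        "delta": delta, "weight": w})
    return tab.sort_values(["aicc", "model"], kind="mergesort").reset_index(drop=True)
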