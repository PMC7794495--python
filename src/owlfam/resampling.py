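"""Randomisation and resampling procedures for dispersal and survival.

Two bespoke procedures:

* a permutation test comparing the natal dispersal distances of
  individuals that delayed dispersal against the distances of
  non-philopatric dispersers: each iteration draws, without
  replacement, a pseudo-group of the same size from the disperser pool
  and records its median; the one-sided p-value is the fraction of
  null medians less than or equal to the observed median (denominator
  exactly n_iter);
* a resampled survival comparison: repeatedly pair the delayers'
  encounter histories with an equal number of disperser histories drawn
  in the delayers' cohort proportions, fit a constant-survival
  constant-recapture CJS model to each group per dataset, and compare
  the across-dataset means with a Z-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cmr import CJSDesign, fit_cjs

__all__ = [
    "PermutationResult",
    "SurvivalComparison",
    "dispersal_permutation_test",
    "bootstrap_survival_comparison",
    "z_test",
]


@dataclass
class PermutationResult:
    observed_statistic: float
    null_draws: np.ndarray
    n_iter: int
    p: float


@dataclass
class SurvivalComparison:
    mean_delayed: float
    ci_delayed: tuple[float, float]
    mean_control: float
    ci_control: tuple[float, float]
    z: float
    p: float
    n_datasets: int


def dispersal_permutation_test(delayed_distances, pool_distances,
                               n_iter: int = 1000, seed: int = 0,
                               statistic: str = "median",
                               plus_one: bool = False) -> PermutationResult:
    """One-sided permutation test: are delayers' dispersal distances short?

    ``statistic``: 'median' (group median per iteration, the default) or
    'individual' (each iteration draws single distances and the observed
    statistic is the group median all the same — a per-individual null).
    ``plus_one`` switches to the (count+1)/(n_iter+1) correction.
    """
    delayed = np.asarray(delayed_distances, dtype=float)
    pool = np.asarray(pool_distances, dtype=float)
    if delayed.size == 0 or pool.size == 0:
        raise ValueError("empty input")
    if statistic not in ("median", "individual"):
        raise ValueError("statistic must be 'median' or 'individual'")
    m = delayed.size if statistic == "median" else 1
    if pool.size < m:
        raise ValueError("pool smaller than the group to be resampled")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(np.median(delayed))
    # vectorised without-replacement draws: smallest-m uniform keys
    keys = rng.random((n_iter, pool.size))
    if m < pool.size:
        idx = np.argpartition(keys, m, axis=1)[:, :m]
    else:
        idx = np.argsort(keys, axis=1)
    null = np.median(pool[idx], axis=1)
    count = int(np.sum(null <= observed))
    p = (count + 1) / (n_iter + 1) if plus_one else count / n_iter
    return PermutationResult(observed, null, n_iter, float(p))


def z_test(mean1: float, se1: float, mean2: float, se2: float,
           tails: int = 1) -> tuple[float, float]:
    """Two-sample Z-test on independent means; one-tailed by default."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    z = (mean1 - mean2) / np.hypot(se1, se2)
    p = stats.norm.sf(z) if tails == 1 else 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _constant_cjs_phi(histories) -> tuple[float, float, float]:
    """phi estimate (est, lo, hi) from a constant-phi constant-p CJS fit."""
    design = CJSDesign(age_classes=False, name="phi(.) p(.)")
    fit = fit_cjs(histories, design)
    return fit.survival("")  # age_classes=False ignores the label


def bootstrap_survival_comparison(delayed_histories, pool_histories,
                                  cohort_of, n_datasets: int = 200,
                                  seed: int = 0) -> SurvivalComparison:
    """Resampled survival comparison of delayers vs matched dispersers.

    ``cohort_of`` maps an individual_id to its natal cohort; each of the
    ``n_datasets`` datasets draws len(delayed) disperser histories in the
    delayers' cohort proportions (without replacement within a dataset),
    fits a constant phi / constant p CJS model to each group, and the
    across-dataset means are compared with a one-tailed Z-test using the
    across-dataset spread as the standard errors. CIs are percentile
    (2.5/97.5) across datasets, degenerating to the delta-method CI of
    the single fit when n_datasets == 1.
    """
    delayed = list(delayed_histories)
    pool = list(pool_histories)
    if not delayed or not pool:
        raise ValueError("empty history sets")
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    rng = np.random.default_rng(seed)

    quotas: dict = {}
    for h in delayed:
        c = cohort_of(h.individual_id)
        quotas[c] = quotas.get(c, 0) + 1
    by_cohort: dict = {}
    for h in pool:
        by_cohort.setdefault(cohort_of(h.individual_id), []).append(h)
    for c, q in quotas.items():
        if len(by_cohort.get(c, [])) < q:
            raise ValueError(f"cohort {c!r}: need {q} disperser histories, "
                             f"have {len(by_cohort.get(c, []))}")

    est_d, lo_d, hi_d = _constant_cjs_phi(delayed)
    phis_c = []
    for _ in range(n_datasets):
        sample = []
        for c, q in quotas.items():
            picks = rng.choice(len(by_cohort[c]), size=q, replace=False)
            sample.extend(by_cohort[c][i] for i in picks)
        e, lo, hi = _constant_cjs_phi(sample)
        phis_c.append((e, lo, hi))
    phis_c = np.array(phis_c)
    mean_c = float(phis_c[:, 0].mean())
    if n_datasets == 1:
        ci_c = (float(phis_c[0, 1]), float(phis_c[0, 2]))
        se_c = (phis_c[0, 2] - phis_c[0, 1]) / (2 * stats.norm.ppf(0.975))
    else:
        ci_c = tuple(np.percentile(phis_c[:, 0], [2.5, 97.5]))
        se_c = float(phis_c[:, 0].std(ddof=1))
    se_d = (hi_d - lo_d) / (2 * stats.norm.ppf(0.975))
    se_d = max(se_d, 1e-9)
    se_c = max(se_c, 1e-9)
    z, p = z_test(est_d, se_d, mean_c, se_c, tails=1)
    return SurvivalComparison(
        mean_delayed=est_d, ci_delayed=(lo_d, hi_d),
        mean_control=mean_c, ci_control=(float(ci_c[0]), float(ci_c[1])),
        z=z, p=p, n_datasets=n_datasets)
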