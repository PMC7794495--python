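"""Likelihood-based relatedness and parentage from microsatellites.

Pairwise relationships are modelled through the identity-by-descent
coefficients (k0, k1, k2): unrelated U = (1, 0, 0), half sibs
HS = (0.5, 0.5, 0), full sibs FS = (0.25, 0.5, 0.25) and
parent–offspring PO = (0, 1, 0). At each locus the joint probability of
an unordered genotype pair is the k-mixture

    L = k0 * P(g1) P(g2) + k1 * S1(g1, g2) + k2 * S2(g1, g2)

with P the Hardy–Weinberg genotype probability, S1 the joint
probability under exactly one shared IBD allele (drawn from the
population, each genotype completed by an independent random allele)
and S2 = P(g1) when the genotypes are identical. Loci are independent
(linkage equilibrium), so log-likelihoods add.

Genotyping error is a per-allele substitution: each observed gene copy
is, with probability e, replaced by a random frequency-weighted allele.
Likelihoods marginalise over the true genotypes with this observation
model, so a single mistyped allele does not produce a hard Mendelian
exclusion at e > 0.

Parentage follows the Cervus logic: a LOD score
log L(candidate is parent) - log L(candidate unrelated), a trio
likelihood when one parent is known, and simulation-calibrated
confidence thresholds on the LOD gap (delta) between the best and the
second-best candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RELATIONSHIP_CLASSES",
    "AlleleFrequencies",
    "LikelihoodTables",
    "allele_frequencies_from_sample",
    "pair_likelihood",
    "ml_relationship",
    "parentage_lod",
    "assignment_confidence",
    "simulate_genotype",
    "mendelian_offspring",
]

# label -> (k0, k1, k2); relatedness r = k1/2 + k2
RELATIONSHIP_CLASSES = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}

LOG_FLOOR = -1e9  # stands in for -inf where a guarded value is required


class AlleleFrequencies(dict):
    """Mapping locus -> {allele: frequency}; frequencies sum to 1 per locus."""

    def __init__(self, data):
        super().__init__(data)
        for locus, freqs in self.items():
            tot = float(sum(freqs.values()))
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"frequencies at locus {locus!r} sum to {tot}, not 1")
            if any(f <= 0 for f in freqs.values()):
                raise ValueError(f"non-positive frequency at locus {locus!r}")


def allele_frequencies_from_sample(genotypes: dict) -> AlleleFrequencies:
    """Allele counts normalised per locus; missing genotypes are skipped.

    ``genotypes``: individual -> {locus: (a1, a2) or None}.
    """
    counts: dict = {}
    for g in genotypes.values():
        for locus, pair in g.items():
            if pair is None:
                continue
            d = counts.setdefault(locus, {})
            for a in pair:
                d[a] = d.get(a, 0) + 1
    if not counts:
        raise ValueError("no typed genotypes")
    out = {}
    for locus, d in counts.items():
        tot = sum(d.values())
        out[locus] = {a: c / tot for a, c in d.items()}
    return AlleleFrequencies(out)


class _LocusTables:
    """Precomputed genotype-pair probability matrices for one locus."""

    def __init__(self, freqs: dict, error_rate: float):
        self.alleles = sorted(freqs)
        self.p = np.array([freqs[a] for a in self.alleles], dtype=float)
        A = len(self.alleles)
        self.genotypes = [(i, j) for i in range(A) for j in range(i, A)]
        self.gidx = {g: k for k, g in enumerate(self.genotypes)}
        G = len(self.genotypes)
        p = self.p

        self.P = np.array([p[i] * p[j] * (1 if i == j else 2)
                           for (i, j) in self.genotypes])
        # Q[g, x] = P(random second allele completes g given one copy is x)
        Q = np.zeros((G, A))
        for k, (i, j) in enumerate(self.genotypes):
            if i == j:
                Q[k, i] = p[i]
            else:
                Q[k, i] = p[j]
                Q[k, j] = p[i]
        self.S1 = Q @ np.diag(p) @ Q.T
        self.S2 = np.diag(self.P)
        self.S0 = np.outer(self.P, self.P)

        # per-copy observation model m[o, t] = (1-e) I + e * p_o
        e = error_rate
        m = (1 - e) * np.eye(A) + e * p[:, None] * np.ones((1, A))
        # E[obs genotype, true genotype]
        E = np.zeros((G, G))
        for ko, (c, d) in enumerate(self.genotypes):
            for kt, (t1, t2) in enumerate(self.genotypes):
                if c == d:
                    E[ko, kt] = m[c, t1] * m[c, t2]
                else:
                    E[ko, kt] = m[c, t1] * m[d, t2] + m[d, t1] * m[c, t2]
        self.E = E

        # Mendelian transmission tensor M[o, mo, fa]
        M = np.zeros((G, G, G))
        for km, (a, b) in enumerate(self.genotypes):
            for kf, (c, d) in enumerate(self.genotypes):
                for x in (a, b):
                    for y in (c, d):
                        ko = self.gidx[(min(x, y), max(x, y))]
                        M[ko, km, kf] += 0.25
        self.M = M

        self.folded = {}
        for label, (k0, k1, k2) in RELATIONSHIP_CLASSES.items():
            J = k0 * self.S0 + k1 * self.S1 + k2 * self.S2
            self.folded[label] = E @ J @ E.T
        # trio joint probability of observed (offspring, mother, father)
        # genotypes when both are the true parents: Mendelian transmission
        # with HWE parental priors, folded by the observation model
        self.T_folded = np.einsum("ot,tmf,m,um,f,vf->ouv",
                                  E, M, self.P, E, self.P, E, optimize=True)
        # marginal observed genotype probabilities (HWE is preserved by the
        # frequency-weighted substitution model, but fold for exactness)
        self.P_obs = E @ self.P
        # folded PO transition numerator for known-parent denominators:
        # joint P(obs_m, obs_o) under PO
        self.PO_obs = self.folded["PO"]

    def index(self, pair) -> int:
        a, b = pair
        i, j = self.alleles.index(a), self.alleles.index(b)
        return self.gidx[(min(i, j), max(i, j))]


class LikelihoodTables:
    """Per-locus probability tables for a frequency set and error rate."""

    def __init__(self, freqs: AlleleFrequencies, error_rate: float = 0.0):
        if not 0 <= error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        self.error_rate = error_rate
        self.loci = {locus: _LocusTables(f, error_rate)
                     for locus, f in freqs.items()}


def _tables(freqs, error_rate) -> LikelihoodTables:
    if isinstance(freqs, LikelihoodTables):
        if abs(freqs.error_rate - error_rate) > 1e-12:
            raise ValueError("tables built with a different error rate")
        return freqs
    return LikelihoodTables(AlleleFrequencies(freqs), error_rate)


def pair_likelihood(g1: dict, g2: dict, freqs, relationship: str,
                    error_rate: float = 0.0) -> float:
    """Log-likelihood of a genotype pair under one relationship class.

    Sums over loci typed in both individuals; returns -inf on a hard
    exclusion (possible only at error_rate 0).
    """
    if relationship not in RELATIONSHIP_CLASSES:
        raise ValueError(f"unknown relationship {relationship!r}")
    tab = _tables(freqs, error_rate)
    total = 0.0
    shared = 0
    for locus, lt in tab.loci.items():
        a, b = g1.get(locus), g2.get(locus)
        if a is None or b is None:
            continue
        shared += 1
        L = lt.folded[relationship][lt.index(a), lt.index(b)]
        if L <= 0:
            return -math.inf
        total += math.log(L)
    if shared == 0:
        raise ValueError("no shared typed loci")
    return total


@dataclass
class RelationshipResult:
    best: str
    r: float
    logliks: dict
    ties: tuple


def ml_relationship(g1: dict, g2: dict, freqs, error_rate: float = 0.0
                    ) -> RelationshipResult:
    """Most likely of U/HS/FS/PO; r is the best class's k1/2 + k2."""
    lls = {rel: pair_likelihood(g1, g2, freqs, rel, error_rate)
           for rel in RELATIONSHIP_CLASSES}
    best = max(lls, key=lambda rel: (lls[rel], rel))
    ties = tuple(sorted(rel for rel in lls
                        if abs(lls[rel] - lls[best]) < 1e-9 or
                        (lls[rel] == -math.inf and lls[best] == -math.inf)))
    k0, k1, k2 = RELATIONSHIP_CLASSES[best]
    return RelationshipResult(best=best, r=k1 / 2 + k2, logliks=lls, ties=ties)


def parentage_lod(offspring: dict, candidate: dict, freqs,
                  error_rate: float = 0.0, known_parent: dict | None = None
                  ) -> float:
    """LOD score of the candidate as a parent of the offspring.

    Without a known parent: log of the PO pair likelihood over the
    unrelated pair likelihood. With a known parent, the trio likelihood
    P(offspring | known parent, candidate) replaces the PO numerator,
    and the denominator treats the candidate as unrelated (offspring
    still the known parent's child). Hard exclusions at error 0 are
    returned as a large negative guard value rather than -inf.
    """
    if offspring is candidate:
        raise ValueError("offspring and candidate are the same individual")
    tab = _tables(freqs, error_rate)
    lod = 0.0
    shared = 0
    for locus, lt in tab.loci.items():
        go, gc = offspring.get(locus), candidate.get(locus)
        if go is None or gc is None:
            continue
        io, ic = lt.index(go), lt.index(gc)
        if known_parent is not None and known_parent.get(locus) is not None:
            im = lt.index(known_parent[locus])
            num = lt.T_folded[io, im, ic]
            den = lt.PO_obs[im, io] * lt.P_obs[ic]
        else:
            num = lt.folded["PO"][io, ic]
            den = lt.P_obs[io] * lt.P_obs[ic]
        shared += 1
        if num <= 0:
            return LOG_FLOOR
        lod += math.log(num) - math.log(den)
    if shared == 0:
        raise ValueError("no shared typed loci")
    return lod


# ---------------------------------------------------------------------------
# simulation helpers (used by the confidence calibration and by tests)

def simulate_genotype(tab: LikelihoodTables, rng: np.random.Generator) -> dict:
    """One Hardy–Weinberg individual (true genotype, no error applied)."""
    g = {}
    for locus, lt in tab.loci.items():
        a = rng.choice(len(lt.alleles), size=2, p=lt.p)
        g[locus] = (lt.alleles[a[0]], lt.alleles[a[1]])
    return g


def mendelian_offspring(mother: dict, father: dict, tab: LikelihoodTables,
                        rng: np.random.Generator,
                        error_rate: float = 0.0) -> dict:
    """Mendelian offspring; each allele is swapped for a random
    frequency-weighted allele with probability ``error_rate``."""
    g = {}
    for locus, lt in tab.loci.items():
        gm, gf = mother.get(locus), father.get(locus)
        if gm is None or gf is None:
            g[locus] = None
            continue
        pair = [gm[rng.integers(2)], gf[rng.integers(2)]]
        for i in range(2):
            if error_rate > 0 and rng.random() < error_rate:
                pair[i] = lt.alleles[rng.choice(len(lt.alleles), p=lt.p)]
        g[locus] = tuple(pair)
    return g


def assignment_confidence(freqs, n_sim: int = 10_000,
                          prop_candidates_sampled: float = 0.7,
                          prop_loci_typed: float = 0.99,
                          error_rate: float = 0.01, seed: int = 0,
                          n_candidates: int = 30,
                          levels: tuple = (0.80, 0.95)) -> dict:
    """Simulation-calibrated LOD-gap (delta) thresholds for parentage.

    Simulated offspring are bred from a random mother and a father who
    is, with probability ``prop_candidates_sampled``, a member of the
    candidate pool. Each simulated offspring is scored against every
    candidate; the threshold for a confidence level c is the smallest
    delta such that, among simulated assignments with delta at or above
    it, the proportion where the top candidate is the true father is at
    least c. Returns {level: threshold} plus the observed assignment
    rate under no thresholding.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for a stable calibration")
    tab = _tables(freqs, error_rate)
    rng = np.random.default_rng(seed)
    loci = list(tab.loci)

    cands = [simulate_genotype(tab, rng) for _ in range(n_candidates)]
    cand_idx = {locus: np.array([tab.loci[locus].index(c[locus]) for c in cands])
                for locus in loci}
    # per-locus LOD lookup tables: LR[obs offspring, obs candidate]
    LR = {}
    for locus, lt in tab.loci.items():
        with np.errstate(divide="ignore"):
            LR[locus] = np.where(
                lt.folded["PO"] > 0,
                np.log(np.maximum(lt.folded["PO"], 1e-300))
                - np.log(np.outer(lt.P_obs, lt.P_obs)),
                LOG_FLOOR)

    deltas = np.empty(n_sim)
    correct = np.zeros(n_sim, dtype=bool)
    for s in range(n_sim):
        mother = simulate_genotype(tab, rng)
        sampled = rng.random() < prop_candidates_sampled
        true_i = int(rng.integers(n_candidates)) if sampled else -1
        father = cands[true_i] if sampled else simulate_genotype(tab, rng)
        off = mendelian_offspring(mother, father, tab, rng, error_rate)
        lods = np.zeros(n_candidates)
        for locus in loci:
            if off[locus] is None or rng.random() > prop_loci_typed:
                continue
            io = tab.loci[locus].index(off[locus])
            lods += LR[locus][io, cand_idx[locus]]
        order = np.argsort(lods)[::-1]
        deltas[s] = lods[order[0]] - (lods[order[1]] if n_candidates > 1 else 0.0)
        correct[s] = sampled and order[0] == true_i
    order = np.argsort(deltas)[::-1]
    cum_correct = np.cumsum(correct[order])
    rate = cum_correct / np.arange(1, n_sim + 1)
    out = {"assignment_rate": float(correct.mean())}
    for level in sorted(levels):
        ok = np.flatnonzero(rate >= level)
        if ok.size == 0:
            out[level] = float("inf")
        else:
            out[level] = float(deltas[order[ok[-1]]])
    # quantile monotonicity: a higher confidence level cannot have a
    # lower threshold
    prev = -np.inf
    for level in sorted(levels):
        out[level] = max(out[level], prev)
        prev = out[level]
    return out
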