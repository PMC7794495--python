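import math

import numpy as np
import pytest

from owlfam import kinship as kin
from owlfam import synthetic_data as sd


@pytest.fixture(scope="module")
def biallelic():
    return kin.AlleleFrequencies({"L1": {1: 0.5, 2: 0.5}})


@pytest.fixture(scope="module")
def panel_17():
    cfg = sd.SimulationConfig(seed=101)
    return sd.random_allele_frequencies(cfg)


class TestAlleleFrequencies:
    def test_validation(self):
        with pytest.raises(ValueError):
            kin.AlleleFrequencies({"L": {1: 0.6, 2: 0.6}})

    def test_monomorphic_sample(self):
        gt = {"a": {"L": (1, 1)}, "b": {"L": (1, 1)}}
        f = kin.allele_frequencies_from_sample(gt)
        assert f["L"][1] == 1.0

    def test_equal_counts(self):
        gt = {"a": {"L": (1, 1)}, "b": {"L": (1, 2)}, "c": {"L": (2, 2)}}
        f = kin.allele_frequencies_from_sample(gt)
        assert f["L"] == {1: 0.5, 2: 0.5}

    def test_hwe_sample_recovery(self, biallelic):
        cfg = sd.SimulationConfig(seed=55, n_loci=1, alleles_per_locus=2)
        tab = kin.LikelihoodTables(
            kin.AlleleFrequencies({"L00": {1: 0.7, 2: 0.3}}), 0.0)
        rng = np.random.default_rng(55)
        gt = {f"i{n}": kin.simulate_genotype(tab, rng) for n in range(500)}
        f = kin.allele_frequencies_from_sample(gt)
        assert abs(f["L00"][1] - 0.7) < 0.05


class TestPairLikelihood:
    def test_unrelated_is_hwe_product(self, biallelic):
        AA = {"L1": (1, 1)}
        ll = kin.pair_likelihood(AA, AA, biallelic, "U")
        assert math.exp(ll) == pytest.approx(0.0625, abs=1e-12)

    def test_po_mendelian_exclusion(self, biallelic):
        ll = kin.pair_likelihood({"L1": (1, 1)}, {"L1": (2, 2)},
                                 biallelic, "PO")
        assert ll == -math.inf

    def test_fs_matches_gamete_enumeration(self):
        freqs = kin.AlleleFrequencies({"L": {1: 0.5, 2: 0.3, 3: 0.2}})
        tab = kin.LikelihoodTables(freqs, 0.0)
        lt = tab.loci["L"]
        A, p, G = len(lt.alleles), lt.p, lt.genotypes
        joint = np.zeros((len(G), len(G)))
        for m1 in range(A):
            for m2 in range(A):
                for f1 in range(A):
                    for f2 in range(A):
                        pr = p[m1] * p[m2] * p[f1] * p[f2] / 16
                        for a1 in (m1, m2):
                            for b1 in (f1, f2):
                                for a2 in (m1, m2):
                                    for b2 in (f1, f2):
                                        g1 = lt.gidx[tuple(sorted((a1, b1)))]
                                        g2 = lt.gidx[tuple(sorted((a2, b2)))]
                                        joint[g1, g2] += pr
        np.testing.assert_allclose(lt.folded["FS"], joint, atol=1e-12)

    def test_error_softens_exclusion(self, biallelic):
        ll = kin.pair_likelihood({"L1": (1, 1)}, {"L1": (2, 2)},
                                 biallelic, "PO", error_rate=0.01)
        assert np.isfinite(ll)
        assert ll < kin.pair_likelihood({"L1": (1, 1)}, {"L1": (1, 2)},
                                        biallelic, "PO", error_rate=0.01)

    def test_no_shared_loci_rejected(self, biallelic):
        with pytest.raises(ValueError):
            kin.pair_likelihood({"L1": None}, {"L1": (1, 1)}, biallelic, "U")


class TestMlRelationship:
    def test_po_r_is_half(self, biallelic):
        assert kin.RELATIONSHIP_CLASSES["PO"] == (0.0, 1.0, 0.0)
        res = kin.ml_relationship({"L1": (1, 2)}, {"L1": (1, 1)}, biallelic)
        assert res.r in (0.0, 0.25, 0.5)

    @staticmethod
    def _apply_error(g, tab, rng, e):
        out = {}
        for locus, pair in g.items():
            lt = tab.loci[locus]
            pair = list(pair)
            for i in range(2):
                if rng.random() < e:
                    pair[i] = lt.alleles[rng.choice(len(lt.alleles), p=lt.p)]
            out[locus] = tuple(pair)
        return out

    def _simulate_pairs(self, panel, relationship, n, rng, error=0.01):
        tab = kin.LikelihoodTables(panel, 0.0)
        pairs = []
        for _ in range(n):
            pa = kin.simulate_genotype(tab, rng)
            pb = kin.simulate_genotype(tab, rng)
            if relationship == "U":
                g1, g2 = pa, pb
            elif relationship == "PO":
                g1 = pa
                g2 = kin.mendelian_offspring(pa, pb, tab, rng)
            elif relationship == "FS":
                g1 = kin.mendelian_offspring(pa, pb, tab, rng)
                g2 = kin.mendelian_offspring(pa, pb, tab, rng)
            else:  # HS
                pc = kin.simulate_genotype(tab, rng)
                g1 = kin.mendelian_offspring(pa, pb, tab, rng)
                g2 = kin.mendelian_offspring(pa, pc, tab, rng)
            if error:
                g1 = self._apply_error(g1, tab, rng, error)
                g2 = self._apply_error(g2, tab, rng, error)
            pairs.append((g1, g2))
        return pairs

    @pytest.mark.parametrize("relationship", ["U", "HS", "FS", "PO"])
    def test_top_two_classification_accuracy(self, panel_17, relationship):
        rng = np.random.default_rng(500)
        pairs = self._simulate_pairs(panel_17, relationship, 60, rng)
        hits = 0
        for g1, g2 in pairs:
            res = kin.ml_relationship(g1, g2, panel_17, error_rate=0.01)
            ranked = sorted(res.logliks, key=res.logliks.get, reverse=True)
            hits += relationship in ranked[:2]
        assert hits / len(pairs) >= 0.90

    def test_unrelated_pairs_low_mean_r(self, panel_17):
        rng = np.random.default_rng(501)
        pairs = self._simulate_pairs(panel_17, "U", 80, rng)
        rs = [kin.ml_relationship(g1, g2, panel_17, 0.01).r
              for g1, g2 in pairs]
        assert np.mean(rs) <= 0.1


class TestParentageLod:
    def test_exclusion_guarded(self, biallelic):
        lod = kin.parentage_lod({"L1": (2, 2)}, {"L1": (1, 1)}, biallelic)
        assert lod == kin.LOG_FLOOR

    def test_single_locus_enumeration(self, biallelic):
        # offspring AB, candidate AA: parent transmits A (prob 1), other
        # allele B from population (0.5); joint = P(AA)*0.5 = 0.125,
        # unrelated joint = P(AB)P(AA) = 0.5*0.25; LOD = log(1) = 0
        lod = kin.parentage_lod({"L1": (1, 2)}, {"L1": (1, 1)}, biallelic)
        assert lod == pytest.approx(0.0, abs=1e-12)

    def test_true_parents_positive_lod_rate(self, panel_17):
        rng = np.random.default_rng(502)
        tab = kin.LikelihoodTables(panel_17, 0.0)
        positive = 0
        n = 150
        for _ in range(n):
            mo = kin.simulate_genotype(tab, rng)
            fa = kin.simulate_genotype(tab, rng)
            off = kin.mendelian_offspring(mo, fa, tab, rng, error_rate=0.01)
            lod = kin.parentage_lod(off, fa, panel_17, error_rate=0.01)
            positive += lod > 0
        assert positive / n >= 0.99

    def test_error_zero_never_excludes_true_parent(self, panel_17):
        rng = np.random.default_rng(503)
        tab = kin.LikelihoodTables(panel_17, 0.0)
        for _ in range(100):
            mo = kin.simulate_genotype(tab, rng)
            fa = kin.simulate_genotype(tab, rng)
            off = kin.mendelian_offspring(mo, fa, tab, rng, error_rate=0.0)
            assert kin.parentage_lod(off, fa, panel_17) > kin.LOG_FLOOR
            assert kin.parentage_lod(off, fa, panel_17,
                                     known_parent=mo) > kin.LOG_FLOOR

    def test_trio_lod_favors_true_father_over_unrelated(self, panel_17):
        rng = np.random.default_rng(504)
        tab = kin.LikelihoodTables(panel_17, 0.0)
        mo = kin.simulate_genotype(tab, rng)
        fa = kin.simulate_genotype(tab, rng)
        other = kin.simulate_genotype(tab, rng)
        off = kin.mendelian_offspring(mo, fa, tab, rng)
        lod_true = kin.parentage_lod(off, fa, panel_17, known_parent=mo)
        lod_other = kin.parentage_lod(off, other, panel_17, known_parent=mo)
        assert lod_true > lod_other

    def test_same_object_rejected(self, biallelic):
        g = {"L1": (1, 2)}
        with pytest.raises(ValueError):
            kin.parentage_lod(g, g, biallelic)


class TestAssignmentConfidence:
    def test_thresholds_monotone_and_rates(self, panel_17):
        res = kin.assignment_confidence(panel_17, n_sim=1500,
                                        prop_candidates_sampled=0.7,
                                        error_rate=0.01, seed=7,
                                        n_candidates=20)
        assert res[0.80] <= res[0.95]
        assert 0.0 < res["assignment_rate"] <= 1.0

    def test_perfect_information_limit(self, panel_17):
        res = kin.assignment_confidence(panel_17, n_sim=1000,
                                        prop_candidates_sampled=1.0,
                                        prop_loci_typed=1.0,
                                        error_rate=0.0, seed=8,
                                        n_candidates=10)
        assert res["assignment_rate"] >= 0.98
        assert np.isfinite(res[0.95])

    def test_fewer_loci_weaker_resolution(self):
        cfg17 = sd.SimulationConfig(seed=77, n_loci=17)
        cfg8 = sd.SimulationConfig(seed=77, n_loci=8)
        f17 = sd.random_allele_frequencies(cfg17)
        f8 = sd.random_allele_frequencies(cfg8)
        r17 = kin.assignment_confidence(f17, n_sim=1500, seed=9,
                                        n_candidates=20)
        r8 = kin.assignment_confidence(f8, n_sim=1500, seed=9,
                                       n_candidates=20)
        assert r8["assignment_rate"] <= r17["assignment_rate"]

    def test_too_few_simulations_rejected(self, biallelic):
        with pytest.raises(ValueError):
            kin.assignment_confidence(biallelic, n_sim=10)
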