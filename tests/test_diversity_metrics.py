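"""Alpha/beta diversity, composite diversity score, replicate precision."""

import numpy as np
import pytest

from ampliscore import (
    ClassificationProfile,
    DiversityScoreInput,
    RelAbundanceProfile,
    alpha_report,
    bray_curtis,
    chao1,
    diversity_score,
    percent_error,
    pielou,
    replicate_site_ratio,
    richness_precision,
    shannon,
)


class TestShannon:
    def test_tier_design_entropy(self, truth):
        assert shannon(truth.abundances) == pytest.approx(2.25, abs=0.005)

    def test_uniform_is_log_k(self):
        for k in (2, 5, 15, 40):
            assert shannon([1.0] * k) == pytest.approx(np.log(k))

    def test_single_taxon_zero(self):
        assert shannon([7.0]) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    def test_maximal_for_uniform_at_fixed_richness(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = rng.random(10) + 0.01
            assert shannon(v) <= np.log(10) + 1e-12


class TestPielou:
    def test_tier_design_evenness(self, truth):
        assert pielou(truth.abundances) == pytest.approx(0.83, abs=0.005)

    def test_uniform_is_one(self):
        assert pielou([2.0] * 8) == pytest.approx(1.0)

    def test_single_taxon_missing(self):
        assert pielou([5.0]) is None

    def test_random_vectors_in_unit_interval_and_match_definition(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            v = rng.random(12) + 1e-3
            j = pielou(v)
            assert 0.0 < j <= 1.0
            assert j == pytest.approx(shannon(v) / np.log(12))


class TestChao1:
    def test_no_singletons_equals_richness(self):
        assert chao1({"a": 5, "b": 3, "c": 10}) == 3.0

    def test_bias_corrected_formula(self):
        # F1=2, F2=1: 3 + 2*1/(2*2) = 3.5
        assert chao1({"a": 1, "b": 1, "c": 2}) == pytest.approx(3.5)

    def test_survives_no_doubletons(self):
        # F1=3, F2=0: 3 + 3*2/2 = 6
        assert chao1({"a": 1, "b": 1, "c": 1}) == pytest.approx(6.0)

    def test_matches_skbio_estimator(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        rng = np.random.default_rng(7)
        for _ in range(10):
            counts = rng.integers(0, 6, size=30)
            if counts.sum() == 0:
                continue
            assert chao1(list(counts)) == pytest.approx(
                float(skbio_alpha.chao1(counts, bias_corrected=True))
            )

    def test_filtered_profiles_lose_chao1_signal(self, truth, noisy_profile):
        """With all low-read taxa removed there are no singletons/doubletons left."""
        from ampliscore import FilterSpec, apply_filter

        filtered, _ = apply_filter(noisy_profile, FilterSpec("fraction", fraction_cutoff=0.004))
        rep = alpha_report(filtered)
        assert rep.chao1 == rep.richness


class TestBrayCurtis:
    def _rel(self, d):
        return RelAbundanceProfile(d)

    def test_identical_profiles_zero(self):
        p = self._rel({"a": 60.0, "b": 40.0})
        assert bray_curtis(p, p) == pytest.approx(0.0)

    def test_disjoint_profiles_one(self):
        assert bray_curtis(self._rel({"a": 100.0}), self._rel({"b": 100.0})) == pytest.approx(1.0)

    def test_symmetry_and_scipy_oracle(self):
        from scipy.spatial import distance

        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(12)]
        for _ in range(20):
            pa = {t: float(x) for t, x in zip(taxa, rng.random(12)) if x > 0.2}
            qa = {t: float(x) for t, x in zip(taxa, rng.random(12)) if x > 0.2}
            if not pa or not qa:
                continue
            a, b = self._rel(pa), self._rel(qa)
            d = bray_curtis(a, b)
            assert d == pytest.approx(bray_curtis(b, a))
            union = sorted(set(pa) | set(qa))
            u = np.array([pa.get(t, 0.0) for t in union])
            v = np.array([qa.get(t, 0.0) for t in union])
            assert d == pytest.approx(distance.braycurtis(u / u.sum(), v / v.sum()))

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(self._rel({}), self._rel({"a": 1.0}))


class TestDiversityScore:
    @pytest.mark.parametrize(
        "errors, expected",
        [
            ((-20.0, 4.9, 14.4, -3.6), 89.3),  # accurate optimized classifier
            ((0.0, 0.0, 0.0, 0.0), 100.0),
            ((100.0, 100.0, 100.0, 100.0), 0.0),
        ],
    )
    def test_reference_values(self, errors, expected):
        inp = DiversityScoreInput(*errors)
        assert diversity_score(inp) == pytest.approx(expected, abs=0.05)

    def test_sign_invariance(self):
        a = diversity_score(DiversityScoreInput(10.0, -5.0, 2.5, -7.5))
        b = diversity_score(DiversityScoreInput(-10.0, 5.0, -2.5, 7.5))
        assert a == b

    def test_percent_error_signed(self):
        assert percent_error(12.0, 15.0) == pytest.approx(-20.0)
        assert percent_error(17.25, 15.0) == pytest.approx(15.0)


class TestReplicatePrecision:
    def test_reference_ratio(self):
        assert replicate_site_ratio([320.0], [611.0]) == pytest.approx(52.4, abs=0.05)

    def test_identical_replicates_100(self):
        sites = {
            "a": [
                ClassificationProfile("a", "x", {"s1 a": 5, "s2 b": 5}, 10)
                for _ in range(3)
            ]
        }
        _, _, ratio = richness_precision(sites)
        assert ratio == pytest.approx(100.0)

    def test_matches_union_and_average_oracle(self):
        rng = np.random.default_rng(6)
        pool = [f"g{i} s{i}" for i in range(30)]
        sites = {}
        for s in range(3):
            reps = []
            for r in range(3):
                chosen = rng.choice(30, size=rng.integers(5, 20), replace=False)
                reps.append(
                    ClassificationProfile(
                        f"site{s}", "x", {pool[i]: 1 for i in chosen}, 100
                    )
                )
            sites[f"site{s}"] = reps
        rep_mean, site_mean, ratio = richness_precision(sites)
        exp_rep = np.mean([len(p.counts) for reps in sites.values() for p in reps])
        exp_site = np.mean(
            [len(set().union(*[set(p.counts) for p in reps])) for reps in sites.values()]
        )
        assert rep_mean == pytest.approx(exp_rep)
        assert site_mean == pytest.approx(exp_site)
        assert ratio == pytest.approx(100 * exp_rep / exp_site)

    def test_zero_site_mean_rejected(self):
        with pytest.raises(ValueError):
            replicate_site_ratio([1.0], [0.0])
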