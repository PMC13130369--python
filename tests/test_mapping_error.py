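"""SAE/RMSE family: decomposition, invariances, modelling grid and correlations."""

import random

import numpy as np
import pytest

from ampliscore import (
    ClassificationProfile,
    abundance_errors,
    double_reads,
    grid_correlations,
    mapping_error,
    modelling_grid,
    rmse_family,
    sae_family,
)
from ampliscore.mapping_error import GridCell, METRIC_VARIANTS, _default_truth, _grid_profile


def _random_profile(truth, rng, total=10_000):
    counts = {}
    for t in truth.taxa:
        if rng.random() < 0.7:
            counts[t.taxon_name] = rng.randint(1, 3000)
    for j in range(rng.randint(0, 8)):
        counts[f"fp_{j:04d}"] = rng.randint(1, 500)
    total = max(total, sum(counts.values()))
    return ClassificationProfile("s", "x", counts, total)


class TestAbundanceErrors:
    def test_perfect_profile_zero_errors(self, truth, perfect_profile):
        errors, U, O = abundance_errors(perfect_profile, truth)
        assert U == pytest.approx(0.0, abs=1e-9)
        assert O == pytest.approx(0.0, abs=1e-9)

    def test_total_swap(self):
        from ampliscore import design_community
        from ampliscore.community_design import TierSpec

        truth = design_community("s", ["aus aus"], (TierSpec("main", 1, 100.0, 1),))
        p = ClassificationProfile("s", "x", {"bus bus": 100}, 100)
        _, U, O = abundance_errors(p, truth)
        assert U == pytest.approx(100.0)
        assert O == pytest.approx(100.0)

    def test_matches_per_taxon_scan(self, truth):
        rng = random.Random(12)
        for _ in range(20):
            p = _random_profile(truth, rng)
            errors, U, O = abundance_errors(p, truth)
            true_pct = {t.taxon_name.lower(): t.abundance_pct for t in truth.taxa}
            obs_pct = {t.lower(): 100.0 * c / p.total_reads for t, c in p.counts.items()}
            u = sum(
                max(v - obs_pct.get(k, 0.0), 0.0) for k, v in true_pct.items()
            )
            o = sum(
                max(v - true_pct.get(k, 0.0), 0.0) for k, v in obs_pct.items()
            )
            assert U == pytest.approx(u) and O == pytest.approx(o)


class TestSAEFamily:
    def test_perfect_profile_zero_for_all_variants(self, truth, perfect_profile):
        for v in METRIC_VARIANTS:
            assert mapping_error(perfect_profile, truth, v).value == pytest.approx(0.0, abs=1e-9)

    def test_weight_one_equals_unweighted(self, truth, noisy_profile):
        w1 = sae_family(noisy_profile, truth, "wnSAE", w=1.0)
        n = sae_family(noisy_profile, truth, "nSAE")
        assert w1.value == pytest.approx(n.value)

    def test_decomposition_identity_on_random_profiles(self, truth):
        rng = random.Random(99)
        for _ in range(1000):
            p = _random_profile(truth, rng)
            for variant, w in (("SAE", 1.0), ("nSAE", 1.0), ("wnSAE", 2.0), ("wnSAE", 3.7)):
                rep = sae_family(p, truth, variant, w)
                assert rep.value == pytest.approx(
                    rep.weight_w * rep.fn_component + rep.fp_component, rel=1e-12
                )

    def test_count_scaling_invariance(self, truth):
        rng = random.Random(31)
        for _ in range(50):
            p = _random_profile(truth, rng)
            d = double_reads(p)
            assert sae_family(d, truth, "nSAE").value == pytest.approx(
                sae_family(p, truth, "nSAE").value
            )
            assert rmse_family(d, truth, "nRMSE").value == pytest.approx(
                rmse_family(p, truth, "nRMSE").value
            )
            # raw-count SAE doubles with the read set
            assert sae_family(d, truth, "SAE").value == pytest.approx(
                2 * sae_family(p, truth, "SAE").value
            )

    def test_adding_fp_never_decreases_sae(self, truth, noisy_profile):
        base = sae_family(noisy_profile, truth, "nSAE").value
        counts = dict(noisy_profile.counts)
        counts["novel fp"] = 500
        grown = ClassificationProfile(
            "s", "x", counts, max(noisy_profile.total_reads, sum(counts.values()))
        )
        assert sae_family(grown, truth, "nSAE").value >= base - 1e-9


class TestRMSEFamily:
    def test_single_taxon_half_abundance(self):
        from ampliscore import design_community
        from ampliscore.community_design import TierSpec

        truth = design_community("s", ["aus aus"], (TierSpec("main", 1, 100.0, 1),))
        p = ClassificationProfile("s", "x", {"aus aus": 50}, 100)
        rep = rmse_family(p, truth, "nRMSE")
        assert rep.value == pytest.approx(50.0)  # one term, |error| = 50

    def test_fp_additions_can_decrease_unweighted_nrmse(self, truth, species_names):
        # the documented pathology: tiny pure-FP taxa grow the denominator
        counts = {n: 100 for n in species_names[:5]}
        base = ClassificationProfile("s", "x", counts, 1000)
        inflated_counts = dict(counts)
        for j in range(10):
            inflated_counts[f"fp_{j:04d}"] = 1
        inflated = ClassificationProfile("s", "x", inflated_counts, 1000)
        assert (
            rmse_family(inflated, truth, "nRMSE").value
            < rmse_family(base, truth, "nRMSE").value
        )

    def test_weighted_rmse_quadrature_identity(self, truth, noisy_profile):
        rep = rmse_family(noisy_profile, truth, "wnRMSE", w=2.0)
        assert rep.value == pytest.approx(
            np.sqrt(2.0 * rep.fn_component**2 + rep.fp_component**2), rel=1e-9
        )


class TestModellingGrid:
    def test_full_cross_populated(self):
        grid = modelling_grid()
        assert len(grid) == 36
        assert {(c.n_true_detected, c.n_false_positive) for c in grid} == {
            (t, f) for t in (0, 3, 6, 9, 12, 15) for f in (0, 3, 6, 9, 12, 15)
        }

    def test_perfect_cell_all_zero(self):
        grid = modelling_grid()
        cell = next(c for c in grid if (c.n_true_detected, c.n_false_positive) == (15, 0))
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in cell.metrics.values())

    def test_total_miss_cells_have_full_fn_component(self, truth):
        for n_fp in (3, 9, 15):
            profile = _grid_profile(_default_truth(), 0, n_fp, 175_000)
            rep = sae_family(profile, _default_truth(), "nSAE")
            assert rep.fn_component == pytest.approx(100.0, abs=0.01)

    def test_grid_matches_independent_recomputation(self):
        """Cell-by-cell oracle on the simple true-value allocation rule."""
        truth = _default_truth()
        grid = modelling_grid(allocation="true_values", total_reads=100_000)
        tier_pct = {"main": 15.0, "mid": 4.5, "rare": 0.5}
        for cell in grid:
            per = cell.n_true_detected // 3
            missed = (
                [15.0] * (5 - per) + [4.5] * (5 - per) + [0.5] * (5 - per)
            )
            m = sum(missed)
            f = cell.n_false_positive
            fp_each = m / f if f and m else 0.0
            U = m
            O = fp_each * f
            assert cell.metrics["nSAE"] == pytest.approx(U + O, abs=0.02)
            sq_fn = sum(x * x for x in missed)
            sq_fp = f * fp_each**2
            n_union = 15 + (f if fp_each > 0 else 0)
            assert cell.metrics["nRMSE"] == pytest.approx(
                np.sqrt((sq_fn + sq_fp) / n_union), abs=0.02
            )


class TestGridCorrelations:
    def test_metric_equal_to_type_ii_count_has_unit_correlation(self):
        cells = [
            GridCell(t, f, {v: float(15 - t) for v in METRIC_VARIANTS})
            for t in (0, 3, 6, 9, 12, 15)
            for f in (0, 3, 6, 9, 12, 15)
        ]
        corr = grid_correlations(cells)
        assert corr["nSAE"]["type_ii"] == pytest.approx(1.0)

    def test_constant_metric_reported_missing(self):
        cells = [
            GridCell(t, f, {v: 5.0 for v in METRIC_VARIANTS})
            for t in (0, 3, 6, 9, 12, 15)
            for f in (0, 3, 6, 9, 12, 15)
        ]
        corr = grid_correlations(cells)
        assert corr["nSAE"]["type_i"] is None

    def test_default_grid_sign_structure(self):
        corr = grid_correlations(modelling_grid())
        assert corr["nRMSE"]["type_i"] < 0
        assert corr["wnRMSE"]["type_i"] > 0 and corr["wnRMSE"]["type_ii"] > 0
        assert corr["wnSAE"]["type_i"] > 0 and corr["wnSAE"]["type_ii"] > 0
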