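import numpy as np
import pytest

from idscn.atlas import dk_atlas
from idscn.synthetic import (
    CohortConfig,
    HoursModel,
    PlantedEffect,
    block_correlation,
    default_planted_edges,
    generate_cohort,
    generate_gaming_hours,
    plant_covariance_effect,
)


@pytest.fixture(scope="module")
def base_corr():
    atlas = dk_atlas()
    return block_correlation(atlas, 0.45, 0.10)


class TestPlantEffect:
    def test_zero_increment_is_identity(self, base_corr):
        out, dist, warn = plant_covariance_effect(base_corr, [(0, 40)], 0.0)
        assert np.array_equal(out, base_corr)
        assert dist == 0.0 and warn == []

    def test_out_of_range_increment_raises(self, base_corr):
        # within-block entry is 0.45; +0.6 would reach 1.05
        atlas = dk_atlas()
        lobes = atlas.lobes()
        i, j = [k for k in range(68) if lobes[k] == lobes[0]][:2]
        with pytest.raises(ValueError, match="outside"):
            plant_covariance_effect(base_corr, [(i, j)], 0.6)

    def test_planted_entries_and_symmetry(self, base_corr):
        edges = default_planted_edges()
        out, dist, _ = plant_covariance_effect(base_corr, edges, 0.35)
        assert np.allclose(out, out.T)
        assert np.allclose(np.diag(out), 1.0)
        for i, j in edges:
            assert out[i, j] == pytest.approx(0.45, abs=0.05 + 1e-9)
        w = np.linalg.eigvalsh(out)
        assert w.min() > 0

    def test_monte_carlo_sample_correlation_matches_plant(self, base_corr):
        """100k draws from the planted model reproduce the 0.45 target within 0.02."""
        edges = default_planted_edges()
        out, _, _ = plant_covariance_effect(base_corr, edges, 0.35)
        L = np.linalg.cholesky(out)
        rng = np.random.default_rng(11)
        X = rng.standard_normal((100_000, 68)) @ L.T
        C = np.corrcoef(X.T)
        for i, j in edges:
            assert C[i, j] == pytest.approx(out[i, j], abs=0.02)


class TestGenerateCohort:
    def test_default_group_sizes(self):
        cohort = generate_cohort(CohortConfig(seed=0))
        t = cohort.table
        sizes = {g: int((t.group == g).sum()) for g in t.group_labels()}
        assert sizes == {"FPS": 39, "MOBA": 40, "CONTROL": 37}

    def test_same_seed_is_byte_identical(self, tmp_path):
        from idscn.atlas import save_ct_table

        a = generate_cohort(CohortConfig(seed=5))
        b = generate_cohort(CohortConfig(seed=5))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        save_ct_table(a.table, pa)
        save_ct_table(b.table, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert a.truth == b.truth

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(seed=5))
        b = generate_cohort(CohortConfig(seed=6))
        assert not np.array_equal(a.table.thickness, b.table.thickness)

    def test_truth_edges_are_unique_pairs(self):
        cohort = generate_cohort(CohortConfig(seed=0))
        for i, j in cohort.planted_edges():
            assert 0 <= i < j < 68

    def test_sample_correlation_converges_to_population(self):
        """Frobenius distance to the configured correlation shrinks with n."""
        dists = []
        for n in (50, 500, 5000):
            cfg = CohortConfig(
                seed=9, group_sizes=(n, 3, 3), planted_effects=(), hours_models={}
            )
            t = generate_cohort(cfg).table
            X = t.thickness[t.group == "FPS"]
            C = np.corrcoef(X.T)
            target = block_correlation(dk_atlas(), cfg.rho_in, cfg.rho_out)
            dists.append(np.linalg.norm(C - target))
        assert dists[0] > dists[1] > dists[2]

    def test_null_cohort_groups_share_correlation_structure(self):
        """With no planted effects, group correlation matrices agree at large n.

        The bound is the ~4.3-sigma order statistic of 2278 correlated edge
        differences at n = 2000/group (per-edge SD sqrt(2/n) ~ 0.032), so the
        worst edge stays below 0.15 in essentially every replicate.
        """
        hits = 0
        for rep in range(10):
            cfg = CohortConfig(
                seed=100 + rep, group_sizes=(2000, 2000, 3),
                planted_effects=(), hours_models={},
            )
            t = generate_cohort(cfg).table
            Ca = np.corrcoef(t.thickness[t.group == "FPS"].T)
            Cb = np.corrcoef(t.thickness[t.group == "MOBA"].T)
            iu = np.triu_indices(68, 1)
            hits += np.max(np.abs(Ca[iu] - Cb[iu])) < 0.15
        assert hits >= 9

    def test_mean_and_sd_scale(self):
        cfg = CohortConfig(seed=2, group_sizes=(4000, 3, 3),
                           planted_effects=(), hours_models={})
        t = generate_cohort(cfg).table
        X = t.thickness[t.group == "FPS"]
        assert X.mean() == pytest.approx(2.5, abs=0.01)
        assert X.std(axis=0).mean() == pytest.approx(0.15, abs=0.01)

    def test_unknown_target_group_raises(self):
        with pytest.raises(ValueError, match="unknown group"):
            generate_cohort(CohortConfig(
                seed=0, planted_effects=(PlantedEffect("RTS", ((0, 40),), 0.2),)
            ))


class TestGamingHours:
    def test_noiseless_hours_track_latent(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=200)
        hours = generate_gaming_hours(latent, HoursModel(50, 5, 0.0), rng)
        assert np.corrcoef(hours, latent)[0, 1] == pytest.approx(1.0)

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            HoursModel(21, 12, -1.0)

    def test_hours_floored_at_zero(self):
        rng = np.random.default_rng(1)
        hours = generate_gaming_hours(np.zeros(500), HoursModel(0, 0, 30), rng)
        assert hours.min() == 0.0

    def test_fps_median_in_published_interquartile_band(self):
        """Default calibration keeps the FPS-group weekly-hours median in [11, 34]."""
        inside = 0
        for rep in range(40):
            t = generate_cohort(CohortConfig(seed=300 + rep)).table
            med = np.median(t.weekly_hours[t.group == "FPS"])
            inside += 11 <= med <= 34
        assert inside >= 38  # >= 95%

    def test_zero_slope_decouples_hours_from_latent(self):
        """With b = 0, hours carry no signal about the planted-edge latent score."""
        ok = 0
        for rep in range(20):
            cfg = CohortConfig(
                seed=500 + rep,
                hours_models={"FPS": HoursModel(21, 0.0, 12), "MOBA": None, "CONTROL": None},
            )
            cohort = generate_cohort(cfg)
            latent = np.asarray(cohort.truth["latent"]["FPS"])
            hours = cohort.table.weekly_hours[cohort.table.group == "FPS"]
            ok += abs(np.corrcoef(hours, latent)[0, 1]) < 0.32  # ~2 sigma at n=39
        assert ok >= 18  # >= 90%

    def test_controls_have_no_hours(self):
        t = generate_cohort(CohortConfig(seed=0)).table
        assert np.all(np.isnan(t.weekly_hours[t.group == "CONTROL"]))
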