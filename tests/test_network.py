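import numpy as np
import pytest
from scipy import stats as sps

from idscn.atlas import CorticalThicknessTable, dk_atlas
from idscn.network import (
    CovarianceNetwork,
    build_idscn_cohort,
    idscn_z,
    pearson_network,
    perturbed_scn,
    reference_scn,
)
from idscn.synthetic import CohortConfig, generate_cohort


def _table(X, atlas, group="CONTROL", prefix="c"):
    return CorticalThicknessTable(
        subject_ids=[f"{prefix}{i}" for i in range(len(X))],
        group=np.array([group] * len(X), dtype=object),
        thickness=X,
        weekly_hours=None,
        atlas=atlas,
    )


class TestPearson:
    def test_matches_scipy_pairwise(self):
        """Brute-force oracle: every entry equals scipy's two-column Pearson r."""
        rng = np.random.default_rng(0)
        X = rng.uniform(1, 4, size=(4, 3))
        r = pearson_network(X)
        for i in range(3):
            for j in range(3):
                expected = 1.0 if i == j else sps.pearsonr(X[:, i], X[:, j]).statistic
                assert r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicated_region_has_unit_correlation(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(2, 3, size=5)
        X = np.column_stack([col, col, rng.uniform(2, 3, size=5)])
        r = pearson_network(X)
        assert r[0, 1] == pytest.approx(1.0)

    def test_constant_region_raises_with_name(self):
        X = np.array([[1.0, 2.0], [1.0, 2.5], [1.0, 2.7]])
        with pytest.raises(ValueError, match="column 0"):
            pearson_network(X)


class TestPerturbedSCN:
    def test_equals_recompute_from_scratch(self, atlas):
        cohort = generate_cohort(CohortConfig(seed=0, group_sizes=(5, 3, 20)))
        t = cohort.table
        controls = t.by_group("CONTROL")
        subject = t.by_group("FPS").thickness[0]
        pert = perturbed_scn(controls, subject, "fps0")
        stacked = np.vstack([controls.thickness, subject])
        oracle = np.ones((68, 68))
        for i in range(68):
            for j in range(i + 1, 68):
                oracle[i, j] = oracle[j, i] = sps.pearsonr(stacked[:, i], stacked[:, j]).statistic
        assert np.max(np.abs(pert.r - oracle)) < 1e-12
        assert pert.n_subjects == controls.n_subjects + 1

    def test_member_rejected_without_loo(self, atlas):
        cohort = generate_cohort(CohortConfig(seed=1, group_sizes=(3, 3, 10)))
        controls = cohort.table.by_group("CONTROL")
        with pytest.raises(ValueError, match="leave-one-out"):
            perturbed_scn(controls, controls.thickness[0], controls.subject_ids[0])

    def test_delta_symmetric_zero_diagonal(self, atlas):
        cohort = generate_cohort(CohortConfig(seed=2, group_sizes=(3, 3, 12)))
        t = cohort.table
        controls = t.by_group("CONTROL")
        ref = reference_scn(controls)
        pert = perturbed_scn(controls, t.by_group("FPS").thickness[0])
        delta = pert.r - ref.r
        assert np.allclose(delta, delta.T)
        assert np.allclose(np.diag(delta), 0.0)


class TestIdscnZ:
    def test_hand_value(self):
        """delta=0.1 on a zero-correlation edge with n=37 gives z = 0.1*36 = 3.6."""
        rn = np.eye(3)
        rp = rn.copy()
        rp[0, 1] = rp[1, 0] = 0.1
        ref = CovarianceNetwork(rn, 37)
        pert = CovarianceNetwork(rp, 38)
        m = idscn_z(ref, pert)
        assert m.z[0, 1] == pytest.approx(3.6)

    def test_zero_delta_gives_zero_z(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(5, 4))
        r = np.corrcoef(A.T)
        m = idscn_z(CovarianceNetwork(r, 10), CovarianceNetwork(r.copy(), 11))
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(m.z[off], 0.0)

    def test_perfect_reference_correlation_masked(self):
        rn = np.eye(3)
        rn[0, 1] = rn[1, 0] = 1.0
        rp = np.eye(3)
        rp[0, 1] = rp[1, 0] = 0.9
        m = idscn_z(CovarianceNetwork(rn, 10), CovarianceNetwork(rp, 11))
        assert m.masked[0, 1]
        assert np.isnan(m.z[0, 1])
        assert not m.masked[0, 2]

    def test_small_reference_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            CovarianceNetwork(np.eye(3), 2)


@pytest.fixture(scope="module")
def small(atlas):
    cohort = generate_cohort(CohortConfig(seed=4, group_sizes=(4, 3, 15)))
    t = cohort.table
    return t.by_group("CONTROL"), t.by_group("FPS")


class TestBuildCohort:
    def test_stack_height_and_composition(self, small):
        controls, fps = small
        stack = build_idscn_cohort(controls, fps, mode="add_in")
        assert stack.n_subjects == 4
        one = idscn_z(reference_scn(controls), perturbed_scn(controls, fps.thickness[0]))
        assert np.allclose(stack.z[0], one.z, equal_nan=True)

    def test_overlap_rejected_in_add_in(self, small):
        controls, _ = small
        with pytest.raises(ValueError, match="overlap"):
            build_idscn_cohort(controls, controls, mode="add_in")

    def test_leave_one_out_matches_definitional_oracle(self, small):
        """LOO for control k == add-in of k over the other n-1 controls."""
        controls, _ = small
        stack = build_idscn_cohort(controls, controls, mode="leave_one_out")
        k = 2
        rest = controls.subset(np.arange(controls.n_subjects) != k)
        oracle = idscn_z(
            reference_scn(rest), perturbed_scn(rest, controls.thickness[k])
        )
        assert np.allclose(stack.z[k], oracle.z, equal_nan=True)
        assert stack.reference_n[k] == controls.n_subjects - 1


class TestStatisticalBehaviour:
    def test_null_subjects_have_zero_mean_z(self, atlas, edges):
        """Subjects drawn from the reference population leave edges unperturbed
        on average: per-edge mean z (averaged over reference draws as well as
        subjects — conditioning on a single finite reference leaves an O(1/sqrt(n))
        offset toward the population correlation) stays within sampling noise
        of zero."""
        reps, per_rep = 25, 20
        rep_means = []
        for r in range(reps):
            cfg = CohortConfig(seed=800 + r, group_sizes=(per_rep, 3, 37),
                               planted_effects=(), hours_models={})
            t = generate_cohort(cfg).table
            stack = build_idscn_cohort(t.by_group("CONTROL"), t.by_group("FPS"),
                                       mode="add_in")
            rep_means.append(edges.extract(stack.z).mean(axis=0))
        rep_means = np.array(rep_means)
        mean = rep_means.mean(axis=0)
        se = rep_means.std(axis=0, ddof=1) / np.sqrt(reps)
        frac_beyond = np.mean(np.abs(mean) > 3 * se)
        assert frac_beyond < 0.015  # 3-sigma exceedances at roughly chance rate

    def test_engineered_outlier_hits_its_edge(self, atlas):
        """A subject built to break one region pair's covariance puts its largest
        |z| on that pair in >= 95% of trials."""
        cfg = CohortConfig(seed=12, group_sizes=(3, 3, 37),
                           planted_effects=(), hours_models={})
        controls = generate_cohort(cfg).table.by_group("CONTROL")
        ref = reference_scn(controls)
        # strongest reference edge: its small 1-r^2 denominator makes it the
        # sharpest covariance pattern to violate
        off = np.abs(ref.r - np.eye(68))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        mu = controls.thickness.mean(axis=0)
        sd = controls.thickness.std(axis=0, ddof=1)
        rng = np.random.default_rng(13)
        hits = 0
        trials = 200
        for _ in range(trials):
            x = mu + sd * rng.standard_normal(68)
            x[i] = mu[i] + 4 * sd[i]
            x[j] = mu[j] - np.sign(ref.r[i, j]) * 4 * sd[j]  # oppose the pattern
            m = idscn_z(ref, perturbed_scn(controls, x))
            za = np.abs(np.nan_to_num(m.z))
            best = np.unravel_index(np.argmax(za), za.shape)
            hits += set(best) == {i, j}
        assert hits / trials >= 0.95
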