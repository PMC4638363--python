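"""The four-criterion applicability-domain analysis and reliability categories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cyplie.datasets import load_fixture
from cyplie.lie import SimulationEnergies, calibrate
from cyplie.reliability import (
    FingerprintProfile,
    ReliabilityReport,
    category_sdep,
    energy_distribution_flag,
    fit_energy_distribution,
    fit_pca_outlier_model,
    mahalanobis_squared,
    pca_distances,
    pca_flags,
    reliability_category,
    run_reliability_analysis,
    similarity_cutoff,
    similarity_flag,
    tanimoto,
    weighted_residue_profile,
)


def fp(compound_id, bits, n_bits=32):
    return FingerprintProfile(compound_id, frozenset(bits), n_bits)


class TestTanimoto:
    def test_identical(self):
        assert tanimoto(fp("a", {1, 2, 3}), fp("b", {1, 2, 3})) == 1.0

    def test_disjoint(self):
        assert tanimoto(fp("a", {1, 2}), fp("b", {3, 4})) == 0.0

    def test_partial_overlap(self):
        assert tanimoto(fp("a", {1, 2, 3}), fp("b", {2, 3, 4})) == 0.5

    def test_both_empty(self):
        assert tanimoto(fp("a", set()), fp("b", set())) == 1.0

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = fp("a", set(rng.integers(0, 32, size=8)))
            b = fp("b", set(rng.integers(0, 32, size=8)))
            assert tanimoto(a, b) == tanimoto(b, a)
            assert (tanimoto(a, b) == 1.0) == (a.bits == b.bits)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(fp("a", {1}, 32), fp("b", {1}, 64))

    def test_maccs_from_smiles(self):
        a = FingerprintProfile.from_smiles("benzene", "c1ccccc1")
        b = FingerprintProfile.from_smiles("toluene", "Cc1ccccc1")
        assert 0.0 < tanimoto(a, b) < 1.0
        assert tanimoto(a, a) == 1.0


class TestSimilarityCutoff:
    def test_best_match_minimum(self):
        # best matches: a<->b at 0.8; c's best is 0.5 (to a) -> cutoff 0.5
        a = fp("a", {1, 2, 3, 4, 5, 6, 7, 8})
        b = fp("b", {1, 2, 3, 4, 5, 6, 7, 8, 9, 10})
        c = fp("c", {1, 2, 3, 4})
        assert tanimoto(a, b) == pytest.approx(0.8)
        assert tanimoto(a, c) == pytest.approx(0.5)
        assert similarity_cutoff([a, b, c]) == pytest.approx(0.5)

    def test_identical_pair(self):
        a, b = fp("a", {1, 2}), fp("b", {1, 2})
        assert similarity_cutoff([a, b]) == 1.0

    def test_needs_two(self):
        with pytest.raises(ValueError):
            similarity_cutoff([fp("a", {1})])


class TestSimilarityFlag:
    training = [fp("t1", {1, 2, 3, 4}), fp("t2", {5, 6, 7, 8})]

    def test_member_not_flagged(self):
        assert similarity_flag(fp("q", {1, 2, 3, 4}), self.training, 0.5) == 0

    def test_dissimilar_flagged(self):
        assert similarity_flag(fp("q", {20, 21}), self.training, 0.5) == 1

    def test_boundary_is_strict(self):
        query = fp("q", {1, 2})  # TS to t1 exactly 0.5
        assert tanimoto(query, self.training[0]) == pytest.approx(0.5)
        assert similarity_flag(query, self.training, 0.5) == 0


def _sims(pairs, ligand="L"):
    return [
        SimulationEnergies(ligand, f"p{i}", v, e, 0.0, 0.0)
        for i, (e, v) in enumerate(pairs)
    ]


class TestEnergyDistribution:
    def test_chi2_threshold_one_dof(self):
        rng = np.random.default_rng(0)
        sims = _sims(rng.normal(size=(50, 2)))
        model = fit_energy_distribution(sims)
        assert model.threshold == pytest.approx(stats.chi2.ppf(0.95, 1), abs=1e-9)
        assert model.threshold == pytest.approx(3.841, abs=0.001)

    def test_two_dof_option(self):
        rng = np.random.default_rng(0)
        model = fit_energy_distribution(_sims(rng.normal(size=(50, 2))), dof=2)
        assert model.threshold == pytest.approx(5.991, abs=0.001)

    def test_degenerate_cloud_rejected(self):
        sims = _sims([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0)])  # collinear
        with pytest.raises(np.linalg.LinAlgError):
            fit_energy_distribution(sims)

    def test_isotropic_cloud_covariance(self):
        rng = np.random.default_rng(42)
        model = fit_energy_distribution(_sims(rng.normal(size=(1000, 2))))
        assert model.covariance == pytest.approx(np.eye(2), abs=0.15)

    def test_center_has_zero_distance(self):
        rng = np.random.default_rng(3)
        model = fit_energy_distribution(_sims(rng.normal(size=(30, 2))))
        assert mahalanobis_squared(model.center, model) == 0.0
        query = _sims([tuple(model.center)], "Q")
        assert energy_distribution_flag(query, model) == 0

    def test_known_squared_distance(self):
        # identity covariance: point at (2.5, 0) has squared distance 6.25
        rng = np.random.default_rng(12)
        base = rng.normal(size=(2000, 2))
        base = (base - base.mean(0)) / base.std(0, ddof=1)
        model = fit_energy_distribution(_sims(base))
        d2 = mahalanobis_squared(model.center + np.array([2.5, 0.0]), model)
        assert d2 == pytest.approx(6.25, abs=0.3)
        assert d2 > model.threshold

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        points = rng.normal(size=(40, 2)) @ np.array([[2.0, 0.3], [0.1, 0.5]])
        transform = np.array([[3.0, -1.0], [0.5, 2.0]])
        queries = rng.normal(size=(10, 2)) * 3
        model = fit_energy_distribution(_sims(points))
        model_t = fit_energy_distribution(_sims(points @ transform.T))
        for q in queries:
            d_raw = mahalanobis_squared(q, model)
            d_t = mahalanobis_squared(transform @ q, model_t)
            assert d_t == pytest.approx(d_raw, rel=1e-8)


class TestWeightedResidueProfile:
    def _sim_with_decomp(self, pose, decomp):
        return SimulationEnergies("L", pose, -30.0, -10.0, 0.0, 0.0, decomp)

    def test_single_simulation_identity(self):
        decomp = {"WAT": (-10.0, -5.0), "THR118": (-2.0, -1.0)}
        profile = weighted_residue_profile([self._sim_with_decomp("p0", decomp)], [1.0], "ele")
        assert profile["WAT"] == -10.0 and profile["THR118"] == -2.0

    def test_equal_weights_mean(self):
        sims = [
            self._sim_with_decomp("p0", {"WAT": (-10.0, -4.0)}),
            self._sim_with_decomp("p1", {"WAT": (-6.0, -2.0)}),
        ]
        assert weighted_residue_profile(sims, [0.5, 0.5], "ele")["WAT"] == -8.0
        assert weighted_residue_profile(sims, [0.5, 0.5], "vdw")["WAT"] == -3.0

    def test_weighted_combination(self):
        sims = [
            self._sim_with_decomp("p0", {"WAT": (-10.0, 0.0)}),
            self._sim_with_decomp("p1", {"WAT": (-2.0, 0.0)}),
        ]
        assert weighted_residue_profile(sims, [0.75, 0.25], "ele")["WAT"] == -8.0

    def test_mismatched_residues_rejected(self):
        sims = [
            self._sim_with_decomp("p0", {"WAT": (0.0, 0.0)}),
            self._sim_with_decomp("p1", {"ASP313": (0.0, 0.0)}),
        ]
        with pytest.raises(ValueError):
            weighted_residue_profile(sims, [0.5, 0.5], "ele")


class TestPcaOutlierModel:
    def _planar_data(self, n=30, p=5, seed=0):
        rng = np.random.default_rng(seed)
        basis = np.linalg.qr(rng.normal(size=(p, 2)))[0]
        scores = rng.normal(size=(n, 2)) * np.array([4.0, 2.0])
        return scores @ basis.T, basis

    def test_sd_crit_two_components(self):
        X, _ = self._planar_data()
        model = fit_pca_outlier_model(X)
        assert model.n_components == 2
        assert model.sd_crit == pytest.approx(np.sqrt(5.991), abs=0.001)

    def test_planar_training_has_zero_od_crit(self):
        X, _ = self._planar_data()
        model = fit_pca_outlier_model(X)
        assert model.od_crit == pytest.approx(0.0, abs=1e-9)

    def test_component_retention_by_variance_share(self):
        rng = np.random.default_rng(5)
        n = 400
        # two dominant directions (~60%/30%) plus tiny noise directions
        X = np.zeros((n, 6))
        X[:, 0] = rng.normal(scale=np.sqrt(60.0), size=n)
        X[:, 1] = rng.normal(scale=np.sqrt(30.0), size=n)
        X[:, 2:] = rng.normal(scale=np.sqrt(10.0 / 4 / 5), size=(n, 4))
        model = fit_pca_outlier_model(X)
        assert model.n_components == 2

    def test_loadings_orthonormal_variances_sorted(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 8)) * np.array([5, 4, 3, 2, 1, 0.5, 0.3, 0.1])
        model = fit_pca_outlier_model(X)
        eye = model.loadings.T @ model.loadings
        assert eye == pytest.approx(np.eye(model.n_components), abs=1e-8)
        assert np.all(np.diff(model.variances) <= 1e-12)
        assert np.all(model.variances > 0)

    def test_query_at_mean_not_flagged(self):
        X, _ = self._planar_data()
        model = fit_pca_outlier_model(X)
        sd, od = pca_distances(X.mean(axis=0), model)
        assert sd == pytest.approx(0.0, abs=1e-9)
        assert od == pytest.approx(0.0, abs=1e-9)
        assert pca_flags(X.mean(axis=0), model) == (0, 0)

    def test_score_outlier_inside_plane(self):
        rng = np.random.default_rng(0)
        X, _ = self._planar_data()
        X = X + rng.normal(scale=0.05, size=X.shape)  # small off-plane noise
        model = fit_pca_outlier_model(X)
        # 10 standard deviations along the first component, inside the plane
        query = model.center + model.loadings[:, 0] * 10.0 * np.sqrt(model.variances[0])
        assert pca_flags(query, model) == (1, 0)

    def test_orthogonal_outlier_off_plane(self):
        rng = np.random.default_rng(8)
        X, basis = self._planar_data(seed=8)
        X = X + rng.normal(scale=0.05, size=X.shape)  # small off-plane noise
        model = fit_pca_outlier_model(X)
        normal = np.linalg.svd(basis.T)[2][-1]  # direction orthogonal to the plane
        query = X.mean(axis=0) + normal * 50.0
        score_out, orth_out = pca_flags(query, model)
        assert orth_out == 1 and score_out == 0

    def test_at_least_half_training_below_od_crit(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 6)) * np.array([5, 3, 0.4, 0.3, 0.2, 0.1])
        model = fit_pca_outlier_model(X)
        Xc = X - model.center
        od = np.linalg.norm(Xc - (Xc @ model.loadings) @ model.loadings.T, axis=1)
        assert np.mean(od <= model.od_crit) >= 0.5

    def test_alternative_median_reading(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5)) * np.array([4, 2, 1, 0.5, 0.2])
        default = fit_pca_outlier_model(X)
        alt = fit_pca_outlier_model(X, transformed_median=False)
        assert default.od_crit != alt.od_crit  # distinct readings of the cutoff

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_pca_outlier_model(np.ones((5, 3)))


class TestCategories:
    def test_category_is_flag_sum(self):
        assert reliability_category((0, 0, 0, 0)) == 0
        assert reliability_category((0, 1, 1, 1)) == 3
        assert reliability_category((0, 0, 1, 0)) == 1
        with pytest.raises(ValueError):
            reliability_category((0, 2, 0, 0))

    def test_reference_table_totals_reproduced(self):
        t4 = load_fixture("table4")
        for row in t4.itertuples(index=False):
            flags = (row.flag_a, row.flag_b, row.flag_c, row.flag_d)
            assert reliability_category(flags) == row.total

    def test_report_category_consistency(self):
        report = ReliabilityReport("q", 1, 0, 1, 0, dg_calc=-20.0, dg_obs=-25.0)
        assert report.category == 2
        assert report.residual == pytest.approx(-5.0)
        with pytest.raises(ValueError):
            ReliabilityReport("q", 1, 0, 0, 0, category=3)

    def test_category_sdep_reference_values(self):
        t4 = load_fixture("table4")
        per_category = category_sdep(list(zip(t4["total"], t4["residual"])))
        assert per_category[0][0] == 14 and round(per_category[0][1], 1) == 4.6
        assert per_category[1][0] == 4 and round(per_category[1][1], 1) == 7.5
        assert per_category[3][0] == 3 and round(per_category[3][1], 1) == 7.6

    def test_single_member_category(self):
        assert category_sdep([(2, -6.4)]) == {2: (1, pytest.approx(6.4))}

    def test_pooled_categories_reproduce_overall_sdep(self):
        t4 = load_fixture("table4")
        per_category = category_sdep(list(zip(t4["total"], t4["residual"])))
        pooled = sum(n * s**2 for n, s in per_category.values())
        total_n = sum(n for n, _ in per_category.values())
        overall = float(np.sqrt(np.mean(t4["residual"] ** 2)))
        assert np.sqrt(pooled / total_n) == pytest.approx(overall, abs=1e-9)


class TestPipeline:
    def test_end_to_end_reports(self, noisy_profiles):
        profiles, _ = noisy_profiles
        train, query = profiles[:25], profiles[25:]
        calibration = calibrate(train, max_poses=4)
        smiles = {p.ligand_id: "c1ccccc1" for p in profiles}  # identical structures
        reports = run_reliability_analysis(
            train, query, calibration, smiles, smiles
        )
        assert len(reports) == len(query)
        for report in reports:
            assert report.flag_similarity == 0  # identical fingerprints
            assert report.category == sum(report.flags)
            assert report.residual is not None
        frame = pd.DataFrame([r.flags for r in reports])
        assert frame.isin([0, 1]).all().all()
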