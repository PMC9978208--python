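"""Superposition, segment RMSDs, correlation and kinase classification."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import rankdata

import statebias as sb
from statebias.metrics import MetricError, rmsd_no_fit

from conftest import as_coords, random_cloud


def brute_force_min_rmsd(p, q, n_grid=14):
    """Independent oracle: grid over SO(3) + simplex refinement of Euler angles.

    Never touches the SVD path: evaluates centred RMSD directly for explicit
    rotations.
    """
    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)

    def cost(angles):
        r = Rotation.from_euler("zyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((p0 @ r.T - q0) ** 2, axis=1)))

    best, best_angles = np.inf, None
    grid = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    grid_beta = np.linspace(0, np.pi, n_grid // 2 + 1)
    for a in grid:
        for b in grid_beta:
            for c in grid:
                value = cost([a, b, c])
                if value < best:
                    best, best_angles = value, [a, b, c]
    refined = minimize(cost, best_angles, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    return min(best, float(refined.fun))


class TestKabsch:
    def test_identical_structures(self):
        rng = np.random.default_rng(0)
        a = as_coords(random_cloud(rng))
        rot, trans, rmsd = sb.kabsch_superpose(a, a)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    def test_pure_translation_recovered(self):
        rng = np.random.default_rng(1)
        xyz = random_cloud(rng)
        a = as_coords(xyz)
        b = as_coords(xyz + [5.0, 0.0, 0.0])
        rot, trans, rmsd = sb.kabsch_superpose(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-7)
        assert np.allclose(trans, [5.0, 0.0, 0.0], atol=1e-7)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_rotation_grid_oracle_with_noise(self, seed):
        rng = np.random.default_rng(seed)
        p = random_cloud(rng, n=10)
        true_rot = Rotation.random(rng=rng).as_matrix()
        q = p @ true_rot.T + rng.normal(0, 0.4, p.shape) + [3.0, -2.0, 1.0]
        _, _, rmsd = sb.kabsch_superpose(as_coords(p), as_coords(q))
        oracle = brute_force_min_rmsd(p, q)
        assert rmsd == pytest.approx(oracle, abs=1e-3)
        # second independent route: scipy's Wahba solver on centred clouds
        _, rssd = Rotation.align_vectors(q - q.mean(axis=0), p - p.mean(axis=0))
        assert rmsd == pytest.approx(rssd / np.sqrt(len(p)), abs=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(5)
        p = random_cloud(rng, n=6)
        q = -p  # mirror image tempts an improper fit
        rot, _, _ = sb.kabsch_superpose(as_coords(p), as_coords(q))
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        line = as_coords(np.outer(np.arange(5), [1.0, 0.0, 0.0]))
        with pytest.raises(MetricError):
            sb.kabsch_superpose(line, line)
        a = as_coords(np.random.default_rng(6).normal(size=(2, 3)))
        with pytest.raises(MetricError):
            sb.kabsch_superpose(a, a)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_rmsd_symmetry_and_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a_xyz = random_cloud(rng)
        b_xyz = a_xyz + rng.normal(0, 1.0, a_xyz.shape)
        a, b = as_coords(a_xyz), as_coords(b_xyz)
        _, _, ab = sb.kabsch_superpose(a, b)
        _, _, ba = sb.kabsch_superpose(b, a)
        assert ab == pytest.approx(ba, abs=1e-9)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(0, 10.0, 3)
        a2 = as_coords(a_xyz @ rot.T + shift)
        b2 = as_coords(b_xyz @ rot.T + shift)
        _, _, moved = sb.kabsch_superpose(a2, b2)
        assert moved == pytest.approx(ab, abs=1e-9)

    def test_scoring_frame_is_optimal_for_its_own_selection(self):
        """No rotation beats the closed-form optimum on the scored selection."""
        rng = np.random.default_rng(9)
        p = random_cloud(rng, n=8)
        q = p + rng.normal(0, 0.8, p.shape)
        _, _, rmsd = sb.kabsch_superpose(as_coords(p), as_coords(q))
        assert rmsd <= brute_force_min_rmsd(p, q, n_grid=10) + 1e-6


class TestSegmentRmsd:
    def test_model_equal_to_reference_scores_zero(self, conformer_pair):
        active, _, segments = conformer_pair
        report = sb.segment_rmsd(active, active, segments)
        assert report.tm_rmsd == pytest.approx(0.0, abs=1e-9)
        assert report.loop_rmsd == pytest.approx(0.0, abs=1e-9)
        assert report.global_rmsd == pytest.approx(0.0, abs=1e-9)
        assert report.n_tm + report.n_loop == report.n_global

    def test_rigidly_displaced_loop_scores_exactly_in_tm_frame(self, conformer_pair):
        active, _, segments = conformer_pair
        tm_res = segments.residues(segments.tm_names())
        loop_res = sorted(set(active.residue_ids.tolist()) - tm_res)
        shifted = active.ca.copy()
        mask = np.isin(active.residue_ids, loop_res)
        shifted[mask] += [0.0, 0.0, 3.0]
        model = sb.StructureCoords(active.residue_ids, shifted)
        report = sb.segment_rmsd(model, active, segments)
        assert report.tm_rmsd == pytest.approx(0.0, abs=1e-9)
        assert report.loop_rmsd == pytest.approx(3.0, abs=1e-9)

    def test_two_segment_toy_matches_closed_form(self):
        """Superposing on one anchored segment leaves the other's shift intact."""
        rng = np.random.default_rng(10)
        seg_a = random_cloud(rng, n=10, spread=4.0)
        seg_b = random_cloud(rng, n=10, spread=4.0) + [20.0, 0.0, 0.0]
        ref = as_coords(np.vstack([seg_a, seg_b]))
        moved = np.vstack([seg_a, seg_b + [0.0, 4.0, 0.0]])
        model = as_coords(moved)
        segments = sb.SegmentMap({"TM1": (1, 10), "LOOPX": (11, 20)})
        report = sb.segment_rmsd(model, ref, segments)
        assert report.tm_rmsd == pytest.approx(0.0, abs=1e-9)
        assert report.loop_rmsd == pytest.approx(4.0, abs=1e-9)

    def test_toy_activation_swing_matches_no_fit_value_on_segment(self, conformer_pair):
        active, inactive, segments = conformer_pair
        assert rmsd_no_fit(
            active, inactive, segments.residues(["TM6"])
        ) == pytest.approx(4.0, abs=1e-6)

    def test_missing_segment_overlap_is_an_error(self, conformer_pair):
        active, _, _ = conformer_pair
        far = sb.SegmentMap({"TM1": (500, 530)})
        with pytest.raises(MetricError):
            sb.segment_rmsd(active, active, far)


class TestEnsembleSummary:
    def test_identical_models_give_identical_rows(self, conformer_pair):
        active, _, segments = conformer_pair
        table, best = sb.ensemble_summary([active] * 3, active, segments)
        assert len(table) == 3
        assert table["tm_rmsd"].nunique() == 1
        assert best == 0  # tie broken by model index

    def test_single_model_is_best(self, conformer_pair):
        active, _, segments = conformer_pair
        _, best = sb.ensemble_summary([active], active, segments)
        assert best == 0

    def test_best_model_minimizes_tm_rmsd(self, conformer_pair):
        active, inactive, segments = conformer_pair
        table, best = sb.ensemble_summary([inactive, active], active, segments)
        assert best == 1
        assert table.loc[1, "tm_rmsd"] < table.loc[0, "tm_rmsd"]


class TestSpearman:
    def test_strictly_decreasing_gives_minus_one(self):
        rho, n = sb.ptm_rmsd_correlation([0.9, 0.8, 0.7, 0.5], [1.0, 2.0, 3.0, 9.0])
        assert rho == pytest.approx(-1.0)
        assert n == 4

    def test_zero_variance_is_na_not_zero(self):
        with pytest.warns(UserWarning):
            rho, n = sb.ptm_rmsd_correlation([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])
        assert np.isnan(rho)
        assert n == 3

    def test_too_few_points_rejected(self):
        with pytest.raises(MetricError):
            sb.ptm_rmsd_correlation([0.5, 0.6], [1.0, 2.0])

    def test_ties_match_hand_ranked_oracle(self):
        """5-point toy with one tie: compare to explicit average-rank formula."""
        ptm = [0.5, 0.6, 0.6, 0.8, 0.9]
        rmsd = [5.0, 4.0, 3.0, 2.0, 1.0]
        rx, ry = rankdata(ptm), rankdata(rmsd)
        expected = float(np.corrcoef(rx, ry)[0, 1])
        rho, _ = sb.ptm_rmsd_correlation(ptm, rmsd)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(11)
        ptm = rng.uniform(0.2, 0.9, 20)
        rmsd = rng.uniform(0.5, 6.0, 20)
        rho, _ = sb.ptm_rmsd_correlation(ptm, rmsd)
        rho2, _ = sb.ptm_rmsd_correlation(np.exp(ptm), rmsd**3)
        assert rho2 == pytest.approx(rho, abs=1e-12)
        assert -1.0 <= rho <= 1.0


class TestKinaseClassification:
    def test_exemplar_self_match(self, kinase_library, kinase_reference_library):
        library, segments = kinase_library
        call = sb.classify_kinase_conformation(
            library[("in", "out")], segments, kinase_reference_library
        )
        assert (call.a_loop, call.ac_helix) == ("in", "out")
        assert call.a_loop_margin > 0
        assert call.ac_helix_margin > 0

    def test_equidistant_midpoint_flags_tie(self, kinase_library, caplog):
        library, segments = kinase_library
        a = library[("in", "in")]
        b = library[("out", "in")]
        midpoint = sb.StructureCoords(a.residue_ids, (a.ca + b.ca) / 2.0)
        refs = [(a, {"a_loop": "in", "ac_helix": "in"}),
                (b, {"a_loop": "out", "ac_helix": "in"})]
        with caplog.at_level("WARNING", logger="statebias.metrics"):
            call = sb.classify_kinase_conformation(midpoint, segments, refs)
        assert call.a_loop == "in"  # tie goes to the lower-index exemplar
        assert call.a_loop_margin == 0.0
        assert any("tie" in m for m in caplog.messages)

    def test_missing_motif_residues_rejected(
        self, kinase_library, kinase_reference_library
    ):
        library, segments = kinase_library
        model = library[("in", "in")]
        truncated = sb.StructureCoords(
            model.residue_ids[:60], model.ca[:60], source="truncated"
        )
        with pytest.raises(MetricError):
            sb.classify_kinase_conformation(
                truncated, segments, kinase_reference_library
            )

    def test_margin_is_distance_gap_between_labels(
        self, kinase_library, kinase_reference_library
    ):
        library, segments = kinase_library
        model = library[("out", "in")]
        call = sb.classify_kinase_conformation(
            model, segments, kinase_reference_library
        )
        assert call.a_loop == "out"
        # the opposing label sits a full 6 A flip away on the motif
        assert call.a_loop_margin > 3.0
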