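"""Ensemble orchestration, the mock predictor, and unfolded-model filtering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import statebias as sb
from statebias.driver import (
    DriverError,
    expected_rg,
    radius_of_gyration,
    run_ensemble,
)

from conftest import as_coords


def gpcr_config(**over):
    args = {"num_models": 8, "seed": 5, "noise_sigma": 0.3}
    args.update(over)
    return sb.resolve_config(args, mode="gpcr")


class TestRunEnsemble:
    def test_dispatches_exactly_n_models(self, gpcr_records, toy_msa):
        cfg = gpcr_config(num_models=50)
        models, manifest = run_ensemble(
            gpcr_records[0].sequence, toy_msa, gpcr_records, cfg
        )
        assert len(models) == 50
        assert len(manifest) == 50
        assert [m.model_index for m in models] == list(range(50))

    def test_fixed_seed_reruns_bitwise_identical(self, gpcr_records, toy_msa):
        cfg = gpcr_config(num_models=1)
        first, _ = run_ensemble(gpcr_records[0].sequence, toy_msa, gpcr_records, cfg)
        second, _ = run_ensemble(gpcr_records[0].sequence, toy_msa, gpcr_records, cfg)
        assert np.array_equal(first[0].coords.ca, second[0].coords.ca)
        assert np.array_equal(first[0].plddt, second[0].plddt)
        assert first[0].ptm == second[0].ptm

    def test_randomized_recipes_reference_distinct_sets(self, gpcr_records, toy_msa):
        cfg = gpcr_config(num_models=12, shuffle_templates=True)
        models, _ = run_ensemble(
            gpcr_records[0].sequence, toy_msa, gpcr_records, cfg
        )
        distinct = {tuple(m.recipe.template_set.labels()) for m in models}
        assert len(distinct) >= 2

    def test_recipes_carry_protocol_parameters(self, gpcr_records, toy_msa):
        cfg = gpcr_config(num_models=3)
        models, _ = run_ensemble(
            gpcr_records[0].sequence, toy_msa, gpcr_records, cfg
        )
        for m in models:
            assert m.recipe.recycles == 0
            assert len(m.recipe.template_set) == 4
            assert m.recipe.msa_provenance == "subsampled"
            assert m.recipe.msa_params["n_clusters"] == 8
            assert m.recipe.msa_params["n_extra"] == 16

    def test_audit_trail_regenerates_identical_model(self, gpcr_records, toy_msa):
        """A surviving model's recipe reconstructs its exact inputs."""
        cfg = gpcr_config(num_models=4)
        models, _ = run_ensemble(
            gpcr_records[0].sequence, toy_msa, gpcr_records, cfg
        )
        target = models[2]
        predictor = sb.MockPredictor(sigma=cfg.noise_sigma)
        clusters, _ = sb.subsample(
            toy_msa,
            sb.SubsampleSpec(
                n_clusters=target.recipe.msa_params["n_clusters"],
                n_extra=target.recipe.msa_params["n_extra"],
                seed=target.recipe.msa_params["seed"],
            ),
        )
        coords, plddt, ptm = predictor(
            gpcr_records[0].sequence,
            clusters,
            target.recipe.template_set,
            target.recipe.recycles,
            target.recipe.seed,
        )
        assert np.array_equal(coords.ca, target.coords.ca)
        assert ptm == target.ptm

    def test_failing_predictor_marks_model_and_run_continues(
        self, gpcr_records, toy_msa
    ):
        calls = {"n": 0}
        good = sb.MockPredictor(sigma=0.0)

        def flaky(query, msa, tset, recycles, seed):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("synthetic predictor crash")
            return good(query, msa, tset, recycles, seed)

        cfg = gpcr_config(num_models=3)
        models, manifest = run_ensemble(
            gpcr_records[0].sequence, toy_msa, gpcr_records, cfg, predictor=flaky
        )
        assert len(models) == 2
        assert [row["status"] for row in manifest] == ["ok", "failed", "ok"]
        assert "synthetic predictor crash" in manifest[1]["error"]

    def test_all_failures_abort_the_run(self, gpcr_records, toy_msa):
        def broken(*args):
            raise RuntimeError("boom")

        with pytest.raises(DriverError):
            run_ensemble(
                gpcr_records[0].sequence, toy_msa, gpcr_records,
                gpcr_config(num_models=2), predictor=broken,
            )


class TestMockPredictor:
    def _single_template_set(self, records, k=1):
        query = sb.StateQuery(mode="gpcr", gpcr_state="Active", k=k)
        survivors = sb.filter_candidates(records, query, "")
        return sb.select_top_k(survivors, query)

    def test_single_template_sigma_zero_reproduces_template(
        self, gpcr_records, conformer_pair, toy_msa
    ):
        tset = self._single_template_set(gpcr_records, k=1)
        predictor = sb.MockPredictor(sigma=0.0)
        coords, plddt, ptm = predictor(
            gpcr_records[0].sequence, toy_msa, tset, 0, seed=1
        )
        template = sb.read_structure(tset.records[0].coords_path)
        assert np.allclose(coords.ca, template.ca, atol=1e-9)
        assert np.all(plddt == 100.0)

    def test_rigid_body_copies_collapse_to_zero_rmsd(self, tmp_path, toy_msa):
        """Two templates that are rotated copies of one structure agree exactly."""
        active, _, segments = sb.make_conformer_pair(sb.ConformerSpec(seed=3))
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        moved = sb.StructureCoords(
            active.residue_ids, active.ca @ rot.T + [8.0, -3.0, 2.0]
        )
        paths = []
        for name, coords in (("t1", active), ("t2", moved)):
            p = tmp_path / f"{name}.pdb"
            sb.write_structure(coords, p)
            paths.append(p)
        records = [
            sb.TemplateRecord(
                pdb_id=f"1AB{i}", chain_id="A", gpcr_state="Active",
                rank_score=10.0 - i, coords_path=str(p),
            )
            for i, p in enumerate(paths)
        ]
        tset = self._single_template_set(records, k=2)
        predictor = sb.MockPredictor(sigma=0.0)
        seq = "A" * len(active)
        coords, plddt, ptm = predictor(seq, None, tset, 0, seed=0)
        _, _, rmsd = sb.kabsch_superpose(coords, active)
        # residual reflects the 3-decimal PDB coordinate precision only
        assert rmsd == pytest.approx(0.0, abs=1e-3)
        assert ptm == pytest.approx(1.0, abs=1e-3)

    def test_consensus_stays_within_noise_bound(self, gpcr_records, toy_msa):
        """Median TM-RMSD of mock models to their own consensus <= sigma*sqrt(3)."""
        sigma = 0.5
        active, _, segments = sb.make_conformer_pair(sb.ConformerSpec(seed=7))
        tset = self._single_template_set(gpcr_records, k=1)
        template = sb.read_structure(tset.records[0].coords_path)
        predictor = sb.MockPredictor(sigma=sigma)
        rmsds = []
        for seed in range(12):
            coords, _, _ = predictor(
                gpcr_records[0].sequence, toy_msa, tset, 0, seed=seed
            )
            report = sb.segment_rmsd(coords, template, segments)
            rmsds.append(report.tm_rmsd)
        assert np.median(rmsds) <= sigma * np.sqrt(3)

    def test_empty_template_set_without_msa_is_an_error(self):
        query = sb.StateQuery(mode="gpcr", gpcr_state="Active", k=1)
        empty = sb.TemplateSet(records=(), query=query)
        with pytest.raises(DriverError):
            sb.MockPredictor()("A" * 30, None, empty, 0, seed=0)

    def test_uncovered_residues_are_extended_not_dropped(self, tmp_path):
        active, _, _ = sb.make_conformer_pair(sb.ConformerSpec(seed=1))
        partial = sb.StructureCoords(
            active.residue_ids[:150], active.ca[:150], source="partial"
        )
        p = tmp_path / "partial.pdb"
        sb.write_structure(partial, p)
        rec = sb.TemplateRecord(
            pdb_id="1ABX", chain_id="A", gpcr_state="Active", coords_path=str(p)
        )
        query = sb.StateQuery(mode="gpcr", gpcr_state="Active", k=1)
        tset = sb.TemplateSet(records=(rec,), query=query)
        coords, plddt, ptm = sb.MockPredictor(sigma=0.0)(
            "A" * len(active), None, tset, 0, seed=0
        )
        assert len(coords) == len(active)
        assert np.all(np.isfinite(coords.ca))
        assert np.all(plddt[150:] == 30.0)  # low confidence where unmodelled


class TestDiscardUnfolded:
    def _model(self, coords, plddt_value=90.0, index=0):
        query = sb.StateQuery(mode="gpcr", gpcr_state="Active", k=1)
        recipe = sb.PredictionRecipe(
            model_index=index, msa_provenance="raw", msa_params={},
            template_set=sb.TemplateSet(records=(), query=query),
            recycles=0, seed=0,
        )
        return sb.PredictedModel(
            model_index=index, coords=coords,
            plddt=np.full(len(coords), plddt_value), ptm=0.8, recipe=recipe,
        )

    def test_compact_confident_models_all_survive(self, conformer_pair):
        active, _, _ = conformer_pair
        models = [self._model(active, 90.0, i) for i in range(3)]
        assert sb.discard_unfolded(models) == models

    def test_extended_chain_removed_by_analytic_rg(self, conformer_pair):
        """A straight 3.8 Å/res chain has Rg = d*sqrt((N^2-1)/12) >> globular."""
        active, _, _ = conformer_pair
        n = len(active)
        line = as_coords(np.outer(np.arange(n), [3.8, 0.0, 0.0]))
        analytic = 3.8 * np.sqrt((n**2 - 1) / 12.0)
        assert radius_of_gyration(line) == pytest.approx(analytic, rel=1e-12)
        assert analytic > 2.5 * expected_rg(n)
        models = [self._model(active, 90.0, 0), self._model(line, 90.0, 1)]
        survivors = sb.discard_unfolded(models)
        assert [m.model_index for m in survivors] == [0]

    def test_low_confidence_model_removed(self, conformer_pair):
        active, _, _ = conformer_pair
        models = [self._model(active, 90.0, 0), self._model(active, 20.0, 1)]
        survivors = sb.discard_unfolded(models, plddt_floor=40.0)
        assert [m.model_index for m in survivors] == [0]

    def test_no_op_bounds_are_identity_and_idempotent(self, conformer_pair):
        active, _, _ = conformer_pair
        models = [self._model(active, 50.0, i) for i in range(4)]
        kept = sb.discard_unfolded(models, plddt_floor=0.0, rg_ceiling=np.inf)
        assert kept == models
        once = sb.discard_unfolded(models)
        assert sb.discard_unfolded(once) == once


class TestBiasProperty:
    def test_state_biased_ensembles_order_by_reference_proximity(
        self, gpcr_records, toy_msa, conformer_pair
    ):
        """The protocol's central premise at mock scale: querying a state
        pulls the ensemble toward that state's reference structure."""
        active_ref, inactive_ref, segments = conformer_pair
        seq = gpcr_records[0].sequence
        medians = {}
        for state in ("Active", "Inactive"):
            cfg = gpcr_config(num_models=10, gpcr_state=state)
            models, _ = run_ensemble(seq, toy_msa, gpcr_records, cfg)
            survivors = sb.discard_unfolded(models)
            table, _ = sb.ensemble_summary(survivors, active_ref, segments)
            medians[state] = table["tm_rmsd"].median()
        assert medians["Active"] < medians["Inactive"]
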