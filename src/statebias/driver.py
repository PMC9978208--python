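"""Orchestrate per-model prediction recipes and post-hoc ensemble filtering.

Each model of an ensemble is produced from its own *recipe*: an MSA variant
(shallow subsample, template-region removal, SPEACH-masked window, or the
full alignment) combined with a template set (fixed top-k or an independent
random draw). Recipes carry every seed they used, so any surviving model
can be regenerated exactly from the run manifest.

The predictor is pluggable behind :class:`PredictorContract`. The packaged
:class:`MockPredictor` is a deterministic geometric consensus builder: it
superposes the selected template structures, averages them per residue,
adds seeded Gaussian noise and emits confidence scores derived from the
inter-template agreement. It embodies the premise under test — that the
predicted ensemble follows the conformation of the supplied templates —
without any learned component, which is exactly what makes the pipeline's
selection and evaluation logic testable offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np

from .config import RunConfig
from .msa import Msa, SubsampleSpec, remove_msa_over_templates, speach_mask_variants, subsample
from .selection import TemplateSet, plan_template_sets
from .structures import StructureCoords, read_structure
from .fixtures import ideal_helix

logger = logging.getLogger(__name__)


class DriverError(RuntimeError):
    """Unrecoverable ensemble-run failure."""


@dataclass(frozen=True)
class PredictionRecipe:
    """Everything needed to regenerate one model."""

    model_index: int
    msa_provenance: str
    msa_params: dict
    template_set: TemplateSet
    recycles: int
    seed: int


@dataclass(frozen=True, eq=False)
class PredictedModel:
    """One predicted structure with confidence scores and its recipe."""

    model_index: int
    coords: StructureCoords
    plddt: np.ndarray  # per residue, [0, 100]
    ptm: float  # [0, 1]
    recipe: PredictionRecipe

    def __post_init__(self) -> None:
        plddt = np.asarray(self.plddt, dtype=float)
        if plddt.shape != (len(self.coords),):
            raise DriverError("plddt length must match the coordinate length")
        if np.any((plddt < 0) | (plddt > 100)):
            raise DriverError("plddt values must lie in [0, 100]")
        if not (0.0 <= self.ptm <= 1.0):
            raise DriverError(f"ptm {self.ptm} outside [0, 1]")
        object.__setattr__(self, "plddt", plddt)

    @property
    def mean_plddt(self) -> float:
        return float(np.mean(self.plddt))


class PredictorContract(Protocol):
    """A structure predictor: deterministic given identical inputs and seed."""

    def __call__(
        self,
        query_sequence: str,
        msa: Msa | None,
        template_set: TemplateSet,
        recycles: int,
        seed: int,
    ) -> tuple[StructureCoords, np.ndarray, float]:
        """Return (coords, per-residue plddt, ptm)."""


def _superpose_onto(
    mobile_xyz: np.ndarray, fixed_xyz: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Plain Kabsch on paired point sets; returns (rotation, translation)."""
    pc, qc = mobile_xyz.mean(axis=0), fixed_xyz.mean(axis=0)
    h = (mobile_xyz - pc).T @ (fixed_xyz - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, qc - rot @ pc


@dataclass
class MockPredictor:
    """Deterministic template-consensus predictor (test double).

    Builds the Cα trace as the per-residue average of the aligned template
    coordinates after mutual superposition, plus seeded Gaussian noise of
    ``sigma`` Å. Residues covered by no template are extended as an ideal
    helix continuing from the nearest modelled flank. Per-residue confidence
    decays with the inter-template spread (agreement = exp(-sd / 2 Å));
    pTM is the coverage-weighted mean agreement.
    """

    sigma: float = 0.5
    chain_cache: dict = field(default_factory=dict)

    def _load(self, record) -> StructureCoords:
        key = (record.coords_path, record.chain_id)
        if key not in self.chain_cache:
            try:
                coords = read_structure(record.coords_path, chain=record.chain_id)
            except Exception:
                coords = read_structure(record.coords_path)
            self.chain_cache[key] = coords
        return self.chain_cache[key]

    def __call__(
        self,
        query_sequence: str,
        msa: Msa | None,
        template_set: TemplateSet,
        recycles: int,
        seed: int,
    ) -> tuple[StructureCoords, np.ndarray, float]:
        n = len(query_sequence)
        if len(template_set) == 0:
            if msa is None or msa.depth <= 1:
                raise DriverError(
                    "empty template set and no MSA: nothing to build a model from"
                )
            # MSA-only fallback: an ideal helix baseline
            xyz = ideal_helix(n, np.zeros(3), np.array([0.0, 0.0, 1.0]))
            plddt = np.full(n, 30.0)
            return (
                StructureCoords(np.arange(1, n + 1), xyz, source="mock:msa_only"),
                plddt,
                0.3,
            )
        templates = [self._load(rec) for rec in template_set.records]
        anchor = templates[0]
        aligned: list[StructureCoords] = [anchor]
        for t in templates[1:]:
            common = np.intersect1d(anchor.residue_ids, t.residue_ids)
            if common.size < 3:
                logger.warning(
                    "template %s shares <3 residues with anchor; skipped", t.source
                )
                continue
            rot, trans = _superpose_onto(
                t.coords_for(common), anchor.coords_for(common)
            )
            aligned.append(replace(t, ca=t.ca @ rot.T + trans))
        # per-residue consensus over templates covering that query position
        sums = np.zeros((n, 3))
        sq_sums = np.zeros(n)
        counts = np.zeros(n, dtype=int)
        for t in aligned:
            in_range = (t.residue_ids >= 1) & (t.residue_ids <= n)
            idx = t.residue_ids[in_range] - 1
            sums[idx] += t.ca[in_range]
            counts[idx] += 1
        mean = np.zeros((n, 3))
        covered = counts > 0
        mean[covered] = sums[covered] / counts[covered, None]
        for t in aligned:
            in_range = (t.residue_ids >= 1) & (t.residue_ids <= n)
            idx = t.residue_ids[in_range] - 1
            sq_sums[idx] += np.sum((t.ca[in_range] - mean[idx]) ** 2, axis=1)
        sd = np.zeros(n)
        sd[covered] = np.sqrt(sq_sums[covered] / counts[covered])
        # extend uncovered stretches as ideal helix from the nearest flank
        if not covered.all():
            if not covered.any():
                raise DriverError("templates cover no query residues")
            mean = self._fill_gaps(mean, covered)
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 31]))
        xyz = mean + rng.normal(0.0, self.sigma, (n, 3)) if self.sigma > 0 else mean
        agreement = np.exp(-sd / 2.0)
        plddt = np.where(covered, 100.0 * agreement, 30.0)
        ptm = float(np.clip(np.mean(np.where(covered, agreement, 0.3)), 0.0, 1.0))
        coords = StructureCoords(np.arange(1, n + 1), xyz, source="mock:consensus")
        return coords, plddt, ptm

    @staticmethod
    def _fill_gaps(mean: np.ndarray, covered: np.ndarray) -> np.ndarray:
        n = mean.shape[0]
        out = mean.copy()
        cov_idx = np.flatnonzero(covered)
        i = 0
        while i < n:
            if covered[i]:
                i += 1
                continue
            j = i
            while j < n and not covered[j]:
                j += 1
            # nearest covered flank anchors the extension direction
            if i > 0:
                anchor = out[i - 1]
                prev = out[i - 2] if i > 1 else anchor - np.array([0.0, 0.0, 1.5])
                axis = anchor - prev
            else:
                anchor = out[j]
                nxt = out[j + 1] if j + 1 < n else anchor + np.array([0.0, 0.0, 1.5])
                axis = anchor - nxt
            norm = np.linalg.norm(axis)
            axis = axis / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
            ext = ideal_helix(j - i + 1, anchor + 1.5 * axis, axis)
            out[i:j] = ext[: j - i] if i > 0 else ext[: j - i][::-1]
            i = j
        del cov_idx
        return out


PREDICTORS: dict[str, Callable[[RunConfig], PredictorContract]] = {
    "mock": lambda cfg: MockPredictor(sigma=cfg.noise_sigma),
}


def register_predictor(name: str, factory: Callable[[RunConfig], PredictorContract]) -> None:
    """Register an external predictor plugin under ``--predictor <name>``."""
    PREDICTORS[name] = factory


def _derive_seed(run_seed: int, model_index: int) -> int:
    ss = np.random.SeedSequence([run_seed & 0x7FFFFFFF, model_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _template_footprint(template_set: TemplateSet, query_length: int) -> set[int]:
    """Query columns covered by >=1 selected template's alignment footprint."""
    covered: set[int] = set()
    loader = MockPredictor()
    for rec in template_set.records:
        try:
            coords = loader._load(rec)
        except Exception:
            continue
        rids = coords.residue_ids
        covered.update(
            int(r) for r in rids[(rids >= 1) & (rids <= query_length)]
        )
    return covered


def build_recipes(
    msa: Msa, template_sets: Sequence[TemplateSet], config: RunConfig
) -> list[tuple[PredictionRecipe, Msa]]:
    """Pair each template set with its per-model MSA variant."""
    speach_variants = (
        speach_mask_variants(msa, config.speach_window, config.speach_stride)
        if config.msa_mode == "speach"
        else []
    )
    out = []
    for i, tset in enumerate(template_sets):
        seed_i = _derive_seed(config.seed, i)
        if config.msa_mode == "shallow":
            clusters, _extras = subsample(
                msa,
                SubsampleSpec(
                    n_clusters=config.subsample.n_clusters,
                    n_extra=config.subsample.n_extra,
                    seed=seed_i,
                ),
            )
            variant = clusters
        elif config.msa_mode == "none":
            footprint = _template_footprint(tset, msa.query_length)
            variant = remove_msa_over_templates(msa, footprint)
        elif config.msa_mode == "speach":
            variant = speach_variants[i % len(speach_variants)]
        else:
            variant = msa
        recipe = PredictionRecipe(
            model_index=i,
            msa_provenance=variant.provenance,
            msa_params=dict(variant.params),
            template_set=tset,
            recycles=config.recycles,
            seed=seed_i,
        )
        out.append((recipe, variant))
    return out


def run_ensemble(
    query_sequence: str,
    msa: Msa,
    records: Sequence,
    config: RunConfig,
    predictor: PredictorContract | None = None,
    query_subfamily: str = "",
) -> tuple[list[PredictedModel], list[dict]]:
    """Generate the full model ensemble for one conformational query.

    Dispatches exactly ``config.n_models`` recipes. A predictor failure on
    one model is logged and recorded in the manifest with its error; the run
    only fails if every model fails. Returns ``(models, manifest_rows)``.
    """
    if predictor is None:
        try:
            predictor = PREDICTORS[config.predictor](config)
        except KeyError:
            raise DriverError(
                f"no predictor registered under {config.predictor!r}"
            ) from None
    template_sets = plan_template_sets(
        records, config.query, config.n_models, query_subfamily
    )
    models: list[PredictedModel] = []
    manifest: list[dict] = []
    for recipe, variant in build_recipes(msa, template_sets, config):
        row = {
            "model_index": recipe.model_index,
            "seed": recipe.seed,
            "msa_provenance": recipe.msa_provenance,
            "templates": recipe.template_set.labels(),
            "status": "ok",
        }
        try:
            coords, plddt, ptm = predictor(
                query_sequence,
                variant,
                recipe.template_set,
                recipe.recycles,
                recipe.seed,
            )
            model = PredictedModel(
                model_index=recipe.model_index,
                coords=coords,
                plddt=plddt,
                ptm=ptm,
                recipe=recipe,
            )
            models.append(model)
            row["ptm"] = ptm
            row["mean_plddt"] = model.mean_plddt
        except Exception as exc:  # failed models stay in the manifest
            logger.error("model %d failed: %s", recipe.model_index, exc)
            row["status"] = "failed"
            row["error"] = str(exc)
        manifest.append(row)
    if not models:
        raise DriverError("all models failed; see manifest for errors")
    return models, manifest


def radius_of_gyration(coords: StructureCoords) -> float:
    xyz = coords.ca
    return float(np.sqrt(np.mean(np.sum((xyz - xyz.mean(axis=0)) ** 2, axis=1))))


def expected_rg(n_residues: int) -> float:
    """Empirical globular-protein radius of gyration, Rg ≈ 2.2·N^0.38 Å."""
    return 2.2 * n_residues**0.38


def discard_unfolded(
    models: Sequence[PredictedModel],
    plddt_floor: float = 40.0,
    rg_ceiling: float = 2.5,
) -> list[PredictedModel]:
    """Drop low-confidence or non-compact models.

    A model survives when its mean pLDDT is at least ``plddt_floor`` and its
    radius of gyration is at most ``rg_ceiling`` times the globular
    expectation for its length. Discards are logged with the reason;
    the operation never adds models and is idempotent.
    """
    if not models:
        raise DriverError("empty ensemble")
    survivors = []
    for m in models:
        rg = radius_of_gyration(m.coords)
        limit = rg_ceiling * expected_rg(len(m.coords))
        if m.mean_plddt < plddt_floor:
            logger.info(
                "discarding model %d: mean pLDDT %.1f < %.1f",
                m.model_index,
                m.mean_plddt,
                plddt_floor,
            )
        elif rg > limit:
            logger.info(
                "discarding model %d: Rg %.1f Å > %.1f Å (unfolded)",
                m.model_index,
                rg,
                limit,
            )
        else:
            survivors.append(m)
    return survivors
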