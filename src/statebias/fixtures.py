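"""Synthetic test inputs: toy conformers, annotation tables, toy MSAs.

Everything the pipeline consumes can be generated offline and reproducibly
from a seed. The toy GPCR is a deliberate cartoon of the real system: seven
ideal α-helices (1.5 Å rise, 100°/residue, 2.3 Å radius) standing
antiparallel on a circle, with "activation" modelled as a rigid outward
displacement of helix 6 — the hallmark motion distinguishing active from
inactive receptor structures. The toy kinase is a small helical
two-lobe cartoon with designated aC-helix, DFG and activation-loop
segments; the DFG flip rigidly relocates the DFG motif together with the
activation loop. These cartoons carry none of real proteins' side chains,
packing or loop physics; they exist so that metric, selection and bias
logic can be tested against displacements that are known in closed form.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .annotations import TemplateRecord, write_annotations
from .msa import Msa, write_a3m
from .segments import SegmentMap
from .structures import StructureCoords, write_structure

_HELIX_RISE = 1.5  # Å per residue along the axis
_HELIX_RADIUS = 2.3  # Å, Cα distance from the helix axis
_HELIX_TWIST = np.deg2rad(100.0)  # per residue
_AA = "ACDEFGHIKLMNPQRSTVWY"


class FixtureError(ValueError):
    """Inconsistent fixture specification."""


@dataclass(frozen=True)
class ConformerSpec:
    """Geometry of a toy conformer pair.

    ``state_displacement`` (Å) is the rigid shift applied to
    ``displaced_segment`` to turn state B into state A; ``noise_sigma`` (Å)
    perturbs the shared base coordinates so repeated specs with different
    seeds give distinct but equally-displaced pairs.
    """

    n_residues: int = 205
    n_helices: int = 7
    state_displacement: float = 4.0
    noise_sigma: float = 0.0
    seed: int = 0
    displaced_segment: str = "TM6"

    def __post_init__(self) -> None:
        if self.state_displacement < 0:
            raise FixtureError("state_displacement must be >= 0")
        if self.n_helices < 1:
            raise FixtureError("n_helices must be >= 1")
        if self.n_residues < 4 * self.n_helices:
            raise FixtureError("too few residues for the requested helix count")


def ideal_helix(
    n: int, origin: np.ndarray, axis: np.ndarray, phase: float = 0.0
) -> np.ndarray:
    """Cα trace of an ideal α-helix of ``n`` residues starting at ``origin``."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame perpendicular to the axis
    probe = np.array([1.0, 0.0, 0.0])
    if abs(axis @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, probe)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    i = np.arange(n)[:, None]
    angle = _HELIX_TWIST * np.arange(n)
    return (
        np.asarray(origin, float)
        + _HELIX_RISE * i * axis
        + _HELIX_RADIUS * (np.cos(angle)[:, None] * u + np.sin(angle)[:, None] * v)
    )


def _bundle(spec: ConformerSpec) -> tuple[np.ndarray, SegmentMap]:
    """Base Cα coordinates and TM segment map of the helical bundle."""
    n_h = spec.n_helices
    loop_len = 4
    helix_len = (spec.n_residues - (n_h - 1) * loop_len) // n_h
    coords: list[np.ndarray] = []
    segments: dict[str, tuple[int, int]] = {}
    ring_radius = 14.0
    next_res = 1
    prev_end: np.ndarray | None = None
    for h in range(n_h):
        theta = 2 * np.pi * h / n_h
        center = ring_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        up = h % 2 == 0
        axis = np.array([0.0, 0.0, 1.0 if up else -1.0])
        z0 = 0.0 if up else _HELIX_RISE * (helix_len - 1)
        origin = center + np.array([0.0, 0.0, z0])
        helix = ideal_helix(helix_len, origin, axis)
        if prev_end is not None:
            # straight connector, end points excluded
            t = np.linspace(0, 1, loop_len + 2)[1:-1, None]
            coords.append(prev_end * (1 - t) + helix[0] * t)
            next_res += loop_len
        segments[f"TM{h + 1}"] = (next_res, next_res + helix_len - 1)
        next_res += helix_len
        coords.append(helix)
        prev_end = helix[-1]
    base = np.concatenate(coords)
    # distribute any leftover residues as a short C-terminal extension
    leftover = spec.n_residues - base.shape[0]
    if leftover > 0:
        direction = base[-1] - base[-2]
        direction = direction / np.linalg.norm(direction) * 3.8
        tail = base[-1] + direction * np.arange(1, leftover + 1)[:, None]
        base = np.concatenate([base, tail])
    return base, SegmentMap(segments)


def make_conformer_pair(
    spec: ConformerSpec, out_dir: str | Path | None = None
) -> tuple[StructureCoords, StructureCoords, SegmentMap]:
    """Build a state-A / state-B toy conformer pair.

    The two structures share identical coordinates except for a rigid
    translation of ``spec.displaced_segment`` by ``spec.state_displacement``
    Å directed radially outward from the bundle centre — so the no-fit RMSD
    over that segment equals the displacement exactly. State A is the
    displaced ("active-like") conformation. When ``out_dir`` is given,
    ``state_A.pdb`` / ``state_B.pdb`` and ``segments.json`` are written.
    """
    base, segments = _bundle(spec)
    if spec.displaced_segment not in segments:
        raise FixtureError(
            f"displaced segment {spec.displaced_segment!r} not in the chain "
            f"(have {segments.names()})"
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 11])
        )
        base = base + rng.normal(0.0, spec.noise_sigma, base.shape)
    rids = np.arange(1, base.shape[0] + 1)
    seg_res = sorted(segments.residues([spec.displaced_segment]))
    seg_idx = np.asarray(seg_res) - 1
    seg_center = base[seg_idx].mean(axis=0)
    radial = seg_center - np.array([0.0, 0.0, seg_center[2]])
    norm = np.linalg.norm(radial)
    direction = radial / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    displaced = base.copy()
    displaced[seg_idx] += spec.state_displacement * direction
    state_a = StructureCoords(rids, displaced, source="toy:state_A")
    state_b = StructureCoords(rids, base, source="toy:state_B")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_structure(state_a, out / "state_A.pdb")
        write_structure(state_b, out / "state_B.pdb")
        segments.to_json(out / "segments.json")
    return state_a, state_b, segments


# --------------------------------------------------------------------------
# Toy kinase: a compact helical core plus aC-helix, DFG and activation loop.
# --------------------------------------------------------------------------


def make_kinase_library(
    displacement: float = 6.0,
    ac_displacement: float = 5.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[tuple[str, str], StructureCoords], SegmentMap]:
    """Toy kinase conformers for every (a_loop, ac_helix) in/out combination.

    The base ("in"/"in") conformer has two core helices, an aC-helix and a
    DFG + activation-loop segment. ``a_loop=out`` rigidly relocates DFG and
    the activation loop by ``displacement`` Å; ``ac_helix=out`` shifts the
    aC-helix by ``ac_displacement`` Å. Returns the four conformers keyed by
    ``(a_loop, ac_helix)`` labels plus the shared motif segment map.
    """
    core1 = ideal_helix(28, np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    core2 = ideal_helix(28, np.array([9.0, 0.0, 40.0]), np.array([0.0, 0.0, -1.0]))
    link1 = np.linspace(core1[-1], core2[0], 8 + 2)[1:-1]
    ac = ideal_helix(14, np.array([0.0, 11.0, 6.0]), np.array([0.0, 0.0, 1.0]))
    link2 = np.linspace(core2[-1], ac[0], 6 + 2)[1:-1]
    aloop_start = ac[-1] + np.array([3.0, -2.0, 1.0])
    aloop = aloop_start + 3.6 * np.arange(14)[:, None] * np.array(
        [0.9, -0.3, 0.3]
    )
    base = np.concatenate([core1, link1, core2, link2, ac, aloop])
    n = base.shape[0]
    ac_start = 28 + 8 + 28 + 6 + 1
    aloop_first = ac_start + 14
    segments = SegmentMap(
        {
            "ac_helix": (ac_start, ac_start + 13),
            "DFG": (aloop_first, aloop_first + 2),
            "a_loop": (aloop_first + 3, n),
        }
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, 13])
        )
        base = base + rng.normal(0.0, noise_sigma, base.shape)
    rids = np.arange(1, n + 1)
    flip_res = sorted(segments.residues(["DFG", "a_loop"]))
    ac_res = sorted(segments.residues(["ac_helix"]))
    library: dict[tuple[str, str], StructureCoords] = {}
    for a_loop in ("in", "out"):
        for ac_helix in ("in", "out"):
            coords = base.copy()
            if a_loop == "out":
                coords[np.asarray(flip_res) - 1] += displacement * np.array(
                    [0.0, -1.0, 0.0]
                )
            if ac_helix == "out":
                coords[np.asarray(ac_res) - 1] += ac_displacement * np.array(
                    [-1.0, 0.0, 0.0]
                )
            library[(a_loop, ac_helix)] = StructureCoords(
                rids, coords, source=f"toy:kinase_aloop_{a_loop}_ach_{ac_helix}"
            )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (a_loop, ac_helix), coords in library.items():
            write_structure(coords, out / f"kinase_aloop-{a_loop}_ach-{ac_helix}.pdb")
        segments.to_json(out / "kinase_segments.json")
    return library, segments


# --------------------------------------------------------------------------
# Annotation fixtures
# --------------------------------------------------------------------------


def _pdb_code(i: int) -> str:
    alphabet = string.ascii_uppercase + string.digits
    return f"9{alphabet[(i // 36) % 36]}{alphabet[i % 36]}{alphabet[(i * 7) % 36]}"


def _noisy_copy(
    coords: StructureCoords, sigma: float, rng: np.random.Generator
) -> StructureCoords:
    return replace(coords, ca=coords.ca + rng.normal(0.0, sigma, coords.ca.shape))


def make_annotation_fixture(
    out_dir: str | Path,
    n_active: int = 10,
    n_inactive: int = 10,
    n_kinase_variants: int = 0,
    seed: int = 0,
    spec: ConformerSpec | None = None,
    template_noise: float = 0.3,
) -> Path:
    """Write a complete offline fixture: TSV, conformer PDBs, segment map.

    Active GPCR records point at noisy copies of the state-A conformer,
    Inactive records at state-B copies; kinase records cycle through every
    (DFG, ac_helix) combination of the toy kinase library with a_loop set
    consistently with DFG. Rank scores and identities are drawn
    reproducibly. Returns the path of the written TSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 17]))
    spec = spec or ConformerSpec(seed=seed)
    records: list[TemplateRecord] = []
    seq = toy_sequence(spec.n_residues, seed)
    if n_active or n_inactive:
        state_a, state_b, segments = make_conformer_pair(spec, out_dir=out)
        segments.to_json(out / "segments.json")
        states = ["Active"] * n_active + ["Inactive"] * n_inactive
        for i, state in enumerate(states):
            ref = state_a if state == "Active" else state_b
            coords = _noisy_copy(ref, template_noise, rng)
            code = _pdb_code(i)
            pdb_path = out / f"{code}_A.pdb"
            write_structure(coords, pdb_path)
            records.append(
                TemplateRecord(
                    pdb_id=code,
                    chain_id="A",
                    sequence=seq,
                    rank_score=float(np.round(rng.uniform(10, 99), 1)),
                    seq_identity=float(np.round(rng.uniform(15, 45), 1)),
                    family="toyGPCR",
                    subfamily=f"subfam{i % 3}",
                    gpcr_state=state,
                    coords_path=str(pdb_path),
                )
            )
    if n_kinase_variants:
        library, ksegs = make_kinase_library(seed=seed, out_dir=out)
        combos = [
            ("in", "in"),
            ("in", "out"),
            ("out", "in"),
            ("out", "out"),
        ]
        for i in range(n_kinase_variants):
            dfg, ac_helix = combos[i % len(combos)]
            a_loop = "in" if dfg == "in" else "out"
            coords = _noisy_copy(library[(a_loop, ac_helix)], template_noise, rng)
            code = _pdb_code(1000 + i)
            pdb_path = out / f"{code}_A.pdb"
            write_structure(coords, pdb_path)
            records.append(
                TemplateRecord(
                    pdb_id=code,
                    chain_id="A",
                    sequence=toy_sequence(len(coords), seed + 1),
                    rank_score=float(np.round(rng.uniform(10, 99), 1)),
                    seq_identity=float(np.round(rng.uniform(20, 60), 1)),
                    family="toyKinase",
                    subfamily=f"kinfam{i % 2}",
                    dfg=dfg,
                    ac_helix=ac_helix,
                    salt_bridge="yes" if ac_helix == "in" else "no",
                    a_loop=a_loop,
                    coords_path=str(pdb_path),
                )
            )
    tsv = out / "annotations.tsv"
    write_annotations(records, tsv)
    return tsv


#: The four active-state templates of the lutropin receptor benchmark with
#: their template-search sequence identities (%), in ranked order, plus the
#: top-4 inactive templates of the leukotriene-B4 receptor benchmark.
LSHR_ACTIVE_TEMPLATES = (
    ("6H7L", "A", 20.6),
    ("6IBL", "A", 15.9),
    ("6K41", "R", 23.1),
    ("6K42", "R", 23.7),
)
LT4R1_INACTIVE_TEMPLATES = (
    ("6VI4", "A", 27.5),
    ("4ZUD", "A", 20.0),
    ("4YAY", "A", 20.1),
    ("4N6H", "A", 20.2),
)


def make_benchmark_fixture(
    out_dir: str | Path,
    benchmark: str = "lshr",
    n_decoys: int = 2,
    n_extra_pool: int = 0,
    seed: int = 0,
) -> Path:
    """Annotation fixture mirroring a published template list.

    ``lshr``: the four ranked active-state templates (synthetic toy
    coordinates standing in for the real chains) plus Inactive decoys.
    ``lt4r1``: the four top-ranked inactive templates plus ``n_extra_pool``
    additional Inactive entries forming the randomization pool.
    """
    if benchmark not in ("lshr", "lt4r1"):
        raise FixtureError(f"unknown benchmark {benchmark!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 19]))
    spec = ConformerSpec(seed=seed)
    state_a, state_b, segments = make_conformer_pair(spec, out_dir=out)
    segments.to_json(out / "segments.json")
    seq = toy_sequence(spec.n_residues, seed)
    named = LSHR_ACTIVE_TEMPLATES if benchmark == "lshr" else LT4R1_INACTIVE_TEMPLATES
    named_state = "Active" if benchmark == "lshr" else "Inactive"
    named_ref = state_a if named_state == "Active" else state_b
    records = []
    n_named = len(named)
    for rank, (pdb_id, chain_id, identity) in enumerate(named):
        coords = _noisy_copy(named_ref, 0.3, rng)
        pdb_path = out / f"{pdb_id}_{chain_id}.pdb"
        write_structure(coords, pdb_path, chain=chain_id)
        records.append(
            TemplateRecord(
                pdb_id=pdb_id,
                chain_id=chain_id,
                sequence=seq,
                rank_score=float(100 - rank),  # preserves the published order
                seq_identity=identity,
                family="toyGPCR",
                subfamily=f"benchfam{rank}",
                gpcr_state=named_state,
                coords_path=str(pdb_path),
            )
        )
    decoy_state = "Inactive" if benchmark == "lshr" else "Active"
    decoy_ref = state_b if decoy_state == "Inactive" else state_a
    for i in range(n_decoys):
        code = _pdb_code(500 + i)
        coords = _noisy_copy(decoy_ref, 0.3, rng)
        pdb_path = out / f"{code}_A.pdb"
        write_structure(coords, pdb_path)
        records.append(
            TemplateRecord(
                pdb_id=code,
                chain_id="A",
                sequence=seq,
                rank_score=float(np.round(rng.uniform(10, 80), 1)),
                seq_identity=float(np.round(rng.uniform(15, 30), 1)),
                family="toyGPCR",
                subfamily="decoyfam",
                gpcr_state=decoy_state,
                coords_path=str(pdb_path),
            )
        )
    for i in range(n_extra_pool):
        code = _pdb_code(700 + i)
        coords = _noisy_copy(named_ref, 0.6, rng)
        pdb_path = out / f"{code}_A.pdb"
        write_structure(coords, pdb_path)
        records.append(
            TemplateRecord(
                pdb_id=code,
                chain_id="A",
                sequence=seq,
                rank_score=float(np.round(rng.uniform(5, 95), 1)),
                seq_identity=float(np.round(rng.uniform(15, 30), 1)),
                family="toyGPCR",
                subfamily=f"poolfam{i % 4}",
                gpcr_state=named_state,
                coords_path=str(pdb_path),
            )
        )
    tsv = out / "annotations.tsv"
    write_annotations(records, tsv)
    return tsv


# --------------------------------------------------------------------------
# Toy MSAs
# --------------------------------------------------------------------------


def toy_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 23]))
    return "".join(rng.choice(list(_AA), size=length))


def make_toy_msa(
    query_length: int,
    depth: int,
    seed: int = 0,
    identity: float = 0.5,
    path: str | Path | None = None,
    query_id: str = "query",
) -> Msa:
    """Query plus ``depth - 1`` homologs mutated to a target identity.

    Each non-query position independently keeps the query residue with
    probability ``identity``, else switches to a uniformly random different
    residue. Written as A3M when ``path`` is given.
    """
    if depth < 1:
        raise FixtureError("depth must be >= 1")
    if not (0.0 <= identity <= 1.0):
        raise FixtureError("identity must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 29]))
    query = toy_sequence(query_length, seed)
    rows = [query]
    headers = [query_id]
    for i in range(1, depth):
        keep = rng.random(query_length) < identity
        mutated = [
            q if k else rng.choice([a for a in _AA if a != q])
            for q, k in zip(query, keep)
        ]
        rows.append("".join(mutated))
        headers.append(f"homolog_{i}")
    msa = Msa(query_id=query_id, headers=tuple(headers), rows=tuple(rows))
    if path is not None:
        write_a3m(msa, path)
    return msa
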