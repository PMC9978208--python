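"""Superposition, segment RMSDs, ensemble summaries and kinase-state calls.

Accuracy of a predicted GPCR model is reported as Cα RMSD over the
transmembrane helices (TM-RMSD) after least-squares superposition on those
same helices; loops are scored in that TM frame, so the loop number reflects
loop placement relative to the helical bundle. Kinase models are classified
by which labelled reference exemplar their activation-loop / aC-helix motif
is nearest to (motif Cα RMSD after superposition on the kinase core).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .segments import SegmentMap
from .structures import StructureCoords, StructureError

logger = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-8


class MetricError(ValueError):
    """Degenerate or unusable input to a structural metric."""


@dataclass(frozen=True)
class RmsdReport:
    """Per-model accuracy: TM, loop and global Cα RMSD (Å) with match counts."""

    tm_rmsd: float
    loop_rmsd: float
    global_rmsd: float
    n_tm: int
    n_loop: int
    n_global: int


def _common_residues(
    mobile: StructureCoords, fixed: StructureCoords, selection: set[int] | None
) -> np.ndarray:
    common = np.intersect1d(mobile.residue_ids, fixed.residue_ids)
    if selection is not None:
        common = np.intersect1d(common, sorted(selection))
    return common


def kabsch_superpose(
    mobile: StructureCoords,
    fixed: StructureCoords,
    selection: set[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``fixed``.

    Returns ``(rotation, translation, rmsd)`` where the transform maps a
    mobile coordinate x to ``rotation @ x + translation`` and ``rmsd`` is the
    Cα RMSD over the selected residues after the transform. The rotation is
    the closed-form least-squares optimum (proper, det = +1). Requires at
    least 3 non-collinear common residues.
    """
    common = _common_residues(mobile, fixed, selection)
    if common.size < 3:
        raise MetricError(
            f"need >= 3 common residues for superposition, found {common.size}"
        )
    p = mobile.coords_for(common)
    q = fixed.coords_for(common)
    p_center = p.mean(axis=0)
    q_center = q.mean(axis=0)
    p0 = p - p_center
    q0 = q - q_center
    singular = np.linalg.svd(q0, compute_uv=False)
    if singular[1] <= _COLLINEAR_TOL * max(singular[0], 1.0):
        raise MetricError("selection is collinear; superposition is degenerate")
    h = p0.T @ q0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = q_center - rotation @ p_center
    moved = p @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rotation, translation, rmsd


def rmsd_no_fit(
    a: StructureCoords, b: StructureCoords, selection: set[int] | None = None
) -> float:
    """Cα RMSD over common (optionally selected) residues without superposition."""
    common = _common_residues(a, b, selection)
    if common.size == 0:
        raise MetricError("no common residues for no-fit RMSD")
    d = a.coords_for(common) - b.coords_for(common)
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


def _rmsd_after(
    mobile: StructureCoords,
    fixed: StructureCoords,
    rotation: np.ndarray,
    translation: np.ndarray,
    residues: np.ndarray,
) -> float:
    p = mobile.coords_for(residues) @ rotation.T + translation
    q = fixed.coords_for(residues)
    return float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1))))


def segment_rmsd(
    model: StructureCoords,
    reference: StructureCoords,
    segments: SegmentMap,
    loop_frame: str = "tm",
) -> RmsdReport:
    """TM-RMSD, loop RMSD and global RMSD of a model against a reference.

    TM-RMSD superposes on the union of ``TM*`` segments and scores there.
    Loops (residues outside every TM segment) are scored in the TM frame by
    default, or after their own superposition with ``loop_frame='independent'``.
    Global RMSD uses all matched residues with its own superposition.
    """
    if loop_frame not in ("tm", "independent"):
        raise MetricError(f"unknown loop_frame {loop_frame!r}")
    tm_names = segments.tm_names() or segments.names()
    tm_sel = segments.residues(tm_names)
    common_all = _common_residues(model, reference, None)
    if common_all.size == 0:
        raise MetricError("model and reference share no residues")
    tm_common = np.intersect1d(common_all, sorted(tm_sel))
    if tm_common.size == 0:
        raise MetricError(
            f"no common residues in segments {tm_names}; check the segment map"
        )
    rot, trans, tm_rmsd = kabsch_superpose(model, reference, set(tm_common.tolist()))
    loop_common = np.setdiff1d(common_all, tm_common)
    if loop_common.size == 0:
        loop_rmsd = float("nan")
    elif loop_frame == "independent" and loop_common.size >= 3:
        _, _, loop_rmsd = kabsch_superpose(
            model, reference, set(loop_common.tolist())
        )
    else:
        loop_rmsd = _rmsd_after(model, reference, rot, trans, loop_common)
    _, _, global_rmsd = kabsch_superpose(model, reference, set(common_all.tolist()))
    return RmsdReport(
        tm_rmsd=tm_rmsd,
        loop_rmsd=loop_rmsd,
        global_rmsd=global_rmsd,
        n_tm=int(tm_common.size),
        n_loop=int(loop_common.size),
        n_global=int(common_all.size),
    )


def ensemble_summary(
    models: Sequence,
    reference: StructureCoords,
    segments: SegmentMap,
    loop_frame: str = "tm",
) -> tuple[pd.DataFrame, int]:
    """Score every model of an ensemble against a reference.

    ``models`` may be :class:`~statebias.driver.PredictedModel` objects or
    bare :class:`StructureCoords`. Returns a table ordered by model index and
    the index of the best model (lowest TM-RMSD, ties to the lower index).
    """
    if len(models) == 0:
        raise MetricError("empty ensemble")
    rows = []
    for i, m in enumerate(models):
        coords = getattr(m, "coords", m)
        idx = getattr(m, "model_index", i)
        report = segment_rmsd(coords, reference, segments, loop_frame=loop_frame)
        rows.append(
            {
                "model_index": idx,
                "tm_rmsd": report.tm_rmsd,
                "loop_rmsd": report.loop_rmsd,
                "global_rmsd": report.global_rmsd,
                "ptm": getattr(m, "ptm", float("nan")),
                "mean_plddt": (
                    float(np.mean(m.plddt)) if hasattr(m, "plddt") else float("nan")
                ),
            }
        )
    table = pd.DataFrame(rows).sort_values("model_index").reset_index(drop=True)
    best = int(table.loc[table["tm_rmsd"].idxmin(), "model_index"])
    return table, best


def ptm_rmsd_correlation(
    ptm: Sequence[float], rmsd: Sequence[float]
) -> tuple[float, int]:
    """Spearman rank correlation between pTM and RMSD (average-rank ties).

    Returns ``(rho, n)``. A zero-variance input makes the correlation
    undefined and yields NaN (flagged with a warning), never 0. Fewer than 3
    finite pairs is an error.
    """
    x = np.asarray(ptm, dtype=float)
    y = np.asarray(rmsd, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise MetricError(f"need >= 3 finite (pTM, RMSD) pairs, found {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: Spearman correlation undefined (NA)")
        return float("nan"), int(x.size)
    rho, _ = stats.spearmanr(x, y)
    return float(rho), int(x.size)


@dataclass(frozen=True)
class KinaseCall:
    """Feature labels assigned to one model, with classification margins (Å)."""

    a_loop: str
    ac_helix: str
    a_loop_margin: float
    ac_helix_margin: float


def _nearest_label(
    distances: list[tuple[float, str, int]], feature: str
) -> tuple[str, float]:
    """Label of the nearest exemplar; margin = gap to the nearest other label."""
    distances = sorted(distances, key=lambda t: (t[0], t[2]))
    best_dist, best_label, best_idx = distances[0]
    other = [d for d, lab, _ in distances if lab != best_label]
    margin = (other[0] - best_dist) if other else float("inf")
    ties = [t for t in distances if abs(t[0] - best_dist) < 1e-9]
    if len({lab for _, lab, _ in ties}) > 1:
        chosen = min(ties, key=lambda t: t[2])
        logger.warning(
            "%s classification tie at %.3f Å; assigning label %r of exemplar %d",
            feature,
            best_dist,
            chosen[1],
            chosen[2],
        )
        return chosen[1], 0.0
    return best_label, margin


def classify_kinase_conformation(
    model: StructureCoords,
    motif_segments: SegmentMap,
    reference_library: Sequence[tuple[StructureCoords, dict[str, str]]],
) -> KinaseCall:
    """Assign a_loop and ac_helix in/out labels by nearest reference exemplar.

    For each exemplar the model is superposed on the kinase core (all
    residues outside the motif segments), then the motif Cα RMSD is measured;
    each feature takes the label of its nearest exemplar. Exact ties go to
    the lower-index exemplar with a warning and zero margin.
    """
    if not reference_library:
        raise MetricError("empty kinase reference library")
    motif_res = motif_segments.residues(motif_segments.motif_names())
    if not motif_res:
        raise MetricError("segment map defines no kinase motifs")
    missing = motif_res - set(model.residue_ids.tolist())
    if missing:
        raise MetricError(
            f"model is missing motif residues: {sorted(missing)[:5]}..."
        )
    features = {
        "a_loop": motif_segments.residues(
            [n for n in ("a_loop", "DFG") if n in motif_segments]
        ),
        "ac_helix": motif_segments.residues(["ac_helix"])
        if "ac_helix" in motif_segments
        else set(),
    }
    core = set(model.residue_ids.tolist()) - motif_res
    dists: dict[str, list[tuple[float, str, int]]] = {f: [] for f in features}
    for idx, (ref, labels) in enumerate(reference_library):
        rot, trans, _ = kabsch_superpose(model, ref, core)
        for feature, residues in features.items():
            if not residues or labels.get(feature) in (None, "unknown"):
                continue
            common = np.intersect1d(
                np.intersect1d(model.residue_ids, ref.residue_ids),
                sorted(residues),
            )
            if common.size == 0:
                raise StructureError(
                    f"exemplar {idx}: no common {feature} motif residues"
                )
            d = _rmsd_after(model, ref, rot, trans, common)
            dists[feature].append((d, labels[feature], idx))
    calls: dict[str, tuple[str, float]] = {}
    for feature in ("a_loop", "ac_helix"):
        if not dists[feature]:
            raise MetricError(f"no exemplar in library carries a {feature} label")
        calls[feature] = _nearest_label(dists[feature], feature)
    return KinaseCall(
        a_loop=calls["a_loop"][0],
        ac_helix=calls["ac_helix"][0],
        a_loop_margin=calls["a_loop"][1],
        ac_helix_margin=calls["ac_helix"][1],
    )
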