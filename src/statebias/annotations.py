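"""Uniform record model for GPCR and kinase template annotations.

Template chains come with functional annotations: a GPCRdb-style activation
state (``Active``, ``Inactive``, ``Intermediate``, or complexed with
``G protein`` / ``Arrestin``) for receptors, or KLIFS-style conformational
features (DFG, aC-helix, K–E salt bridge, activation loop) for kinases.
Every source of annotations — the packaged fixture TSV store or a remote web
API — is funnelled into the same :class:`TemplateRecord` so that selection
and evaluation never see source-specific schemas.

The fixture store is a tab-separated table with a fixed header
(:data:`TSV_COLUMNS`), one row per template chain; empty label cells are
read as ``unknown``, never dropped.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .segments import SegmentMap

GPCR_STATES = ("Active", "Inactive", "Intermediate", "G protein", "Arrestin", "unknown")
DFG_VALUES = ("out", "in", "out-like", "unknown")
AC_HELIX_VALUES = ("out", "in", "unknown")
SALT_BRIDGE_VALUES = ("yes", "no", "unknown")
A_LOOP_VALUES = ("in", "out", "unknown")

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")

TSV_COLUMNS = (
    "pdb_id",
    "chain_id",
    "sequence",
    "rank_score",
    "seq_identity",
    "family",
    "subfamily",
    "gpcr_state",
    "dfg",
    "ac_helix",
    "salt_bridge",
    "a_loop",
    "coords_path",
)


class AnnotationError(ValueError):
    """Malformed annotation source or record."""


@dataclass(frozen=True)
class TemplateRecord:
    """One annotated template chain.

    A record is typed by whichever label block is populated: GPCR records
    carry a known ``gpcr_state``, kinase records a known ``dfg``. The
    ``rank_score`` is the upstream template-search ranking (higher is
    better); ``seq_identity`` is percent identity to the query in [0, 100].
    """

    pdb_id: str
    chain_id: str
    sequence: str = ""
    rank_score: float = 0.0
    seq_identity: float = 0.0
    family: str = ""
    subfamily: str = ""
    gpcr_state: str = "unknown"
    dfg: str = "unknown"
    ac_helix: str = "unknown"
    salt_bridge: str = "unknown"
    a_loop: str = "unknown"
    coords_path: str = ""

    def __post_init__(self) -> None:
        if not _PDB_ID_RE.match(self.pdb_id):
            raise AnnotationError(f"invalid pdb_id {self.pdb_id!r}")
        if not (0.0 <= self.seq_identity <= 100.0):
            raise AnnotationError(
                f"{self.pdb_id}_{self.chain_id}: seq_identity "
                f"{self.seq_identity} outside [0, 100]"
            )
        if self.rank_score < 0:
            raise AnnotationError(
                f"{self.pdb_id}_{self.chain_id}: negative rank_score"
            )
        for fname, value, allowed in (
            ("gpcr_state", self.gpcr_state, GPCR_STATES),
            ("dfg", self.dfg, DFG_VALUES),
            ("ac_helix", self.ac_helix, AC_HELIX_VALUES),
            ("salt_bridge", self.salt_bridge, SALT_BRIDGE_VALUES),
            ("a_loop", self.a_loop, A_LOOP_VALUES),
        ):
            if value not in allowed:
                raise AnnotationError(
                    f"{self.pdb_id}_{self.chain_id}: unrecognized {fname} "
                    f"value {value!r} (allowed: {', '.join(allowed)})"
                )
        if self.gpcr_state == "unknown" and self.dfg == "unknown":
            raise AnnotationError(
                f"{self.pdb_id}_{self.chain_id}: record carries neither a "
                "GPCR activation state nor a kinase DFG label"
            )

    @property
    def label(self) -> str:
        return f"{self.pdb_id}_{self.chain_id}"

    @property
    def is_gpcr(self) -> bool:
        return self.gpcr_state != "unknown"

    @property
    def is_kinase(self) -> bool:
        return self.dfg != "unknown"


@dataclass(frozen=True)
class AnnotationSource:
    """Where annotations come from: a fixture table or a remote API."""

    kind: str  # fixture | gpcrdb_api | klifs_api
    location: str
    cache_dir: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixture", "gpcrdb_api", "klifs_api"):
            raise AnnotationError(f"unknown source kind {self.kind!r}")


def _parse_row(row: dict[str, str], row_number: int) -> TemplateRecord:
    def label(col: str) -> str:
        v = (row.get(col) or "").strip()
        return v if v else "unknown"

    try:
        return TemplateRecord(
            pdb_id=(row.get("pdb_id") or "").strip(),
            chain_id=(row.get("chain_id") or "").strip(),
            sequence=(row.get("sequence") or "").strip(),
            rank_score=float(row.get("rank_score") or 0.0),
            seq_identity=float(row.get("seq_identity") or 0.0),
            family=(row.get("family") or "").strip(),
            subfamily=(row.get("subfamily") or "").strip(),
            gpcr_state=label("gpcr_state"),
            dfg=label("dfg"),
            ac_helix=label("ac_helix"),
            salt_bridge=label("salt_bridge"),
            a_loop=label("a_loop"),
            coords_path=(row.get("coords_path") or "").strip(),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, AnnotationError):
            raise AnnotationError(f"row {row_number}: {exc}") from None
        raise AnnotationError(f"row {row_number}: malformed field ({exc})") from None


def load_annotations(source: AnnotationSource) -> list[TemplateRecord]:
    """Load template records from a source, preserving row order.

    Unknown labels are kept as ``unknown``; rows are never dropped silently.
    Raises :class:`AnnotationError` naming the offending row on malformed
    input and ``OSError`` naming the path on unreadable sources.
    """
    if source.kind != "fixture":
        raise AnnotationError(
            f"source kind {source.kind!r} requires a remote client; use "
            "GpcrdbClient/KlifsClient and pass their records directly"
        )
    path = Path(source.location)
    if not path.is_file():
        raise FileNotFoundError(f"annotation fixture not readable: {path}")
    records: list[TemplateRecord] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "pdb_id" not in reader.fieldnames:
            raise AnnotationError(f"{path}: missing TSV header with pdb_id column")
        for i, row in enumerate(reader, start=2):  # header is line 1
            records.append(_parse_row(row, i))
    return records


def write_annotations(records: Iterable[TemplateRecord], path: str | Path) -> None:
    """Serialize records to the fixture TSV dialect (lossless round-trip)."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for rec in records:
            writer.writerow([getattr(rec, col) for col in TSV_COLUMNS])


def fetch_segment_map(source: AnnotationSource, query_id: str) -> SegmentMap:
    """Retrieve the named residue ranges (TM helices or kinase motifs) for a query.

    The fixture format is a JSON object mapping query identifiers to
    ``{segment_name: [start, end]}`` in 1-based inclusive numbering.
    """
    if source.kind != "fixture":
        raise AnnotationError("segment maps are only served from fixture sources")
    path = Path(source.location)
    if not path.is_file():
        raise FileNotFoundError(f"segment-map fixture not readable: {path}")
    payload = json.loads(path.read_text())
    if query_id not in payload:
        raise LookupError(f"query {query_id!r} not present in {path}")
    return SegmentMap({n: (int(b[0]), int(b[1])) for n, b in payload[query_id].items()})


# --------------------------------------------------------------------------
# Remote-API adapters. These map web-server payloads onto TemplateRecord and
# are exercised in tests only through an injected transport; all downstream
# logic is source-agnostic.
# --------------------------------------------------------------------------

Transport = Callable[[str], bytes]


def _default_transport(url: str) -> bytes:
    import urllib.request

    with urllib.request.urlopen(url, timeout=30) as resp:  # pragma: no cover
        return resp.read()


# GPCRdb structure payloads separate the refined "state" from the bound
# signalling partner; both collapse into the single gpcr_state enum here.
# "agonist"-type states map to Active, "inverse-agonist" to Inactive; a bound
# G protein or arrestin takes precedence as its own label. This mapping is
# this package's reading of the public schema, not a vendored one.
_GPCRDB_STATE_MAP = {
    "active": "Active",
    "inactive": "Inactive",
    "intermediate": "Intermediate",
}


@dataclass
class GpcrdbClient:
    """Minimal GPCRdb structure-annotation client behind the record model."""

    base_url: str = "https://gpcrdb.org/services"
    transport: Transport = field(default=_default_transport)

    def fetch_records(self, receptor_family: str) -> list[TemplateRecord]:
        raw = self.transport(f"{self.base_url}/structure/")
        rows = json.loads(raw.decode())
        records = []
        for row in rows:
            state = str(row.get("state", "")).strip().lower()
            partner = str(row.get("signalling_protein", "")).strip().lower()
            if "arrestin" in partner:
                gpcr_state = "Arrestin"
            elif partner.startswith("g"):
                gpcr_state = "G protein"
            else:
                gpcr_state = _GPCRDB_STATE_MAP.get(state, "unknown")
            records.append(
                TemplateRecord(
                    pdb_id=str(row["pdb_code"]).strip(),
                    chain_id=str(row.get("preferred_chain", "A")).strip() or "A",
                    sequence=str(row.get("sequence", "")),
                    rank_score=float(row.get("rank_score", 0.0)),
                    seq_identity=float(row.get("seq_identity", 0.0)),
                    family=receptor_family,
                    subfamily=str(row.get("protein", "")),
                    gpcr_state=gpcr_state,
                    coords_path=str(row.get("coords_path", "")),
                )
            )
        return records


@dataclass
class KlifsClient:
    """Minimal KLIFS kinase-conformation client behind the record model."""

    base_url: str = "https://klifs.net/api"
    transport: Transport = field(default=_default_transport)

    def fetch_records(self, kinase_family: str) -> list[TemplateRecord]:
        raw = self.transport(f"{self.base_url}/structures_list")
        rows = json.loads(raw.decode())
        records = []
        for row in rows:
            records.append(
                TemplateRecord(
                    pdb_id=str(row["pdb"]).strip(),
                    chain_id=str(row.get("chain", "A")).strip() or "A",
                    sequence=str(row.get("sequence", "")),
                    rank_score=float(row.get("rank_score", 0.0)),
                    seq_identity=float(row.get("seq_identity", 0.0)),
                    family=kinase_family,
                    subfamily=str(row.get("kinase", "")),
                    dfg=str(row.get("dfg", "unknown")).strip().lower() or "unknown",
                    ac_helix=str(row.get("ac_helix", "unknown")).strip().lower()
                    or "unknown",
                    salt_bridge=str(row.get("salt_bridge", "unknown")).strip().lower()
                    or "unknown",
                    a_loop=str(row.get("a_loop", "unknown")).strip().lower()
                    or "unknown",
                    coords_path=str(row.get("coords_path", "")),
                )
            )
        return records
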