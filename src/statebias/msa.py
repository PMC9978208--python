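"""A3M alignments and the three MSA interventions used to bias predictions.

Template-based biasing only works when the evolutionary signal in the MSA
does not overrule the templates. Three interventions weaken it selectively:

* **shallow subsampling** — keep only a small number of "cluster" rows plus
  "extra" rows, drawn at random (query always retained);
* **noMSA** — gap out every non-query row over the columns covered by the
  selected templates, so those regions become purely template-driven;
* **SPEACH-style masking** — generate one alignment variant per placement of
  a sliding window of masked columns, perturbing a different region each time.

A3M convention: the first row is the query; uppercase letters and ``-`` are
match columns (one per query residue), lowercase letters are insertions
relative to the query and do not count toward match-column length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class MsaError(ValueError):
    """Malformed alignment or invalid MSA operation."""


def match_length(row: str) -> int:
    """Number of match columns in an A3M row (lowercase insertions excluded)."""
    return sum(1 for c in row if not c.islower())


def _match_positions(row: str) -> list[int]:
    """String index of each match column, in order."""
    return [i for i, c in enumerate(row) if not c.islower()]


@dataclass(frozen=True)
class Msa:
    """Query-anchored alignment with provenance.

    ``rows[0]`` is the query and contains no gaps; all rows share the same
    match-column length. ``provenance`` records which interventions produced
    this alignment (``raw``, ``subsampled``, ``nomsa``, ``speach_masked``)
    together with their parameters.
    """

    query_id: str
    headers: tuple[str, ...]
    rows: tuple[str, ...]
    provenance: str = "raw"
    params: dict = field(default_factory=dict)
    #: anchored MSAs start with the ungapped query row; the "extra rows"
    #: block of a shallow subsample is unanchored (disjoint from clusters)
    anchored: bool = True

    def __post_init__(self) -> None:
        if self.anchored and len(self.rows) < 1:
            raise MsaError("an anchored MSA needs at least the query row")
        if len(self.headers) != len(self.rows):
            raise MsaError("headers and rows differ in length")
        if self.anchored and (
            "-" in self.rows[0] or any(c.islower() for c in self.rows[0])
        ):
            raise MsaError("query row must be ungapped with no insertions")
        widths = {match_length(row) for row in self.rows}
        if len(widths) > 1:
            bad = next(
                h for h, r in zip(self.headers, self.rows)
                if match_length(r) != match_length(self.rows[0])
            )
            raise MsaError(
                f"row {bad!r}: match-column length differs from query length"
            )
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "headers", tuple(self.headers))

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def query(self) -> str:
        if not self.anchored:
            raise MsaError("unanchored MSA block carries no query row")
        return self.rows[0]

    @property
    def query_length(self) -> int:
        return match_length(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class SubsampleSpec:
    """Counts handed to the predictor: cluster rows and extra rows."""

    n_clusters: int = 8
    n_extra: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise MsaError("n_clusters must be >= 1")
        if self.n_extra < 0:
            raise MsaError("n_extra must be >= 0")


def read_a3m(path: str | Path, query_id: str | None = None) -> Msa:
    """Parse an A3M file. The first sequence is taken as the query."""
    headers: list[str] = []
    rows: list[str] = []
    current: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            continue
        if line.startswith(">"):
            if headers:
                rows.append("".join(current))
            headers.append(line[1:].strip())
            current = []
        elif line.strip():
            current.append(line.strip())
    if headers:
        rows.append("".join(current))
    if not headers:
        raise MsaError(f"{path}: no sequences found")
    return Msa(
        query_id=query_id or headers[0].split()[0],
        headers=tuple(headers),
        rows=tuple(rows),
    )


def write_a3m(msa: Msa, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for header, row in zip(msa.headers, msa.rows):
            handle.write(f">{header}\n{row}\n")


def subsample(msa: Msa, spec: SubsampleSpec) -> tuple[Msa, Msa]:
    """Draw a shallow MSA: (cluster rows with query first, extra rows).

    The two draws are disjoint, uniform without replacement, and fully
    reproducible from ``spec.seed``. Shortfalls (depth smaller than the
    requested counts) are tolerated and simply yield fewer rows.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF]))
    others = np.arange(1, msa.depth)
    rng.shuffle(others)
    n_cluster_others = min(spec.n_clusters - 1, len(others))
    cluster_idx = [0] + sorted(others[:n_cluster_others].tolist())
    remaining = sorted(others[n_cluster_others:].tolist())
    n_extra = min(spec.n_extra, len(remaining))
    extra_idx = remaining[:n_extra]

    def take(indices: Sequence[int], tag: str) -> Msa:
        return Msa(
            query_id=msa.query_id,
            headers=tuple(msa.headers[i] for i in indices),
            rows=tuple(msa.rows[i] for i in indices),
            provenance="subsampled",
            params={
                "role": tag,
                "n_clusters": spec.n_clusters,
                "n_extra": spec.n_extra,
                "seed": spec.seed,
            },
            anchored=(tag == "cluster"),
        )

    return take(cluster_idx, "cluster"), take(extra_idx, "extra")


def remove_msa_over_templates(msa: Msa, covered_columns: Iterable[int]) -> Msa:
    """Gap out non-query rows at template-covered query columns (noMSA).

    ``covered_columns`` are 1-based match-column indices. The query row and
    all uncovered columns are untouched; depth is unchanged. Idempotent.
    """
    covered = sorted(set(int(c) for c in covered_columns))
    length = msa.query_length
    if covered and (covered[0] < 1 or covered[-1] > length):
        raise MsaError(
            f"covered column outside [1, {length}]: "
            f"{covered[0] if covered[0] < 1 else covered[-1]}"
        )
    covered_set = set(covered)
    new_rows = [msa.rows[0]]
    for row in msa.rows[1:]:
        chars = list(row)
        for col_number, str_index in enumerate(_match_positions(row), start=1):
            if col_number in covered_set:
                chars[str_index] = "-"
        new_rows.append("".join(chars))
    return replace(
        msa,
        rows=tuple(new_rows),
        provenance="nomsa",
        params={"n_covered": len(covered_set)},
    )


def speach_mask_variants(
    msa: Msa, window: int, stride: int | None = None
) -> list[Msa]:
    """Sliding-window masked alignment variants.

    Each variant masks exactly ``window`` consecutive match columns in every
    non-query row. Windows start at 1 and advance by ``stride`` (default:
    ``window``, i.e. non-overlapping); the final window is right-aligned so
    the union of windows covers every column.
    """
    if window <= 0:
        raise MsaError("window must be positive")
    length = msa.query_length
    if window > length:
        raise MsaError(f"window {window} exceeds query length {length}")
    stride = window if stride is None else stride
    if stride <= 0:
        raise MsaError("stride must be positive")
    starts: list[int] = []
    pos = 1
    while pos + window - 1 <= length:
        starts.append(pos)
        pos += stride
    last = length - window + 1
    if not starts or starts[-1] != last:
        starts.append(last)
    variants = []
    for start in starts:
        cols = range(start, start + window)
        masked = remove_msa_over_templates(msa, cols)
        variants.append(
            replace(
                masked,
                provenance="speach_masked",
                params={"window": window, "stride": stride, "start": start},
            )
        )
    return variants
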