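"""Named residue-range maps (transmembrane helices, kinase motifs).

A :class:`SegmentMap` assigns names to inclusive, 1-based residue ranges of a
query protein: ``TM1``..``TM7`` for a GPCR, or ``DFG`` / ``ac_helix`` /
``a_loop`` for a kinase. Ranges must not overlap; residues outside every
segment are implicitly "loop" (GPCR mode) or "core" (kinase mode).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class SegmentError(ValueError):
    """Invalid or inconsistent segment definition."""


# Kinase motif segments recognised by the conformational classifier.
KINASE_MOTIFS = ("DFG", "ac_helix", "a_loop")


@dataclass(frozen=True)
class SegmentMap:
    """Non-overlapping named residue ranges in 1-based query numbering.

    Parameters
    ----------
    segments
        Mapping from segment name to ``(start, end)`` inclusive bounds.
    """

    segments: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[int, int]] = {}
        for name, bounds in self.segments.items():
            start, end = int(bounds[0]), int(bounds[1])
            if start < 1 or end < start:
                raise SegmentError(
                    f"segment {name!r}: invalid range [{start}, {end}] "
                    "(1-based, start <= end required)"
                )
            clean[str(name)] = (start, end)
        spans = sorted(clean.items(), key=lambda kv: kv[1])
        for (name_a, (_, end_a)), (name_b, (start_b, _)) in zip(spans, spans[1:]):
            if start_b <= end_a:
                raise SegmentError(
                    f"segments {name_a!r} and {name_b!r} overlap"
                )
        object.__setattr__(self, "segments", clean)

    def __len__(self) -> int:
        return len(self.segments)

    def __contains__(self, name: str) -> bool:
        return name in self.segments

    def names(self) -> list[str]:
        return list(self.segments)

    def residues(self, names: Iterable[str] | None = None) -> set[int]:
        """Set of residue indices covered by the named segments (all if None)."""
        picked = self.segments if names is None else {
            n: self._get(n) for n in names
        }
        out: set[int] = set()
        for start, end in picked.values():
            out.update(range(start, end + 1))
        return out

    def tm_names(self) -> list[str]:
        """Names of transmembrane-helix segments (``TM``-prefixed)."""
        return [n for n in self.segments if n.upper().startswith("TM")]

    def motif_names(self) -> list[str]:
        """Kinase motif segments present in this map."""
        return [n for n in KINASE_MOTIFS if n in self.segments]

    def span(self) -> tuple[int, int]:
        """Lowest and highest residue index covered by any segment."""
        if not self.segments:
            raise SegmentError("empty segment map has no span")
        starts, ends = zip(*self.segments.values())
        return min(starts), max(ends)

    def _get(self, name: str) -> tuple[int, int]:
        try:
            return self.segments[name]
        except KeyError:
            raise SegmentError(f"unknown segment {name!r}") from None

    def to_json(self, path: str | Path) -> None:
        payload = {n: list(b) for n, b in self.segments.items()}
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SegmentMap":
        payload = json.loads(Path(path).read_text())
        return cls({n: (int(b[0]), int(b[1])) for n, b in payload.items()})
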