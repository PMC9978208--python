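"""Filter, rank and select template sets matching a conformational query.

GPCR queries name an activation state; by default a request for ``Active``
also accepts templates bound to a signalling protein (``G protein`` /
``Arrestin``), since a receptor engaging a transducer is in an active-like
conformation. Kinase queries combine three KLIFS-style criteria (DFG,
aC-helix, salt bridge), each of which may be the wildcard ``all``.

Selection is either deterministic top-k — the survivors keep the upstream
template-search ranking carried in ``rank_score`` — or randomized: an
independent uniform draw of k survivors per model, which widens the region
of conformational space the ensemble samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import (
    AC_HELIX_VALUES,
    DFG_VALUES,
    GPCR_STATES,
    SALT_BRIDGE_VALUES,
    TemplateRecord,
)

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    """No templates satisfy the query, or the query itself is invalid."""


@dataclass(frozen=True)
class StateQuery:
    """User-defined functional/structural criteria plus selection policy.

    ``mode`` is ``gpcr`` (activation-state filter) or ``kinase`` (DFG /
    aC-helix / salt-bridge filters; ``all`` disables a criterion). ``k`` is
    the number of templates per model; ``randomize`` switches from top-k to
    per-model random draws seeded by ``(seed, draw_index)``.
    """

    mode: str = "gpcr"
    gpcr_state: str | None = None
    dfg: str = "all"
    ac_helix: str = "all"
    salt_bridge: str = "all"
    k: int = 4
    exclude_same_subfamily: bool = True
    randomize: bool = False
    min_rank_score: float = 0.0
    min_seq_identity: float = 0.0
    seed: int = 0
    #: treat G protein / Arrestin complexes as satisfying an Active query
    complex_counts_as_active: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("gpcr", "kinase"):
            raise SelectionError(f"unknown query mode {self.mode!r}")
        if self.k < 1:
            raise SelectionError("k must be >= 1")
        if self.min_rank_score < 0:
            raise SelectionError("min_rank_score must be >= 0")
        if self.mode == "gpcr":
            if self.gpcr_state is None:
                raise SelectionError("gpcr mode requires gpcr_state")
            if self.gpcr_state not in GPCR_STATES or self.gpcr_state == "unknown":
                raise SelectionError(f"invalid gpcr_state {self.gpcr_state!r}")
        else:
            for name, value, allowed in (
                ("dfg", self.dfg, DFG_VALUES),
                ("ac_helix", self.ac_helix, AC_HELIX_VALUES),
                ("salt_bridge", self.salt_bridge, SALT_BRIDGE_VALUES),
            ):
                if value != "all" and (value not in allowed or value == "unknown"):
                    raise SelectionError(f"invalid {name} value {value!r}")

    def accepted_gpcr_states(self) -> set[str]:
        assert self.gpcr_state is not None
        accepted = {self.gpcr_state}
        if self.complex_counts_as_active and self.gpcr_state == "Active":
            accepted |= {"G protein", "Arrestin"}
        return accepted

    def describe_filters(self) -> str:
        if self.mode == "gpcr":
            parts = [f"gpcr_state in {sorted(self.accepted_gpcr_states())}"]
        else:
            parts = [
                f"{name}={value}"
                for name, value in (
                    ("dfg", self.dfg),
                    ("ac_helix", self.ac_helix),
                    ("salt_bridge", self.salt_bridge),
                )
                if value != "all"
            ] or ["no kinase feature filter"]
        if self.exclude_same_subfamily:
            parts.append("exclude_same_subfamily")
        if self.min_rank_score > 0:
            parts.append(f"rank_score>={self.min_rank_score}")
        if self.min_seq_identity > 0:
            parts.append(f"seq_identity>={self.min_seq_identity}")
        return ", ".join(parts)


@dataclass(frozen=True)
class TemplateSet:
    """An ordered set of templates selected for one model."""

    records: tuple[TemplateRecord, ...]
    query: StateQuery
    draw_index: int = 0

    def __post_init__(self) -> None:
        if len(self.records) > self.query.k:
            raise SelectionError(
                f"template set of size {len(self.records)} exceeds k={self.query.k}"
            )
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]


def _matches(record: TemplateRecord, query: StateQuery) -> bool:
    if query.mode == "gpcr":
        return record.gpcr_state in query.accepted_gpcr_states()
    for want, have in (
        (query.dfg, record.dfg),
        (query.ac_helix, record.ac_helix),
        (query.salt_bridge, record.salt_bridge),
    ):
        if want != "all" and have != want:
            return False
    return True


def filter_candidates(
    records: Sequence[TemplateRecord],
    query: StateQuery,
    query_subfamily: str = "",
) -> list[TemplateRecord]:
    """Keep templates matching the query's state/feature criteria, in order.

    Removes same-subfamily templates when the query asks for it and applies
    the rank-score / identity floors. Raises :class:`SelectionError` listing
    the active filters when nothing survives.
    """
    survivors = []
    for rec in records:
        if not _matches(rec, query):
            logger.info("filtered %s: state/feature mismatch", rec.label)
            continue
        if (
            query.exclude_same_subfamily
            and query_subfamily
            and rec.subfamily == query_subfamily
        ):
            logger.info("filtered %s: same subfamily %r", rec.label, rec.subfamily)
            continue
        if rec.rank_score < query.min_rank_score:
            logger.info("filtered %s: rank_score below floor", rec.label)
            continue
        if rec.seq_identity < query.min_seq_identity:
            logger.info("filtered %s: seq_identity below floor", rec.label)
            continue
        survivors.append(rec)
    if not survivors:
        raise SelectionError(
            "no templates satisfy query (active filters: "
            f"{query.describe_filters()})"
        )
    return survivors


def rank_survivors(survivors: Sequence[TemplateRecord]) -> list[TemplateRecord]:
    """Order by rank_score descending; ties broken by (pdb_id, chain_id)."""
    return sorted(
        survivors, key=lambda r: (-r.rank_score, r.pdb_id.lower(), r.chain_id)
    )


def select_top_k(
    survivors: Sequence[TemplateRecord], query: StateQuery
) -> TemplateSet:
    """First min(k, |survivors|) templates in ranking order."""
    ranked = rank_survivors(survivors)
    if len(ranked) < query.k:
        logger.warning(
            "only %d templates available for k=%d", len(ranked), query.k
        )
    return TemplateSet(records=tuple(ranked[: query.k]), query=query, draw_index=0)


def select_random_k(
    survivors: Sequence[TemplateRecord],
    query: StateQuery,
    draw_index: int = 0,
) -> TemplateSet:
    """Uniform sample of min(k, |survivors|) templates without replacement.

    Reproducible from ``(query.seed, draw_index)``; distinct draw indices
    give independent draws, so per-model template sets can be regenerated in
    any order.
    """
    if not survivors:
        raise SelectionError("cannot draw templates from an empty survivor list")
    rng = np.random.default_rng(
        np.random.SeedSequence([query.seed & 0x7FFFFFFF, draw_index])
    )
    k = min(query.k, len(survivors))
    idx = rng.choice(len(survivors), size=k, replace=False)
    picked = tuple(survivors[i] for i in sorted(idx.tolist()))
    return TemplateSet(records=picked, query=query, draw_index=draw_index)


def plan_template_sets(
    records: Sequence[TemplateRecord],
    query: StateQuery,
    n_models: int,
    query_subfamily: str = "",
) -> list[TemplateSet]:
    """One template set per model: identical top-k sets, or independent draws."""
    if n_models < 1:
        raise SelectionError("n_models must be >= 1")
    survivors = filter_candidates(records, query, query_subfamily)
    if not query.randomize:
        top = select_top_k(survivors, query)
        return [
            TemplateSet(records=top.records, query=query, draw_index=i)
            for i in range(n_models)
        ]
    return [select_random_k(survivors, query, draw_index=i) for i in range(n_models)]
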