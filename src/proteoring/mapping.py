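"""Resolve experiment records to positions in the reference.

The reference may list the same protein id in several sets (a protein can
belong to more than one functionally annotated complex, or to several baits'
prey lists in a lenticular comparison).  *Reappearance mapping* controls how
such redundancy is drawn:

* **ON** -- every occurrence of a matched prey yields an arc (redundant view;
  shows overlap between sets).
* **OFF** -- only the first occurrence, in reference-file order (lowest set
  index, then entry index), yields an arc (non-redundant view; shows what is
  new relative to earlier sets).

Preys absent from the reference are never fatal: they are reported in the
:class:`MappingResult` and logged as warnings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

from proteoring.formats import (
    ColorScheme,
    Experiment,
    ExperimentRecord,
    RGB,
    Reference,
)

logger = logging.getLogger(__name__)


class Occurrence(NamedTuple):
    """A position in the reference: (set index, entry index), both 0-based."""

    set_index: int
    entry_index: int


@dataclass(frozen=True)
class MappedArc:
    """One drawable interaction: an experiment record resolved to one occurrence."""

    record_index: int
    arc_class: str
    prey_id: str
    occurrence: Occurrence


@dataclass
class MappingResult:
    """Resolved arcs plus the unmatched-prey report.

    Every experiment record ends up either in ``arcs`` (one or more entries
    when reappearance is on) or in ``unmatched``, never both.
    """

    arcs: list[MappedArc] = field(default_factory=list)
    unmatched: list[tuple[int, str]] = field(default_factory=list)
    reappearance_on: bool = True


def find_occurrences(prey_id: str, reference: Reference) -> list[Occurrence]:
    """All reference positions whose protein id equals ``prey_id``.

    Ordered by (set_index, entry_index) ascending, i.e. reference-file
    order.  Absence is a valid result (empty list), not an error.
    """
    hits: list[Occurrence] = []
    for si, pset in enumerate(reference.sets):
        for ei, entry in enumerate(pset.entries):
            if entry.protein_id == prey_id:
                hits.append(Occurrence(si, ei))
    return hits


def dedupe_records(e: Experiment) -> tuple[Experiment, list[tuple[int, ExperimentRecord]]]:
    """Collapse exact duplicate rows to their first occurrence.

    Returns the deduplicated experiment and a report of removals as
    ``(original_index, record)`` pairs.  Rows differing in arc class are
    distinct records, not duplicates.
    """
    seen: set[ExperimentRecord] = set()
    kept: list[ExperimentRecord] = []
    removed: list[tuple[int, ExperimentRecord]] = []
    for i, rec in enumerate(e.records):
        if rec in seen:
            removed.append((i, rec))
            logger.warning(
                "duplicate experiment row %d (%s,%s,%s) removed",
                i, rec.bait_id, rec.arc_class, rec.prey_id,
            )
        else:
            seen.add(rec)
            kept.append(rec)
    return Experiment(bait_id=e.bait_id, records=kept), removed


def map_experiment(
    e: Experiment,
    reference: Reference,
    reappearance_on: bool = True,
    dedupe: bool = True,
) -> MappingResult:
    """Resolve every experiment record against the reference.

    With ``reappearance_on`` each record contributes one arc per occurrence
    of its prey, in occurrence order; otherwise only the first occurrence.
    Records whose prey is absent go to ``unmatched``.  Arcs are ordered by
    (record index, occurrence order).

    ``dedupe`` collapses exact duplicate rows first (they would overdraw
    invisibly); record indices in the result refer to the deduplicated
    record list.
    """
    if dedupe:
        e, _ = dedupe_records(e)
    result = MappingResult(reappearance_on=reappearance_on)
    for i, rec in enumerate(e.records):
        occs = find_occurrences(rec.prey_id, reference)
        if not occs:
            logger.warning("prey %r (record %d) not found in reference", rec.prey_id, i)
            result.unmatched.append((i, rec.prey_id))
            continue
        if not reappearance_on:
            occs = occs[:1]
        for occ in occs:
            result.arcs.append(MappedArc(i, rec.arc_class, rec.prey_id, occ))
    return result


def assign_set_colors(reference: Reference, scheme: ColorScheme) -> list[RGB]:
    """One color per protein set, cycling the scheme when sets outnumber colors."""
    if not scheme.colors:
        raise ValueError("color scheme is empty")
    n = len(scheme.colors)
    return [scheme.colors[k % n] for k in range(len(reference.sets))]
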