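"""Seeded synthetic fixtures: experiment / reference / color-scheme trios.

The generator emulates the shape of a filtered AP-MS run projected onto an
annotated reference: a handful of protein sets of realistic sizes, a
controlled fraction of proteins shared between two sets (the cross-set
redundancy that reappearance mapping makes visible), a controlled fraction
of experiment preys absent from the reference, and optional exact-duplicate
experiment rows.  Ground-truth mapping counts are recorded *by construction*
at generation time, so the whole pipeline can be verified against an
independent bookkeeping rather than against itself.

All randomness flows through one ``random.Random(seed)`` stream; the same
spec yields byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from proteoring.formats import (
    ColorScheme,
    Experiment,
    ExperimentRecord,
    ProteinEntry,
    ProteinSet,
    Reference,
    write_color_scheme,
    write_experiment,
    write_reference,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic trio.

    ``cross_set_duplication`` is the fraction of base reference entries that
    are copied into a second set; ``unmatched_fraction`` the fraction of
    experiment rows whose prey is absent from the reference;
    ``n_duplicate_rows`` exact-copy rows injected into the experiment.
    """

    n_sets: int = 4
    set_sizes: Optional[Sequence[int]] = None
    size_range: tuple[int, int] = (5, 15)
    n_ppi: int = 12
    n_ivtk: int = 4
    cross_set_duplication: float = 0.2
    unmatched_fraction: float = 0.1
    n_duplicate_rows: int = 0
    bait_id: str = "BAIT"
    seed: int = 0

    def __post_init__(self):
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.set_sizes is not None and len(self.set_sizes) != self.n_sets:
            raise ValueError("set_sizes length must equal n_sets")
        if not 0 <= self.cross_set_duplication <= 1:
            raise ValueError("cross_set_duplication must be in [0, 1]")
        if not 0 <= self.unmatched_fraction <= 1:
            raise ValueError("unmatched_fraction must be in [0, 1]")
        if min(self.n_ppi, self.n_ivtk, self.n_duplicate_rows) < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class FixtureTruth:
    """Mapping counts recorded while the fixture was built."""

    expected_on_arcs: int
    expected_off_arcs: int
    expected_unmatched: int
    duplicate_rows_injected: int


class Fixture(NamedTuple):
    experiment: str
    reference: str
    scheme: str
    truth: FixtureTruth


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build one deterministic trio of input files plus its ground truth.

    Raises ``ValueError`` on infeasible specs, e.g. more matched experiment
    rows of one class than distinct reference proteins, or cross-set
    duplication requested with a single set.
    """
    rng = random.Random(spec.seed)

    sizes = list(spec.set_sizes) if spec.set_sizes is not None else [
        rng.randint(*spec.size_range) for _ in range(spec.n_sets)
    ]
    if any(s < 0 for s in sizes):
        raise ValueError("set sizes must be >= 0")

    total_base = sum(sizes)
    protein_ids = [f"P{idx:05d}" for idx in range(total_base)]
    sets: list[ProteinSet] = []
    cursor = 0
    for k, size in enumerate(sizes):
        name = f"Set {chr(ord('A') + k % 26)}{k // 26 if k >= 26 else ''}"
        entries = [
            ProteinEntry(f"protein {pid}", pid, name)
            for pid in protein_ids[cursor:cursor + size]
        ]
        sets.append(ProteinSet(name=name, entries=entries))
        cursor += size

    # duplicate a fraction of entries into a second, different set
    n_dup = int(round(spec.cross_set_duplication * total_base))
    occurrence_count = {pid: 1 for pid in protein_ids}
    if n_dup > 0:
        if spec.n_sets < 2:
            raise ValueError("cross_set_duplication needs at least 2 sets")
        home_set = {}
        for si, s in enumerate(sets):
            for e in s.entries:
                home_set[e.protein_id] = si
        for pid in rng.sample(protein_ids, n_dup):
            choices = [i for i in range(spec.n_sets) if i != home_set[pid]]
            target = rng.choice(choices)
            sets[target].entries.append(ProteinEntry(f"protein {pid}", pid, sets[target].name))
            occurrence_count[pid] += 1

    reference = Reference(sets=sets)

    # experiment rows: classes interleaved, then shuffled
    n_total = spec.n_ppi + spec.n_ivtk
    if n_total == 0:
        raise ValueError("experiment needs at least one row (n_ppi + n_ivtk > 0)")
    classes = ["ppi"] * spec.n_ppi + ["ivtk"] * spec.n_ivtk
    rng.shuffle(classes)
    n_unmatched = int(round(spec.unmatched_fraction * n_total))
    unmatched_slots = set(rng.sample(range(n_total), n_unmatched))

    matched_per_class = {
        "ppi": sum(1 for i, c in enumerate(classes) if c == "ppi" and i not in unmatched_slots),
        "ivtk": sum(1 for i, c in enumerate(classes) if c == "ivtk" and i not in unmatched_slots),
    }
    for cls, need in matched_per_class.items():
        if need > len(protein_ids):
            raise ValueError(
                f"infeasible: {need} matched {cls} rows but only "
                f"{len(protein_ids)} distinct reference proteins"
            )

    picks = {
        cls: iter(rng.sample(protein_ids, matched_per_class[cls]))
        for cls in ("ppi", "ivtk")
    }
    records: list[ExperimentRecord] = []
    expected_on = expected_off = 0
    for i, cls in enumerate(classes):
        if i in unmatched_slots:
            prey = f"ABSENT{i:04d}"
        else:
            prey = next(picks[cls])
            expected_off += 1
            expected_on += occurrence_count[prey]
        records.append(ExperimentRecord(spec.bait_id, cls, prey))

    # inject exact duplicate rows (removed again by dedupe, by design)
    base = list(records)
    for _ in range(spec.n_duplicate_rows):
        victim = rng.choice(base)
        records.insert(rng.randint(0, len(records)), victim)

    experiment = Experiment(bait_id=spec.bait_id, records=records)

    n_colors = max(2, min(spec.n_sets, 6)) if spec.n_sets > 1 else 1
    scheme = ColorScheme(
        colors=[
            (rng.randrange(256), rng.randrange(256), rng.randrange(256))
            for _ in range(n_colors)
        ]
    )

    truth = FixtureTruth(
        expected_on_arcs=expected_on,
        expected_off_arcs=expected_off,
        expected_unmatched=n_unmatched,
        duplicate_rows_injected=spec.n_duplicate_rows,
    )
    return Fixture(
        experiment=write_experiment(experiment),
        reference=write_reference(reference),
        scheme=write_color_scheme(scheme),
        truth=truth,
    )
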