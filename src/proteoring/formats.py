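"""Readers and writers for the three comma-delimited input dialects.

An AP-MS visualization run consumes three plain-text files:

* **experiment** -- one row per interaction: ``bait_id,arc_class,prey_id``
  where ``arc_class`` is ``ppi`` (protein-protein interaction, colored arc)
  or ``ivtk`` (in vitro kinase substrate, black arc).  A file describes a
  single bait.
* **reference** -- FASTA-like blocks of protein sets.  A line starting with
  ``>`` names a set; subsequent rows are ``desc_left,protein_id,desc_right``.
  The same protein id may occur in several sets; that redundancy is what
  reappearance mapping exploits.
* **color scheme** -- rows of ``R,G,B`` integers in [0, 255], cycled over
  sets when sets outnumber colors.

Fields are split on literal commas; no quoting dialect exists, so ids and
descriptions must not contain commas.  Identifiers are compared as exact,
case-sensitive strings after stripping surrounding whitespace only.  Blank
lines are skipped everywhere; LF and CRLF are both accepted on read, LF is
written; a leading UTF-8 byte-order mark is tolerated.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Union

logger = logging.getLogger(__name__)

ARC_CLASSES = ("ppi", "ivtk")

RGB = tuple[int, int, int]

TextSource = Union[str, IO[str], Iterable[str]]


class ParseError(ValueError):
    """A malformed input line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ExperimentRecord:
    """One classed bait->prey interaction row."""

    bait_id: str
    arc_class: str  # 'ppi' or 'ivtk'
    prey_id: str

    def __post_init__(self):
        if self.arc_class not in ARC_CLASSES:
            raise ValueError(f"arc_class must be one of {ARC_CLASSES}, got {self.arc_class!r}")
        if not self.bait_id or not self.prey_id:
            raise ValueError("bait_id and prey_id must be non-empty")


@dataclass
class Experiment:
    """A single-bait AP-MS experiment: an ordered list of interaction rows."""

    bait_id: str
    records: list[ExperimentRecord] = field(default_factory=list)


@dataclass(frozen=True)
class ProteinEntry:
    """A reference row: the id in column 2 flanked by free-text descriptions."""

    desc_left: str
    protein_id: str
    desc_right: str

    def __post_init__(self):
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")


@dataclass
class ProteinSet:
    """A named, ordered group of proteins (one colored sector in the diagram)."""

    name: str
    entries: list[ProteinEntry] = field(default_factory=list)


@dataclass
class Reference:
    """Ordered protein sets the experiment is projected onto."""

    sets: list[ProteinSet] = field(default_factory=list)

    def total_entries(self) -> int:
        return sum(len(s.entries) for s in self.sets)


@dataclass
class ColorScheme:
    """Ordered RGB triples, cycled over protein sets."""

    colors: list[RGB] = field(default_factory=list)


def _iter_lines(stream: TextSource) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, line) with newlines and a leading BOM stripped.

    Blank lines are skipped but still counted.
    """
    if isinstance(stream, str):
        lines: Iterable[str] = io.StringIO(stream)
    else:
        lines = stream
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if i == 1 and line.startswith("\ufeff"):
            line = line[1:]
        if line.strip() == "":
            continue
        yield i, line


def _split3(line: str, lineno: int, what: str) -> tuple[str, str, str]:
    fields = line.split(",")
    if len(fields) != 3:
        raise ParseError(
            f"{what} row must have exactly 3 comma-delimited fields, got {len(fields)}",
            lineno,
        )
    a, b, c = (f.strip() for f in fields)
    return a, b, c


def parse_experiment(stream: TextSource) -> Experiment:
    """Parse an experiment file into a single-bait :class:`Experiment`.

    Raises :class:`ParseError` on rows without exactly three fields, on an
    unknown arc class, on more than one distinct bait id ("multiple baits"),
    and on an input with no records at all.
    """
    records: list[ExperimentRecord] = []
    bait_id: str | None = None
    for lineno, line in _iter_lines(stream):
        bait, arc_class, prey = _split3(line, lineno, "experiment")
        if not bait:
            raise ParseError("empty bait_id", lineno)
        if not prey:
            raise ParseError("empty prey_id", lineno)
        if arc_class not in ARC_CLASSES:
            raise ParseError(
                f"arc_class must be 'ppi' or 'ivtk', got {arc_class!r}", lineno
            )
        if bait_id is None:
            bait_id = bait
        elif bait != bait_id:
            raise ParseError(
                f"multiple baits: file declares bait {bait_id!r} but row has {bait!r}",
                lineno,
            )
        records.append(ExperimentRecord(bait, arc_class, prey))
    if bait_id is None:
        raise ParseError("no records: experiment file is empty")
    return Experiment(bait_id=bait_id, records=records)


def parse_reference(stream: TextSource) -> Reference:
    """Parse a FASTA-like reference file into ordered protein sets.

    Each ``>`` line opens a new set named by the remainder of the line;
    subsequent 3-column rows become its entries, in file order.  An empty
    set is legal but logged as a warning.
    """
    sets: list[ProteinSet] = []
    for lineno, line in _iter_lines(stream):
        if line.startswith(">"):
            name = line[1:].strip()
            if not name:
                raise ParseError("protein set header has an empty name", lineno)
            sets.append(ProteinSet(name=name))
            continue
        if not sets:
            raise ParseError("data row before any '>' set header", lineno)
        left, protein_id, right = _split3(line, lineno, "reference")
        if not protein_id:
            raise ParseError("empty protein_id in column 2", lineno)
        sets[-1].entries.append(ProteinEntry(left, protein_id, right))
    if not sets:
        raise ParseError("reference file defines no protein sets")
    for s in sets:
        if not s.entries:
            logger.warning("protein set %r is empty", s.name)
    return Reference(sets=sets)


def parse_color_scheme(stream: TextSource) -> ColorScheme:
    """Parse rows of ``R,G,B`` integers into a :class:`ColorScheme`."""
    colors: list[RGB] = []
    for lineno, line in _iter_lines(stream):
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(
                f"color row must have 3 comma-delimited integers, got {len(parts)} fields",
                lineno,
            )
        triple = []
        for p in parts:
            p = p.strip()
            try:
                v = int(p)
            except ValueError:
                raise ParseError(f"color component {p!r} is not an integer", lineno) from None
            if not 0 <= v <= 255:
                raise ParseError(f"color component {v} outside [0, 255]", lineno)
            triple.append(v)
        colors.append((triple[0], triple[1], triple[2]))
    if not colors:
        raise ParseError("color scheme is empty")
    return ColorScheme(colors=colors)


def _emit(text: str, stream: IO[str] | None) -> str:
    if stream is not None:
        stream.write(text)
    return text


def write_experiment(e: Experiment, stream: IO[str] | None = None) -> str:
    """Serialize an experiment; refuses to write one with zero records."""
    if not e.records:
        raise ValueError("refusing to write an experiment with no records")
    text = "".join(f"{r.bait_id},{r.arc_class},{r.prey_id}\n" for r in e.records)
    return _emit(text, stream)


def write_reference(r: Reference, stream: IO[str] | None = None) -> str:
    if not r.sets:
        raise ValueError("refusing to write a reference with no protein sets")
    out: list[str] = []
    for s in r.sets:
        out.append(f">{s.name}\n")
        for entry in s.entries:
            out.append(f"{entry.desc_left},{entry.protein_id},{entry.desc_right}\n")
    return _emit("".join(out), stream)


def write_color_scheme(c: ColorScheme, stream: IO[str] | None = None) -> str:
    if not c.colors:
        raise ValueError("refusing to write an empty color scheme")
    text = "".join(f"{r},{g},{b}\n" for r, g, b in c.colors)
    return _emit(text, stream)
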