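"""Reading and writing RepeatMasker-style repeat annotations.

Coordinates follow the RepeatMasker convention throughout: 1-based, fully
closed intervals, on both the genomic sequence and the family consensus.
Minus-strand rows (printed with orientation ``C`` and consensus coordinates
in ``(left) end begin`` order) are normalised on parse so that
``consensus_start < consensus_end`` always holds; the strand field records
the orientation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "RepeatHit",
    "RepeatAnnotation",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "filter_families",
]


@dataclass(frozen=True)
class RepeatHit:
    """One repeat-annotation row: a fragment of a repeat copy in a genome."""

    sequence_id: str
    genome_start: int
    genome_end: int
    strand: str
    family: str
    repeat_class: str
    consensus_start: int
    consensus_end: int
    divergence: float = 0.0
    score: float = 0.0
    hit_id: str = ""
    overlap_flag: bool = False

    def __post_init__(self) -> None:
        if self.genome_start >= self.genome_end:
            raise ValueError(
                f"genome interval must satisfy start < end, got "
                f"[{self.genome_start}, {self.genome_end}]"
            )
        if self.consensus_start >= self.consensus_end:
            raise ValueError(
                f"consensus interval must satisfy start < end, got "
                f"[{self.consensus_start}, {self.consensus_end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def genome_length(self) -> int:
        return self.genome_end - self.genome_start + 1


class RepeatAnnotation:
    """An ordered collection of :class:`RepeatHit` for one genome.

    Hits are sorted by ``(sequence_id, genome_start)`` on construction and
    the order is preserved thereafter.
    """

    def __init__(self, hits: Iterable[RepeatHit], source_label: str = "") -> None:
        self.hits: list[RepeatHit] = sorted(
            hits, key=lambda h: (h.sequence_id, h.genome_start, h.genome_end)
        )
        self.source_label = source_label
        ids = [h.hit_id for h in self.hits]
        if len(set(ids)) != len(ids):
            raise ValueError("hit_id values must be unique within an annotation")

    @property
    def family_catalog(self) -> frozenset[str]:
        return frozenset(h.family for h in self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[RepeatHit]:
        return iter(self.hits)

    def by_sequence(self) -> dict[str, list[RepeatHit]]:
        out: dict[str, list[RepeatHit]] = {}
        for h in self.hits:
            out.setdefault(h.sequence_id, []).append(h)
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RepeatAnnotation)
            and self.hits == other.hits
            and self.source_label == other.source_label
        )

    def __repr__(self) -> str:
        return (
            f"RepeatAnnotation({len(self.hits)} hits, "
            f"{len(self.family_catalog)} families, {self.source_label!r})"
        )


_HEADER = (
    "   SW   perc perc perc  query      position in query"
    "              matching       repeat            position in repeat\n"
    "score   div. del. ins.  sequence     begin    end          (left)"
    "   repeat         class/family      begin  end    (left)     ID\n"
    "\n"
)


def _parse_row(fields: Sequence[str], lineno: int) -> RepeatHit:
    try:
        score = float(fields[0])
        divergence = float(fields[1])
        sequence_id = fields[4]
        genome_start = int(fields[5])
        genome_end = int(fields[6])
        orientation = fields[8]
        family = fields[9]
        repeat_class = fields[10]
        if orientation == "+":
            strand = "+"
            consensus_start = int(fields[11])
            consensus_end = int(fields[12])
        elif orientation in ("C", "-"):
            # complement rows print consensus as (left) end begin
            strand = "-"
            consensus_end = int(fields[12])
            consensus_start = int(fields[13])
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        hit_id = fields[14] if len(fields) > 14 else str(lineno)
        overlap = len(fields) > 15 and fields[15] == "*"
        return RepeatHit(
            sequence_id=sequence_id,
            genome_start=genome_start,
            genome_end=genome_end,
            strand=strand,
            family=family,
            repeat_class=repeat_class,
            consensus_start=min(consensus_start, consensus_end),
            consensus_end=max(consensus_start, consensus_end),
            divergence=divergence,
            score=score,
            hit_id=hit_id,
            overlap_flag=overlap,
        )
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed repeat row at line {lineno}: {exc}") from exc


def parse_repeatmasker_out(
    stream: io.TextIOBase | str | Iterable[str], source_label: str = ""
) -> RepeatAnnotation:
    """Parse a RepeatMasker ``.out`` table (or headerless equivalent).

    Header lines (anything whose first token is not a number) are skipped.
    An empty stream yields an empty annotation.  Rows flagged with the
    trailing ``*`` (higher-scoring overlap) are retained with
    ``overlap_flag=True``.  Duplicate ID values (RepeatMasker reuses the ID
    for fragments of one interrupted element) are disambiguated with a
    positional suffix so that ``hit_id`` is unique within the file.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    hits: list[RepeatHit] = []
    seen: dict[str, int] = {}
    for lineno, line in enumerate(stream, start=1):
        fields = line.split()
        if not fields:
            continue
        try:
            float(fields[0])
        except ValueError:
            continue  # header line
        hit = _parse_row(fields, lineno)
        if hit.hit_id in seen:
            seen[hit.hit_id] += 1
            hit = replace(hit, hit_id=f"{hit.hit_id}.{seen[hit.hit_id]}")
        else:
            seen[hit.hit_id] = 0
        hits.append(hit)
    return RepeatAnnotation(hits, source_label=source_label)


def write_repeatmasker_out(
    annotation: RepeatAnnotation, stream: io.TextIOBase, header: bool = True
) -> None:
    """Write an annotation as a RepeatMasker ``.out`` table."""
    if header:
        stream.write(_HEADER)
    for h in annotation:
        if h.strand == "+":
            orient, rep = "+", f"{h.consensus_start:>6} {h.consensus_end:>5} {'(0)':>7}"
        else:
            orient, rep = "C", f"{'(0)':>6} {h.consensus_end:>5} {h.consensus_start:>7}"
        star = " *" if h.overlap_flag else ""
        stream.write(
            f"{h.score:>7.0f} {h.divergence:>5.1f}  0.0  0.0  "
            f"{h.sequence_id:<12} {h.genome_start:>8} {h.genome_end:>8} (0) "
            f"{orient} {h.family:<16} {h.repeat_class:<18} {rep} {h.hit_id:>6}{star}\n"
        )


def filter_families(
    annotation: RepeatAnnotation, families: Iterable[str]
) -> RepeatAnnotation:
    """Restrict an annotation to hits from the given families.

    Families absent from the annotation's catalog trigger a warning, not an
    error (a pre-selected screening set need not occur in every genome).
    """
    fam = set(families)
    if not fam:
        raise ValueError("family set must not be empty")
    absent = fam - annotation.family_catalog
    if absent:
        warnings.warn(
            f"families not present in {annotation.source_label or 'annotation'}: "
            f"{sorted(absent)}",
            stacklevel=2,
        )
    return RepeatAnnotation(
        (h for h in annotation if h.family in fam),
        source_label=annotation.source_label,
    )
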