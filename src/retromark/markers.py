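"""Presence/absence retroposon marker matrices.

A marker is one retroposon insertion at one orthologous genomic locus, scored
across taxa as present (``+``), absent (``-``), missing data (``?``) or
deleted (``d``).  A locus-specific deletion destroys the insertion site, so
the presence state there is unknowable; deletions are therefore treated as
missing for all downstream counting and tree scoring.

The module packages a transcription of a published 21-taxon x 53-marker
marsupial matrix (all seven marsupial orders plus a human outgroup scored
absent throughout) as :func:`load_marsupial_matrix`.  Because two different
taxa in that table share the abbreviation "Pt", taxon identity is positional
and the packaged fixture uses full species names.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Unicode minus sign, as printed in the source table.
_MINUS = "−"

PRESENT, ABSENT, MISSING, DELETED = "+", "-", "?", "d"
_SYMBOLS = {PRESENT, ABSENT, MISSING, DELETED}


class MarkerState(enum.Enum):
    """State of one marker in one taxon."""

    present = "+"
    absent = "-"
    missing = "?"
    deleted = "d"

    @classmethod
    def from_symbol(cls, symbol: str) -> "MarkerState":
        symbol = {_MINUS: "-", "1": "+", "0": "-"}.get(symbol, symbol)
        try:
            return cls(symbol)
        except ValueError:
            raise ValueError(f"unknown marker symbol {symbol!r}") from None

    @property
    def scored(self) -> bool:
        """Whether the state pins down presence or absence."""
        return self in (MarkerState.present, MarkerState.absent)


@dataclass(frozen=True)
class SupportPattern:
    """Counts of markers supporting a hypothesis edge and its two rivals."""

    k: int
    l: int = 0
    m: int = 0

    def __post_init__(self) -> None:
        if min(self.k, self.l, self.m) < 0:
            raise ValueError("support counts must be non-negative")

    def __str__(self) -> str:
        return f"[{self.k} {self.l} {self.m}]"


class MarkerMatrix:
    """Taxa x markers table of presence/absence states.

    Parameters
    ----------
    taxa:
        Ordered taxon labels (unique).
    markers:
        Ordered marker identifiers (unique).
    states:
        T x M array-like of symbols drawn from ``{+, -, ?, d}``.
    outgroup:
        Optional taxon label used to root parsimony analyses.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        markers: Sequence[str],
        states: Sequence[Sequence[str]],
        outgroup: str | None = None,
    ) -> None:
        self.taxa = list(taxa)
        self.markers = list(markers)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker identifiers must be unique")
        arr = np.asarray(states, dtype="<U1")
        if arr.shape != (len(self.taxa), len(self.markers)):
            raise ValueError(
                f"state table shape {arr.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.markers)} markers"
            )
        bad = ~np.isin(arr, sorted(_SYMBOLS))
        if bad.any():
            t, m = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid state {arr[t, m]!r} at taxon {self.taxa[t]!r}, "
                f"marker {self.markers[m]!r}"
            )
        if outgroup is not None and outgroup not in self.taxa:
            raise ValueError(f"outgroup {outgroup!r} not among taxa")
        self.states = arr
        self.outgroup = outgroup
        self._taxon_index = {t: i for i, t in enumerate(self.taxa)}
        self._marker_index = {m: j for j, m in enumerate(self.markers)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def state(self, taxon: str, marker: str) -> MarkerState:
        i = self._taxon_index[taxon]
        j = self._marker_index[marker]
        return MarkerState.from_symbol(self.states[i, j])

    def to_binary(self) -> np.ndarray:
        """Encode as int8: present=1, absent=0, missing/deleted=-1.

        Deletions are coded missing: the site is destroyed, so presence of
        the original insertion cannot be scored either way.
        """
        out = np.full(self.states.shape, -1, dtype=np.int8)
        out[self.states == PRESENT] = 1
        out[self.states == ABSENT] = 0
        return out

    def subset_taxa(self, taxa: Sequence[str]) -> "MarkerMatrix":
        rows = [self._taxon_index[t] for t in taxa]
        og = self.outgroup if self.outgroup in taxa else None
        return MarkerMatrix(list(taxa), self.markers, self.states[rows], og)

    def present_set(self, marker: str) -> frozenset[str]:
        j = self._marker_index[marker]
        return frozenset(
            t for i, t in enumerate(self.taxa) if self.states[i, j] == PRESENT
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MarkerMatrix)
            and self.taxa == other.taxa
            and self.markers == other.markers
            and bool(np.array_equal(self.states, other.states))
            and self.outgroup == other.outgroup
        )

    def __repr__(self) -> str:
        return f"MarkerMatrix({self.n_taxa} taxa x {self.n_markers} markers)"


def parse_matrix(
    stream: io.TextIOBase | str,
    outgroup: str | None = None,
    delimiter: str = "\t",
) -> MarkerMatrix:
    """Read a delimited marker table (rows = taxa, header = marker IDs).

    Accepts symbols ``+ - ? d``, the typographic minus, and binary ``1 0 ?``
    coding.  Raises ``ValueError`` naming the offending row/column for ragged
    rows or unknown symbols.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if not lines:
        raise ValueError("empty marker table")
    header = lines[0].split(delimiter)
    markers = header[1:]
    taxa: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(delimiter)
        if len(parts) != len(header):
            raise ValueError(
                f"row {lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        taxa.append(parts[0])
        row = []
        for col, sym in enumerate(parts[1:], start=2):
            try:
                row.append(MarkerState.from_symbol(sym.strip()).value)
            except ValueError:
                raise ValueError(
                    f"row {lineno}, column {col}: unknown symbol {sym!r}"
                ) from None
        rows.append(row)
    return MarkerMatrix(taxa, markers, rows, outgroup=outgroup)


def write_matrix(matrix: MarkerMatrix, stream: io.TextIOBase, delimiter: str = "\t") -> None:
    """Write a matrix in the delimited format read by :func:`parse_matrix`."""
    stream.write(delimiter.join(["taxon", *matrix.markers]) + "\n")
    for i, taxon in enumerate(matrix.taxa):
        stream.write(delimiter.join([taxon, *matrix.states[i]]) + "\n")


def write_nexus(matrix: MarkerMatrix, stream: io.TextIOBase) -> None:
    """Write a NEXUS data block (binary coding; ``?`` for missing/deleted)."""
    symbol = {PRESENT: "1", ABSENT: "0", MISSING: "?", DELETED: "?"}
    stream.write("#NEXUS\nBEGIN DATA;\n")
    stream.write(
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_markers};\n"
    )
    stream.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
    stream.write("    MATRIX\n")
    width = max(len(t) for t in matrix.taxa) + 2
    for i, taxon in enumerate(matrix.taxa):
        row = "".join(symbol[s] for s in matrix.states[i])
        stream.write(f"    {taxon.replace(' ', '_'):<{width}}{row}\n")
    stream.write("    ;\nEND;\n")


def load_marsupial_matrix() -> MarkerMatrix:
    """Load the packaged 21-taxon x 53-marker marsupial matrix.

    Taxon order matches the source table; the human outgroup is scored
    absent for every marker.
    """
    text = (
        resources.files("retromark.data")
        .joinpath("marsupial_markers.tsv")
        .read_text()
    )
    return parse_matrix(text, outgroup="Homo_sapiens")


def _clade_support(
    matrix: MarkerMatrix, clade: frozenset[str], frame: frozenset[str]
) -> int:
    """Markers present in every scored clade taxon, absent in every scored
    frame taxon outside the clade; markers unscored on either side skipped."""
    inside = [matrix._taxon_index[t] for t in sorted(clade)]
    outside = [matrix._taxon_index[t] for t in sorted(frame - clade)]
    count = 0
    for j in range(matrix.n_markers):
        col = matrix.states[:, j]
        ins = [col[i] for i in inside if col[i] in (PRESENT, ABSENT)]
        outs = [col[i] for i in outside if col[i] in (PRESENT, ABSENT)]
        if not ins or not outs:
            continue
        if all(s == PRESENT for s in ins) and all(s == ABSENT for s in outs):
            count += 1
    return count


def support_pattern(
    matrix: MarkerMatrix,
    focal_clade: Iterable[str],
    frame: Iterable[str],
    alternatives: tuple[Iterable[str], Iterable[str]] | None = None,
) -> SupportPattern:
    """Count markers supporting a focal clade against its local rivals.

    ``k`` counts markers present in every scored taxon of ``focal_clade`` and
    absent in every scored taxon of ``frame`` outside it; missing and deleted
    states are compatible with either side and are skipped, and a marker with
    no scored taxon on one side is ignored.  When ``alternatives`` names the
    two rival clades of the local trichotomy, ``l`` and ``m`` count their
    supporting markers the same way (the rooted-triplet test); otherwise the
    outside is a single unresolved group and ``l = m = 0``.
    """
    focal = frozenset(focal_clade)
    frame_set = frozenset(frame)
    if not focal:
        raise ValueError("focal clade must not be empty")
    if not focal < frame_set:
        raise ValueError("focal clade must be a proper subset of the frame")
    unknown = frame_set - set(matrix.taxa)
    if unknown:
        raise ValueError(f"taxa not in matrix: {sorted(unknown)}")
    k = _clade_support(matrix, focal, frame_set)
    l = m = 0
    if alternatives is not None:
        alt1, alt2 = (frozenset(a) for a in alternatives)
        l = _clade_support(matrix, alt1, frame_set)
        m = _clade_support(matrix, alt2, frame_set)
    return SupportPattern(k=k, l=l, m=m)


# ---------------------------------------------------------------------------
# Orthologous-locus validation
# ---------------------------------------------------------------------------

GAP = "-"


@dataclass(frozen=True)
class ElementCall:
    """Annotation of a candidate element in one taxon of a locus alignment."""

    span: tuple[int, int]  # 0-based inclusive alignment columns
    strand: str = "+"
    subtype: str = ""
    tsd: str | None = None


@dataclass
class MarkerLocus:
    """One orthologous locus alignment carrying a candidate insertion.

    ``alignment`` maps taxon -> gapped sequence (equal lengths over
    ``ACGTN-``); ``candidate_span`` gives the 0-based inclusive alignment
    columns of the putative element in the reference taxon.  ``calls`` may
    carry per-taxon element annotations (span/strand/subtype/TSD) from a
    repeat screen; taxa without a call are assessed from the alignment alone.
    """

    locus_id: str
    alignment: Mapping[str, str]
    candidate_span: tuple[int, int]
    element_subtype: str = ""
    element_strand: str = "+"
    tsd: str | None = None
    calls: Mapping[str, ElementCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.alignment.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        lo, hi = self.candidate_span
        n = lengths.pop() if lengths else 0
        if not (0 <= lo <= hi < n):
            raise ValueError(f"candidate span {self.candidate_span} out of bounds")


def locus_from_fasta(
    stream,
    candidate_span: tuple[int, int],
    locus_id: str = "locus",
    element_subtype: str = "",
    element_strand: str = "+",
    tsd: str | None = None,
) -> MarkerLocus:
    """Build a :class:`MarkerLocus` from a gapped FASTA alignment.

    Record IDs become taxon names; sequences must be pre-aligned (equal
    lengths).  ``candidate_span`` gives the element's 0-based inclusive
    alignment columns in the reference taxon.
    """
    from Bio import SeqIO

    alignment = {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(stream, "fasta")
    }
    if not alignment:
        raise ValueError("no FASTA records found")
    return MarkerLocus(
        locus_id=locus_id,
        alignment=alignment,
        candidate_span=candidate_span,
        element_subtype=element_subtype,
        element_strand=element_strand,
        tsd=tsd,
    )


@dataclass(frozen=True)
class TaxonValidation:
    state: MarkerState
    failed_criteria: tuple[int, ...] = ()


# The six orthology criteria, by number:
#   1 identical insertion point  2 identical orientation  3 identical subtype
#   4 concurrent flanking repeats (TSD)  5 shared diagnostic indels
#   6 consistency across representative species
_FLANK = 10          # columns of flank examined on each side
_OCCUPANCY = 0.5     # minimum non-gap fraction for "sequence present"


def _gap_columns(seq: str, lo: int, hi: int) -> frozenset[int]:
    return frozenset(c for c in range(lo, hi + 1) if seq[c] == GAP)


def _flank_aligned(seq: str, lo: int, hi: int) -> bool:
    left = seq[max(0, lo - _FLANK): lo]
    right = seq[hi + 1: hi + 1 + _FLANK]
    flank = left + right
    if not flank:
        return False
    return sum(c != GAP for c in flank) / len(flank) >= _OCCUPANCY


def validate_marker(
    locus: MarkerLocus,
    reference_taxon: str,
    slop: int = 2,
) -> tuple[dict[str, MarkerState], dict[str, TaxonValidation]]:
    """Score each taxon of a locus alignment against six orthology criteria.

    A taxon is called present only if every checkable criterion passes: the
    element occupies the reference columns within ``slop``, matches strand and
    subtype, reproduces the recorded target-site duplication, and shares the
    reference's diagnostic indels.  Absent requires a clean empty site (flanks
    aligned, span gapped, no partial element).  Anything else is missing, and
    the report lists the criteria that failed.
    """
    if reference_taxon not in locus.alignment:
        raise ValueError(f"alignment lacks reference taxon {reference_taxon!r}")
    lo, hi = locus.candidate_span
    ref_seq = locus.alignment[reference_taxon]
    ref_call = locus.calls.get(reference_taxon) or ElementCall(
        span=(lo, hi), strand=locus.element_strand,
        subtype=locus.element_subtype, tsd=locus.tsd,
    )
    ref_gaps = _gap_columns(ref_seq, lo, hi)
    if all(c == GAP for c in ref_seq[lo: hi + 1]):
        raise ValueError("reference taxon does not carry the element")

    states: dict[str, MarkerState] = {}
    report: dict[str, TaxonValidation] = {}
    for taxon, seq in locus.alignment.items():
        if taxon == reference_taxon:
            states[taxon] = MarkerState.present
            report[taxon] = TaxonValidation(MarkerState.present)
            continue
        call = locus.calls.get(taxon)
        span_seq = seq[lo: hi + 1]
        occupancy = sum(c != GAP for c in span_seq) / len(span_seq)
        flanks_ok = _flank_aligned(seq, lo, hi)

        if call is None and occupancy == 0.0 and flanks_ok:
            states[taxon] = MarkerState.absent
            report[taxon] = TaxonValidation(MarkerState.absent)
            continue

        failed: list[int] = []
        if call is not None:
            if abs(call.span[0] - ref_call.span[0]) > slop or \
               abs(call.span[1] - ref_call.span[1]) > slop:
                failed.append(1)
            if call.strand != ref_call.strand:
                failed.append(2)
            if call.subtype and ref_call.subtype and call.subtype != ref_call.subtype:
                failed.append(3)
            if call.tsd is not None and ref_call.tsd is not None and \
               call.tsd != ref_call.tsd:
                failed.append(4)
        else:
            if occupancy < _OCCUPANCY:
                failed.append(6)  # partial/unclear element: inconsistent site
        if not flanks_ok:
            failed.append(6)
        if occupancy > 0 and _gap_columns(seq, lo, hi) != ref_gaps and 1 not in failed:
            failed.append(5)

        if not failed and occupancy > 0:
            states[taxon] = MarkerState.present
            report[taxon] = TaxonValidation(MarkerState.present)
        else:
            states[taxon] = MarkerState.missing
            report[taxon] = TaxonValidation(
                MarkerState.missing, tuple(sorted(set(failed)))
            )
    return states, report
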