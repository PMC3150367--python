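"""Protein multiple-sequence-alignment data model and reference-frame projection.

An :class:`Alignment` is an ordered set of equal-length gapped protein
sequences.  Every user-facing coordinate is 1-based in the frame of a chosen
reference sequence; internal column indices are 0-based half-open.  The
reference frame also carries an optional alternative numbering (piecewise
offsets), so positions can be reported in two numbering systems at once, as
is customary when two homologous structures use different residue numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import AlignmentError, FormatError

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: accepted but excluded from frequency counts
AMBIGUOUS = "XBZ"
_VALID = set(AMINO_ACIDS) | set(AMBIGUOUS) | {GAP}


@dataclass
class Alignment:
    """Ordered gapped protein sequences with optional subfamily labels.

    Invariants: equal lengths >= 1, unique ids, residues drawn from the
    20-letter alphabet plus ambiguity codes and the gap symbol.
    """

    ids: list[str]
    seqs: list[str]
    label_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seqs:
            raise AlignmentError("alignment must contain at least one sequence")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in count")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1 or 0 in lengths:
            raise AlignmentError(f"ragged or empty sequences: lengths {sorted(lengths)}")
        if len(set(self.ids)) != len(self.ids):
            dups = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dups}")
        for sid, seq in zip(self.ids, self.seqs):
            bad = set(seq) - _VALID
            if bad:
                raise FormatError(
                    f"illegal character(s) {sorted(bad)} in sequence {sid!r}"
                )

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    def row(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(seq_id) from None

    def column(self, i: int) -> str:
        if not 0 <= i < self.length:
            raise IndexError(f"column {i} out of range 0..{self.length - 1}")
        return "".join(s[i] for s in self.seqs)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n{seq}\n")


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(path, label_map: dict[str, str] | None = None) -> Alignment:
    """Read an aligned FASTA file; '.' gaps are normalized to '-'.

    Raises FormatError for empty files, duplicate ids or illegal characters,
    and AlignmentError for ragged sequence lengths.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [_normalize(str(r.seq)) for r in records]
    return Alignment(ids, seqs, dict(label_map or {}))


@dataclass
class ReferenceFrame:
    """Mapping from alignment columns to 1-based reference positions.

    ``col_to_ref[c]`` is the reference position of column ``c`` or None for
    columns where the reference has a gap (insertions relative to it).
    ``offset_map`` is a list of ``(start, end, offset)`` triples (1-based,
    inclusive) defining the alternative numbering.
    """

    ref_id: str
    col_to_ref: list[int | None]
    offset_map: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        mapped = [p for p in self.col_to_ref if p is not None]
        if mapped != sorted(mapped) or len(set(mapped)) != len(mapped):
            raise AlignmentError("reference positions must be strictly increasing")

    @property
    def ref_length(self) -> int:
        return sum(p is not None for p in self.col_to_ref)

    def column_of(self, pos: int) -> int:
        """Alignment column holding reference position ``pos``."""
        for c, p in enumerate(self.col_to_ref):
            if p == pos:
                return c
        raise IndexError(f"reference position {pos} not mapped")

    def dual_position(self, pos: int) -> tuple[int, int]:
        """Return ``(primary, alternative)`` numbering for a reference position."""
        if not 1 <= pos <= self.ref_length:
            raise IndexError(f"position {pos} outside 1..{self.ref_length}")
        for start, end, offset in self.offset_map:
            if start <= pos <= end:
                return pos, pos + offset
        return pos, pos

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tref_pos\talt_pos\n")
            for c, p in enumerate(self.col_to_ref):
                alt = self.dual_position(p)[1] if p is not None else ""
                fh.write(f"{c}\t{'' if p is None else p}\t{alt}\n")


def project_to_reference(
    aln: Alignment,
    ref_id: str,
    offset_map: list[tuple[int, int, int]] | None = None,
) -> tuple[Alignment, ReferenceFrame]:
    """Drop all columns where the reference sequence has a gap.

    Returns the projected alignment (length = ungapped reference length) and
    a ReferenceFrame over the ORIGINAL columns, so insertions relative to the
    reference remain identifiable (col_to_ref is None there).
    """
    ref_row = aln.row(ref_id)  # KeyError if absent
    if set(ref_row) == {GAP}:
        raise AlignmentError(f"reference {ref_id!r} is all gaps")
    col_to_ref: list[int | None] = []
    pos = 0
    keep: list[int] = []
    for c, ch in enumerate(ref_row):
        if ch == GAP:
            col_to_ref.append(None)
        else:
            pos += 1
            col_to_ref.append(pos)
            keep.append(c)
    projected = Alignment(
        list(aln.ids),
        ["".join(s[c] for c in keep) for s in aln.seqs],
        dict(aln.label_map),
    )
    frame = ReferenceFrame(ref_id, col_to_ref, list(offset_map or []))
    return projected, frame
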