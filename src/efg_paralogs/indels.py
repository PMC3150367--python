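"""Indel-region detection in subfamily alignments.

Maximal per-sequence gap runs (GapBlocks) are clustered into indel regions:
connected components of column-overlapping blocks supported by at least
``min_support`` sequences (default 5).  Regions whose member blocks share
identical endpoints are length-conserved; the rest are variable-length.
Polarity is assigned against a reference frame: gaps over reference-mapped
columns are deletions (members lack residues the reference has), gaps over
unmapped columns are insertions.  Terminal gap runs are excluded by default
as likely sequence-fragment artifacts.

A small diagnostic-motif scanner detects short subfamily-diagnostic
insertions (e.g. the three-residue "KDG" insertion in the switch I region
characteristic of the spdEFG1 subfamily).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .alignment import GAP, Alignment, ReferenceFrame


@dataclass(frozen=True)
class GapBlock:
    """Maximal gap run of one sequence over half-open columns [start, end)."""

    seq_id: str
    start: int
    end: int

    def overlaps(self, other: "GapBlock") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class IndelRegion:
    start: int
    end: int  # half-open columns
    member_ids: frozenset[str]
    blocks: tuple[GapBlock, ...]
    polarity: str | None = None  # insertion | deletion
    label: str = ""
    size_class: str = "variable-length"

    @property
    def support(self) -> int:
        return len(self.member_ids)


def gap_blocks(aln: Alignment, include_terminal: bool = True) -> list[GapBlock]:
    """All maximal gap runs; optionally excluding runs touching alignment ends."""
    blocks = []
    L = aln.length
    for sid, seq in zip(aln.ids, aln.seqs):
        start = None
        for c, ch in enumerate(seq + "\x00"):  # sentinel flushes trailing run
            if ch == GAP:
                if start is None:
                    start = c
            elif start is not None:
                if include_terminal or (start > 0 and c < L):
                    blocks.append(GapBlock(sid, start, c))
                start = None
    return blocks


def detect_indel_regions(
    aln: Alignment,
    min_support: int = 5,
    include_terminal: bool = False,
) -> list[IndelRegion]:
    """Cluster overlapping gap blocks into regions with >= min_support members.

    Regions are maximal unions of column-overlapping blocks, sorted by start
    column; identical member endpoints upgrade size_class to conserved-length.
    """
    blocks = sorted(gap_blocks(aln, include_terminal), key=lambda b: (b.start, b.end))
    regions: list[IndelRegion] = []
    component: list[GapBlock] = []
    comp_end = -1
    for b in blocks + [GapBlock("\x00sentinel", 1 << 60, 1 << 60)]:
        if component and b.start >= comp_end:
            regions.append(_make_region(component))
            component = []
        component.append(b)
        comp_end = max(comp_end, b.end)
    regions = [r for r in regions if r.support >= min_support]
    for i, r in enumerate(regions, start=1):
        if not r.label:
            r.label = str(i)
    return regions


def _make_region(blocks: list[GapBlock]) -> IndelRegion:
    start = min(b.start for b in blocks)
    end = max(b.end for b in blocks)
    identical = len({(b.start, b.end) for b in blocks}) == 1
    return IndelRegion(
        start=start,
        end=end,
        member_ids=frozenset(b.seq_id for b in blocks),
        blocks=tuple(blocks),
        size_class="conserved-length" if identical else "variable-length",
    )


def assign_polarity(region: IndelRegion, frame: ReferenceFrame) -> list[IndelRegion]:
    """Split a region at mapped/unmapped boundaries and set polarity.

    Columns mapped in the reference frame carry deletions (the members lack
    residues the reference has); unmapped columns carry insertions (residues
    absent from the reference).  A region straddling both is split.
    """
    runs: list[tuple[int, int, bool]] = []
    for c in range(region.start, region.end):
        mapped = frame.col_to_ref[c] is not None
        if runs and runs[-1][2] == mapped and runs[-1][1] == c:
            runs[-1] = (runs[-1][0], c + 1, mapped)
        else:
            runs.append((c, c + 1, mapped))
    out = []
    for start, end, mapped in runs:
        sub_blocks = tuple(
            b for b in region.blocks if b.start < end and start < b.end
        )
        out.append(
            replace(
                region,
                start=start,
                end=end,
                member_ids=frozenset(b.seq_id for b in sub_blocks),
                blocks=sub_blocks,
                polarity="deletion" if mapped else "insertion",
                size_class=(
                    "conserved-length"
                    if len({(b.start, b.end) for b in sub_blocks}) == 1
                    else "variable-length"
                ),
            )
        )
    return out


def label_regions(
    regions: list[IndelRegion],
    frame: ReferenceFrame,
    label_map: list[tuple[int, int, str]] | None = None,
) -> list[IndelRegion]:
    """Attach user labels (e.g. Roman numerals) from reference intervals;
    regions outside the map keep ordinal labels."""
    if not label_map:
        return regions
    for r in regions:
        ref_positions = [
            frame.col_to_ref[c]
            for c in range(r.start, r.end)
            if frame.col_to_ref[c] is not None
        ]
        anchor = ref_positions[0] if ref_positions else None
        if anchor is None:
            # insertion: anchor at the last mapped position to its left
            for c in range(r.start - 1, -1, -1):
                if frame.col_to_ref[c] is not None:
                    anchor = frame.col_to_ref[c]
                    break
        if anchor is None:
            continue
        for start, end, label in label_map:
            if start <= anchor <= end:
                r.label = label
                break
    return regions


def detect_diagnostic_insertion(
    aligned_seq: str,
    frame: ReferenceFrame,
    window: tuple[int, int],
    consensus: str = "KDG",
    max_mismatch: int = 1,
) -> tuple[bool, tuple[int, int] | None]:
    """Scan insertion columns inside a reference window for a short motif.

    ``window`` is a 1-based inclusive reference interval (e.g. switch I).
    Returns (found, (start_col, end_col)) for the first inserted run of
    ``len(consensus)`` residues matching with at most ``max_mismatch``
    mismatches.
    """
    if len(aligned_seq) != len(frame.col_to_ref):
        raise ValueError("sequence length does not match reference frame")
    lo, hi = window
    if lo < 1 or hi > frame.ref_length or lo > hi:
        raise IndexError(f"window {window} outside reference 1..{frame.ref_length}")
    # insertion runs anchored (by the mapped position to their left) in the window
    runs: list[tuple[int, int]] = []
    last_mapped = 0
    start = None
    n_cols = len(frame.col_to_ref)
    for c in range(n_cols + 1):
        p = frame.col_to_ref[c] if c < n_cols else -1  # sentinel: mapped
        if p is None:
            if start is None:
                start = c
        else:
            if start is not None:
                if lo - 1 <= last_mapped <= hi:
                    runs.append((start, c))
                start = None
            if p != -1:
                last_mapped = p
    k = len(consensus)
    for rs, re_ in runs:
        inserted = aligned_seq[rs:re_].replace(GAP, "")
        for i in range(0, len(inserted) - k + 1):
            sub = inserted[i : i + k]
            mism = sum(a != b for a, b in zip(sub, consensus))
            if mism <= max_mismatch:
                return True, (rs, re_)
    return False, None


def write_region_report(
    regions: list[IndelRegion],
    frame: ReferenceFrame | None,
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("label\tcolumns\tref_interval\tpolarity\tsupport\tsize_class\tmembers\n")
        for r in regions:
            if frame is not None:
                mapped = [
                    frame.col_to_ref[c]
                    for c in range(r.start, r.end)
                    if frame.col_to_ref[c] is not None
                ]
                ref_iv = f"{mapped[0]}-{mapped[-1]}" if mapped else "insertion"
            else:
                ref_iv = ""
            fh.write(
                f"{r.label}\t{r.start}-{r.end}\t{ref_iv}\t{r.polarity or ''}\t"
                f"{r.support}\t{r.size_class}\t{','.join(sorted(r.member_ids))}\n"
            )
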