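"""Per-column conservation profiling and differential-conservation typing.

A column's conservation is measured as sequence-logo information content:
``info_bits = log2(20) - H`` where ``H`` is the Shannon entropy (bits) of the
amino-acid frequencies over countable residues (gaps and ambiguity codes are
excluded from the denominator).  A position counts as conserved when the logo
height is at least ``bit_threshold`` (default 3 bits).

Two subfamily profiles of the same position are then typed:

* type I  - conserved in both subfamilies (>= 3 bits and >= 80 % each) with
  *different* top residues: different amino acids are under selection.
* type II - conserved in the second subfamily (>= 3 bits, >= 80 %) but
  relaxed in the first, with a conservation difference of at least 25
  percentage points.
* shared  - conserved in both with the same top residue.
* none    - anything else.

Categories are mutually exclusive with precedence type I > type II > shared.
Threshold comparisons use half-up integer-rounded percentages, mirroring the
integer precision at which subfamily conservation tables are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .alignment import AMINO_ACIDS, GAP, Alignment
from .errors import ConsistencyError

MAX_BITS = math.log2(20)

#: Fraction of gaps above which a column is not callable.
DEFAULT_MAX_GAP_FRACTION = 0.5


def round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass
class ColumnProfile:
    """Amino-acid frequency profile of one alignment column."""

    position: int
    freqs: dict[str, float]
    gap_fraction: float
    info_bits: float | None
    top_residue: str | None
    top_conservation_pct: float
    callable: bool = True
    n_counted: int = 0


def column_profile(
    aln: Alignment,
    column: int,
    position: int | None = None,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
    small_sample_correction: bool = False,
) -> ColumnProfile:
    """Profile one column; gaps and X/B/Z are excluded from frequencies.

    An all-gap (or all-ambiguous) column is returned flagged not-callable
    rather than raising.  ``small_sample_correction`` subtracts the standard
    (e_n = 19 / (2 ln 2 n)) bias term from the logo height.
    """
    col = aln.column(column)
    counts: dict[str, int] = {}
    gaps = 0
    for ch in col:
        if ch == GAP:
            gaps += 1
        elif ch in AMINO_ACIDS:
            counts[ch] = counts.get(ch, 0) + 1
    n = sum(counts.values())
    gap_fraction = gaps / len(col)
    pos = column + 1 if position is None else position
    if n == 0:
        return ColumnProfile(pos, {}, gap_fraction, None, None, 0.0, callable=False)
    freqs = {aa: c / n for aa, c in counts.items()}
    entropy = -sum(p * math.log2(p) for p in freqs.values())
    bits = MAX_BITS - entropy
    if small_sample_correction:
        bits = max(0.0, bits - 19.0 / (2.0 * math.log(2) * n))
    top = max(freqs, key=lambda aa: (freqs[aa], aa))
    return ColumnProfile(
        position=pos,
        freqs=freqs,
        gap_fraction=gap_fraction,
        info_bits=bits,
        top_residue=top,
        top_conservation_pct=100.0 * freqs[top],
        callable=gap_fraction <= max_gap_fraction,
        n_counted=n,
    )


def is_conserved(profile: ColumnProfile, bit_threshold: float = 3.0) -> bool:
    """True iff the logo height is at least ``bit_threshold`` bits (inclusive)."""
    if not profile.callable or profile.info_bits is None:
        warnings.warn(
            f"position {profile.position}: not callable, treated as not conserved",
            stacklevel=2,
        )
        return False
    return profile.info_bits >= bit_threshold


@dataclass
class ConservedPositionCall:
    """Typed comparison of one position between two subfamily profiles."""

    position: int
    alt_position: int | None
    category: str  # shared | type_I | type_II | none
    profile_1: ColumnProfile
    profile_2: ColumnProfile
    difference_pct: float
    domain_label: str = ""


def conservation_difference(p1_top_pct: float, p2_top_pct: float) -> float:
    """Signed difference (subfamily 2 minus subfamily 1) of top-residue
    conservation; exact integer arithmetic when both inputs are integers."""
    return p2_top_pct - p1_top_pct


def classify_position(
    p1: ColumnProfile,
    p2: ColumnProfile,
    bit_threshold: float = 3.0,
    aa_pct: float = 80.0,
    diff_pct: float = 25.0,
    alt_position: int | None = None,
    domain_label: str = "",
) -> ConservedPositionCall:
    """Type one position from its two subfamily profiles.

    All three thresholds are inclusive; percentages are rounded half-up to
    integers before comparison (table precision).
    """
    if p1.position != p2.position:
        raise ConsistencyError(
            f"profiles refer to different positions ({p1.position} vs {p2.position})"
        )
    c1 = is_conserved(p1, bit_threshold) if p1.callable else False
    c2 = is_conserved(p2, bit_threshold) if p2.callable else False
    pct1 = round_half_up(p1.top_conservation_pct)
    pct2 = round_half_up(p2.top_conservation_pct)
    diff = conservation_difference(pct1, pct2)

    if c1 and c2 and pct1 >= aa_pct and pct2 >= aa_pct and p1.top_residue != p2.top_residue:
        category = "type_I"
    elif c2 and pct2 >= aa_pct and diff >= diff_pct:
        category = "type_II"
    elif c1 and c2 and p1.top_residue == p2.top_residue:
        category = "shared"
    else:
        category = "none"
    return ConservedPositionCall(
        position=p1.position,
        alt_position=alt_position,
        category=category,
        profile_1=p1,
        profile_2=p2,
        difference_pct=diff,
        domain_label=domain_label,
    )


def classify_alignment_pair(
    aln1: Alignment,
    aln2: Alignment,
    bit_threshold: float = 3.0,
    aa_pct: float = 80.0,
    diff_pct: float = 25.0,
    offset_map: list[tuple[int, int, int]] | None = None,
    domains: dict[str, tuple[int, int]] | None = None,
) -> list[ConservedPositionCall]:
    """Classify every shared position of two reference-framed alignments."""
    if aln1.length != aln2.length:
        raise ConsistencyError(
            f"alignments have different lengths ({aln1.length} vs {aln2.length})"
        )
    from .alignment import ReferenceFrame  # local to avoid cycle at import time

    frame = ReferenceFrame("ref", list(range(1, aln1.length + 1)), list(offset_map or []))
    calls = []
    for c in range(aln1.length):
        p1 = column_profile(aln1, c)
        p2 = column_profile(aln2, c)
        alt = frame.dual_position(c + 1)[1]
        calls.append(
            classify_position(
                p1,
                p2,
                bit_threshold,
                aa_pct,
                diff_pct,
                alt_position=alt,
                domain_label=_domain_of(c + 1, domains),
            )
        )
    return calls


def _domain_of(pos: int, domains: dict[str, tuple[int, int]] | None) -> str:
    for label, (start, end) in (domains or {}).items():
        if start <= pos <= end:
            return label
    return ""


def hydropathy(residue: str, scale: dict[str, float] = KYTE_DOOLITTLE) -> float:
    """Kyte-Doolittle hydropathy index (positive = hydrophobic)."""
    try:
        return scale[residue.upper()]
    except KeyError:
        raise KeyError(f"no hydropathy index for residue {residue!r}") from None


def domain_conservation(
    conserved: list[bool],
    domains: dict[str, tuple[int, int]],
) -> dict[str, float | None]:
    """Percent of conserved positions per domain interval (1-based inclusive).

    Intervals must lie within the reference length and not overlap; an empty
    interval yields None.
    """
    length = len(conserved)
    seen: set[int] = set()
    out: dict[str, float | None] = {}
    for label, (start, end) in domains.items():
        if start > end:
            out[label] = None
            continue
        if start < 1 or end > length:
            raise IndexError(f"domain {label!r} interval {start}-{end} outside 1..{length}")
        positions = set(range(start, end + 1))
        if positions & seen:
            raise ConsistencyError(f"domain {label!r} overlaps a previous domain")
        seen |= positions
        flags = conserved[start - 1 : end]
        out[label] = 100.0 * sum(flags) / len(flags)
    return out


@dataclass
class CallTable:
    """TSV serialization of a list of ConservedPositionCall."""

    calls: list[ConservedPositionCall] = field(default_factory=list)

    HEADER = (
        "position\talt_position\tcategory\ttop1\tpct1\ttop2\tpct2\t"
        "difference\tbits1\tbits2\tdomain\thydropathy1\thydropathy2"
    )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.HEADER + "\n")
            for c in self.calls:
                h1 = _safe_hp(c.profile_1.top_residue)
                h2 = _safe_hp(c.profile_2.top_residue)
                fh.write(
                    f"{c.position}\t{c.alt_position or ''}\t{c.category}\t"
                    f"{c.profile_1.top_residue or ''}\t"
                    f"{round_half_up(c.profile_1.top_conservation_pct)}\t"
                    f"{c.profile_2.top_residue or ''}\t"
                    f"{round_half_up(c.profile_2.top_conservation_pct)}\t"
                    f"{c.difference_pct:g}\t"
                    f"{'' if c.profile_1.info_bits is None else f'{c.profile_1.info_bits:.3f}'}\t"
                    f"{'' if c.profile_2.info_bits is None else f'{c.profile_2.info_bits:.3f}'}\t"
                    f"{c.domain_label}\t{h1}\t{h2}\n"
                )


def _safe_hp(residue: str | None) -> str:
    if residue is None:
        return ""
    try:
        return f"{hydropathy(residue):g}"
    except KeyError:
        return ""
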