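"""Consensus strings, G-motif pattern grammar, and rule-based subfamily calls.

Consensus symbols use three conservation tiers per column: capital letters
above 70 %, small letters in the 60-70 % band, dashes below 60 % (the bands
partition (0, 100]: capitals are strictly above 70, small letters are
(60, 70]).  Frequencies are taken over all rows, gaps included in the
denominator, so gappy columns read as weak.

Pattern grammar (one slot per alignment position of the motif window):

* uppercase letter        - required residue ("RGITI")
* "A/B" alternatives      - required set; lowercase first letter makes the
  whole set weak ("r/k")
* lowercase letter        - weak residue: scored but never blocks a match
* "x" or "X"              - wildcard

A window matches when every required slot is satisfied.  The score is the
fraction of satisfied slots, weak slots counting half.  Ranked assignment
additionally orders equal scores by pattern specificity (more constrained
slots first) and reports residual ties explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import AMINO_ACIDS, GAP, Alignment
from .errors import ConfigError, PatternParseError

UPPER_PCT = 70.0
LOWER_PCT = 60.0


@dataclass
class ConsensusString:
    symbols: str
    upper_pct: float = UPPER_PCT
    lower_pct: float = LOWER_PCT

    def __str__(self) -> str:
        return self.symbols


def consensus_symbol(
    top_residue: str | None,
    top_pct: float,
    upper_pct: float = UPPER_PCT,
    lower_pct: float = LOWER_PCT,
) -> str:
    if top_residue is None or top_pct <= lower_pct:
        return "-"
    if top_pct > upper_pct:
        return top_residue.upper()
    return top_residue.lower()


def consensus_string(
    aln: Alignment,
    upper_pct: float = UPPER_PCT,
    lower_pct: float = LOWER_PCT,
) -> ConsensusString:
    """Three-tier consensus over all columns; all-gap columns give dashes."""
    symbols = []
    for c in range(aln.length):
        col = aln.column(c)
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP and ch in AMINO_ACIDS:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            symbols.append("-")
            continue
        top = max(counts, key=lambda aa: (counts[aa], aa))
        pct = 100.0 * counts[top] / len(col)
        symbols.append(consensus_symbol(top, pct, upper_pct, lower_pct))
    return ConsensusString("".join(symbols), upper_pct, lower_pct)


@dataclass(frozen=True)
class Slot:
    residues: frozenset[str]  # empty set = wildcard
    required: bool

    @property
    def wildcard(self) -> bool:
        return not self.residues

    @property
    def specificity(self) -> float:
        """1/|choices|; wildcards count as one of 20, weak slots half."""
        if self.wildcard:
            return 1.0 / 20.0
        s = 1.0 / len(self.residues)
        return s if self.required else 0.5 * s


@dataclass
class MotifPattern:
    name: str
    slots: tuple[Slot, ...]

    def __post_init__(self) -> None:
        if not self.slots:
            raise PatternParseError("pattern has no slots")

    def __len__(self) -> int:
        return len(self.slots)

    @property
    def specificity(self) -> float:
        return sum(s.specificity for s in self.slots)


def parse_pattern(text: str, name: str = "") -> MotifPattern:
    """Parse a motif pattern string into slots (see module docstring)."""
    slots: list[Slot] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in "xX":
            slots.append(Slot(frozenset(), required=True))
            i += 1
            continue
        if not ch.isalpha() or ch.upper() not in AMINO_ACIDS:
            raise PatternParseError(f"illegal character {ch!r}", position=i)
        required = ch.isupper()
        residues = {ch.upper()}
        i += 1
        while i < len(text) and text[i] == "/":
            if i + 1 >= len(text):
                raise PatternParseError("dangling '/'", position=i)
            alt = text[i + 1]
            if not alt.isalpha() or alt.upper() not in AMINO_ACIDS or alt in "xX":
                raise PatternParseError(f"illegal alternative {alt!r}", position=i + 1)
            residues.add(alt.upper())
            i += 2
        slots.append(Slot(frozenset(residues), required))
    return MotifPattern(name or text, tuple(slots))


def format_pattern(pattern: MotifPattern) -> str:
    """Inverse of parse_pattern (alternatives emitted in alphabetical order)."""
    parts = []
    for slot in pattern.slots:
        if slot.wildcard:
            parts.append("x")
        else:
            residues = sorted(slot.residues)
            text = "/".join(residues)
            parts.append(text if slot.required else text.lower())
    return "".join(parts)


def match_pattern(window: str, pattern: MotifPattern) -> tuple[float, bool]:
    """Score a residue window against a pattern.

    Returns (score, match): match requires every required slot satisfied;
    score is the satisfied-slot fraction with weak slots at half weight and
    wildcards always satisfied.
    """
    window = window.upper()
    if len(window) != len(pattern):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(pattern)}"
        )
    score = 0.0
    match = True
    for ch, slot in zip(window, pattern.slots):
        if slot.wildcard:
            score += 1.0
        elif ch in slot.residues:
            score += 1.0 if slot.required else 0.5
        elif slot.required:
            match = False
    return score / len(pattern), match


@dataclass
class PatternAssignment:
    pattern: MotifPattern
    score: float
    match: bool
    tied: bool = False


def assign_sub_subgroup(
    window: str, patterns: list[MotifPattern]
) -> list[PatternAssignment]:
    """Rank patterns against a motif window (best first).

    Ordering: matches before non-matches, then score, then pattern
    specificity; assignments whose (match, score) equal the best one are
    flagged tied.
    """
    if not patterns:
        raise ConfigError("empty pattern list")
    scored = []
    for p in patterns:
        score, match = match_pattern(window, p)
        scored.append(PatternAssignment(p, score, match))
    scored.sort(key=lambda a: (a.match, a.score, a.pattern.specificity), reverse=True)
    best = scored[0]
    for a in scored[1:]:
        if (
            a.match == best.match
            and a.score == best.score
            and a.pattern.specificity == best.pattern.specificity
        ):
            a.tied = best.tied = True
    return scored


def read_pattern_file(path) -> list[MotifPattern]:
    """One pattern per line: name TAB pattern; '#' comments allowed."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, text = line.partition("\t")
            if not text:
                name, text = line, line
            patterns.append(parse_pattern(text.strip(), name=name.strip()))
    return patterns


SUBFAMILIES = ("EFG_I", "spdEFG1", "spdEFG2", "EFG_II", "unresolved")


@dataclass
class SubfamilyCall:
    subfamily: str
    fired_rules: list[str] = field(default_factory=list)
    conflict: str | None = None


def classify_subfamily(
    copy_count_in_genome: int | None = None,
    in_str_operon: bool | None = None,
    has_kdg_insertion: bool | None = None,
    g2_matches_rgiti: bool | None = None,
    g2_matches_xxxsx: bool | None = None,
) -> SubfamilyCall:
    """Rule-based subfamily call from genome and motif evidence.

    Rule order: a single EFG copy in the genome is EFG I without exception;
    a switch-I KDG insertion is diagnostic for spdEFG1; residence in the str
    operon marks EFG I; a relaxed G2 (matches xxxSx but not RGITI) marks
    EFG II; otherwise unresolved.  Contradictory evidence (KDG insertion
    together with str-operon residence) is reported as unresolved with a
    conflict note.  Unknown fields (None) simply skip their rule.
    """
    trace: list[str] = []
    if has_kdg_insertion and in_str_operon:
        return SubfamilyCall(
            "unresolved",
            ["kdg_insertion", "str_operon"],
            conflict="KDG insertion and str-operon residence are mutually exclusive",
        )
    if copy_count_in_genome == 1:
        trace.append("single_copy")
        return SubfamilyCall("EFG_I", trace)
    if has_kdg_insertion:
        trace.append("kdg_insertion")
        return SubfamilyCall("spdEFG1", trace)
    if in_str_operon:
        trace.append("str_operon")
        return SubfamilyCall("EFG_I", trace)
    if g2_matches_xxxsx and g2_matches_rgiti is False:
        trace.append("g2_relaxed")
        return SubfamilyCall("EFG_II", trace)
    return SubfamilyCall("unresolved", trace)
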