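"""Synthetic inputs with controlled statistical structure for every stage.

All generators are deterministic in their seed.  The profile-alignment
generator embeds specified per-column residue frequencies by exact
largest-remainder count apportionment, so conservation percentages recovered
by the pipeline equal the specified ones to integer rounding; unspecified
columns draw from a low-conservation background whose top frequency is
capped (default 40 %), guaranteeing they never reach the 3-bit conservation
call.  Residual frequency mass at specified columns tops up the listed minor
residues in order, capped one percentage point below the top residue so the
intended top residue always stays on top; overflow goes to a single unlisted
residue.  A multinomial sampling mode exists for stochastic property tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, GAP, Alignment
from .errors import SpecError
from .fate import STOP_CODONS, LossScenario
from . import profiles

_BACKGROUND_SHAPE = (0.30, 0.25, 0.20, 0.15, 0.10)  # max 30 % < 40 % cap


@dataclass
class ProfileSpec:
    """Target per-position residue percentages for one subfamily alignment.

    ``positions`` maps a 1-based position to an ordered residue->percent
    dict: first key is the top residue, later keys are minor residues in
    residual-fill priority order.  Percent sums may be below 100; the
    remainder is assigned by the residual rule.
    """

    length: int
    n_seqs: int
    positions: dict[int, dict[str, float]] = field(default_factory=dict)
    background_max: float = 0.40

    def __post_init__(self) -> None:
        if self.n_seqs < 1 or self.length < 1:
            raise SpecError("need n_seqs >= 1 and length >= 1")
        for pos, freqs in self.positions.items():
            if not 1 <= pos <= self.length:
                raise SpecError(f"position {pos} outside 1..{self.length}")
            total = sum(freqs.values())
            if total > 100 + 1e-9:
                raise SpecError(f"position {pos}: frequencies sum to {total} > 100")
            if any(v < 0 for v in freqs.values()):
                raise SpecError(f"position {pos}: negative frequency")


def largest_remainder(targets: dict[str, float], n: int) -> dict[str, int]:
    """Apportion n items to targets (fractions summing to ~1) by largest
    remainder; deterministic tie-break by residue order in ``targets``."""
    raw = {k: v * n for k, v in targets.items()}
    counts = {k: int(np.floor(x)) for k, x in raw.items()}
    left = n - sum(counts.values())
    order = sorted(
        targets, key=lambda k: (raw[k] - counts[k], -list(targets).index(k)), reverse=True
    )
    for k in itertools.islice(itertools.cycle(order), left):
        counts[k] += 1
    return counts


def _resolve_residuals(freqs: dict[str, float]) -> dict[str, float]:
    """Apply the residual rule in percent space; returns fractions."""
    keys = list(freqs)
    top = keys[0]
    pct = dict(freqs)
    residual = 100.0 - sum(pct.values())
    cap = pct[top] - 1.0
    for minor in keys[1:]:
        if residual <= 0:
            break
        add = min(residual, max(0.0, cap - pct[minor]))
        pct[minor] += add
        residual -= add
    if residual > 1e-9:
        spare = next(aa for aa in AMINO_ACIDS if aa not in pct)
        pct[spare] = residual
    return {aa: v / 100.0 for aa, v in pct.items() if v > 0}


def _background_column(rng: np.random.Generator, n: int, cap: float) -> list[str]:
    residues = rng.choice(list(AMINO_ACIDS), size=len(_BACKGROUND_SHAPE), replace=False)
    shape = np.array(_BACKGROUND_SHAPE)
    shape = np.minimum(shape, cap)  # cap already respected by construction
    counts = largest_remainder(dict(zip(residues, shape / shape.sum())), n)
    col = [aa for aa, c in counts.items() for _ in range(c)]
    rng.shuffle(col)
    return col


def make_profile_alignment(
    spec: ProfileSpec,
    seed: int,
    exact_counts: bool = True,
    id_prefix: str = "seq",
) -> Alignment:
    """Alignment realizing the spec's per-column frequencies.

    With ``exact_counts`` each specified column contains largest-remainder
    apportioned residue counts; otherwise residues are drawn multinomially
    from the same target frequencies.
    """
    rng = np.random.default_rng(seed)
    n, L = spec.n_seqs, spec.length
    columns: list[list[str]] = []
    for c in range(1, L + 1):
        if c in spec.positions:
            fractions = _resolve_residuals(spec.positions[c])
            if exact_counts:
                counts = largest_remainder(fractions, n)
            else:
                draw = rng.multinomial(n, np.array(list(fractions.values())))
                counts = dict(zip(fractions, draw))
            col = [aa for aa, k in counts.items() for _ in range(k)]
            rng.shuffle(col)
        else:
            col = _background_column(rng, n, spec.background_max)
        columns.append(col)
    seqs = ["".join(columns[c][r] for c in range(L)) for r in range(n)]
    ids = [f"{id_prefix}{r + 1:03d}" for r in range(n)]
    return Alignment(ids, seqs)


def subfamily_profile_specs(
    include_background: bool = True,
) -> tuple[ProfileSpec, ProfileSpec]:
    """ProfileSpecs embedding the curated EFG I / EFG II conservation
    percentages at their reference positions (114 and 140 sequences)."""
    length = profiles.REFERENCE_LENGTH if include_background else max(profiles.ALL_CANDIDATE_PROFILES)
    spec1 = ProfileSpec(
        length=length,
        n_seqs=profiles.EFG_I_N_SEQS,
        positions={p: dict(v["efg1"]) for p, v in profiles.ALL_CANDIDATE_PROFILES.items()},
    )
    spec2 = ProfileSpec(
        length=length,
        n_seqs=profiles.EFG_II_N_SEQS,
        positions={p: dict(v["efg2"]) for p, v in profiles.ALL_CANDIDATE_PROFILES.items()},
    )
    return spec1, spec2


def make_indel_alignment(
    n_seqs: int,
    length: int,
    blocks: list[tuple[int, int, int, bool]],
    seed: int,
) -> Alignment:
    """Ungapped random alignment with requested gap blocks embedded.

    ``blocks`` entries are (start_col, end_col, n_supporters,
    identical_endpoints); columns 0-based half-open.  With
    ``identical_endpoints`` False, supporter end columns are jittered to
    produce a variable-length region (blocks still overlap).
    """
    rng = np.random.default_rng(seed)
    grid = rng.choice(list(AMINO_ACIDS), size=(n_seqs, length))
    owners: dict[int, list[tuple[int, int]]] = {}
    for start, end, supporters, identical in blocks:
        if not 0 <= start < end <= length:
            raise SpecError(f"block ({start}, {end}) outside alignment")
        if supporters > n_seqs:
            raise SpecError(f"{supporters} supporters > {n_seqs} sequences")
        rows = rng.choice(n_seqs, size=supporters, replace=False)
        for k, r in enumerate(sorted(rows)):
            b_start, b_end = start, end
            if not identical and end - start >= 2:
                b_end = end - (k % 2)
            for prev_s, prev_e in owners.get(r, []):
                if b_start < prev_e and prev_s < b_end:
                    raise SpecError(f"overlapping block specs on sequence row {r}")
            owners.setdefault(r, []).append((b_start, b_end))
            grid[r, b_start:b_end] = GAP
    seqs = ["".join(row) for row in grid]
    ids = [f"seq{r + 1:03d}" for r in range(n_seqs)]
    return Alignment(ids, seqs)


def make_neighborhood_tables(
    n_genomes: int,
    overlap_design: int | dict[tuple[int, int], int],
    seed: int,
    flank: int = 5,
) -> dict[str, pd.DataFrame]:
    """Per-genome gene tables whose EFG-gene neighborhoods realize the
    requested pairwise shared-neighbor counts.

    ``overlap_design`` is either a single count shared by *all* genome pairs
    (via a common core of groups) or a dict {(i, j): count} realized with
    pair-private groups; each genome carries 2*flank neighbor groups.
    """
    total = 2 * flank
    shared_groups: dict[int, list[str]] = {i: [] for i in range(n_genomes)}
    if isinstance(overlap_design, int):
        if not 0 <= overlap_design <= total:
            raise SpecError(f"shared count {overlap_design} outside 0..{total}")
        core = [f"core{k}" for k in range(overlap_design)]
        for i in range(n_genomes):
            shared_groups[i].extend(core)
    else:
        for (i, j), k in overlap_design.items():
            if not (0 <= i < n_genomes and 0 <= j < n_genomes and i != j):
                raise SpecError(f"bad genome pair ({i}, {j})")
            if k < 0:
                raise SpecError("negative shared count")
            groups = [f"pair{min(i, j)}_{max(i, j)}_{k_}" for k_ in range(k)]
            shared_groups[i].extend(groups)
            shared_groups[j].extend(groups)
        for i, groups in shared_groups.items():
            if len(groups) > total:
                raise SpecError(
                    f"genome {i} needs {len(groups)} shared neighbors > {total}"
                )
    rng = np.random.default_rng(seed)
    tables = {}
    for i in range(n_genomes):
        genome = f"g{i:03d}"
        groups = list(shared_groups[i])
        groups += [f"uniq_{genome}_{k}" for k in range(total - len(groups))]
        rng.shuffle(groups)
        rows = []
        for rank, grp in enumerate(groups[:flank]):
            rows.append((genome, "c1", rank, f"{genome}_gene{rank}", grp))
        rows.append((genome, "c1", flank, f"{genome}_efg", "efg"))
        for rank, grp in enumerate(groups[flank:], start=flank + 1):
            rows.append((genome, "c1", rank, f"{genome}_gene{rank}", grp))
        tables[genome] = pd.DataFrame(
            rows, columns=["genome_id", "contig", "position_rank", "gene_id", "ortholog_group"]
        )
    return tables


_FOURFOLD_BASE = "GCT"  # Ala: any third-position change is synonymous
_NONSYN_BASE = "AAA"  # Lys: first position -> C/G is non-synonymous, stop-free


def make_codon_pair(
    n_codons: int, n_syn: int, n_nonsyn: int, seed: int
) -> tuple[str, str]:
    """CDS pair with exactly the requested single-position codon changes.

    Synonymous changes are third-position substitutions in four-fold
    degenerate codons; non-synonymous changes are first-position
    substitutions that avoid stop codons.
    """
    if n_syn + n_nonsyn > n_codons:
        raise SpecError(
            f"{n_syn}+{n_nonsyn} changed codons do not fit in {n_codons}"
        )
    rng = np.random.default_rng(seed)
    safe = sorted(set(CODONS_NO_STOP) - {"ATG", "TGG"})  # keep some degeneracy
    codons_a = [safe[i] for i in rng.integers(0, len(safe), size=n_codons)]
    slots = rng.permutation(n_codons)
    syn_slots = slots[:n_syn]
    nonsyn_slots = slots[n_syn : n_syn + n_nonsyn]
    codons_b = list(codons_a)
    for s in syn_slots:
        codons_a[s] = _FOURFOLD_BASE
        third = rng.choice([b for b in "ACG" if b != _FOURFOLD_BASE[2]])
        codons_b[s] = _FOURFOLD_BASE[:2] + third
    for s in nonsyn_slots:
        codons_a[s] = _NONSYN_BASE
        first = rng.choice(["C", "G"])
        codons_b[s] = first + _NONSYN_BASE[1:]
    return "".join(codons_a), "".join(codons_b)


CODONS_NO_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def make_loss_scenario(
    n_leaves: int, deletion_leaf_fraction: float, seed: int
) -> tuple[LossScenario, dict[str, bool]]:
    """Random ladder species tree with one duplication at the root and leaf
    deletion branches removing ``round(fraction * n_leaves)`` genomes."""
    if not 0 <= deletion_leaf_fraction <= 1:
        raise SpecError("deletion_leaf_fraction must be in [0, 1]")
    if n_leaves < 2:
        raise SpecError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"L{i + 1}" for i in range(n_leaves)]
    order = list(rng.permutation(labels))
    newick = order[0]
    for leaf in order[1:]:
        newick = f"({leaf},{newick})"
    tree = dendropy.Tree.get(data=newick + "dup;", schema="newick")
    n_deleted = int(round(deletion_leaf_fraction * n_leaves))
    deleted = set(rng.choice(labels, size=n_deleted, replace=False))
    scenario = LossScenario(tree, "dup", frozenset(deleted))
    presence = {leaf: leaf not in deleted for leaf in labels}
    return scenario, presence
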