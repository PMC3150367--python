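"""Duplicate-fate analysis: pairwise dN/dS, retention models, loss accounting.

dN and dS are estimated with Nei-Gojobori (1986) counting: per-codon
synonymous/non-synonymous site fractions averaged over the two sequences,
pathway-averaged difference counts for multi-hit codons, and Jukes-Cantor
correction of both proportions.  Conventions: mutations to stop codons count
as non-synonymous when sites are tallied; mutational pathways passing
through a stop codon are excluded from the pathway average (if every pathway
hits a stop, all are kept and stop steps count as non-synonymous).

Downstream, pairs with dS > 3 are discarded as saturated, omega = dN/dS is
binned into purifying / neutral / positive selection, and points are placed
against duplicate-retention model envelopes: the neutral line dN = dS, the
sub-functionalization line dN = theta1 * dS (0 < theta1 <= 1), and a
configurable neo-functionalization mean curve with 5 %/95 % quantile
envelope.  The neo-curve parameter values are not built in; they are user
configuration, and the module degrades to the two analytic lines without
them.  Duplicate survival over a dS-like time proxy follows a Weibull
survival function S(t) = exp(-(t/scale)^shape).

Loss-scenario accounting takes a rooted species tree, a duplication node and
a set of deletion branches below it, and reports the percentage of genomes
under the duplication that lack the duplicate copy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable

import dendropy
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy.stats import weibull_min

from .errors import ConsistencyError, SequenceError

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = set(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)
BASES = "ACGT"

SATURATION_DS = 3.0


@dataclass
class SubstitutionPair:
    id_a: str
    id_b: str
    dN: float
    dS: float
    omega: float | None  # None when dS == 0
    saturated: bool
    n_sites: float = 0.0  # non-synonymous sites N
    s_sites: float = 0.0  # synonymous sites S


def _check_cds(seq: str, name: str) -> str:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise SequenceError(f"{name}: length {len(seq)} is not a multiple of 3")
    bad = set(seq) - set(BASES)
    if bad:
        raise SequenceError(f"{name}: non-nucleotide characters {sorted(bad)}")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise SequenceError(f"{name}: internal stop codon {c} at codon {i + 1}")
    return seq


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site count of one codon.

    Each position contributes 1/3 of a site per possible change; changes to
    stop codons count as non-synonymous.
    """
    if codon in STOP_CODONS:
        return 0.0, 0.0
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, non-synonymous) differences between two
    codons.  Pathways through stop codons are dropped from the average; if
    none survive, all pathways are used with stop steps scored non-synonymous.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        steps = []
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            if nxt in STOP_CODONS and nxt != codon_b:
                through_stop = True
            current = nxt
        paths.append((steps, through_stop))
    usable = [steps for steps, bad in paths if not bad]
    if not usable:
        usable = [steps for steps, _ in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for c1, c2 in steps:
            if (
                c1 not in STOP_CODONS
                and c2 not in STOP_CODONS
                and CODON_TO_AA[c1] == CODON_TO_AA[c2]
            ):
                syn += 1.0
            else:
                nonsyn += 1.0
    k = len(usable)
    return syn / k, nonsyn / k


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction d = -3/4 ln(1 - 4p/3); inf for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(
    cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b"
) -> SubstitutionPair:
    """Nei-Gojobori dN/dS for a pair of in-frame, equal-length CDSs."""
    cds_a = _check_cds(cds_a, id_a)
    cds_b = _check_cds(cds_b, id_b)
    if len(cds_a) != len(cds_b):
        raise SequenceError(
            f"length mismatch: {id_a} has {len(cds_a)} nt, {id_b} has {len(cds_b)} nt"
        )
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    if S <= 0 or N <= 0:
        raise SequenceError("no countable sites")
    pS, pN = Sd / S, Nd / N
    dS, dN = jukes_cantor(pS), jukes_cantor(pN)
    saturated = dS > SATURATION_DS  # includes the infinite (p >= 3/4) case
    if dS == 0:
        omega = None
    elif math.isinf(dS):
        omega = None if math.isinf(dN) else 0.0
    else:
        omega = dN / dS
    return SubstitutionPair(id_a, id_b, dN, dS, omega, saturated, n_sites=N, s_sites=S)


def saturation_filter(
    pairs: list[SubstitutionPair], ds_max: float = SATURATION_DS
) -> tuple[list[SubstitutionPair], list[SubstitutionPair]]:
    """Drop pairs with dS strictly above ``ds_max`` (dS = 3.0 exactly is kept).

    Returns (retained, removed).
    """
    retained = [p for p in pairs if p.dS <= ds_max]
    removed = [p for p in pairs if p.dS > ds_max]
    return retained, removed


def selection_class(
    omega: float | None, neutral_band: tuple[float, float] = (0.8, 1.2)
) -> str:
    """Bin omega into purifying / neutral / positive selection."""
    if omega is None or not math.isfinite(omega):
        return "unclassified"
    lo, hi = neutral_band
    if omega < lo:
        return "purifying"
    if omega > hi:
        return "positive"
    return "neutral"


@dataclass
class NeoModel:
    """Neo-functionalization mean curve with quantile envelope.

    The functional form and its parameters are configuration: callables
    mapping dS to dN for the mean and the 5 %/95 % quantiles.
    """

    mean: Callable[[float], float]
    q05: Callable[[float], float]
    q95: Callable[[float], float]


def power_law_neo(a: float, b: float, q05_scale: float = 0.5, q95_scale: float = 1.5) -> NeoModel:
    """Convenience power-law neo-model dN = a * dS**b with scaled quantiles."""
    if a <= 0 or q05_scale <= 0 or q95_scale <= q05_scale:
        raise ValueError("need a > 0 and 0 < q05_scale < q95_scale")
    mean = lambda ds: a * ds**b if ds > 0 else 0.0  # noqa: E731
    return NeoModel(mean, lambda ds: q05_scale * mean(ds), lambda ds: q95_scale * mean(ds))


@dataclass
class FateModelParams:
    theta1: float = 0.3  # sub-functionalization ratio dN/dS
    weibull_shape: float = 1.0
    weibull_scale: float = 1.0
    neo: NeoModel | None = None

    def __post_init__(self) -> None:
        if not 0 < self.theta1 <= 1:
            raise ValueError("theta1 must be in (0, 1]")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")


def model_curves(
    dS_grid: list[float], params: FateModelParams
) -> dict[str, list[float] | None]:
    """Per-model dN values on a dS grid.

    Always returns the neutral (dN = dS) and sub-functionalization
    (dN = theta1 * dS) lines; neo curves are None when no neo model is
    configured.
    """
    out: dict[str, list[float] | None] = {
        "neutral": [float(ds) for ds in dS_grid],
        "subfunctionalization": [params.theta1 * ds for ds in dS_grid],
    }
    if params.neo is None:
        out["neo_mean"] = out["neo_q05"] = out["neo_q95"] = None
    else:
        out["neo_mean"] = [params.neo.mean(ds) for ds in dS_grid]
        out["neo_q05"] = [params.neo.q05(ds) for ds in dS_grid]
        out["neo_q95"] = [params.neo.q95(ds) for ds in dS_grid]
    return out


def classify_fate_point(
    pair: SubstitutionPair,
    params: FateModelParams,
    neutral_tol: float = 0.05,
) -> dict[str, str]:
    """Place one unsaturated (dS, dN) point against each model band.

    For the analytic lines (neutral, sub-functionalization) the point is
    "within" when |dN - line| <= neutral_tol * max(1, line); for the neo
    model, membership in the 5-95 % quantile envelope is reported.
    """
    if pair.saturated:
        raise ConsistencyError(
            f"pair ({pair.id_a}, {pair.id_b}) is saturated (dS = {pair.dS:g})"
        )
    out = {}
    for name, line in (
        ("neutral", pair.dS),
        ("subfunctionalization", params.theta1 * pair.dS),
    ):
        tol = neutral_tol * max(1.0, abs(line))
        if pair.dN > line + tol:
            out[name] = "above"
        elif pair.dN < line - tol:
            out[name] = "below"
        else:
            out[name] = "within"
    if params.neo is not None:
        lo, hi = params.neo.q05(pair.dS), params.neo.q95(pair.dS)
        if pair.dN > hi:
            out["neo"] = "above_q95"
        elif pair.dN < lo:
            out["neo"] = "below_q05"
        else:
            out["neo"] = "within_envelope"
    return out


def weibull_survival(t: float, shape: float, scale: float) -> float:
    """Weibull survival S(t) = exp(-(t/scale)^shape) for t >= 0."""
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    if t < 0:
        raise ValueError("t must be non-negative")
    return float(weibull_min.sf(t, shape, scale=scale))


@dataclass
class LossScenario:
    """A duplication on a species tree with subsequent deletion branches.

    ``duplication_node`` and ``deletion_branches`` name nodes by taxon label
    (leaves) or node label (internal nodes); every deletion branch must
    descend from the duplication node.
    """

    tree: dendropy.Tree
    duplication_node: str
    deletion_branches: frozenset[str] = field(default_factory=frozenset)

    def _find(self, label: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if (node.taxon is not None and node.taxon.label == label) or (
                node.label == label
            ):
                return node
        raise KeyError(f"no node labeled {label!r}")

    def __post_init__(self) -> None:
        dup = self._find(self.duplication_node)
        under = {
            n.taxon.label for n in dup.leaf_iter()
        }
        for b in self.deletion_branches:
            node = self._find(b)
            leaves = {n.taxon.label for n in node.leaf_iter()}
            if not leaves <= under:
                raise ConsistencyError(
                    f"deletion branch {b!r} is not below the duplication node"
                )

    def leaves_under_duplication(self) -> list[str]:
        dup = self._find(self.duplication_node)
        return [n.taxon.label for n in dup.leaf_iter()]

    def leaves_deleted(self) -> set[str]:
        out: set[str] = set()
        for b in self.deletion_branches:
            node = self._find(b)
            out |= {n.taxon.label for n in node.leaf_iter()}
        return out


@dataclass
class LossReport:
    loss_pct: float
    n_leaves: int
    n_lost: int
    duplication_count: int
    deletion_count: int


def loss_fraction(scenario: LossScenario, presence: dict[str, bool]) -> LossReport:
    """Percent of genomes under the duplication node lacking the duplicate.

    ``presence`` maps each leaf label to whether the duplicate copy is
    present; it must be consistent with the deletion branches (every leaf
    below a deletion branch lacks the copy, every other leaf has it).
    """
    under = scenario.leaves_under_duplication()
    deleted = scenario.leaves_deleted()
    offenders = [
        leaf
        for leaf in under
        if presence.get(leaf, leaf not in deleted) != (leaf not in deleted)
    ]
    if offenders:
        raise ConsistencyError(
            f"presence table contradicts deletion branches for leaves: {sorted(offenders)}"
        )
    n_lost = sum(not presence.get(leaf, leaf not in deleted) for leaf in under)
    return LossReport(
        loss_pct=100.0 * n_lost / len(under),
        n_leaves=len(under),
        n_lost=n_lost,
        duplication_count=1,
        deletion_count=len(scenario.deletion_branches),
    )


def write_pair_report(pairs: list[SubstitutionPair], path, params: FateModelParams | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tdN\tdS\tomega\tsaturated\tselection\tfate_bands\n")
        for p in pairs:
            bands = ""
            if params is not None and not p.saturated:
                bands = ";".join(f"{k}={v}" for k, v in classify_fate_point(p, params).items())
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{p.dN:.6f}\t{p.dS:.6f}\t"
                f"{'' if p.omega is None else f'{p.omega:.6f}'}\t"
                f"{int(p.saturated)}\t{selection_class(p.omega)}\t{bands}\n"
            )
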