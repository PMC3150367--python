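"""Gene-neighborhood (genome-context) conservation analysis.

The neighborhood of a gene is the set of ortholog-group labels of up to five
genes on each side on the same contig, order discarded and the query's own
group excluded.  Pairwise distance between two neighborhoods A, B is

    d = 1 - |A intersect B| / max(|A|, |B|)

which lies in [0, 1], is symmetric, and penalizes truncated contexts (contig
edges) on the larger side.  The matrix of distances is clustered with
neighbor joining (Saitou-Nei, scikit-bio implementation; negative branch
lengths clamped to zero).  str-operon membership is called when at least two
configured marker groups (ribosomal proteins S12/S7, EF-Tu) are among the
neighbors, tolerating local rearrangement or truncation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .errors import ConfigError

GENE_TABLE_COLUMNS = ["genome_id", "contig", "position_rank", "gene_id", "ortholog_group"]

#: default str-operon marker ortholog groups (ribosomal proteins S12 and S7,
#: and EF-Tu, the operon partners of the EFG gene)
STR_OPERON_MARKERS = frozenset({"rpsL", "rpsG", "tuf"})


@dataclass(frozen=True)
class NeighborhoodContext:
    gene_id: str
    genome_id: str
    neighbor_groups: frozenset[str]
    degenerate: bool = False  # no neighbors at all (single-gene contig)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"position_rank": int})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"gene table missing columns: {sorted(missing)}")
    return df


def neighborhood(table: pd.DataFrame, gene_id: str, flank: int = 5) -> NeighborhoodContext:
    """Neighbor ortholog groups of one gene: up to ``flank`` genes each side
    on the same contig (fewer at contig ends), order discarded, own group
    excluded."""
    rows = table[table["gene_id"] == gene_id]
    if rows.empty:
        raise KeyError(gene_id)
    row = rows.iloc[0]
    contig = table[
        (table["genome_id"] == row["genome_id"]) & (table["contig"] == row["contig"])
    ].sort_values("position_rank").reset_index(drop=True)
    idx = int(contig.index[contig["gene_id"] == gene_id][0])
    lo = max(0, idx - flank)
    neighbors = pd.concat([contig.iloc[lo:idx], contig.iloc[idx + 1 : idx + 1 + flank]])
    groups = frozenset(neighbors["ortholog_group"]) - {row["ortholog_group"]}
    return NeighborhoodContext(
        gene_id=gene_id,
        genome_id=row["genome_id"],
        neighbor_groups=groups,
        degenerate=len(groups) == 0,
    )


def context_distance(a: NeighborhoodContext, b: NeighborhoodContext) -> float:
    """Shared-neighbor distance 1 - |A&B|/max(|A|,|B|) in [0, 1]."""
    na, nb = len(a.neighbor_groups), len(b.neighbor_groups)
    if na == 0 and nb == 0:
        warnings.warn(
            f"both neighborhoods empty ({a.gene_id}, {b.gene_id}); distance undefined, "
            "returning 1",
            stacklevel=2,
        )
        return 1.0
    shared = len(a.neighbor_groups & b.neighbor_groups)
    return 1.0 - shared / max(na, nb)


@dataclass
class ContextDistanceMatrix:
    ids: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (self.d < -1e-12).any() or (self.d > 1 + 1e-12).any():
            raise ValueError("context distances must lie in [0, 1]")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for sid, row in zip(self.ids, self.d):
                fh.write(sid.ljust(10) + " ".join(f"{x:.6f}" for x in row) + "\n")


def distance_matrix(contexts: list[NeighborhoodContext]) -> ContextDistanceMatrix:
    n = len(contexts)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = context_distance(contexts[i], contexts[j])
    return ContextDistanceMatrix([c.gene_id for c in contexts], d)


def neighbor_joining(m: ContextDistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string with the input
    leaf set and non-negative (clamped) branch lengths.  Requires n >= 3."""
    if len(m.ids) < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {len(m.ids)}")
    tree = nj(DistanceMatrix(m.d, m.ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


def detect_str_operon(
    ctx: NeighborhoodContext,
    operon_markers: frozenset[str] = STR_OPERON_MARKERS,
    min_markers: int = 2,
) -> bool:
    """True iff at least ``min_markers`` operon marker groups neighbor the gene."""
    if not operon_markers:
        raise ConfigError("empty operon marker set")
    return len(ctx.neighbor_groups & operon_markers) >= min_markers
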