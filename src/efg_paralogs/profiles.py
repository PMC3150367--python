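"""Curated reference data for the EFG I / EFG II subfamily comparison.

Per-position conservation percentages of the differentially conserved
positions of the two large EFG subfamilies (EFG I, n = 114 sequences;
EFG II, n = 140), in the numbering of the *T. thermophilus* EFG-2 crystal
structure (1WDT), with the alternative EFG-1 numbering given by a piecewise
offset map.  Within each per-subfamily residue dict the first key is the top
residue; subsequent keys are minor residues in residual-fill priority order
(percent values; unassigned mass is handled by the synthetic generator's
residual rule).

Also here: the nine EFG II sub-subgroup-specific G2-motif patterns, the
trGTPase G2 consensus (RGITI) and its relaxed EFG II form (xxxSx), and an
illustrative five-domain boundary map on the 1WDT frame (domain boundaries
are configuration, not derivable from sequence alone).
"""

from __future__ import annotations

EFG_I_N_SEQS = 114
EFG_II_N_SEQS = 140

REFERENCE_LENGTH = 610

#: positions conserved with *different* residues in the two subfamilies
TYPE_I_CANDIDATE_PROFILES: dict[int, dict[str, dict[str, float]]] = {
    16: {"efg1": {"A": 100}, "efg2": {"G": 86}},
    25: {"efg1": {"T": 95}, "efg2": {"L": 99}},
    # position 61 narrowly misses the 80 % residue threshold in EFG II and
    # therefore classifies as neither type; kept here deliberately
    61: {"efg1": {"T": 100}, "efg2": {"S": 76}},
    291: {"efg1": {"I": 87, "V": 13}, "efg2": {"T": 81}},
    333: {"efg1": {"A": 80}, "efg2": {"G": 98}},
    352: {"efg1": {"G": 100}, "efg2": {"K": 86, "R": 14}},
}

#: positions relaxed in EFG I but under strong selection in EFG II
TYPE_II_CANDIDATE_PROFILES: dict[int, dict[str, dict[str, float]]] = {
    216: {"efg1": {"D": 61, "S": 26, "N": 10}, "efg2": {"D": 88}},
    250: {"efg1": {"V": 42, "M": 33, "A": 10}, "efg2": {"V": 90}},
    264: {"efg1": {"L": 38, "M": 36, "V": 19}, "efg2": {"L": 88}},
    471: {"efg1": {"V": 45, "K": 35, "I": 15}, "efg2": {"K": 84}},
    472: {"efg1": {"K": 56, "R": 43, "H": 1}, "efg2": {"K": 89}},
    513: {"efg1": {"E": 36, "D": 35, "N": 6}, "efg2": {"E": 87}},
    603: {"efg1": {"G": 71, "A": 9, "D": 9}, "efg2": {"G": 96}},
}

ALL_CANDIDATE_PROFILES = {**TYPE_I_CANDIDATE_PROFILES, **TYPE_II_CANDIDATE_PROFILES}

#: printed pairwise conservation differences (EFG II minus EFG I top residue)
TYPE_II_PRINTED_DIFFERENCES = {216: 27, 250: 48, 264: 50, 471: 39, 472: 33, 513: 51, 603: 25}

#: piecewise offsets from 1WDT numbering to the EFG-1 alternative numbering,
#: interpolated between the anchors sampled by the curated positions
#: (16->19, 61->64, 216->224, 264->272, 291->316, 333->360, 472->499,
#: 513->543, 603->633)
ALT_NUMBERING_OFFSETS: list[tuple[int, int, int]] = [
    (1, 215, 3),
    (216, 290, 8),
    (291, 291, 25),
    (292, 472, 27),
    (473, REFERENCE_LENGTH, 30),
]

#: illustrative five-domain layout on the 1WDT frame (configuration)
DOMAIN_BOUNDARIES: dict[str, tuple[int, int]] = {
    "I": (1, 285),
    "II": (286, 400),
    "III": (401, 480),
    "IV": (481, 600),
    "V": (601, REFERENCE_LENGTH),
}

#: trGTPase-family G2 consensus and its relaxed EFG II form
G2_TRGTPASE_CONSENSUS = "RGITI"
G2_EFG_II_RELAXED = "xxxSx"

#: the nine EFG II sub-subgroup-specific G2 motif patterns
G2_SUB_SUBGROUP_PATTERNS: dict[str, str] = {
    "delta-proteobacteria": "RxxT/SI",
    "beta-gamma-proteobacteria": "xxHSL",
    "Actinobacteria": "qqRSV",
    "alpha-proteobacteria/Cyanobacteria": "R/HxMS/GV",
    "Thermotogae": "r/kGxSx",
    "Chloroflexi": "r/kxxSI",
    "Clostridia": "RxxSI",
    "Bacteroidetes": "YGYSV",
    "Chlorobi": "rxhSl",
}

#: switch I interval on the 1WDT frame (configuration; hosts the spdEFG1
#: diagnostic KDG insertion)
SWITCH_I_WINDOW = (40, 70)
KDG_CONSENSUS = "KDG"
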