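# efg-paralogs

Bacterial elongation factor G (EFG) is one of the few essential,
highly-expressed genes that is nevertheless frequently duplicated, and its
ancient duplicates have diverged into distinct subfamilies (EFG I, spdEFG1,
spdEFG2, EFG II) with different genomic contexts, indel repertoires and
motif variants.  This package provides, for people studying paralog
divergence in protein families, a tested implementation of the analyses
used to characterize such subfamilies:

* **Differential conservation typing** — per-column sequence-logo
  information content (`info_bits = log2 20 − H`), the 3-bit conservation
  call, and classification of positions as *type I* (conserved in both
  subfamilies, ≥ 80 %, with different residues) or *type II* (conserved in
  one subfamily, relaxed in the other, difference ≥ 25 points), with
  dual-numbering and hydropathy annotation.
* **Indel regions** — maximal gap-run clustering with a ≥ 5-sequence
  support rule, insertion/deletion polarity against a reference frame, and
  detection of short diagnostic insertions (the switch-I "KDG" of spdEFG1).
* **Motif classification** — three-tier consensus strings (>70 % / 60–70 %
  / <60 %), a grammar for G2-motif patterns (`RGITI`, `xxxSx`,
  `R/HxMS/GV`, ...), ranked sub-subgroup assignment, and rule-based
  subfamily calls (single copy → EFG I; KDG → spdEFG1; *str* operon →
  EFG I; relaxed G2 → EFG II).
* **Genome context** — shared-neighbor distance
  `d = 1 − |A∩B| / max(|A|,|B|)` over ±5-gene neighborhoods, neighbor-
  joining clustering, and *str*-operon membership detection.
* **Duplicate fate** — Nei–Gojobori dN/dS with Jukes–Cantor correction,
  the dS > 3 saturation filter, selection classes, retention-model
  envelopes (neutral dN = dS, sub-functionalization dN = θ₁·dS,
  configurable neo-functionalization quantile envelope), Weibull survival,
  and duplication/loss accounting on species trees.
* **Synthetic data** — deterministic generators for every input above,
  including alignments that embed specified per-column conservation
  percentages by exact count apportionment.

See `docs/methods.md` for the models, defaults and numerical decisions.

## Worked example

```python
from efg_paralogs import classify_alignment_pair, make_profile_alignment
from efg_paralogs.synth import subfamily_profile_specs
from efg_paralogs import profiles

spec1, spec2 = subfamily_profile_specs()          # 114 and 140 sequences
aln1 = make_profile_alignment(spec1, seed=11)
aln2 = make_profile_alignment(spec2, seed=12)
calls = classify_alignment_pair(aln1, aln2,
                                offset_map=profiles.ALT_NUMBERING_OFFSETS)
for c in calls:
    if c.category != "none":
        print(c.position, c.alt_position, c.category,
              c.profile_1.top_residue, c.profile_2.top_residue, c.difference_pct)
```

prints the twelve subfamily-specific positions:

```
16 19 type_I A G -14
25 28 type_I T L 4
216 224 type_II D D 27
250 258 type_II V V 48
264 272 type_II L L 50
291 316 type_I I T -6
333 360 type_I A G 18
352 379 type_I G K -14
471 498 type_II V K 39
472 499 type_II K K 33
513 543 type_II E E 51
603 633 type_II G G 25
```

Five type I positions (16, 25, 291, 333, 352: different residues conserved
in the two subfamilies — e.g. Ala→Gly at 16 increases hydrophilicity in the
P-loop) and seven type II positions (216, 250, 264, 471, 472, 513, 603:
relaxed in EFG I, under strong selection in EFG II), each shown with both
residue numberings and the signed conservation difference.

The numbered scripts under `analysis/` run each stage end to end
(alignment generation, conservation typing, indel regions, motif
assignment, context clustering, duplicate fate) and write their tables
under `results/`.  The same stages are available from the shell via the
`efg-paralogs` command (`synth`, `conservation`, `indels`, `motifs`,
`context`, `fate`).

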