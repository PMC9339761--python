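# haploshare

Analysis of chloroplast (cpDNA) haplotype sharing among closely related
plant species, built around one question: when two species carry the same
plastid haplotype, is that **shared ancestral polymorphism** or
**introgression**? The two processes leave different geographic footprints —
ancestral haplotypes are shared *randomly* across the species' ranges, while
introgressed haplotypes are shared *locally*, between populations close
enough to hybridise. `haploshare` implements the full pipeline that turns
per-locus plastid alignments plus population coordinates into that
discrimination, together with a ground-truthed synthetic-data generator so
every stage is testable without any external download.

The package is aimed at phylogeographers working with non-recombining,
maternally inherited markers (plastid spacers in particular), where the unit
of analysis is the haplotype: a unique combination of states across coded
characters, sampled per individual, tallied per population.

## What it computes

**Character coding** (`haploshare.coding`). Non-coding alignments are coded
into a character matrix: one character per substitution column; indels via
simple gap coding (each distinct start/end gap run is a single binary
mutation event; a sequence whose gap overlaps but does not match is scored
missing); a configured inversion region re-oriented by reverse complement
and coded as one binary character; length variation inside mononucleotide
repeats (runs ≥ 5 bp by default) excluded as homoplasy-prone. Individuals
with identical state vectors collapse into haplotypes H1, H2, …
(frequency-ranked; a label map is accepted for reproduction runs).

**Median-joining network** (`haploshare.network`). Hamming distances (each
indel/inversion = 1 step) feed a median-joining construction: iterated
minimum-spanning networks (union of all MSTs, tie links kept) augmented with
median vectors (per-character majority of connected triples) and pruned of
peripheral unobserved nodes. Diagnostic characters cut the network into
lineages.

**Diversity and differentiation** (`haploshare.popstats`). Per population:
number of haplotypes *h*, unbiased gene diversity
*H*<sub>d</sub> = *n*(1 − Σ*p*<sub>i</sub>²)/(*n* − 1), and per-site
nucleotide diversity π. Per species and pooled: the unbiased
multi-population estimators *h*<sub>S</sub> (mean within-population
diversity) and *h*<sub>T</sub> (total diversity with the small-sample
correction *h*<sub>S</sub>/(ñ·K)), their distance-weighted analogues, and
G<sub>ST</sub> = (*h*<sub>T</sub> − *h*<sub>S</sub>)/*h*<sub>T</sub> versus
N<sub>ST</sub>, whose excess over G<sub>ST</sub> (tested by permuting
haplotype identities in the distance matrix) indicates phylogeographic
structure.

**AMOVA** (`haploshare.amova`). Distance-based hierarchical variance
decomposition on squared mutation counts, two-level (populations) or
three-level (species / populations / individuals), with unequal-size
coefficients, signed variance components, F<sub>CT</sub>/F<sub>SC</sub>/F<sub>ST</sub>
and scheme-specific permutation tests.

**Spatial autocorrelation** (`haploshare.spatial`). The multivariate
individual-level autocorrelation coefficient *r* per 50-km distance class
(double-centred squared genetic distances), with wholesale-shuffle
permutation bounds and within-class pair bootstrap CIs.

**The sharing test** (`haploshare.sharing`). For every heterospecific
population pair: great-circle distance and gene identity
*J* = Σ*x*<sub>i</sub>*y*<sub>i</sub> / √(Σ*x*<sub>i</sub>²·Σ*y*<sub>i</sub>²).
Pairs are grouped into G1 (< 300 km and sharing a haplotype), G2 (< 300 km)
and G3 (≥ 300 km); the group means M1/M2/M3 are compared by two-sided
Wilcoxon rank-sum tests (P12, P13, P23), with and without the most
widespread haplotype. A significant M2 > M3 after that exclusion is the
signature of local haplotype exchange, i.e. introgression.

**Synthetic data** (`haploshare.synthetic_data`). Generates actual aligned
sequences (two loci, 726 + 614 bp) for three species across refugium
clusters: three lineages separated by an A/G transition and an 8-bp indel,
widespread ancestral cores shared geography-independently, private tip
haplotypes, a plantable 32-bp inversion, and optional introgression events
copied only between nearby heterospecific populations — with full ground
truth for every planted feature.

## Worked example

```python
from haploshare import analyze
from haploshare.synthetic_data import SimulationParams, inversion_config, simulate_dataset

params = SimulationParams(seed=42, pops_per_species=(8, 6, 7))
dataset, truth = simulate_dataset(params)
dataset.config = {
    "loci": [
        {"name": locus, "inversion": {"start": s, "end": e}}
        for locus, (s, e) in inversion_config(params, truth).items()
    ]
}
result = analyze(dataset, seed=1, n_permutations=1000)

print(f"{len(result.catalog.haplotypes)} haplotypes from "
      f"{result.catalog.n_individuals} individuals, "
      f"{len(result.catalog.characters)} coded characters")
print(result.diversity[["group", "hT", "hS", "GST", "NST", "p_NST_gt_GST"]].round(3).to_string(index=False))
print(result.sharing_results["excluding_H1"].round(3).to_string(index=False))
```

prints

```
27 haplotypes from 236 individuals, 48 coded characters

group    hT    hS   GST   NST  p_NST_gt_GST
  sp1 0.781 0.209 0.733 0.742         0.377
  sp2 0.854 0.280 0.672 0.673         0.513
  sp3 0.515 0.200 0.612 0.563         0.704
  all 0.795 0.226 0.716 0.717         0.477

species_group exclusion  N1    M1  N2    M2  N3    M3   P12   P13   P23
      sp1-sp2        H1   1 0.196   3 0.065  27 0.011 0.617 0.008 0.242
      sp1-sp3        H1   0   NaN   3 0.000  21 0.015   NaN   NaN 0.544
      sp2-sp3        H1   0   NaN   7 0.000  13 0.143   NaN   NaN 0.323
          all        H1   1 0.196  13 0.015  61 0.041 0.025 0.011 0.635
```

Reading the output: the coding stack recovered all 27 planted haplotypes and
48 characters. Differentiation among populations is high (pooled
G<sub>ST</sub> ≈ 0.72) but N<sub>ST</sub> does not exceed G<sub>ST</sub>
(p ≈ 0.48): related haplotypes are not clustered geographically, as expected
when widespread ancestral haplotypes dominate. At this small size (21
populations, default 5% introgression) the H1-excluded near/far comparison
(P23) is not significant — the introgression signal needs the full 93-population
design or a higher planted rate, which is exactly what the acceptance
properties check.

The same pipeline runs from the shell:

```bash
haploshare simulate --seed 42 --out data/
haploshare analyze \
    --alignment atpB-rbcL data/atpB-rbcL.fasta \
    --alignment trnH-psbA data/trnH-psbA.fasta \
    --populations data/populations.tsv \
    --config config.yaml --seed 1 --out results/
```

writing the haplotype table, GraphML + edge-list network, per-population
statistics, diversity/differentiation, AMOVA, sharing and pair-list TSVs.

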