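# Methods

## The problem and the discriminating signal

Chloroplast DNA in oaks (and most angiosperms) is maternally inherited,
effectively non-recombining and seed-dispersed only. Closely related,
co-distributed species therefore often carry identical plastid haplotypes,
for two very different reasons. Haplotypes present in the common ancestor
can persist through speciation (shared ancestral polymorphism); because each
descendant inherits them everywhere, they end up **randomly** distributed
across both species' ranges. Alternatively a haplotype can cross the species
boundary by hybridisation and backcrossing (chloroplast capture); since
pollen does not move plastids, this requires physical proximity and leaves
**locally** shared haplotypes. The package turns this geographic contrast
into a test: compare interspecific gene identities of nearby versus distant
population pairs, with the dominant (presumably ancestral) haplotype removed
so it cannot mask the local signal.

Assumptions inherited from the marker: one non-recombining haplotype per
individual; no heteroplasmy; alignments are given (the package never aligns);
haplotype identity is exact, so any missing state removes the individual
from the catalog rather than guessing a match.

## Character coding

* **Substitutions** — one character per alignment column with ≥ 2 distinct
  bases. Gaps and N at that column are missing states. Columns polymorphic
  only between a base and a gap belong to an indel and are not substitution
  characters.
* **Indels, simple gap coding** — every maximal gap run with a given
  (start, end) is one binary character: T = gap present, A = absent. A
  sequence whose own gap strictly contains, or partially overlaps, the
  character's coordinates cannot be scored and is missing. Identity of an
  indel requires *both* coordinates to match; overlapping-but-distinct
  indels are separate characters with mutual missing states. Treating each
  indel as one mutation event regardless of length keeps a multi-bp deletion
  from dominating distances.
* **Mononucleotide repeats** — length variation in homopolymer runs is
  microsatellite-like and homoplasy-prone. Columns in a consensus run of
  ≥ `min_run` identical bases (default 5, the shortest run usually treated
  as a homopolymer microsatellite; configurable) are masked for indel
  coding. Substitutions to a *different* base inside a run remain callable —
  only length variation is excluded.
* **Inversions** — small hairpin-mediated inversions flip a segment without
  changing its information content. The region is config-specified (not
  auto-detected); rows whose segment matches the reverse complement of the
  majority consensus better than the consensus itself are rewritten to the
  majority orientation, and orientation becomes one binary character. On an
  exact 50/50 split the first row defines the reference orientation.
* **Collapsing** — individuals with identical vectors share a haplotype.
  Labels are assigned by descending total count, ties by first occurrence,
  so the labelling is deterministic and row-order invariant. Published
  haplotype numbering is rarely frequency-ranked, so a user label map is
  accepted. Individuals with any missing state at a retained character are
  excluded with a logged warning: exact identity is preferred over imputation
  because a single mis-joined haplotype distorts every downstream statistic.

## Median-joining network

Distances are Hamming counts over coded characters (all characters weight 1).
The minimum-spanning network keeps an edge iff its endpoints are not
connected by strictly cheaper edges — exactly the union of all minimum
spanning trees, so tied alternatives are never dropped. Median joining then
iterates: propose, for every triple connected in the current MSN, the
per-character majority vector; add the proposals whose connection cost is
within `epsilon` of the minimum (default `epsilon = 0`, the common software
default); prune unobserved nodes of degree ≤ 2; repeat to a fixpoint (a
50-round safety bound guards against pathological inputs; typical data
converge in < 5). Determinism: nodes are ordered observed-before-median then
by label, candidate medians lexicographically; a three-way per-character tie
keeps the first node's state. Node frequency is display metadata only and
never affects topology.

Lineages are obtained by deleting every edge whose differing characters
include a user-chosen diagnostic character (e.g. the A/G transition and the
8-bp indel of the planted structure) and labelling components by descending
sample count.

## Diversity, differentiation, permutation null

Per population: h (distinct haplotypes), unbiased gene diversity
Hd = n(1 − Σp²)/(n − 1), and nucleotide diversity
π = n/(n − 1) · Σᵢⱼ pᵢpⱼdᵢⱼ / L with d counted over substitution characters
only and L the concatenated alignment length — indel and inversion characters
are not per-site events, so they are excluded from π (gap-free site counting).

Across populations the estimators are population-weighted equally
(unweighted), the convention of the standard software for these statistics:
hS is the mean unbiased within-population diversity, and
hT = 1 − Σx̄ᵢ² + hS/(ñK) on the mean frequencies x̄, where ñ is the harmonic
mean sample size; hT < hS excursions are possible for near-identical
populations and are reported as computed, never clipped. The
distance-weighted analogues vS and vT use Σᵢⱼ dᵢⱼxᵢxⱼ in place of 1 − Σxᵢ²
and reduce *exactly* to hS/hT when all inter-haplotype distances are equal —
a property the tests assert. GST = (hT − hS)/hT, NST = (vT − vS)/vT.
Populations with n < 2 are excluded from these estimators (the unbiased
within-population term is undefined) but kept in all haplotype tallies.

Standard errors for hS, hT, GST and NST are delete-one-population jackknife
estimates. The point estimators follow the published equations exactly; for
the SEs the jackknife was chosen over the original closed-form variance
expressions as the standard resampling equivalent — worth knowing when
comparing SE columns against legacy software output.

The phylogeographic-structure test is one-tailed (NST > GST, the directional
question), built by permuting haplotype identities in the distance matrix
(10,000 permutations by default) with the +1 correction; GST is invariant
under the shuffle, so the statistic reduces to NST.

## AMOVA

Distances between individuals are squared mutation counts (the squared
Euclidean form the sums-of-squares identity requires; haplotypic
pairwise-difference data enter as d²). SS per stratum is the within-group sum
of squared distances over group size; variance components come from the
expected mean squares with the standard unequal-size coefficients; negative
components are retained with a logged warning and percentages are computed
over the signed total. F_CT = σ²ₐ/σ²ₜ, F_SC = σ²ᵦ/(σ²ᵦ+σ²c),
F_ST = (σ²ₐ+σ²ᵦ)/σ²ₜ, and the three-level identity
F_ST = F_CT + (1 − F_CT)·F_SC holds to numerical precision. When every
species holds exactly one population the middle stratum is empty and the
design collapses to the two-level decomposition (F_SC = 0). All-identical
data yield zero total variance: the indices are undefined and flagged rather
than invented. Permutation schemes per index: individuals among populations
(F_ST, two-level), whole populations among species (F_CT), individuals among
populations within species (F_SC); p = (#{F* ≥ F} + 1)/(n + 1).

## Spatial autocorrelation

The squared genetic-distance matrix between individuals (squared
inter-haplotype mutation count by default — the haploid convention;
0/1 mismatch available) is double-centred, c = −½(d² − row − col + grand),
and per distance class h the coefficient is
r(h) = Σ 2cᵢⱼ / Σ (cᵢᵢ + cⱼⱼ) over the unordered pairs of that class.
Classes are discrete half-open 50-km bins [0,50), [50,100), … (not
cumulative), 20 by default; pairs beyond the last bin are excluded with a
reported count. Under the null E[r] = −1/(n − 1), the estimator's
small-sample bias — near zero for large n. Inference: (a) the
individual→location mapping is shuffled wholesale, once per replicate for
all classes; r is significant when above the 97.5th percentile of the null;
(b) pairs within a class are bootstrap-resampled; significant when the 95%
CI excludes zero. Empty classes and all-identical genotype matrices (c ≡ 0)
yield flagged NaNs, never silent zeros.

## The sharing test

Gene identity between two populations' haplotype frequency vectors is the
normalised form J = Σxᵢyᵢ/√(Σxᵢ²·Σyᵢ²), bounded in [0,1]; the unnormalised
Σxᵢyᵢ of part of the older literature is available as `identity="raw"`.
Heterospecific pairs are grouped with a strict < threshold (300 km default,
where the autocorrelation of such data typically stops declining): G1 =
nearby and sharing ≥ 1 haplotype, G2 = nearby, G3 = distant; G1 ⊆ G2 and
G2/G3 partition all pairs. Group means M1/M2/M3 are unweighted means over
pairs. P12/P13/P23 are two-sided Wilcoxon rank-sum p-values (exact when both
groups have n ≤ 20 without ties, tie-corrected normal approximation with
continuity correction otherwise; the approximation deviates from the exact
law by up to ~0.01 at n = 8, which is why the exact branch exists).

Exclusion mode removes all *individuals* carrying the named haplotype —
populations fixed for it disappear and pair counts shrink — and the G1
sharing flag is evaluated after exclusion, so a pair sharing only the
excluded haplotype is not "sharing". Excluding a label nobody carries is a
no-op; excluding one that empties an entire species is an error. The
pair-list enumeration (`enumerate_sharing_pairs`) is gentler: it only
ignores the excluded haplotype in the shared-label sets.

Caveat: J values of pairs that reuse the same population are not
independent, and the rank-sum test ignores that dependence. The generator
null calibration shows the realised size stays near α at the default design,
but the p-values should be read as descriptive at heavily unbalanced
designs.

## Synthetic data: what it emulates, what it does not

The generator emits real aligned sequences — two loci of 726 and 614 bp —
so the entire coding stack is exercised, never bypassed. Planted structure
and defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| species × populations | 3 × (33, 19, 41) | the three-species sampling design the analysis targets |
| individuals / population | uniform 5–19 | field-collection range |
| lineages | 3, split by one A/G transition and one 8-bp indel | the diagnostic-character structure the network cut expects |
| tips / lineage | 8 (27 haplotypes total) | matches the observed catalog size |
| core haplotype mass | 0.16 / 0.39 / 0.11 | frequencies of the three widespread ancestral haplotypes |
| resident fidelity | 0.95 | reproduces near-fixed populations: mean Hd ≈ 0.11–0.15, mean h ≈ 1.6, per-species GST ≈ 0.75–0.88 |
| introgression rate | 0.05 of eligible nearby heterospecific pairs | yields ≈ 10–20 events per dataset, the order of the locally-shared pair counts such studies report |
| introgression radius | 300 km | the sharing-test threshold |
| copy fraction | Beta(1, 3) | introgressed haplotypes locally common but rarely fixed |
| inversion | one 32-bp region, one carrier tip | exercises the re-orientation code; orientation = 1 mutation step |

Mechanics worth knowing: cores are assigned to individuals of **all**
species with geography-independent probabilities (the ancestral-sharing
mode); tips live in a single (species, refugium-cluster) cell unless
introgressed; introgressed copies replace only core-carrying individuals in
the sink, so earlier events are never silently overwritten; after sampling,
every pool haplotype is guaranteed ≥ 1 carrier (a coverage pass), which
makes the planted character count exactly recoverable by the coding module.
Roots are generated with no homopolymer run > 3 so the repeat mask never
collides with planted indels; the inversion region is re-drawn until
sufficiently asymmetric under reverse complement to be detectable.

Not emulated: coalescent genealogies and migration (core frequencies are
drawn once globally and sampled binomially — there is no drift history),
mutation-rate heterogeneity, sequencing error, missing data, and range
shifts. Passing tests therefore demonstrate that the statistics and tests
behave correctly on data with the assumed structure, not that real data
satisfy that structure.

## Test and acceptance design

Every statistic with a closed form is checked against an independent
brute-force transcription (1e-9); AMOVA toys use two haplotypes so
individuals embed on a 1-D line and classical unbalanced ANOVA
method-of-moments is the oracle; the MSN is compared against exhaustive
spanning-tree enumeration on 6-node instances; the Wilcoxon exact branch
against full enumeration. Permutation tests are calibrated on 500–600 null
simulations (size 5% ± 2% at α = 0.05 with 99 permutations, which makes the
nominal size exactly 0.05). Parameter recovery uses 100 replicates per
regime at 3 × 10 populations (rate 1 vs rate 0) — sizes chosen so the whole
suite runs in a couple of minutes while keeping the binomial noise on the
power estimate small. The acceptance script uses the full default design
(93 populations, ≈ 1100 individuals) with 10,000 / 1,000 / 999 permutations
for the differentiation / AMOVA / spatial tests and a 400-individual
subsample for the autocorrelogram.

## Known limitations

* Reproduction of a published study's exact numbers requires its
  per-population haplotype table and coordinates; the package provides the
  interfaces (label map, TSV layouts mirroring the standard table shapes)
  but ships no third-party data.
* `epsilon > 0` median joining keeps slightly more edges than the strict
  definition (connectivity is evaluated against accepted edges only); with
  the default `epsilon = 0` the construction is exact.
* Jackknife SEs (see above) may differ from legacy closed-form SE columns.
* The spatial permutation test shuffles whole individuals; it does not
  implement heterogeneity tests across whole correlograms.
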