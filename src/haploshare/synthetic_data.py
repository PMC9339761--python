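"""Ground-truthed synthetic datasets for the haplotype-sharing analysis.

The generator emits actual aligned nucleotide sequences (two non-coding
plastid loci), so the full coding stack — substitution calls, simple gap
coding, repeat masking, inversion re-orientation — is exercised end to end
rather than bypassed with abstract haplotype IDs.

The planted structure mirrors what the analysis is designed to detect:

* three haplotype lineages whose cores are separated by one A/G
  substitution (A | B) and one 8-bp indel (B | C);
* high-frequency ancestral core haplotypes assigned to individuals of all
  species with geography-independent probabilities (shared ancestral
  polymorphism: random interspecific sharing);
* low-frequency tip haplotypes derived from the cores by 1-3 extra
  mutations (one tip carries a 5-bp indel, one the 32-bp inversion), each
  private to a single (species, refugium-cluster) cell;
* optional introgression: for a Bernoulli(introgression_rate) subset of
  heterospecific population pairs within ``introgression_radius_km``, a tip
  haplotype is copied from source to sink at a Beta-distributed frequency
  (local interspecific sharing).

Populations sit in refugium clusters inside a bounding box; most
individuals carry their population's resident haplotype, so populations are
near-fixed and among-population differentiation is high. Core frequencies
are drawn once globally and sampled per individual rather than from an
explicit coalescent (full coalescent realism is out of scope).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import reverse_complement
from .dataio import Alignment, Dataset, PopulationTable, write_alignment, write_population_table
from .spatial import haversine_km

log = logging.getLogger(__name__)

_BASES = "ACGT"
LINEAGES = ("A", "B", "C")


@dataclass
class SimulationParams:
    """Study-condition defaults: 3 species, 33/19/41 populations, 5-19
    individuals each, 27 haplotypes in 3 lineages, loci of 726 and 614 bp."""

    seed: int
    n_species: int = 3
    species_names: tuple[str, ...] = ("sp1", "sp2", "sp3")
    pops_per_species: tuple[int, ...] = (33, 19, 41)
    n_per_pop: tuple[int, int] = (5, 19)
    n_lineages: int = 3
    tips_per_lineage: int = 8
    core_frequencies: tuple[float, float, float] = (0.16, 0.39, 0.11)  # lineages A, B, C
    resident_fidelity: float = 0.95
    introgression_rate: float = 0.05
    introgression_radius_km: float = 300.0
    introgression_beta: tuple[float, float] = (1.0, 3.0)
    bbox: tuple[float, float, float, float] = (24.0, 40.0, 100.0, 122.0)  # lat lo/hi, lon lo/hi
    n_clusters: int = 5
    cluster_sd_deg: float = 0.6
    locus_names: tuple[str, str] = ("atpB-rbcL", "trnH-psbA")
    locus_lengths: tuple[int, int] = (726, 614)
    inversion_length: int = 32

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_lineages != 3:
            raise ValueError("this generator plants exactly 3 lineages")
        if self.n_species != len(self.species_names) or self.n_species != len(self.pops_per_species):
            raise ValueError("species_names/pops_per_species must match n_species")
        for p in (*self.core_frequencies, self.resident_fidelity, self.introgression_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.core_frequencies) >= 1.0 and self.tips_per_lineage > 0:
            raise ValueError("core frequencies must leave mass for tip haplotypes")


@dataclass
class PoolHaplotype:
    name: str
    lineage: str
    kind: str  # "core" | "tip"
    subs: dict  # (locus_index, 0-based position) -> base
    gaps: frozenset  # of (locus_index, start, end) 0-based inclusive
    inverted: bool
    rows: tuple[str, str] = ("", "")


@dataclass
class GroundTruth:
    haplotypes: dict = field(default_factory=dict)  # name -> {lineage, kind, mode, home}
    events: list = field(default_factory=list)  # {source, sink, haplotype, n_copied}
    assignments: dict = field(default_factory=dict)  # individual -> pool haplotype name
    n_substitution_columns: int = 0
    n_indel_characters: int = 0
    n_inversion_characters: int = 0
    diagnostic_ab: tuple | None = None  # (locus_name, 1-based position)
    diagnostic_bc: tuple | None = None  # (locus_name, 1-based start, end)
    inversion_region: tuple | None = None  # (locus_name, 1-based start, end)

    @property
    def n_planted_characters(self) -> int:
        return (
            self.n_substitution_columns
            + self.n_indel_characters
            + self.n_inversion_characters
        )


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    """Random sequence with no mononucleotide run longer than 3."""
    seq: list[str] = []
    for _ in range(length):
        choices = _BASES
        if len(seq) >= 3 and seq[-1] == seq[-2] == seq[-3]:
            choices = _BASES.replace(seq[-1], "")
        seq.append(choices[rng.integers(len(choices))])
    return seq


class _PositionRegistry:
    """Hands out unused alignment columns/windows per locus."""

    def __init__(self, rng: np.random.Generator, lengths: tuple[int, ...]):
        self.rng = rng
        self.lengths = lengths
        self.used: list[set[int]] = [set() for _ in lengths]

    def take_position(self, locus: int, predicate=None) -> int:
        for _ in range(10000):
            pos = int(self.rng.integers(self.lengths[locus]))
            if pos in self.used[locus]:
                continue
            if predicate is not None and not predicate(pos):
                continue
            self.used[locus].add(pos)
            return pos
        raise RuntimeError("could not place a mutation: locus saturated")

    def take_window(self, locus: int, width: int, margin: int = 2) -> tuple[int, int]:
        for _ in range(10000):
            s = int(self.rng.integers(self.lengths[locus] - width))
            cols = range(s - margin, s + width + margin)
            if any(c in self.used[locus] for c in cols):
                continue
            self.used[locus].update(range(s, s + width))
            return s, s + width - 1
        raise RuntimeError("could not place a window: locus saturated")


def simulate_haplotype_pool(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[list[PoolHaplotype], GroundTruth, list[list[str]]]:
    """Build the haplotype pool: roots, lineage cores, derived tips.

    Returns the pool, a partially filled GroundTruth, and the per-locus root
    sequences (as mutable lists).
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    roots = [_random_sequence(rng, n) for n in params.locus_lengths]
    registry = _PositionRegistry(rng, params.locus_lengths)
    truth = GroundTruth()

    # diagnostic A | B transition: a position where the root carries A
    pos_ab = registry.take_position(0, predicate=lambda p: roots[0][p] == "A")
    truth.diagnostic_ab = (params.locus_names[0], pos_ab + 1)
    # diagnostic B | C: an 8-bp indel in the second locus
    bc_s, bc_e = registry.take_window(1, 8)
    truth.diagnostic_bc = (params.locus_names[1], bc_s + 1, bc_e + 1)

    inv_region = None
    if params.tips_per_lineage > 0:
        inv_s, inv_e = registry.take_window(1, params.inversion_length)
        # the region must be detectably asymmetric under reverse complement
        for _ in range(100):
            segment = "".join(roots[1][inv_s : inv_e + 1])
            mismatches = sum(a != b for a, b in zip(segment, reverse_complement(segment)))
            if mismatches >= params.inversion_length // 2:
                break
            fresh = _random_sequence(rng, params.inversion_length)
            roots[1][inv_s : inv_e + 1] = fresh
        inv_region = (inv_s, inv_e)
        truth.inversion_region = (params.locus_names[1], inv_s + 1, inv_e + 1)

    core_mutations = {
        "A": {"subs": {(0, pos_ab): "G"}, "gaps": frozenset()},
        "B": {"subs": {}, "gaps": frozenset()},
        "C": {"subs": {}, "gaps": frozenset({(1, bc_s, bc_e)})},
    }
    pool: list[PoolHaplotype] = []
    n_subs = 1  # the A|B transition
    n_indels = 1  # the B|C indel
    n_inversions = 0
    for lin in LINEAGES:
        pool.append(
            PoolHaplotype(
                f"{lin}_core", lin, "core",
                dict(core_mutations[lin]["subs"]), core_mutations[lin]["gaps"], False,
            )
        )
    for lin in LINEAGES:
        base_subs = core_mutations[lin]["subs"]
        base_gaps = core_mutations[lin]["gaps"]
        for t in range(params.tips_per_lineage):
            subs = dict(base_subs)
            gaps = set(base_gaps)
            inverted = False
            if lin == "A" and t == 0:
                s, e = registry.take_window(0, 5)
                gaps.add((0, s, e))
                n_indels += 1
            elif lin == "B" and t == 0:
                inverted = True
                n_inversions += 1
            else:
                for _ in range(int(rng.integers(1, 4))):
                    locus = int(rng.integers(2))
                    if locus == 1 and inv_region is not None:
                        lo, hi = inv_region
                        pos = registry.take_position(1, predicate=lambda p: not lo <= p <= hi)
                    else:
                        pos = registry.take_position(locus)
                    current = roots[locus][pos]
                    alt = _BASES.replace(current, "")[rng.integers(3)]
                    subs[(locus, pos)] = alt
                    n_subs += 1
            pool.append(
                PoolHaplotype(f"{lin}_tip{t + 1}", lin, "tip", subs, frozenset(gaps), inverted)
            )

    for hap in pool:
        hap.rows = _build_rows(hap, roots, inv_region)
    truth.n_substitution_columns = n_subs
    truth.n_indel_characters = n_indels
    truth.n_inversion_characters = n_inversions
    for hap in pool:
        truth.haplotypes[hap.name] = {
            "lineage": hap.lineage,
            "kind": hap.kind,
            "mode": "random-shared" if hap.kind == "core" else "private",
            "home": None,
        }
    return pool, truth, roots


def _build_rows(hap: PoolHaplotype, roots, inv_region) -> tuple[str, str]:
    rows = []
    for locus, root in enumerate(roots):
        seq = list(root)
        for (loc, pos), base in hap.subs.items():
            if loc == locus:
                seq[pos] = base
        for loc, s, e in hap.gaps:
            if loc == locus:
                seq[s : e + 1] = ["-"] * (e - s + 1)
        if locus == 1 and hap.inverted and inv_region is not None:
            s, e = inv_region
            seq[s : e + 1] = list(reverse_complement("".join(seq[s : e + 1])))
        rows.append("".join(seq))
    return tuple(rows)


def _place_populations(params: SimulationParams, rng) -> pd.DataFrame:
    lat_lo, lat_hi, lon_lo, lon_hi = params.bbox
    lon_centers = np.linspace(lon_lo + 2, lon_hi - 2, params.n_clusters)
    lat_centers = np.where(
        np.arange(params.n_clusters) % 2 == 0,
        lat_lo + 0.3 * (lat_hi - lat_lo),
        lat_lo + 0.7 * (lat_hi - lat_lo),
    ) + rng.normal(0, 0.5, params.n_clusters)
    rows = []
    for sp, count in zip(params.species_names, params.pops_per_species):
        for k in range(count):
            cluster = int(rng.integers(params.n_clusters))
            lat = float(np.clip(lat_centers[cluster] + rng.normal(0, params.cluster_sd_deg), lat_lo, lat_hi))
            lon = float(np.clip(lon_centers[cluster] + rng.normal(0, params.cluster_sd_deg), lon_lo, lon_hi))
            rows.append(
                {
                    "population_code": f"{sp}_P{k + 1:02d}",
                    "species": sp,
                    "cluster": cluster,
                    "latitude": round(lat, 4),
                    "longitude": round(lon, 4),
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(params: SimulationParams) -> tuple[Dataset, GroundTruth]:
    """Generate a full dataset (two aligned loci + metadata) with ground truth."""
    rng = np.random.default_rng(params.seed)
    pool, truth, _ = simulate_haplotype_pool(params, rng)
    by_name = {h.name: h for h in pool}
    cores = [h for h in pool if h.kind == "core"]
    tips = [h for h in pool if h.kind == "tip"]
    core_names = [h.name for h in cores]
    core_p = np.array(params.core_frequencies, dtype=float)
    core_mass = core_p.sum()
    core_p_norm = core_p / core_mass

    pops = _place_populations(params, rng)

    # tip home cells, drawn among occupied (species, cluster) cells
    occupied = sorted({(r.species, r.cluster) for r in pops.itertuples()})
    for tip in tips:
        home = occupied[int(rng.integers(len(occupied)))]
        truth.haplotypes[tip.name]["home"] = list(home)
    tips_of_cell: dict[tuple, list[str]] = {}
    for tip in tips:
        tips_of_cell.setdefault(tuple(truth.haplotypes[tip.name]["home"]), []).append(tip.name)

    # per-population haplotype assignment
    assignment: dict[str, list[str]] = {}
    for row in pops.itertuples():
        cell_tips = tips_of_cell.get((row.species, row.cluster), [])
        if rng.random() < core_mass or not cell_tips:
            resident = core_names[int(rng.choice(len(core_names), p=core_p_norm))]
        else:
            resident = cell_tips[int(rng.integers(len(cell_tips)))]
        n = int(rng.integers(params.n_per_pop[0], params.n_per_pop[1] + 1))
        haps = []
        for _ in range(n):
            if rng.random() < params.resident_fidelity:
                haps.append(resident)
            else:
                haps.append(core_names[int(rng.choice(len(core_names), p=core_p_norm))])
        assignment[row.population_code] = haps

    # introgression: copy a tip haplotype into nearby heterospecific sinks
    lat = pops["latitude"].to_numpy()
    lon = pops["longitude"].to_numpy()
    codes = list(pops["population_code"])
    species = list(pops["species"])
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            if species[i] == species[j]:
                continue
            if haversine_km(lat[i], lon[i], lat[j], lon[j]) >= params.introgression_radius_km:
                continue
            if rng.random() >= params.introgression_rate:
                continue
            directions = []
            for src, snk in ((i, j), (j, i)):
                src_tips = sorted(
                    {h for h in assignment[codes[src]] if by_name[h].kind == "tip"}
                )
                if src_tips:
                    directions.append((src, snk, src_tips))
            if not directions:
                continue
            src, snk, src_tips = directions[int(rng.integers(len(directions)))]
            hap = src_tips[int(rng.integers(len(src_tips)))]
            sink_haps = assignment[codes[snk]]
            # introgressed copies establish in the resident core background so
            # earlier events are never silently overwritten by later ones
            replaceable = [k for k, h in enumerate(sink_haps) if by_name[h].kind == "core"]
            if not replaceable:
                continue
            frac = rng.beta(*params.introgression_beta)
            n_copy = min(max(1, int(round(frac * len(sink_haps)))), len(replaceable))
            idx = rng.choice(len(replaceable), size=n_copy, replace=False)
            for k in idx:
                sink_haps[replaceable[k]] = hap
            truth.events.append(
                {"source": codes[src], "sink": codes[snk], "haplotype": hap, "n_copied": int(n_copy)}
            )
            truth.haplotypes[hap]["mode"] = "introgressed"

    _ensure_coverage(assignment, pool, truth, pops, rng)

    individuals, ind_pop, ind_hap = [], [], []
    for row in pops.itertuples():
        for k, hap in enumerate(assignment[row.population_code]):
            ind = f"{row.population_code}_{k + 1:02d}"
            individuals.append(ind)
            ind_pop.append(row.population_code)
            ind_hap.append(hap)
            truth.assignments[ind] = hap

    pop_info = pops.set_index("population_code")
    frame = pd.DataFrame(
        {
            "individual_id": individuals,
            "population_code": ind_pop,
            "species": [pop_info.at[p, "species"] for p in ind_pop],
            "latitude": [pop_info.at[p, "latitude"] for p in ind_pop],
            "longitude": [pop_info.at[p, "longitude"] for p in ind_pop],
        }
    )
    alignments = [
        Alignment(
            params.locus_names[locus],
            list(individuals),
            [by_name[h].rows[locus] for h in ind_hap],
        )
        for locus in range(2)
    ]
    dataset = Dataset(alignments, PopulationTable(frame))
    return dataset, truth


def _ensure_coverage(assignment, pool, truth, pops, rng) -> None:
    """Guarantee every pool haplotype is carried by >= 1 emitted individual."""
    pop_rows = {r.population_code: r for r in pops.itertuples()}
    for _ in range(5):
        counts: dict[str, int] = {}
        for haps in assignment.values():
            for h in haps:
                counts[h] = counts.get(h, 0) + 1
        missing = [h for h in pool if counts.get(h.name, 0) == 0]
        if not missing:
            return
        for hap in missing:
            home = truth.haplotypes[hap.name]["home"]
            if home is not None:
                candidates = [
                    c for c, r in pop_rows.items()
                    if r.species == home[0] and r.cluster == home[1]
                ]
            else:
                candidates = list(pop_rows)
            target = max(candidates, key=lambda c: len(assignment[c]))
            haps = assignment[target]
            # replace a carrier of the locally commonest haplotype
            local = {}
            for h in haps:
                local[h] = local.get(h, 0) + 1
            donor = max(local, key=lambda h: (local[h], h))
            haps[haps.index(donor)] = hap.name
    log.warning("coverage enforcement did not stabilise in 5 rounds")


def inversion_config(params: SimulationParams, truth: GroundTruth) -> dict[str, tuple[int, int]]:
    """Per-locus inversion regions in the form the coding module expects."""
    if truth.inversion_region is None:
        return {}
    locus, s, e = truth.inversion_region
    return {locus: (s, e)}


def write_dataset(dataset: Dataset, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write FASTA per locus, metadata TSV and the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for aln in dataset.alignments:
        write_alignment(aln, out / f"{aln.locus_name}.fasta")
    write_population_table(dataset.populations, out / "populations.tsv")
    payload = asdict(truth)
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    log.info("wrote synthetic dataset to %s", out)
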