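"""End-to-end orchestration: dataset -> catalog -> network -> statistics.

Glue between the dataset container and the stage modules; every stage is
also usable on its own. Results are plain dataclass/DataFrame bundles that
the writers in :mod:`haploshare.dataio` know how to serialise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import popstats, sharing, spatial
from .amova import AmovaResult, amova as run_amova, amova_permutation, squared_distance_matrix
from .coding import HaplotypeCatalog, build_coded_matrix, collapse_haplotypes
from .dataio import (
    Dataset,
    write_haplotype_table,
    write_network,
    write_table,
)
from .network import HaploNetwork, hamming_matrix, median_joining

log = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    catalog: HaplotypeCatalog
    network: HaploNetwork
    pop_stats: pd.DataFrame
    diversity: pd.DataFrame  # Table-1-shaped: species, hT(SE), hS(SE), GST(SE), NST(SE), p
    amova_tables: dict[str, AmovaResult]
    sharing_results: dict[str, pd.DataFrame]  # per exclusion mode
    sharing_pairs: pd.DataFrame
    correlogram: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def build_catalog(dataset: Dataset, mask_min_run: int = 5) -> HaplotypeCatalog:
    """Code every locus of the dataset and collapse into haplotypes."""
    inversions = {}
    for locus_cfg in dataset.config.get("loci", []):
        inv = locus_cfg.get("inversion")
        if inv:
            inversions[locus_cfg["name"]] = (inv["start"], inv["end"])
    mask_min_run = dataset.config.get("mask_min_run", mask_min_run)
    matrix = build_coded_matrix(dataset.alignments, inversions, mask_min_run)
    return collapse_haplotypes(matrix, dataset.populations)


def _assignment_indices(catalog: HaplotypeCatalog, individuals: list[str]) -> np.ndarray:
    label_index = {lab: i for i, lab in enumerate(catalog.labels)}
    return np.array([label_index[catalog.assignments[i]] for i in individuals])


def analyze(
    dataset: Dataset,
    seed: int = 0,
    n_permutations: int = 10000,
    threshold_km: float = 300.0,
    spatial_permutations: int = 0,
    spatial_max_individuals: int = 500,
) -> AnalysisResult:
    """Run the full analysis with one master seed for every permutation test."""
    rng = np.random.default_rng(seed)
    catalog = build_catalog(dataset)
    dist = hamming_matrix(catalog)
    subst_dist = hamming_matrix(catalog, kinds={"substitution"})
    total_length = sum(a.length for a in dataset.alignments)
    net = median_joining(catalog)

    counts = catalog.counts_matrix(dataset.populations)
    coords = dataset.populations.coordinates()
    pop_stats = popstats.population_diversity(counts, subst_dist, total_length)
    pop_stats = pop_stats.join(coords)

    diversity_rows = []
    species_of_pop = dataset.populations.species_of_population()
    groups = {sp: [p for p, s in species_of_pop.items() if s == sp] for sp in dataset.populations.species}
    groups["all"] = list(counts.index)
    for name, pops in groups.items():
        sub = counts.loc[pops]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        sub_dist = dist[np.ix_(
            [catalog.labels.index(c) for c in sub.columns],
            [catalog.labels.index(c) for c in sub.columns],
        )]
        div = popstats.multi_population_diversity(sub)
        diff = popstats.differentiation(sub, sub_dist, n_permutations, rng)
        diversity_rows.append(
            {
                "group": name,
                "K": div.n_populations,
                "hT": div.h_t, "hT_SE": div.se_h_t,
                "hS": div.h_s, "hS_SE": div.se_h_s,
                "GST": diff.g_st, "GST_SE": diff.se_g_st,
                "NST": diff.n_st, "NST_SE": diff.se_n_st,
                "p_NST_gt_GST": diff.p_value,
            }
        )
    diversity = pd.DataFrame(diversity_rows)

    individuals = dataset.individuals
    assign_idx = _assignment_indices(catalog, [i for i in individuals if i in catalog.assignments])
    kept = [i for i in individuals if i in catalog.assignments]
    pop_of = dataset.populations.population_of()
    pop_labels = np.array([pop_of[i] for i in kept])
    sp_labels = np.array([species_of_pop[p] for p in pop_labels])
    d2 = squared_distance_matrix(dist, assign_idx)
    amova_tables = {"three_level": run_amova(d2, pop_labels, sp_labels)}
    amova_tables["three_level"].p_values["F_CT"] = amova_permutation(
        d2, pop_labels, sp_labels, "F_CT", n_permutations, rng
    )
    for sp in dataset.populations.species:
        sel = sp_labels == sp
        amova_tables[sp] = run_amova(d2[np.ix_(sel, sel)], pop_labels[sel])

    sharing_results = {}
    pairs_by_mode = {}
    top = sharing.most_widespread_haplotype(counts)
    for mode, exclude in (("none", None), (f"excluding_{top}", top)):
        res, pairs = sharing.sharing_test(counts, coords, threshold_km, exclude)
        sharing_results[mode] = sharing.results_table(res)
        pairs_by_mode[mode] = pairs
    sharing_pairs = sharing.enumerate_sharing_pairs(counts, coords, threshold_km, top)

    correlogram = None
    if spatial_permutations > 0:
        lat = np.array([coords.at[p, "latitude"] for p in pop_labels])
        lon = np.array([coords.at[p, "longitude"] for p in pop_labels])
        idx = np.arange(len(kept))
        if len(idx) > spatial_max_individuals:
            idx = np.sort(rng.choice(len(kept), spatial_max_individuals, replace=False))
        geo = spatial.pairwise_haversine(lat[idx], lon[idx])
        gen = spatial.individual_genetic_d2(dist, assign_idx[idx])
        corr = spatial.autocorrelogram(gen, geo)
        correlogram = spatial.autocorr_inference(
            corr, spatial_permutations, spatial_permutations, rng
        )

    return AnalysisResult(
        catalog,
        net,
        pop_stats,
        diversity,
        amova_tables,
        sharing_results,
        sharing_pairs,
        correlogram,
        extras={"excluded_haplotype": top, "pairs_by_mode": pairs_by_mode},
    )


def write_results(result: AnalysisResult, dataset: Dataset, out_dir: str | Path) -> list[Path]:
    """Write every result table; returns the list of files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(frame: pd.DataFrame, name: str, index: bool = False):
        path = out / name
        write_table(frame, path, index=index)
        written.append(path)

    write_haplotype_table(result.catalog, dataset.populations, out / "haplotypes.tsv")
    written.append(out / "haplotypes.tsv")
    write_network(result.network, out / "network.graphml", out / "network_edges.tsv")
    written.extend([out / "network.graphml", out / "network_edges.tsv"])
    _w(result.pop_stats, "population_stats.tsv", index=True)
    _w(result.diversity, "diversity_differentiation.tsv")
    for name, table in result.amova_tables.items():
        frame = table.rows.copy()
        frame["F_ST"] = table.f_st
        if table.f_ct is not None:
            frame["F_CT"] = table.f_ct
            frame["F_SC"] = table.f_sc
        for k, v in table.p_values.items():
            frame[f"p_{k}"] = v
        _w(frame, f"amova_{name}.tsv")
    for mode, frame in result.sharing_results.items():
        _w(frame, f"sharing_{mode}.tsv")
    _w(result.sharing_pairs, "sharing_pairs.tsv")
    if result.correlogram is not None:
        _w(result.correlogram, "correlogram.tsv")
    return written
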