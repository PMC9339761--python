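"""Ground-truth properties of the synthetic-data generator."""
import numpy as np
import pytest

from haploshare import build_catalog
from haploshare.coding import build_coded_matrix, collapse_haplotypes
from haploshare.network import cut_lineages, hamming_matrix, median_joining
from haploshare.sharing import enumerate_sharing_pairs, most_widespread_haplotype
from haploshare.synthetic_data import (
    SimulationParams,
    inversion_config,
    simulate_dataset,
    simulate_haplotype_pool,
    write_dataset,
)

SMALL = dict(pops_per_species=(6, 6, 6), n_per_pop=(5, 10), tips_per_lineage=3)


def build(seed, **overrides):
    params = SimulationParams(seed=seed, **{**SMALL, **overrides})
    dataset, truth = simulate_dataset(params)
    dataset.config = {
        "loci": [
            {"name": locus, "inversion": {"start": s, "end": e}}
            for locus, (s, e) in inversion_config(params, truth).items()
        ]
    }
    return params, dataset, truth


class TestHaplotypePool:
    def test_pool_size_and_lineage_composition(self):
        params = SimulationParams(seed=3, tips_per_lineage=4)
        pool, truth, _ = simulate_haplotype_pool(params)
        assert len(pool) == 3 * (1 + 4)
        assert sum(h.kind == "core" for h in pool) == 3
        assert truth.n_inversion_characters == 1

    def test_no_tips_yields_path_network_with_diagnostic_edges(self):
        _, dataset, truth = build(5, tips_per_lineage=0)
        catalog = build_catalog(dataset)
        assert len(catalog.haplotypes) == 3
        net = median_joining(catalog)
        degrees = sorted(d for _, d in net.graph.degree())
        assert degrees == [1, 1, 2]  # a path: core B between cores A and C
        # two diagnostic characters cut it into the three planted lineages
        diag = [i for i, _ in enumerate(catalog.characters)]
        part = cut_lineages(net, diag)
        assert len(set(part.labels.values())) == 3

    def test_seed_reproducibility(self):
        p1, _, _ = simulate_haplotype_pool(SimulationParams(seed=9))
        p2, _, _ = simulate_haplotype_pool(SimulationParams(seed=9))
        assert [h.rows for h in p1] == [h.rows for h in p2]

    def test_inversion_orientation_is_one_step(self):
        params = SimulationParams(seed=3)
        pool, truth, _ = simulate_haplotype_pool(params)
        by_name = {h.name: h for h in pool}
        flipped = by_name["B_tip1"]
        assert flipped.inverted
        assert flipped.rows[0] == by_name["B_core"].rows[0]
        assert flipped.rows[1] != by_name["B_core"].rows[1]


class TestDataset:
    def test_coding_recovers_planted_character_count(self):
        _, dataset, truth = build(11)
        catalog = build_catalog(dataset)
        assert len(catalog.characters) == truth.n_planted_characters
        assert len(catalog.haplotypes) == 3 * (1 + SMALL["tips_per_lineage"])
        assert catalog.excluded == []

    def test_catalog_matches_planted_assignment(self):
        _, dataset, truth = build(13)
        catalog = build_catalog(dataset)
        # individuals planted with the same pool haplotype collapse together
        planted_of_label = {}
        for ind, label in catalog.assignments.items():
            planted = truth.assignments[ind]
            planted_of_label.setdefault(label, set()).add(planted)
        assert all(len(v) == 1 for v in planted_of_label.values())

    def test_lineage_partition_recovers_planted_lineages(self):
        _, dataset, truth = build(17)
        catalog = build_catalog(dataset)
        net = median_joining(catalog)
        # locate the two diagnostic characters among the coded characters
        ab_locus, ab_pos = truth.diagnostic_ab
        bc_locus, bc_s, bc_e = truth.diagnostic_bc
        diag = [
            i
            for i, c in enumerate(catalog.characters)
            if (c.locus == ab_locus and c.start == ab_pos and c.kind == "substitution")
            or (c.locus == bc_locus and (c.start, c.end) == (bc_s, bc_e) and c.kind == "indel")
        ]
        assert len(diag) == 2
        part = cut_lineages(net, diag)
        # every planted lineage maps to exactly one component
        planted_of_component = {}
        label_of_ind = catalog.assignments
        for ind, pool_name in truth.assignments.items():
            lin = truth.haplotypes[pool_name]["lineage"]
            comp = part.labels[label_of_ind[ind]]
            planted_of_component.setdefault(comp, set()).add(lin)
        assert all(len(v) == 1 for v in planted_of_component.values())
        assert len(planted_of_component) == 3

    def test_rate_zero_no_tip_in_two_species(self):
        _, dataset, truth = build(19, introgression_rate=0.0)
        catalog = build_catalog(dataset)
        assert truth.events == []
        species_of_planted = {}
        sp_of_pop = dataset.populations.species_of_population()
        pop_of = dataset.populations.population_of()
        for ind, pool_name in truth.assignments.items():
            if truth.haplotypes[pool_name]["kind"] == "tip":
                species_of_planted.setdefault(pool_name, set()).add(sp_of_pop[pop_of[ind]])
        assert all(len(v) == 1 for v in species_of_planted.values())

    def test_rate_one_events_recovered_by_enumeration(self):
        _, dataset, truth = build(23, introgression_rate=1.0)
        assert truth.events
        catalog = build_catalog(dataset)
        counts = catalog.counts_matrix(dataset.populations)
        coords = dataset.populations.coordinates()
        top = most_widespread_haplotype(counts)
        pairs = enumerate_sharing_pairs(counts, coords, 300.0, exclude=top)
        pair_shared = {
            frozenset((r.pop_x, r.pop_y)): set(r.shared_haplotypes.split(","))
            for r in pairs.itertuples()
        }
        # map planted haplotype names to catalog labels via an individual
        label_of_planted = {}
        for ind, label in catalog.assignments.items():
            label_of_planted[truth.assignments[ind]] = label
        for event in truth.events:
            key = frozenset((event["source"], event["sink"]))
            shared = pair_shared.get(key)
            if shared is None:
                # the sink's introgressed copies were later overwritten by a
                # second event between the same populations; skip those
                others = [e for e in truth.events if frozenset((e["source"], e["sink"])) == key]
                assert len(others) >= 1
                continue
            assert label_of_planted[event["haplotype"]] in shared

    def test_byte_identical_outputs_for_fixed_seed(self, tmp_path):
        for run in ("a", "b"):
            params, dataset, truth = build(29)
            write_dataset(dataset, truth, tmp_path / run)
        for name in ("atpB-rbcL.fasta", "trnH-psbA.fasta", "populations.tsv", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_row_order_does_not_change_statistics(self, rng):
        """Permuting individuals leaves every downstream statistic identical."""
        from haploshare.popstats import gst_nst

        _, dataset, _ = build(31)
        matrix = build_coded_matrix(dataset.alignments)
        catalog = collapse_haplotypes(matrix, dataset.populations)
        perm = rng.permutation(len(dataset.individuals))
        shuffled = [dataset.alignments[0].sequence_ids[i] for i in perm]
        alns = [a.reordered(shuffled) for a in dataset.alignments]
        catalog2 = collapse_haplotypes(build_coded_matrix(alns), dataset.populations)
        c1 = catalog.counts_matrix(dataset.populations)
        c2 = catalog2.counts_matrix(dataset.populations)
        d1, d2 = hamming_matrix(catalog), hamming_matrix(catalog2)
        g1 = gst_nst(c1.to_numpy(float), d1.astype(float))
        g2 = gst_nst(c2.to_numpy(float), d2.astype(float))
        assert g1 == g2


class TestStudyRegimeFixture:
    def test_default_fixture_is_highly_differentiated(self):
        """The seed-42 default dataset sits in the high-GST regime."""
        from haploshare.popstats import gst_nst

        params = SimulationParams(seed=42)
        dataset, truth = simulate_dataset(params)
        dataset.config = {
            "loci": [
                {"name": locus, "inversion": {"start": s, "end": e}}
                for locus, (s, e) in inversion_config(params, truth).items()
            ]
        }
        catalog = build_catalog(dataset)
        assert len(catalog.haplotypes) == 27
        counts = catalog.counts_matrix(dataset.populations)
        dist = hamming_matrix(catalog).astype(float)
        sp_of = dataset.populations.species_of_population()
        for sp in dataset.populations.species:
            pops = [p for p, s in sp_of.items() if s == sp]
            sub = counts.loc[pops]
            sub = sub.loc[:, sub.sum(axis=0) > 0]
            cols = [catalog.labels.index(c) for c in sub.columns]
            g, _ = gst_nst(sub.to_numpy(float), dist[np.ix_(cols, cols)])
            assert g > 0.5
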