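"""Shared fixtures and small object factories for the test suite."""
from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from haploshare.coding import CodedCharacter, CodedMatrix, Haplotype, HaplotypeCatalog
from haploshare.dataio import Alignment, PopulationTable


def make_alignment(rows, ids=None, locus="locusX") -> Alignment:
    ids = ids or [f"ind{i + 1}" for i in range(len(rows))]
    return Alignment(locus, ids, [r.upper() for r in rows])


def make_poptable(assignments, coords=None, species=None) -> PopulationTable:
    """assignments: individual -> population; coords: pop -> (lat, lon)."""
    pops = sorted(set(assignments.values()))
    coords = coords or {p: (30.0 + i, 110.0 + i) for i, p in enumerate(pops)}
    species = species or {p: "sp1" for p in pops}
    rows = [
        {
            "individual_id": ind,
            "population_code": pop,
            "species": species[pop],
            "latitude": coords[pop][0],
            "longitude": coords[pop][1],
        }
        for ind, pop in assignments.items()
    ]
    return PopulationTable(pd.DataFrame(rows))


def make_catalog(vectors, pop_counts, species=None, kinds=None) -> HaplotypeCatalog:
    """Catalog from raw state vectors.

    vectors: label -> state tuple; pop_counts: label -> {pop: count};
    kinds: per-character kind list (defaults to all substitutions).
    """
    labels = list(vectors)
    n_chars = len(next(iter(vectors.values())))
    kinds = kinds or ["substitution"] * n_chars
    characters = [
        CodedCharacter("locusX", kind, i + 1, i + 1, tuple())
        for i, kind in enumerate(kinds)
    ]
    species = species or {}
    haplotypes = []
    assignments = {}
    counter = 0
    for label in labels:
        counts = Counter(pop_counts[label])
        total = sum(counts.values())
        sp = {species.get(p, "sp1") for p in counts}
        haplotypes.append(Haplotype(label, tuple(vectors[label]), total, counts, sp))
        for pop, k in counts.items():
            for _ in range(k):
                counter += 1
                assignments[f"i{counter}"] = label
    return HaplotypeCatalog(haplotypes, assignments, characters)


def make_matrix(rows, individuals=None, kinds=None) -> CodedMatrix:
    individuals = individuals or [f"ind{i + 1}" for i in range(len(rows))]
    n_chars = len(rows[0])
    kinds = kinds or ["substitution"] * n_chars
    characters = [
        CodedCharacter("locusX", kind, i + 1, i + 1, tuple(r[i] for r in rows))
        for i, kind in enumerate(kinds)
    ]
    return CodedMatrix(individuals, characters, np.array([list(r) for r in rows], dtype="<U1"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
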