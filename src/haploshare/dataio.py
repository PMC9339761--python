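"""Reading and writing of alignments, population metadata and result tables.

All tabular artifacts are UTF-8 tab-separated files; networks are exported
both as GraphML and as a plain edge list so they can be consumed without a
graph library. Coordinates are decimal degrees (WGS84 assumed, never
projected).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml
from Bio import SeqIO

log = logging.getLogger(__name__)

#: Symbols permitted in an aligned plastid sequence.
VALID_SYMBOLS = frozenset("ACGTN-")

POPULATION_COLUMNS = ["individual_id", "population_code", "species", "latitude", "longitude"]


@dataclass
class Alignment:
    """A single pre-aligned locus: equal-length rows over {A,C,G,T,-,N}."""

    locus_name: str
    sequence_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.sequence_ids) != len(self.rows):
            raise ValueError("sequence_ids and rows differ in length")
        if not self.rows:
            raise ValueError(f"{self.locus_name}: no records")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError(f"{self.locus_name}: duplicate sequence ids")
        length = len(self.rows[0])
        if length == 0:
            raise ValueError(f"{self.locus_name}: zero-length alignment")
        for sid, row in zip(self.sequence_ids, self.rows):
            if len(row) != length:
                raise ValueError(
                    f"{self.locus_name}: not aligned (record {sid!r} has length "
                    f"{len(row)}, expected {length})"
                )
            bad = set(row) - VALID_SYMBOLS
            if bad:
                ch = next(c for c in row if c in bad)
                raise ValueError(
                    f"{self.locus_name}: bad character {ch!r} in record {sid!r} "
                    f"at position {row.index(ch) + 1}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def row_of(self, individual_id: str) -> str:
        return self.rows[self.sequence_ids.index(individual_id)]

    def reordered(self, ids: list[str]) -> "Alignment":
        """Return a copy with rows in the given individual order."""
        index = {sid: i for i, sid in enumerate(self.sequence_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise ValueError(f"{self.locus_name}: individuals missing from alignment: {missing[:5]}")
        return Alignment(self.locus_name, list(ids), [self.rows[index[i]] for i in ids])


@dataclass
class PopulationTable:
    """Per-individual metadata: population, species and sampling coordinates."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"population table missing columns: {missing}")
        df = df[POPULATION_COLUMNS].copy()
        df["latitude"] = df["latitude"].astype(float)
        df["longitude"] = df["longitude"].astype(float)
        if df["individual_id"].duplicated().any():
            dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
            raise ValueError(f"duplicate individual_id {dup!r}")
        if ((df["latitude"] < -90) | (df["latitude"] > 90)).any():
            raise ValueError("latitude out of range [-90, 90]")
        if ((df["longitude"] < -180) | (df["longitude"] > 180)).any():
            raise ValueError("longitude out of range [-180, 180]")
        for pop, sub in df.groupby("population_code"):
            if sub["species"].nunique() != 1:
                raise ValueError(f"population {pop!r} maps to multiple species")
            if sub["latitude"].nunique() != 1 or sub["longitude"].nunique() != 1:
                raise ValueError(f"population {pop!r} has inconsistent coordinates")
        self.frame = df.reset_index(drop=True)

    @property
    def individuals(self) -> list[str]:
        return list(self.frame["individual_id"])

    @property
    def populations(self) -> list[str]:
        return sorted(self.frame["population_code"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.frame["individual_id"], self.frame["population_code"]))

    def species_of_population(self) -> dict[str, str]:
        return {
            pop: sub["species"].iloc[0]
            for pop, sub in self.frame.groupby("population_code")
        }

    def coordinates(self) -> pd.DataFrame:
        """One row per population: species, latitude, longitude."""
        out = (
            self.frame.groupby("population_code")
            .agg(species=("species", "first"), latitude=("latitude", "first"), longitude=("longitude", "first"))
            .sort_index()
        )
        return out

    def individuals_of(self, population: str) -> list[str]:
        sub = self.frame[self.frame["population_code"] == population]
        return list(sub["individual_id"])


@dataclass
class Dataset:
    """Joint dataset: one or more aligned loci over an identical individual set."""

    alignments: list[Alignment]
    populations: PopulationTable
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.alignments:
            raise ValueError("dataset needs at least one alignment")
        meta_ids = set(self.populations.individuals)
        for aln in self.alignments:
            aln_ids = set(aln.sequence_ids)
            absent = meta_ids - aln_ids
            if absent:
                raise ValueError(
                    f"individuals in metadata but absent from locus {aln.locus_name!r}: "
                    f"{sorted(absent)[:5]}"
                )
            extra = aln_ids - meta_ids
            if extra:
                raise ValueError(
                    f"individuals in locus {aln.locus_name!r} missing from metadata: "
                    f"{sorted(extra)[:5]}"
                )
        order = self.populations.individuals
        self.alignments = [a.reordered(order) for a in self.alignments]

    @property
    def individuals(self) -> list[str]:
        return self.populations.individuals


def read_alignment(path: str | Path, locus_name: str) -> Alignment:
    """Read a FASTA alignment; rows are upper-cased, lengths must agree."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no records")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return Alignment(locus_name, ids, rows)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, row in zip(alignment.sequence_ids, alignment.rows):
            fh.write(f">{sid}\n{row}\n")


def read_population_table(path: str | Path) -> PopulationTable:
    """Read the TSV metadata table (individual_id, population_code, species, latitude, longitude)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "population_code": str, "species": str})
    return PopulationTable(df)


def write_population_table(table: PopulationTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    """Load the YAML configuration (mask/inversion regions, thresholds, seeds)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
    log.info("wrote table %s (%d rows)", path, len(frame))


def write_haplotype_table(catalog, populations: PopulationTable, path: str | Path) -> None:
    """Haplotype catalog as TSV: label, total, species occupancy, per-population counts."""
    pops = populations.populations
    rows = []
    for hap in catalog.haplotypes:
        row = {
            "haplotype": hap.label,
            "total": hap.total,
            "species": ",".join(sorted(hap.species)),
        }
        for pop in pops:
            row[pop] = hap.pop_counts.get(pop, 0)
        rows.append(row)
    write_table(pd.DataFrame(rows), path)


def read_haplotype_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("haplotype")


def write_network(network, graphml_path: str | Path, edgelist_path: str | Path) -> None:
    """Export a haplotype network as GraphML plus a plain edge-list TSV."""
    graph = network.graph.copy()
    for _, data in graph.nodes(data=True):
        data.pop("vector", None)  # tuples are not GraphML-serialisable
        if "species" in data and not isinstance(data["species"], str):
            data["species"] = ",".join(sorted(data["species"]))
    for _, _, data in graph.edges(data=True):
        if "diff_chars" in data:
            data["diff_chars"] = ",".join(str(i) for i in data["diff_chars"])
    nx.write_graphml(graph, str(graphml_path))
    rows = [
        {"node_a": a, "node_b": b, "mutations": data["mutations"]}
        for a, b, data in sorted(network.graph.edges(data=True))
    ]
    write_table(pd.DataFrame(rows, columns=["node_a", "node_b", "mutations"]), edgelist_path)
    log.info("wrote network %s / %s", graphml_path, edgelist_path)
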