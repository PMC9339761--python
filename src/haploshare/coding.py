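"""Character coding of non-coding plastid alignments and haplotype collapsing.

An aligned locus is converted into a matrix of coded characters:

* substitutions — one character per column carrying at least two distinct
  bases (base-vs-gap polymorphism alone belongs to an indel, not here);
* indels — simple gap coding (Simmons & Ochoterena): every maximal gap run
  with identical start/end coordinates is one binary presence/absence
  character, treated downstream as a single mutation event. A sequence whose
  own gap overlaps but does not equal the indel's coordinates cannot be
  scored and is recorded as missing for that character;
* inversions — a configured region is re-oriented (rows closer to the
  reverse complement of the majority consensus are rewritten) and the
  orientation becomes one binary character.

Length variation inside mononucleotide repeats is masked before indel
coding because such microsatellite-like runs are prone to homoplasy.
Binary characters use A (absent / majority orientation) and T (present /
inverted) as their two states. Missing states are written ``?``.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .dataio import Alignment, PopulationTable

log = logging.getLogger(__name__)

MISSING = "?"
GAP = "-"

KIND_SUBSTITUTION = "substitution"
KIND_INDEL = "indel"
KIND_INVERSION = "inversion"

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodedCharacter:
    """One coded character with per-individual states.

    ``start``/``end`` are 1-based inclusive alignment coordinates. States are
    single symbols (nucleotides, or A/T for binary indel/inversion
    characters) with ``?`` marking a missing state. ``length`` carries the
    indel length in bp (1 for substitutions, region length for inversions).
    """

    locus: str
    kind: str
    start: int
    end: int
    states: tuple[str, ...]
    length: int = 1

    def observed_states(self) -> set[str]:
        return {s for s in self.states if s != MISSING}

    @property
    def is_polymorphic(self) -> bool:
        return len(self.observed_states()) >= 2


@dataclass
class CodedMatrix:
    """Individuals x coded characters, the substrate for all downstream stages."""

    individuals: list[str]
    characters: list[CodedCharacter]
    states: np.ndarray  # shape (n_individuals, n_characters), dtype <U1

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.individuals), len(self.characters)):
            raise ValueError("state matrix shape does not match individuals x characters")

    @property
    def n_characters(self) -> int:
        return len(self.characters)


@dataclass
class Haplotype:
    label: str
    vector: tuple[str, ...]
    total: int
    pop_counts: Counter
    species: set[str]
    lineage: str | None = None


@dataclass
class HaplotypeCatalog:
    """Distinct haplotypes plus the individual -> haplotype assignment map."""

    haplotypes: list[Haplotype]
    assignments: dict[str, str]
    characters: list[CodedCharacter]
    excluded: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.haplotypes]

    def get(self, label: str) -> Haplotype:
        for h in self.haplotypes:
            if h.label == label:
                return h
        raise KeyError(label)

    def vectors(self) -> np.ndarray:
        """Haplotype state matrix (n_haplotypes x n_characters) in label order."""
        return np.array([list(h.vector) for h in self.haplotypes], dtype="<U1")

    @property
    def n_individuals(self) -> int:
        return sum(h.total for h in self.haplotypes)

    def counts_matrix(self, populations: PopulationTable):
        """Per-population haplotype counts as a populations x haplotypes DataFrame."""
        import pandas as pd

        pops = populations.populations
        data = {
            h.label: [h.pop_counts.get(p, 0) for p in pops] for h in self.haplotypes
        }
        return pd.DataFrame(data, index=pops)


def mask_mononucleotide_repeats(alignment: Alignment, min_run: int = 5) -> set[int]:
    """0-based columns lying in a mononucleotide run of >= ``min_run`` bases.

    Runs are measured on the column consensus; all-gap columns inside a run
    do not interrupt it (gaps are ignored when measuring run length).
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    consensus = _column_consensus(alignment)
    mask: set[int] = set()
    run_cols: list[int] = []
    run_base: str | None = None
    run_len = 0  # non-gap columns only

    def flush() -> None:
        nonlocal run_cols, run_len, run_base
        if run_len >= min_run:
            mask.update(run_cols)
        run_cols, run_len, run_base = [], 0, None

    for col, base in enumerate(consensus):
        if base == GAP:
            if run_base is not None:
                run_cols.append(col)  # interior gap column, does not break the run
            continue
        if base == run_base:
            run_cols.append(col)
            run_len += 1
        else:
            flush()
            run_base, run_cols, run_len = base, [col], 1
    flush()
    return mask


def _base_counts(arr: np.ndarray) -> np.ndarray:
    """Per-column counts of A, C, G, T (shape 4 x n_columns)."""
    return np.stack([(arr == b).sum(axis=0) for b in "ACGT"])


def _column_consensus(alignment: Alignment) -> str:
    arr = np.array([list(r) for r in alignment.rows], dtype="<U1")
    counts = _base_counts(arr)
    # majority base; argmax breaks ties alphabetically, all-gap columns -> '-'
    best = np.array(list("ACGT"))[counts.argmax(axis=0)]
    best[counts.sum(axis=0) == 0] = GAP
    return "".join(best)


def call_substitutions(alignment: Alignment) -> list[CodedCharacter]:
    """One character per column with >= 2 distinct bases; gaps/N are missing."""
    arr = np.array([list(r) for r in alignment.rows], dtype="<U1")
    polymorphic = np.flatnonzero((_base_counts(arr) > 0).sum(axis=0) >= 2)
    chars: list[CodedCharacter] = []
    for col in polymorphic:
        column = arr[:, col]
        states = tuple(c if c in "ACGT" else MISSING for c in column)
        chars.append(
            CodedCharacter(alignment.locus_name, KIND_SUBSTITUTION, int(col) + 1, int(col) + 1, states)
        )
    return chars


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal gap runs as 0-based inclusive (start, end)."""
    runs = []
    start = None
    for i, ch in enumerate(row):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(row) - 1))
    return runs


def code_indels(alignment: Alignment, mask: set[int] | None = None) -> list[CodedCharacter]:
    """Simple gap coding: one binary character per distinct gap coordinate pair.

    A = gap absent, T = gap present; a sequence whose own gap overlaps the
    indel without matching both coordinates is scored missing. Indels lying
    entirely inside the mononucleotide-repeat mask are not coded.
    """
    mask = mask or set()
    per_row_runs = [_gap_runs(row) for row in alignment.rows]
    candidates = sorted({run for runs in per_row_runs for run in runs})
    chars: list[CodedCharacter] = []
    for s, e in candidates:
        if all(col in mask for col in range(s, e + 1)):
            log.debug("%s: indel %d-%d inside repeat mask, not coded", alignment.locus_name, s + 1, e + 1)
            continue
        states = []
        for runs in per_row_runs:
            if (s, e) in runs:
                states.append("T")
            elif any(rs <= e and re >= s for rs, re in runs):
                states.append(MISSING)  # nested or partially overlapping gap
            else:
                states.append("A")
        char = CodedCharacter(
            alignment.locus_name, KIND_INDEL, s + 1, e + 1, tuple(states), length=e - s + 1
        )
        if char.is_polymorphic:
            chars.append(char)
    return chars


def apply_inversion(
    alignment: Alignment, start: int, end: int
) -> tuple[Alignment, CodedCharacter | None]:
    """Re-orient rows carrying the inverted region; code orientation as A/T.

    ``start``/``end`` are 1-based inclusive. A row is called inverted when
    its region matches the reverse complement of the majority-orientation
    consensus better than the consensus itself. Inverted rows are replaced
    by the reverse complement of their region so that downstream characters
    see a homogeneous orientation; one binary character records orientation
    (A = majority, T = inverted). Returns the character as ``None`` when all
    rows share one orientation.
    """
    if not (1 <= start <= end <= alignment.length):
        raise ValueError(
            f"inversion region {start}-{end} out of bounds for {alignment.locus_name} "
            f"(length {alignment.length})"
        )
    lo, hi = start - 1, end
    region_consensus = _column_consensus(
        Alignment(alignment.locus_name, alignment.sequence_ids, [r[lo:hi] for r in alignment.rows])
    )
    rc_consensus = reverse_complement(region_consensus)

    def score(seg: str, ref: str) -> int:
        return sum(a == b for a, b in zip(seg, ref) if a in "ACGT" and b in "ACGT")

    inverted = []
    for row in alignment.rows:
        seg = row[lo:hi]
        inverted.append(score(seg, rc_consensus) > score(seg, region_consensus))
    n_inv = sum(inverted)
    # minority class is the "inverted" one; on an exact tie the first row
    # defines the reference orientation
    if n_inv * 2 > len(inverted) or (n_inv * 2 == len(inverted) and inverted[0]):
        inverted = [not f for f in inverted]
    if not any(inverted):
        return alignment, None
    new_rows = []
    for row, inv in zip(alignment.rows, inverted):
        if inv:
            row = row[:lo] + reverse_complement(row[lo:hi]) + row[hi:]
        new_rows.append(row)
    states = tuple("T" if inv else "A" for inv in inverted)
    char = CodedCharacter(
        alignment.locus_name, KIND_INVERSION, start, end, states, length=end - start + 1
    )
    return Alignment(alignment.locus_name, list(alignment.sequence_ids), new_rows), char


def code_alignment(
    alignment: Alignment,
    inversion: tuple[int, int] | None = None,
    mask_min_run: int = 5,
) -> list[CodedCharacter]:
    """Full coding of one locus: inversion, repeat mask, substitutions, indels."""
    chars: list[CodedCharacter] = []
    if inversion is not None:
        alignment, inv_char = apply_inversion(alignment, *inversion)
        if inv_char is not None:
            chars.append(inv_char)
    mask = mask_mononucleotide_repeats(alignment, mask_min_run)
    chars.extend(call_substitutions(alignment))
    chars.extend(code_indels(alignment, mask))
    chars.sort(key=lambda c: (c.start, c.end, c.kind))
    return [c for c in chars if c.is_polymorphic]


def build_coded_matrix(
    alignments: list[Alignment],
    inversions: dict[str, tuple[int, int]] | None = None,
    mask_min_run: int = 5,
) -> CodedMatrix:
    """Code every locus and concatenate the characters into one matrix.

    All alignments must cover the same individual set; rows are reordered to
    the first alignment's order. Monomorphic characters never enter the
    matrix.
    """
    inversions = inversions or {}
    order = list(alignments[0].sequence_ids)
    if any(set(a.sequence_ids) != set(order) for a in alignments):
        raise ValueError("alignments do not share an identical individual set")
    characters: list[CodedCharacter] = []
    columns: list[tuple[str, ...]] = []
    for aln in alignments:
        aln = aln.reordered(order)
        for char in code_alignment(aln, inversions.get(aln.locus_name), mask_min_run):
            characters.append(char)
            columns.append(char.states)
    states = (
        np.array(columns, dtype="<U1").T
        if columns
        else np.empty((len(order), 0), dtype="<U1")
    )
    return CodedMatrix(order, characters, states)


def collapse_haplotypes(
    matrix: CodedMatrix,
    populations: PopulationTable,
    label_map: dict[str, str] | None = None,
) -> HaplotypeCatalog:
    """Collapse identical state vectors into haplotypes.

    Missing states match nothing: individuals with any ``?`` at a retained
    character are excluded (with a warning) so that haplotype identity stays
    exact. Labels are H1, H2, ... by descending total count, ties broken by
    first occurrence in input order; ``label_map`` can rename the
    frequency-ranked labels for reproduction runs against published numbers.
    """
    pop_of = populations.population_of()
    species_of_pop = populations.species_of_population()

    excluded = [
        ind
        for ind, row in zip(matrix.individuals, matrix.states)
        if MISSING in row
    ]
    if excluded:
        log.warning(
            "%d individual(s) excluded from the catalog for missing states: %s%s",
            len(excluded),
            ", ".join(excluded[:5]),
            "..." if len(excluded) > 5 else "",
        )
    kept = [i for i, ind in enumerate(matrix.individuals) if ind not in set(excluded)]

    first_seen: dict[tuple[str, ...], int] = {}
    members: dict[tuple[str, ...], list[str]] = {}
    for rank, i in enumerate(kept):
        vec = tuple(matrix.states[i])
        if vec not in first_seen:
            first_seen[vec] = rank
            members[vec] = []
        members[vec].append(matrix.individuals[i])

    ordered = sorted(members, key=lambda v: (-len(members[v]), first_seen[v]))
    haplotypes: list[Haplotype] = []
    assignments: dict[str, str] = {}
    for k, vec in enumerate(ordered, start=1):
        label = f"H{k}"
        if label_map:
            label = label_map.get(label, label)
        inds = members[vec]
        pop_counts = Counter(pop_of[i] for i in inds)
        species = {species_of_pop[p] for p in pop_counts}
        haplotypes.append(Haplotype(label, vec, len(inds), pop_counts, species))
        for ind in inds:
            assignments[ind] = label
    return HaplotypeCatalog(haplotypes, assignments, list(matrix.characters), excluded)
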