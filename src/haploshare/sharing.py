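"""Interspecific gene-identity sharing test.

The core question: do nearby heterospecific populations look more alike in
haplotype composition than distant ones? Shared ancestral polymorphism
predicts geographically random sharing; introgression predicts local
sharing. For every pair of populations from different species we compute the
gene identity J of their haplotype frequency vectors, split the pairs into

* G1 — separated by < threshold km AND sharing >= 1 haplotype,
* G2 — separated by < threshold km (regardless of sharing),
* G3 — separated by >= threshold km,

and compare the J distributions with two-sided Wilcoxon rank-sum tests
(P12, P13, P23). The whole analysis is run with and without the most
widespread haplotype: excluding it removes the signal of the dominant
ancestral haplotype, so a surviving excess of nearby identity (M2 > M3,
small P23) points to introgression.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spatial import haversine_km

log = logging.getLogger(__name__)

GROUP_NEAR_SHARING = "G1"
GROUP_NEAR = "G2"
GROUP_FAR = "G3"


@dataclass
class SharingResult:
    species_pair: str
    exclusion: str | None
    threshold_km: float
    n1: int
    n2: int
    n3: int
    m1: float
    m2: float
    m3: float
    p12: float
    p13: float
    p23: float


def gene_identity(freq_x: np.ndarray, freq_y: np.ndarray, mode: str = "normalized") -> float:
    """Gene identity between two haplotype frequency vectors.

    ``normalized`` is the Nei normalized identity
    J = sum x_i y_i / sqrt(sum x_i^2 * sum y_i^2), bounded in [0, 1];
    ``raw`` is the unnormalized sum x_i y_i used in part of the older
    literature.
    """
    x = np.asarray(freq_x, dtype=float)
    y = np.asarray(freq_y, dtype=float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("gene identity undefined for an empty population")
    raw = float(x @ y)
    if mode == "raw":
        return raw
    if mode == "normalized":
        return raw / float(np.sqrt((x**2).sum() * (y**2).sum()))
    raise ValueError(f"unknown identity mode {mode!r}")


def exclude_haplotype(counts: pd.DataFrame, label: str) -> pd.DataFrame:
    """Drop all carriers of one haplotype; populations left empty disappear.

    A label no population carries is a no-op. Species-level emptiness is the
    caller's concern (see :func:`sharing_test`, which refuses an exclusion
    that wipes out a whole species).
    """
    if label not in counts.columns:
        return counts.copy()
    out = counts.drop(columns=[label])
    emptied = out.sum(axis=1) == 0
    if emptied.any():
        log.info("exclusion of %s drops %d population(s): %s", label, int(emptied.sum()),
                 ", ".join(out.index[emptied][:5]))
    return out.loc[~emptied]


def most_widespread_haplotype(counts: pd.DataFrame) -> str:
    """Label of the haplotype with the highest total count."""
    return str(counts.sum(axis=0).idxmax())


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value.

    Exact distribution when both samples have n <= 20 and no ties; normal
    approximation with tie correction (and continuity correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def pair_identities(
    counts: pd.DataFrame,
    coordinates: pd.DataFrame,
    threshold_km: float = 300.0,
    identity: str = "normalized",
) -> pd.DataFrame:
    """One row per heterospecific population pair: distance, J, sharing, group.

    ``counts`` is populations x haplotypes; ``coordinates`` has species,
    latitude, longitude indexed by population. Grouping uses a strict <
    threshold for "nearby".
    """
    pops = [p for p in counts.index if p in coordinates.index]
    freqs = counts.loc[pops].div(counts.loc[pops].sum(axis=1), axis=0)
    present = counts.loc[pops] > 0
    meta = coordinates.loc[pops]
    rows = []
    for x, y in itertools.combinations(pops, 2):
        if meta.at[x, "species"] == meta.at[y, "species"]:
            continue
        dist = float(
            haversine_km(
                meta.at[x, "latitude"], meta.at[x, "longitude"],
                meta.at[y, "latitude"], meta.at[y, "longitude"],
            )
        )
        j = gene_identity(freqs.loc[x].to_numpy(), freqs.loc[y].to_numpy(), identity)
        shared = sorted(counts.columns[(present.loc[x] & present.loc[y]).to_numpy()])
        near = dist < threshold_km
        rows.append(
            {
                "pop_x": x,
                "pop_y": y,
                "species_x": meta.at[x, "species"],
                "species_y": meta.at[y, "species"],
                "species_pair": "-".join(sorted([meta.at[x, "species"], meta.at[y, "species"]])),
                "distance_km": dist,
                "J": j,
                "shares_any": bool(shared),
                "shared_haplotypes": ",".join(shared),
                "group": GROUP_NEAR if near else GROUP_FAR,
                "in_g1": near and bool(shared),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pop_x", "pop_y", "species_x", "species_y", "species_pair",
            "distance_km", "J", "shares_any", "shared_haplotypes", "group", "in_g1",
        ],
    )


def _result_from_pairs(
    pairs: pd.DataFrame, species_pair: str, exclusion: str | None, threshold_km: float
) -> SharingResult:
    g1 = pairs.loc[pairs["in_g1"].astype(bool), "J"].to_numpy()
    g2 = pairs.loc[pairs["group"] == GROUP_NEAR, "J"].to_numpy()
    g3 = pairs.loc[pairs["group"] == GROUP_FAR, "J"].to_numpy()

    def mean(v):
        return float(np.mean(v)) if len(v) else float("nan")

    def wtest(u, v):
        if len(u) == 0 or len(v) == 0:
            return float("nan")
        return wilcoxon_rank_sum(u, v)

    return SharingResult(
        species_pair, exclusion, threshold_km,
        len(g1), len(g2), len(g3),
        mean(g1), mean(g2), mean(g3),
        wtest(g1, g2), wtest(g1, g3), wtest(g2, g3),
    )


def sharing_test(
    counts: pd.DataFrame,
    coordinates: pd.DataFrame,
    threshold_km: float = 300.0,
    exclude: str | None = None,
    identity: str = "normalized",
) -> tuple[dict[str, SharingResult], pd.DataFrame]:
    """Gene-identity comparison per species pair and pooled over all species.

    With ``exclude`` set, the named haplotype's carriers are removed before
    anything else (so G1's sharing flag never counts the excluded haplotype
    and populations fixed for it vanish, shrinking the pair counts).
    Returns the per-group results plus the underlying pair table.
    """
    species = coordinates["species"].unique()
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    if exclude is not None:
        kept = exclude_haplotype(counts, exclude)
        surviving = coordinates.loc[[p for p in kept.index if p in coordinates.index], "species"]
        lost = set(species) - set(surviving.unique())
        if lost:
            raise ValueError(f"excluding {exclude!r} empties species: {sorted(lost)}")
        counts = kept
    pairs = pair_identities(counts, coordinates, threshold_km, identity)
    results = {}
    for sp_pair, sub in pairs.groupby("species_pair"):
        results[sp_pair] = _result_from_pairs(sub, sp_pair, exclude, threshold_km)
    if len(species) > 2 and not pairs.empty:
        results["all"] = _result_from_pairs(pairs, "all", exclude, threshold_km)
    return results, pairs


def enumerate_sharing_pairs(
    counts: pd.DataFrame,
    coordinates: pd.DataFrame,
    threshold_km: float = 300.0,
    exclude: str | None = None,
) -> pd.DataFrame:
    """Nearby heterospecific pairs sharing >= 1 haplotype other than ``exclude``.

    Unlike :func:`sharing_test`, the excluded haplotype is only removed from
    the shared-label sets; populations keep their other haplotypes.
    """
    if exclude is not None and exclude in counts.columns:
        counts = counts.drop(columns=[exclude])
        counts = counts.loc[counts.sum(axis=1) > 0]
    pairs = pair_identities(counts, coordinates, threshold_km)
    out = pairs[pairs["in_g1"].astype(bool)].copy()
    return out[
        ["pop_x", "pop_y", "species_x", "species_y", "species_pair", "distance_km", "shared_haplotypes", "J"]
    ].reset_index(drop=True)


def results_table(results: dict[str, SharingResult]) -> pd.DataFrame:
    """Flatten SharingResults into a table shaped like the published layout."""
    rows = []
    for key in sorted(results, key=lambda k: (k == "all", k)):
        r = results[key]
        rows.append(
            {
                "species_group": r.species_pair,
                "exclusion": r.exclusion or "none",
                "N1": r.n1, "M1": r.m1,
                "N2": r.n2, "M2": r.m2,
                "N3": r.n3, "M3": r.m3,
                "P12": r.p12, "P13": r.p13, "P23": r.p23,
            }
        )
    return pd.DataFrame(rows)
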