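"""Individual-level multivariate spatial autocorrelation (Smouse & Peakall).

The squared genetic-distance matrix between individuals is double-centred
into a covariance-like matrix C; for each geographic distance class h the
autocorrelation coefficient is

    r(h) = sum_{(i,j) in h} 2 c_ij / sum_{(i,j) in h} (c_ii + c_jj)

over unordered pairs. Inference is by (a) permuting the individual ->
location mapping wholesale (one null network per replicate, shared by all
classes) with the observed r called significant when it exceeds the upper
95% permutation bound, and (b) bootstrap resampling of pairs within a class,
significant when the 95% CI excludes zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    lat, lon = np.asarray(lat, dtype=float), np.asarray(lon, dtype=float)
    return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


def distance_classes(
    distances_km: np.ndarray, width_km: float = 50.0, n_classes: int = 20
) -> np.ndarray:
    """Half-open 1-based distance classes [0,w), [w,2w), ...; 0 = beyond the last bin."""
    if width_km <= 0:
        raise ValueError("width_km must be > 0")
    d = np.asarray(distances_km, dtype=float)
    cls = np.floor(d / width_km).astype(int) + 1
    excluded = cls > n_classes
    if excluded.any():
        log.info("%d pair distance(s) beyond the last class excluded", int(excluded.sum()))
    cls[excluded] = 0
    return cls


def gower_center(d2: np.ndarray) -> np.ndarray:
    """Double-centre a squared-distance matrix into a covariance-like matrix."""
    d2 = np.asarray(d2, dtype=float)
    row = d2.mean(axis=1, keepdims=True)
    return -0.5 * (d2 - row - row.T + d2.mean())


@dataclass
class Correlogram:
    table: pd.DataFrame  # class, lo_km, hi_km, n_pairs, r (+ inference columns)
    c_matrix: np.ndarray
    class_pairs: dict[int, tuple[np.ndarray, np.ndarray]]
    width_km: float
    n_classes: int


def _r_from_pairs(c: np.ndarray, i: np.ndarray, j: np.ndarray) -> float:
    den = (c[i, i] + c[j, j]).sum()
    if den == 0:
        return float("nan")
    return float(2.0 * c[i, j].sum() / den)


def autocorrelogram(
    genetic_d2: np.ndarray,
    geo_km: np.ndarray,
    width_km: float = 50.0,
    n_classes: int = 20,
) -> Correlogram:
    """Autocorrelation coefficient r per distance class.

    ``genetic_d2`` holds squared genetic distances between individuals and
    ``geo_km`` the matching geographic distances. Classes without pairs, or
    an all-identical genotype matrix (C = 0), yield r = NaN and are flagged
    in the table.
    """
    genetic_d2 = np.asarray(genetic_d2, dtype=float)
    n = genetic_d2.shape[0]
    if np.asarray(geo_km).shape != (n, n):
        raise ValueError("genetic and geographic matrices are not conformable")
    c = gower_center(genetic_d2)
    iu, ju = np.triu_indices(n, k=1)
    cls = distance_classes(np.asarray(geo_km)[iu, ju], width_km, n_classes)
    class_pairs = {}
    rows = []
    for h in range(1, n_classes + 1):
        sel = cls == h
        i, j = iu[sel], ju[sel]
        class_pairs[h] = (i, j)
        r = _r_from_pairs(c, i, j) if len(i) else float("nan")
        rows.append(
            {
                "class": h,
                "lo_km": (h - 1) * width_km,
                "hi_km": h * width_km,
                "n_pairs": len(i),
                "r": r,
                "flagged": len(i) == 0 or not np.isfinite(r),
            }
        )
    return Correlogram(pd.DataFrame(rows), c, class_pairs, width_km, n_classes)


def autocorr_inference(
    correlogram: Correlogram,
    n_permutations: int = 9999,
    n_bootstrap: int = 9999,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Permutation bounds, permutation p and bootstrap CI per distance class."""
    rng = np.random.default_rng(rng)
    c = correlogram.c_matrix
    n = c.shape[0]
    table = correlogram.table.copy()
    classes = [h for h in correlogram.class_pairs if len(correlogram.class_pairs[h][0])]

    perm_r = {h: np.empty(n_permutations) for h in classes}
    for b in range(n_permutations):
        perm = rng.permutation(n)
        for h in classes:
            i, j = correlogram.class_pairs[h]
            perm_r[h][b] = _r_from_pairs(c, perm[i], perm[j])

    boot_lo = {}
    boot_hi = {}
    for h in classes:
        i, j = correlogram.class_pairs[h]
        m = len(i)
        if n_bootstrap == 0:
            boot_lo[h] = boot_hi[h] = float("nan")
            continue
        if m < 2:
            log.info("class %d has < 2 pairs: bootstrap skipped", h)
            boot_lo[h] = boot_hi[h] = float("nan")
            continue
        stats = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            pick = rng.integers(0, m, size=m)
            stats[b] = _r_from_pairs(c, i[pick], j[pick])
        boot_lo[h], boot_hi[h] = np.nanpercentile(stats, [2.5, 97.5])

    lower, upper, pvals, lo_ci, hi_ci = [], [], [], [], []
    for _, row in table.iterrows():
        h = int(row["class"])
        if h not in classes:
            lower.append(float("nan"))
            upper.append(float("nan"))
            pvals.append(float("nan"))
            lo_ci.append(float("nan"))
            hi_ci.append(float("nan"))
            continue
        null = perm_r[h]
        lower.append(float(np.nanpercentile(null, 2.5)))
        upper.append(float(np.nanpercentile(null, 97.5)))
        pvals.append(float((np.sum(null >= row["r"]) + 1) / (n_permutations + 1)))
        lo_ci.append(boot_lo[h])
        hi_ci.append(boot_hi[h])
    table["perm_lower"] = lower
    table["perm_upper"] = upper
    table["perm_p"] = pvals
    table["boot_lo"] = lo_ci
    table["boot_hi"] = hi_ci
    table["significant_perm"] = table["r"] > table["perm_upper"]
    table["significant_boot"] = (table["boot_lo"] > 0) | (table["boot_hi"] < 0)
    return table


def individual_genetic_d2(hap_distance: np.ndarray, assignments: np.ndarray, squared: bool = True) -> np.ndarray:
    """Individual-level genetic distance matrix from haplotype assignments.

    The default is the squared inter-haplotype mutation count (the haploid
    convention of the multivariate autocorrelation method); ``squared=False``
    gives a 0/1 haplotype mismatch distance instead.
    """
    hap_distance = np.asarray(hap_distance, dtype=float)
    d = hap_distance[np.ix_(assignments, assignments)]
    return d**2 if squared else (d > 0).astype(float)
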