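"""Population diversity and GST/NST differentiation with permutation tests.

Per-population statistics follow the classic unbiased estimators: the
haplotype (gene) diversity Hd = n(1 - sum p_i^2)/(n - 1) and the per-site
nucleotide diversity pi computed from substitution-only haplotype
differences over the concatenated alignment length.

Multi-population diversity uses the Pons & Petit estimators with equal
population weights: hS is the mean unbiased within-population diversity,
hT the total diversity on mean haplotype frequencies with the small-sample
correction hS/(n~ K), where n~ is the harmonic mean sample size. NST is the
distance-weighted analogue (vS, vT) and reduces exactly to GST when all
inter-haplotype distances are equal. The NST > GST permutation test shuffles
haplotype identities in the distance matrix.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class SpeciesDiversity:
    h_s: float
    h_t: float
    se_h_s: float
    se_h_t: float
    n_populations: int
    harmonic_n: float


@dataclass
class DifferentiationResult:
    g_st: float
    n_st: float
    se_g_st: float
    se_n_st: float
    p_value: float
    n_permutations: int


def nei_gene_diversity(counts: np.ndarray) -> float:
    """Unbiased haplotype diversity; 0 when n = 1."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("population with n = 0")
    if n == 1:
        return 0.0
    p = counts / n
    return float(n / (n - 1) * (1.0 - (p**2).sum()))


def nucleotide_diversity(counts: np.ndarray, subst_dist: np.ndarray, length: int) -> float:
    """Per-site nucleotide diversity from substitution-only haplotype distances."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("population with n = 0")
    if n == 1:
        return 0.0
    p = counts / n
    mean_d = float(p @ subst_dist @ p)  # = sum_{i<j} 2 p_i p_j d_ij
    return n / (n - 1) * mean_d / length


def population_diversity(
    counts_matrix: pd.DataFrame, subst_dist: np.ndarray, length: int
) -> pd.DataFrame:
    """Per-population table: n, number of haplotypes h, Hd and pi.

    ``counts_matrix`` is populations x haplotypes (column order must match
    the distance matrix).
    """
    rows = []
    for pop, counts in counts_matrix.iterrows():
        c = counts.to_numpy(dtype=float)
        rows.append(
            {
                "population": pop,
                "n": int(c.sum()),
                "h": int((c > 0).sum()),
                "Hd": nei_gene_diversity(c),
                "pi": nucleotide_diversity(c, subst_dist, length),
            }
        )
    return pd.DataFrame(rows).set_index("population")


def _pons_petit(counts: np.ndarray, dist: np.ndarray | None) -> tuple[float, float]:
    """(within, total) diversity; ``dist=None`` gives the hS/hT pair.

    With a distance matrix the same estimator yields vS/vT: substituting
    d_ij = 1 for all i != j recovers hS/hT exactly.
    """
    counts = np.asarray(counts, dtype=float)
    n_k = counts.sum(axis=1)
    keep = n_k >= 2
    if (~keep).any():
        log.warning("%d population(s) with n < 2 excluded from hS/hT", int((~keep).sum()))
    counts, n_k = counts[keep], n_k[keep]
    k = counts.shape[0]
    if k < 2:
        raise ValueError("need >= 2 populations with n >= 2")
    x = counts / n_k[:, None]
    if dist is None:
        within_k = n_k / (n_k - 1) * (1.0 - (x**2).sum(axis=1))
        mean_x = x.mean(axis=0)
        total_raw = 1.0 - (mean_x**2).sum()
    else:
        within_k = n_k / (n_k - 1) * np.einsum("ki,ij,kj->k", x, dist, x)
        mean_x = x.mean(axis=0)
        total_raw = float(mean_x @ dist @ mean_x)
    within = float(within_k.mean())
    harmonic_n = k / (1.0 / n_k).sum()
    total = total_raw + within / (harmonic_n * k)
    return within, float(total)


def _jackknife_se(counts: np.ndarray, stat) -> float:
    """Delete-one-population jackknife standard error of ``stat(counts)``."""
    k = counts.shape[0]
    if k < 3:
        return float("nan")
    vals = np.array([stat(np.delete(counts, i, axis=0)) for i in range(k)])
    return float(np.sqrt((k - 1) / k * ((vals - vals.mean()) ** 2).sum()))


def _eligible(counts: np.ndarray) -> np.ndarray:
    """Drop populations with n < 2 (unbiased estimators undefined there)."""
    return counts[counts.sum(axis=1) >= 2]


def multi_population_diversity(counts_matrix: pd.DataFrame) -> SpeciesDiversity:
    """Pons & Petit hS/hT over populations (equal population weights)."""
    counts = _eligible(counts_matrix.to_numpy(dtype=float))
    h_s, h_t = _pons_petit(counts, None)
    n_k = counts.sum(axis=1)
    return SpeciesDiversity(
        h_s,
        h_t,
        _jackknife_se(counts, lambda c: _pons_petit(c, None)[0]),
        _jackknife_se(counts, lambda c: _pons_petit(c, None)[1]),
        len(n_k),
        float(len(n_k) / (1.0 / n_k).sum()),
    )


def gst_nst(counts: np.ndarray, dist: np.ndarray) -> tuple[float, float]:
    """Point estimates of GST and NST for a populations x haplotypes matrix."""
    h_s, h_t = _pons_petit(counts, None)
    if h_t == 0:
        raise ValueError("hT = 0: GST undefined")
    v_s, v_t = _pons_petit(counts, dist)
    return (h_t - h_s) / h_t, (v_t - v_s) / v_t


def differentiation(
    counts_matrix: pd.DataFrame,
    hap_distance: np.ndarray,
    n_permutations: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> DifferentiationResult:
    """GST, NST and a one-tailed permutation p for NST > GST.

    The null is built by shuffling haplotype identities in the distance
    matrix (GST is invariant to the shuffle, so the test reduces to
    NST_perm >= NST_obs), with the +1 small-sample correction.
    """
    rng = np.random.default_rng(rng)
    counts = _eligible(counts_matrix.to_numpy(dtype=float))
    dist = np.asarray(hap_distance, dtype=float)
    g_st, n_st = gst_nst(counts, dist)
    n_hap = dist.shape[0]
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_hap)
        _, n_st_perm = gst_nst(counts, dist[np.ix_(perm, perm)])
        if n_st_perm >= n_st:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return DifferentiationResult(
        g_st,
        n_st,
        _jackknife_se(counts, lambda c: gst_nst(c, dist)[0]),
        _jackknife_se(counts, lambda c: gst_nst(c, dist)[1]),
        p,
        n_permutations,
    )


def geo_trend(stats: pd.DataFrame, measures: tuple[str, ...] = ("h", "Hd", "pi")) -> pd.DataFrame:
    """OLS of each diversity measure on latitude and longitude.

    Fits linear and quadratic models per measure x predictor and reports the
    slope terms with t-test p-values and the model R^2. Requires >= 4
    populations and non-constant predictors.
    """
    import statsmodels.api as sm

    if len(stats) < 4:
        raise ValueError("need >= 4 populations for the diversity trend regression")
    rows = []
    for predictor in ("latitude", "longitude"):
        x = stats[predictor].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"constant predictor {predictor}")
        for measure in measures:
            y = stats[measure].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                # a flat response carries no trend; the t-test is undefined
                rows.append(
                    {
                        "measure": measure, "predictor": predictor,
                        "slope": 0.0, "p_linear": float("nan"), "r2_linear": float("nan"),
                        "p_quadratic": float("nan"), "r2_quadratic": float("nan"),
                    }
                )
                continue
            lin = sm.OLS(y, sm.add_constant(x)).fit()
            quad = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
            rows.append(
                {
                    "measure": measure,
                    "predictor": predictor,
                    "slope": lin.params[1],
                    "p_linear": lin.pvalues[1],
                    "r2_linear": lin.rsquared,
                    "p_quadratic": quad.pvalues[2],
                    "r2_quadratic": quad.rsquared,
                }
            )
    return pd.DataFrame(rows)
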