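"""Distance-based hierarchical analysis of molecular variance (AMOVA).

Implements the classic Excoffier molecular-variance decomposition on squared
inter-haplotype mutation counts: sums of squares are within-group sums of
squared distances divided by the group size, variance components come from
the expected mean squares with unequal-sample-size coefficients, and the
fixation indices F_CT, F_SC, F_ST are ratios of the (signed) components.
Negative components are reported as computed, never zeroed. Significance is
by permutation with the +1 correction, each index with its own permutation
scheme:

* F_ST (two-level): individuals permuted among populations;
* F_CT: whole populations permuted among species;
* F_SC: individuals permuted among populations within species.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class AmovaResult:
    rows: pd.DataFrame  # source, df, SS, VC, PV
    f_st: float
    f_sc: float | None = None
    f_ct: float | None = None
    degenerate: bool = False
    p_values: dict = field(default_factory=dict)
    n_permutations: int = 0

    @property
    def total_variance(self) -> float:
        return float(self.rows["VC"].sum())


def _ssd(d2: np.ndarray, idx: np.ndarray) -> float:
    """Within-set sum of squared distances / set size."""
    block = d2[np.ix_(idx, idx)]
    return float(block.sum() / (2.0 * len(idx)))


def _group_indices(labels: np.ndarray) -> dict:
    return {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}


def amova(
    d2: np.ndarray,
    populations: np.ndarray,
    species: np.ndarray | None = None,
    _warn: bool = True,
) -> AmovaResult:
    """AMOVA over individuals given squared pairwise distances.

    ``d2`` is the N x N matrix of squared mutation counts between
    individuals; ``populations`` the per-individual population labels;
    ``species`` optional per-individual group labels for the three-level
    design. Every population (and species) must hold >= 2 units.
    """
    d2 = np.asarray(d2, dtype=float)
    populations = np.asarray(populations)
    n = len(populations)
    if d2.shape != (n, n):
        raise ValueError("d2 shape does not match the number of individuals")
    pops = _group_indices(populations)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    for pop, idx in pops.items():
        if len(idx) < 1:
            raise ValueError(f"empty population {pop!r}")
    ss_total = _ssd(d2, np.arange(n))
    ss_wp = sum(_ssd(d2, idx) for idx in pops.values())
    n_p = np.array([len(idx) for idx in pops.values()], dtype=float)

    if species is None:
        return _two_level(ss_total, ss_wp, n, n_p, _warn)
    species = np.asarray(species)
    return _three_level(d2, populations, species, ss_total, ss_wp, n, _warn)


def _two_level(ss_total, ss_wp, n, n_p, warn=True) -> AmovaResult:
    p = len(n_p)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = p - 1, n - p
    if df_wp <= 0:
        raise ValueError("every population needs >= 2 individuals overall")
    ms_ap, ms_wp = ss_ap / df_ap, ss_wp / df_wp
    n0 = (n - (n_p**2).sum() / n) / (p - 1)
    sigma_w = ms_wp
    sigma_a = (ms_ap - sigma_w) / n0
    total = sigma_a + sigma_w
    degenerate = total == 0
    if degenerate:
        log.warning("all distances zero: fixation indices undefined")
    f_st = sigma_a / total if not degenerate else float("nan")
    rows = pd.DataFrame(
        {
            "source": ["Among populations", "Within populations"],
            "df": [df_ap, df_wp],
            "SS": [ss_ap, ss_wp],
            "VC": [sigma_a, sigma_w],
            "PV": [100 * sigma_a / total if not degenerate else float("nan"),
                   100 * sigma_w / total if not degenerate else float("nan")],
        }
    )
    if sigma_a < 0 and warn:
        log.warning("negative variance component (among populations): %.4g", sigma_a)
    return AmovaResult(rows, f_st, degenerate=degenerate)


def _three_level(d2, populations, species, ss_total, ss_wp, n, warn=True) -> AmovaResult:
    groups = _group_indices(species)
    g = len(groups)
    if g < 2:
        raise ValueError("need >= 2 species for the three-level design")
    pop_of_species = {}
    for sp, idx in groups.items():
        pop_of_species[sp] = pd.unique(populations[idx])
    for sp, pop_list in pop_of_species.items():
        if len(pop_list) < 2 and g > 2:
            log.warning("species %r holds a single population", sp)
    p = len(pd.unique(populations))

    ss_wg = sum(_ssd(d2, idx) for idx in groups.values())  # within species, all strata below
    ss_ag = ss_total - ss_wg
    ss_ap_wg = ss_wg - ss_wp

    if p == g:
        # one population per species: the among-populations stratum is empty
        # and the design collapses to a two-level AMOVA over species
        two = _two_level(ss_total, ss_wp, n, np.array([len(i) for i in groups.values()], float), warn)
        rows = pd.DataFrame(
            {
                "source": [
                    "Among species",
                    "Among populations within species",
                    "Within populations",
                ],
                "df": [g - 1, 0, n - p],
                "SS": [two.rows["SS"][0], 0.0, two.rows["SS"][1]],
                "VC": [two.rows["VC"][0], 0.0, two.rows["VC"][1]],
                "PV": [two.rows["PV"][0], 0.0, two.rows["PV"][1]],
            }
        )
        return AmovaResult(rows, two.f_st, 0.0, two.f_st, degenerate=two.degenerate)

    df_ag, df_ap, df_wp = g - 1, p - g, n - p
    if min(df_ag, df_ap, df_wp) <= 0:
        raise ValueError("degenerate design: a stratum with < 2 units")
    ms_ag, ms_ap, ms_wp = ss_ag / df_ag, ss_ap_wg / df_ap, ss_wp / df_wp

    pop_sizes = {pop: np.count_nonzero(populations == pop) for pop in pd.unique(populations)}
    n_g = {sp: len(idx) for sp, idx in groups.items()}
    sum_np2_over_ng = sum(
        sum(pop_sizes[pop] ** 2 for pop in pop_of_species[sp]) / n_g[sp] for sp in groups
    )
    sum_np2_over_n = sum(v**2 for v in pop_sizes.values()) / n
    sum_ng2_over_n = sum(v**2 for v in n_g.values()) / n

    n_coef = (n - sum_np2_over_ng) / (p - g)
    n_coef_p = (sum_np2_over_ng - sum_np2_over_n) / (g - 1)
    n_coef_pp = (n - sum_ng2_over_n) / (g - 1)

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_coef
    sigma_a = (ms_ag - sigma_c - n_coef_p * sigma_b) / n_coef_pp
    total = sigma_a + sigma_b + sigma_c
    degenerate = total == 0
    if degenerate:
        log.warning("all distances zero: fixation indices undefined")
        f_ct = f_sc = f_st = float("nan")
    else:
        f_ct = sigma_a / total
        f_sc = sigma_b / (sigma_b + sigma_c)
        f_st = (sigma_a + sigma_b) / total
    for name, v in (("among species", sigma_a), ("among populations", sigma_b)) if warn else ():
        if v < 0:
            log.warning("negative variance component (%s): %.4g", name, v)
    rows = pd.DataFrame(
        {
            "source": [
                "Among species",
                "Among populations within species",
                "Within populations",
            ],
            "df": [df_ag, df_ap, df_wp],
            "SS": [ss_ag, ss_ap_wg, ss_wp],
            "VC": [sigma_a, sigma_b, sigma_c],
            "PV": [
                100 * sigma_a / total if not degenerate else float("nan"),
                100 * sigma_b / total if not degenerate else float("nan"),
                100 * sigma_c / total if not degenerate else float("nan"),
            ],
        }
    )
    return AmovaResult(rows, f_st, f_sc, f_ct, degenerate=degenerate)


def amova_permutation(
    d2: np.ndarray,
    populations: np.ndarray,
    species: np.ndarray | None,
    which_index: str,
    n_permutations: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value for one fixation index, p = (#{F* >= F} + 1)/(n + 1)."""
    rng = np.random.default_rng(rng)
    populations = np.asarray(populations)
    species = None if species is None else np.asarray(species)
    observed = amova(d2, populations, species)
    obs = {"F_ST": observed.f_st, "F_CT": observed.f_ct, "F_SC": observed.f_sc}[which_index]
    if obs is None or np.isnan(obs):
        raise ValueError(f"{which_index} not defined for this design")
    exceed = 0
    for _ in range(n_permutations):
        if which_index == "F_ST" and species is None:
            perm_pops = rng.permutation(populations)
            stat = amova(d2, perm_pops, None, _warn=False).f_st
        elif which_index == "F_CT":
            pop_list = list(pd.unique(populations))
            sp_of_pop = {p: species[populations == p][0] for p in pop_list}
            shuffled = rng.permutation([sp_of_pop[p] for p in pop_list])
            new_sp_of_pop = dict(zip(pop_list, shuffled))
            perm_species = np.array([new_sp_of_pop[p] for p in populations])
            stat = amova(d2, populations, perm_species, _warn=False).f_ct
        elif which_index == "F_SC":
            perm_pops = populations.copy()
            for sp in pd.unique(species):
                idx = np.flatnonzero(species == sp)
                perm_pops[idx] = rng.permutation(populations[idx])
            stat = amova(d2, perm_pops, species, _warn=False).f_sc
        else:
            raise ValueError(f"unknown index {which_index!r}")
        if stat >= obs:
            exceed += 1
    return (exceed + 1) / (n_permutations + 1)


def squared_distance_matrix(hap_distance: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """Individual-level squared distances from haplotype distances + assignment indices."""
    hap_distance = np.asarray(hap_distance, dtype=float)
    d = hap_distance[np.ix_(assignments, assignments)]
    return d**2
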