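"""Per-group diversity statistics and pairwise Weir-Cockerham Fst.

Diversity follows the classic population-genetics summary table: mean number
of alleles per locus (K), rarefied allelic richness (AR, hypergeometric
rarefaction to a common number of gene copies), private alleles (Priv),
observed heterozygosity (Ho) and unbiased expected heterozygosity (He,
Nei's small-sample correction 2p(1-p) * 2n/(2n-1)).

Fst is the Weir & Cockerham (1984) theta: per-locus variance components
a (among populations), b (among individuals within populations) and
c (within individuals), combined multilocus as sum(a)/sum(a+b+c).
Significance comes from permuting individuals between the two groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix, PopulationMap

__all__ = ["diversity_table", "pairwise_fst", "weir_cockerham_theta", "FstMatrix"]


def _require_complete_biallelic(gm: GenotypeMatrix) -> None:
    if not (gm.biallelic_mask().all() and not gm.missing_mask().any()):
        raise ValueError("statistics require a complete biallelic matrix; run filter_complete_biallelic")


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _rarefied_richness(counts: np.ndarray, total: np.ndarray, g: int) -> np.ndarray:
    """Expected allele count when drawing g of ``total`` gene copies.

    ``counts``: (n_loci, n_alleles) copies per allele; ``total``: (n_loci,).
    AR = sum_alleles [1 - C(total - count, g) / C(total, g)].
    """
    with np.errstate(invalid="ignore"):
        rest = total[:, None] - counts
        miss = np.where(
            rest >= g,
            np.exp(_log_comb(rest, g) - _log_comb(total, g)[:, None]),
            0.0,
        )
    present = counts > 0
    return np.where(present, 1.0 - miss, 0.0).sum(axis=1)


def diversity_table(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    rarefaction_n: int | None = None,
) -> pd.DataFrame:
    """Per-group diversity summary (rows = groups, means +- per-locus SD).

    ``rarefaction_n`` is the number of gene copies AR rarefies to; by default
    twice the smallest group size.  Must be >= 2 and <= 2 * min group size.
    """
    _require_complete_biallelic(gm)
    pm.validate(gm)
    groups = pm.groups
    sizes = {g: len(m) for g, m in groups.items()}
    if min(sizes.values()) == 0:
        raise ValueError("empty group")
    if rarefaction_n is None:
        rarefaction_n = 2 * min(sizes.values())
    if rarefaction_n < 2:
        raise ValueError("rarefaction_n must be >= 2")
    if rarefaction_n > 2 * min(sizes.values()):
        raise ValueError("rarefaction_n exceeds 2 * smallest group size")

    L = gm.n_loci
    # per-group per-locus allele-1 copy counts and het proportions
    counts1 = {}
    het = {}
    hom_counts = {}
    for g, members in groups.items():
        idx = [gm.individual_index(i) for i in members]
        sub = gm.calls[:, idx, :]  # (L, n, 2) of 0/1
        counts1[g] = sub.sum(axis=(1, 2))
        het[g] = (sub[:, :, 0] != sub[:, :, 1]).mean(axis=1)
        hom_counts[g] = 2 * len(members) - counts1[g]

    # private alleles: (locus, allele) observed in exactly one group
    presence = {
        g: np.stack([hom_counts[g] > 0, counts1[g] > 0], axis=1) for g in groups
    }  # (L, 2) bool
    n_groups_with = sum(p.astype(int) for p in presence.values())

    rows = []
    for g, members in groups.items():
        n = len(members)
        c1 = counts1[g].astype(float)
        total = np.full(L, 2.0 * n)
        p = c1 / total
        k_per_locus = (c1 > 0).astype(int) + (c1 < total).astype(int)
        counts_2col = np.stack([total - c1, c1], axis=1)
        ar = _rarefied_richness(counts_2col, total, rarefaction_n)
        he = 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0)
        ho = het[g]
        priv = int((presence[g] & (n_groups_with == 1)).sum())
        rows.append(
            {
                "group": g,
                "N": n,
                "K": k_per_locus.mean(),
                "K_sd": k_per_locus.std(ddof=0),
                "AR": ar.mean(),
                "AR_sd": ar.std(ddof=0),
                "Priv": priv,
                "Ho": ho.mean(),
                "Ho_sd": ho.std(ddof=0),
                "He": he.mean(),
                "He_sd": he.std(ddof=0),
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(
    counts1: np.ndarray, het_counts: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components for r populations.

    ``counts1``: (r, L) copies of allele 1; ``het_counts``: (r, L) heterozygote
    individuals; ``sizes``: (r,) individuals per population.  Returns
    (a, a+b+c), each (L,).
    """
    r = len(sizes)
    n_i = sizes.astype(float)[:, None]  # individuals
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    p_i = counts1 / (2.0 * n_i)
    h_i = het_counts / n_i
    pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, a + b + c


def weir_cockerham_theta(
    gm: GenotypeMatrix, pm: PopulationMap, groups: list[str] | None = None
) -> float:
    """Multilocus WC84 theta across the given groups (default: all groups)."""
    _require_complete_biallelic(gm)
    if groups is None:
        groups = list(pm.groups)
    counts1, hets, sizes = _group_arrays(gm, pm, groups)
    a, abc = _wc_components(counts1, hets, sizes)
    denom = abc.sum()
    if denom == 0:
        warnings.warn("monomorphic group pair: Fst undefined")
        return float("nan")
    return float(a.sum() / denom)


def _group_arrays(gm, pm, groups):
    counts1, hets, sizes = [], [], []
    for g in groups:
        idx = [gm.individual_index(i) for i in pm.members(g)]
        sub = gm.calls[:, idx, :]
        counts1.append(sub.sum(axis=(1, 2)))
        hets.append((sub[:, :, 0] != sub[:, :, 1]).sum(axis=1))
        sizes.append(len(idx))
    return np.stack(counts1), np.stack(hets), np.array(sizes)


@dataclass
class FstMatrix:
    """Pairwise multilocus theta with permutation p-values."""

    fst: pd.DataFrame
    pvalues: pd.DataFrame
    n_permutations: int
    seed: int


def pairwise_fst(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    n_perm: int = 1000,
    seed: int = 0,
) -> FstMatrix:
    """All pairwise WC84 theta values with individual-permutation p-values.

    The permutation unit is the individual (both alleles move together);
    p = proportion of permuted datasets whose theta is >= the observed value.
    Deterministic for a fixed seed.
    """
    _require_complete_biallelic(gm)
    pm.validate(gm)
    groups = list(pm.groups)
    for g in groups:
        if len(pm.members(g)) < 2:
            raise ValueError(f"group {g!r} needs >= 2 individuals for Fst")
    rng = np.random.default_rng(seed)
    fst = pd.DataFrame(np.nan, index=groups, columns=groups)
    pvals = pd.DataFrame(np.nan, index=groups, columns=groups)

    # per-individual per-locus summaries for fast permutation
    ind_counts = gm.calls.sum(axis=2).T.astype(np.int32)  # (N, L) copies of allele 1
    ind_het = (gm.calls[:, :, 0] != gm.calls[:, :, 1]).T.astype(np.int32)  # (N, L)

    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            idx1 = np.array([gm.individual_index(x) for x in pm.members(g1)])
            idx2 = np.array([gm.individual_index(x) for x in pm.members(g2)])
            obs = _theta_from_ind(ind_counts, ind_het, idx1, idx2)
            if np.isnan(obs):
                warnings.warn(f"pair ({g1}, {g2}) monomorphic: Fst undefined")
                p = np.nan
            else:
                pool = np.concatenate([idx1, idx2])
                n1 = len(idx1)
                hits = 0
                for _ in range(n_perm):
                    perm = rng.permutation(pool)
                    t = _theta_from_ind(ind_counts, ind_het, perm[:n1], perm[n1:])
                    if not np.isnan(t) and t >= obs:
                        hits += 1
                p = hits / n_perm
            fst.loc[g1, g2] = fst.loc[g2, g1] = obs
            pvals.loc[g1, g2] = pvals.loc[g2, g1] = p
    return FstMatrix(fst, pvals, n_perm, seed)


def _theta_from_ind(ind_counts, ind_het, idx1, idx2) -> float:
    counts1 = np.stack([ind_counts[idx1].sum(axis=0), ind_counts[idx2].sum(axis=0)])
    hets = np.stack([ind_het[idx1].sum(axis=0), ind_het[idx2].sum(axis=0)])
    sizes = np.array([len(idx1), len(idx2)])
    a, abc = _wc_components(counts1, hets, sizes)
    denom = abc.sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)
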