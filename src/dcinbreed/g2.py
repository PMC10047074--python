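"""Identity disequilibrium (g2) for multilocus microsatellite panels.

g2 measures the excess covariance in heterozygosity across loci created by
variance in inbreeding among individuals; it is the standard check of whether
a marker panel carries any inbreeding signal at all. The estimator follows
the missing-data form of David et al. (2007): for every ordered pair of loci
the within-individual joint heterozygosity is contrasted with the
between-individual product, each normalized by its own count of usable
(typed) comparisons, and g2 is the ratio of the pair-summed numerator to the
pair-summed denominator, minus one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeTable


@dataclass
class G2Result:
    g2: float
    p_value: float
    ci_low: float
    ci_high: float
    n_perm: int
    n_boot: int


def _g2_from_matrices(het: np.ndarray, valid: np.ndarray) -> float:
    """g2 from a heterozygosity indicator matrix and a typed mask (n x L)."""
    h = np.where(valid, het, 0.0).astype(float)
    v = valid.astype(float)
    # pairwise within-individual sums: M1[k,l] = sum_i h_ik h_il, N1 = sum_i v_ik v_il
    M1 = h.T @ h
    N1 = v.T @ v
    # between-individual: sum_{i != j} h_ik h_jl = (sum_i h_ik)(sum_j h_jl) - M1[k,l]
    ch = h.sum(axis=0)
    cv = v.sum(axis=0)
    M2 = np.outer(ch, ch) - M1
    N2 = np.outer(cv, cv) - N1
    L = h.shape[1]
    off = ~np.eye(L, dtype=bool)
    usable = off & (N1 > 0) & (N2 > 0)
    if not usable.any():
        raise ValueError("no usable locus pairs for g2")
    num = (M1[usable] / N1[usable]).sum()
    den = (M2[usable] / N2[usable]).sum()
    if den == 0:
        return float("nan")
    return num / den - 1.0


def g2_point_estimate(table: GenotypeTable) -> float:
    """Point estimate of g2 from a genotype table (no resampling)."""
    return _g2_from_matrices(table.heterozygous_mask(), table.typed_mask())


def g2_microsats(
    table: GenotypeTable,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> G2Result:
    """g2 with a permutation p-value and a bootstrap confidence interval.

    The null distribution is built by independently permuting each locus's
    single-locus heterozygosity column across individuals (destroying any
    across-locus correlation while keeping locus-wise heterozygosity and
    missingness patterns); the p-value is the one-sided fraction of permuted
    g2 values at least as large as the observed one. The CI resamples
    individuals with replacement.
    """
    if n_perm < 1 or n_boot < 1:
        raise ValueError("n_perm and n_boot must be >= 1")
    if table.n_loci < 2 or table.n_individuals < 2:
        raise ValueError("g2 needs at least 2 loci and 2 individuals")
    rng = np.random.default_rng(seed)
    het = table.heterozygous_mask()
    valid = table.typed_mask()
    obs = _g2_from_matrices(het, valid)

    n = het.shape[0]
    exceed = 0
    for _ in range(n_perm):
        hp = het.copy()
        vp = valid.copy()
        for l in range(het.shape[1]):
            perm = rng.permutation(n)
            hp[:, l] = het[perm, l]
            vp[:, l] = valid[perm, l]
        if _g2_from_matrices(hp, vp) >= obs:
            exceed += 1
    p_value = (exceed + 1) / (n_perm + 1)

    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boots[b] = _g2_from_matrices(het[idx], valid[idx])
        except ValueError:
            boots[b] = np.nan
    alpha = (1 - ci_level) / 2
    lo, hi = np.nanquantile(boots, [alpha, 1 - alpha])
    return G2Result(obs, p_value, float(lo), float(hi), n_perm, n_boot)
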