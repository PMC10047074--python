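"""Gibbs sampler for individual inbreeding coefficients from multilocus genotypes.

Step 1 of the two-step analysis. The model treats each individual's two
alleles at each typed locus as identical by descent (IBD) with probability
F_i, via latent indicators x_il: a heterozygote is never IBD; a homozygote
for allele m is IBD with conditional probability

    q = F p_lm / (F p_lm + (1 - F) p_lm^2)

where p_lm is the frequency of allele m at locus l. Conjugate full
conditionals give a pure Gibbs cycle: F_i from a Beta updated by the IBD
count, and p_l from a Dirichlet updated by the counts of alleles identical
by state that are not also IBD (an IBD pair counts once, a non-IBD
homozygote counts twice). A Bayes-Laplace Beta(1, 1) prior sits on each F_i
and a uniform Dirichlet on each allele-frequency simplex. Loci are assumed
unlinked and independent.

Data cloning replicates the genotype data K times, with F_i and p_l shared
across clones and the indicators latent per clone, so the posterior for F_i
tightens toward a point mass at its maximum-likelihood value as K grows.
Because the K clone indicators for one (individual, locus) cell are iid
Bernoulli(q) given (F, p), the sampler stores the clone-0 indicator plus the
Binomial(K-1, q) sum of the rest -- an equivalent but K-independent-cost
representation of the cloned state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import gelman_rubin
from .genotypes import GenotypeTable


@dataclass
class IBDConfig:
    beta_prior_a: float = 1.0
    beta_prior_b: float = 1.0
    bernoulli_floor: float = 0.00001
    bernoulli_ceiling: float = 0.99999
    chains: int = 3
    iterations: int = 10000
    burn_in: int = 5000
    thin: int = 5
    clone_schedule: tuple[int, ...] = (1, 5, 10, 20, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.bernoulli_floor < self.bernoulli_ceiling < 1):
            raise ValueError("need 0 < floor < ceiling < 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be below iterations")
        if list(self.clone_schedule) != sorted(set(self.clone_schedule)) or min(
            self.clone_schedule
        ) < 1:
            raise ValueError("clone_schedule must be increasing positive counts")


class GenotypeArrays:
    """Integer-coded view of a GenotypeTable used by the sampler."""

    def __init__(self, table: GenotypeTable):
        a0, a1 = table.allele_index_arrays()
        self.typed = a0 >= 0
        self.hom = self.typed & (a0 == a1)
        self.het = self.typed & (a0 != a1)
        self.hom_allele = np.where(self.hom, a0, 0)
        self.L_i = self.typed.sum(axis=1)
        self.n, self.L = a0.shape
        self.n_alleles = np.array(
            [len(table.alleles[name]) for name in table.locus_names]
        )
        self.A_max = int(self.n_alleles.max())
        # static per-locus allele counts contributed by heterozygous calls
        self.het_counts = np.zeros((self.L, self.A_max))
        for l in range(self.L):
            idx = np.where(self.het[:, l])[0]
            np.add.at(self.het_counts[l], a0[idx, l], 1)
            np.add.at(self.het_counts[l], a1[idx, l], 1)
        self.allele_valid = (
            np.arange(self.A_max)[None, :] < self.n_alleles[:, None]
        )
        # flattened (locus, allele) index for homozygote Z contributions
        self.hom_flat_idx = (
            np.arange(self.L)[None, :] * self.A_max + self.hom_allele
        )


@dataclass
class IBDChainState:
    """Current state of one chain at clone level K.

    ``x0`` is the clone-0 IBD indicator per (individual, locus); ``rest`` the
    summed indicators of the remaining K-1 clones; together they carry the
    full cloned indicator information (clones are exchangeable given F, p).
    """

    K: int
    F: np.ndarray  # (n,)
    p: np.ndarray  # (L, A_max) padded allele-frequency simplexes
    x0: np.ndarray  # (n, L) int8
    rest: np.ndarray  # (n, L) int64

    def total_x(self) -> np.ndarray:
        return self.x0.astype(np.int64) + self.rest


def init_state(g: GenotypeArrays, K: int, rng: np.random.Generator) -> IBDChainState:
    p = np.where(g.allele_valid, 1.0, 0.0) + g.het_counts
    p /= p.sum(axis=1, keepdims=True)
    return IBDChainState(
        K=K,
        F=rng.uniform(0.01, 0.1, size=g.n),
        p=p,
        x0=np.zeros((g.n, g.L), dtype=np.int8),
        rest=np.zeros((g.n, g.L), dtype=np.int64),
    )


def update_ibd_indicators(
    state: IBDChainState, g: GenotypeArrays, config: IBDConfig, rng: np.random.Generator
) -> None:
    """Draw the IBD indicators for every clone x individual x typed locus.

    Heterozygous and missing cells stay 0; homozygous cells draw from
    Bernoulli(q) with the Bernoulli probability built from the clamped F.
    """
    Ft = np.clip(state.F, config.bernoulli_floor, config.bernoulli_ceiling)
    p_hom = state.p[np.arange(g.L)[None, :], g.hom_allele]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = Ft[:, None] / (Ft[:, None] + (1.0 - Ft[:, None]) * p_hom)
    q = np.where(g.hom, q, 0.0)
    state.x0 = (rng.random((g.n, g.L)) < q).astype(np.int8)
    state.x0[~g.hom] = 0
    if state.K > 1:
        state.rest = rng.binomial(state.K - 1, np.where(g.hom, q, 0.0))
        state.rest[~g.hom] = 0
    else:
        state.rest = np.zeros_like(state.rest)


def update_inbreeding(
    state: IBDChainState, g: GenotypeArrays, config: IBDConfig, rng: np.random.Generator
) -> None:
    """Conjugate Beta draw of each F_i from the summed clone IBD counts."""
    s = state.total_x().sum(axis=1)
    a = config.beta_prior_a + s
    b = config.beta_prior_b + state.K * g.L_i - s
    state.F = rng.beta(a, b)


def compute_Z(state: IBDChainState, g: GenotypeArrays) -> np.ndarray:
    """Non-IBD identical-by-state allele counts per (locus, allele).

    A heterozygote contributes one copy of each of its alleles per clone; a
    homozygote contributes two copies when not IBD and a single copy when
    IBD. Summed over individuals and clones.
    """
    Z = state.K * g.het_counts.copy()
    weights = np.where(g.hom, 2 * state.K - state.total_x(), 0).astype(float)
    flat = np.zeros(g.L * g.A_max)
    np.add.at(flat, g.hom_flat_idx.ravel(), weights.ravel())
    return Z + flat.reshape(g.L, g.A_max)


def update_allele_frequencies(
    state: IBDChainState, g: GenotypeArrays, rng: np.random.Generator
) -> None:
    """Dirichlet(1 + Z_l) draw of each locus's allele-frequency simplex."""
    Z = compute_Z(state, g)
    gam = rng.gamma(np.where(g.allele_valid, 1.0 + Z, 1.0))
    gam[~g.allele_valid] = 0.0
    state.p = gam / gam.sum(axis=1, keepdims=True)


@dataclass
class InbreedingSummary:
    id: str
    typed_loci: int
    modal_ibd_count: float
    A: float
    B: float
    posterior_mean_F: float
    rhat_F: float


def summarize_to_beta(histogram: np.ndarray, L_i: int) -> tuple[float, float]:
    """Beta(A, B) measurement distribution from the posterior IBD-count histogram.

    The modal count is used (ties averaged across all modes, per the
    multimodal rule); the Bayes-Laplace conjugate update of a binomial count
    then gives A = 1 + k_bar, B = 1 + L_i - k_bar.
    """
    histogram = np.asarray(histogram, dtype=float)
    if histogram.sum() <= 0:
        raise ValueError("empty IBD-count histogram")
    modes = np.where(histogram == histogram.max())[0]
    k_bar = float(modes.mean())
    return 1.0 + k_bar, 1.0 + L_i - k_bar


@dataclass
class IBDResult:
    summaries: list[InbreedingSummary]
    rhat: np.ndarray  # per individual, at the final clone level
    posterior_mean_F: np.ndarray
    count_histograms: np.ndarray  # (n, L_max + 1) pooled at final clone level
    scaled_var_by_K: dict[int, float]  # mean over individuals of var_K / var_1
    var_by_K: dict[int, np.ndarray]
    clone_schedule: tuple[int, ...]
    convergence_warning: bool
    f_draws: np.ndarray | None = None  # (chains, saved, n) at final clone level

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.summaries])


def run_ibd_sampler(
    table: GenotypeTable,
    config: IBDConfig | None = None,
    keep_final_draws: bool = False,
) -> IBDResult:
    """Run the full clone schedule and summarize each F_i posterior to a Beta.

    For each clone count K in the schedule the Gibbs cycle (x -> F -> Z -> p)
    runs for ``config.chains`` chains; saved draws are post burn-in and
    thinned. The per-clone IBD-count histogram (clone 0's sum over loci,
    pooled over chains) at the final K parameterizes the Beta(A_i, B_i)
    measurement distributions; R-hat is reported per F_i at the final K.
    """
    config = config or IBDConfig()
    if table.n_individuals == 0 or table.n_loci == 0:
        raise ValueError("empty genotype table")
    g = GenotypeArrays(table)
    if (g.L_i == 0).any():
        bad = [table.individual_ids[i] for i in np.where(g.L_i == 0)[0]]
        raise ValueError(f"individuals with no typed loci: {bad}")
    root = np.random.default_rng(config.seed)
    chain_seeds = root.integers(0, 2**31 - 1, size=(len(config.clone_schedule), config.chains))

    n = g.n
    var_by_K: dict[int, np.ndarray] = {}
    final_hist = np.zeros((n, int(g.L_i.max()) + 1))
    final_means = np.zeros(n)
    final_rhat = np.zeros(n)
    f_draws_final = None

    for ki, K in enumerate(config.clone_schedule):
        n_save = (config.iterations - config.burn_in) // config.thin
        draws = np.empty((config.chains, n_save, n))
        hist = np.zeros_like(final_hist)
        for c in range(config.chains):
            rng = np.random.default_rng(int(chain_seeds[ki, c]))
            state = init_state(g, K, rng)
            kept = 0
            for it in range(config.iterations):
                update_ibd_indicators(state, g, config, rng)
                update_inbreeding(state, g, config, rng)
                update_allele_frequencies(state, g, rng)
                if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                    draws[c, kept] = state.F
                    s0 = state.x0.sum(axis=1)
                    hist[np.arange(n), s0] += 1
                    kept += 1
        var_by_K[K] = draws.reshape(-1, n).var(axis=0, ddof=1)
        if K == config.clone_schedule[-1]:
            final_hist = hist
            final_means = draws.reshape(-1, n).mean(axis=0)
            final_rhat = gelman_rubin(draws)
            if keep_final_draws:
                f_draws_final = draws

    base = var_by_K[config.clone_schedule[0]]
    scaled = {
        K: float(np.mean(v / base)) for K, v in var_by_K.items()
    }
    summaries = []
    for i, ident in enumerate(table.individual_ids):
        A, B = summarize_to_beta(final_hist[i, : g.L_i[i] + 1], int(g.L_i[i]))
        summaries.append(
            InbreedingSummary(
                id=ident,
                typed_loci=int(g.L_i[i]),
                modal_ibd_count=A - 1.0,
                A=A,
                B=B,
                posterior_mean_F=float(final_means[i]),
                rhat_F=float(final_rhat[i]),
            )
        )
    warn = bool(np.any(final_rhat > 1.1))
    return IBDResult(
        summaries=summaries,
        rhat=final_rhat,
        posterior_mean_F=final_means,
        count_histograms=final_hist,
        scaled_var_by_K=scaled,
        var_by_K=var_by_K,
        clone_schedule=tuple(config.clone_schedule),
        convergence_warning=warn,
        f_draws=f_draws_final,
    )
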