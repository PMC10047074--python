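"""Synthetic genotypes and life histories with the pipeline's assumed structure.

The generator emulates the study design end to end: per-locus microsatellite
allele-frequency simplexes, Beta- or mixture-distributed individual
inbreeding coefficients, genotypes drawn under the identity-by-descent model
(with probability F_i the two alleles are one copied draw), and life
histories built generatively from the fitness families -- age at first
reproduction from NB(4, p_i), death from the censored geometric survival
model, and pupping intervals from the first-pup/subsequent-pup geometric
wait model. Only reproductive females are retained, mirroring the sampling
frame of the study (mothers only); discarded zero-pup draws are counted.

Default effect sizes place the population in the regime the analysis is
built for: weak inbreeding depression against a background of mostly
outbred females (90% F = 0, 10% F = 0.25).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .genotypes import GenotypeTable, write_genepop
from .life_history import (
    DEFAULT_HORIZON,
    MIN_AFR,
    LifeHistory,
    write_life_histories,
)
from .models import (
    afr_p_from_eta,
    survival_from_eta,
    wait_pi_from_eta,
)

#: intercepts/slopes per family chosen so the natural-scale quantities match
#: a long-lived phocid: annual adult survival 0.945, mean age at first
#: reproduction 7.39 y, first-year reproduction probability 0.548 with the
#: post-first-pup wait 2.08 times longer, and weak inbreeding depression in
#: lifetime reproductive success (slope -0.1056 per unit F).
DEFAULT_COEFFICIENTS = {
    "ri": {"beta0": 0.1927, "beta1": -0.1056, "beta2": 0.0, "beta3": 0.0},
    "death": {"beta0": float(np.log(0.055 / 0.945)), "beta1": -float(np.log(1.02) / 0.0625),
              "beta2": 0.0, "beta3": 0.0},
    "afr": {"beta0": float(np.log(3.39)), "beta1": float(np.log(3.6856 / 3.39) / 0.0625),
            "beta2": 0.0, "beta3": 0.0},
    "wait": {"beta0": float(np.log(0.452 / 0.548)), "beta1": float(np.log(1.06) / 0.0625),
             "beta2": 0.0, "beta3": 0.0, "beta4": float(np.log(2.08))},
}


@dataclass
class SimScenario:
    n_individuals: int = 154
    n_loci: int = 29
    min_alleles: int = 4
    max_alleles: int = 15
    dirichlet_concentration: float = 1.0
    # F distribution: two-point mixture by default, Beta as an option
    f_mixture: tuple[float, float, float] | None = (0.9, 0.0, 0.25)  # (w0, F_low, F_high)
    f_beta: tuple[float, float] | None = None  # (a, b) overrides mixture when set
    coefficients: dict = field(default_factory=lambda: {
        fam: dict(c) for fam, c in DEFAULT_COEFFICIENTS.items()
    })
    sigma_r: float = 0.05
    sigma_gamma: float = 0.01
    sigma_theta: float = 0.0
    colony_prob: float = 0.5
    year_min: int = 1980
    year_max: int = 1992
    horizon: int = DEFAULT_HORIZON
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_beta is None and self.f_mixture is None:
            raise ValueError("need either f_beta or f_mixture")
        if not (2 <= self.min_alleles <= self.max_alleles):
            raise ValueError("allele-count range invalid")


def sim_allele_frequencies(
    scenario: SimScenario, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-locus allele-frequency simplexes: Dirichlet draws of random dimension."""
    freqs = []
    for _ in range(scenario.n_loci):
        k = int(rng.integers(scenario.min_alleles, scenario.max_alleles + 1))
        freqs.append(rng.dirichlet(np.full(k, scenario.dirichlet_concentration)))
    return freqs


def sim_inbreeding_coefficients(
    scenario: SimScenario, rng: np.random.Generator
) -> np.ndarray:
    """True individual inbreeding coefficients from the configured distribution."""
    n = scenario.n_individuals
    if scenario.f_beta is not None:
        a, b = scenario.f_beta
        return rng.beta(a, b, size=n)
    w0, lo, hi = scenario.f_mixture
    return np.where(rng.random(n) < w0, lo, hi)


def sim_genotypes(
    freqs: list[np.ndarray], F: np.ndarray, rng: np.random.Generator
) -> GenotypeTable:
    """Genotypes under the IBD model: with probability F_i one allele is copied.

    Allele labels are 2-digit codes (up to 99 alleles per locus).
    """
    n = len(F)
    ids = [f"ind{i + 1:03d}" for i in range(n)]
    loci = [f"loc{l + 1:02d}" for l in range(len(freqs))]
    calls: list[list[tuple[str, str] | None]] = []
    for i in range(n):
        row: list[tuple[str, str] | None] = []
        for p in freqs:
            if rng.random() < F[i]:
                a = int(rng.choice(len(p), p=p))
                b = a
            else:
                a = int(rng.choice(len(p), p=p))
                b = int(rng.choice(len(p), p=p))
            pair = sorted((f"{a + 1:02d}", f"{b + 1:02d}"))
            row.append((pair[0], pair[1]))
        calls.append(row)
    alleles = {
        name: [f"{j + 1:02d}" for j in range(len(p))] for name, p in zip(loci, freqs)
    }
    return GenotypeTable(ids, loci, calls, alleles=alleles)


def synthetic_measurement_beta(
    F: np.ndarray, L: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Beta(A, B) measurement distributions with the genotype step's structure.

    Draws the realized IBD count k_i ~ Binomial(L, F_i) at L typed loci and
    applies the Bayes-Laplace conjugate summarization A = 1 + k, B = 1 + L - k.
    A fast stand-in for the full Gibbs step in large simulation studies; the
    full step is exercised separately.
    """
    k = rng.binomial(L, F)
    return 1.0 + k, 1.0 + L - k


def _eta(coef: dict, F: float, col: int, theta_y: float = 0.0, gamma_y: float = 0.0,
         first: int = 0) -> float:
    return (
        coef["beta0"]
        + (coef.get("beta1", 0.0) + theta_y) * F
        + coef.get("beta2", 0.0) * col
        + coef.get("beta3", 0.0) * F * col
        + coef.get("beta4", 0.0) * first
        + gamma_y
    )


def sim_life_histories(
    scenario: SimScenario,
    F: np.ndarray,
    rng: np.random.Generator,
    max_redraws: int = 10000,
) -> tuple[list[LifeHistory], dict]:
    """Generative life histories from the death/afr/wait families.

    Per individual: a birth year and colony flag; age at first reproduction
    4 + NB(4, p_i); age at death geometric in annual survival, censored at
    the horizon; subsequent pup ages by geometric waits (first interval
    flagged). Individuals that die before their first pup are redrawn (only
    mothers enter the sample); the redraw count is returned in the truth
    record.
    """
    n = len(F)
    years = np.arange(scenario.year_min, scenario.year_max + 1)
    gamma = {
        fam: rng.normal(0.0, scenario.sigma_gamma, size=len(years))
        if scenario.sigma_gamma > 0
        else np.zeros(len(years))
        for fam in ("death", "afr", "wait")
    }
    theta = {
        fam: rng.normal(0.0, scenario.sigma_theta, size=len(years))
        if scenario.sigma_theta > 0
        else np.zeros(len(years))
        for fam in ("death", "afr", "wait")
    }
    histories: list[LifeHistory] = []
    redraws = 0
    for i in range(n):
        birth_year = int(rng.choice(years))
        yi = birth_year - scenario.year_min
        col = int(rng.random() < scenario.colony_prob)
        for _ in range(max_redraws):
            eta_afr = _eta(scenario.coefficients["afr"], F[i], col,
                           theta["afr"][yi], gamma["afr"][yi])
            afr = MIN_AFR + int(rng.negative_binomial(4, afr_p_from_eta(np.array(eta_afr))))
            eta_death = _eta(scenario.coefficients["death"], F[i], col,
                             theta["death"][yi], gamma["death"][yi])
            s = survival_from_eta(np.array(eta_death))
            death = int(rng.geometric(np.clip(1.0 - s, 1e-12, 1.0)) - 1)
            death = min(death, scenario.horizon)
            if afr > min(death, scenario.horizon):
                redraws += 1
                continue
            pup_ages = [afr]
            age = afr
            first = 1
            while True:
                eta_w = _eta(scenario.coefficients["wait"], F[i], col,
                             theta["wait"][yi], gamma["wait"][yi], first=first)
                wait = 1 + int(rng.geometric(np.clip(wait_pi_from_eta(np.array(eta_w)),
                                                     1e-12, 1.0)) - 1)
                age += wait
                if age > min(death, scenario.horizon):
                    break
                pup_ages.append(age)
                first = 0
            histories.append(
                LifeHistory(
                    id=f"ind{i + 1:03d}",
                    birth_year=birth_year,
                    dellbridge=col,
                    pup_ages=pup_ages,
                    last_observed_age=min(death, scenario.horizon),
                    horizon=scenario.horizon,
                )
            )
            break
        else:
            raise RuntimeError(
                "scenario makes reproduction before the horizon almost impossible"
            )
    truth = {
        "F": F.tolist(),
        "coefficients": scenario.coefficients,
        "gamma": {k: v.tolist() for k, v in gamma.items()},
        "theta": {k: v.tolist() for k, v in theta.items()},
        "zero_pup_redraws": redraws,
        "seed": scenario.seed,
    }
    return histories, truth


def sim_direct_ri(
    scenario: SimScenario,
    F: np.ndarray,
    rng: np.random.Generator,
    col: np.ndarray | None = None,
    upper: float = 0.3819509,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direct draws of r_i from the zero-truncated, upper-censored normal.

    Returns (y, censored, col). Bypasses the life-history construction for
    clean recovery tests of the ri regression family.
    """
    from scipy import stats

    n = len(F)
    if col is None:
        col = (rng.random(n) < scenario.colony_prob).astype(float)
    coef = scenario.coefficients["ri"]
    mu = np.array([_eta(coef, F[i], int(col[i])) for i in range(n)])
    a = (0.0 - mu) / scenario.sigma_r
    y = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=scenario.sigma_r,
                            random_state=rng)
    censored = y >= upper
    return np.minimum(y, upper), censored, col


def make_fixture(scenario: SimScenario, out_dir: str) -> dict[str, str]:
    """Write a complete synthetic study to ``out_dir``.

    Produces a GenePop genotype file, a life-history CSV, a truth JSON (true
    F, coefficients, year effects, redraw count) and a YAML config that
    reproduces the run. Deterministic given the scenario seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    freqs = sim_allele_frequencies(scenario, rng)
    F = sim_inbreeding_coefficients(scenario, rng)
    table = sim_genotypes(freqs, F, rng)
    histories, truth = sim_life_histories(scenario, F, rng)
    truth["allele_frequencies"] = [p.tolist() for p in freqs]
    paths = {
        "genotypes": str(out / "genotypes.gen"),
        "life_histories": str(out / "life_histories.csv"),
        "truth": str(out / "truth.json"),
        "config": str(out / "scenario.yaml"),
    }
    write_genepop(table, paths["genotypes"], title="synthetic microsatellite panel")
    write_life_histories(histories, paths["life_histories"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(scenario), fh)
    return paths
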