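"""Information criteria, Delta tables, and the evidential equivalence rule.

Models are ranked by BIC (primary evidence function, the more conservative
criterion for detecting inbreeding depression) with AICc reported alongside;
criterion differences below 2.77 are treated as evidential equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelSpec

EQUIVALENCE_THRESHOLD = 2.77


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """(BIC, AICc) from a log-likelihood, parameter count and sample size."""
    if n <= k + 1:
        raise ValueError("AICc undefined: need n > k + 1")
    bic = -2.0 * loglik + k * np.log(n)
    aicc = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    return float(bic), float(aicc)


@dataclass
class ModelComparison:
    table: pd.DataFrame  # converged models, ordered by delta_bic
    excluded: pd.DataFrame  # non-converged models
    n_effective: int
    equivalence_threshold: float = EQUIVALENCE_THRESHOLD


def delta_table(
    entries: list[tuple[ModelSpec, "DCFit", float]],
    n: int,
) -> ModelComparison:
    """Delta-BIC / Delta-AICc table from (spec, fit, marginal loglik) triples.

    Non-converged fits are listed separately and excluded from the Delta
    reference; ties in the minimum criterion break toward the smaller k.
    ``n`` is the independent-unit count (individuals, or intervals for the
    wait family).
    """
    rows, excl = [], []
    for spec, fit, ll in entries:
        bic, aicc = information_criteria(ll, spec.k_params, n)
        row = {
            "model": spec.label,
            "K": spec.k_params,
            "loglik": ll,
            "BIC": bic,
            "AICc": aicc,
            "converged": bool(fit.converged),
        }
        (rows if fit.converged else excl).append(row)
    if not rows:
        raise ValueError("no converged models to compare")
    df = pd.DataFrame(rows)
    for crit in ("BIC", "AICc"):
        order = np.lexsort((df["K"].values, df[crit].values))
        best = df[crit].values[order[0]]
        df[f"delta_{crit}"] = df[crit] - best
        df[f"equivalent_{crit}"] = df[f"delta_{crit}"] < EQUIVALENCE_THRESHOLD
    df = df.sort_values(["delta_BIC", "K"], kind="stable").reset_index(drop=True)
    return ModelComparison(
        table=df,
        excluded=pd.DataFrame(excl),
        n_effective=n,
    )


def candidate_set(family: str, include_year_variants: bool = False) -> list[ModelSpec]:
    """The nested candidate sequence for one fitness family.

    The base sequence adds INB, then COL, then the INBxCOL interaction to the
    intercept model; the wait family carries FIRST in every candidate.
    ``include_year_variants`` appends richest-model variants with the
    birth-year random intercept (and, outside the ri family, the year random
    slope on F).
    """
    base: tuple[str, ...] = ("FIRST",) if family == "wait" else ()
    seqs = [
        base,
        base + ("INB",),
        base + ("INB", "COL"),
        base + ("INB", "COL", "INBxCOL"),
    ]
    out = [ModelSpec(family, terms) for terms in seqs]
    if include_year_variants:
        richest = seqs[-1]
        out.append(ModelSpec(family, richest, year_random_intercept=True))
        if family != "ri":
            out.append(
                ModelSpec(
                    family,
                    richest,
                    year_random_intercept=True,
                    year_random_slope_on_F=True,
                )
            )
    return out


def render_markdown(comparison: ModelComparison) -> str:
    """Markdown rendering of the Delta table in the standard layout."""
    df = comparison.table[["model", "K", "delta_BIC", "delta_AICc"]].copy()
    df.columns = ["Model Structure", "K", "dBIC", "dAICc"]
    lines = ["| Model Structure | K | ΔBIC | ΔAICc |", "| --- | --- | --- | --- |"]
    for r in df.itertuples(index=False):
        lines.append(
            f"| {r[0]} | {r[1]} | {r[2]:.2f} | {r[3]:.2f} |"
        )
    lines.append("")
    lines.append(
        f"Models within ΔBIC/ΔAICc < {comparison.equivalence_threshold} are "
        "considered evidentially equivalent. K counts regression parameters "
        "(plus the residual SD for the r_i family); random-effect "
        "hyperparameters are not counted."
    )
    return "\n".join(lines)
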