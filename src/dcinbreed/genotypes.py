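"""Codominant multilocus genotype data: GenePop I/O and single-population summaries.

The container is built for microsatellite panels of the kind used in
heterozygosity–fitness studies: a modest number of individuals typed at a few
dozen codominant loci, with per-call missingness. Allele labels are the
zero-padded digit codes of the GenePop dialect the file was read from (or
arbitrary strings for tables built in memory).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PopGen import GenePop as _genepop


class GenePopParseError(ValueError):
    """Raised when a GenePop file cannot be parsed or fails validation."""


@dataclass
class GenotypeTable:
    """Individuals x loci codominant allele-pair calls with missing support.

    ``calls[i][l]`` is either ``None`` (missing) or an unordered pair of
    allele labels, stored as a sorted 2-tuple of strings. ``alleles[l]`` is
    the registry of labels observed at locus ``l``.
    """

    individual_ids: list[str]
    locus_names: list[str]
    calls: list[list[tuple[str, str] | None]]
    alleles: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("duplicate locus names")
        if not self.alleles:
            self.alleles = {name: [] for name in self.locus_names}
            for row in self.calls:
                for l, call in enumerate(row):
                    if call is None:
                        continue
                    reg = self.alleles[self.locus_names[l]]
                    for a in call:
                        if a not in reg:
                            reg.append(a)
            for reg in self.alleles.values():
                reg.sort()
        for i, row in enumerate(self.calls):
            if len(row) != len(self.locus_names):
                raise ValueError(f"row {self.individual_ids[i]!r} has wrong length")
            for l, call in enumerate(row):
                if call is None:
                    continue
                if len(call) != 2:
                    raise ValueError("calls must have exactly two allele labels")
                reg = self.alleles[self.locus_names[l]]
                if call[0] not in reg or call[1] not in reg:
                    raise ValueError(
                        f"allele outside registry at {self.individual_ids[i]}/{self.locus_names[l]}"
                    )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) array, True where a call is present."""
        return np.array(
            [[c is not None for c in row] for row in self.calls], dtype=bool
        )

    def heterozygous_mask(self) -> np.ndarray:
        """Boolean array, True where typed and the two alleles differ."""
        return np.array(
            [[(c is not None and c[0] != c[1]) for c in row] for row in self.calls],
            dtype=bool,
        )

    def allele_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer-coded calls: two (n, L) arrays of registry indices, -1 = missing."""
        n, L = self.n_individuals, self.n_loci
        a0 = np.full((n, L), -1, dtype=np.int32)
        a1 = np.full((n, L), -1, dtype=np.int32)
        lut = [
            {lab: j for j, lab in enumerate(self.alleles[name])}
            for name in self.locus_names
        ]
        for i, row in enumerate(self.calls):
            for l, call in enumerate(row):
                if call is not None:
                    a0[i, l] = lut[l][call[0]]
                    a1[i, l] = lut[l][call[1]]
        return a0, a1

    def typed_locus_counts(self) -> np.ndarray:
        """Per-individual count of typed loci (the L_i carried to later stages)."""
        return self.typed_mask().sum(axis=1)


def _detect_digits(path_or_text: str, is_text: bool) -> tuple[str, int]:
    text = path_or_text if is_text else open(path_or_text).read()
    digits = 0
    pop_seen = False
    for line in text.splitlines():
        if line.strip().lower() == "pop":
            pop_seen = True
            continue
        if pop_seen and "," in line:
            codes = line.split(",", 1)[1].split()
            for code in codes:
                if not code.isdigit():
                    raise GenePopParseError(f"non-numeric allele code {code!r}")
                if len(code) not in (4, 6):
                    raise GenePopParseError(
                        f"allele code {code!r} is not 4 or 6 digits (2- or 3-digit dialect)"
                    )
                width = len(code) // 2
                if digits and width != digits:
                    raise GenePopParseError("mixed 2- and 3-digit codes in one file")
                digits = width
    if not pop_seen:
        raise GenePopParseError("no 'Pop' line found")
    return text, digits or 2


def read_genepop(path: str) -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit dialect) into a :class:`GenotypeTable`.

    All populations in the file are concatenated; 00/000 codes become missing
    calls; allele labels are the zero-padded digit codes.
    """
    text, digits = _detect_digits(path, is_text=False)
    try:
        record = _genepop.read(io.StringIO(text))
    except ValueError as exc:  # Biopython raises bare ValueError on bad headers
        raise GenePopParseError(f"malformed GenePop file {path}: {exc}") from exc
    fmt = f"0{digits}d"
    ids: list[str] = []
    calls: list[list[tuple[str, str] | None]] = []
    for pop in record.populations:
        for name, genotypes in pop:
            ident = name.strip()
            if ident in ids:
                raise GenePopParseError(f"duplicate individual id {ident!r}")
            ids.append(ident)
            row: list[tuple[str, str] | None] = []
            for g in genotypes:
                if g is None or g[0] is None or g[1] is None or 0 in g:
                    row.append(None)
                else:
                    pair = sorted(format(a, fmt) for a in g)
                    row.append((pair[0], pair[1]))
            calls.append(row)
    return GenotypeTable(ids, [l.strip() for l in record.loci_list], calls)


def write_genepop(table: GenotypeTable, path: str, title: str = "dcinbreed export") -> None:
    """Write a table as a single-population GenePop file.

    Uses the 3-digit dialect if any allele label has 3 digits, else 2-digit.
    """
    width = max((len(a) for reg in table.alleles.values() for a in reg), default=2)
    if width not in (2, 3):
        raise ValueError("allele labels must be 2- or 3-digit codes for GenePop export")
    miss = "0" * width * 2
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in table.locus_names:
            fh.write(name + "\n")
        fh.write("Pop\n")
        for ident, row in zip(table.individual_ids, table.calls):
            codes = [
                miss if c is None else c[0].zfill(width) + c[1].zfill(width)
                for c in row
            ]
            fh.write(f"{ident} , " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class LocusSummary:
    locus: str
    n_typed: int
    n_alleles: int
    expected_het: float
    observed_het: float
    fis: float  # NaN when undefined (monomorphic locus)
    null_allele_freq: float


def _locus_counts(table: GenotypeTable, l: int) -> tuple[dict[str, int], int, int]:
    """Allele counts, number typed, number heterozygous at locus index l."""
    counts: dict[str, int] = {}
    n_typed = n_het = 0
    for row in table.calls:
        call = row[l]
        if call is None:
            continue
        n_typed += 1
        if call[0] != call[1]:
            n_het += 1
        for a in call:
            counts[a] = counts.get(a, 0) + 1
    return counts, n_typed, n_het


def weir_cockerham_f(p: np.ndarray, n: int, h_obs: float) -> float:
    """Single-population Weir–Cockerham f (F_IS) for one locus.

    Uses the small-sample corrected gene diversity
    ``Hs = n/(n-1) * (1 - sum p^2 - Ho/(2n))`` and returns ``1 - Ho/Hs``.
    NaN when the locus carries no variation.
    """
    hs = n / (n - 1.0) * (1.0 - float(np.sum(p**2)) - h_obs / (2.0 * n)) if n > 1 else 0.0
    if hs <= 0:
        return float("nan")
    return 1.0 - h_obs / hs


def locus_summaries(
    table: GenotypeTable,
) -> tuple[list[LocusSummary], dict[str, float]]:
    """Per-locus summaries plus overall means.

    Expected heterozygosity is the plug-in gene diversity ``1 - sum p_hat^2``;
    observed heterozygosity is the fraction of typed individuals that are
    heterozygous; f is the Weir–Cockerham (1984) single-population estimator.
    Loci with no typed individuals are excluded with a warning.

    Returns (summaries, overall) where overall has ``mean_expected_het`` with a
    normal-theory 95% CI across loci, ``mean_n_alleles``, and ``mean_observed_het``.
    """
    out: list[LocusSummary] = []
    for l, name in enumerate(table.locus_names):
        counts, n_typed, n_het = _locus_counts(table, l)
        if n_typed == 0:
            warnings.warn(f"locus {name} has no typed individuals; excluded")
            continue
        p = np.array(list(counts.values()), dtype=float)
        p /= p.sum()
        he = 1.0 - float(np.sum(p**2))
        ho = n_het / n_typed
        out.append(
            LocusSummary(
                locus=name,
                n_typed=n_typed,
                n_alleles=len(counts),
                expected_het=he,
                observed_het=ho,
                fis=weir_cockerham_f(p, n_typed, ho),
                null_allele_freq=brookfield_null_freq(he, ho),
            )
        )
    he_vals = np.array([s.expected_het for s in out])
    se = he_vals.std(ddof=1) / np.sqrt(len(he_vals)) if len(he_vals) > 1 else 0.0
    overall = {
        "mean_expected_het": float(he_vals.mean()),
        "mean_expected_het_ci_low": float(he_vals.mean() - 1.96 * se),
        "mean_expected_het_ci_high": float(he_vals.mean() + 1.96 * se),
        "mean_n_alleles": float(np.mean([s.n_alleles for s in out])),
        "mean_observed_het": float(np.mean([s.observed_het for s in out])),
    }
    return out, overall


def summaries_to_frame(summaries: list[LocusSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def brookfield_null_freq(expected_het: float, observed_het: float) -> float:
    """Brookfield (1996) estimator 1 of null-allele frequency.

    ``r = (He - Ho) / (1 + He)`` for a locus with no observed null
    homozygotes, clamped at zero when heterozygotes are in excess.
    """
    if not (0 <= expected_het <= 1 and 0 <= observed_het <= 1):
        raise ValueError("heterozygosities must be proportions")
    return max(0.0, (expected_het - observed_het) / (1.0 + expected_het))


def multilocus_homozygosity(table: GenotypeTable, individual: str) -> float:
    """Fraction of an individual's typed loci that are homozygous."""
    i = table.individual_ids.index(individual)
    typed = hom = 0
    for call in table.calls[i]:
        if call is None:
            continue
        typed += 1
        if call[0] == call[1]:
            hom += 1
    if typed == 0:
        raise ValueError(f"individual {individual!r} has no typed loci")
    return hom / typed


def het_f_correlation(table: GenotypeTable, f_estimates: np.ndarray) -> float:
    """Pearson correlation of multilocus homozygosity with F point estimates.

    Returns NaN (with a warning) when either vector is constant.
    """
    f_estimates = np.asarray(f_estimates, dtype=float)
    if len(f_estimates) != table.n_individuals:
        raise ValueError("f_estimates must align with table individuals")
    mlh = np.array(
        [multilocus_homozygosity(table, ident) for ident in table.individual_ids]
    )
    if np.std(mlh) == 0 or np.std(f_estimates) == 0:
        warnings.warn("zero variance; homozygosity-F correlation undefined")
        return float("nan")
    return float(np.corrcoef(mlh, f_estimates)[0, 1])
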