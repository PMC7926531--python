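"""Marker diversity statistics and Hardy–Weinberg testing.

For a locus with allele frequencies :math:`p_1,\\dots,p_n` the three
classical informativeness measures are

* expected heterozygosity  :math:`H_e = 1 - \\sum_i p_i^2`,
* effective allele number  :math:`N_e = 1 / \\sum_i p_i^2`,
* polymorphism information content
  :math:`PIC = 1 - \\sum_i p_i^2 - \\sum_{i<j} 2 p_i^2 p_j^2`.

All three are computed from genotype *counts*, the canonical inputs;
published frequency tables are rounded and propagate rounding error, so
fixtures reconstruct counts first.  PIC classification follows the usual
convention: below 0.25 low, between 0.25 and 0.5 moderate, 0.5 and above
high.

Hardy–Weinberg deviation is tested with the uncorrected Pearson chi-square
over the three diallelic genotype classes against expectations
:math:`(p^2 n,\\; 2pq\\,n,\\; q^2 n)`, on 1 degree of freedom (three classes,
one estimated allele frequency).  No continuity correction is applied.

The module also screens for pairs of loci whose genotype columns are
identical after allele-role alignment — the pattern reported in candidate
gene studies as complete linkage between mutation sites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticError, ValidationError
from .io import GenotypeTable, Locus

POLYMORPHISM_CATEGORIES = ("low", "moderate", "high")


def round_half_away(x: float, digits: int = 3) -> float:
    """Round half away from zero (the convention of published genotype tables)."""
    factor = 10.0 ** digits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three diallelic genotype classes at one locus."""

    n_refref: int
    n_refalt: int
    n_altalt: int

    def __post_init__(self) -> None:
        if min(self.n_refref, self.n_refalt, self.n_altalt) < 0:
            raise ValidationError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_refref + self.n_refalt + self.n_altalt


@dataclass(frozen=True)
class AlleleFreqs:
    """Reference (p) and alternate (q) allele frequencies, p + q = 1."""

    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValidationError("allele frequencies must lie in [0, 1]")
        if abs(self.p + self.q - 1.0) > 1e-12:
            raise ValidationError("allele frequencies must sum to 1")


@dataclass(frozen=True)
class DiversityStats:
    he: float
    ne: float
    pic: float
    category: str


@dataclass(frozen=True)
class HWETestResult:
    chi2: float
    df: int
    p_value: float
    expected_counts: tuple[float, float, float]


# ---------------------------------------------------------------------------
# counting and frequencies
# ---------------------------------------------------------------------------

def genotype_counts(table: GenotypeTable, locus: Locus | str) -> GenotypeCounts:
    """Count ref/ref, ref/alt, alt/alt genotypes, excluding missing cells."""
    locus_id = locus if isinstance(locus, str) else locus.id
    loc = table.locus(locus_id)
    column = table.column(locus_id)
    homref = "".join(sorted(loc.ref_allele * 2))
    het = "".join(sorted(loc.ref_allele + loc.alt_allele))
    homalt = "".join(sorted(loc.alt_allele * 2))
    counts = {homref: 0, het: 0, homalt: 0}
    for g in column:
        if g is None:
            continue
        if g not in counts:
            raise ValidationError(
                f"genotype {g!r} inconsistent with alleles of locus {locus_id}"
            )
        counts[g] += 1
    return GenotypeCounts(counts[homref], counts[het], counts[homalt])


def allele_frequencies(counts: GenotypeCounts) -> AlleleFreqs:
    """Allele frequencies from counts: p = (2*hom_ref + het) / 2n."""
    if counts.n == 0:
        raise DegenerateStatisticError("allele frequencies undefined for n = 0")
    p = (2 * counts.n_refref + counts.n_refalt) / (2 * counts.n)
    return AlleleFreqs(p, 1.0 - p)


def _freq_vector(freqs: AlleleFreqs | np.ndarray) -> np.ndarray:
    if isinstance(freqs, AlleleFreqs):
        return np.array([freqs.p, freqs.q])
    return np.asarray(freqs, dtype=float)


def expected_heterozygosity(freqs: AlleleFreqs | np.ndarray) -> float:
    """He = 1 - sum(p_i^2); accepts a frequency pair or a general vector."""
    p = _freq_vector(freqs)
    return float(1.0 - np.sum(p ** 2))


def effective_allele_number(freqs: AlleleFreqs | np.ndarray) -> float:
    """Ne = 1 / sum(p_i^2)."""
    p = _freq_vector(freqs)
    return float(1.0 / np.sum(p ** 2))


def polymorphism_information_content(freqs: AlleleFreqs | np.ndarray) -> float:
    """General n-allele PIC: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = _freq_vector(freqs)
    cross = 0.0
    for i, j in itertools.combinations(range(len(p)), 2):
        cross += 2.0 * p[i] ** 2 * p[j] ** 2
    return float(1.0 - np.sum(p ** 2) - cross)


def classify_polymorphism(pic: float) -> str:
    """Low below 0.25, moderate in (0.25, 0.5), high at 0.5 and above."""
    if pic >= 0.5:
        return "high"
    if pic > 0.25:
        return "moderate"
    return "low"


def diversity_stats(freqs: AlleleFreqs | np.ndarray) -> DiversityStats:
    pic = polymorphism_information_content(freqs)
    return DiversityStats(
        he=expected_heterozygosity(freqs),
        ne=effective_allele_number(freqs),
        pic=pic,
        category=classify_polymorphism(pic),
    )


# ---------------------------------------------------------------------------
# Hardy–Weinberg test
# ---------------------------------------------------------------------------

def hwe_chi_square(counts: GenotypeCounts) -> HWETestResult:
    """Pearson chi-square test of Hardy–Weinberg proportions, df = 1.

    Expected counts are (p^2 n, 2pq n, q^2 n) from the observed allele
    frequencies.  No continuity correction.  Monomorphic loci (q = 0 or
    p = 0) have no free genotype class and raise
    :class:`DegenerateStatisticError`.
    """
    freqs = allele_frequencies(counts)
    p, q = freqs.p, freqs.q
    if p == 0.0 or q == 0.0:
        raise DegenerateStatisticError("HWE test undefined for a monomorphic locus")
    n = counts.n
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    observed = (counts.n_refref, counts.n_refalt, counts.n_altalt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWETestResult(chi2=float(chi2), df=1, p_value=p_value, expected_counts=expected)


# ---------------------------------------------------------------------------
# per-locus summary
# ---------------------------------------------------------------------------

def summarize_loci(table: GenotypeTable, digits: int = 3) -> pd.DataFrame:
    """One summary row per locus: counts, frequencies, He/Ne/PIC, HWE p.

    Raw values are reported alongside copies rounded half-away-from-zero to
    ``digits`` decimals (columns suffixed ``_r``).  Degenerate loci (no
    typed animals, or monomorphic) are flagged in the ``note`` column
    rather than raising; a monomorphic locus gets He = 0, Ne = 1, PIC = 0
    and no HWE p-value.
    """
    rows = []
    for loc in table.loci:
        counts = genotype_counts(table, loc)
        row: dict[str, object] = {
            "locus": loc.id,
            "n": counts.n,
            "n_refref": counts.n_refref,
            "n_refalt": counts.n_refalt,
            "n_altalt": counts.n_altalt,
            "note": "",
        }
        if counts.n == 0:
            row["note"] = "no typed animals"
            rows.append(row)
            continue
        freqs = allele_frequencies(counts)
        ds = diversity_stats(freqs)
        row.update({
            "freq_refref": counts.n_refref / counts.n,
            "freq_refalt": counts.n_refalt / counts.n,
            "freq_altalt": counts.n_altalt / counts.n,
            "p_ref": freqs.p, "q_alt": freqs.q,
            "he": ds.he, "ne": ds.ne, "pic": ds.pic, "category": ds.category,
        })
        try:
            hwe = hwe_chi_square(counts)
            row["hwe_chi2"] = hwe.chi2
            row["hwe_p"] = hwe.p_value
        except DegenerateStatisticError:
            row["note"] = "monomorphic: HWE test not applicable"
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("freq_refref", "freq_refalt", "freq_altalt", "p_ref", "q_alt",
                "he", "ne", "pic", "hwe_p"):
        if col in df.columns:
            df[col + "_r"] = df[col].map(
                lambda v: round_half_away(v, digits) if pd.notna(v) else v
            )
    return df


# ---------------------------------------------------------------------------
# concordant-locus (complete linkage) screening
# ---------------------------------------------------------------------------

def _alt_dosage(column: np.ndarray, locus: Locus) -> np.ndarray:
    """Encode genotypes as alt-allele dosage 0/1/2 (NaN where missing)."""
    out = np.full(len(column), np.nan)
    for i, g in enumerate(column):
        if g is not None:
            out[i] = sum(1 for a in g if a == locus.alt_allele)
    return out


def find_concordant_loci(table: GenotypeTable) -> list[tuple[str, str]]:
    """All unordered locus pairs with identical genotype patterns.

    Two loci are concordant when, over samples typed at both, their
    alt-allele dosage vectors are identical either directly or after
    swapping allele roles (the ref/alt labels of the two markers need not
    agree for the columns to carry the same information).  Pairs with no
    jointly typed sample are not reported.
    """
    if len(table.loci) < 2:
        return []
    dosages = {loc.id: _alt_dosage(table.column(loc.id), loc) for loc in table.loci}
    pairs = []
    for a, b in itertools.combinations([l.id for l in table.loci], 2):
        da, db = dosages[a], dosages[b]
        mask = ~np.isnan(da) & ~np.isnan(db)
        if not mask.any():
            continue
        if np.array_equal(da[mask], db[mask]) or np.array_equal(da[mask], 2 - db[mask]):
            pairs.append((a, b))
    return pairs
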