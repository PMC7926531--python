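"""Fixed-effects genotype–litter-size association analysis.

The model is the classical two-marker fixed-effects linear model

    y = mu + P + G1 + G2 + G1xG2 + e

with y the litter size of one parity record, P a fixed parity effect, G1
and G2 the genotype factors of the two candidate loci, G1xG2 their
interaction, and e i.i.d. Gaussian error.  Each parity record is an
independent observation.  Because field data are unbalanced, terms are
tested with sequential (Type I) sums of squares in the stated entry
order; F statistics are formed against the residual mean square.

Group comparisons use least-squares means (model predictions averaged
with equal weight over the levels of the other factors) separated by
Duncan's multiple range test: for a span of p ordered means the critical
range is

    R_p = q(alpha_p, p, df) * sqrt(MSE / n_h),

with protection level alpha_p = 1 - (1 - alpha)^(p - 1), q the
studentized-range quantile, and n_h the harmonic mean of the group
replications (the standard unbalanced extension).  A span is never
declared significant inside a larger non-significant span.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticError, ValidationError
from .io import Dataset

logger = logging.getLogger(__name__)

TERM_ORDER = ("parity", "g1", "g2", "g1:g2")


@dataclass
class DesignMatrix:
    """Treatment-coded design for the litter-size model.

    ``terms`` maps each fitted term (``intercept``, ``parity``, ``g1``,
    ``g2``, ``g1:g2``) to its column indices in ``X``, in entry order.
    Interaction columns for genotype combinations never observed are
    dropped (recorded in ``dropped_columns``); terms whose factor has a
    single observed level are dropped entirely.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    terms: dict[str, list[int]]
    factor_levels: dict[str, list]
    rows: pd.DataFrame
    n_dropped_records: int
    dropped_columns: list[str]
    dropped_terms: list[str]


@dataclass
class FitResult:
    design: DesignMatrix
    coefficients: np.ndarray
    coefficient_covariance: np.ndarray
    residual_ss: float
    residual_df: int
    residual_ms: float
    sequential_ss: dict[str, float]
    term_df: dict[str, int]

    @property
    def total_ss(self) -> float:
        y = self.design.y
        return float(np.sum((y - y.mean()) ** 2))


@dataclass
class LSMeans:
    factor: str
    table: pd.DataFrame  # level, estimate, se, n_records, estimable


@dataclass
class DuncanGrouping:
    factor: str
    alpha: float
    table: pd.DataFrame  # level, ls_mean, n_records, letters
    critical_ranges: dict[int, float]  # span p -> R_p

    def letters(self) -> dict:
        return dict(zip(self.table["level"], self.table["letters"]))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(dataset: Dataset, g1: str, g2: str) -> DesignMatrix:
    """Assemble the treatment-coded design matrix for two genotype factors.

    Phenotype records whose animal is untyped at either locus are dropped
    (count logged).  Factor levels are the observed genotype categories;
    the first level in sorted order is the reference level.
    """
    table = dataset.genotypes
    g1_geno = dict(zip(table.sample_ids, table.column(g1)))
    g2_geno = dict(zip(table.sample_ids, table.column(g2)))

    rows = []
    n_dropped = 0
    for rec in dataset.phenotypes:
        a, b = g1_geno[rec.animal_id], g2_geno[rec.animal_id]
        if a is None or b is None:
            n_dropped += 1
            continue
        rows.append({"animal_id": rec.animal_id, "parity": rec.parity,
                     "g1": a, "g2": b, "y": float(rec.litter_size)})
    if n_dropped:
        logger.info("dropped %d phenotype record(s) with missing genotypes", n_dropped)
    if not rows:
        raise ValidationError("no usable records after dropping missing genotypes")
    df = pd.DataFrame(rows)

    levels = {f: sorted(df[f].unique()) for f in ("parity", "g1", "g2")}
    n = len(df)
    X_cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    terms: dict[str, list[int]] = {"intercept": [0]}
    dropped_terms: list[str] = []
    dropped_columns: list[str] = []

    def try_add(col: np.ndarray, name: str) -> bool:
        """Add a column unless it is aliased by the columns already entered.

        Mirrors the pivoting of standard linear-model fitters: a column
        linearly dependent on earlier ones (sparse data can alias even a
        main-effect dummy) is dropped, in entry order, with a warning.
        """
        candidate = np.column_stack(X_cols + [col])
        if np.linalg.matrix_rank(candidate) == len(X_cols) + 1:
            X_cols.append(col)
            names.append(name)
            return True
        dropped_columns.append(name)
        logger.warning("design column %s is aliased by earlier columns; dropped", name)
        return False

    def add_factor(term: str) -> None:
        lv = levels[term]
        if len(lv) < 2:
            logger.warning("factor %s has a single observed level (%r); term dropped",
                           term, lv[0] if lv else None)
            dropped_terms.append(term)
            return
        idx = []
        for level in lv[1:]:
            pos = len(X_cols)
            if try_add((df[term] == level).to_numpy(float), f"{term}[{level}]"):
                idx.append(pos)
        if idx:
            terms[term] = idx
        else:
            raise ValidationError(
                f"factor {term} is completely confounded with earlier terms"
            )

    add_factor("parity")
    add_factor("g1")
    add_factor("g2")

    if "g1" in terms and "g2" in terms:
        idx = []
        observed = set(zip(df["g1"], df["g2"]))
        for l1, l2 in itertools.product(levels["g1"][1:], levels["g2"][1:]):
            name = f"g1[{l1}]:g2[{l2}]"
            if (l1, l2) not in observed:
                dropped_columns.append(name)
                logger.info("empty interaction cell: column %s dropped", name)
                continue
            pos = len(X_cols)
            if try_add(((df["g1"] == l1) & (df["g2"] == l2)).to_numpy(float), name):
                idx.append(pos)
        if idx:
            terms["g1:g2"] = idx
        else:
            dropped_terms.append("g1:g2")
    else:
        dropped_terms.append("g1:g2")

    X = np.column_stack(X_cols)
    return DesignMatrix(X=X, y=df["y"].to_numpy(float), columns=names, terms=terms,
                        factor_levels=levels, rows=df,
                        n_dropped_records=n_dropped,
                        dropped_columns=dropped_columns, dropped_terms=dropped_terms)


# ---------------------------------------------------------------------------
# least-squares fit with sequential sums of squares
# ---------------------------------------------------------------------------

def fit_fixed_effects(design: DesignMatrix) -> FitResult:
    """Least-squares fit with sequential (Type I) sums of squares.

    Terms enter in the model's stated order (parity, G1, G2, G1xG2); the
    QR factorization of the ordered design orthogonalizes each term
    against everything before it, so per-term squared projections are the
    sequential sums of squares.
    """
    X, y = design.X, design.y
    n, k = X.shape
    if n <= k:
        raise ValidationError(f"{n} observations cannot support {k} design columns")
    Q, R = np.linalg.qr(X)
    effects = Q.T @ y
    beta = np.linalg.solve(R, effects)
    fitted = X @ beta
    residual_ss = float(np.sum((y - fitted) ** 2))
    residual_df = n - k
    residual_ms = residual_ss / residual_df if residual_df > 0 else float("nan")
    Rinv = np.linalg.inv(R)
    cov = residual_ms * (Rinv @ Rinv.T)

    seq_ss = {}
    term_df = {}
    for term, idx in design.terms.items():
        if term == "intercept":
            continue
        seq_ss[term] = float(np.sum(effects[idx] ** 2))
        term_df[term] = len(idx)
    return FitResult(design=design, coefficients=beta, coefficient_covariance=cov,
                     residual_ss=residual_ss, residual_df=residual_df,
                     residual_ms=residual_ms, sequential_ss=seq_ss, term_df=term_df)


def anova_table(fit: FitResult) -> pd.DataFrame:
    """Sequential ANOVA table: one row per term plus the residual row.

    With a saturated (perfect-fit) model the residual mean square is zero
    and F/p are reported as NaN rather than invented.
    """
    rows = []
    for term in [t for t in TERM_ORDER if t in fit.sequential_ss]:
        ss = fit.sequential_ss[term]
        dfree = fit.term_df[term]
        ms = ss / dfree
        if fit.residual_df > 0 and fit.residual_ms > 0:
            F = ms / fit.residual_ms
            p = float(stats.f.sf(F, dfree, fit.residual_df))
        else:
            F, p = float("nan"), float("nan")
        rows.append({"term": term, "df": dfree, "ss": ss, "ms": ms, "F": F, "p": p})
    rows.append({"term": "residual", "df": fit.residual_df, "ss": fit.residual_ss,
                 "ms": fit.residual_ms, "F": float("nan"), "p": float("nan")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# least-squares means
# ---------------------------------------------------------------------------

def _row_vector(design: DesignMatrix, parity, g1, g2) -> np.ndarray:
    """Design row for one (parity, g1, g2) cell, over the fitted columns."""
    x = np.zeros(design.X.shape[1])
    x[0] = 1.0
    lookup = {name: i for i, name in enumerate(design.columns)}
    for name in (f"parity[{parity}]", f"g1[{g1}]", f"g2[{g2}]", f"g1[{g1}]:g2[{g2}]"):
        if name in lookup:
            x[lookup[name]] = 1.0
    return x


def ls_means(fit: FitResult, factor: str) -> LSMeans:
    """Least-squares means of one factor.

    Each level's mean is the model prediction averaged with equal weight
    over every observed combination of the other factors' levels; the
    standard error comes from the coefficient covariance.  A level whose
    required genotype combinations were never observed (dropped
    interaction cells) is averaged over its observed cells only and
    flagged non-estimable.
    """
    design = fit.design
    if factor not in ("parity", "g1", "g2"):
        raise ValidationError(f"unknown factor {factor!r}")
    others = [f for f in ("parity", "g1", "g2") if f != factor]
    observed_cells = set(zip(design.rows["g1"], design.rows["g2"]))
    has_interaction = "g1:g2" in design.terms

    rows = []
    for level in design.factor_levels[factor]:
        cell_vectors = []
        any_missing = False
        for combo in itertools.product(*(design.factor_levels[f] for f in others)):
            cell = dict(zip(others, combo))
            cell[factor] = level
            if has_interaction and (cell["g1"], cell["g2"]) not in observed_cells:
                any_missing = True
                continue
            cell_vectors.append(_row_vector(design, cell["parity"], cell["g1"], cell["g2"]))
        n_records = int((design.rows[factor] == level).sum())
        if not cell_vectors:
            rows.append({"level": level, "estimate": float("nan"), "se": float("nan"),
                         "n_records": n_records, "estimable": False})
            continue
        c = np.mean(cell_vectors, axis=0)
        est = float(c @ fit.coefficients)
        se = float(np.sqrt(c @ fit.coefficient_covariance @ c))
        rows.append({"level": level, "estimate": est, "se": se,
                     "n_records": n_records, "estimable": not any_missing})
    return LSMeans(factor=factor, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def studentized_range_quantile(alpha_p: float, p: int, df: int) -> float:
    """Upper-tail studentized-range quantile q such that P(Q > q) = alpha_p.

    Obtained by numeric inversion of the distribution function (scipy);
    the inversion is accurate well beyond 1e-6.  Cached because the
    inversion is expensive and Duncan sweeps reuse few (p, df) pairs.
    """
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p, df))


def duncan_critical_ranges(n_means: int, df: int, mse: float, n_h: float,
                           alpha: float = 0.05) -> dict[int, float]:
    """Critical ranges R_p for spans p = 2..n_means."""
    if df <= 0:
        raise DegenerateStatisticError("Duncan test undefined with zero residual df")
    if mse <= 0:
        return {p: 0.0 for p in range(2, n_means + 1)}
    ranges = {}
    for p in range(2, n_means + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = studentized_range_quantile(alpha_p, p, df)
        ranges[p] = q * np.sqrt(mse / n_h)
    return ranges


def _assign_letters(means_desc: list[float], ranges: dict[int, float]) -> list[set[str]]:
    """Letter sweep over means sorted in descending order.

    Maximal non-significant spans each receive one letter; containment in
    a larger non-significant span protects sub-spans, so members of such
    a span always share its letter.
    """
    k = len(means_desc)
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and (means_desc[i] - means_desc[j + 1]) <= ranges.get(j + 1 - i + 1, 0.0):
            j += 1
        intervals.append((i, j))
    # keep maximal intervals only
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)]
    maximal.sort()
    letters: list[set[str]] = [set() for _ in range(k)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (i, j) in enumerate(maximal):
        letter = alphabet[idx % len(alphabet)]
        for t in range(i, j + 1):
            letters[t].add(letter)
    return letters


def duncan_letters(means: dict, n_records: dict, mse: float, df: int,
                   alpha: float = 0.05, factor: str = "") -> DuncanGrouping:
    """Duncan multiple-range grouping of arbitrary group means.

    ``means`` maps level -> group mean and ``n_records`` level -> group
    replication; the replication enters through its harmonic mean.
    """
    if len(means) < 2:
        raise DegenerateStatisticError("Duncan test needs at least two group means")
    if df <= 0:
        raise DegenerateStatisticError("Duncan test undefined with zero residual df")
    levels = sorted(means, key=lambda l: means[l], reverse=True)
    n_h = len(levels) / sum(1.0 / n_records[l] for l in levels)
    ranges = duncan_critical_ranges(len(levels), df, mse, n_h, alpha)
    letters = _assign_letters([means[l] for l in levels], ranges)
    table = pd.DataFrame({
        "level": levels,
        "ls_mean": [means[l] for l in levels],
        "n_records": [n_records[l] for l in levels],
        "letters": ["".join(sorted(s)) for s in letters],
    })
    return DuncanGrouping(factor=factor, alpha=alpha, table=table,
                          critical_ranges=ranges)


def duncan_groups(fit: FitResult, factor: str, alpha: float = 0.05) -> DuncanGrouping:
    """Duncan multiple-range letter groups on the least-squares means."""
    lsm = ls_means(fit, factor).table
    lsm = lsm[np.isfinite(lsm["estimate"])]
    if len(lsm) < 2:
        raise DegenerateStatisticError(
            f"factor {factor!r} has fewer than two estimable levels"
        )
    grouping = duncan_letters(dict(zip(lsm["level"], lsm["estimate"])),
                              dict(zip(lsm["level"], lsm["n_records"])),
                              fit.residual_ms, fit.residual_df, alpha, factor=factor)
    se = dict(zip(lsm["level"], lsm["se"]))
    grouping.table.insert(2, "se", [se[l] for l in grouping.table["level"]])
    return grouping


# ---------------------------------------------------------------------------
# raw per-genotype summaries
# ---------------------------------------------------------------------------

def genotype_summary(dataset: Dataset, locus: str) -> pd.DataFrame:
    """Raw complete-case mean +/- SD and record count per genotype class.

    Sample SD (ddof = 1); a class with a single record reports SD 0.0.
    Empty classes are simply absent.
    """
    table = dataset.genotypes
    geno = dict(zip(table.sample_ids, table.column(locus)))
    groups: dict[str, list[float]] = {}
    for rec in dataset.phenotypes:
        g = geno[rec.animal_id]
        if g is None:
            continue
        groups.setdefault(g, []).append(float(rec.litter_size))
    rows = []
    for g in sorted(groups):
        vals = np.array(groups[g])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"genotype": g, "n_records": len(vals),
                     "mean": float(vals.mean()), "sd": sd})
    return pd.DataFrame(rows, columns=["genotype", "n_records", "mean", "sd"])
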