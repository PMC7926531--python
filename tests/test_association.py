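import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ovistat import (
    Dataset,
    DegenerateStatisticError,
    PhenotypeRecord,
    ValidationError,
    anova_table,
    build_design,
    duncan_groups,
    duncan_letters,
    fit_fixed_effects,
    genotype_summary,
    ls_means,
)
from ovistat.association import duncan_critical_ranges, studentized_range_quantile
from ovistat.simdata import GenoSimParams, PhenoSimParams, simulate_genotypes, simulate_phenotypes

from conftest import make_table, simulated_dataset


def full_factorial_dataset(reps=2, y_fn=None):
    """Balanced 2 parity x 3 g1 x 3 g2 dataset with a deterministic response."""
    genos = ["AA", "AG", "GG"]
    animals, g1_col, g2_col, records = [], [], [], []
    y_fn = y_fn or (lambda parity, a, b: 2.0)
    idx = 0
    for a, b in itertools.product(genos, genos):
        for _ in range(reps):
            name = f"s{idx}"
            idx += 1
            animals.append(name)
            g1_col.append(a)
            g2_col.append(b)
            for parity in (1, 2):
                records.append(PhenotypeRecord(name, parity, y_fn(parity, a, b)))
    table = make_table({"l1": g1_col, "l2": g2_col}, sample_prefix="zz")
    table.sample_ids = animals  # align ids with the phenotype records
    return Dataset(table, records)


def sequential_ss_oracle(design):
    """Brute-force sequential SS via nested least-squares refits."""
    X, y = design.X, design.y
    order = ["intercept"] + [t for t in ("parity", "g1", "g2", "g1:g2")
                             if t in design.terms]
    rss_prev = float(np.sum((y - 0) ** 2))
    cols: list[int] = []
    out = {}
    for term in order:
        cols = cols + design.terms[term]
        beta, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        rss = float(np.sum((y - X[:, cols] @ beta) ** 2))
        out[term] = rss_prev - rss
        rss_prev = rss
    return out, rss_prev


class TestBuildDesign:
    def test_full_factorial_rank(self):
        ds = full_factorial_dataset()
        design = build_design(ds, "l1", "l2")
        # 1 intercept + 1 parity + 2 g1 + 2 g2 + 4 interaction contrasts
        assert design.X.shape[1] == 10
        assert np.linalg.matrix_rank(design.X) == 10
        assert [len(design.terms[t]) for t in ("parity", "g1", "g2", "g1:g2")] == [1, 2, 2, 4]

    def test_two_level_factor_contributes_one_column(self):
        table = make_table({"l1": ["AA", "AG", "AA", "AG"],
                            "l2": ["AA", "AA", "AG", "AG"]})
        recs = [PhenotypeRecord(s, p, 2) for s in table.sample_ids for p in (1, 2)]
        design = build_design(Dataset(table, recs), "l1", "l2")
        assert len(design.terms["g1"]) == 1

    def test_empty_cells_drop_interaction_columns(self):
        ds = full_factorial_dataset()
        # remove every GG x GG animal -> that interaction contrast disappears
        keep = [i for i, (a, b) in enumerate(zip(ds.genotypes.column("l1"),
                                                 ds.genotypes.column("l2")))
                if not (a == "GG" and b == "GG")]
        table = ds.genotypes
        import numpy as _np
        sub = table.__class__([table.sample_ids[i] for i in keep], table.loci,
                              table.genotypes[keep])
        recs = [r for r in ds.phenotypes if r.animal_id in set(sub.sample_ids)]
        design = build_design(Dataset(sub, recs), "l1", "l2")
        assert design.dropped_columns == ["g1[GG]:g2[GG]"]
        assert len(design.terms["g1:g2"]) == 3
        assert np.linalg.matrix_rank(design.X) == design.X.shape[1]

    def test_missing_genotypes_dropped_with_count(self):
        table = make_table({"l1": ["AA", None, "AG"], "l2": ["AA", "AG", "AA"]})
        recs = [PhenotypeRecord(s, 1, 2) for s in table.sample_ids]
        design = build_design(Dataset(table, recs), "l1", "l2")
        assert design.n_dropped_records == 1
        assert len(design.rows) == 2


class TestSequentialFit:
    def test_parity_only_signal_leaves_genotype_ss_zero(self):
        ds = full_factorial_dataset(y_fn=lambda parity, a, b: 1.0 + parity)
        fit = fit_fixed_effects(build_design(ds, "l1", "l2"))
        assert fit.sequential_ss["parity"] > 0
        for term in ("g1", "g2", "g1:g2"):
            assert fit.sequential_ss[term] == pytest.approx(0.0, abs=1e-18)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-18)

    def test_matches_bruteforce_projection_oracle(self):
        """Sequential SS on a small unbalanced dataset equal nested refits."""
        rng = np.random.default_rng(5)
        table = make_table({"l1": ["AA", "AA", "AG", "AG", "GG", "AA", "AG", "AA"],
                            "l2": ["AA", "AG", "AA", "AG", "AA", "AA", "AG", "AG"]})
        recs = []
        for i, s in enumerate(table.sample_ids):
            for parity in (1, 2):
                recs.append(PhenotypeRecord(s, parity, float(rng.integers(1, 4))))
        design = build_design(Dataset(table, recs), "l1", "l2")
        fit = fit_fixed_effects(design)
        oracle_ss, oracle_rss = sequential_ss_oracle(design)
        for term, ss in fit.sequential_ss.items():
            assert ss == pytest.approx(oracle_ss[term], abs=1e-8)
        assert fit.residual_ss == pytest.approx(oracle_rss, abs=1e-8)

    def test_matches_statsmodels_sequential_anova(self):
        """Cross-check df, SS, F and p against statsmodels anova_lm type I."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        ds = simulated_dataset(seed=42, g1_effects={"AA": 0, "AG": 0.4, "GG": -0.5},
                               g2_effects={"AA": 0, "AG": 0.9, "GG": 0.9})
        design = build_design(ds, "locus_1", "locus_2")
        fit = fit_fixed_effects(design)
        table = anova_table(fit).set_index("term")
        m = smf.ols("y ~ C(parity) + C(g1) + C(g2) + C(g1):C(g2)",
                    data=design.rows).fit()
        ref = sm.stats.anova_lm(m, typ=1)
        for term, ref_term in [("parity", "C(parity)"), ("g1", "C(g1)"),
                               ("g2", "C(g2)"), ("g1:g2", "C(g1):C(g2)")]:
            if ref_term not in ref.index:
                continue
            assert table.loc[term, "df"] == ref.loc[ref_term, "df"]
            assert table.loc[term, "ss"] == pytest.approx(ref.loc[ref_term, "sum_sq"])
            assert table.loc[term, "F"] == pytest.approx(ref.loc[ref_term, "F"])
            assert table.loc[term, "p"] == pytest.approx(ref.loc[ref_term, "PR(>F)"])
        assert fit.residual_ss == pytest.approx(ref.loc["Residual", "sum_sq"])

    def test_shift_invariance_and_ss_conservation(self):
        ds = simulated_dataset(seed=7)
        design = build_design(ds, "locus_1", "locus_2")
        fit = fit_fixed_effects(design)
        total = fit.total_ss
        assert sum(fit.sequential_ss.values()) + fit.residual_ss == pytest.approx(
            total, rel=1e-8)
        shifted = build_design(Dataset(ds.genotypes, [
            PhenotypeRecord(r.animal_id, r.parity, r.litter_size + 3)
            for r in ds.phenotypes]), "locus_1", "locus_2")
        fit2 = fit_fixed_effects(shifted)
        for term in fit.sequential_ss:
            assert fit2.sequential_ss[term] == pytest.approx(
                fit.sequential_ss[term], rel=1e-8, abs=1e-10)

    def test_planted_effect_recovery_within_3_se(self):
        effects = {"AA": 0.0, "AG": 0.4, "GG": -0.5}
        ds = simulated_dataset(seed=11, g1_effects=effects)
        design = build_design(ds, "locus_1", "locus_2")
        fit = fit_fixed_effects(design)
        cols = {name: i for i, name in enumerate(design.columns)}
        for level in ("AG", "GG"):
            name = f"g1[{level}]"
            if name not in cols:
                continue
            i = cols[name]
            se = np.sqrt(fit.coefficient_covariance[i, i])
            assert abs(fit.coefficients[i] - effects[level]) < 3 * se

    def test_saturated_model_reports_nan_f(self):
        table = make_table({"l1": ["AA", "AG"], "l2": ["AA", "AA"]})
        recs = [PhenotypeRecord(s, 1, v) for s, v in zip(table.sample_ids, (1, 3))]
        with pytest.raises(ValidationError):
            # 2 observations cannot support intercept + g1
            fit_fixed_effects(build_design(Dataset(table, recs), "l1", "l2"))


class TestTypeIError:
    def test_g1_f_test_calibrated_under_null(self):
        """Null rejection rate at alpha=0.05 stays in the binomial 99% band."""
        n_reps, rejections = 400, 0
        for rep in range(n_reps):
            ds = simulated_dataset(seed=30_000 + rep)
            fit = fit_fixed_effects(build_design(ds, "locus_1", "locus_2"))
            table = anova_table(fit).set_index("term")
            rejections += table.loc["g1", "p"] < 0.05
        lo = stats.binom.ppf(0.005, n_reps, 0.05) / n_reps
        hi = stats.binom.ppf(0.995, n_reps, 0.05) / n_reps
        assert lo <= rejections / n_reps <= hi


class TestLSMeans:
    def test_balanced_design_equals_raw_means(self):
        rng = np.random.default_rng(3)
        values = {}
        ds = full_factorial_dataset(
            reps=2, y_fn=lambda parity, a, b: values.setdefault(
                (parity, a, b), float(rng.uniform(1.5, 3.0))))
        design = build_design(ds, "l1", "l2")
        fit = fit_fixed_effects(design)
        lsm = ls_means(fit, "g1").table.set_index("level")
        raw = design.rows.groupby("g1")["y"].mean()
        for level in raw.index:
            assert lsm.loc[level, "estimate"] == pytest.approx(raw[level])
        assert (lsm["se"] > 0).all()

    def test_unbalanced_ls_means_equal_equal_weight_cell_average(self):
        ds = simulated_dataset(seed=21, g2_effects={"AA": 0, "AG": 0.9, "GG": 0.9})
        design = build_design(ds, "locus_1", "locus_2")
        fit = fit_fixed_effects(design)
        lsm = ls_means(fit, "g2").table.set_index("level")
        # brute-force prediction grid over observed cells
        beta = dict(zip(design.columns, fit.coefficients))
        observed = set(zip(design.rows["g1"], design.rows["g2"]))
        for level in lsm.index:
            preds = []
            for parity in design.factor_levels["parity"]:
                for g1v in design.factor_levels["g1"]:
                    if "g1:g2" in design.terms and (g1v, level) not in observed:
                        continue
                    pred = beta["intercept"]
                    pred += beta.get(f"parity[{parity}]", 0.0)
                    pred += beta.get(f"g1[{g1v}]", 0.0)
                    pred += beta.get(f"g2[{level}]", 0.0)
                    pred += beta.get(f"g1[{g1v}]:g2[{level}]", 0.0)
                    preds.append(pred)
            assert lsm.loc[level, "estimate"] == pytest.approx(np.mean(preds))

    def test_heterozygote_advantage_pattern(self):
        """With a planted heterozygote advantage the AG LS mean is highest."""
        ds = simulated_dataset(seed=2, g1_effects={"AA": 0, "AG": 0.5, "GG": -0.3})
        fit = fit_fixed_effects(build_design(ds, "locus_1", "locus_2"))
        lsm = ls_means(fit, "g1").table.set_index("level")
        assert lsm["estimate"].idxmax() == "AG"


class TestDuncan:
    def test_textbook_five_treatment_oracle(self):
        """Letter groups match hand-computed ranges from published tables.

        Five treatments, 5 replicates each, MSE 8.06 on 20 df, means
        9.8 / 15.4 / 17.6 / 21.6 / 10.8.  Published significant
        studentized ranges r_p(0.05; p, 20) = 2.95, 3.10, 3.18, 3.25 give
        critical ranges 3.75, 3.93, 4.04, 4.13 (x sqrt(8.06/5) = 1.27),
        hence groups {T4} > {T3, T2} > {T5, T1}.
        """
        means = {"T1": 9.8, "T2": 15.4, "T3": 17.6, "T4": 21.6, "T5": 10.8}
        g = duncan_letters(means, {k: 5 for k in means}, mse=8.06, df=20)
        published = {2: 3.75, 3: 3.93, 4: 4.04, 5: 4.13}
        for p, r in published.items():
            assert g.critical_ranges[p] == pytest.approx(r, abs=0.02)
        letters = g.letters()
        assert letters["T4"] == "a"
        assert letters["T3"] == letters["T2"] == "b"
        assert letters["T5"] == letters["T1"] == "c"

    def test_equal_means_share_a_letter(self):
        g = duncan_letters({"a": 2.0, "b": 2.0, "c": 2.0},
                           {"a": 5, "b": 5, "c": 5}, mse=1.0, df=12)
        assert set(g.letters().values()) == {"a"}

    def test_wide_separation_distinct_letters(self):
        g = duncan_letters({"lo": 0.0, "mid": 10.0, "hi": 20.0},
                           {"lo": 5, "mid": 5, "hi": 5}, mse=1.0, df=12)
        assert len(set(g.letters().values())) == 3

    def test_span2_range_is_unprotected_pairwise_range(self):
        ranges = duncan_critical_ranges(4, df=20, mse=2.0, n_h=5.0, alpha=0.05)
        q2 = studentized_range_quantile(0.05, 2, 20)
        assert ranges[2] == pytest.approx(q2 * np.sqrt(2.0 / 5.0))
        spans = [ranges[p] for p in sorted(ranges)]
        assert all(a <= b + 1e-12 for a, b in zip(spans, spans[1:]))

    def test_contiguity_protects_inner_spans(self):
        # outer span (hi-lo) below its critical range: all share one letter
        # even if an inner pair alone would exceed the span-2 range
        ranges = duncan_critical_ranges(3, df=10, mse=100.0, n_h=4.0)
        means = {"a": 0.0, "b": ranges[2] * 1.01, "c": ranges[3] * 0.99}
        g = duncan_letters(means, {k: 4 for k in means}, mse=100.0, df=10)
        assert len(set(g.letters().values())) == 1

    def test_zero_residual_df_refused(self):
        with pytest.raises(DegenerateStatisticError):
            duncan_letters({"a": 1.0, "b": 2.0}, {"a": 2, "b": 2}, mse=1.0, df=0)

    def test_groups_from_model_fit(self):
        ds = simulated_dataset(seed=12, g2_effects={"AA": 0, "AG": 0.9, "GG": 0.9})
        fit = fit_fixed_effects(build_design(ds, "locus_1", "locus_2"))
        g = duncan_groups(fit, "g2", alpha=0.05)
        letters = g.letters()
        assert set(letters["AG"]) & set(letters["GG"])  # mutants not separated
        assert not set(letters["AA"]) & set(letters["AG"])  # wild type separated


class TestGenotypeSummary:
    def test_single_animal_two_records(self):
        table = make_table({"l1": ["AG"], "l2": ["AA"]})
        ds = Dataset(table, [PhenotypeRecord("s0", 1, 2), PhenotypeRecord("s0", 2, 2)])
        df = genotype_summary(ds, "l1").set_index("genotype")
        assert df.loc["AG", "mean"] == pytest.approx(2.0)
        assert df.loc["AG", "sd"] == pytest.approx(0.0)
        assert df.loc["AG", "n_records"] == 2

    def test_matches_bruteforce_and_omits_empty_classes(self):
        ds = simulated_dataset(seed=9)
        df = genotype_summary(ds, "locus_1")
        geno = dict(zip(ds.genotypes.sample_ids, ds.genotypes.column("locus_1")))
        for _, row in df.iterrows():
            vals = [r.litter_size for r in ds.phenotypes
                    if geno[r.animal_id] == row["genotype"]]
            assert row["n_records"] == len(vals) > 0
            assert row["mean"] == pytest.approx(np.mean(vals))
            if len(vals) > 1:
                assert row["sd"] == pytest.approx(np.std(vals, ddof=1))
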