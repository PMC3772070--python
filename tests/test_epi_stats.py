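"""Heterogeneity and trend tests, odds ratios, logistic regression."""

import numpy as np
import pandas as pd
import pytest

from smokestat import (
    ContingencyTable,
    cochran_armitage,
    crosstab,
    fit_logistic,
    missingness_table,
    odds_ratio,
    pearson_chi2,
)
from smokestat.epi_stats import format_p, proportions


def table(rows, ordinal=False, labels=None):
    labels = labels or [f"r{i}" for i in range(len(rows))]
    return ContingencyTable(labels, ["event", "no_event"], rows, ordinal=ordinal)


def random_table(rng, k=3, null=True):
    """Random k x 2 table with positive margins."""
    n_i = rng.integers(30, 200, size=k)
    if null:
        p = rng.uniform(0.2, 0.8)
        r_i = rng.binomial(n_i, p)
    else:
        r_i = rng.binomial(n_i, rng.uniform(0.2, 0.8, size=k))
    r_i = np.clip(r_i, 1, n_i - 1)  # keep margins positive
    return table(np.column_stack([r_i, n_i - r_i]), ordinal=True)


# ---------------------------------------------------------------------------
# Pearson chi-squared
# ---------------------------------------------------------------------------

def test_identical_row_proportions_give_zero_statistic():
    stat, df, p = pearson_chi2(table([[10, 10], [20, 20]]))
    assert stat == pytest.approx(0.0)
    assert (df, p) == (1, pytest.approx(1.0))


def test_hand_computed_2x2_chi2():
    # expected counts 15/15 per row; X^2 = sum (obs-exp)^2/exp = 13.33...
    stat, df, _ = pearson_chi2(table([[10, 10], [20, 0]]))
    assert df == 1
    assert stat == pytest.approx(40.0 / 3.0)


def test_zero_marginal_is_an_error():
    with pytest.raises(ValueError):
        pearson_chi2(table([[0, 10], [0, 20]]))


# ---------------------------------------------------------------------------
# Cochran-Armitage trend
# ---------------------------------------------------------------------------

def test_equal_proportions_have_no_trend():
    stat, p = cochran_armitage(table([[5, 5], [10, 10], [20, 20]], ordinal=True))
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_trend_needs_three_ordered_categories():
    with pytest.raises(ValueError):
        cochran_armitage(table([[5, 5], [10, 10]], ordinal=True))


def test_trend_statistic_matches_correlation_oracle():
    """The trend chi-squared equals N times the squared Pearson correlation
    between row score and outcome on the row-expanded individual data."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        t = random_table(rng, k=int(rng.integers(3, 6)), null=False)
        stat, _ = cochran_armitage(t)
        scores, events = [], []
        for i, (r, nr) in enumerate(t.counts):
            scores += [i] * int(r + nr)
            events += [1] * int(r) + [0] * int(nr)
        r_corr = np.corrcoef(scores, events)[0, 1]
        assert stat == pytest.approx(len(scores) * r_corr**2, rel=1e-10)


def test_trend_is_affine_invariant_in_scores():
    rng = np.random.default_rng(1)
    for _ in range(50):
        t = random_table(rng, null=False)
        base, _ = cochran_armitage(t)
        shifted, _ = cochran_armitage(t, scores=[7 + 3 * i for i in range(3)])
        assert shifted == pytest.approx(base, rel=1e-10)


def test_heterogeneity_dominates_trend():
    """Pearson X^2 >= the 1-df trend component of the same k x 2 table."""
    rng = np.random.default_rng(2)
    for _ in range(200):
        t = random_table(rng, k=int(rng.integers(3, 7)), null=False)
        het, _, _ = pearson_chi2(t)
        trend, _ = cochran_armitage(t)
        assert het >= trend - 1e-9


# ---------------------------------------------------------------------------
# Odds ratios
# ---------------------------------------------------------------------------

def test_unit_table_gives_unit_or_with_symmetric_ci():
    r = odds_ratio(table([[1, 1], [1, 1]]))
    assert r.estimate == pytest.approx(1.0)
    assert r.ci_low * r.ci_high == pytest.approx(1.0)


def test_zero_cell_is_an_error_unless_corrected():
    t = table([[0, 10], [5, 5]])
    with pytest.raises(ValueError, match="continuity"):
        odds_ratio(t)
    r = odds_ratio(t, haldane=True)
    assert 0 < r.estimate < 1


def test_reference_row_flips_the_ratio():
    t = table([[30, 12], [25, 40]])
    assert odds_ratio(t, reference=1).estimate == pytest.approx(
        1.0 / odds_ratio(t, reference=0).estimate
    )


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def test_grouped_and_expanded_fits_agree():
    grouped = pd.DataFrame({"x": [0.0, 1.0, 2.0], "k": [14, 19, 26], "n": [40, 40, 40]})
    rows = []
    for _, r in grouped.iterrows():
        rows += [{"x": r["x"], "y": 1}] * int(r["k"])
        rows += [{"x": r["x"], "y": 0}] * int(r["n"] - r["k"])
    expanded = pd.DataFrame(rows)
    fg = fit_logistic(grouped, "k", ["x"], trials="n")
    fe = fit_logistic(expanded, "y", ["x"])
    assert fg.n_used == fe.n_used == 120
    assert np.allclose(fg.params, fe.params, rtol=1e-8)
    assert np.allclose(fg.cov, fe.cov, rtol=1e-6)


def test_categorical_terms_use_first_level_as_reference():
    df = pd.DataFrame({
        "grp": pd.Categorical(["a"] * 2 + ["b"] * 2, categories=["a", "b"]),
        "k": [20, 20, 30, 30],
        "n": [50, 50, 50, 50],
    })
    fit = fit_logistic(df, "k", ["grp"], trials="n")
    assert list(fit.params.index) == ["intercept", "grp[b]"]
    # OR(b vs a) = (60/40) / (40/60) = 2.25
    assert np.exp(fit.coefficients["grp[b]"]) == pytest.approx(2.25, rel=1e-6)


def test_reference_levels_survive_unknown_removal():
    """Dropping 'unknown' levels for complete-case fits must not reorder
    the categories: single stays the marital reference."""
    from datetime import date as D

    from smokestat import Patient
    from smokestat.epi_stats import unadjusted_odds_ratios
    from smokestat.patient_pipeline import cohort_frame
    from smokestat import PatientSmokingStatus

    patients, resolved = [], {}
    maritals = ["single", "cohabiting", "separated_widowed", "unknown"]
    for i in range(80):
        pid = f"m{i}"
        patients.append(Patient(
            patient_id=pid, age_at_referral=30 + i % 40, sex="male",
            marital=maritals[i % 4], deprivation_tertile="middle",
            diagnosis="schizophrenia", referral_date=D(2009, 1, 1),
            care_end_date=D(2010, 1, 1)))
        resolved[pid] = PatientSmokingStatus(
            pid, "current" if (i * 7) % 10 < 6 - i % 4 else "never",
            D(2009, 2, 1), "text")
    out = unadjusted_odds_ratios(cohort_frame(patients, resolved))
    assert "marital[cohabiting]" in out.index
    assert "marital[separated_widowed]" in out.index
    assert "marital[single]" not in out.index  # single is the reference


def test_separation_is_flagged_and_blocks_estimates():
    df = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1], "y": [0, 0, 0, 1, 1, 1]})
    fit = fit_logistic(df, "x", ["y"])
    assert not fit.converged
    with pytest.raises(RuntimeError, match="converge"):
        fit.odds_ratios()


def test_individual_outcome_must_be_binary():
    df = pd.DataFrame({"x": [0, 1], "y": [0, 2]})
    with pytest.raises(ValueError):
        fit_logistic(df, "y", ["x"])


# ---------------------------------------------------------------------------
# Cross-tabulation and missingness
# ---------------------------------------------------------------------------

def test_crosstab_counts_and_complete_case():
    frame = pd.DataFrame({
        "sex": pd.Categorical(["male"] * 4 + ["female"] * 4),
        "current": [True, True, False, None, True, False, False, None],
    })
    t = crosstab(frame, "sex")
    assert t.row_labels == ["female", "male"] or t.row_labels == ["male", "female"]
    assert t.total == 6  # the two unknown-outcome rows are dropped
    assert proportions(t).sum() > 0


def test_crosstab_recovers_generator_prevalences(register):
    """Realised stratum prevalences track the configured logistic model."""
    from smokestat.patient_pipeline import cohort_frame
    from smokestat import CohortSpec, build_cohort
    from datetime import date as D

    cohort = build_cohort(register.patients,
                          CohortSpec(referral_window=(D(2008, 1, 1), D(2011, 12, 31)),
                                     min_care_months=None))
    truth = register.truth.true_status
    frame = cohort_frame(cohort, {})
    frame["current"] = [truth[pid] == "current" for pid in frame["patient_id"]]
    t = crosstab(frame, "sex")
    p_by_sex = dict(zip(t.row_labels, proportions(t)))
    # female coefficient log(0.62) lowers the odds relative to males
    assert p_by_sex["female"] < p_by_sex["male"]
    for label, row in zip(t.row_labels, t.counts):
        n = row.sum()
        se = np.sqrt(0.25 / n)
        assert abs(row[0] / n - (0.62 if label == "male" else 0.50)) < 4 * se + 0.05


def test_missingness_table_with_no_missingness():
    frame = pd.DataFrame({
        "sex": pd.Categorical(["male"] * 5 + ["female"] * 5),
        "missing": [False] * 10,
    })
    out = missingness_table(frame, ["sex"])
    t = out["sex"]["table"]
    assert (t.counts[:, 0] == 0).all()
    assert out["sex"]["chi2"] == pytest.approx(0.0)


def test_p_value_formatting_convention():
    assert format_p(0.0004) == "<0.001"
    assert format_p(0.023) == "0.02"
    assert format_p(0.49) == "0.49"
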