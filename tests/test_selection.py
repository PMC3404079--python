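"""Univariate screening, backward elimination and the prognostic index."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from survsig.coding import CodedMatrix
from survsig.selection import (univariate_screen, backward_eliminate,
                               prognostic_index, independent_columns,
                               PrognosticModel)
from survsig.survival import SurvivalData

from conftest import bernoulli_coded, survival_for


def _coded_from(X, names=None):
    names = names or [f"M{j:02d}" for j in range(X.shape[1])]
    df = pd.DataFrame(np.asarray(X, dtype=float),
                      index=[f"S{i:04d}" for i in range(X.shape[0])],
                      columns=names)
    return CodedMatrix(df, {c: c for c in names})


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------


def test_duplicate_columns_get_identical_statistics():
    rng = np.random.default_rng(1)
    x = (rng.random(80) < 0.3).astype(float)
    coded = _coded_from(np.column_stack([x, x]), ["a", "b"])
    surv, _ = survival_for(coded, seed=1)
    rep = univariate_screen(coded, surv).table.set_index("variable")
    for col in ("p", "hr", "ci_lower", "ci_upper"):
        assert rep.loc["a", col] == rep.loc["b", col]


def test_univariate_power_for_planted_marker():
    """HR 2.0, carrier 0.3, n = 300, ~30% censoring: detected in >= 27/30."""
    hits = 0
    for s in range(30):
        coded = bernoulli_coded(300, 1, seed=s)
        surv, _ = survival_for(coded, seed=s, effects=[("M00", 2.0)],
                               rate=0.03)
        hits += bool(univariate_screen(coded, surv).table["significant"].iloc[0])
    assert hits >= 27


def test_univariate_type_one_error_within_binomial_band():
    """Null markers reject at ~5%: count inside the exact binomial 95% band."""
    R = 200
    rej = 0
    for s in range(R):
        coded = bernoulli_coded(100, 1, seed=1000 + s)
        surv, _ = survival_for(coded, seed=1000 + s, rate=0.03)
        rej += bool(univariate_screen(coded, surv).table["significant"].iloc[0])
    lo, hi = stats.binom.interval(0.95, R, 0.05)
    assert lo <= rej <= hi


def test_univariate_sorted_by_p_and_reports_all():
    coded = bernoulli_coded(120, 6, seed=3)
    surv, _ = survival_for(coded, seed=3)
    tab = univariate_screen(coded, surv).table
    assert len(tab) == 6
    ps = tab.loc[~tab["fit_failed"], "p"].to_numpy()
    assert np.all(np.diff(ps) >= 0)


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------


def test_single_strong_variable_is_retained():
    coded = bernoulli_coded(200, 1, seed=5)
    surv, _ = survival_for(coded, seed=5, effects=[("M00", 3.0)])
    model = backward_eliminate(coded, surv)
    assert model.variables == ["M00"]
    assert model.p[0] < 0.10


def test_selection_frequency_two_planted_eight_null():
    """Planted HR 2.0 / 0.4 survive; null retention stays near p_remove."""
    both = 0
    null_counts = []
    R = 25
    for s in range(R):
        coded = bernoulli_coded(400, 10, seed=s)
        surv, _ = survival_for(coded, seed=s,
                               effects=[("M00", 2.0), ("M01", 0.4)])
        model = backward_eliminate(coded, surv)
        both += ("M00" in model.variables) and ("M01" in model.variables)
        null_counts.append(
            sum(v not in ("M00", "M01") for v in model.variables))
    assert both >= 20  # >= 80% joint retention
    # mean retained nulls <= 8 * p_remove + Monte-Carlo margin
    assert np.mean(null_counts) <= 8 * 0.10 + 0.7


def test_all_null_selection_stays_sparse():
    """With 10 null markers the final model is empty in a sizeable fraction of
    replicates and retains ~p_remove * 10 variables on average."""
    empty = 0
    retained = []
    R = 30
    for s in range(R):
        coded = bernoulli_coded(100, 10, seed=2000 + s)
        surv, _ = survival_for(coded, seed=2000 + s)
        model = backward_eliminate(coded, surv)
        empty += model.empty
        retained.append(len(model.variables))
    # simulation oracle at 400 replicates gives empty fraction ~0.39 and mean
    # retained ~1.2; allow 3 sigma at R = 30
    assert 0.10 <= empty / R <= 0.70
    assert np.mean(retained) <= 2.2


def test_mandatory_covariate_never_removed():
    coded = bernoulli_coded(150, 4, seed=8)
    data = coded.data.copy()
    rng = np.random.default_rng(8)
    data["stage"] = (rng.random(150) < 0.5).astype(float)
    surv, _ = survival_for(coded, seed=8)
    model = backward_eliminate(data, surv, mandatory=["stage"])
    assert "stage" in model.variables  # stays even under the null


def test_row_order_invariance():
    coded = bernoulli_coded(150, 6, seed=9)
    surv, _ = survival_for(coded, seed=9, effects=[("M00", 2.5)])
    model1 = backward_eliminate(coded, surv)
    perm = np.random.default_rng(0).permutation(150)
    shuffled = CodedMatrix(coded.data.iloc[perm], dict(coded.locus_of))
    surv_shuffled = SurvivalData(surv.time[perm], surv.event[perm])
    model2 = backward_eliminate(shuffled, surv_shuffled)
    assert model1.variables == model2.variables
    np.testing.assert_allclose(model1.coef, model2.coef, atol=1e-8)


def test_entry_mode_univariate_restricts_candidates():
    coded = bernoulli_coded(200, 6, seed=11)
    surv, _ = survival_for(coded, seed=11, effects=[("M00", 3.0)])
    model = backward_eliminate(coded, surv, entry="univariate")
    sig = set(univariate_screen(coded, surv).significant)
    assert set(model.variables) <= sig


def test_p_remove_validation():
    coded = bernoulli_coded(50, 2, seed=1)
    surv, _ = survival_for(coded, seed=1)
    with pytest.raises(ValueError):
        backward_eliminate(coded, surv, p_remove=0.0)


def test_collinear_reference_level_dropped_most_frequent():
    """An exhaustive genotype triple loses its most frequent member."""
    rng = np.random.default_rng(13)
    g = rng.choice(3, size=200, p=[0.2, 0.5, 0.3])
    X = np.column_stack([(g == k).astype(float) for k in range(3)])
    coded = _coded_from(X, ["S*A/A", "S*A/G", "S*G/G"])
    kept, dropped = independent_columns(coded.data)
    assert dropped == ["S*A/G"]  # the heterozygote reference
    assert kept == ["S*A/A", "S*G/G"]


# ---------------------------------------------------------------------------
# prognostic index
# ---------------------------------------------------------------------------


def _model(variables, hrs):
    beta = np.array([math.log(h) for h in hrs])
    se = np.full(len(beta), 0.1)
    return PrognosticModel(variables=list(variables), coef=beta, se=se,
                           p=np.full(len(beta), 0.01), hr=np.exp(beta),
                           ci_lower=np.exp(beta - 0.2),
                           ci_upper=np.exp(beta + 0.2),
                           loglik=0.0, empty=len(beta) == 0)


def test_empty_model_scores_zero():
    m = _model([], [])
    assert prognostic_index(m, {"anything": 1.0}) == 0.0


def test_single_active_term():
    m = _model(["a", "b"], [math.exp(0.7), math.exp(-0.8)])
    assert prognostic_index(m, {"a": 1.0, "b": 0.0}) == pytest.approx(0.7)


def test_reported_signature_profile_score():
    """Subject carrying only the DRB1 risk allele and the SNP homozygote:
    PI = ln(1.948) + ln(1.484) ~ 1.062."""
    m = _model(["B*38", "C*15", "C*03", "DRB1*15", "CT60*G/G"],
               [0.097, 0.387, 0.449, 1.948, 1.484])
    x = {"B*38": 0, "C*15": 0, "C*03": 0, "DRB1*15": 1, "CT60*G/G": 1}
    pi = prognostic_index(m, x)
    assert pi == pytest.approx(math.log(1.948) + math.log(1.484), abs=1e-12)
    assert pi == pytest.approx(1.062, abs=5e-4)


def test_pi_additive_over_disjoint_sets():
    m = _model(["a", "b", "c"], [2.0, 0.5, 1.5])
    x_ab = {"a": 1.0, "b": 1.0, "c": 0.0}
    x_c = {"a": 0.0, "b": 0.0, "c": 1.0}
    x_all = {"a": 1.0, "b": 1.0, "c": 1.0}
    assert prognostic_index(m, x_all) == pytest.approx(
        prognostic_index(m, x_ab) + prognostic_index(m, x_c))


def test_pi_missing_variable_errors():
    m = _model(["a", "b"], [2.0, 0.5])
    with pytest.raises(ValueError, match="b"):
        prognostic_index(m, {"a": 1.0})
    with pytest.raises(ValueError, match="missing"):
        prognostic_index(m, pd.DataFrame({"a": [1.0], "b": [np.nan]}))


def test_pi_tracks_true_linear_predictor():
    """Kendall correlation between fitted PI and the generating linear
    predictor is positive in planted cohorts."""
    positive = 0
    for s in range(10):
        coded = bernoulli_coded(250, 8, seed=400 + s)
        effects = [("M00", 2.2), ("M01", 0.4)]
        surv, _ = survival_for(coded, seed=400 + s, effects=effects)
        model = backward_eliminate(coded, surv)
        if model.empty:
            continue
        pi = prognostic_index(model, coded.data)
        true_lp = (math.log(2.2) * coded.data["M00"]
                   + math.log(0.4) * coded.data["M01"])
        tau = stats.kendalltau(pi, true_lp).statistic
        positive += tau > 0
    assert positive >= 9
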