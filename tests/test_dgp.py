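"""Structural-simulator tests: determinism, counterfactual consistency,
scenario contracts and exhaustive-sum truth oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

from ehrcausal.dgp import (
    SCENARIO_NAMES,
    CovariateSpec,
    ConfigurationError,
    DGPConfig,
    LinearCoefs,
    MonitoringCoefs,
    OutcomeCoefs,
    config_from_yaml,
    config_to_yaml,
    read_cohort_csv,
    scenario_preset,
    simulate_cohort,
    true_estimands,
    write_cohort_csv,
)


def simple_config(**overrides) -> DGPConfig:
    base = dict(
        covariates=(CovariateSpec("binary", p=0.5), CovariateSpec("binary", p=0.3)),
        treatment_coefs=LinearCoefs(intercept=-0.2, main=(0.6, -0.4)),
        monitoring_coefs=MonitoringCoefs(intercept=0.3, main=(0.8, 0.2), treatment=0.5),
        outcome_coefs=OutcomeCoefs(
            intercept=-1.0, treatment=0.5, main=(0.7, 0.3), interaction=(-0.8, 0.0)
        ),
        seed=42,
    )
    base.update(overrides)
    return DGPConfig(**base)


# ---------------------------------------------------------------------------
# Independent exhaustive-sum oracle (hand-rolled, bypasses the package's own
# truth calculator): enumerates the binary covariate support and recomputes
# all structural probabilities from the raw coefficient fields.
# ---------------------------------------------------------------------------

def oracle_truth(config: DGPConfig) -> dict:
    assert config.all_binary and config.mediator is None
    p = config.n_covariates
    psi = {0: 0.0, 1: 0.0}
    num_restrict = {0: 0.0, 1: 0.0}
    mass_restrict = 0.0
    p_delta_marginal = 0.0
    for cell in itertools.product((0, 1), repeat=p):
        w = np.asarray(cell, dtype=float)
        fw = np.prod([c.p if v else 1 - c.p for c, v in zip(config.covariates, cell)])
        pA = expit(config.treatment_coefs.intercept + w @ np.asarray(config.treatment_coefs.main))
        q = {}
        for a in (0, 1):
            oc = config.outcome_coefs
            inter = np.asarray(oc.interaction) if oc.interaction else np.zeros(p)
            sq = np.asarray(oc.squared) if oc.squared else np.zeros(p)
            q[a] = expit(oc.intercept + oc.treatment * a + w @ np.asarray(oc.main)
                         + a * (w @ inter) + (w ** 2) @ sq)
            psi[a] += fw * q[a]
        pD = {a: expit(config.monitoring_coefs.intercept
                       + w @ np.asarray(config.monitoring_coefs.main)
                       + config.monitoring_coefs.treatment * a)
              for a in (0, 1)}
        pD_w = pA * pD[1] + (1 - pA) * pD[0]
        p_delta_marginal += fw * pD_w
        mass_restrict += fw * pD_w
        for a in (0, 1):
            num_restrict[a] += fw * pD_w * q[a]
    return {
        "psi1": psi[1],
        "psi0": psi[0],
        "rr": psi[1] / psi[0],
        "restrict": (num_restrict[1] / mass_restrict) / (num_restrict[0] / mass_restrict),
        "p_delta": p_delta_marginal,
    }


# ---------------------------------------------------------------------------


def test_simulation_is_deterministic_and_csv_round_trips(tmp_path):
    config = simple_config()
    a = simulate_cohort(config, 500, seed=7)
    b = simulate_cohort(config, 500, seed=7)
    pd.testing.assert_frame_equal(a.full_frame(), b.full_frame())

    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort_csv(a, p1, with_truth=True)
    write_cohort_csv(b, p2, with_truth=True)
    assert p1.read_bytes() == p2.read_bytes()

    write_cohort_csv(a, tmp_path / "obs.csv")
    header = (tmp_path / "obs.csv").read_text().splitlines()[0]
    assert header == "W1,W2,A,Delta,Y"
    loaded = read_cohort_csv(tmp_path / "obs.csv")
    pd.testing.assert_frame_equal(loaded.observed_frame(), a.observed_frame())


def test_outcome_missing_exactly_when_unmonitored():
    cohort = simulate_cohort(simple_config(), 2000, seed=3)
    df = cohort.observed_frame()
    assert (df.loc[df["Delta"] == 0, "Y"].isna()).all()
    assert (df.loc[df["Delta"] == 1, "Y"].notna()).all()


def test_counterfactual_consistency_record_by_record():
    cohort = simulate_cohort(simple_config(), 5000, seed=11)
    full = cohort.full_frame()
    mon = full[full["Delta"] == 1]
    factual = np.where(mon["A"] == 1, mon["Y1"], mon["Y0"])
    assert (mon["Y"].to_numpy(dtype=float) == factual).all()


def test_degenerate_monitoring_yields_full_observation():
    config = simple_config(
        monitoring_coefs=MonitoringCoefs(intercept=50.0, main=(0.0, 0.0), treatment=0.0)
    )
    df = simulate_cohort(config, 1000, seed=5).observed_frame()
    assert (df["Delta"] == 1).all()
    assert df["Y"].notna().all()


def test_null_scenario_counterfactual_ratio_near_one():
    """With a zero treatment coefficient the hidden counterfactual columns
    have the same law; their empirical ratio must sit at the null."""
    config = scenario_preset("figure3_null")
    full = simulate_cohort(config, 50_000, seed=123).full_frame()
    ratio = full["Y1"].mean() / full["Y0"].mean()
    assert ratio == pytest.approx(1.0, abs=0.03)


def test_monitoring_rate_matches_quadrature_oracle():
    config = scenario_preset("figure1")
    df = simulate_cohort(config, 100_000, seed=99).observed_frame()
    assert df["Delta"].mean() == pytest.approx(oracle_truth(config)["p_delta"], abs=0.01)


def test_truth_calculator_matches_exhaustive_oracle():
    config = scenario_preset("figure1")
    truth = true_estimands(config)
    oracle = oracle_truth(config)
    assert truth.psi1 == pytest.approx(oracle["psi1"], abs=1e-12)
    assert truth.psi0 == pytest.approx(oracle["psi0"], abs=1e-12)
    assert truth.restrict_target == pytest.approx(oracle["restrict"], abs=1e-12)


def test_differential_monitoring_separates_restrict_from_truth():
    """The differential-monitoring preset must make the complete-case target
    visibly different from the marginal risk ratio."""
    oracle = oracle_truth(scenario_preset("figure1"))
    assert abs(np.log(oracle["restrict"]) - np.log(oracle["rr"])) > 0.05


def test_null_preset_has_unit_risk_ratio():
    truth = true_estimands(scenario_preset("figure3_null"))
    assert truth.risk_ratio == pytest.approx(1.0, abs=1e-3)
    assert truth.restrict_target == pytest.approx(1.0, abs=1e-3)


def test_random_monitoring_collapses_restrict_to_truth():
    truth = true_estimands(scenario_preset("random_monitoring"))
    assert truth.restrict_target == pytest.approx(truth.risk_ratio, abs=1e-12)


def test_fully_null_model_is_exactly_null():
    config = simple_config(
        outcome_coefs=OutcomeCoefs(
            intercept=-1.0, treatment=0.0, main=(0.7, 0.3), interaction=(0.0, 0.0)
        ),
        monitoring_coefs=MonitoringCoefs(intercept=0.5, main=(0.0, 0.0), treatment=0.0),
    )
    truth = true_estimands(config)
    assert truth.risk_ratio == pytest.approx(1.0, abs=1e-14)
    assert truth.restrict_target == pytest.approx(1.0, abs=1e-14)


@given(
    coefs=st.lists(st.floats(-1.5, 1.5), min_size=7, max_size=7),
    probs=st.lists(st.floats(0.1, 0.9), min_size=2, max_size=2),
)
def test_independent_monitoring_never_shifts_the_restrict_target(coefs, probs):
    """Whenever monitoring depends on nothing (intercept only), the covariate
    law given monitoring equals the marginal law, so both standardizations
    agree exactly."""
    config = DGPConfig(
        covariates=tuple(CovariateSpec("binary", p=p) for p in probs),
        treatment_coefs=LinearCoefs(intercept=coefs[0], main=(coefs[1], coefs[2])),
        monitoring_coefs=MonitoringCoefs(intercept=0.4, main=(0.0, 0.0), treatment=0.0),
        outcome_coefs=OutcomeCoefs(
            intercept=coefs[3], treatment=coefs[4], main=(coefs[5], coefs[6])
        ),
    )
    truth = true_estimands(config)
    assert truth.restrict_target == pytest.approx(truth.risk_ratio, rel=1e-10)


@given(
    coefs=st.lists(st.floats(-1.5, 1.5), min_size=6, max_size=6),
)
def test_zero_treatment_effect_collapses_to_unit_ratio(coefs):
    config = DGPConfig(
        covariates=(CovariateSpec("binary", p=0.4), CovariateSpec("binary", p=0.6)),
        treatment_coefs=LinearCoefs(intercept=coefs[0], main=(coefs[1], coefs[2])),
        monitoring_coefs=MonitoringCoefs(
            intercept=0.2, main=(coefs[3], 0.0), treatment=0.3
        ),
        outcome_coefs=OutcomeCoefs(
            intercept=-0.5, treatment=0.0, main=(coefs[4], coefs[5])
        ),
    )
    assert true_estimands(config).risk_ratio == pytest.approx(1.0, abs=1e-14)


def test_mediator_scenario_generates_mediator_column():
    config = scenario_preset("mediator_conditioning")
    full = simulate_cohort(config, 2000, seed=1).full_frame()
    assert "M" in full.columns
    assert set(np.unique(full["M"])) <= {0, 1}
    # treatment raises mediator prevalence by construction
    assert full.loc[full["A"] == 1, "M"].mean() > full.loc[full["A"] == 0, "M"].mean()


def test_mediator_truth_integrates_mediator():
    """Exhaustive truth with a mediator equals a direct two-layer sum."""
    config = scenario_preset("mediator_conditioning")
    truth = true_estimands(config)
    psi = {0: 0.0, 1: 0.0}
    for cell in itertools.product((0, 1), repeat=2):
        w = np.asarray(cell, dtype=float)
        fw = np.prod([c.p if v else 1 - c.p for c, v in zip(config.covariates, cell)])
        for a in (0, 1):
            med = config.mediator
            pm = expit(med.intercept + med.treatment * a + w @ np.asarray(med.main))
            oc = config.outcome_coefs
            base = oc.intercept + oc.treatment * a + w @ np.asarray(oc.main)
            ey = pm * expit(base + med.outcome_coef) + (1 - pm) * expit(base)
            psi[a] += fw * ey
    assert truth.risk_ratio == pytest.approx(psi[1] / psi[0], abs=1e-12)


@pytest.mark.parametrize("name", SCENARIO_NAMES)
def test_presets_are_valid_and_truths_well_formed(name):
    truth = true_estimands(scenario_preset(name))
    assert 0.0 < truth.psi1 < 1.0
    assert 0.0 < truth.psi0 < 1.0
    assert truth.risk_ratio > 0.0


def test_unknown_scenario_lists_options():
    with pytest.raises(ValueError, match="figure1"):
        scenario_preset("nope")


def test_mismatched_coefficients_name_the_block():
    with pytest.raises(ConfigurationError, match="treatment_coefs"):
        simple_config(treatment_coefs=LinearCoefs(intercept=0.0, main=(0.1,)))
    with pytest.raises(ConfigurationError, match="outcome_coefs.interaction"):
        simple_config(
            outcome_coefs=OutcomeCoefs(
                intercept=0.0, treatment=0.0, main=(0.1, 0.2), interaction=(0.5,)
            )
        )


def test_yaml_config_round_trip():
    for name in ("figure1", "mediator_conditioning"):
        config = scenario_preset(name)
        assert config_from_yaml(config_to_yaml(config)) == config
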