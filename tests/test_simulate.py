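"""Synthetic two-trial generator: calibration, rules, outcome embedding."""
import numpy as np
import pytest

from hteforest.covariates import derive_covariates
from hteforest.errors import ConfigurationError
from hteforest.simulate import (
    EffectRule,
    GeneratorConfig,
    build_dictionary,
    default_config,
    embed_outcomes,
    generate_cohort,
    null_config,
    recovery_config,
    reference_line,
    true_cate,
    validate_rules,
)


def test_default_cell_sizes_match_published_counts(table1_config):
    sizes = {k: spec.n for k, spec in table1_config.cells.items()}
    assert sizes == {("ACCORD", 0): 5123, ("ACCORD", 1): 5128,
                     ("VADT", 0): 899, ("VADT", 1): 892}
    assert sum(sizes.values()) == 12042


def test_generation_deterministic(table1_config):
    small = table1_config.scaled(1 / 20)
    a = generate_cohort(small, seed=4)
    b = generate_cohort(small, seed=4)
    assert a.df.equals(b.df)
    c = generate_cohort(small, seed=5)
    assert not a.df["age"].equals(c.df["age"])


def test_rules_are_mutually_exclusive(table1_config):
    validate_rules(table1_config)
    validate_rules(recovery_config())
    overlapping = (
        EffectRule((("age", "ge", 60.0),), 0.1),
        EffectRule((("age", "ge", 70.0),), -0.1),
    )
    broken = GeneratorConfig(cells=table1_config.cells,
                             effect_rules=overlapping)
    with pytest.raises(ConfigurationError, match="overlap"):
        validate_rules(broken)


def test_truncation_bounds_hold_and_barely_shift_means(small_default_cohort,
                                                       table1_config):
    df = small_default_cohort.df
    for var, (lo, hi) in table1_config.truncation.items():
        assert df[var].min() >= lo
        assert df[var].max() <= hi
    # for age / bmi / creatinine the bounds are several SDs out, so the
    # realized means stay within 0.5% of the configured cell means
    std_acc = df[(df.study == "ACCORD") & (df.arm == 0)]
    for var in ("age", "bmi", "creatinine"):
        target = table1_config.cells[("ACCORD", 0)].continuous[var][0]
        assert abs(std_acc[var].mean() - target) / target < 0.02


def test_true_cate_matches_rule_and_default(table1_config):
    record = {"hba1c": 12.0, "glucose": 150.0, "age": 70.0, "bmi": 33.0,
              "creatinine": 0.9, "female": 0.0, "black": 0.0}
    # HGI of this record is far above 0.84 -> first rule
    assert true_cate(table1_config, record) == pytest.approx(0.031)
    no_rules = GeneratorConfig(cells=table1_config.cells, default_tau=0.0)
    assert true_cate(no_rules, record) == 0.0


def test_true_cate_average_is_share_weighted_mixture(table1_config):
    cohort, truth = generate_cohort(table1_config.scaled(0.5), seed=8,
                                    return_truth=True)
    taus = np.array([0.0] + [r.tau for r in table1_config.effect_rules])
    shares = np.bincount(truth["cell"], minlength=len(taus)) / len(truth)
    assert truth["tau"].mean() == pytest.approx(float(shares @ taus),
                                                abs=1e-12)


def test_null_config_equalizes_arms():
    cohort = generate_cohort(null_config().scaled(1 / 3), seed=9)
    df = cohort.df
    r1 = df.loc[df.arm == 1, "mace"].mean()
    r0 = df.loc[df.arm == 0, "mace"].mean()
    n = len(df) // 2
    mc_se = np.sqrt(2 * 0.1 * 0.9 / n)
    assert abs(r1 - r0) < 4 * mc_se


def test_event_probability_construction():
    """With no dropout, P(event) equals the planted probability."""
    base = default_config()
    cfg = GeneratorConfig(cells=base.cells, base_risk=base.base_risk,
                          truncation=base.truncation,
                          followup_years=base.followup_years)
    cohort, truth = generate_cohort(cfg.scaled(0.5), seed=10,
                                    return_truth=True)
    rate = cohort.df["mace"].mean()
    p_bar = truth["p"].mean()
    mc_se = np.sqrt(p_bar * (1 - p_bar) / len(truth))
    assert abs(rate - p_bar) < 3 * mc_se


def test_planted_rd_realized(table1_config):
    """The -5.1% cell's realized arm contrast matches the plant."""
    diffs = []
    for seed in range(12):
        cohort, truth = generate_cohort(table1_config, seed=100 + seed,
                                        return_truth=True)
        m = truth["cell"].to_numpy() == 5  # the tau = -0.051 rule
        arm = cohort.arm.astype(int)
        y = cohort.df["mace"].to_numpy()
        diffs.append(y[m & (arm == 1)].mean() - y[m & (arm == 0)].mean())
    n_cell = int(m.sum() / 2)
    mc_se = np.sqrt(2 * 0.12 * 0.88 / n_cell) / np.sqrt(len(diffs))
    assert table1_config.effect_rules[4].tau == pytest.approx(-0.051)
    assert abs(np.mean(diffs) - (-0.051)) < 3 * mc_se


def test_embed_outcomes_redraws_outcomes_only(small_default_cohort,
                                              table1_config):
    redrawn = embed_outcomes(small_default_cohort, table1_config.scaled(1 / 6),
                             seed=123)
    assert redrawn.df["age"].equals(small_default_cohort.df["age"])
    assert not redrawn.df["mace"].equals(small_default_cohort.df["mace"])


def test_dropout_censors_before_followup(table1_config):
    cfg = table1_config.scaled(1 / 10)
    lossy = GeneratorConfig(
        cells=cfg.cells, base_risk=cfg.base_risk, truncation=cfg.truncation,
        followup_years=cfg.followup_years, dropout_rate=0.15,
        effect_rules=cfg.effect_rules)
    cohort = generate_cohort(lossy, seed=11)
    df = cohort.df
    early = df[(df.censored == 1) & (df.study == "ACCORD")]
    assert (early["event_time"] < 3.7 - 1e-9).any()
    clean = generate_cohort(cfg, seed=11).df
    cens = clean[(clean.censored == 1) & (clean.study == "ACCORD")]
    assert np.allclose(cens["event_time"], 3.7)


def test_yaml_round_trip_of_config(tmp_path, table1_config):
    # the shipped file parses into the same structure it serializes from
    cfg = table1_config
    assert cfg.rho_glucose_hba1c == 0.52
    assert cfg.followup_years == {"ACCORD": 3.7, "VADT": 5.6}
    d = build_dictionary(cfg)
    assert d.treatment == "arm"
    assert "insulin_use" in d.covariates
    assert len(d.covariates) == 30


def test_reference_line_matches_calibration_algebra(table1_config):
    beta0, beta1 = reference_line(table1_config)
    # beta1 = rho * pooled sd ratio; VADT mean HGI = dH - beta1 * dG ~ 0.8
    assert beta1 == pytest.approx(0.0102, abs=5e-4)
    d_h = 9.4 - (5123 * 8.3 + 5128 * 8.3) / 10251
    d_g = 205.9 - (5123 * 175.7 + 5128 * 174.7) / 10251
    assert d_h - beta1 * d_g == pytest.approx(0.79, abs=0.02)


def test_hgi_contrast_emerges_through_pipeline(table1_config):
    cohort = generate_cohort(table1_config.scaled(1 / 4), seed=12)
    derived, model = derive_covariates(cohort)
    df = derived.df
    acc = df.loc[df.study == "ACCORD", "hgi"]
    vadt = df.loc[df.study == "VADT", "hgi"]
    assert abs(acc.mean()) < 1e-10          # reference residuals center at 0
    assert vadt.mean() == pytest.approx(0.8, abs=0.2)
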