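import numpy as np
import pandas as pd
import pytest

from schedquit.compliance_metrics import COAssessment, assess_compliance
from schedquit.synthetic_trial import (
    ARMS,
    VISITS,
    TrialConfig,
    apply_missingness,
    generate_trial,
    implied_noncomplier_prob,
    read_trial_csv,
    simulate_co,
    simulate_compliance_and_outcome,
    stratified_allocate,
    true_complier_effect,
    untreated_complier_prob,
    write_trial_csv,
)


class TestConfig:
    def test_defaults_valid(self):
        cfg = TrialConfig()
        assert cfg.n_per_arm == {"SSNP": 273, "SS": 268, "EUC": 279}
        assert cfg.compliance_prob["SSNP"] == pytest.approx(0.509)
        assert cfg.compliance_prob["SS"] == pytest.approx(0.265)
        assert cfg.response_rate["EUC"]["2wk"] == pytest.approx(239 / 279)

    def test_generating_effect_matches_config(self):
        cfg = TrialConfig()
        for arm in ("SSNP", "SS"):
            for visit in VISITS:
                assert true_complier_effect(cfg, arm, visit) == pytest.approx(
                    cfg.complier_effect[arm][visit], abs=1e-9
                )

    def test_euc_compliance_must_be_zero(self):
        with pytest.raises(ValueError):
            TrialConfig(compliance_prob={"SSNP": 0.5, "SS": 0.3, "EUC": 0.1})

    def test_rho_bounds(self):
        with pytest.raises(ValueError):
            TrialConfig(confound_rho=0.9)  # exceeds sqrt(1 - 0.5)

    def test_from_dict_merges(self):
        cfg = TrialConfig.from_dict(
            {"confound_rho": 0.0, "compliance_prob": {"SSNP": 0.6}}
        )
        assert cfg.confound_rho == 0.0
        assert cfg.compliance_prob["SSNP"] == 0.6
        assert cfg.compliance_prob["SS"] == pytest.approx(0.265)  # untouched default

    def test_selection_math_is_coherent(self):
        # Mixture of class-conditional untreated probabilities recovers
        # the control marginal.
        pi, p0, rho = 0.509, 0.25, 0.3
        pc = untreated_complier_prob(pi, p0, rho)
        pnc = implied_noncomplier_prob(pi, p0, rho)
        assert pi * pc + (1 - pi) * pnc == pytest.approx(p0, abs=1e-12)
        assert pc > p0 > pnc  # positive rho: compliers are better-off anyway


class TestStratifiedAllocate:
    def test_single_stratum_exact_balance(self):
        arms = stratified_allocate(["s"] * 6, {"SSNP": 2, "SS": 2, "EUC": 2}, rng=0)
        assert sorted(arms) == ["EUC", "EUC", "SS", "SS", "SSNP", "SSNP"]

    def test_unequal_marginals_achievable(self):
        rng = np.random.default_rng(3)
        strata = rng.choice([f"s{j}" for j in range(16)], size=916)
        arms = stratified_allocate(strata, {"SSNP": 306, "SS": 309, "EUC": 301}, rng=rng)
        counts = pd.Series(arms).value_counts().to_dict()
        assert counts == {"SSNP": 306, "SS": 309, "EUC": 301}

    def test_within_stratum_balance(self):
        rng = np.random.default_rng(4)
        strata = rng.choice(["a", "b", "c"], size=300)
        arms = stratified_allocate(strata, {"SSNP": 100, "SS": 100, "EUC": 100}, rng=rng)
        df = pd.DataFrame({"stratum": strata, "arm": arms})
        for _, grp in df.groupby("stratum"):
            counts = grp["arm"].value_counts().reindex(ARMS, fill_value=0)
            assert counts.max() - counts.min() <= 1

    def test_determinism(self):
        strata = ["a"] * 50 + ["b"] * 49
        t = {"SSNP": 33, "SS": 33, "EUC": 33}
        a1 = stratified_allocate(strata, t, rng=np.random.default_rng(9))
        a2 = stratified_allocate(strata, t, rng=np.random.default_rng(9))
        assert (a1 == a2).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stratified_allocate([], {"SSNP": 0, "SS": 0, "EUC": 0})

    def test_mismatched_total_rejected(self):
        with pytest.raises(ValueError):
            stratified_allocate(["s"] * 5, {"SSNP": 2, "SS": 2, "EUC": 2})


class TestComplianceAndOutcome:
    def test_boundary_all_compliers(self):
        cfg = TrialConfig(compliance_prob={"SSNP": 1.0, "SS": 0.265, "EUC": 0.0})
        rng = np.random.default_rng(0)
        complier, _ = simulate_compliance_and_outcome(cfg, "SSNP", 500, rng)
        assert complier.all()

    def test_independence_limit(self):
        # With rho = 0, compliance and outcomes are uncorrelated in the
        # untreated state: noncomplier rate matches the control marginal.
        cfg = TrialConfig(confound_rho=0.0)
        rng = np.random.default_rng(1)
        complier, y = simulate_compliance_and_outcome(cfg, "SS", 20000, rng)
        noncomp_rate = y[~complier, 0].mean()
        assert noncomp_rate == pytest.approx(cfg.control_abstinence_prob["2wk"], abs=0.02)

    def test_compliance_calibration(self):
        cfg = TrialConfig()
        rng = np.random.default_rng(2)
        fracs = []
        for _ in range(200):
            complier, _ = simulate_compliance_and_outcome(cfg, "SSNP", 273, rng)
            fracs.append(complier.mean())
        assert np.mean(fracs) == pytest.approx(0.509, abs=0.01)

    def test_class_conditional_abstinence_calibration(self):
        cfg = TrialConfig()
        rng = np.random.default_rng(3)
        complier, y = simulate_compliance_and_outcome(cfg, "SSNP", 60000, rng)
        target = cfg.resolved_complier_prob("SSNP", "2wk")
        assert y[complier, 0].mean() == pytest.approx(target, abs=0.01)
        implied = implied_noncomplier_prob(
            cfg.compliance_prob["SSNP"], cfg.control_abstinence_prob["2wk"], cfg.confound_rho
        )
        assert y[~complier, 0].mean() == pytest.approx(implied, abs=0.01)

    def test_confounding_direction(self):
        # Positive rho: naive complier-vs-control contrast overstates the
        # true complier causal effect.
        cfg = TrialConfig(confound_rho=0.5)
        rng = np.random.default_rng(4)
        complier, y = simulate_compliance_and_outcome(cfg, "SSNP", 60000, rng)
        _, y_c = simulate_compliance_and_outcome(cfg, "EUC", 60000, rng)
        naive = y[complier, 0].mean() - y_c[:, 0].mean()
        assert naive > true_complier_effect(cfg, "SSNP", "2wk") + 0.02

    def test_exclusion_restriction_null_effect(self):
        # Zero complier effect: assignment has no pathway to outcomes.
        null = {a: {v: 0.0 for v in VISITS} for a in ("SSNP", "SS")}
        cfg = TrialConfig(complier_effect=null)
        rng = np.random.default_rng(5)
        _, y_t = simulate_compliance_and_outcome(cfg, "SSNP", 60000, rng)
        _, y_c = simulate_compliance_and_outcome(cfg, "EUC", 60000, rng)
        assert y_t[:, 0].mean() == pytest.approx(y_c[:, 0].mean(), abs=0.012)

    def test_arm_exchangeability_given_class(self):
        # Identical compliance and effect parameters across scheduled
        # arms: class-conditional outcome rates are exchangeable.
        cfg = TrialConfig(
            compliance_prob={"SSNP": 0.4, "SS": 0.4, "EUC": 0.0},
            complier_effect={
                "SSNP": {v: 0.2 for v in VISITS},
                "SS": {v: 0.2 for v in VISITS},
            },
        )
        rng = np.random.default_rng(6)
        c1, y1 = simulate_compliance_and_outcome(cfg, "SSNP", 60000, rng)
        c2, y2 = simulate_compliance_and_outcome(cfg, "SS", 60000, rng)
        assert y1[c1, 0].mean() == pytest.approx(y2[c2, 0].mean(), abs=0.015)
        assert y1[~c1, 0].mean() == pytest.approx(y2[~c2, 0].mean(), abs=0.015)


class TestSimulateCO:
    def test_classification_forced(self):
        rng = np.random.default_rng(0)
        complier = np.array([True] * 50 + [False] * 50)
        co_b, co_f = simulate_co(np.full(100, 23.0), complier, rng)
        assert (co_b > 0).all() and (co_f > 0).all()
        for b, f, c in zip(co_b, co_f, complier):
            assert assess_compliance(COAssessment(b, f)).compliant == c

    def test_determinism(self):
        complier = np.array([True, False, True])
        a = simulate_co(np.full(3, 20.0), complier, np.random.default_rng(7))
        b = simulate_co(np.full(3, 20.0), complier, np.random.default_rng(7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_positive_cpd_required(self):
        with pytest.raises(ValueError):
            simulate_co(np.array([0.0]), np.array([True]), np.random.default_rng(0))


class TestApplyMissingness:
    def test_full_response(self):
        rng = np.random.default_rng(0)
        y = np.ones((50, 4), dtype=int)
        out = apply_missingness(y, {v: 1.0 for v in VISITS}, rng)
        assert not np.isnan(out).any()

    def test_zero_response(self):
        rng = np.random.default_rng(0)
        out = apply_missingness(np.ones((50, 4)), {v: 0.0 for v in VISITS}, rng)
        assert np.isnan(out).all()

    def test_euc_2wk_rate(self):
        # Mean observed fraction over 500 replicates ~ 239/279.
        rng = np.random.default_rng(1)
        rate = 239 / 279
        fracs = []
        for _ in range(500):
            out = apply_missingness(np.ones((279, 4)), {v: rate for v in VISITS}, rng)
            fracs.append(1 - np.isnan(out[:, 0]).mean())
        assert np.mean(fracs) == pytest.approx(rate, abs=0.005)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            apply_missingness(np.ones((5, 4)), [1.1, 0.5, 0.5, 0.5], np.random.default_rng(0))


class TestGenerateTrial:
    def test_arm_sizes(self, default_trial):
        counts = default_trial["arm"].value_counts().to_dict()
        assert counts == {"SSNP": 273, "SS": 268, "EUC": 279}

    def test_reproducibility_bit_exact(self):
        a = generate_trial(TrialConfig(), seed=11).participants
        b = generate_trial(TrialConfig(), seed=11).participants
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_different_seeds_differ(self):
        a = generate_trial(TrialConfig(), seed=11).participants
        b = generate_trial(TrialConfig(), seed=12).participants
        assert not a.equals(b)

    def test_euc_has_no_compliance_label(self, default_trial):
        assert default_trial.loc[default_trial["arm"] == "EUC", "complier"].isna().all()
        sched = default_trial["arm"].isin(("SSNP", "SS"))
        assert default_trial.loc[sched, "complier"].notna().all()

    def test_co_consistent_with_complier_flag(self, default_trial):
        sched = default_trial[default_trial["arm"].isin(("SSNP", "SS"))]
        for row in sched.itertuples():
            expected = bool(row.complier)
            got = assess_compliance(COAssessment(row.co_baseline, row.co_final)).compliant
            assert got == expected

    def test_csv_roundtrip(self, tmp_path, default_trial):
        from schedquit.synthetic_trial import TrialDataset

        ds = TrialDataset(participants=default_trial, config=TrialConfig(), seed=1)
        path = tmp_path / "trial.csv"
        write_trial_csv(ds, path)
        assert (tmp_path / "trial.csv.config.json").exists()
        back = read_trial_csv(path)
        assert list(back.columns) == list(default_trial.columns)
        assert len(back) == len(default_trial)
        pd.testing.assert_series_equal(back["y_2wk"], default_trial["y_2wk"].reset_index(drop=True), check_names=True)

    def test_response_rates_close_to_config(self, default_trial):
        cfg = TrialConfig()
        for arm in ARMS:
            sub = default_trial[default_trial["arm"] == arm]
            observed = sub["y_2wk"].notna().mean()
            assert observed == pytest.approx(cfg.response_rate[arm]["2wk"], abs=0.08)
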