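import numpy as np
import pandas as pd
import pytest

from tempodisc import (
    CohortConfig,
    ParticipantTruth,
    build_choice_design,
    generate_cohort,
    simulate_choices,
)
from tempodisc.cohort import ConfigError


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_participants", 1),
            ("female_fraction", 1.5),
            ("income_missing_rate", -0.1),
            ("beta_mean", 2.0),
            ("lnk_sd", -1.0),
            ("memory_latent_corr", 2.0),
        ],
    )
    def test_invalid_values_name_the_field(self, field, value):
        config = CohortConfig(**{field: value})
        with pytest.raises(ConfigError, match=field):
            config.validate()

    def test_gap_must_be_scalar_or_triple(self):
        with pytest.raises(ConfigError, match="memory_gender_gap"):
            CohortConfig(memory_gender_gap=(0.1, 0.2)).validate()


class TestGenerateCohort:
    def test_null_configuration_equalizes_genders(self):
        """With zero gap and zero interaction, score means match across gender."""
        config = CohortConfig(
            n_participants=2000,
            memory_gender_gap=0.0,
            effect_gender_memory_on_lnk=0.0,
            seed=11,
        )
        cohort = generate_cohort(config)
        for score, sd in [("fnpa_pf", 0.2), ("igd_c1", 0.25), ("igd_c2", 0.2)]:
            means = cohort.groupby("gender")[score].mean()
            se = sd * np.sqrt(2 / 1000)
            assert abs(means["female"] - means["male"]) < 3 * se

    def test_gendered_means_match_configuration(self):
        """Defaults reproduce the configured group means (women above men)."""
        config = CohortConfig(n_participants=3000, seed=5)
        cohort = generate_cohort(config)
        means = cohort.groupby("gender")["fnpa_pf"].mean()
        se = config.fnpa_pf_sd / np.sqrt(1500)
        assert abs(means["male"] - 0.33) < 2 * se + 0.025  # rounding to counts
        assert abs(means["female"] - 0.57) < 2 * se + 0.025

    def test_income_missingness_binomial(self):
        config = CohortConfig(n_participants=60, income_missing_rate=0.1, seed=0)
        counts = [
            generate_cohort(
                CohortConfig(n_participants=60, income_missing_rate=0.1, seed=s)
            )["income"].isna().sum()
            for s in range(30)
        ]
        # mean ~6, binomial(60, .1) sd ~2.3
        assert abs(np.mean(counts) - 6.0) < 3 * 2.33 / np.sqrt(30)

    @pytest.mark.parametrize("seed", range(5))
    def test_score_and_parameter_ranges(self, seed):
        cohort = generate_cohort(CohortConfig(n_participants=50, seed=seed))
        assert cohort["fnpa_pf"].between(-1, 1).all()
        assert cohort["igd_c1"].between(0, 2).all()
        assert cohort["igd_c2"].between(0, 2).all()
        assert cohort["true_beta"].between(0, 1).all()
        assert cohort["true_delta"].between(0, 1).all()
        assert (cohort["true_k"] >= 0).all()
        assert cohort["age"].between(60, 89).all()
        assert cohort["fnpa_hits"].between(0, 20).all()
        assert cohort["fnpa_fa"].between(0, 20).all()
        assert (cohort["c2_yes"] <= cohort["c2_answered"]).all()

    def test_interaction_injection_shifts_lnk(self):
        """The configured gender x IGD-C2 slope appears in female ln k."""
        base = CohortConfig(n_participants=4000, seed=3, lnk_sd=0.1,
                            effect_gender_memory_on_lnk=2.0)
        cohort = generate_cohort(base)
        women = cohort[cohort["gender"] == "female"]
        slope = np.polyfit(women["igd_c2"], women["true_ln_k"], 1)[0]
        assert slope == pytest.approx(2.0, abs=0.3)
        men = cohort[cohort["gender"] == "male"]
        slope_m = np.polyfit(men["igd_c2"], men["true_ln_k"], 1)[0]
        assert abs(slope_m) < 0.3

    def test_determinism(self):
        a = generate_cohort(CohortConfig(seed=9))
        b = generate_cohort(CohortConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestSimulateChoices:
    def make_truth(self, beta=1.0, delta=1.0, temp=np.inf):
        return ParticipantTruth(
            k_true=0.0, beta_true=beta, delta_true=delta,
            choice_temperature=temp, gender="female",
        )

    def test_no_discounting_deterministic(self, design):
        """beta=delta=1, temp=inf: later whenever it pays more; 20-20 tie 50/50."""
        truth = self.make_truth()
        trials = simulate_choices(truth, design, seed=0)
        strictly_less = trials["sooner_amount"] < 20.0
        assert (trials.loc[strictly_less, "choice"] == "later").all()
        ties = pd.concat(
            simulate_choices(truth, design, seed=s) for s in range(40)
        )
        tie_trials = ties[ties["sooner_amount"] == 20.0]
        frac_sooner = (tie_trials["choice"] == "sooner").mean()
        assert 0.35 < frac_sooner < 0.65

    def test_closed_form_threshold_block1(self, design):
        """beta=.5, delta=.98, temp=inf: later iff amount < 20*.5*.98^3 in block 1."""
        truth = self.make_truth(beta=0.5, delta=0.98)
        trials = simulate_choices(truth, design, seed=1)
        block1 = trials[trials["block"] == 1]
        threshold = 20 * 0.5 * 0.98**3
        later = block1["choice"] == "later"
        assert (later == (block1["sooner_amount"] < threshold)).all()

    def test_zero_temperature_is_coin_flip(self, design):
        truth = self.make_truth(beta=0.5, delta=0.9, temp=0.0)
        trials = pd.concat(
            simulate_choices(truth, design, seed=s) for s in range(30)
        )
        assert (trials["choice"] == "later").mean() == pytest.approx(0.5, abs=0.03)

    def test_malformed_design_rejected(self, design):
        broken = design.copy()
        broken.loc[0, "sooner_amount"] = np.nan
        with pytest.raises(ValueError, match="malformed"):
            simulate_choices(self.make_truth(), broken, seed=0)

    def test_truth_bounds_validated(self):
        with pytest.raises(ValueError):
            ParticipantTruth(k_true=0.1, beta_true=1.5, delta_true=0.9,
                             choice_temperature=1.0, gender="male")
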