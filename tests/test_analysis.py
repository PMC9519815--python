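import math

import numpy as np
import pandas as pd
import pytest

from cswlkit.analysis import (
    SIGMA2_LOGISTIC,
    AnalysisError,
    PowerSpec,
    accuracy_summary,
    combine_odds,
    exclude_rt_outliers,
    icc_logistic,
    make_datasets,
    power_one_sample_t,
    r2_nakagawa,
)
from cswlkit.simulate import ParticipantConfig, simulate_cohort


def _records(rts, participant="p1"):
    n = len(rts)
    return pd.DataFrame(
        {
            "participant_id": [participant] * n,
            "trial_index": range(n),
            "set_label": ["PP_plus"] * n,
            "repetition": [1] * n,
            "probe_word": ["w"] * n,
            "chosen_object": ["o"] * n,
            "correct": [True] * n,
            "rt_ms": rts,
        }
    )


class TestRtExclusion:
    def test_identical_rts_nothing_excluded(self):
        out, n = exclude_rt_outliers(_records([800.0] * 50))
        assert n == 0 and len(out) == 50

    def test_single_extreme_outlier_removed(self):
        out, n = exclude_rt_outliers(_records([800.0] * 100 + [30000.0]))
        assert n == 1
        assert out["rt_ms"].max() == 800.0

    def test_infinite_k_is_identity(self):
        rec = _records([100.0, 200.0, 9000.0])
        out, n = exclude_rt_outliers(rec, k=math.inf)
        assert n == 0
        pd.testing.assert_frame_equal(out, rec)

    def test_single_row_scope_no_exclusion(self):
        out, n = exclude_rt_outliers(_records([123.0]))
        assert n == 0 and len(out) == 1

    def test_per_participant_scope(self):
        slow = _records([800.0] * 30 + [20000.0], participant="slowp")
        fast = _records([30000.0] * 31, participant="fastp")
        rec = pd.concat([slow, fast], ignore_index=True)
        out, n = exclude_rt_outliers(rec, scope="per_participant")
        # the 20 s trial is an outlier for slowp but 30 s is normal for fastp
        assert n == 1
        assert (out[out["participant_id"] == "fastp"]["rt_ms"] == 30000.0).all()

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(AnalysisError):
            exclude_rt_outliers(_records([0.0, 100.0]))

    def test_conservation(self, study_design):
        rec = simulate_cohort(study_design, 20, ParticipantConfig(), seed=4)
        out, n = exclude_rt_outliers(rec)
        assert len(rec) == len(out) + n


class TestMakeDatasets:
    def test_full_and_halved_row_counts(self, study_design):
        # constant RTs: nothing for the 3-SD rule to remove
        config = ParticipantConfig(contamination_rate=0.0, rt_log_sd=0.0)
        rec = simulate_cohort(study_design, 30, config, seed=8)
        full, halved = make_datasets(rec)
        assert len(full.rows) == 720 and full.n_excluded == 0
        assert len(halved.rows) == 360
        assert (halved.rows["repetition"] == 1).all()

    def test_offset_is_logit_quarter(self, study_design):
        rec = simulate_cohort(study_design, 3, ParticipantConfig(), seed=8)
        full, halved = make_datasets(rec)
        for ds in (full, halved):
            assert ds.offset == pytest.approx(math.log(1 / 3), abs=1e-12)

    def test_participant_missing_second_repetition_does_not_affect_halved(
        self, study_design
    ):
        config = ParticipantConfig(contamination_rate=0.0)
        rec = simulate_cohort(study_design, 4, config, seed=9)
        drop = (rec["participant_id"] == "p001") & (rec["repetition"] == 2)
        _, halved_ref = make_datasets(rec)
        _, halved_cut = make_datasets(rec[~drop])
        pd.testing.assert_frame_equal(
            halved_ref.rows.reset_index(drop=True),
            halved_cut.rows.reset_index(drop=True),
        )

    def test_missing_columns_reported(self):
        with pytest.raises(AnalysisError, match="missing columns"):
            make_datasets(pd.DataFrame({"rt_ms": [1.0]}))


class TestDerivedQuantities:
    def test_combine_odds_published_products(self):
        assert combine_odds(7.61, 1.19) == pytest.approx(9.06, abs=0.005)
        assert combine_odds(6.25, 1.56) == pytest.approx(9.75, abs=0.005)

    def test_combine_odds_identity_and_domain(self):
        assert combine_odds(3.3, 1.0) == pytest.approx(3.3)
        with pytest.raises(AnalysisError):
            combine_odds(-1.0, 2.0)

    def test_icc_published_variance_components(self):
        assert icc_logistic([2.35, 0.21]) == pytest.approx(0.44, abs=0.005)
        assert icc_logistic([1.45, 0.09]) == pytest.approx(0.32, abs=0.005)

    def test_icc_degenerate_and_domain(self):
        assert icc_logistic([0.0, 0.0]) == 0.0
        with pytest.raises(AnalysisError):
            icc_logistic([-0.1])

    def test_latent_residual_variance_value(self):
        assert round(SIGMA2_LOGISTIC, 2) == 3.29

    def test_r2_reduces_to_icc_without_fixed_variance(self):
        taus = [2.35, 0.21]
        r2m, r2c = r2_nakagawa(0.0, taus)
        assert r2m == 0.0
        assert r2c == pytest.approx(icc_logistic(taus))

    def test_r2_closed_form_point(self):
        r2m, r2c = r2_nakagawa(SIGMA2_LOGISTIC, [], SIGMA2_LOGISTIC)
        assert r2m == pytest.approx(0.5) and r2c == pytest.approx(0.5)

    def test_conditional_at_least_marginal(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            vf, t1, t2, s2 = rng.uniform(0, 5, size=4)
            r2m, r2c = r2_nakagawa(vf, [t1, t2], s2 + 1e-6)
            assert r2c >= r2m - 1e-12


class TestAccuracySummary:
    def test_all_correct_gives_degenerate_interval(self, study_design):
        rec = simulate_cohort(
            study_design, 5,
            ParticipantConfig(learner="associative", softmax_temperature=0.0),
            seed=0,
        )
        full, _ = make_datasets(rec)
        summ = accuracy_summary(full, n_boot=200, seed=0)
        assert (summ["mean_accuracy"] == 1.0).all()
        assert (summ["ci_low"] == 1.0).all() and (summ["ci_high"] == 1.0).all()

    def test_guesser_interval_covers_chance(self, study_design):
        rec = simulate_cohort(
            study_design, 60, ParticipantConfig(learner="guesser"), seed=2
        )
        full, _ = make_datasets(rec)
        summ = accuracy_summary(full, n_boot=500, seed=1)
        for _, row in summ.iterrows():
            assert row["ci_low"] <= 0.25 <= row["ci_high"]
            assert row["ci_low"] <= row["mean_accuracy"] <= row["ci_high"]

    def test_deterministic_under_seed(self, study_design):
        rec = simulate_cohort(study_design, 10, ParticipantConfig(), seed=3)
        full, _ = make_datasets(rec)
        a = accuracy_summary(full, n_boot=100, seed=5)
        b = accuracy_summary(full, n_boot=100, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestPower:
    def test_zero_effect_gives_alpha(self):
        assert power_one_sample_t(
            PowerSpec(effect_size_d=0.0, n=30, alpha=0.05)
        ) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_n(self):
        powers = [
            power_one_sample_t(PowerSpec(effect_size_d=0.5, n=n)) for n in range(2, 60, 4)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_invalid_spec(self):
        with pytest.raises(AnalysisError):
            PowerSpec(effect_size_d=1.0, n=1)
        with pytest.raises(AnalysisError):
            PowerSpec(effect_size_d=1.0, n=10, alpha=1.5)
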