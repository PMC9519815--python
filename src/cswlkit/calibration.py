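"""Simulation-based calibration of the pipeline under the study conditions.

The published odds ratios cannot be recomputed without the human response
data, so the pipeline's statistical validity is established by construction
checks instead: an ideal co-occurrence learner must be perfectly separable
under every generated design; the chance-anchored simulation must give
near-nominal Wald coverage of the null intercept; the generative/analysis
model pair must recover its own parameters with small bias; and the RT
filter must catch exactly the planted contamination.  Every function here is
pure computation from a seed, shared by the test suite and the acceptance
script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import fit_glmm_frequentist, make_datasets
from .design import Design, DesignSpec, default_words_objects, generate_design
from .simulate import ParticipantConfig, simulate_cohort, train_associative, choose_at_test


def make_study_design(seed: int = 0, version: str = "A") -> Design:
    """The 12-pair, 36-training / 24-test design over generic ids."""
    words, objects = default_words_objects(6)
    spec = DesignSpec(seed=int(seed) % 2**31, counterbalance_version=version)
    return generate_design(words, objects, spec)


def ideal_learner_accuracy(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """Accuracy of the noiseless associative learner (temperature 0, no
    lapses) across freshly generated designs; separability of the design
    guarantees 1.0 on every seed."""
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_seeds)]
    config = ParticipantConfig(learner="associative", softmax_temperature=0.0, lapse_rate=0.0)
    accs = []
    for s in seeds:
        design = make_study_design(seed=s)
        matrix = train_associative(design.training)
        rng = np.random.default_rng(s)
        referent = design.referent_of
        correct = [
            choose_at_test(matrix, t, config, rng) == referent[t.probe_word]
            for t in design.test
        ]
        accs.append(float(np.mean(correct)))
    return {"min_accuracy": min(accs), "mean_accuracy": float(np.mean(accs)), "n_seeds": n_seeds}


def intercept_coverage(
    n_reps: int = 500,
    n_participants: int = 12,
    base_seed: int = 0,
) -> dict:
    """Type-I calibration at exact chance: simulate beta0 = delta = 0 with no
    random heterogeneity and count how often the intercept's 95% Wald
    interval (odds-ratio scale) covers 1, and how often the PP+ interval
    covers 1 (complement = type-I error of the set effect)."""
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n_reps)
    config = ParticipantConfig(
        learner="glmm_generative", beta0=0.0, delta_pp_plus=0.0,
        tau_participant=0.0, tau_stimulus=0.0,
    )
    cover_int, cover_pp, n_ok = 0, 0, 0
    for child in children:
        s1, s2 = (int(x % 2**31) for x in child.generate_state(2))
        design = make_study_design(seed=s1)
        records = simulate_cohort(design, n_participants, config, seed=s2)
        full, _ = make_datasets(records)
        res = fit_glmm_frequentist(full)
        fe = res.fixed["intercept_PPminus"]
        pp = res.fixed["PPplus"]
        if not (np.isfinite(fe.ci_low) and np.isfinite(fe.ci_high)):
            continue
        n_ok += 1
        cover_int += int(fe.ci_low <= 1.0 <= fe.ci_high)
        cover_pp += int(pp.ci_low <= 1.0 <= pp.ci_high)
    return {
        "intercept_coverage": cover_int / n_ok,
        "ppplus_coverage": cover_pp / n_ok,
        "ppplus_type1": 1.0 - cover_pp / n_ok,
        "n_replicates": n_ok,
        "n_participants": n_participants,
    }


@dataclass(frozen=True)
class RecoveryTruth:
    beta0: float = 1.0
    delta: float = 0.5
    tau_participant: float = 1.0
    tau_stimulus: float = 0.3


def parameter_recovery(
    n_cohorts: int = 100,
    n_participants: int = 60,
    truth: RecoveryTruth = RecoveryTruth(),
    base_seed: int = 0,
) -> dict:
    """Fit the analysis model to cohorts simulated from its own generative
    counterpart and summarize bias and 95% interval coverage of the fixed
    effects."""
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(n_cohorts)
    config = ParticipantConfig(
        learner="glmm_generative",
        beta0=truth.beta0,
        delta_pp_plus=truth.delta,
        tau_participant=truth.tau_participant,
        tau_stimulus=truth.tau_stimulus,
    )
    est0, est1, cov0, cov1 = [], [], [], []
    for child in children:
        s1, s2 = (int(x % 2**31) for x in child.generate_state(2))
        design = make_study_design(seed=s1)
        records = simulate_cohort(design, n_participants, config, seed=s2)
        full, _ = make_datasets(records)
        res = fit_glmm_frequentist(full)
        fe0 = res.fixed["intercept_PPminus"]
        fe1 = res.fixed["PPplus"]
        est0.append(fe0.estimate)
        est1.append(fe1.estimate)
        cov0.append(fe0.ci_low <= np.exp(truth.beta0) <= fe0.ci_high)
        cov1.append(fe1.ci_low <= np.exp(truth.delta) <= fe1.ci_high)
    return {
        "beta0_bias": float(np.mean(est0) - truth.beta0),
        "delta_bias": float(np.mean(est1) - truth.delta),
        "beta0_coverage": float(np.mean(cov0)),
        "delta_coverage": float(np.mean(cov1)),
        "n_cohorts": n_cohorts,
        "n_participants": n_participants,
    }


def rt_filter_recall(
    n_participants: int = 30,
    contamination_rate: float = 0.02,
    seed: int = 0,
) -> dict:
    """Plant far-tail RT contamination and check the 3-SD filter removes
    exactly the planted rows (perfect recall and precision under the default
    contamination range)."""
    design = make_study_design(seed=seed)
    config = ParticipantConfig(
        learner="glmm_generative", contamination_rate=contamination_rate
    )
    records = simulate_cohort(design, n_participants, config, seed=seed + 1)
    full, _ = make_datasets(records)
    kept = set(zip(full.rows["participant_id"], full.rows["trial_index"]))
    planted = records[records["contaminated"]]
    removed_planted = sum(
        1
        for _, r in planted.iterrows()
        if (r["participant_id"], r["trial_index"]) not in kept
    )
    n_planted = int(records["contaminated"].sum())
    return {
        "n_planted": n_planted,
        "n_excluded": full.n_excluded,
        "recall": removed_planted / n_planted if n_planted else 1.0,
        "precision": removed_planted / full.n_excluded if full.n_excluded else 1.0,
        "n_trials": len(records),
    }
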