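import itertools

import numpy as np
import pytest

from cswlkit.design import (
    TRIAL_TIMING_MS,
    DesignError,
    DesignSpec,
    build_pairing_schedule,
    counterbalance_assignment,
    default_words_objects,
    generate_design,
    read_design,
    validate_design,
    write_design,
)


WORDS, OBJECTS = default_words_objects(6)


class TestCounterbalance:
    def test_version_b_switches_objects_across_sets(self):
        a = counterbalance_assignment(WORDS, OBJECTS, "A", seed=5)
        b = counterbalance_assignment(WORDS, OBJECTS, "B", seed=5)
        set_of_obj_a = {p.object_id: p.set_label for p in a}
        for pa, pb in zip(a, b):
            assert pa.word_id == pb.word_id and pa.set_label == pb.set_label
            assert set_of_obj_a[pb.object_id] != pb.set_label
        assert not ({(p.word_id, p.object_id) for p in a}
                    & {(p.word_id, p.object_id) for p in b})

    def test_same_seed_reproduces_assignment(self):
        assert counterbalance_assignment(WORDS, OBJECTS, "A", 9) == \
            counterbalance_assignment(WORDS, OBJECTS, "A", 9)

    def test_count_mismatch_error(self):
        with pytest.raises(DesignError):
            counterbalance_assignment(WORDS, OBJECTS[:-1], "A", 0)


class TestPairingSchedule:
    def test_each_label_appears_six_times_with_five_or_six_partners(self):
        rng = np.random.default_rng(0)
        ids = [f"w{i}" for i in range(6)]
        sched = build_pairing_schedule(ids, 6, rng)
        assert len(sched) == 18
        appearances = {w: 0 for w in ids}
        partners = {w: set() for w in ids}
        for pairing in sched:
            a, b = sorted(pairing)
            appearances[a] += 1
            appearances[b] += 1
            partners[a].add(b)
            partners[b].add(a)
        assert all(v == 6 for v in appearances.values())
        assert all(len(p) == 5 for p in partners.values())
        # all 15 distinct pairings present, 3 of them twice
        distinct = set(sched)
        assert len(distinct) == 15
        assert sum(sched.count(p) == 2 for p in distinct) == 3

    def test_two_labels_one_exposure(self):
        rng = np.random.default_rng(0)
        assert build_pairing_schedule(["a", "b"], 1, rng) == [frozenset({"a", "b"})]

    def test_infeasible_parameters(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DesignError):
            build_pairing_schedule([f"w{i}" for i in range(6)], 4, rng)


class TestGeneratedDesign:
    def test_counts_and_timing(self, study_design):
        report = validate_design(study_design)
        assert report.n_training == 36
        assert report.n_test == 24
        assert set(report.trials_per_set.values()) == {18}
        assert report.trial_duration_ms == sum(TRIAL_TIMING_MS) == 3992
        assert abs(report.trial_duration_ms - 4000) < 50

    def test_each_pair_tested_twice_and_first_occurrence_is_repetition_one(
        self, study_design
    ):
        seen = {}
        for t in sorted(study_design.test, key=lambda t: t.index):
            seen.setdefault(t.probe_word, []).append(t.repetition)
        assert all(reps == [1, 2] for reps in seen.values())

    def test_warmups_use_familiar_objects(self, study_design):
        assert len(study_design.warmup) == 2
        for t in study_design.warmup:
            assert t.repetition == 0
            assert set(t.objects) == {"house", "duck", "ball", "cat"}
            assert t.objects[t.target_position] == t.probe_word

    def test_first_word_side_balance(self, study_design):
        first_left = sum(
            1
            for t in study_design.training
            if study_design.referent_of[t.first_word] == t.left_object
        )
        assert abs(first_left - 18) <= 1

    def test_interleave_run_length(self, study_design):
        labels = [t.set_label for t in study_design.training]
        longest = max(len(list(g)) for _, g in itertools.groupby(labels))
        assert longest <= study_design.spec.max_same_set_run

    def test_target_corners_balanced_per_set(self, study_design):
        report = validate_design(study_design)
        for counts in report.target_position_counts.values():
            assert set(counts.values()) == {3}

    @pytest.mark.parametrize("seed", range(40))
    def test_separability_invariants_across_seeds(self, seed):
        spec = DesignSpec(seed=seed)
        design = generate_design(WORDS, OBJECTS, spec)
        report = validate_design(design)
        assert report.violations == []
        assert report.diagonal_min == 6
        assert report.within_set_offdiag_max == 2
        assert report.cross_set_max == 0
        assert report.diagonal_min / max(report.within_set_offdiag_max, 1) >= 3
        assert all(s <= 1 for s in report.foil_spread.values())

    def test_word_order_side_correlation_near_zero(self):
        corrs = [
            validate_design(generate_design(WORDS, OBJECTS, DesignSpec(seed=s))
                            ).word_order_side_correlation
            for s in range(20)
        ]
        assert abs(float(np.mean(corrs))) < 0.1
        assert all(abs(c) < 0.35 for c in corrs)

    def test_alternation_policy(self):
        spec = DesignSpec(seed=1, interleave_policy="alternate")
        design = generate_design(WORDS, OBJECTS, spec)
        labels = [t.set_label for t in design.training]
        assert labels == [labels[0], labels[1]] * 18

    def test_determinism_and_io_round_trip(self, tmp_path):
        d1 = generate_design(WORDS, OBJECTS, DesignSpec(seed=11))
        d2 = generate_design(WORDS, OBJECTS, DesignSpec(seed=11))
        assert d1.training == d2.training and d1.test == d2.test
        write_design(d1, tmp_path)
        back = read_design(tmp_path)
        assert back.training == d1.training
        assert back.test == d1.test
        assert back.pairs == d1.pairs

    def test_empty_design_report(self):
        from cswlkit.design import Design

        pairs = counterbalance_assignment(WORDS, OBJECTS, "A", 0)
        empty = Design(pairs=pairs, training=[], test=[], warmup=[], spec=DesignSpec())
        report = validate_design(empty)
        assert report.n_training == 0 and report.n_test == 0
        assert report.violations == []
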