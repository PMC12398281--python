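import numpy as np
import pytest

from gsda.features import default_atlas
from gsda.synthetic import (
    SyntheticConfig,
    default_config,
    generate,
    planted_recovery_report,
)
from gsda.workflow import (
    LateralizationMask,
    PartitionScheme,
    apply_mask_to_model,
    assemble_second_order_design,
    derive_mask,
    hemisphere_split_partition,
    interaction_sign_counts,
    lobe_average_degree,
    run_first_order,
    run_second_order,
    shared_exclusive_partition,
    subject_holdout_partition,
    top_fraction_indices,
)


def small_samples(n_subjects=10, h=6, seed=0):
    samples, _ = generate(SyntheticConfig(n_subjects_per_group=n_subjects, h=h, seed=seed))
    return samples


class TestHemisphereSplitPartition:
    def test_counts_and_sides(self):
        samples = small_samples(n_subjects=2)  # 4 subjects total
        train, test = hemisphere_split_partition(samples, seed=0)
        assert len(train) == 4 and len(test) == 4
        by_subject = {}
        for idx in train:
            by_subject.setdefault(samples[idx].subject_id, []).append("train")
        for idx in test:
            by_subject.setdefault(samples[idx].subject_id, []).append("test")
        for sides in by_subject.values():
            assert sorted(sides) == ["test", "train"]

    def test_exact_label_balance(self):
        samples = small_samples(n_subjects=10)
        for seed in range(20):
            train, test = hemisphere_split_partition(samples, seed=seed)
            train_labels = [samples[i].hemisphere for i in train]
            assert sum(train_labels) * 2 == len(train_labels)
            test_labels = [samples[i].hemisphere for i in test]
            assert sum(test_labels) * 2 == len(test_labels)

    def test_no_subject_contributes_both_hemispheres_to_train(self):
        samples = small_samples(n_subjects=10)  # 20 subjects
        for seed in range(100):
            train, _ = hemisphere_split_partition(samples, seed=seed)
            seen = {}
            for idx in train:
                s = samples[idx]
                assert seen.setdefault(s.subject_id, s.hemisphere) == s.hemisphere
            assert len(seen) == len(train)

    def test_covers_all_samples_disjointly(self):
        samples = small_samples()
        train, test = hemisphere_split_partition(samples, seed=3)
        assert sorted(np.concatenate([train, test]).tolist()) == list(range(len(samples)))

    def test_missing_hemisphere_rejected(self):
        samples = small_samples()[:-1]
        with pytest.raises(ValueError, match="missing a hemisphere"):
            hemisphere_split_partition(samples, seed=0)

    def test_group_stratification(self):
        samples = small_samples(n_subjects=8)
        train, _ = hemisphere_split_partition(samples, seed=1)
        groups = [samples[i].group for i in train]
        assert sum(groups) * 2 == len(groups)


class TestSubjectHoldoutPartition:
    def test_holdout_counts(self):
        samples = small_samples(n_subjects=5)  # 10 subjects
        part = subject_holdout_partition(samples, holdout_fraction=0.2, seed=0)
        heldout_subjects = {samples[i].subject_id for i in part.heldout}
        assert len(heldout_subjects) == 2
        assert len(part.heldout) == 4  # both hemispheres of each

    def test_heldout_disjoint_from_train(self):
        samples = small_samples(n_subjects=10)
        for seed in range(50):
            part = subject_holdout_partition(samples, 0.2, seed=seed)
            train_subjects = {samples[i].subject_id for i in part.train}
            heldout_subjects = {samples[i].subject_id for i in part.heldout}
            assert not (train_subjects & heldout_subjects)
            # remaining subjects still hemisphere-disjoint
            seen = {}
            for idx in part.train:
                s = samples[idx]
                assert seen.setdefault(s.subject_id, s.hemisphere) == s.hemisphere

    def test_invalid_fraction(self):
        with pytest.raises(ValueError, match="holdout_fraction"):
            subject_holdout_partition(small_samples(), holdout_fraction=1.5)


class TestRunFirstOrder:
    def test_record_count_single_repetition(self):
        samples = small_samples(n_subjects=10)
        ens = run_first_order(
            samples, lam_grid=(0.0, 5.0), target_groups=(0, 1), n_repetitions=1
        )
        assert len(ens) == 4

    def test_gsi_rises_with_lambda_on_planted_data(self, divergent_dataset):
        samples, _ = divergent_dataset
        ens = run_first_order(
            samples, lam_grid=(0.0, 5.0), target_groups=(0,), n_repetitions=20,
            base_seed=11,
        )
        df = ens.to_dataframe()
        mean_gsi = df.groupby("lam")["gsi"].mean()
        assert mean_gsi[5.0] > mean_gsi[0.0]

    def test_lambda_zero_gap_small_without_exclusive_lateralization(self):
        cfg = default_config(
            seed=5, n_subjects_per_group=150,
            shared_scales=(1.0, 1.0), exclusive_offset=0.0,
        )
        samples, _ = generate(cfg)
        ens = run_first_order(
            samples, lam_grid=(0.0,), target_groups=(0, 1), n_repetitions=20
        )
        df = ens.to_dataframe()
        # averaging the target-minus-nontarget gap over both target groups
        # cancels realization-level differences in group difficulty
        gap = df.groupby("target_group").apply(
            lambda s: 100 * (s["bat"].mean() - s["bant"].mean()),
            include_groups=False,
        )
        assert abs(gap.mean()) < 2.0

    def test_reproducible_from_base_seed(self):
        samples = small_samples(n_subjects=10)
        kwargs = dict(lam_grid=(1.0,), target_groups=(0,), n_repetitions=2, base_seed=9)
        e1 = run_first_order(samples, **kwargs)
        e2 = run_first_order(samples, **kwargs)
        np.testing.assert_array_equal(
            e1.weight_matrix(1.0, 0), e2.weight_matrix(1.0, 0)
        )

    def test_subject_holdout_scheme_records_heldout_accuracy(self):
        samples = small_samples(n_subjects=10)
        ens = run_first_order(
            samples,
            scheme=PartitionScheme(kind="subject_holdout", holdout_fraction=0.2),
            lam_grid=(0.0,),
            target_groups=(0,),
            n_repetitions=2,
        )
        assert all(r.bat_heldout is not None for r in ens.records)

    def test_invalid_repetitions(self):
        with pytest.raises(ValueError, match="n_repetitions"):
            run_first_order(small_samples(), n_repetitions=0)


class TestSecondOrder:
    def test_design_shape_and_labels(self):
        samples = small_samples(n_subjects=10)
        ens_a = run_first_order(samples, lam_grid=(1.0,), target_groups=(0,), n_repetitions=3)
        ens_b = run_first_order(samples, lam_grid=(1.0,), target_groups=(1,), n_repetitions=3)
        X, y = assemble_second_order_design(ens_a, ens_b, 1.0)
        assert X.shape == (6, samples[0].features.shape[0])
        np.testing.assert_array_equal(y, [0, 0, 0, 1, 1, 1])

    def test_single_model_per_side(self):
        samples = small_samples(n_subjects=10)
        ens_a = run_first_order(samples, lam_grid=(0.0,), target_groups=(0,), n_repetitions=1)
        ens_b = run_first_order(samples, lam_grid=(0.0,), target_groups=(1,), n_repetitions=1)
        X, y = assemble_second_order_design(ens_a, ens_b, 0.0)
        assert X.shape[0] == 2

    def test_missing_lambda_raises(self):
        samples = small_samples(n_subjects=10)
        ens = run_first_order(samples, lam_grid=(0.0,), target_groups=(0,), n_repetitions=1)
        with pytest.raises(ValueError, match="lam"):
            assemble_second_order_design(ens, ens, 3.0)

    def test_separable_design_perfect_accuracy(self, rng):
        X = np.vstack([rng.normal(size=(20, 5)) + 8, rng.normal(size=(20, 5)) - 8])
        y = np.repeat([0, 1], 20)
        result = run_second_order(X, y, n_splits=5)
        np.testing.assert_array_equal(result.accuracies, 1.0)

    def test_permuted_labels_at_chance(self, rng):
        X = rng.normal(size=(100, 8))
        y = np.repeat([0, 1], 50)
        result = run_second_order(X, y, n_splits=50, base_seed=2)
        n_test = 20
        half_width = 1.96 * np.sqrt(0.25 / (50 * n_test))
        assert abs(result.mean_accuracy - 0.5) <= 3 * half_width + 0.05

    def test_split_count(self, rng):
        X = np.vstack([rng.normal(size=(10, 3)), rng.normal(size=(10, 3)) + 5])
        y = np.repeat([0, 1], 10)
        result = run_second_order(X, y, n_splits=3)
        assert result.accuracies.shape == (3,)
        assert result.weights.shape == (3, 3)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            run_second_order(rng.normal(size=(10, 2)), np.zeros(10), n_splits=1)


class TestMask:
    def test_identical_vectors_full_overlap(self, rng):
        w = rng.normal(size=7503)
        mask = derive_mask(w, w.copy(), top_fraction=0.05)
        assert len(mask) == 375  # floor(0.05 * 7503)

    def test_disjoint_top_sets_empty_mask(self):
        a = np.array([10.0, 9.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1] * 2)
        b = np.array([0.1, 0.1, 10.0, 9.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1] * 2)
        assert len(derive_mask(a, b, top_fraction=0.1)) == 0

    def test_toy_matches_brute_force_sort_intersect(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        frac = 0.25
        k = int(np.floor(frac * 20))
        top_a = set(sorted(range(20), key=lambda i: (-abs(a[i]), i))[:k])
        top_b = set(sorted(range(20), key=lambda i: (-abs(b[i]), i))[:k])
        mask = derive_mask(a, b, top_fraction=frac)
        assert set(mask.indices) == (top_a & top_b)

    def test_tie_broken_by_lower_index(self):
        w = np.array([1.0, 1.0, 1.0, 0.0])
        np.testing.assert_array_equal(top_fraction_indices(w, 0.5), [0, 1])

    def test_apply_mask_subset_returned(self, rng):
        w = np.zeros(20)
        w[[2, 5, 7]] = [3.0, -2.0, 1.5]
        mask = LateralizationMask(frozenset({2, 5}), 0.2)
        out = apply_mask_to_model(w, mask, top_fraction=0.2)
        assert out == [(2, 3.0), (5, -2.0)]

    def test_apply_empty_mask(self, rng):
        out = apply_mask_to_model(rng.normal(size=10), LateralizationMask(frozenset(), 0.1), 0.1)
        assert out == []

    def test_apply_mask_toy_vs_brute_force(self, rng):
        w = rng.normal(size=20)
        frac = 0.3
        k = int(np.floor(frac * 20))
        own_top = set(sorted(range(20), key=lambda i: (-abs(w[i]), i))[:k])
        mask = LateralizationMask(frozenset(rng.choice(20, size=8, replace=False).tolist()), frac)
        expected = sorted(own_top & set(mask.indices))
        assert [i for i, _ in apply_mask_to_model(w, mask, frac)] == expected


class TestSharedExclusive:
    def test_identical_lists_all_shared(self):
        out = shared_exclusive_partition({"d1": {0: [1, 2, 3], 1: [1, 2, 3]}})
        assert out["datasets"]["d1"]["shared"] == {1, 2, 3}
        assert out["datasets"]["d1"]["exclusive"][0] == set()

    def test_disjoint_lists_all_exclusive(self):
        out = shared_exclusive_partition({"d1": {0: [1, 2], 1: [3, 4]}})
        assert out["datasets"]["d1"]["shared"] == set()
        assert out["datasets"]["d1"]["exclusive"] == {0: {1, 2}, 1: {3, 4}}

    def test_four_lists_hand_enumeration(self):
        sel = {
            "d1": {0: [1, 2, 5], 1: [2, 5, 9]},
            "d2": {0: [2, 7], 1: [2, 8]},
        }
        out = shared_exclusive_partition(sel)
        assert out["datasets"]["d1"]["shared"] == {2, 5}
        assert out["datasets"]["d1"]["exclusive"] == {0: {1}, 1: {9}}
        assert out["datasets"]["d2"]["shared"] == {2}
        assert out["datasets"]["d2"]["exclusive"] == {0: {7}, 1: {8}}
        assert out["unique"] == {1, 2, 5, 7, 8, 9}


class TestLobeStatistics:
    def atlas(self):
        # h=9: three lobes of 3 homologue ROIs each
        return default_atlas(h=9, lobes=("A", "B", "C"))

    def test_single_intra_lobe_chord(self):
        atlas = default_atlas(h=10, lobes=("solo",))
        from gsda.features import pair_to_linear_index

        idx = pair_to_linear_index(2, 3, 10)
        deg = lobe_average_degree([idx], atlas)
        assert deg["solo"] == pytest.approx(2 / 10)

    def test_chord_spanning_lobes(self):
        atlas = self.atlas()
        from gsda.features import pair_to_linear_index

        idx = pair_to_linear_index(0, 4, 9)  # lobe A (0-2) to lobe B (3-5)
        deg = lobe_average_degree([idx], atlas)
        assert deg["A"] == pytest.approx(1 / 3)
        assert deg["B"] == pytest.approx(1 / 3)
        assert deg["C"] == 0.0

    def test_toy_mask_hand_count(self):
        atlas = self.atlas()
        from gsda.features import pair_to_linear_index

        chords = [(0, 1), (0, 2), (3, 4), (0, 4), (6, 8), (2, 7)]
        idxs = [pair_to_linear_index(i, j, 9) for i, j in chords]
        deg = lobe_average_degree(idxs, atlas)
        # endpoints: A gets 2+2+1+1 = 6; B gets 2+1 = 3; C gets 2+1 = 3
        assert deg == {"A": pytest.approx(6 / 3), "B": pytest.approx(3 / 3), "C": pytest.approx(3 / 3)}

    def test_interaction_sign_counts_single_cell(self):
        atlas = self.atlas()
        from gsda.features import pair_to_linear_index

        sel = {0: [(pair_to_linear_index(0, 1, 9), 0.5), (pair_to_linear_index(1, 2, 9), 0.1)]}
        counts = interaction_sign_counts(sel, atlas)
        assert counts[(0, "intra", "positive")] == 2
        assert sum(v for k, v in counts.items() if k != (0, "intra", "positive")) == 0

    def test_interaction_sign_counts_mixed_hand_tally(self):
        atlas = self.atlas()
        from gsda.features import pair_to_linear_index

        sel = {
            0: [
                (pair_to_linear_index(0, 1, 9), 0.5),   # intra A, +
                (pair_to_linear_index(0, 4, 9), -0.2),  # inter A-B, -
                (pair_to_linear_index(6, 7, 9), 0.0),   # intra C, zero counts +
            ],
            1: [
                (pair_to_linear_index(3, 8, 9), -1.0),  # inter B-C, -
            ],
        }
        counts = interaction_sign_counts(sel, atlas)
        assert counts[(0, "intra", "positive")] == 2
        assert counts[(0, "inter", "negative")] == 1
        assert counts[(1, "inter", "negative")] == 1
        assert counts[(0, "intra", "negative")] == 0

    def test_empty_selection_all_zero(self):
        counts = interaction_sign_counts({0: []}, self.atlas())
        assert all(v == 0 for v in counts.values())


class TestEndToEndRecovery:
    def test_mask_recovers_planted_shared_connections(self):
        hits = []
        for seed in range(3):
            cfg = default_config(seed=seed, n_subjects_per_group=150)
            samples, truth = generate(cfg)
            ens_m = run_first_order(
                samples, lam_grid=(5.0,), target_groups=(0,), n_repetitions=10,
                base_seed=100 + seed,
            )
            ens_f = run_first_order(
                samples, lam_grid=(5.0,), target_groups=(1,), n_repetitions=10,
                base_seed=200 + seed,
            )
            mask = derive_mask(
                ens_m.mean_weights(5.0, 0), ens_f.mean_weights(5.0, 1), top_fraction=0.05
            )
            report = planted_recovery_report(mask.sorted_indices(), truth.shared_indices)
            hits.append((report["precision"], report["recall"]))
        mean_precision = np.mean([h[0] for h in hits])
        mean_recall = np.mean([h[1] for h in hits])
        assert mean_precision >= 0.8
        assert mean_recall >= 0.8
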