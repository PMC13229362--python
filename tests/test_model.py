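"""Tensor encodings, label space, synthesis, and classifier training."""

import numpy as np
import pytest

from seedpolish.model import (
    EncodingError,
    ErrorPattern,
    ModelConfig,
    PatternModel,
    corrupt_by_pattern,
    encode_context,
    encode_seed_structure,
    enumerate_label_space,
    homopolymer_flags,
    label_to_pattern,
    make_ideal_member_fn,
    n_labels,
    pattern_to_label,
    predict_patterns,
    synthesize_training_set,
    train_model,
)
from seedpolish.seeds import GAConfig, SeedSet, SpacedSeed, ga_design


class TestSeedStructureTensor:
    def test_single_all_care_seed(self):
        S = encode_seed_structure(SeedSet((SpacedSeed.from_string("11111"),)))
        assert S.shape == (5, 1)
        assert (S == 1).all()

    def test_column_sums_equal_weights(self, seed_set_k21):
        S = encode_seed_structure(seed_set_k21)
        assert list(S.sum(axis=0)) == [s.weight for s in seed_set_k21]

    def test_direct_transcription(self):
        sset = SeedSet(
            (
                SpacedSeed.from_string("10101", anchored=False),
                SpacedSeed.from_string("01010", anchored=False),
            )
        )
        S = encode_seed_structure(sset)
        assert S.tolist() == [[1, 0], [0, 1], [1, 0], [0, 1], [1, 0]]


class TestLabelSpace:
    def test_small_window_count(self):
        assert len(enumerate_label_space(1)) == 6

    def test_default_window_count(self):
        assert len(enumerate_label_space(5)) == 352

    @pytest.mark.parametrize("w", [1, 2, 3, 4, 5, 6])
    def test_size_formula(self, w):
        labels = enumerate_label_space(w)
        assert len(labels) == (2**w) * (2 * w + 1)
        assert len({p.label_id for p in labels}) == len(labels)

    def test_label_zero_is_noop(self):
        assert enumerate_label_space(5)[0].is_noop

    def test_round_trip_bijection(self):
        w = 4
        for lid in range(n_labels(w)):
            assert pattern_to_label(label_to_pattern(lid, w)) == lid

    def test_invalid_patterns_rejected(self):
        with pytest.raises(ValueError):
            ErrorPattern((0, 0, 0), ("del", 4))
        with pytest.raises(ValueError):
            ErrorPattern((0, 0, 0), ("dup", 1))


def test_homopolymer_flags():
    assert homopolymer_flags("AACGG").tolist() == [0, 1, 0, 0, 1]


class TestContextEncoding:
    def test_clean_region_has_full_membership_at_zero_gap(
        self, small_genome, seed_set_k21
    ):
        k, w = 21, 5
        truth = small_genome[1000 : 1000 + 2 * (k - 1) + 2 * w]
        member = make_ideal_member_fn(truth, seed_set_k21)
        ctx = truth[: (k - 1) + w + (k - 1)]
        X = encode_context(ctx, k - 1, seed_set_k21, w, member)
        assert X.shape == (len(ctx) - k + 1, 1 + 3 * (w + 1))
        for j in range(3):
            assert (X[:, 1 + j * (w + 1)] == 1).all()

    def test_too_short_sequence_raises(self, seed_set_k21):
        with pytest.raises(EncodingError):
            encode_context("ACGT", 2, seed_set_k21, 5, lambda j, win: True)

    def test_membership_is_content_agnostic(self, small_genome, seed_set_k21):
        # Relabeling the alphabet consistently (preserving complement
        # pairing: A<->G, C<->T) must leave membership columns intact.
        k, w = 21, 5
        trans = str.maketrans("ACGT", "GTAC")
        rng = np.random.default_rng(3)
        pat = ErrorPattern((1, 0, 1, 0, 0), ("none", 0))
        truth = small_genome[2000 : 2000 + 2 * (k - 1) + 2 * w]
        draft = corrupt_by_pattern(truth, k - 1, pat, rng)
        ctx = draft[: (k - 1) + w + (k - 1)]
        X1 = encode_context(
            ctx, k - 1, seed_set_k21, w, make_ideal_member_fn(truth, seed_set_k21)
        )
        X2 = encode_context(
            ctx.translate(trans),
            k - 1,
            seed_set_k21,
            w,
            make_ideal_member_fn(truth.translate(trans), seed_set_k21),
        )
        assert np.array_equal(X1[:, 1:], X2[:, 1:])


class TestCorruption:
    @pytest.mark.parametrize(
        "indel", [("none", 0), ("del", 2), ("ins", 3)]
    )
    def test_corruption_changes_sequence(self, small_genome, indel, rng):
        pat = ErrorPattern((1, 0, 0, 1, 0), indel)
        truth = small_genome[100:200]
        draft = corrupt_by_pattern(truth, 40, pat, rng)
        assert draft != truth
        kind, d = indel
        expect = {"none": 0, "del": d, "ins": -d}[kind]
        assert len(draft) - len(truth) == expect

    def test_noop_label_is_identity(self, small_genome, rng):
        pat = ErrorPattern((0, 0, 0, 0, 0))
        truth = small_genome[100:200]
        assert corrupt_by_pattern(truth, 40, pat, rng) == truth


class TestSynthesis:
    def test_balanced_sampling(self, small_genome, seed_set_k15):
        ds = synthesize_training_set(
            [small_genome], [seed_set_k15], w=2, n_samples=100, rng_seed=0
        )
        counts = np.bincount(
            np.concatenate([g.y for g in ds.groups]), minlength=n_labels(2)
        )
        assert counts.max() - counts.min() <= 1
        assert ds.n_samples == 100

    def test_reproducible(self, small_genome, seed_set_k15):
        a = synthesize_training_set(
            [small_genome], [seed_set_k15], w=2, n_samples=60, rng_seed=5
        )
        b = synthesize_training_set(
            [small_genome], [seed_set_k15], w=2, n_samples=60, rng_seed=5
        )
        assert all(
            np.array_equal(ga.X, gb.X) and np.array_equal(ga.y, gb.y)
            for ga, gb in zip(a.groups, b.groups)
        )


class TestTraining:
    def test_loss_decreases_over_epochs(self, small_genome):
        sets = [ga_design(15, 3, GAConfig(n_generations=20, rng_seed=s)) for s in (0, 1)]
        ds = synthesize_training_set([small_genome], sets, w=5, n_samples=1500, rng_seed=1)
        model = train_model(ds, ModelConfig(n_epochs=10, rng_seed=0))
        losses = [r["train_loss"] for r in model.history]
        assert np.mean(losses[5:10]) < np.mean(losses[:5])

    def test_training_reproducible(self, small_genome, seed_set_k15):
        ds = synthesize_training_set(
            [small_genome], [seed_set_k15], w=2, n_samples=200, rng_seed=2
        )
        cfg = ModelConfig(n_epochs=2, rng_seed=9, w=2)
        a = train_model(ds, cfg, validation=ds)
        b = train_model(ds, cfg, validation=ds)
        assert a.history[-1]["val_acc"] == pytest.approx(b.history[-1]["val_acc"])

    def test_rejects_degenerate_dataset(self, small_genome, seed_set_k15):
        ds = synthesize_training_set(
            [small_genome], [seed_set_k15], w=2, n_samples=1, rng_seed=0
        )
        with pytest.raises(ValueError):
            train_model(ds, ModelConfig(n_epochs=1, w=2))

    def test_generalizes_across_k(self, tiny_model, small_genome):
        # Trained on k=15 seed sets; shape-compatible with unseen k=25.
        sset = ga_design(25, 3, GAConfig(n_generations=10, rng_seed=8))
        ds = synthesize_training_set([small_genome], [sset], w=5, n_samples=10, rng_seed=3)
        g = ds.groups[0]
        ranked = predict_patterns(tiny_model, g.S, g.X[0], T=3)
        assert len(ranked) == 3


class TestPrediction:
    def test_top1_and_ordering(self, tiny_model, small_genome, seed_set_k15):
        ds = synthesize_training_set(
            [small_genome], [seed_set_k15], w=5, n_samples=20, rng_seed=4
        )
        g = ds.groups[0]
        one = predict_patterns(tiny_model, g.S, g.X[0], T=1)
        assert len(one) == 1
        many = predict_patterns(tiny_model, g.S, g.X[0], T=5)
        confs = [c for _, c in many]
        assert confs == sorted(confs, reverse=True)
        assert sum(confs) <= 1.0 + 1e-9
        assert one[0][0] == many[0][0]

    def test_topk_recall_monotone_in_T(self, tiny_model, small_genome, seed_set_k15):
        ds = synthesize_training_set(
            [small_genome], [seed_set_k15], w=5, n_samples=150, rng_seed=6
        )
        g = ds.groups[0]
        recalls = []
        for T in (1, 3, 10):
            hit = 0
            for i in range(len(g.y)):
                ranked = predict_patterns(tiny_model, g.S, g.X[i], T=T)
                hit += any(p.label_id == g.y[i] for p, _ in ranked)
            recalls.append(hit / len(g.y))
        assert recalls == sorted(recalls)


def test_checkpoint_round_trip(tmp_path, tiny_model, small_genome, seed_set_k15):
    ds = synthesize_training_set(
        [small_genome], [seed_set_k15], w=5, n_samples=5, rng_seed=8
    )
    g = ds.groups[0]
    before = tiny_model.predict_proba(g.S, g.X[0])
    path = tmp_path / "model.json"
    tiny_model.save(path)
    loaded = PatternModel.load(path)
    after = loaded.predict_proba(g.S, g.X[0])
    assert np.allclose(before, after)


def test_history_tsv(tmp_path, tiny_model):
    from seedpolish.model import write_history_tsv

    path = tmp_path / "hist.tsv"
    write_history_tsv(tiny_model, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0] == "epoch\ttrain_loss\tval_loss\tval_acc"
    assert len(lines) == 1 + len(tiny_model.history)
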