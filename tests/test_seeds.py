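"""Spaced-seed matching, detectability enumeration, and GA design."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedpolish.seeds import (
    GAConfig,
    SeedSet,
    SpacedSeed,
    detectable_patterns,
    ga_design,
    ga_fitness,
    read_seed_set,
    seed_matches,
    write_seed_set,
)

BASES = "ACGT"


def brute_force_match(mask, ref, query):
    return all(r == q for m, r, q in zip(mask, ref, query) if m)


class TestSpacedSeed:
    def test_anchored_validation(self):
        with pytest.raises(ValueError):
            SpacedSeed.from_string("01001")  # unanchored ends
        s = SpacedSeed.from_string("01001", anchored=False)
        assert s.weight == 2 and s.k == 5

    def test_weight_and_care_positions(self):
        s = SpacedSeed.from_string("10101", anchored=False)
        assert s.care_positions == (0, 2, 4)
        assert s.dont_care_positions == (1, 3)

    @pytest.mark.parametrize("bad", ["1", "11211", "10"])
    def test_invalid_masks(self, bad):
        with pytest.raises(ValueError):
            SpacedSeed.from_string(bad, anchored=False)

    def test_seed_set_rejects_duplicates_and_mixed_k(self):
        a = SpacedSeed.from_string("111")
        with pytest.raises(ValueError):
            SeedSet((a, a))
        with pytest.raises(ValueError):
            SeedSet((a, SpacedSeed.from_string("1111")))


class TestSeedMatches:
    def test_dense_cluster_tolerated_by_do_not_care_positions(self):
        # Mismatch pattern M*MM* is invisible to a seed caring only at
        # the second and fifth positions.
        seed = SpacedSeed.from_string("01001", anchored=False)
        assert seed_matches(seed, "ACGTA", "TCAGA")

    def test_all_care_is_exact_matching(self):
        seed = SpacedSeed.from_string("11111")
        assert seed_matches(seed, "ACGTA", "ACGTA")
        assert not seed_matches(seed, "ACGTA", "ACGTT")

    def test_tolerant_window_count_is_four_per_dont_care(self):
        seed = SpacedSeed.from_string("101", anchored=False)
        n = sum(
            seed_matches(seed, "ACG", "".join(q))
            for q in itertools.product(BASES, repeat=3)
        )
        assert n == 4  # 4 ** (number of don't-care positions)

    def test_length_mismatch_raises(self):
        seed = SpacedSeed.from_string("111")
        with pytest.raises(ValueError):
            seed_matches(seed, "ACGT", "ACG")

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(2000):
            k = int(rng.integers(3, 12))
            mask = rng.integers(0, 2, k)
            mask[0] = mask[-1] = 1
            seed = SpacedSeed(tuple(int(b) for b in mask))
            ref = "".join(rng.choice(list(BASES), k))
            query = "".join(rng.choice(list(BASES), k))
            assert seed_matches(seed, ref, query) == brute_force_match(
                seed.mask, ref, query
            )


def brute_force_detectable(seed_set, max_len=None):
    """Exhaustive 2^k enumeration oracle."""
    k = seed_set.k
    if max_len is None:
        max_len = k
    out = set()
    for bits in itertools.product((0, 1), repeat=k):
        pos = [i for i, b in enumerate(bits) if b]
        if pos and pos[-1] - pos[0] + 1 > max_len:
            continue
        for seed in seed_set:
            if all(p in seed.dont_care_positions for p in pos):
                out.add(bits)
                break
        else:
            if not pos:
                out.add(bits)
    return out


class TestDetectablePatterns:
    def test_exact_seed_detects_only_the_zero_mask(self):
        sset = SeedSet((SpacedSeed.from_string("11111"),))
        assert detectable_patterns(sset) == {(0, 0, 0, 0, 0)}

    def test_worked_example_union_count(self):
        sset = SeedSet(
            (
                SpacedSeed.from_string("10101", anchored=False),
                SpacedSeed.from_string("01010", anchored=False),
            )
        )
        assert len(detectable_patterns(sset)) == 11

    def test_substring_01001_pattern_is_detectable(self):
        # A seed containing 01001 tolerates mismatches at the three
        # don't-care offsets of that substring.
        sset = SeedSet((SpacedSeed.from_string("1010011"),))
        got = detectable_patterns(sset)
        # Mismatches at every don't-care of the seed (positions 1, 3, 4,
        # i.e. the three don't-cares of the 01001 substring).
        assert (0, 1, 0, 1, 1, 0, 0) in got

    def test_equals_exhaustive_enumeration(self, rng):
        for k in (6, 8, 10, 12):
            masks = []
            while len(masks) < 3:
                m = rng.integers(0, 2, k)
                m[0] = m[-1] = 1
                t = tuple(int(b) for b in m)
                if sum(t) >= 2 and t not in masks:
                    masks.append(t)
            sset = SeedSet(tuple(SpacedSeed(m) for m in masks))
            for max_len in (k, 4):
                assert detectable_patterns(sset, max_len) == brute_force_detectable(
                    sset, max_len
                )

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            SeedSet(())


class TestGAFitness:
    def test_single_exact_seed_fitness_is_one(self):
        sset = SeedSet((SpacedSeed.from_string("11111"),))
        assert ga_fitness(sset, GAConfig(weight_penalty=0.0)) == 1.0

    def test_worked_example_fitness(self):
        sset = SeedSet(
            (
                SpacedSeed.from_string("10101", anchored=False),
                SpacedSeed.from_string("01010", anchored=False),
            )
        )
        assert ga_fitness(sset, GAConfig(weight_penalty=0.0)) == 11.0

    def test_new_pattern_at_equal_weight_increases_fitness(self):
        cfg = GAConfig(weight_penalty=0.1)
        one = SeedSet((SpacedSeed.from_string("11011", anchored=False),))
        two = SeedSet(
            (
                SpacedSeed.from_string("11011", anchored=False),
                SpacedSeed.from_string("10111", anchored=False),
            )
        )
        # Same per-seed weight; the added seed contributes new patterns
        # worth more than its don't-care penalty.
        assert ga_fitness(two, cfg) > ga_fitness(one, cfg)


class TestGADesign:
    def test_zero_generations_returns_initial_best(self):
        cfg = GAConfig(n_generations=0, rng_seed=3)
        sset, history = ga_design(21, 3, cfg, return_history=True)
        assert len(history) == 1
        assert sset.n_seeds == 3

    def test_best_fitness_is_non_decreasing(self):
        cfg = GAConfig(n_generations=30, rng_seed=42)
        _, history = ga_design(21, 3, cfg, return_history=True)
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_reproducible_under_fixed_seed(self):
        cfg = GAConfig(n_generations=15, rng_seed=7)
        a = ga_design(25, 3, cfg)
        b = ga_design(25, 3, cfg)
        assert [s.mask for s in a] == [s.mask for s in b]

    def test_designed_seeds_are_anchored_and_distinct(self):
        sset = ga_design(31, 3, GAConfig(n_generations=10, rng_seed=0))
        masks = [s.mask for s in sset]
        assert len(set(masks)) == 3
        for m in masks:
            assert m[0] == 1 and m[-1] == 1

    def test_infeasible_k_rejected(self):
        with pytest.raises(ValueError):
            ga_design(4, 3, GAConfig())


@st.composite
def mask_ref_query(draw):
    k = draw(st.integers(3, 14))
    mask = [1] + [draw(st.integers(0, 1)) for _ in range(k - 2)] + [1]
    ref = "".join(draw(st.sampled_from("ACGT")) for _ in range(k))
    query = "".join(draw(st.sampled_from("ACGT")) for _ in range(k))
    return tuple(mask), ref, query


@settings(max_examples=300, derandomize=True, deadline=None)
@given(mask_ref_query())
def test_seed_matches_property(case):
    mask, ref, query = case
    seed = SpacedSeed(mask)
    assert seed_matches(seed, ref, query) == brute_force_match(mask, ref, query)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(mask_ref_query())
def test_matching_is_reflexive_and_symmetric(case):
    mask, ref, query = case
    seed = SpacedSeed(mask)
    assert seed_matches(seed, ref, ref)
    assert seed_matches(seed, ref, query) == seed_matches(seed, query, ref)


def test_seed_set_file_round_trip(tmp_path, seed_set_k21):
    path = tmp_path / "seeds.txt"
    write_seed_set(seed_set_k21, path)
    text = path.read_text()
    assert text.startswith("#k=21\n")
    loaded = read_seed_set(path)
    assert [s.mask for s in loaded] == [s.mask for s in seed_set_k21]
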