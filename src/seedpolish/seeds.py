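"""Spaced seeds and genetic-algorithm seed design.

A spaced seed is a binary mask over a k-mer: positions marked 1 ("care")
must match between two windows, positions marked 0 ("do not care") are
ignored.  A set of seeds therefore tolerates mismatch patterns whose
mismatches all fall on don't-care positions of at least one seed — the
property that lets a polisher keep matching read k-mers across dense
error clusters that defeat exact k-mer lookup.

Seed sets are designed with a small genetic algorithm whose objective is
the number of distinct mismatch signatures the set can detect, minus a
penalty on don't-care (low-weight) positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

#: Default mismatch-span window used by the GA objective (and by the
#: error-pattern model downstream).
DEFAULT_WINDOW = 5

#: Default number of seeds per designed set.
DEFAULT_N_SEEDS = 3


@dataclass(frozen=True)
class SpacedSeed:
    """A care/don't-care mask of span ``k``.

    ``anchored=True`` (the default, and required for designed seeds and
    seed-set files) additionally demands that the first and last
    positions are care positions, which prevents trivially shifted
    duplicate masks.  Ad-hoc masks used for local matching checks may be
    built with ``anchored=False``.
    """

    mask: tuple[int, ...]
    anchored: bool = True

    def __post_init__(self) -> None:
        mask = tuple(int(b) for b in self.mask)
        object.__setattr__(self, "mask", mask)
        if any(b not in (0, 1) for b in mask):
            raise ValueError("mask must be binary")
        if len(mask) < 2 or sum(mask) < 2:
            raise ValueError("seed needs span >= 2 and weight >= 2")
        if self.anchored and not (mask[0] == 1 and mask[-1] == 1):
            raise ValueError("anchored seed must start and end with a care position")

    @classmethod
    def from_string(cls, s: str, anchored: bool = True) -> "SpacedSeed":
        return cls(tuple(int(c) for c in s), anchored=anchored)

    @property
    def k(self) -> int:
        return len(self.mask)

    @property
    def weight(self) -> int:
        return sum(self.mask)

    @property
    def care_positions(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.mask) if b)

    @property
    def dont_care_positions(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.mask) if not b)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.mask)


@dataclass(frozen=True)
class SeedSet:
    """An ordered collection of distinct spaced seeds sharing one span k."""

    seeds: tuple[SpacedSeed, ...]

    def __post_init__(self) -> None:
        seeds = tuple(self.seeds)
        object.__setattr__(self, "seeds", seeds)
        if not seeds:
            raise ValueError("seed set must contain at least one seed")
        ks = {s.k for s in seeds}
        if len(ks) != 1:
            raise ValueError("all seeds in a set must share the same k")
        if len({s.mask for s in seeds}) != len(seeds):
            raise ValueError("duplicate seed masks in set")

    @property
    def k(self) -> int:
        return self.seeds[0].k

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    def __iter__(self):
        return iter(self.seeds)

    def __len__(self) -> int:
        return len(self.seeds)


@dataclass
class GAConfig:
    """Knobs for the genetic seed designer."""

    population_size: int = 50
    n_generations: int = 200
    mutation_rate: float = 0.02
    crossover_rate: float = 0.7
    weight_penalty: float = 0.1
    rng_seed: int = 0
    #: Minimum care positions per seed; None -> ceil(2k/3).  Maximizing
    #: detectable patterns alone is degenerate (an all-don't-care block
    #: wins), so specificity is kept by constraint, not just penalty.
    min_weight: int | None = None
    #: Optional cap on runs of consecutive don't-care positions
    #: (None = unconstrained).  Contiguous don't-care blocks turn out to
    #: maximize the objective *and* keep error signatures distinct, so
    #: no cap is applied by default; the knob remains for experiments
    #: with scattered seed layouts.
    max_dc_run: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        for name in ("mutation_rate", "crossover_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.weight_penalty < 0:
            raise ValueError("weight_penalty must be >= 0")


# ---------------------------------------------------------------------------
# Matching and detectability


def seed_matches(seed: SpacedSeed, ref_window: str, query_window: str) -> bool:
    """True iff the two length-k windows agree at every care position."""
    if len(ref_window) != seed.k or len(query_window) != seed.k:
        raise ValueError("windows must have length k")
    return all(ref_window[i] == query_window[i] for i in seed.care_positions)


def detectable_patterns(
    seed_set: SeedSet, max_len: int | None = None
) -> set[tuple[int, ...]]:
    """All mismatch bitmasks of length k detectable by the set.

    A mismatch bitmask is detectable when its mismatch positions are a
    subset of the don't-care positions of at least one seed.  ``max_len``
    caps the span (distance from first to last mismatch, inclusive) of
    the returned masks; by default the full seed span is allowed.  The
    all-zero mask (no mismatch) is always included.
    """
    k = seed_set.k
    if max_len is None:
        max_len = k
    if not 1 <= max_len <= k:
        raise ValueError("max_len must be in [1, k]")
    found: set[tuple[int, ...]] = set()
    zero = (0,) * k
    found.add(zero)
    for seed in seed_set:
        dc = seed.dont_care_positions
        # Enumerate subsets window-by-window so spans stay bounded; for
        # max_len == k this is a single window (the full mask).
        for off in range(0, k - max_len + 1):
            local = [p for p in dc if off <= p < off + max_len]
            for r in range(1, len(local) + 1):
                for combo in itertools.combinations(local, r):
                    if combo[-1] - combo[0] + 1 > max_len:
                        continue
                    m = list(zero)
                    for p in combo:
                        m[p] = 1
                    found.add(tuple(m))
    return found


def ga_fitness(
    seed_set: SeedSet, config: GAConfig, window: int | None = None
) -> float:
    """Detectable-pattern count minus a linear don't-care penalty.

    ``window`` bounds the mismatch span considered (default
    ``min(DEFAULT_WINDOW, k)``, the span the downstream error-pattern
    model operates on).
    """
    k = seed_set.k
    if window is None:
        window = min(DEFAULT_WINDOW, k)
    n_patterns = len(detectable_patterns(seed_set, max_len=window))
    penalty = config.weight_penalty * sum(k - s.weight for s in seed_set)
    return float(n_patterns) - penalty


# ---------------------------------------------------------------------------
# Genetic algorithm

Individual = tuple[tuple[int, ...], ...]  # tuple of masks


def _break_long_runs(mask: list[int], max_run: int | None) -> list[int]:
    if max_run is None:
        return mask
    run = 0
    for i in range(len(mask)):
        if mask[i] == 0:
            run += 1
            if run > max_run:
                mask[i] = 1
                run = 0
        else:
            run = 0
    return mask


def _random_mask(
    k: int,
    rng: np.random.Generator,
    min_weight: int = 2,
    max_run: int = 2,
    p_care: float = 0.75,
) -> tuple[int, ...]:
    while True:
        mask = [1] + [int(rng.random() < p_care) for _ in range(k - 2)] + [1]
        mask = _break_long_runs(mask, max_run)
        if sum(mask) >= min_weight:
            return tuple(mask)


def _ensure_distinct(masks: list[tuple[int, ...]], k: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    seen: set[tuple[int, ...]] = set()
    out = []
    for m in masks:
        while m in seen:
            i = int(rng.integers(1, k - 1))
            mm = list(m)
            mm[i] ^= 1
            m = tuple(mm)
        seen.add(m)
        out.append(m)
    return out


def _mutate(
    mask: tuple[int, ...],
    rate: float,
    rng: np.random.Generator,
    min_weight: int,
    max_run: int,
) -> tuple[int, ...]:
    m = list(mask)
    for i in range(1, len(m) - 1):  # keep anchored ends
        if rng.random() < rate:
            m[i] ^= 1
    m = _break_long_runs(m, max_run)
    if sum(m) < min_weight:
        # Repair: promote random don't-care positions back to care.
        dc = [i for i in range(1, len(m) - 1) if m[i] == 0]
        rng.shuffle(dc)
        for i in dc[: min_weight - sum(m)]:
            m[i] = 1
    return tuple(m)


def _crossover(a: tuple[int, ...], b: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
    return tuple(a[i] if rng.random() < 0.5 else b[i] for i in range(len(a)))


def ga_design(
    k: int,
    n_seeds: int = DEFAULT_N_SEEDS,
    config: GAConfig | None = None,
    window: int | None = None,
    return_history: bool = False,
):
    """Design an anchored seed set of ``n_seeds`` masks of span ``k``.

    Uses tournament selection (size 2), uniform crossover, per-bit
    mutation restricted to interior positions, and elitism of one, so
    the best fitness seen is non-decreasing across generations.  Fully
    reproducible under ``config.rng_seed``.

    Returns the best :class:`SeedSet`; with ``return_history=True``
    returns ``(seed_set, best_fitness_per_generation)``.
    """
    if k < 5:
        raise ValueError("k must be >= 5")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if config is None:
        config = GAConfig()
    rng = np.random.default_rng(config.rng_seed)
    min_weight = config.min_weight
    if min_weight is None:
        min_weight = max(2, -(-2 * k // 3))  # ceil(2k/3)
    if min_weight > k:
        raise ValueError("min_weight exceeds k")
    cache: dict[Individual, float] = {}

    def fitness(ind: Individual) -> float:
        if ind not in cache:
            sset = SeedSet(tuple(SpacedSeed(m) for m in ind))
            cache[ind] = ga_fitness(sset, config, window=window)
        return cache[ind]

    max_run = config.max_dc_run

    def make_individual() -> Individual:
        masks = [_random_mask(k, rng, min_weight, max_run) for _ in range(n_seeds)]
        return tuple(_ensure_distinct(masks, k, rng))

    pop = [make_individual() for _ in range(config.population_size)]
    best = max(pop, key=fitness)
    history = [fitness(best)]

    for _ in range(config.n_generations):
        new_pop: list[Individual] = [best]  # elitism
        while len(new_pop) < config.population_size:
            # Tournament selection of size 2, twice.
            parents = []
            for _ in range(2):
                i, j = rng.integers(0, len(pop), size=2)
                parents.append(max((pop[int(i)], pop[int(j)]), key=fitness))
            pa, pb = parents
            if rng.random() < config.crossover_rate:
                child = tuple(
                    _crossover(ma, mb, rng) for ma, mb in zip(pa, pb)
                )
            else:
                child = pa
            child = tuple(
                _mutate(m, config.mutation_rate, rng, min_weight, max_run)
                for m in child
            )
            child = tuple(
                m if sum(m) >= min_weight
                else _random_mask(k, rng, min_weight, max_run)
                for m in child
            )
            child = tuple(_ensure_distinct(list(child), k, rng))
            new_pop.append(child)
        pop = new_pop
        cand = max(pop, key=fitness)
        if fitness(cand) > fitness(best):
            best = cand
        history.append(fitness(best))

    result = SeedSet(tuple(SpacedSeed(m) for m in best))
    if return_history:
        return result, history
    return result


# ---------------------------------------------------------------------------
# Seed-set file I/O (plain text: header "#k=<int>", one 0/1 mask per line)


def write_seed_set(seed_set: SeedSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k={seed_set.k}\n")
        for seed in seed_set:
            fh.write(str(seed) + "\n")


def read_seed_set(path) -> SeedSet:
    seeds: list[SpacedSeed] = []
    k = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#k="):
                    k = int(line[3:])
                continue
            seeds.append(SpacedSeed.from_string(line))
    sset = SeedSet(tuple(seeds))
    if k is not None and sset.k != k:
        raise ValueError(f"header k={k} disagrees with mask length {sset.k}")
    return sset
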