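"""Error-pattern classification from spaced-seed match signals.

The classifier never sees raw sequence content.  Its two inputs are:

* ``S`` — the seed-structure tensor, shape ``(k, n_seeds)``, with
  ``S[i, j] = 1`` when base ``i`` of seed ``j`` is a care position; and
* ``X`` — the context tensor for a suspect region, shape
  ``(L, 1 + n_seeds * (w + 1))``.  Column 0 flags homopolymer positions
  (base identical to its predecessor).  Column ``1 + j*(w+1) + g``
  holds the membership of seed ``j`` at each placement after a gap of
  ``g`` bases is hypothesised at the region start — either ``g``
  wildcards inserted (re-aligning a region missing ``g`` bases; a
  wildcard matches only on don't-care positions) or ``g`` region bases
  removed (re-aligning one with ``g`` surplus bases).  Either way an
  indel lights up the column of its true length, which is what lets
  the model see indels in both directions.

Labels enumerate compact edit signatures: a mismatch bitmask over a
window of ``w`` draft bases plus at most one indel of length <= ``w``
anchored at the region start.  The indel is applied first; the mask
then marks the first ``w`` retained draft bases at the anchor, so every
(mask, indel) combination has a distinct corruption signature.

Training data is synthesized under ideal conditions: a truth substring
is corrupted by a known label, and membership bits are computed against
the exact set of the truth's seed projections (no Bloom filter).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._nn import AdamW, TwoEncoderClassifier
from .index import ConfidenceIndex, reverse_complement
from .regions import ErrorRegion
from .seeds import SeedSet

log = logging.getLogger(__name__)

GAP_CHAR = "#"
DEFAULT_W = 5
_BASES = "ACGT"


class EncodingError(ValueError):
    """Raised when a region is too short to encode after flank truncation."""


# ---------------------------------------------------------------------------
# Label space


@dataclass(frozen=True)
class ErrorPattern:
    """Edit signature: mismatch mask over w draft bases + one optional indel.

    ``indel`` is ``("none", 0)``, ``("del", d)`` (remove d draft bases at
    the anchor) or ``("ins", d)`` (insert d bases at the anchor).
    """

    mismatch_mask: tuple[int, ...]
    indel: tuple[str, int] = ("none", 0)

    def __post_init__(self) -> None:
        kind, d = self.indel
        w = len(self.mismatch_mask)
        if kind not in ("none", "del", "ins"):
            raise ValueError(f"bad indel kind {kind!r}")
        if kind == "none" and d != 0:
            raise ValueError("indel 'none' must have length 0")
        if kind != "none" and not 1 <= d <= w:
            raise ValueError("indel length must be in [1, w]")

    @property
    def w(self) -> int:
        return len(self.mismatch_mask)

    @property
    def is_noop(self) -> bool:
        return self.indel[0] == "none" and not any(self.mismatch_mask)

    @property
    def label_id(self) -> int:
        return pattern_to_label(self)


def _indel_index(indel: tuple[str, int], w: int) -> int:
    kind, d = indel
    if kind == "none":
        return 0
    if kind == "del":
        return d
    return w + d


def pattern_to_label(pattern: ErrorPattern) -> int:
    w = pattern.w
    mask_int = sum(b << i for i, b in enumerate(pattern.mismatch_mask))
    return mask_int * (2 * w + 1) + _indel_index(pattern.indel, w)


def label_to_pattern(label_id: int, w: int) -> ErrorPattern:
    n_indel = 2 * w + 1
    mask_int, idx = divmod(label_id, n_indel)
    mask = tuple((mask_int >> i) & 1 for i in range(w))
    if idx == 0:
        indel = ("none", 0)
    elif idx <= w:
        indel = ("del", idx)
    else:
        indel = ("ins", idx - w)
    return ErrorPattern(mask, indel)


def n_labels(w: int) -> int:
    return (2**w) * (2 * w + 1)


def enumerate_label_space(w: int) -> list[ErrorPattern]:
    """All patterns in stable label_id order; label 0 is the no-edit pattern."""
    if w < 1:
        raise ValueError("w must be >= 1")
    return [label_to_pattern(i, w) for i in range(n_labels(w))]


# ---------------------------------------------------------------------------
# Tensor encodings


def encode_seed_structure(seed_set: SeedSet) -> np.ndarray:
    """S tensor: (k, n_seeds) binary; column sums equal seed weights."""
    S = np.zeros((seed_set.k, seed_set.n_seeds), dtype=np.float64)
    for j, seed in enumerate(seed_set):
        for i in seed.care_positions:
            S[i, j] = 1.0
    return S


def homopolymer_flags(seq: str) -> np.ndarray:
    flags = np.zeros(len(seq))
    for i in range(1, len(seq)):
        if seq[i] == seq[i - 1] and seq[i] != GAP_CHAR:
            flags[i] = 1.0
    return flags


MemberFn = Callable[[int, str], bool]


def encode_context(
    seq: str,
    region_offset: int,
    seed_set: SeedSet,
    w: int,
    member: MemberFn,
) -> np.ndarray:
    """Context tensor X for ``seq`` with the suspect region at ``region_offset``.

    ``member(seed_id, window)`` answers spaced-seed membership; during
    polishing this is the Bloom-filter index, during training synthesis
    an exact set of the truth's projections.
    """
    k = seed_set.k
    n_seeds = seed_set.n_seeds
    # Rows index seed placements (window start positions), of which the
    # ungapped sequence has len - k + 1; every row therefore carries a
    # real membership decision rather than padding.
    L = len(seq) - k + 1
    if L < 1:
        raise EncodingError("sequence shorter than k")
    X = np.zeros((L, 1 + n_seeds * (w + 1)))
    X[:, 0] = homopolymer_flags(seq)[:L]
    # The gap of g bases is hypothesised on either side of the alignment:
    # g wildcards inserted at the region start re-align a region that is
    # missing g bases, while removing g region bases re-aligns one that
    # carries g surplus bases.  A membership bit is set when the seed
    # matches under either hypothesis, so both indel directions produce
    # a bright column at their true length.
    for g in range(w + 1):
        gap_ins = seq[:region_offset] + GAP_CHAR * g + seq[region_offset:]
        gap_del = seq[:region_offset] + seq[region_offset + g :]
        for j in range(n_seeds):
            col = 1 + j * (w + 1) + g
            for i in range(L):
                if i + k <= len(gap_ins) and member(j, gap_ins[i : i + k]):
                    X[i, col] = 1.0
                elif g and i + k <= len(gap_del) and member(j, gap_del[i : i + k]):
                    X[i, col] = 1.0
    return X


def encode_region_context(
    region: ErrorRegion,
    index: ConfidenceIndex,
    w: int,
    anchor_shift: int = 0,
) -> np.ndarray:
    """Standardized context tensor for a scanned region.

    The window of ``w`` draft bases anchored at the region start (plus
    ``anchor_shift``) is framed by up to ``k - 1`` flanking bases on
    each side, matching the geometry of the synthesized training data.
    """
    k = index.k
    seq_all = (
        region.left_flank + region.sequence + region.right_flank + region.right_ext
    )
    anchor = len(region.left_flank) + anchor_shift
    lo = max(0, anchor - (k - 1))
    hi = min(len(seq_all), anchor + w + (k - 1))
    ctx = seq_all[lo:hi]
    if len(ctx) < k:
        raise EncodingError(
            f"region {region.contig_id}:{region.start}-{region.end} too short to encode"
        )
    return encode_context(ctx, anchor - lo, index.seed_set, w, index.has_seed)


# ---------------------------------------------------------------------------
# Ideal membership (training synthesis)


def make_ideal_member_fn(truth_seq: str, seed_set: SeedSet) -> MemberFn:
    """Exact spaced-seed membership over a truth sequence (no Bloom filter)."""
    k = seed_set.k
    cares = [s.care_positions for s in seed_set]
    sets: list[set[str]] = [set() for _ in seed_set]
    rc = reverse_complement(truth_seq)
    n = len(truth_seq)
    for i in range(n - k + 1):
        fwd = truth_seq[i : i + k]
        rev = rc[n - k - i : n - i]
        for j, care in enumerate(cares):
            sets[j].add("".join(fwd[p] for p in care))
            sets[j].add("".join(rev[p] for p in care))

    def member(seed_id: int, window: str) -> bool:
        care = cares[seed_id]
        proj = [window[p] for p in care]
        if GAP_CHAR in proj:
            return False
        if "".join(proj) in sets[seed_id]:
            return True
        wrc = reverse_complement(window)
        proj_rc = [wrc[p] for p in care]
        if GAP_CHAR in proj_rc:
            return False
        return "".join(proj_rc) in sets[seed_id]

    return member


# ---------------------------------------------------------------------------
# Training-set synthesis


@dataclass
class SampleGroup:
    """Samples sharing one seed set (hence one S tensor and one shape)."""

    S: np.ndarray  # (k, n_seeds)
    X: np.ndarray  # (N, L, n_feat)
    y: np.ndarray  # (N,)


@dataclass
class TrainingSet:
    groups: list[SampleGroup]
    w: int

    @property
    def n_samples(self) -> int:
        return sum(len(g.y) for g in self.groups)


def _substitute(rng: np.random.Generator, base: str) -> str:
    alts = [b for b in _BASES if b != base]
    return alts[int(rng.integers(0, 3))]


def corrupt_by_pattern(
    truth: str, anchor: int, pattern: ErrorPattern, rng: np.random.Generator
) -> str:
    """Apply the inverse of ``pattern`` to a truth string to make a draft.

    Applying ``pattern`` (as an edit) to the returned draft at the same
    anchor restores ``truth``.
    """
    kind, d = pattern.indel
    if kind == "del":
        # Draft carries d extra (random) bases at the anchor; the mask
        # marks post-deletion positions, i.e. truth coordinates.
        tail = list(truth[anchor:])
        for j, bit in enumerate(pattern.mismatch_mask):
            if bit:
                tail[j] = _substitute(rng, tail[j])
        junk = "".join(_BASES[int(rng.integers(0, 4))] for _ in range(d))
        return truth[:anchor] + junk + "".join(tail)
    if kind == "ins":
        # Draft is missing d truth bases at the anchor; the mask marks
        # the first w retained draft bases, i.e. truth[anchor+d ...].
        tail = list(truth[anchor + d :])
        for j, bit in enumerate(pattern.mismatch_mask):
            if bit:
                tail[j] = _substitute(rng, tail[j])
        return truth[:anchor] + "".join(tail)
    tail = list(truth[anchor:])
    for j, bit in enumerate(pattern.mismatch_mask):
        if bit:
            tail[j] = _substitute(rng, tail[j])
    return truth[:anchor] + "".join(tail)


def synthesize_training_set(
    references: Sequence[str],
    seed_sets: Sequence[SeedSet],
    w: int = DEFAULT_W,
    n_samples: int = 20_000,
    rng_seed: int = 0,
) -> TrainingSet:
    """Class-balanced ideal samples over the given seed sets.

    Every sample draws a seed set uniformly, a truth substring from a
    random reference, corrupts it with one enumerated label, and encodes
    the context tensor against the truth's exact projections.
    """
    rng = np.random.default_rng(rng_seed)
    labels = enumerate_label_space(w)
    C = len(labels)
    per_label = [n_samples // C + (1 if i < n_samples % C else 0) for i in range(C)]
    ks = {ss.k for ss in seed_sets}
    min_len = 3 * max(ks)
    for ref in references:
        if len(ref) < min_len:
            raise ValueError("reference too short to draw substrings")

    # Collect per-seed-set sample lists.
    per_set_X: list[list[np.ndarray]] = [[] for _ in seed_sets]
    per_set_y: list[list[int]] = [[] for _ in seed_sets]
    jobs = []
    for lbl_id, n in enumerate(per_label):
        jobs.extend([lbl_id] * n)
    set_choice = rng.integers(0, len(seed_sets), size=len(jobs))
    for job_i, lbl_id in enumerate(jobs):
        si = int(set_choice[job_i])
        sset = seed_sets[si]
        k = sset.k
        tlen = 2 * (k - 1) + 2 * w
        ref = references[int(rng.integers(0, len(references)))]
        start = int(rng.integers(0, len(ref) - tlen + 1))
        truth = ref[start : start + tlen]
        anchor = k - 1
        pattern = labels[lbl_id]
        draft = corrupt_by_pattern(truth, anchor, pattern, rng)
        ctx = draft[: anchor + w + (k - 1)]
        member = make_ideal_member_fn(truth, sset)
        X = encode_context(ctx, anchor, sset, w, member)
        per_set_X[si].append(X)
        per_set_y[si].append(lbl_id)

    groups = []
    for si, sset in enumerate(seed_sets):
        if not per_set_y[si]:
            continue
        L = max(x.shape[0] for x in per_set_X[si])
        N = len(per_set_y[si])
        F = per_set_X[si][0].shape[1]
        X = np.zeros((N, L, F))
        for i, x in enumerate(per_set_X[si]):
            X[i, : x.shape[0], :] = x
        groups.append(
            SampleGroup(
                S=encode_seed_structure(sset),
                X=X,
                y=np.asarray(per_set_y[si], dtype=np.int64),
            )
        )
    return TrainingSet(groups, w)


# ---------------------------------------------------------------------------
# Training and inference


@dataclass
class ModelConfig:
    hidden_size: int = 32
    learning_rate: float = 0.001
    n_epochs: int = 100
    rng_seed: int = 0
    w: int = DEFAULT_W
    batch_size: int = 8
    weight_decay: float = 0.0
    #: Randomly permute seed order (S columns together with the X
    #: membership column blocks) per batch; the task is symmetric under
    #: seed reordering, and exposing that symmetry improves transfer to
    #: unseen seed sets.
    augment_permutations: bool = True
    #: Cosine decay of the learning rate from its initial value to 10%
    #: over the training run.
    lr_decay: bool = True
    #: Bloom-filter false positives can only flip membership bits from
    #: 0 to 1.  When positive, each batch applies such flips at a rate
    #: drawn uniformly from [0, augment_fp_noise].  Off by default: it
    #: trades clean-filter accuracy for noise tolerance, and the
    #: corrector's support-gated search already absorbs filter noise.
    augment_fp_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


@dataclass
class PatternModel:
    """A trained classifier plus the conventions it was trained under."""

    net: TwoEncoderClassifier
    config: ModelConfig
    n_seeds: int
    history: list[dict] = field(default_factory=list)

    @property
    def w(self) -> int:
        return self.config.w

    def predict_proba(self, S: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Softmax confidences over the label space for one region."""
        return self.net.predict_proba(S[None, :, :], X[None, :, :])[0]

    # -- checkpointing (JSON, versioned) ---------------------------------
    def save(self, path) -> None:
        payload = {
            "format_version": 1,
            "config": {
                "hidden_size": self.config.hidden_size,
                "learning_rate": self.config.learning_rate,
                "n_epochs": self.config.n_epochs,
                "rng_seed": self.config.rng_seed,
                "w": self.config.w,
                "batch_size": self.config.batch_size,
                "weight_decay": self.config.weight_decay,
            },
            "n_seeds": self.n_seeds,
            "params": {
                k: v.tolist() for k, v in self.net.named_params().items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PatternModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != 1:
            raise ValueError("unsupported model format")
        config = ModelConfig(**payload["config"])
        n_seeds = payload["n_seeds"]
        net = TwoEncoderClassifier(
            n_in_s=n_seeds,
            n_in_x=1 + n_seeds * (config.w + 1),
            hidden=config.hidden_size,
            n_labels=n_labels(config.w),
            rng=np.random.default_rng(0),
        )
        net.set_params({k: np.asarray(v) for k, v in payload["params"].items()})
        return cls(net=net, config=config, n_seeds=n_seeds)


def _iter_batches(ts: TrainingSet, batch_size: int, rng: np.random.Generator):
    """Batches within one seed-set group, groups interleaved at random."""
    batches = []
    for gi, g in enumerate(ts.groups):
        order = rng.permutation(len(g.y))
        for i in range(0, len(order), batch_size):
            batches.append((gi, order[i : i + batch_size]))
    for bi in rng.permutation(len(batches)):
        yield batches[int(bi)]


def _evaluate(net: TwoEncoderClassifier, ts: TrainingSet, batch_size: int = 256):
    """Mean loss and top-1 accuracy over a dataset."""
    total_loss = 0.0
    correct = 0
    n = 0
    for g in ts.groups:
        N = len(g.y)
        Sb_full = np.broadcast_to(g.S, (batch_size, *g.S.shape))
        for i in range(0, N, batch_size):
            y = g.y[i : i + batch_size]
            B = len(y)
            Sb = np.ascontiguousarray(Sb_full[:B])
            lg, _ = net.logits(Sb, g.X[i : i + B])
            lg = lg - lg.max(axis=1, keepdims=True)
            e = np.exp(lg)
            p = e / e.sum(axis=1, keepdims=True)
            total_loss -= np.log(np.maximum(p[np.arange(B), y], 1e-12)).sum()
            correct += int((p.argmax(axis=1) == y).sum())
            n += B
    return total_loss / n, correct / n


def train_model(
    dataset: TrainingSet,
    config: ModelConfig | None = None,
    validation: TrainingSet | None = None,
) -> PatternModel:
    """Train the two-encoder classifier with AdamW / cross-entropy.

    When a validation set is given, the parameters with the highest
    validation accuracy across epochs are returned.  Raises on
    non-finite loss (divergence).
    """
    if config is None:
        config = ModelConfig()
    if not dataset.groups:
        raise ValueError("empty dataset")
    if len(set(np.concatenate([g.y for g in dataset.groups]))) < 2:
        raise ValueError("dataset needs >= 2 distinct labels")
    n_seeds = dataset.groups[0].S.shape[1]
    rng = np.random.default_rng(config.rng_seed)
    net = TwoEncoderClassifier(
        n_in_s=n_seeds,
        n_in_x=1 + n_seeds * (config.w + 1),
        hidden=config.hidden_size,
        n_labels=n_labels(config.w),
        rng=rng,
    )
    opt = AdamW(
        net.named_params(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    w = config.w
    history: list[dict] = []
    best_acc = -1.0
    best_params = None
    for epoch in range(1, config.n_epochs + 1):
        if config.lr_decay:
            frac = (epoch - 1) / max(1, config.n_epochs - 1)
            opt.lr = config.learning_rate * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac)))
        losses = []
        for gi, idx in _iter_batches(dataset, config.batch_size, rng):
            g = dataset.groups[gi]
            B = len(idx)
            S, Xb = g.S, g.X[idx]
            if config.augment_fp_noise > 0:
                rate = rng.uniform(0, config.augment_fp_noise)
                if rate > 0:
                    flips = rng.random(Xb.shape) < rate
                    flips[:, :, 0] = False  # homopolymer column is exact
                    Xb = np.where(flips, 1.0, Xb)
            if config.augment_permutations and n_seeds > 1:
                perm = rng.permutation(n_seeds)
                if not np.array_equal(perm, np.arange(n_seeds)):
                    S = S[:, perm]
                    cols = [0] + [
                        1 + j * (w + 1) + gg for j in perm for gg in range(w + 1)
                    ]
                    Xb = np.ascontiguousarray(Xb[:, :, cols])
            Sb = np.ascontiguousarray(np.broadcast_to(S, (B, *S.shape)))
            loss, grads = net.loss_and_grads(Sb, Xb, g.y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            opt.step(grads)
            losses.append(loss)
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if validation is not None:
            val_loss, val_acc = _evaluate(net, validation)
            rec["val_loss"] = float(val_loss)
            rec["val_acc"] = float(val_acc)
            if val_acc > best_acc:
                best_acc = val_acc
                best_params = net.copy_params()
        history.append(rec)
        log.info("epoch %d: %s", epoch, rec)
    if best_params is not None:
        net.set_params(best_params)
    return PatternModel(net=net, config=config, n_seeds=n_seeds, history=history)


def predict_patterns(
    model: PatternModel, S: np.ndarray, X: np.ndarray, T: int = 3
) -> list[tuple[ErrorPattern, float]]:
    """Top-T patterns by softmax confidence, descending; ties by label id."""
    if T < 1:
        raise ValueError("T must be >= 1")
    proba = model.predict_proba(S, X)
    order = np.lexsort((np.arange(len(proba)), -proba))[:T]
    return [(label_to_pattern(int(i), model.w), float(proba[i])) for i in order]


def train_default_model(
    references: Sequence[str],
    k: int = 35,
    w: int = DEFAULT_W,
    n_train_sets: int = 40,
    n_val_sets: int = 2,
    n_samples: int = 20_000,
    n_epochs: int = 30,
    rng_seed: int = 0,
    ga_generations: int = 60,
    hidden_size: int = 32,
    learning_rate: float = 0.001,
):
    """Design seed sets, synthesize ideal samples, and train the classifier.

    Training seed sets vary in minimum weight to diversify the match
    structures the model sees; validation seed sets are held out
    entirely (the generalization the polisher depends on is across seed
    sets, not substrings).  Returns ``(model, train_sets, val_sets,
    val_dataset)``.
    """
    from .seeds import GAConfig, ga_design

    base = (rng_seed % 100_000) * 1000
    train_sets = []
    for i in range(n_train_sets):
        mw = (22 * k // 35, 24 * k // 35, 26 * k // 35)[i % 3]
        cfg = GAConfig(
            n_generations=ga_generations,
            rng_seed=base + i,
            min_weight=max(2, mw),
        )
        train_sets.append(ga_design(k, 3, cfg))
    val_sets = [
        ga_design(
            k, 3, GAConfig(n_generations=ga_generations, rng_seed=base + 500 + i)
        )
        for i in range(n_val_sets)
    ]
    train_ds = synthesize_training_set(
        references, train_sets, w, n_samples, rng_seed=base + 1
    )
    val_ds = synthesize_training_set(
        references, val_sets, w, max(704, n_samples // 10), rng_seed=base + 2
    )
    config = ModelConfig(
        hidden_size=hidden_size,
        learning_rate=learning_rate,
        n_epochs=n_epochs,
        rng_seed=rng_seed,
        w=w,
    )
    model = train_model(train_ds, config, validation=val_ds)
    return model, train_sets, val_sets, val_ds


def write_history_tsv(model: PatternModel, path) -> None:
    """Training history as TSV (epoch, train_loss, val_loss, val_acc)."""
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\tval_acc\n")
        for rec in model.history:
            fh.write(
                f"{rec['epoch']}\t{rec['train_loss']:.6f}\t"
                f"{rec.get('val_loss', float('nan')):.6f}\t"
                f"{rec.get('val_acc', float('nan')):.6f}\n"
            )
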