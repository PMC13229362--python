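"""End-to-end polishing: index, scan, classify, correct, post-process.

The pipeline counts read k-mers, picks the confidence threshold from
the histogram, builds the Bloom-filter index, scans the draft for
unsupported regions and N-gaps, runs the error-pattern classifier and
support-gated corrector per region, applies accepted edits, and
finally runs a lightweight sparse pass (reusing the same k-mer filter)
that fixes isolated single-base errors the model stage missed.
All edits are reported in a VCF on input-draft coordinates.
"""

from __future__ import annotations

import logging
import time
from bisect import bisect_right
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Mapping

from . import io as spio
from .correct import (
    CorrectionResult,
    VcfRecord,
    correct_region,
    records_from_results,
    resolve_gap,
    emit_vcf,
)
from .index import (
    ConfidenceIndex,
    KmerHistogram,
    build_index_from_counts,
    count_kmer_multiplicities,
    select_threshold,
)
from .model import (
    EncodingError,
    PatternModel,
    encode_region_context,
    encode_seed_structure,
)
from .regions import ErrorRegion, find_error_regions, find_gap_regions
from .seeds import SeedSet

log = logging.getLogger(__name__)


@dataclass
class PolishConfig:
    k: int = 35
    w: int = 5
    T: int = 3
    p: float = 0.5
    fpr: float = 0.001
    threads: int = 1
    rng_seed: int = 0
    model_path: str | None = None
    seed_set_path: str | None = None
    run_post_pass: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must be in (0,1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.k <= self.w:
            raise ValueError("k must exceed w")


@dataclass
class PolishResult:
    polished: dict[str, str]
    records: list[VcfRecord]
    results: list[CorrectionResult]
    report: dict
    index: ConfidenceIndex
    threshold: int


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Edit application and coordinate mapping


def _apply_ops(seq: str, ops: list[tuple[int, str, str, str]]) -> str:
    """Apply non-overlapping ops (draft coords) right-to-left."""
    out = seq
    for pos, kind, ref, alt in sorted(ops, key=lambda o: o[0], reverse=True):
        if kind == "SUB":
            out = out[:pos] + alt + out[pos + 1 :]
        elif kind == "DEL":
            out = out[:pos] + out[pos + len(ref) :]
        elif kind == "INS":
            out = out[:pos] + alt + out[pos:]
        elif kind == "GAP":
            out = out[:pos] + alt + out[pos + len(ref) :]
        else:
            raise ValueError(kind)
    return out


class _CoordMap:
    """Maps positions on an edited contig back to input-draft positions."""

    def __init__(self, ops: list[tuple[int, str, str, str]]):
        self.segs: list[tuple[int, int, int]] = []  # (edited_start, edited_end, shift)
        shift = 0
        for pos, kind, ref, alt in sorted(ops, key=lambda o: o[0]):
            if kind == "SUB":
                continue
            len_ref = len(ref) if kind != "INS" else 0
            len_alt = len(alt) if kind != "DEL" else 0
            e_start = pos + shift
            self.segs.append((e_start, e_start + len_alt, shift))
            shift += len_alt - len_ref
        self.final_shift = shift
        self._starts = [s for s, _, _ in self.segs]

    def to_draft(self, edited_pos: int) -> int | None:
        """Draft position, or None inside a replaced segment (ambiguous)."""
        i = bisect_right(self._starts, edited_pos) - 1
        if i < 0:
            return edited_pos
        e_start, e_end, shift = self.segs[i]
        if edited_pos < e_end:
            return None
        # shift *after* segment i
        len_alt = e_end - e_start
        next_shift = self.segs[i + 1][2] if i + 1 < len(self.segs) else self.final_shift
        return edited_pos - next_shift


# ---------------------------------------------------------------------------
# Sparse post-pass


def sparse_post_pass(
    assembly: Mapping[str, str], index: ConfidenceIndex
) -> tuple[dict[str, str], dict[str, list[tuple[int, str, str, str]]]]:
    """Fix isolated errors left after the model stage.

    For every remaining maximal unsupported run spanning <= k window
    starts, each draft position in the windows' intersection is tried
    with every single-base substitution, insertion and deletion; an
    edit is applied only when it is the unique fix that makes all
    covering k-mers supported.  Ambiguous or unfixable sites stay
    unchanged.  Returns the edited assembly and per-contig ops in the
    *input* (this function's input) coordinates.
    """
    k = index.k
    polished: dict[str, str] = {}
    all_ops: dict[str, list[tuple[int, str, str, str]]] = {}
    for contig_id, seq in assembly.items():
        n_win = len(seq) - k + 1
        if n_win < 1:
            polished[contig_id] = seq
            continue
        supported = [index.has_kmer(seq[i : i + k]) for i in range(n_win)]
        ops: list[tuple[int, str, str, str]] = []
        i = 0
        while i < n_win:
            if supported[i]:
                i += 1
                continue
            j = i
            while j + 1 < n_win and not supported[j + 1]:
                j += 1
            span = j - i + 1
            if span <= k:
                op = _fix_site(seq, i, j, k, index)
                if op is not None:
                    ops.append(op)
            i = j + 1
        if ops:
            # Drop overlapping fixes (left-most wins) before applying.
            ops.sort(key=lambda o: o[0])
            pruned = [ops[0]]
            for op in ops[1:]:
                if op[0] > pruned[-1][0] + max(1, len(pruned[-1][2])):
                    pruned.append(op)
            polished[contig_id] = _apply_ops(seq, pruned)
            all_ops[contig_id] = pruned
        else:
            polished[contig_id] = seq
            all_ops[contig_id] = []
    return polished, all_ops


def _fix_site(
    seq: str, first: int, last: int, k: int, index: ConfidenceIndex
) -> tuple[int, str, str, str] | None:
    """Unique single-base fix for an unsupported run, else None."""
    lo_pos = max(0, last)
    hi_pos = min(len(seq), first + k)
    # One fixed evaluation window for every candidate, so edits with the
    # same net effect (homopolymer indels at shifted offsets) deduplicate.
    local_lo = max(0, lo_pos - k)
    local_hi = min(len(seq), hi_pos + k)
    local = seq[local_lo:local_hi]
    fixes: dict[str, tuple[int, str, str, str]] = {}
    for pos in range(lo_pos, hi_pos):
        ref = seq[pos]
        rel = pos - local_lo
        cands: list[tuple[int, str, str, str]] = []
        cands.extend((pos, "SUB", ref, b) for b in "ACGT" if b != ref)
        cands.append((pos, "DEL", ref, ""))
        cands.extend((pos, "INS", "", b) for b in "ACGT")
        for op in cands:
            edited = _apply_ops(local, [(rel, op[1], op[2], op[3])])
            if len(edited) < k or edited in fixes:
                continue
            if all(
                index.has_kmer(edited[t : t + k])
                for t in range(len(edited) - k + 1)
            ):
                fixes[edited] = op
    if len(fixes) == 1:
        return next(iter(fixes.values()))
    return None


# ---------------------------------------------------------------------------
# Main pipeline


#: Anchor shifts at which the classifier is consulted per region.
PREDICT_SHIFTS = (0, -1, 1)

#: Max relaxed-mask fallback candidates per region.
MAX_FALLBACKS = 4


def rank_candidates(
    region: ErrorRegion,
    index: ConfidenceIndex,
    model: PatternModel,
    S,
    config: PolishConfig,
):
    """Ranked primary patterns and relaxed-mask fallbacks for a region.

    The classifier is consulted at slightly shifted anchors (scanned
    region boundaries are inexact); per pattern the best confidence
    across shifts is kept and the top T become the primary candidates.
    Because indel type and length are predicted far more reliably than
    individual mask bits, an all-ones-mask variant of each distinct
    indel seen near the top of the ranking is prepared as a fallback —
    its placeholder resolution can recover any mask configuration, at
    the price of a wider search.
    """
    import numpy as np

    from .model import label_to_pattern

    cands: dict[tuple, tuple] = {}
    for shift in PREDICT_SHIFTS:
        try:
            X = encode_region_context(region, index, config.w, anchor_shift=shift)
        except EncodingError:
            continue
        proba = model.predict_proba(S, X)
        for i in np.argsort(-proba)[: max(10, config.T)]:
            pat = label_to_pattern(int(i), config.w)
            conf = float(proba[i])
            key = (pat.mismatch_mask, pat.indel)
            if key not in cands or conf > cands[key][1]:
                cands[key] = (pat, conf)
    ranked_all = sorted(cands.values(), key=lambda pc: -pc[1])
    primary = ranked_all[: config.T]
    primary_keys = [(p.mismatch_mask, p.indel) for p, _ in primary]
    ones = (1,) * config.w
    fallbacks = []
    seen_indels: list[tuple] = []
    from .model import ErrorPattern as _EP

    for pat, conf in ranked_all[: max(10, config.T)]:
        if pat.indel in seen_indels:
            continue
        seen_indels.append(pat.indel)
        if len(fallbacks) < MAX_FALLBACKS and (ones, pat.indel) not in primary_keys:
            fallbacks.append((_EP(ones, pat.indel), conf * 0.5))
    return primary, fallbacks


def _process_region(
    region: ErrorRegion,
    index: ConfidenceIndex,
    model: PatternModel,
    S,
    config: PolishConfig,
) -> CorrectionResult:
    from .index import CachedIndex

    cached = CachedIndex(index)
    if region.is_gap:
        return resolve_gap(region, cached, config.p, config.w)
    primary, fallbacks = rank_candidates(region, cached, model, S, config)
    if not primary:
        log.info("region %s:%d-%d too short to encode; skipped",
                 region.contig_id, region.start, region.end)
        return CorrectionResult(region=region, status="filtered")
    result = correct_region(region, primary, cached, config.p)
    if result.status != "edited" and fallbacks:
        fb = correct_region(region, fallbacks, cached, config.p)
        if fb.status == "edited":
            return fb
    if result.status != "edited":
        # Last resort: the complete relaxed family (all-ones mask with
        # every indel state not already tried).  The classifier's job
        # is ranking and speed; this bounded sweep makes correction
        # complete when its predictions fail, and the support gate
        # still rejects anything unsupported by the reads.
        from .model import ErrorPattern as _EP

        ones = (1,) * config.w
        tried = {p.indel for p, _ in fallbacks} | {
            p.indel for p, _ in primary if p.mismatch_mask == ones
        }
        sweep = []
        for indel in (
            [("none", 0)]
            + [("del", d) for d in range(1, config.w + 1)]
            + [("ins", d) for d in range(1, config.w + 1)]
        ):
            if indel not in tried:
                sweep.append((_EP(ones, indel), 0.0))
        if sweep:
            # The sweep was not ranked by the model, so it must clear a
            # stricter bar: a real error resolves to near-full support,
            # while a coverage dropout (e.g. a contig end) offers no
            # assignment the reads actually confirm.
            fb = correct_region(region, sweep, cached, max(config.p, 0.8))
            if fb.status == "edited":
                return fb
    return result


def polish(
    draft: Mapping[str, str] | str,
    reads: Iterable[str] | str,
    config: PolishConfig,
    model: PatternModel | None = None,
    seed_set: SeedSet | None = None,
    counts: Mapping[str, int] | None = None,
    index: ConfidenceIndex | None = None,
) -> PolishResult:
    """Polish a draft assembly against a read set.

    ``draft``/``reads`` may be file paths or in-memory collections.
    ``model`` and ``seed_set`` default to the paths in ``config``;
    precomputed ``counts`` or a prebuilt ``index`` short-circuit the
    counting stage (used when polishing repeatedly at one k).
    """
    t0 = time.monotonic()
    report: dict = {"stages": {}}
    if isinstance(draft, str):
        draft = spio.read_fasta(draft)
    draft = {name: seq.upper() for name, seq in draft.items()}

    if model is None:
        if config.model_path is None:
            raise ConfigurationError("a trained model (or model_path) is required")
        model = PatternModel.load(config.model_path)
    if seed_set is None:
        if config.seed_set_path is None:
            raise ConfigurationError("a seed set (or seed_set_path) is required")
        from .seeds import read_seed_set

        seed_set = read_seed_set(config.seed_set_path)
    if seed_set.k != config.k:
        raise ConfigurationError(
            f"seed set k={seed_set.k} incompatible with configured k={config.k}"
        )
    if model.w != config.w or model.n_seeds != seed_set.n_seeds:
        raise ConfigurationError("model window/seed-count incompatible with config")

    # Stage 1-2: counting, thresholding, index construction.
    threshold = None
    if index is None:
        if counts is None:
            read_iter = spio.iter_reads(reads) if isinstance(reads, str) else reads
            counts = count_kmer_multiplicities(read_iter, config.k)
        hist_counts: dict[int, int] = {}
        for c in counts.values():
            hist_counts[min(c, 10_000)] = hist_counts.get(min(c, 10_000), 0) + 1
        threshold = select_threshold(KmerHistogram(hist_counts, config.k))
        index = build_index_from_counts(counts, config.k, seed_set, threshold, config.fpr)
    else:
        threshold = index.threshold
    report["threshold"] = threshold
    report["stages"]["index"] = time.monotonic() - t0
    t1 = time.monotonic()

    # Stage 3: region location.
    gap_regions = find_gap_regions(draft, max_gap=config.w, k=config.k)
    error_regions = find_error_regions(draft, index)
    regions = sorted(
        gap_regions + error_regions,
        key=lambda r: (list(draft).index(r.contig_id), r.start),
    )
    report["n_regions"] = len(regions)
    report["stages"]["scan"] = time.monotonic() - t1
    t2 = time.monotonic()

    # Stage 4: classify and correct. Ordered merge keeps the output
    # independent of the worker count.
    S = encode_seed_structure(seed_set)
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(
                pool.map(
                    lambda r: _process_region(r, index, model, S, config), regions
                )
            )
    else:
        results = [_process_region(r, index, model, S, config) for r in regions]
    report["stages"]["correct"] = time.monotonic() - t2
    t3 = time.monotonic()

    # Apply accepted edits (drop any overlapping a previously applied one).
    per_contig_ops: dict[str, list[tuple[int, str, str, str]]] = {
        name: [] for name in draft
    }
    last_end: dict[str, int] = {}
    for res in results:
        if res.applied is None:
            continue
        contig = res.region.contig_id
        if res.region.start < last_end.get(contig, -1):
            log.warning("overlapping edit at %s:%d dropped", contig, res.region.start)
            res.applied = None
            res.status = "filtered"
            continue
        per_contig_ops[contig].extend(res.applied.ops)
        last_end[contig] = res.region.end
    polished = {
        name: _apply_ops(seq, per_contig_ops[name]) for name, seq in draft.items()
    }
    records = records_from_results(results, dict(draft))

    # Stage 5: sparse post-pass, reusing the k-mer filter.
    n_post = 0
    if config.run_post_pass:
        polished, post_ops = sparse_post_pass(polished, index)
        for contig, ops in post_ops.items():
            cmap = _CoordMap(per_contig_ops[contig])
            for pos, kind, ref, alt in ops:
                dpos = cmap.to_draft(pos)
                if dpos is None:
                    log.info("post-pass edit at %s:%d inside a model edit; "
                             "not representable on draft coordinates", contig, pos)
                    continue
                from .correct import _op_to_record

                try:
                    rec = _op_to_record(
                        contig, draft[contig], (dpos, kind, ref, alt), {"STAGE": "post"}
                    )
                except (ValueError, IndexError):
                    log.info("post-pass edit at %s:%d not anchored on draft", contig, pos)
                    continue
                records.append(rec)
                n_post += 1
    report["stages"]["post"] = time.monotonic() - t3
    report["n_edited"] = sum(1 for r in results if r.status == "edited")
    report["n_filtered"] = sum(1 for r in results if r.status == "filtered")
    report["n_gaps_resolved"] = sum(1 for r in results if r.status == "gap_resolved")
    report["n_post_edits"] = n_post
    report["total_time"] = time.monotonic() - t0
    return PolishResult(
        polished=polished,
        records=records,
        results=results,
        report=report,
        index=index,
        threshold=threshold,
    )


def write_outputs(result: PolishResult, draft: Mapping[str, str], prefix: str) -> None:
    """Polished FASTA, VCF, and a TSV run report under ``prefix``."""
    spio.write_fasta(result.polished, f"{prefix}.polished.fa")
    emit_vcf(result.records, dict(draft), f"{prefix}.vcf")
    with open(f"{prefix}.report.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for key in ("threshold", "n_regions", "n_edited", "n_filtered",
                    "n_gaps_resolved", "n_post_edits"):
            fh.write(f"{key}\t{result.report[key]}\n")
        for stage, secs in result.report["stages"].items():
            fh.write(f"time_{stage}_s\t{secs:.2f}\n")
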