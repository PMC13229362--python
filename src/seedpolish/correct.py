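"""Turning ranked error patterns into accepted edits.

Each candidate pattern is applied to the region's context (flanks plus
suspect bases): marked bases are deleted, insertion sites receive
placeholder symbols, and mismatch positions become placeholders whose
alternatives exclude the current draft base.  Placeholders are then
permuted over {A,C,G,T} and every concrete assignment is scored by its
*support ratio* — the fraction of its k-mer windows found in the
high-confidence filter.  The highest-ranking pattern whose best
assignment reaches support >= p and strictly improves on the unedited
region is applied; later acceptable candidates are reported as
potentially heterozygous alternates; regions with no acceptable edit
are recorded as filtered.

Because scanned region boundaries are inexact, every pattern is also
tried at anchors jittered by up to two bases around the region start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .index import ConfidenceIndex
from .model import GAP_CHAR, ErrorPattern
from .regions import ErrorRegion

log = logging.getLogger(__name__)

#: Max placeholders permuted per candidate; the branch-and-bound
#: resolver's evaluation cap keeps worst-case cost bounded.
PLACEHOLDER_BUDGET = 10

#: Heterozygous alternates kept per region in the VCF.
MAX_ALTERNATES = 4

#: Anchor offsets searched around the region start.
ANCHOR_JITTER = (0, -1, 1, -2, 2)

#: Partial assignments kept per placeholder during beam resolution.
BEAM_WIDTH = 16

_BASES = "ACGT"


@dataclass
class CandidateEdit:
    """One concrete resolved edit for a region."""

    pattern: ErrorPattern
    anchor_shift: int
    edited_context: str
    support: float
    ops: list[tuple[int, str, str, str]]  # (draft pos, SUB/INS/DEL/GAP, ref, alt)
    confidence: float = 0.0


@dataclass
class CorrectionResult:
    region: ErrorRegion
    status: str  # edited | filtered | gap_resolved
    applied: CandidateEdit | None = None
    alternates: list[CandidateEdit] = field(default_factory=list)
    base_support: float = 0.0


# ---------------------------------------------------------------------------
# Pattern application


@dataclass
class _Placeholder:
    context_pos: int | None  # None for inserted bases
    choices: str


@dataclass
class _PatternApplication:
    text: str  # context with GAP_CHAR placeholders
    placeholders: list[_Placeholder]
    del_at: int | None = None  # context pos of deletion start
    del_len: int = 0
    ins_at: int | None = None  # context pos insertion precedes
    ins_len: int = 0


def _apply_pattern_meta(
    seq: str, pattern: ErrorPattern, anchor: int
) -> _PatternApplication | None:
    """Apply indel-then-mask to ``seq`` at ``anchor``; None if out of range."""
    if not 0 <= anchor <= len(seq):
        return None
    kind, d = pattern.indel
    placeholders: list[_Placeholder] = []
    prefix = seq[:anchor]
    meta = _PatternApplication(text="", placeholders=placeholders)
    if kind == "del":
        if anchor + d > len(seq):
            return None
        retained_start = anchor + d
        meta.del_at, meta.del_len = anchor, d
        mid = ""
    elif kind == "ins":
        retained_start = anchor
        meta.ins_at, meta.ins_len = anchor, d
        mid = GAP_CHAR * d
        for _ in range(d):
            placeholders.append(_Placeholder(None, _BASES))
    else:
        retained_start = anchor
        mid = ""
    tail = list(seq[retained_start:])
    for j, bit in enumerate(pattern.mismatch_mask):
        if not bit:
            continue
        if j >= len(tail):
            return None  # mask extends past available sequence
        # All four bases are allowed (keeping the draft base is a no-op
        # for that position), which makes correction robust to predicted
        # masks that over-mark positions; strict-improvement acceptance
        # still rejects fully no-op candidates.
        tail[j] = GAP_CHAR
        placeholders.append(_Placeholder(retained_start + j, _BASES))
    # Keep placeholder order equal to text order (insertions precede subs).
    placeholders.sort(key=lambda p: (0, 0) if p.context_pos is None else (1, p.context_pos))
    meta.text = prefix + mid + "".join(tail)
    return meta


def apply_pattern(seq: str, pattern: ErrorPattern, anchor: int = 0) -> str | None:
    """Context with placeholders after applying ``pattern`` at ``anchor``.

    Deleted bases are removed, inserted bases and mismatch positions
    appear as the placeholder symbol.  Returns None when the pattern
    extends past the available sequence.
    """
    meta = _apply_pattern_meta(seq, pattern, anchor)
    return None if meta is None else meta.text


# ---------------------------------------------------------------------------
# Scoring


def support_ratio(sequence: str, index: ConfidenceIndex) -> float:
    """Fraction of the sequence's k-mer windows in the k-mer filter."""
    k = index.k
    n = len(sequence) - k + 1
    if n < 1:
        raise ValueError("sequence shorter than k")
    hits = sum(1 for i in range(n) if index.has_kmer(sequence[i : i + k]))
    return hits / n


def resolve_placeholders(
    text: str,
    index: ConfidenceIndex,
    p: float,
    choices: list[str] | None = None,
) -> tuple[str, float] | None:
    """Best concrete assignment of the placeholders in ``text``.

    Enumerates the per-placeholder alternatives (default {A,C,G,T}) in
    lexicographic order, scores each assignment by support ratio, and
    returns the maximum (first-in-order on ties, hence deterministic).
    Returns None when the best support is below ``p`` or the
    placeholder count exceeds the budget.
    """
    best = _resolve_best(text, choices, index, p=p)
    if best is None or best[1] < p:
        return None
    return best


def _resolve_best(
    text: str,
    choices: list[str] | None,
    index: ConfidenceIndex,
    p: float | None = None,
) -> tuple[str, float] | None:
    """Maximize support over placeholder assignments by beam search.

    Placeholders are assigned left to right; each k-mer window is
    scored as soon as its last placeholder is fixed, and the best
    partial assignments (by miss count, ties by assignment string)
    survive each step.  The true assignment's prefixes carry zero
    genuine misses — the filters have no false negatives — so they
    survive any beam wide enough for the occasional false-positive
    tie.  Deterministic; among equal-support optima the
    lexicographically first is returned.
    """
    n_ph = text.count(GAP_CHAR)
    if choices is None:
        choices = [_BASES] * n_ph
    if len(choices) != n_ph:
        raise ValueError("one choice string per placeholder required")
    if n_ph > PLACEHOLDER_BUDGET:
        log.info("candidate with %d placeholders exceeds budget; rejected", n_ph)
        return None
    k = index.k
    n_windows = len(text) - k + 1
    if n_windows < 1:
        return None
    if n_ph == 0:
        return text, support_ratio(text, index)
    ph_pos = [i for i, c in enumerate(text) if c == GAP_CHAR]
    # Windows grouped by the placeholder that completes them; windows
    # with no placeholder are scored once up front.
    decide: list[list[int]] = [[] for _ in range(n_ph)]
    base_misses = 0
    for s in range(n_windows):
        inside = [pi for pi, p in enumerate(ph_pos) if s <= p < s + k]
        if inside:
            decide[max(inside)].append(s)
        elif not index.has_kmer(text[s : s + k]):
            base_misses += 1

    chars = list(text)
    best_misses = [n_windows + 1]
    best_assign: list[str | None] = [None]
    # Window-evaluation budget; the beam never exceeds this for the
    # supported placeholder count, it is a pure safety net.
    budget = [8000]

    # Beam search over placeholder assignments, left to right.  Every
    # window is scored as soon as its last placeholder is assigned, so
    # a partial assignment's miss count only ever grows; the true
    # assignment's prefixes have zero genuine misses (no false
    # negatives), so they survive any beam wide enough to hold the
    # occasional false-positive tie.  Candidates are ordered by
    # (misses, assignment), making the result deterministic and, among
    # equal-support optima, lexicographically first.
    beam: list[tuple[int, str]] = [(base_misses, "")]
    for pi in range(n_ph):
        last_level = pi == n_ph - 1
        cur_min = n_windows + 1
        nxt: list[tuple[int, str]] = []
        for misses, assign in beam:
            # Restore chars for this partial assignment.
            for pj, b in enumerate(assign):
                chars[ph_pos[pj]] = b
            for pj in range(len(assign), n_ph):
                chars[ph_pos[pj]] = GAP_CHAR
            for base in choices[pi]:
                chars[ph_pos[pi]] = base
                m = misses
                for s in decide[pi]:
                    budget[0] -= 1
                    if not index.has_kmer("".join(chars[s : s + k])):
                        m += 1
                        # At the final level only the minimum matters;
                        # a candidate strictly above it cannot win, so
                        # stop scoring it (its truncated count stays
                        # above cur_min, keeping the sort's top exact).
                        if last_level and m > cur_min:
                            break
                else:
                    cur_min = min(cur_min, m)
                nxt.append((m, assign + base))
            if budget[0] <= 0:
                break
        nxt.sort()
        beam = nxt[:BEAM_WIDTH]
        if budget[0] <= 0:
            break
    best_misses[0], best = beam[0]
    best_assign[0] = best + "A" * (n_ph - len(best))  # budget exhaustion pad
    if best_assign[0] is None:
        return None
    assign = best_assign[0]
    out = []
    ai = 0
    for c in text:
        if c == GAP_CHAR:
            out.append(assign[ai])
            ai += 1
        else:
            out.append(c)
    seq = "".join(out)
    return seq, (n_windows - best_misses[0]) / n_windows


# ---------------------------------------------------------------------------
# Region correction


def _ops_from_candidate(
    region: ErrorRegion,
    meta: _PatternApplication,
    assignment: str,
    ctx_to_draft: int,
) -> list[tuple[int, str, str, str]]:
    """Concrete (draft pos, op, ref, alt) list for a resolved candidate."""
    ops: list[tuple[int, str, str, str]] = []
    # meta.placeholders is sorted in text order (insertions precede the
    # retained tail), matching the assignment string.
    assigned = list(assignment)
    context = region.left_flank + region.sequence + region.right_flank
    ins_bases = []
    for ph, base in zip(meta.placeholders, assigned):
        if ph.context_pos is None:
            ins_bases.append(base)
        else:
            ref = context[ph.context_pos]
            if base != ref:  # keeping the draft base is a no-op
                ops.append((ctx_to_draft + ph.context_pos, "SUB", ref, base))
    if meta.del_at is not None:
        ref = context[meta.del_at : meta.del_at + meta.del_len]
        ops.append((ctx_to_draft + meta.del_at, "DEL", ref, ""))
    if meta.ins_at is not None:
        ops.append((ctx_to_draft + meta.ins_at, "INS", "", "".join(ins_bases)))
    ops.sort(key=lambda o: o[0])
    return ops


def correct_region(
    region: ErrorRegion,
    ranked_patterns: list[tuple[ErrorPattern, float]],
    index: ConfidenceIndex,
    p: float,
) -> CorrectionResult:
    """Evaluate ranked patterns and pick the first acceptable edit.

    Acceptance demands support >= p *and* strict improvement over the
    unedited region's own support.  Later-ranked acceptable candidates
    become heterozygous alternates (capped).
    """
    context = region.left_flank + region.sequence + region.right_flank
    ctx_to_draft = region.start - len(region.left_flank)
    base_support = support_ratio(context, index)
    base_count = round(base_support * (len(context) - index.k + 1))
    anchor0 = len(region.left_flank)
    applied: CandidateEdit | None = None
    alternates: list[CandidateEdit] = []
    for pattern, conf in ranked_patterns:
        best: CandidateEdit | None = None
        for shift in ANCHOR_JITTER:
            if best is not None and best.support == 1.0:
                break
            meta = _apply_pattern_meta(context, pattern, anchor0 + shift)
            if meta is None:
                continue
            choices = [ph.choices for ph in meta.placeholders]
            res = _resolve_best(meta.text, choices, index, p=p)
            if res is None:
                continue
            seq, support = res
            if best is None or support > best.support:
                # Re-extract placeholder assignment from the winning seq.
                assignment = _extract_assignment(meta.text, seq)
                best = CandidateEdit(
                    pattern=pattern,
                    anchor_shift=shift,
                    edited_context=seq,
                    support=support,
                    ops=_ops_from_candidate(region, meta, assignment, ctx_to_draft),
                    confidence=conf,
                )
        if best is None:
            continue
        # Improvement is measured in supported-window *count*, not just
        # ratio: a deletion shrinks the window denominator, so a
        # ratio-only test would happily trim unsupported-but-correct
        # sequence (e.g. coverage dropouts at contig ends).
        best_count = round(best.support * (len(best.edited_context) - index.k + 1))
        if best.support >= p and best_count > base_count:
            if applied is None:
                applied = best
            elif len(alternates) < MAX_ALTERNATES and best.edited_context != applied.edited_context:
                alternates.append(best)
    status = "edited" if applied is not None else "filtered"
    return CorrectionResult(
        region=region,
        status=status,
        applied=applied,
        alternates=alternates,
        base_support=base_support,
    )


def _extract_assignment(text: str, resolved: str) -> str:
    """Bases that filled the placeholders of ``text`` to give ``resolved``."""
    out = []
    for t, r in zip(text, resolved):
        if t == GAP_CHAR:
            out.append(r)
    return "".join(out)


def resolve_gap(
    region: ErrorRegion,
    index: ConfidenceIndex,
    p: float,
    w: int,
) -> CorrectionResult:
    """Fill (or shrink) an N-gap region by placeholder permutation.

    Every N becomes a free placeholder; additionally the run is tried
    shrunk by 1..run_length deletions, since a drafted gap length is
    only an estimate.  The best assignment with support >= p wins.
    """
    if not region.is_gap:
        raise ValueError("resolve_gap requires a gap region")
    run = region.length
    lf, rf = region.left_flank, region.right_flank
    base_context = lf + region.sequence + rf
    best: tuple[str, float, int] | None = None  # (seq, support, fill_len)
    for fill_len in range(run, -1, -1):
        text = lf + GAP_CHAR * fill_len + rf
        if len(text) < index.k:
            continue
        res = _resolve_best(text, [_BASES] * fill_len, index)
        if res is None:
            continue
        seq, support = res
        if best is None or support > best[1]:
            best = (seq, support, fill_len)
    if best is None or best[1] < p:
        return CorrectionResult(region=region, status="filtered", base_support=0.0)
    seq, support, fill_len = best
    fill = seq[len(lf) : len(lf) + fill_len]
    cand = CandidateEdit(
        pattern=ErrorPattern((0,) * w),
        anchor_shift=0,
        edited_context=seq,
        support=support,
        ops=[(region.start, "GAP", region.sequence, fill)],
    )
    return CorrectionResult(
        region=region, status="gap_resolved", applied=cand, base_support=0.0
    )


# ---------------------------------------------------------------------------
# VCF output


VCF_HEADER = """\
##fileformat=VCFv4.2
##source=seedpolish
##INFO=<ID=HET,Number=1,Type=Integer,Description="Acceptable but unapplied (potentially heterozygous) edit">
##INFO=<ID=STAGE,Number=1,Type=String,Description="Pipeline stage that produced the edit (model or post)">
##INFO=<ID=SUPPORT,Number=1,Type=Float,Description="High-confidence k-mer support ratio of the accepted candidate">
##INFO=<ID=END,Number=1,Type=Integer,Description="End of a filtered region (1-based, inclusive)">
##FILTER=<ID=lowsupport,Description="No candidate edit reached the support threshold">
##ALT=<ID=REGION,Description="Unresolved suspect region">
"""


@dataclass
class VcfRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    filter: str = "PASS"
    info: dict = field(default_factory=dict)

    def line(self) -> str:
        info = ";".join(
            f"{k}={v}" for k, v in self.info.items()
        ) or "."
        return f"{self.chrom}\t{self.pos}\t.\t{self.ref}\t{self.alt}\t.\t{self.filter}\t{info}"


def _op_to_record(
    contig_id: str, draft_seq: str, op: tuple[int, str, str, str], info: dict
) -> VcfRecord:
    pos, kind, ref, alt = op
    if kind == "SUB":
        if draft_seq[pos] != ref:
            raise ValueError(
                f"REF mismatch at {contig_id}:{pos}: draft {draft_seq[pos]} vs op {ref}"
            )
        return VcfRecord(contig_id, pos + 1, ref, alt, info=dict(info))
    if kind == "DEL":
        if draft_seq[pos : pos + len(ref)] != ref:
            raise ValueError(f"REF mismatch for DEL at {contig_id}:{pos}")
        if pos > 0:
            anchor = draft_seq[pos - 1]
            return VcfRecord(contig_id, pos, anchor + ref, anchor, info=dict(info))
        anchor = draft_seq[pos + len(ref)]
        return VcfRecord(contig_id, 1, ref + anchor, anchor, info=dict(info))
    if kind == "INS":
        if pos > 0:
            anchor = draft_seq[pos - 1]
            return VcfRecord(contig_id, pos, anchor, anchor + alt, info=dict(info))
        anchor = draft_seq[0]
        return VcfRecord(contig_id, 1, anchor, alt + anchor, info=dict(info))
    if kind == "GAP":
        if draft_seq[pos : pos + len(ref)] != ref:
            raise ValueError(f"REF mismatch for GAP at {contig_id}:{pos}")
        if len(ref) == len(alt):
            return VcfRecord(contig_id, pos + 1, ref, alt, info=dict(info))
        if pos > 0:
            anchor = draft_seq[pos - 1]
            return VcfRecord(contig_id, pos, anchor + ref, anchor + alt, info=dict(info))
        anchor = draft_seq[pos + len(ref)]
        return VcfRecord(contig_id, 1, ref + anchor, alt + anchor, info=dict(info))
    raise ValueError(f"unknown op kind {kind}")


def records_from_results(
    results: list[CorrectionResult], draft: dict[str, str]
) -> list[VcfRecord]:
    records: list[VcfRecord] = []
    for res in results:
        contig = res.region.contig_id
        seq = draft[contig]
        if res.applied is not None:
            info = {"STAGE": "model", "SUPPORT": f"{res.applied.support:.3f}"}
            for op in res.applied.ops:
                records.append(_op_to_record(contig, seq, op, info))
            for alt_cand in res.alternates:
                het = {"HET": 1, "STAGE": "model", "SUPPORT": f"{alt_cand.support:.3f}"}
                for op in alt_cand.ops:
                    records.append(_op_to_record(contig, seq, op, het))
        else:
            records.append(
                VcfRecord(
                    contig,
                    res.region.start + 1,
                    seq[res.region.start],
                    "<REGION>",
                    filter="lowsupport",
                    info={"END": res.region.end},
                )
            )
    return records


def emit_vcf(
    records: list[VcfRecord],
    draft: dict[str, str],
    path,
) -> None:
    """Write a VCFv4.2 file; records must already be draft-verified."""
    order = {name: i for i, name in enumerate(draft)}
    records = sorted(records, key=lambda r: (order[r.chrom], r.pos))
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for name, seq in draft.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            fh.write(rec.line() + "\n")
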