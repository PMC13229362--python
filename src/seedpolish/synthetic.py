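"""Synthetic genomes, erroneous drafts, reads, and a residual-error evaluator.

The generator emulates the study conditions a polisher faces: a random
reference genome, a draft derived from it by injected mismatches and
short indels — including dense clusters of several errors within one
k-mer span — and reads sampled from the reference at a stated depth and
per-base substitution error rate.  The evaluator aligns a polished
assembly back to the truth (banded global alignment via edlib) and
reports mismatches and indel events per 100 kbp.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

_BASES = "ACGT"


@dataclass
class ErrorProfile:
    """Draft corruption profile.

    ``cluster_fraction`` of injected errors are placed in dense clusters
    (>= 2 errors within a span of ``cluster_span`` bases, which also
    puts them within one k-mer span for any realistic k).  ``max_indel``
    stays at or below the pattern-model window so injected indels are
    within the recoverable signature family.
    """

    mismatch_rate: float = 0.005
    indel_rate: float = 0.0005
    max_indel: int = 3
    cluster_fraction: float = 0.3
    cluster_span: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mismatch_rate < 1.0:
            raise ValueError("mismatch_rate out of range")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel_rate out of range")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction out of range")
        if self.max_indel < 1:
            raise ValueError("max_indel must be >= 1")


@dataclass
class TruthEdit:
    """One injected corruption, recorded in both coordinate systems.

    ``ref`` is the original (truth) allele, ``alt`` the drafted one;
    ``pos`` is the draft coordinate, ``truth_pos`` the reference one.
    """

    contig: str
    pos: int
    truth_pos: int
    ref: str
    alt: str
    kind: str  # mismatch | insertion | deletion (relative to truth)


def generate_genome(
    length: int,
    gc: float = 0.5,
    repeat_fraction: float = 0.0,
    rng_seed: int = 0,
) -> str:
    """Random genome with the stated GC content and optional repeats.

    Repeats are emulated by re-pasting previously drawn 500 bp segments
    until ``repeat_fraction`` of the genome is duplicated material.
    """
    if length < 10:
        raise ValueError("length too small")
    rng = np.random.default_rng(rng_seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    seq = arr.tobytes().decode()
    n_repeat = int(length * repeat_fraction)
    if n_repeat > 0:
        seg = 500
        chars = list(seq)
        placed = 0
        while placed < n_repeat:
            src = int(rng.integers(0, length - seg))
            dst = int(rng.integers(0, length - seg))
            chars[dst : dst + seg] = chars[src : src + seg]
            placed += seg
        seq = "".join(chars)
    return seq


def _sample_positions(
    rng: np.random.Generator, length: int, n: int, min_dist: int
) -> list[int]:
    """n positions with pairwise distance >= min_dist (rejection sampling)."""
    taken: list[int] = []
    occupied = np.zeros(length, dtype=bool)
    attempts = 0
    while len(taken) < n and attempts < 50 * n + 1000:
        pos = int(rng.integers(min_dist, length - min_dist))
        lo, hi = max(0, pos - min_dist), min(length, pos + min_dist)
        if not occupied[lo:hi].any():
            occupied[pos] = True
            taken.append(pos)
        attempts += 1
    if len(taken) < n:
        raise ValueError("could not place that many separated errors")
    return sorted(taken)


def inject_errors(
    sequence: str, profile: ErrorProfile
) -> tuple[str, list[TruthEdit]]:
    """Corrupt a reference into a draft, returning the truth edit list.

    Error *sites* are kept at least 150 bp apart so each produces its
    own suspect region; a clustered site carries 2-3 errors within
    ``cluster_span`` bases, an isolated site exactly one.
    """
    rng = np.random.default_rng(profile.rng_seed)
    L = len(sequence)
    n_mismatch = int(rng.binomial(L, profile.mismatch_rate))
    n_indel = int(rng.binomial(L, profile.indel_rate))

    # Partition mismatches into clustered groups and isolated singles.
    n_clustered = int(round(n_mismatch * profile.cluster_fraction))
    groups: list[list[tuple[str, int]]] = []  # events per site
    remaining = n_clustered
    while remaining >= 2:
        size = int(min(remaining, 2 + (rng.random() < 0.3)))
        offsets = sorted(
            rng.choice(profile.cluster_span, size=size, replace=False).tolist()
        )
        groups.append([("mismatch", off) for off in offsets])
        remaining -= size
    for _ in range(n_mismatch - n_clustered + remaining):
        groups.append([("mismatch", 0)])
    for _ in range(n_indel):
        kind = "insertion" if rng.random() < 0.5 else "deletion"
        d = int(rng.integers(1, profile.max_indel + 1))
        groups.append([(kind, d)])

    sites = _sample_positions(rng, L, len(groups), min_dist=150)
    order = rng.permutation(len(groups))
    site_events = sorted(
        (sites[i], groups[int(gi)]) for i, gi in enumerate(order)
    )

    out: list[str] = []
    edits: list[TruthEdit] = []
    cursor = 0
    draft_len = 0
    for pos, events in site_events:
        out.append(sequence[cursor:pos])
        draft_len += pos - cursor
        cursor = pos
        for kind, arg in events:
            if kind == "mismatch":
                tpos = pos + arg
                out.append(sequence[cursor:tpos])
                draft_len += tpos - cursor
                ref = sequence[tpos]
                alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
                out.append(alt)
                edits.append(TruthEdit("", draft_len, tpos, ref, alt, "mismatch"))
                draft_len += 1
                cursor = tpos + 1
            elif kind == "insertion":
                # Draft gains arg random bases absent from the truth.
                ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=arg))
                out.append(ins)
                edits.append(TruthEdit("", draft_len, pos, "", ins, "insertion"))
                draft_len += arg
            else:  # deletion: draft loses arg truth bases
                ref = sequence[cursor : cursor + arg]
                edits.append(TruthEdit("", draft_len, pos, ref, "", "deletion"))
                cursor += arg
    out.append(sequence[cursor:])
    return "".join(out), edits


def sample_reads(
    genome: str,
    depth: float,
    read_length: int,
    per_base_error: float = 0.0,
    rng_seed: int = 0,
) -> list[str]:
    """Uniform-start, both-strand reads with substitution-only errors."""
    from .index import reverse_complement

    L = len(genome)
    if read_length > L:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(rng_seed)
    n_reads = int(round(depth * L / read_length))
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    strands = rng.random(n_reads) < 0.5
    reads: list[str] = []
    for s, rev in zip(starts, strands):
        read = genome[int(s) : int(s) + read_length]
        if rev:
            read = reverse_complement(read)
        if per_base_error > 0:
            n_err = rng.binomial(read_length, per_base_error)
            if n_err:
                chars = list(read)
                for pos in rng.choice(read_length, size=n_err, replace=False):
                    ref = chars[int(pos)]
                    chars[int(pos)] = _BASES[
                        (int(rng.integers(1, 4)) + _BASES.index(ref)) % 4
                    ]
                read = "".join(chars)
        reads.append(read)
    return reads


_GAPRUN = re.compile(r"-+")


def evaluate_errors(
    polished: str | dict[str, str], truth: str | dict[str, str]
) -> tuple[float, float]:
    """(mismatches, indel events) per 100 kbp of truth.

    Contigs are paired by name when dicts are given.  Substituted
    alignment columns count individually; each maximal gap run counts
    as one indel event, the per-event convention of assembly QC.
    """
    if isinstance(polished, str):
        polished = {"seq": polished}
        truth = {"seq": truth}  # type: ignore[assignment]
    total_mismatch = 0
    total_indel = 0
    total_len = 0
    for name, tseq in truth.items():  # type: ignore[union-attr]
        pseq = polished[name]
        total_len += len(tseq)
        res = edlib.align(pseq, tseq, mode="NW", task="path")
        cigar = res["cigar"]
        ops = re.findall(r"(\d+)([=XIDM])", cigar)
        prev_gap = False
        for n_str, op in ops:
            n = int(n_str)
            if op == "X":
                total_mismatch += n
                prev_gap = False
            elif op in "ID":
                if not prev_gap:
                    total_indel += 1
                prev_gap = True
            else:
                prev_gap = False
    scale = 100_000 / total_len
    return total_mismatch * scale, total_indel * scale


def edits_to_tsv(edits: list[TruthEdit], contig: str, path) -> None:
    """Truth edits as TSV: contig, pos (draft), truth_pos, ref, alt, type."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\ttruth_pos\tref\talt\ttype\n")
        for e in edits:
            fh.write(
                f"{contig}\t{e.pos}\t{e.truth_pos}\t{e.ref or '.'}\t{e.alt or '.'}\t{e.kind}\n"
            )
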