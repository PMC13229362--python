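"""Locating error regions in a draft assembly.

A draft window is *unsupported* when its canonical k-mer is absent from
the high-confidence filter.  A true base-level error knocks out every
k-mer window covering it, so errors appear as maximal runs of
consecutive unsupported windows.  Runs separated by fewer than k
supported positions share affected k-mers and are merged.  The suspect
base interval is derived from the run geometry: a run spanning fewer
than k window starts is point-like and localized to the intersection of
its windows; a longer run covers the interior of their union.

Runs of N in the draft are reported separately as gap regions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .index import ConfidenceIndex

log = logging.getLogger(__name__)

#: Regions longer than this multiple of k are split at supported anchors
#: or dropped; the pattern model's context window is local.
MAX_REGION_FACTOR = 4


@dataclass
class ErrorRegion:
    """A suspect stretch of a draft contig (0-based, half-open)."""

    contig_id: str
    start: int
    end: int
    left_flank: str
    right_flank: str
    sequence: str = ""
    is_gap: bool = False
    missing_run_length: int = 0
    #: Extra draft bases beyond the right flank, kept so the classifier
    #: can always frame a full-width context window.
    right_ext: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


EXT_BASES = 8  # right-context bases kept beyond the k-1 flank


def _flanks(seq: str, start: int, end: int, k: int) -> tuple[str, str, str]:
    return (
        seq[max(0, start - (k - 1)) : start],
        seq[end : end + k - 1],
        seq[end + k - 1 : end + k - 1 + EXT_BASES],
    )


def _runs_of_false(mask: Sequence[bool]) -> list[tuple[int, int]]:
    """Maximal [first, last] index runs where mask is False."""
    runs = []
    start = None
    for i, ok in enumerate(mask):
        if not ok and start is None:
            start = i
        elif ok and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def _suspect_interval(first: int, last: int, k: int, contig_len: int) -> tuple[int, int]:
    span = last - first + 1
    if span < k:
        # Point-like: intersection of the unsupported windows.
        start, end = last, first + k
    else:
        # Interior of the union of the windows.
        start, end = first + k - 1, last + 1
    start = max(0, min(start, contig_len - 1))
    end = max(start + 1, min(end, contig_len))
    return start, end


def _region_from_run(
    contig_id: str,
    seq: str,
    first: int,
    last: int,
    n_missing: int,
    k: int,
) -> ErrorRegion | None:
    start, end = _suspect_interval(first, last, k, len(seq))
    if "N" in seq[start:end].upper():
        # N-runs are handled by the gap machinery, not the error scanner.
        return None
    lf, rf, ext = _flanks(seq, start, end, k)
    return ErrorRegion(
        contig_id=contig_id,
        start=start,
        end=end,
        left_flank=lf,
        right_flank=rf,
        sequence=seq[start:end],
        is_gap=False,
        missing_run_length=n_missing,
        right_ext=ext,
    )


def scan_contig(contig_id: str, seq: str, index: ConfidenceIndex) -> list[ErrorRegion]:
    """Error regions of one contig, sorted by start coordinate."""
    k = index.k
    seq = seq.upper()
    n_windows = len(seq) - k + 1
    if n_windows < 1:
        log.info("contig %s shorter than k=%d; skipped", contig_id, k)
        return []
    supported = [index.has_kmer(seq[i : i + k]) for i in range(n_windows)]
    raw = _runs_of_false(supported)
    if not raw:
        return []
    # Merge runs separated by < k supported positions.
    merged: list[list[int]] = []  # [first, last, n_missing]
    for first, last in raw:
        n = last - first + 1
        if merged and first - merged[-1][1] - 1 < k:
            merged[-1][1] = last
            merged[-1][2] += n
        else:
            merged.append([first, last, n])
    regions: list[ErrorRegion] = []
    max_len = MAX_REGION_FACTOR * k
    for first, last, n_missing in merged:
        start, end = _suspect_interval(first, last, k, len(seq))
        if end - start > max_len:
            # Split an over-long merged region back into its raw runs
            # (each raw run ends at a supported anchor window).
            parts = [r for r in raw if first <= r[0] and r[1] <= last]
            for pf, pl in parts:
                ps, pe = _suspect_interval(pf, pl, k, len(seq))
                if pe - ps > max_len:
                    log.warning(
                        "contig %s: region [%d,%d) longer than %d; left uncorrected",
                        contig_id, ps, pe, max_len,
                    )
                    continue
                reg = _region_from_run(contig_id, seq, pf, pl, pl - pf + 1, k)
                if reg is not None:
                    regions.append(reg)
        else:
            reg = _region_from_run(contig_id, seq, first, last, n_missing, k)
            if reg is not None:
                regions.append(reg)
    regions.sort(key=lambda r: r.start)
    return regions


def find_error_regions(
    assembly: Iterable[tuple[str, str]] | dict, index: ConfidenceIndex
) -> list[ErrorRegion]:
    """Scan every contig; results ordered by (contig input order, start)."""
    items = assembly.items() if isinstance(assembly, dict) else assembly
    out: list[ErrorRegion] = []
    for contig_id, seq in items:
        out.extend(scan_contig(contig_id, seq, index))
    return out


_N_RUN = re.compile(r"N+")


def find_gap_regions(
    assembly: Iterable[tuple[str, str]] | dict, max_gap: int, k: int | None = None
) -> list[ErrorRegion]:
    """Maximal N-runs of length <= max_gap, as gap regions.

    ``k`` controls flank length (k-1); defaults to ``max_gap + 1`` when
    no index k is supplied.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if k is None:
        k = max_gap + 1
    items = assembly.items() if isinstance(assembly, dict) else assembly
    out: list[ErrorRegion] = []
    for contig_id, seq in items:
        s = seq.upper()
        for m in _N_RUN.finditer(s):
            if m.end() - m.start() > max_gap:
                continue
            lf, rf, ext = _flanks(s, m.start(), m.end(), k)
            out.append(
                ErrorRegion(
                    contig_id=contig_id,
                    start=m.start(),
                    end=m.end(),
                    left_flank=lf,
                    right_flank=rf,
                    sequence=s[m.start() : m.end()],
                    is_gap=True,
                    missing_run_length=0,
                    right_ext=ext,
                )
            )
    return out


def regions_to_bed(regions: Iterable[ErrorRegion]) -> str:
    """BED (0-based half-open) text for inspection."""
    lines = [
        f"{r.contig_id}\t{r.start}\t{r.end}\t{'gap' if r.is_gap else 'error'}"
        for r in regions
    ]
    return "\n".join(lines) + ("\n" if lines else "")
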