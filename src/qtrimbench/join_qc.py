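"""Paired-end read merging with a percent-maximum-difference criterion,
quality reconciliation, and mean-quality filtering.

The merger reverse-complements R2, scans every candidate overlap length
from ``min_overlap`` up to the shorter read length, and selects the
overlap with the smallest mismatch percentage (ties broken toward the
longer overlap). The pair is rejected when even the best overlap exceeds
``p_max_diff`` percent mismatches (strictly), so a threshold of 0 still
admits perfect overlaps.

Overlap qualities are reconciled per position: agreeing bases keep the
higher of the two qualities; disagreeing positions keep the base with the
higher quality and are assigned the absolute quality difference (equal
qualities fall back to R1's base with quality 0).

Reads that survive joining and whose mean quality clears a threshold are
the "good reads" of the benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .amplicon_reference import reverse_complement
from .io_formats import ReadRecord

_BASE_CODES = tuple(ord(c) for c in "ACGT")


@dataclass(frozen=True)
class JoinConfig:
    p_max_diff: float = 8.0  # percent; the merger's default
    min_overlap: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.p_max_diff <= 100):
            raise ValueError("p_max_diff must be in [0, 100]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass(frozen=True)
class JoinResult:
    status: Literal["joined", "rejected"]
    merged: Optional[ReadRecord]
    overlap_len: int
    mismatches: int
    mismatch_pct: float
    reason: Optional[str] = None

    @property
    def joined(self) -> bool:
        return self.status == "joined"


def _seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """matches[o] = number of equal bases when the last o bases of `a` are
    aligned with the first o bases of `b`, for o = 1 .. min(len(a), len(b)).

    Computed as a 4-channel one-hot cross-correlation so every candidate
    overlap is scored in one C-level pass. Bases outside {A,C,G,T} (e.g. N)
    never match anything.
    """
    l1, l2 = len(a), len(b)
    total = np.zeros(l1 + l2 - 1)
    for code in _BASE_CODES:
        total += np.correlate(
            (a == code).astype(float), (b == code).astype(float), mode="full"
        )
    max_o = min(l1, l2)
    o = np.arange(1, max_o + 1)
    return np.rint(total[l1 + l2 - 1 - o]).astype(np.int64)


def join_pair(r1: ReadRecord, r2: ReadRecord, cfg: JoinConfig) -> JoinResult:
    """Merge a read pair, or reject it.

    R2 is reverse-complemented (qualities reversed) before the overlap
    scan. On success the merged read is the non-overlapping prefix of R1,
    the reconciled overlap, and the non-overlapping suffix of
    revcomp(R2).
    """
    if len(r1) == 0 or len(r2) == 0:
        return JoinResult("rejected", None, 0, 0, 0.0, reason="empty-read")
    b_seq = reverse_complement(r2.sequence)
    b_qual = np.asarray(r2.qualities[::-1], dtype=np.int64)
    a = _seq_to_u8(r1.sequence)
    b = _seq_to_u8(b_seq)
    l1, l2 = len(a), len(b)
    max_o = min(l1, l2)
    if max_o < cfg.min_overlap:
        return JoinResult(
            "rejected", None, 0, 0, 0.0, reason="no-overlap-candidate"
        )
    matches = _match_counts(a, b)
    overlaps = np.arange(cfg.min_overlap, max_o + 1)
    mism = overlaps - matches[cfg.min_overlap - 1 :]
    pct = 100.0 * mism / overlaps
    # smallest mismatch percentage; ties broken toward the longest overlap
    best_rel = len(pct) - 1 - int(np.argmin(pct[::-1]))
    best_o = int(overlaps[best_rel])
    best_mism = int(mism[best_rel])
    best_pct = float(pct[best_rel])
    if best_pct > cfg.p_max_diff:
        return JoinResult(
            "rejected", None, best_o, best_mism, best_pct,
            reason="max-difference-exceeded",
        )
    o = best_o
    a_ov = a[l1 - o :]
    b_ov = b[:o]
    q1 = np.asarray(r1.qualities[l1 - o :], dtype=np.int64)
    q2 = b_qual[:o]
    eq = a_ov == b_ov
    take_a = eq | (q1 >= q2)  # equal qualities at a mismatch -> R1's base
    bases = np.where(take_a, a_ov, b_ov)
    quals = np.where(eq, np.maximum(q1, q2), np.abs(q1 - q2))
    merged_seq = r1.sequence[: l1 - o] + bases.tobytes().decode("ascii") + b_seq[o:]
    merged_qual = (
        r1.qualities[: l1 - o]
        + tuple(int(q) for q in quals)
        + tuple(int(q) for q in b_qual[o:])
    )
    merged = ReadRecord(r1.id, merged_seq, merged_qual)
    return JoinResult("joined", merged, o, best_mism, best_pct)


def mean_quality_filter(read: ReadRecord, min_mean_q: float) -> bool:
    """True (keep) iff the read's mean quality is >= min_mean_q.

    Empty reads are dropped.
    """
    if len(read) == 0:
        return False
    return read.mean_quality() >= min_mean_q


def good_read_fraction(raw_count: int, good_count: int) -> float:
    """Good reads divided by the original number of raw reads."""
    if raw_count <= 0:
        raise ValueError("raw_count must be > 0")
    if not (0 <= good_count <= raw_count):
        raise ValueError("good_count must be in [0, raw_count]")
    return good_count / raw_count


def join_sample(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]], cfg: JoinConfig
) -> tuple[list[ReadRecord], dict]:
    """Join every pair of a sample; returns merged reads and counts."""
    merged: list[ReadRecord] = []
    rejected = 0
    n = 0
    for r1, r2 in pairs:
        n += 1
        result = join_pair(r1, r2, cfg)
        if result.joined:
            merged.append(result.merged)
        else:
            rejected += 1
    return merged, {"pairs_in": n, "joined": len(merged), "rejected": rejected}


def qc_sample(
    reads: Iterable[ReadRecord], min_mean_q: float
) -> tuple[list[ReadRecord], dict]:
    """Apply the mean-quality filter; returns kept reads and counts."""
    reads = list(reads)
    kept = [r for r in reads if mean_quality_filter(r, min_mean_q)]
    return kept, {"reads_in": len(reads), "qc_pass": len(kept)}
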