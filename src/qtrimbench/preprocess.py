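"""Primer trimming, right-side quality trimming, and overlap arithmetic.

Primer bases sit at the 5' end of each simulated read (17 for R1, 21 for
R2) and are removed by position. Quality trimming then cuts the right
(3') end, either with the Mott maximum-sum rule or by cutting at the
first base below the threshold. Operations run in that order: primer
trim, then quality trim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .io_formats import ReadRecord

TrimAlgorithm = Literal["mott", "first_below"]

DEFAULT_FWD_PRIMER_LEN = 17
DEFAULT_REV_PRIMER_LEN = 21


@dataclass(frozen=True)
class TrimConfig:
    fwd_primer_len: int = DEFAULT_FWD_PRIMER_LEN
    rev_primer_len: int = DEFAULT_REV_PRIMER_LEN
    q_thr: int = 0
    algorithm: TrimAlgorithm = "mott"
    min_len: int = 50  # pairs with a mate shorter than this are discarded

    def __post_init__(self) -> None:
        if self.fwd_primer_len < 0 or self.rev_primer_len < 0:
            raise ValueError("primer lengths must be >= 0")
        if self.q_thr < 0:
            raise ValueError("q_thr must be >= 0")
        if self.algorithm not in ("mott", "first_below"):
            raise ValueError(f"unknown trim algorithm {self.algorithm!r}")


def trim_primer(read: ReadRecord, n: int) -> ReadRecord:
    """Remove the first n bases and qualities; n >= len gives an empty read."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return read
    return ReadRecord(read.id, read.sequence[n:], read.qualities[n:])


def _mott_cut(quals: Sequence[int], q_thr: float) -> int:
    """Prefix length k maximizing sum(Q_i - q_thr, i < k), ties -> longest."""
    scores = np.asarray(quals, dtype=float) - q_thr
    cum = np.concatenate(([0.0], np.cumsum(scores)))
    # last argmax == longest prefix among ties
    return int(len(cum) - 1 - np.argmax(cum[::-1]))


def _first_below_cut(quals: Sequence[int], q_thr: float) -> int:
    for i, q in enumerate(quals):
        if q < q_thr:
            return i
    return len(quals)


def quality_trim_right(
    read: ReadRecord, q_thr: float, algorithm: TrimAlgorithm = "mott"
) -> ReadRecord:
    """Trim the 3' end of a read at quality threshold q_thr.

    mott: keep the prefix with the maximum cumulative (Q - q_thr) score,
    breaking ties toward the longest prefix (may keep nothing).
    first_below: keep everything before the first base with Q < q_thr.
    """
    if q_thr < 0:
        raise ValueError("q_thr must be >= 0")
    if algorithm == "mott":
        k = _mott_cut(read.qualities, q_thr)
    elif algorithm == "first_below":
        k = _first_below_cut(read.qualities, q_thr)
    else:
        raise ValueError(f"unknown trim algorithm {algorithm!r}")
    if k == len(read):
        return read
    return ReadRecord(read.id, read.sequence[:k], read.qualities[:k])


def compute_overlap(len_r1: int, len_r2: int, amplicon_len: int) -> int:
    """Signed overlap of a read pair spanning an amplicon of amplicon_len.

    len_r1 + len_r2 - amplicon_len; negative values are the gap between
    the reads, making merging impossible.
    """
    if min(len_r1, len_r2, amplicon_len) < 0:
        raise ValueError("lengths must be >= 0")
    return len_r1 + len_r2 - amplicon_len


def trim_pair(
    r1: ReadRecord, r2: ReadRecord, cfg: TrimConfig
) -> tuple[ReadRecord, ReadRecord]:
    """Primer-trim then quality-trim both mates of a pair."""
    r1 = quality_trim_right(
        trim_primer(r1, cfg.fwd_primer_len), cfg.q_thr, cfg.algorithm
    )
    r2 = quality_trim_right(
        trim_primer(r2, cfg.rev_primer_len), cfg.q_thr, cfg.algorithm
    )
    return r1, r2


def trim_sample(
    r1_reads: Sequence[ReadRecord],
    r2_reads: Sequence[ReadRecord],
    cfg: TrimConfig,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], dict]:
    """Trim all pairs of a sample, discarding pairs with a too-short mate.

    Returns the kept pairs and a summary: pairs in, pairs discarded, and
    mean retained lengths (over all trimmed pairs, before discarding).
    """
    if len(r1_reads) != len(r2_reads):
        raise ValueError("R1 and R2 read counts differ")
    kept: list[tuple[ReadRecord, ReadRecord]] = []
    discarded = 0
    l1_sum = l2_sum = 0
    for r1, r2 in zip(r1_reads, r2_reads):
        t1, t2 = trim_pair(r1, r2, cfg)
        l1_sum += len(t1)
        l2_sum += len(t2)
        if len(t1) < cfg.min_len or len(t2) < cfg.min_len:
            discarded += 1
        else:
            kept.append((t1, t2))
    n = len(r1_reads)
    summary = {
        "pairs_in": n,
        "pairs_discarded": discarded,
        "mean_len_r1": l1_sum / n if n else float("nan"),
        "mean_len_r2": l2_sum / n if n else float("nan"),
    }
    return kept, summary
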