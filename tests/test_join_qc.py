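import numpy as np
import pytest

from qtrimbench.amplicon_reference import reverse_complement
from qtrimbench.io_formats import ReadRecord
from qtrimbench.join_qc import (
    JoinConfig,
    good_read_fraction,
    join_pair,
    join_sample,
    mean_quality_filter,
)

_BASES = "ACGT"


def _pair_from_fragment(fragment, l1, l2, q1=None, q2=None):
    """Build an R1/R2 pair reading the same fragment from both ends."""
    q1 = q1 or [40] * l1
    q2 = q2 or [40] * l2
    r1 = ReadRecord("p", fragment[:l1], tuple(q1))
    r2 = ReadRecord("p", reverse_complement(fragment[-l2:]), tuple(q2))
    return r1, r2


def _random_fragment(rng, n):
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


class TestJoinPair:
    def test_exact_overlap_reconciles_to_max_quality(self, rng):
        fragment = _random_fragment(rng, 40)
        q1 = list(rng.integers(10, 41, 30))
        q2 = list(rng.integers(10, 41, 30))
        r1, r2 = _pair_from_fragment(fragment, 30, 30, q1, q2)
        res = join_pair(r1, r2, JoinConfig(p_max_diff=8))
        assert res.joined
        assert res.overlap_len == 20
        assert res.mismatches == 0
        assert res.merged.sequence == fragment
        # overlap covers fragment[10:30]; R2 qualities are reversed on revcomp
        q2_fwd = q2[::-1]
        for i in range(10, 30):
            assert res.merged.qualities[i] == max(q1[i], q2_fwd[i - 10])

    def test_mismatch_rate_above_threshold_rejects(self):
        # overlap 10 with 2 mismatches = 20% > 8%
        fragment = "ACGTACGTAC"
        r1 = ReadRecord("p", fragment, (40,) * 10)
        mutated = "TT" + fragment[2:]
        r2 = ReadRecord("p", reverse_complement(mutated), (30,) * 10)
        res = join_pair(r1, r2, JoinConfig(p_max_diff=8, min_overlap=10))
        assert not res.joined
        assert res.reason == "max-difference-exceeded"
        assert res.mismatch_pct == pytest.approx(20.0)

    def test_mismatch_takes_higher_quality_base_with_difference(self):
        # single mismatching position inside a 20-base overlap
        fragment = "A" * 20
        q1 = [30] * 20
        q2 = [20] * 20
        r1 = ReadRecord("p", fragment, tuple(q1))
        r2_seq = reverse_complement("C" + fragment[1:])  # mismatch at pos 0
        r2 = ReadRecord("p", r2_seq, tuple(q2))
        res = join_pair(r1, r2, JoinConfig(p_max_diff=8))
        assert res.joined and res.overlap_len == 20
        assert res.merged.sequence[0] == "A"  # base with the higher quality
        assert res.merged.qualities[0] == 10  # |30 - 20|

    def test_equal_quality_mismatch_keeps_r1_base_with_zero_quality(self):
        fragment = "G" * 12
        r1 = ReadRecord("p", fragment, (25,) * 12)
        r2 = ReadRecord("p", reverse_complement("T" + fragment[1:]), (25,) * 12)
        res = join_pair(r1, r2, JoinConfig(p_max_diff=10))
        assert res.joined
        assert res.merged.sequence[0] == "G"
        assert res.merged.qualities[0] == 0

    def test_empty_read_rejected_with_reason(self):
        r1 = ReadRecord("p", "", ())
        r2 = ReadRecord("p", "ACGTACGT", (40,) * 8)
        res = join_pair(r1, r2, JoinConfig())
        assert res.reason == "empty-read"

    def test_p_zero_admits_perfect_overlap(self, rng):
        fragment = _random_fragment(rng, 30)
        r1, r2 = _pair_from_fragment(fragment, 20, 20)
        res = join_pair(r1, r2, JoinConfig(p_max_diff=0))
        assert res.joined and res.mismatch_pct == 0.0


def _brute_force_join(r1, r2, cfg):
    """Enumerate every overlap, recompute mismatch %, rebuild the merge."""
    b_seq = reverse_complement(r2.sequence)
    b_qual = list(r2.qualities[::-1])
    l1, l2 = len(r1), len(r2)
    best = None  # (pct, o, mism)
    for o in range(cfg.min_overlap, min(l1, l2) + 1):
        mism = sum(
            1 for x, y in zip(r1.sequence[l1 - o :], b_seq[:o]) if x != y
        )
        pct = 100.0 * mism / o
        if best is None or pct < best[0] or (pct == best[0] and o > best[1]):
            best = (pct, o, mism)
    if best is None or best[0] > cfg.p_max_diff:
        return None, best
    pct, o, mism = best
    seq, quals = [], []
    for i in range(o):
        x, y = r1.sequence[l1 - o + i], b_seq[i]
        qx, qy = r1.qualities[l1 - o + i], b_qual[i]
        if x == y:
            seq.append(x)
            quals.append(max(qx, qy))
        else:
            seq.append(x if qx >= qy else y)
            quals.append(abs(qx - qy))
    merged_seq = r1.sequence[: l1 - o] + "".join(seq) + b_seq[o:]
    merged_quals = list(r1.qualities[: l1 - o]) + quals + b_qual[o:]
    return ReadRecord(r1.id, merged_seq, tuple(merged_quals)), best


def test_join_matches_brute_force_on_random_reads():
    """Oracle equivalence on several hundred random small read pairs."""
    rng = np.random.default_rng(99)
    cfg = JoinConfig(p_max_diff=12, min_overlap=3)
    for _ in range(400):
        l1 = int(rng.integers(3, 41))
        l2 = int(rng.integers(3, 41))
        r1 = ReadRecord("a", _random_fragment(rng, l1),
                        tuple(int(q) for q in rng.integers(0, 42, l1)))
        r2 = ReadRecord("a", _random_fragment(rng, l2),
                        tuple(int(q) for q in rng.integers(0, 42, l2)))
        expected, best = _brute_force_join(r1, r2, cfg)
        res = join_pair(r1, r2, cfg)
        if expected is None:
            assert not res.joined
        else:
            assert res.joined
            assert (res.mismatch_pct, res.overlap_len, res.mismatches) == (
                pytest.approx(best[0]), best[1], best[2])
            assert res.merged == expected


def test_joined_fraction_monotone_in_p_max_diff(rng):
    """Loosening the rejection threshold can only join more pairs."""
    pairs = []
    for _ in range(60):
        fragment = _random_fragment(rng, 50)
        q1 = [int(q) for q in rng.integers(5, 41, 35)]
        q2 = [int(q) for q in rng.integers(5, 41, 35)]
        r1, r2 = _pair_from_fragment(fragment, 35, 35, q1, q2)
        # sprinkle disagreements
        n_mut = int(rng.integers(0, 6))
        seq = list(r1.sequence)
        for pos in rng.integers(0, 35, n_mut):
            seq[pos] = _BASES[(_BASES.index(seq[pos]) + 1) % 4]
        pairs.append((ReadRecord("p", "".join(seq), r1.qualities), r2))
    fractions = []
    for p in (0, 4, 8, 16, 40):
        merged, stats = join_sample(pairs, JoinConfig(p_max_diff=p))
        assert stats["joined"] + stats["rejected"] == stats["pairs_in"]
        fractions.append(stats["joined"])
    assert fractions == sorted(fractions)


class TestQc:
    def test_mean_quality_keep_and_drop(self):
        keep = ReadRecord("r", "ACGT", (40,) * 4)
        drop = ReadRecord("r", "ACGT", (10,) * 4)
        assert mean_quality_filter(keep, 25)
        assert not mean_quality_filter(drop, 25)

    def test_boundary_mean_kept(self):
        read = ReadRecord("r", "AC", (30, 20))
        assert mean_quality_filter(read, 25)

    def test_empty_read_dropped(self):
        assert not mean_quality_filter(ReadRecord("r", "", ()), 0)

    def test_good_read_fraction(self):
        assert good_read_fraction(100, 80) == pytest.approx(0.8)
        assert good_read_fraction(7, 7) == 1.0
        with pytest.raises(ValueError):
            good_read_fraction(0, 0)
        with pytest.raises(ValueError):
            good_read_fraction(5, 6)
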