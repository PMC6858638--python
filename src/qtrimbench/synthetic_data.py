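"""Synthetic inputs: reference sequences with embedded primer sites and
pools of positional quality profiles.

These generators stand in for the two external inputs of the benchmark —
a 16S reference database and quality-score pools harvested from real
2x300 V3-V4 FASTQ runs — so the full pipeline runs self-contained.

The quality model is a plateau followed by a linear decline with additive
Gaussian noise: read starts at a high plateau (default Q38), stays flat up
to ``decay_start``, then drops ``decay_rate`` phred units per base toward a
floor (default Q2, Illumina's no-call sentinel). R2 profiles are shifted
down by ``r2_penalty`` — the reverse read of a paired-end run is
systematically worse than the forward read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .amplicon_reference import (
    FWD_PRIMER_341F,
    IUPAC_SETS,
    REV_PRIMER_785R,
    find_primer_site,
    reverse_complement,
)
from .io_formats import PathLike, SeqRecord

Mate = Literal["R1", "R2"]

_BASES = np.array(list("ACGT"))

QUAL_FLOOR = 2
QUAL_CEIL = 40


@dataclass(frozen=True)
class DecayParams:
    """Positional quality-decay model for one sequencing run.

    plateau_q : phred score before decline starts (default 38).
    floor_q : lowest expected score the decline can reach (default 2).
    decay_start : 0-based position where the linear decline begins.
    decay_rate : phred units lost per base after decay_start.
    noise_sd : per-position Gaussian noise (phred units).
    r2_penalty : phred units subtracted from the R2 expectation.
    """

    plateau_q: int = 38
    floor_q: int = 2
    decay_start: int = 150
    decay_rate: float = 0.2
    noise_sd: float = 3.0
    r2_penalty: int = 5

    def __post_init__(self) -> None:
        if self.floor_q > self.plateau_q:
            raise ValueError("floor_q must not exceed plateau_q")
        if self.decay_start < 0:
            raise ValueError("decay_start must be >= 0")
        if self.decay_rate < 0 or self.noise_sd < 0 or self.r2_penalty < 0:
            raise ValueError("decay_rate, noise_sd, r2_penalty must be >= 0")


@dataclass
class QualityProfilePool:
    """Pools of per-position quality vectors for R1 and R2 reads.

    Mirrors the benchmark's 'two text files of shuffled quality strings':
    simulation samples rows uniformly with replacement.
    """

    r1_profiles: np.ndarray  # shape (n, read_length), dtype int
    r2_profiles: np.ndarray
    read_length: int

    def __post_init__(self) -> None:
        for name, arr in (("r1", self.r1_profiles), ("r2", self.r2_profiles)):
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 2 or arr.shape[0] == 0:
                raise ValueError(f"{name} pool must be a non-empty 2-D array")
            if arr.shape[1] != self.read_length:
                raise ValueError(
                    f"{name} profiles have length {arr.shape[1]}, "
                    f"expected {self.read_length}"
                )
            if arr.min() < QUAL_FLOOR or arr.max() > QUAL_CEIL:
                raise ValueError(
                    f"{name} pool values outside [{QUAL_FLOOR}, {QUAL_CEIL}]"
                )
        self.r1_profiles = np.asarray(self.r1_profiles, dtype=np.int64)
        self.r2_profiles = np.asarray(self.r2_profiles, dtype=np.int64)

    def profiles(self, mate: Mate) -> np.ndarray:
        if mate == "R1":
            return self.r1_profiles
        if mate == "R2":
            return self.r2_profiles
        raise ValueError(f"mate must be 'R1' or 'R2', got {mate!r}")

    def sample(self, mate: Mate, rng: np.random.Generator) -> np.ndarray:
        pool = self.profiles(mate)
        return pool[rng.integers(0, pool.shape[0])]


def _realize_degenerate(primer: str, rng: np.random.Generator) -> str:
    """Replace each IUPAC code by a uniformly chosen concrete base."""
    out = []
    for code in primer:
        choices = sorted(IUPAC_SETS[code] & set("ACGT"))
        if not choices:
            raise ValueError(f"IUPAC code {code!r} matches no concrete base")
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def generate_references(
    n: int,
    amplicon_len_mean: float = 465.0,
    amplicon_len_sd: float = 10.0,
    fwd_primer: str = FWD_PRIMER_341F,
    rev_primer: str = REV_PRIMER_785R,
    flank_len: int = 50,
    rng_seed: int | np.random.Generator = 0,
) -> list[SeqRecord]:
    """Generate reference sequences that each carry exactly one forward-primer
    site and, downstream, one reverse-primer binding site.

    The distance from the forward-primer start to the end of the
    reverse-primer site is drawn from Normal(amplicon_len_mean,
    amplicon_len_sd), rounded, and clipped to >= 311 so 310-base read
    templates are always extractable. Random flanks of ``flank_len`` bases
    are added on both sides. Candidates where the random context creates a
    spurious primer hit are redrawn, so primer search is guaranteed to
    recover the intended amplicon.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    min_len = len(fwd_primer) + len(rev_primer)
    if amplicon_len_mean < 2 * min_len:
        raise ValueError(
            "amplicon_len_mean too small for the primer pair geometry"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    rev_site = reverse_complement(rev_primer)
    records: list[SeqRecord] = []
    width = max(4, len(str(n)))
    for i in range(n):
        target = int(round(rng.normal(amplicon_len_mean, amplicon_len_sd)))
        target = max(target, 311, min_len + 1)
        for _attempt in range(100):
            fwd = _realize_degenerate(fwd_primer, rng)
            rev = _realize_degenerate(rev_site, rng)
            middle = _random_bases(target - len(fwd) - len(rev), rng)
            seq = (
                _random_bases(flank_len, rng)
                + fwd
                + middle
                + rev
                + _random_bases(flank_len, rng)
            )
            if find_primer_site(seq, fwd_primer) != flank_len:
                continue  # spurious upstream forward-primer hit
            downstream = seq[flank_len + len(fwd_primer) :]
            rel = find_primer_site(downstream, rev_site)
            intended = target - len(fwd_primer) - len(rev_site)
            if rel != intended:
                continue  # spurious proximal reverse-site hit
            records.append(
                SeqRecord(id=f"ref{i + 1:0{width}d}", sequence=seq)
            )
            break
        else:
            raise RuntimeError("could not place primers after 100 attempts")
    return records


def generate_quality_pool(
    n_profiles: int,
    read_length: int,
    params: DecayParams,
    mate: Mate,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n_profiles`` quality vectors from the plateau-decay model.

    Expected quality at position p is plateau (minus r2_penalty for R2)
    up to decay_start, then declines linearly at decay_rate, floored at
    floor_q; Gaussian noise of sd noise_sd is added per position, and the
    result is rounded and clipped to [2, 40].
    """
    if n_profiles < 1:
        raise ValueError("n_profiles must be >= 1")
    if mate not in ("R1", "R2"):
        raise ValueError(f"mate must be 'R1' or 'R2', got {mate!r}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    pos = np.arange(read_length, dtype=float)
    plateau = params.plateau_q - (params.r2_penalty if mate == "R2" else 0)
    expected = plateau - params.decay_rate * np.maximum(
        0.0, pos - params.decay_start
    )
    expected = np.maximum(expected, params.floor_q)
    noise = rng.normal(0.0, params.noise_sd, size=(n_profiles, read_length))
    profiles = np.rint(expected[None, :] + noise)
    return np.clip(profiles, QUAL_FLOOR, QUAL_CEIL).astype(np.int64)


def make_pool(
    n_profiles: int,
    read_length: int = 310,
    params: DecayParams | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> QualityProfilePool:
    """Generate matched R1/R2 pools with one call."""
    params = params or DecayParams()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    r1 = generate_quality_pool(n_profiles, read_length, params, "R1", rng)
    r2 = generate_quality_pool(n_profiles, read_length, params, "R2", rng)
    return QualityProfilePool(r1, r2, read_length)


def write_pool_file(profiles: np.ndarray, path: PathLike) -> None:
    """Write one space-separated integer quality vector per line."""
    with open(path, "wt") as handle:
        for row in np.asarray(profiles, dtype=np.int64):
            handle.write(" ".join(str(int(q)) for q in row) + "\n")


def read_pool_file(path: PathLike) -> np.ndarray:
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line:
                rows.append([int(tok) for tok in line.split()])
    if not rows:
        raise ValueError(f"{path}: empty quality pool file")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: inconsistent profile lengths {sorted(lengths)}")
    return np.asarray(rows, dtype=np.int64)


def load_pool(r1_path: PathLike, r2_path: PathLike) -> QualityProfilePool:
    r1 = read_pool_file(r1_path)
    r2 = read_pool_file(r2_path)
    if r1.shape[1] != r2.shape[1]:
        raise ValueError("R1 and R2 pools have different profile lengths")
    return QualityProfilePool(r1, r2, r1.shape[1])
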