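"""Simulate paired-end amplicon samples and their error-free gold standards.

Each sample draws a random subset of amplicon references, a random copy
count per reference, and per-copy quality vectors from a profile pool;
bases are then resampled position-by-position according to the quality
score. For every sample an error-free twin ("gold standard") is emitted:
the same reads (same ids, same templates, same multiset) with unmutated
sequences and a constant high quality.

Two quality-to-probability mappings are provided:

standard_phred
    The phred definition: error probability 10^(-Q/10), so the called base
    keeps probability 1 - 10^(-Q/10) and each alternative gets
    10^(-Q/10)/3. Default.
as_printed
    The inverted mapping in which the called base keeps probability
    10^(-Q/10) itself (at Q=2 that is 0.63, each alternative (1-0.63)/3 =
    0.123). Retained to reproduce that worked example verbatim; it makes
    high-quality bases almost always wrong, so it is not the default.

Read ids are formatted ``{sample}.{ref_id}.{copy}`` — the provenance
channel the evaluation stage uses to recover the true composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .amplicon_reference import AmpliconReference
from .io_formats import ReadRecord
from .synthetic_data import QualityProfilePool

logger = logging.getLogger(__name__)

ErrorModel = Literal["standard_phred", "as_printed", "none"]

_BASE_TO_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i
_IDX_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for one simulated dataset."""

    n_samples: int = 10
    min_refs_per_sample: int = 20
    max_refs_per_sample: int = 60
    min_copies: int = 1
    max_copies: int = 100
    template_length: int = 310
    gold_quality: int = 40
    error_model: ErrorModel = "standard_phred"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.min_refs_per_sample, self.min_copies) < 1:
            raise ValueError("counts must be positive")
        if self.max_refs_per_sample < self.min_refs_per_sample:
            raise ValueError("max_refs_per_sample < min_refs_per_sample")
        if self.max_copies < self.min_copies:
            raise ValueError("max_copies < min_copies")
        if not (2 <= self.gold_quality <= 41):
            raise ValueError("gold_quality must be in [2, 41]")
        if self.error_model not in ("standard_phred", "as_printed", "none"):
            raise ValueError(f"unknown error model {self.error_model!r}")


@dataclass(frozen=True)
class SampleTruth:
    """Gold composition: reference id -> copy count for one sample."""

    sample_id: str
    counts: Mapping[str, int]

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


@dataclass
class SimulatedSample:
    sample_id: str
    r1: list[ReadRecord]
    r2: list[ReadRecord]
    gold_r1: list[ReadRecord]
    gold_r2: list[ReadRecord]
    truth: SampleTruth


def phred_to_probs(q: float, model: str) -> tuple[float, float]:
    """Map a phred score to (p_called, p_each_alt) under the given model.

    p_called + 3 * p_each_alt == 1 holds for both models.
    """
    if q < 0:
        raise ValueError(f"phred score must be >= 0, got {q}")
    if model == "as_printed":
        p_called = 10.0 ** (-q / 10.0)
    elif model == "standard_phred":
        p_called = 1.0 - 10.0 ** (-q / 10.0)
    else:
        raise ValueError(f"unknown error model {model!r}")
    return p_called, (1.0 - p_called) / 3.0


def _p_called_vector(quals: np.ndarray, model: str) -> np.ndarray:
    err = 10.0 ** (-quals.astype(float) / 10.0)
    if model == "as_printed":
        return err
    if model == "standard_phred":
        return 1.0 - err
    raise ValueError(f"unknown error model {model!r}")


def inject_errors(
    template: str,
    quals: Sequence[int],
    model: str,
    rng: np.random.Generator,
) -> str:
    """Resample each base independently according to its quality score.

    The called base survives with p_called; otherwise one of the three
    alternatives is chosen uniformly, i.e. with (1 - p_called)/3 each.
    N bases in the template are first replaced by a uniform random base
    (logged), then resampled like any other position.
    """
    quals = np.asarray(quals, dtype=np.int64)
    if len(template) != len(quals):
        raise ValueError("template and quality lengths differ")
    if model == "none":
        raise ValueError("error model 'none' has no error process to apply")
    idx = _BASE_TO_IDX[np.frombuffer(template.encode("ascii"), dtype=np.uint8)]
    n_mask = idx < 0
    if n_mask.any():
        logger.info("substituting %d N bases with random bases", n_mask.sum())
        idx = idx.copy()
        idx[n_mask] = rng.integers(0, 4, size=int(n_mask.sum()))
    idx = idx.astype(np.int64)
    p_called = _p_called_vector(quals, model)
    err = rng.random(len(quals)) >= p_called
    if err.any():
        shift = rng.integers(1, 4, size=int(err.sum()))
        idx[err] = (idx[err] + shift) % 4
    return _IDX_TO_BASE[idx].tobytes().decode("ascii")


def simulate_sample(
    refs: Sequence[AmpliconReference],
    pool: QualityProfilePool,
    cfg: SimConfig,
    sample_id: str,
    rng: np.random.Generator,
) -> SimulatedSample:
    """Simulate one sample plus its gold standard.

    Returns paired R1/R2 reads with pool-drawn qualities and injected
    errors, the matching gold reads (identical ids and templates, pristine
    sequences, constant gold quality), and the ground-truth composition.
    """
    if not refs:
        raise ValueError("reference set is empty")
    if pool.read_length != cfg.template_length:
        raise ValueError(
            f"pool read length {pool.read_length} != template length "
            f"{cfg.template_length}"
        )
    n_refs = int(
        rng.integers(
            cfg.min_refs_per_sample,
            min(cfg.max_refs_per_sample, len(refs)) + 1,
        )
    )
    chosen = rng.choice(len(refs), size=n_refs, replace=False)
    gold_quals = (cfg.gold_quality,) * cfg.template_length
    r1, r2, gold_r1, gold_r2 = [], [], [], []
    counts: dict[str, int] = {}
    for ref_idx in chosen:
        ref = refs[int(ref_idx)]
        n_copies = int(rng.integers(cfg.min_copies, cfg.max_copies + 1))
        counts[ref.ref_id] = n_copies
        for copy in range(1, n_copies + 1):
            read_id = f"{sample_id}.{ref.ref_id}.{copy}"
            q1 = pool.sample("R1", rng)
            q2 = pool.sample("R2", rng)
            if cfg.error_model == "none":
                s1, s2 = ref.r1_template, ref.r2_template
            else:
                s1 = inject_errors(ref.r1_template, q1, cfg.error_model, rng)
                s2 = inject_errors(ref.r2_template, q2, cfg.error_model, rng)
            r1.append(ReadRecord(read_id, s1, tuple(int(q) for q in q1)))
            r2.append(ReadRecord(read_id, s2, tuple(int(q) for q in q2)))
            gold_r1.append(ReadRecord(read_id, ref.r1_template, gold_quals))
            gold_r2.append(ReadRecord(read_id, ref.r2_template, gold_quals))
    return SimulatedSample(
        sample_id=sample_id,
        r1=r1,
        r2=r2,
        gold_r1=gold_r1,
        gold_r2=gold_r2,
        truth=SampleTruth(sample_id=sample_id, counts=counts),
    )


def simulate_dataset(
    refs: Sequence[AmpliconReference],
    pool: QualityProfilePool,
    cfg: SimConfig,
) -> list[SimulatedSample]:
    """Simulate cfg.n_samples samples deterministically from cfg.rng_seed."""
    rng = np.random.default_rng(cfg.rng_seed)
    return [
        simulate_sample(refs, pool, cfg, f"S{i + 1:02d}", rng)
        for i in range(cfg.n_samples)
    ]


def parse_read_id(read_id: str) -> tuple[str, str, int]:
    """Recover (sample_id, ref_id, copy index) from a simulator read id."""
    head, _, copy = read_id.rpartition(".")
    sample, _, ref_id = head.partition(".")
    if not sample or not ref_id or not copy.isdigit():
        raise ValueError(f"read id {read_id!r} is not simulator-formatted")
    return sample, ref_id, int(copy)
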