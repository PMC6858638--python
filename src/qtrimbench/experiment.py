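"""End-to-end sweep: trimming thresholds x merge stringency -> good-read
fractions, overlap lengths, FP/FN rates and gold-standard distances.

One experiment builds a synthetic world (references, quality pool,
simulated samples with gold standards) from a single seed, then for every
(quality-trimming threshold, percent-maximum-difference) cell runs primer
trim -> quality trim -> pair joining -> mean-quality filter -> composition
recovery, and scores each sample against its gold standard. Gold reads go
through the identical pipeline.

The per-pair overlap reported for a cell is
``len(R1') + len(R2') - (amplicon_len - fwd_primer_len - rev_primer_len)``
— the trimmed reads measured against the primer-trimmed amplicon span, so
a negative value means an actual gap and merging is impossible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .amplicon_reference import (
    AmpliconReference,
    FWD_PRIMER_341F,
    REV_PRIMER_785R,
    extract_amplicons,
)
from .evaluation import (
    build_composition_row,
    composition_table,
    expected_joined_products,
    fp_fn_percent,
    jaccard_matrix,
    pcoa_gold_distance,
)
from .io_formats import PathLike, ReadRecord
from .join_qc import JoinConfig, join_sample, qc_sample
from .preprocess import TrimConfig, compute_overlap, trim_pair
from .read_simulator import SimConfig, SimulatedSample, parse_read_id, simulate_dataset
from .synthetic_data import DecayParams, QualityProfilePool, make_pool, generate_references

logger = logging.getLogger(__name__)

GOLD_SUFFIX = "_gold"


@dataclass(frozen=True)
class SweepConfig:
    """Full configuration of one sweep experiment."""

    # synthetic world
    n_refs: int = 60
    amplicon_len_mean: float = 465.0
    amplicon_len_sd: float = 10.0
    flank_len: int = 50
    fwd_primer: str = FWD_PRIMER_341F
    rev_primer: str = REV_PRIMER_785R
    pool_size: int = 200
    decay: DecayParams = field(default_factory=DecayParams)
    # simulation
    n_samples: int = 10
    min_refs_per_sample: int = 20
    max_refs_per_sample: int = 60
    min_copies: int = 1
    max_copies: int = 100
    template_length: int = 310
    gold_quality: int = 40
    error_model: str = "standard_phred"
    # sweep grid
    q_thr_values: tuple[int, ...] = tuple(range(0, 21, 2))
    p_values: tuple[int, ...] = (4, 8, 12)
    # preprocessing / joining / QC
    trim_algorithm: str = "mott"
    min_len: int = 50
    min_overlap: int = 6
    min_mean_q: float = 25.0
    composition_mode: str = "provenance"
    jaccard_mode: str = "binary"
    # reproducibility
    rng_seed: int = 0

    def trim_config(self, q_thr: int) -> TrimConfig:
        return TrimConfig(
            fwd_primer_len=len(self.fwd_primer),
            rev_primer_len=len(self.rev_primer),
            q_thr=q_thr,
            algorithm=self.trim_algorithm,
            min_len=self.min_len,
        )

    def join_config(self, p: float) -> JoinConfig:
        return JoinConfig(p_max_diff=p, min_overlap=self.min_overlap)

    def sim_config(self, rng_seed: int) -> SimConfig:
        return SimConfig(
            n_samples=self.n_samples,
            min_refs_per_sample=self.min_refs_per_sample,
            max_refs_per_sample=self.max_refs_per_sample,
            min_copies=self.min_copies,
            max_copies=self.max_copies,
            template_length=self.template_length,
            gold_quality=self.gold_quality,
            error_model=self.error_model,
            rng_seed=rng_seed,
        )

    def to_yaml(self, path: PathLike) -> None:
        data = asdict(self)
        data["decay"] = asdict(self.decay)
        data["q_thr_values"] = list(self.q_thr_values)
        data["p_values"] = list(self.p_values)
        with open(path, "wt") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "SweepConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "decay" in data:
            data["decay"] = DecayParams(**data["decay"])
        for key in ("q_thr_values", "p_values"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _sub_seeds(seed: int, n: int = 3) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def build_world(
    cfg: SweepConfig,
) -> tuple[list[AmpliconReference], QualityProfilePool, list[SimulatedSample]]:
    """Generate references, quality pools and simulated samples from one seed."""
    seed_refs, seed_pool, seed_sim = _sub_seeds(cfg.rng_seed)
    records = generate_references(
        cfg.n_refs,
        amplicon_len_mean=cfg.amplicon_len_mean,
        amplicon_len_sd=cfg.amplicon_len_sd,
        fwd_primer=cfg.fwd_primer,
        rev_primer=cfg.rev_primer,
        flank_len=cfg.flank_len,
        rng_seed=seed_refs,
    )
    amp_refs, skipped = extract_amplicons(
        records, cfg.fwd_primer, cfg.rev_primer, cfg.template_length
    )
    if skipped:
        logger.warning("skipped %d references: %s", len(skipped), skipped[:5])
    pool = make_pool(cfg.pool_size, cfg.template_length, cfg.decay, seed_pool)
    samples = simulate_dataset(amp_refs, pool, cfg.sim_config(seed_sim))
    return amp_refs, pool, samples


def _process_reads(
    r1_reads: Sequence[ReadRecord],
    r2_reads: Sequence[ReadRecord],
    trim_cfg: TrimConfig,
    join_cfg: JoinConfig,
    min_mean_q: float,
    amp_span: dict[str, int],
) -> dict:
    """Trim, join and QC one read set; returns counts and overlap stats."""
    overlaps = []
    kept_pairs = []
    discarded = 0
    for r1, r2 in zip(r1_reads, r2_reads):
        t1, t2 = trim_pair(r1, r2, trim_cfg)
        _, ref_id, _ = parse_read_id(r1.id)
        overlaps.append(compute_overlap(len(t1), len(t2), amp_span[ref_id]))
        if len(t1) < trim_cfg.min_len or len(t2) < trim_cfg.min_len:
            discarded += 1
        else:
            kept_pairs.append((t1, t2))
    merged, join_stats = join_sample(kept_pairs, join_cfg)
    good, qc_stats = qc_sample(merged, min_mean_q)
    return {
        "raw_pairs": len(r1_reads),
        "trim_discarded": discarded,
        "joined": join_stats["joined"],
        "rejected": join_stats["rejected"] + discarded,
        "qc_pass": qc_stats["qc_pass"],
        "mean_overlap": float(np.mean(overlaps)) if overlaps else float("nan"),
        "good_reads": good,
    }


def run_cell(
    samples: Sequence[SimulatedSample],
    amp_refs: Sequence[AmpliconReference],
    q_thr: int,
    p: float,
    cfg: SweepConfig,
) -> list[dict]:
    """Run the pipeline on every sample (and its gold) at one grid cell."""
    trim_cfg = cfg.trim_config(q_thr)
    join_cfg = cfg.join_config(p)
    amp_span = {
        r.ref_id: len(r.amplicon) - len(cfg.fwd_primer) - len(cfg.rev_primer)
        for r in amp_refs
    }
    products = (
        expected_joined_products(
            amp_refs, len(cfg.fwd_primer), len(cfg.rev_primer)
        )
        if cfg.composition_mode == "exact_match"
        else None
    )
    per_sample: dict[str, dict] = {}
    comp_rows: dict[str, dict] = {}
    for sample in samples:
        stats = _process_reads(
            sample.r1, sample.r2, trim_cfg, join_cfg, cfg.min_mean_q, amp_span
        )
        gold_stats = _process_reads(
            sample.gold_r1, sample.gold_r2, trim_cfg, join_cfg,
            cfg.min_mean_q, amp_span,
        )
        counts, _ = build_composition_row(
            stats.pop("good_reads"), cfg.composition_mode, products
        )
        gold_counts, _ = build_composition_row(
            gold_stats.pop("good_reads"), cfg.composition_mode, products
        )
        comp_rows[sample.sample_id] = dict(counts)
        comp_rows[sample.sample_id + GOLD_SUFFIX] = dict(gold_counts)
        per_sample[sample.sample_id] = {
            "stats": stats,
            "observed": set(counts),
            "gold_observed": set(gold_counts),
        }
    table = composition_table(comp_rows)
    nonzero = table.loc[table.sum(axis=1) > 0]
    distances: dict[tuple[str, str], float] = {}
    pairs = [
        (s.sample_id, s.sample_id + GOLD_SUFFIX)
        for s in samples
        if s.sample_id in nonzero.index
        and s.sample_id + GOLD_SUFFIX in nonzero.index
    ]
    if len(nonzero) >= 2 and pairs:
        dist = jaccard_matrix(nonzero, cfg.jaccard_mode)
        distances = pcoa_gold_distance(dist, pairs)
    rows = []
    for sample in samples:
        info = per_sample[sample.sample_id]
        stats = info["stats"]
        observed, gold_observed = info["observed"], info["gold_observed"]
        if gold_observed:
            fp, fn = fp_fn_percent(observed, gold_observed)
        else:  # gold pipeline produced nothing: scoring undefined
            fp, fn = float("nan"), float("nan")
        gd = distances.get(
            (sample.sample_id, sample.sample_id + GOLD_SUFFIX), float("nan")
        )
        rows.append(
            {
                "sample": sample.sample_id,
                "q_thr": q_thr,
                "p_max_diff": p,
                **stats,
                "good_fraction": stats["qc_pass"] / stats["raw_pairs"],
                "fp_pct": fp,
                "fn_pct": fn,
                "n_observed": len(observed),
                "gold_distance": gd,
            }
        )
    return rows


def run_experiment(cfg: SweepConfig) -> pd.DataFrame:
    """Run the full sweep; one row per (sample, q_thr, p_max_diff).

    Failures in individual grid cells are logged and skipped; the sweep
    continues. Deterministic given cfg.rng_seed.
    """
    amp_refs, _pool, samples = build_world(cfg)
    rows: list[dict] = []
    for q_thr in cfg.q_thr_values:
        for p in cfg.p_values:
            try:
                rows.extend(run_cell(samples, amp_refs, q_thr, p, cfg))
            except Exception:
                logger.exception(
                    "cell q_thr=%s p=%s failed; continuing", q_thr, p
                )
    df = pd.DataFrame(rows)
    df.attrs["rng_seed"] = cfg.rng_seed
    return df


# ---------------------------------------------------------------------------
# optional figures (matplotlib imported lazily)

def plot_good_fraction(df: pd.DataFrame, path: PathLike) -> None:
    """Mean good-read fraction vs trimming threshold, one curve per p."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p, sub in df.groupby("p_max_diff"):
        agg = sub.groupby("q_thr")["good_fraction"].agg(["mean", "sem"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], label=f"p = {p}")
    ax.set_xlabel("quality trimming threshold")
    ax.set_ylabel("good reads / raw reads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_overlap(df: pd.DataFrame, path: PathLike) -> None:
    """Mean post-trimming overlap vs threshold; negative = gap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    agg = df.groupby("q_thr")["mean_overlap"].agg(["mean", "sem"])
    ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"])
    ax.axhline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("quality trimming threshold")
    ax.set_ylabel("calculated overlap (bases)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_good_heatmap(df: pd.DataFrame, path: PathLike) -> None:
    """Heat map of mean good-read fraction over the (q_thr, p) grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = df.pivot_table(
        index="p_max_diff", columns="q_thr", values="good_fraction"
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(grid.to_numpy(), aspect="auto", origin="lower")
    ax.set_xticks(range(len(grid.columns)), grid.columns)
    ax.set_yticks(range(len(grid.index)), grid.index)
    ax.set_xlabel("quality trimming threshold")
    ax.set_ylabel("percent maximum difference")
    fig.colorbar(im, ax=ax, label="good reads / raw reads")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
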