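"""Composition recovery and comparison to the gold standard.

Good reads are tallied into a samples x references count matrix, either by
provenance (the simulator encodes the source reference in each read id) or
by exact sequence match against the expected joined product of each
reference. Samples are compared to their gold standards with:

- false-positive / false-negative percentages on the observed reference
  sets (FP relative to the observed set, FN relative to the gold set);
- a Jaccard distance matrix (binary presence/absence by default, or the
  quantitative min/max variant);
- classical principal coordinates analysis (PCoA) of that matrix, with the
  per-sample Euclidean distance to its gold standard measured in the
  embedded space.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .amplicon_reference import AmpliconReference
from .io_formats import ReadRecord
from .read_simulator import parse_read_id

CompositionMode = Literal["provenance", "exact_match"]
JaccardMode = Literal["binary", "abundance"]

PCOA_EIG_TOL = 1e-10

UNASSIGNED = "__unassigned__"


def expected_joined_products(
    refs: Sequence[AmpliconReference],
    fwd_primer_len: int = 17,
    rev_primer_len: int = 21,
) -> dict[str, str]:
    """Map each reference's expected error-free joined product to its id.

    The product of joining untrimmed (q_thr = 0) primer-trimmed reads is
    the amplicon minus its primer-binding regions. Products shared by more
    than one reference are dropped (assignment must be unique).
    """
    products: dict[str, str] = {}
    ambiguous: set[str] = set()
    for ref in refs:
        product = ref.amplicon[fwd_primer_len : len(ref.amplicon) - rev_primer_len]
        if product in products:
            ambiguous.add(product)
        else:
            products[product] = ref.ref_id
    for product in ambiguous:
        del products[product]
    return products


def build_composition_row(
    good_reads: Iterable[ReadRecord],
    mode: CompositionMode = "provenance",
    products: Mapping[str, str] | None = None,
) -> tuple[Counter, int]:
    """Count good reads per reference id.

    provenance: the reference id is parsed from the simulator read id
    (unparseable ids raise, naming the read). exact_match: a read is
    assigned to the unique reference whose expected joined product equals
    its sequence exactly; non-matching reads are counted as unassigned.

    Returns (counts, n_unassigned); n_unassigned is 0 in provenance mode.
    """
    counts: Counter = Counter()
    unassigned = 0
    if mode == "provenance":
        for read in good_reads:
            _, ref_id, _ = parse_read_id(read.id)
            counts[ref_id] += 1
    elif mode == "exact_match":
        if products is None:
            raise ValueError("exact_match mode requires the products mapping")
        for read in good_reads:
            ref_id = products.get(read.sequence)
            if ref_id is None:
                unassigned += 1
            else:
                counts[ref_id] += 1
    else:
        raise ValueError(f"unknown composition mode {mode!r}")
    return counts, unassigned


def composition_table(rows: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Assemble per-sample counts into a samples x references matrix.

    All-zero columns are dropped; cells are non-negative integers.
    """
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if table.shape[1]:
        table = table.loc[:, table.sum(axis=0) > 0]
    return table.sort_index(axis=1)


def fp_fn_percent(
    observed: set[str], gold: set[str]
) -> tuple[float, float]:
    """False-positive and false-negative percentages of an observed set.

    FP% = 100 * |observed \\ gold| / |observed| (0 when nothing observed);
    FN% = 100 * |gold \\ observed| / |gold|.
    """
    if not gold:
        raise ValueError("gold set must be non-empty")
    fp = 100.0 * len(observed - gold) / len(observed) if observed else 0.0
    fn = 100.0 * len(gold - observed) / len(gold)
    return fp, fn


def jaccard_matrix(
    table: pd.DataFrame, mode: JaccardMode = "binary"
) -> pd.DataFrame:
    """Pairwise Jaccard distances between the rows of a composition table.

    binary: 1 - |A n B| / |A u B| on presence/absence.
    abundance: 1 - sum(min(x, y)) / sum(max(x, y)) on counts.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    values = table.to_numpy(dtype=float)
    zero_rows = np.where(~values.any(axis=1))[0]
    if zero_rows.size:
        raise ValueError(
            f"all-zero composition rows: {list(table.index[zero_rows])}"
        )
    if mode == "binary":
        condensed = pdist(values > 0, metric="jaccard")
        dist = squareform(condensed)
    elif mode == "abundance":
        mins = np.minimum(values[:, None, :], values[None, :, :]).sum(axis=2)
        maxs = np.maximum(values[:, None, :], values[None, :, :]).sum(axis=2)
        dist = 1.0 - mins / maxs
        np.fill_diagonal(dist, 0.0)
    else:
        raise ValueError(f"unknown Jaccard mode {mode!r}")
    return pd.DataFrame(dist, index=table.index, columns=table.index)


def pcoa_coordinates(
    dist: pd.DataFrame, tol: float = PCOA_EIG_TOL
) -> pd.DataFrame:
    """Classical PCoA of a distance matrix.

    Double-centers -D^2/2 with the centering projector, eigendecomposes,
    keeps axes with eigenvalue > tol (negative eigenvalues of
    non-Euclidean matrices are dropped, no correction), and scales each
    kept eigenvector by the square root of its eigenvalue.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    return pd.DataFrame(
        coords,
        index=dist.index,
        columns=[f"PC{i + 1}" for i in range(int(keep.sum()))],
    )


def pcoa_gold_distance(
    dist: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Euclidean sample-to-gold distances in the joint PCoA embedding.

    Samples and their gold standards must be rows of the same distance
    matrix so that a between-point distance is well defined; all retained
    axes contribute.
    """
    coords = pcoa_coordinates(dist)
    missing = {s for pair in pairs for s in pair} - set(coords.index)
    if missing:
        raise ValueError(f"ids missing from the distance matrix: {sorted(missing)}")
    out = {}
    for sample, gold in pairs:
        delta = coords.loc[sample].to_numpy() - coords.loc[gold].to_numpy()
        out[(sample, gold)] = float(np.linalg.norm(delta))
    return out
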