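"""Locate degenerate primers and extract V3-V4 amplicons with read templates.

The forward primer (341F region) is searched on the forward strand; the
reverse primer (785R region) binds the reverse strand, so its binding site
appears on the forward strand as the primer's reverse complement downstream
of the forward site. The amplicon spans from the start of the forward
primer through the end of the reverse-primer binding site, i.e. it includes
both primer regions — the simulated reads therefore carry primer bases at
their 5' ends, which are later removed by primer trimming.

From each accepted amplicon two read templates are cut: the first L bases
(R1) and the reverse complement of the last L bases (R2), with L = 310 by
default. Amplicons shorter than L are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .io_formats import SeqRecord

# Published degenerate primer sequences for the bacterial V3-V4 region
# (341F / 785R pair); lengths 17 and 21 match the primer-trim lengths used
# downstream.
FWD_PRIMER_341F = "CCTACGGGNGGCWGCAG"
REV_PRIMER_785R = "GACTACHVGGGTATCTAATCC"

DEFAULT_TEMPLATE_LENGTH = 310

#: IUPAC code -> set of concrete bases it matches
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}


def iupac_match(pattern_char: str, base: str) -> bool:
    """True iff `base` belongs to the degeneracy set of IUPAC `pattern_char`."""
    try:
        allowed = IUPAC_SETS[pattern_char]
    except KeyError:
        raise ValueError(f"unknown IUPAC code {pattern_char!r}") from None
    return base in allowed


def find_primer_site(seq: str, primer: str) -> Optional[int]:
    """0-based start of the first IUPAC-aware occurrence of `primer` in `seq`.

    Returns None when the primer does not occur. No mismatches are
    tolerated beyond the degeneracy encoded in the primer itself.
    """
    if not primer:
        raise ValueError("primer must be non-empty")
    sets = [IUPAC_SETS[c] if c in IUPAC_SETS else _unknown(c) for c in primer]
    m = len(primer)
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if all(b in s for b, s in zip(window, sets)):
            return i
    return None


def _unknown(c: str):
    raise ValueError(f"unknown IUPAC code {c!r}")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class AmpliconReference:
    """One reference's extracted amplicon plus its paired read templates."""

    ref_id: str
    amplicon: str
    r1_template: str
    r2_template: str
    template_length: int

    def __post_init__(self) -> None:
        L = self.template_length
        if len(self.amplicon) < L:
            raise ValueError(
                f"{self.ref_id}: amplicon shorter than template length {L}"
            )
        if len(self.r1_template) != L or len(self.r2_template) != L:
            raise ValueError(f"{self.ref_id}: templates must have length {L}")


@dataclass(frozen=True)
class SkippedReference:
    ref_id: str
    reason: str  # fwd-primer-not-found | rev-primer-not-found | amplicon-too-short


ExtractResult = Union[AmpliconReference, SkippedReference]


def extract_amplicon(
    ref: SeqRecord,
    fwd_primer: str = FWD_PRIMER_341F,
    rev_primer: str = REV_PRIMER_785R,
    template_length: int = DEFAULT_TEMPLATE_LENGTH,
) -> ExtractResult:
    """Extract the primer-delimited amplicon and its 2xL read templates.

    Coordinates are 0-based half-open. The reverse-primer site is the first
    occurrence of revcomp(rev_primer) downstream of the forward site (the
    proximal site, i.e. the shortest amplicon). References missing either
    primer, or whose amplicon is shorter than `template_length`, are
    returned as SkippedReference with a machine-readable reason.
    """
    fwd_start = find_primer_site(ref.sequence, fwd_primer)
    if fwd_start is None:
        return SkippedReference(ref.id, "fwd-primer-not-found")
    search_from = fwd_start + len(fwd_primer)
    rev_site = reverse_complement(rev_primer)
    rel = find_primer_site(ref.sequence[search_from:], rev_site)
    if rel is None:
        return SkippedReference(ref.id, "rev-primer-not-found")
    rev_end = search_from + rel + len(rev_site)
    amplicon = ref.sequence[fwd_start:rev_end]
    L = template_length
    if len(amplicon) < L:
        return SkippedReference(ref.id, "amplicon-too-short")
    return AmpliconReference(
        ref_id=ref.id,
        amplicon=amplicon,
        r1_template=amplicon[:L],
        r2_template=reverse_complement(amplicon[-L:]),
        template_length=L,
    )


def extract_amplicons(
    refs: Iterable[SeqRecord],
    fwd_primer: str = FWD_PRIMER_341F,
    rev_primer: str = REV_PRIMER_785R,
    template_length: int = DEFAULT_TEMPLATE_LENGTH,
) -> tuple[list[AmpliconReference], list[SkippedReference]]:
    """Extract amplicons from a reference set; skips are reported, not raised."""
    accepted: list[AmpliconReference] = []
    skipped: list[SkippedReference] = []
    for ref in refs:
        result = extract_amplicon(ref, fwd_primer, rev_primer, template_length)
        if isinstance(result, AmpliconReference):
            accepted.append(result)
        else:
            skipped.append(result)
    return accepted, skipped
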