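"""Alignment diversity statistics: per-column entropy, SNP calls, ORF checks.

Diversity at a column is the Shannon entropy of its residue frequencies in
natural-log units, H = -sum_s f(s) ln f(s), computed over non-gap symbols.
The headline statistic for a group of same-length, same-pattern sequences
is the mean column entropy of the nucleotide alignment, the mean column
entropy of its translation, and their ratio.  Because a single nucleotide
substitution perturbs one of three nucleotide columns under an amino-acid
column, a ratio above one indicates an excess of non-synonymous change.

SNP calling follows the variation-frequency convention: a column is
polymorphic iff it carries at least two distinct non-gap symbols, and its
variation frequency is the fraction of covering sequences that do not carry
the majority symbol.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum

from Bio.Seq import Seq

from .elements import MosaicAlignment
from .errors import ContractError

__all__ = [
    "ColumnFrequencies",
    "DiversityProfile",
    "OrfReport",
    "OrfStatus",
    "SnpCall",
    "alignment_diversity",
    "call_snps",
    "check_orf",
    "column_entropy",
    "column_frequencies",
]


@dataclass(frozen=True)
class ColumnFrequencies:
    """Non-gap symbol frequencies at one alignment column."""

    freqs: dict
    gap_fraction: float

    def __post_init__(self) -> None:
        if self.freqs:
            total = sum(self.freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ContractError(f"column frequencies sum to {total}, not 1")
            if any(f < 0 for f in self.freqs.values()):
                raise ContractError("negative frequency")


def column_frequencies(column: str) -> ColumnFrequencies:
    """Frequencies of non-gap symbols in one column string."""
    nongap = [c for c in column if c != "-"]
    n = len(nongap)
    counts = Counter(nongap)
    freqs = {s: c / n for s, c in counts.items()} if n else {}
    gap_fraction = 1.0 - n / len(column) if column else 0.0
    return ColumnFrequencies(freqs, gap_fraction)


def column_entropy(freqs: ColumnFrequencies | dict) -> float:
    """Shannon entropy in nats, -sum f ln f, with 0 ln 0 = 0."""
    if isinstance(freqs, dict):
        freqs = ColumnFrequencies(freqs, 0.0)
    return -sum(f * math.log(f) for f in freqs.freqs.values() if f > 0.0)


@dataclass(frozen=True)
class DiversityProfile:
    """Per-column entropies and their alignment-wide means.

    ``ratio`` is mean amino-acid diversity over mean nucleotide diversity
    (None when the nucleotide mean is zero).
    """

    nt_entropies: tuple[float, ...]
    aa_entropies: tuple[float, ...] | None
    mean_nt_diversity: float
    mean_aa_diversity: float | None

    @property
    def ratio(self) -> float | None:
        if self.mean_aa_diversity is None or self.mean_nt_diversity == 0.0:
            return None
        return self.mean_aa_diversity / self.mean_nt_diversity


def alignment_diversity(
    aln: MosaicAlignment, translate: bool = True, frame: int = 0
) -> DiversityProfile:
    """Mean per-column entropy of a same-length, same-pattern group.

    Grouping by identical ungapped length (the enforced proxy for "same
    length and element pattern") makes the gapped and ungapped column sets
    equivalent — shared gaps are all-gap columns, which carry no
    frequencies — so entropies are computed position-wise on the ungapped
    sequences.  When ``translate`` is set, each sequence is translated in
    the common reading frame (a trailing stop is dropped) and amino-acid
    entropies are computed over the codon columns.
    """
    if len(aln) == 0:
        raise ContractError("empty alignment")
    ungapped = [aln.ungapped(i) for i in range(len(aln))]
    if len({len(u) for u in ungapped}) != 1:
        raise ContractError(
            "diversity groups must contain sequences of identical ungapped length"
            " (one length per element pattern)"
        )
    nt_entropies = [
        column_entropy(column_frequencies("".join(u[c] for u in ungapped)))
        for c in range(len(ungapped[0]))
    ]
    mean_nt = sum(nt_entropies) / len(nt_entropies) if nt_entropies else 0.0

    aa_entropies = None
    mean_aa = None
    if translate:
        proteins = []
        for seq in ungapped:
            seq = seq[frame:]
            seq = seq[: len(seq) - len(seq) % 3]
            aa = str(Seq(seq).translate())
            if aa.endswith("*"):
                aa = aa[:-1]
            proteins.append(aa)
        if len({len(p) for p in proteins}) != 1:
            raise ContractError("translated rows differ in length")
        aa_entropies = [
            column_entropy(column_frequencies("".join(p[c] for p in proteins)))
            for c in range(len(proteins[0]))
        ]
        mean_aa = sum(aa_entropies) / len(aa_entropies) if aa_entropies else 0.0
    return DiversityProfile(
        tuple(nt_entropies),
        tuple(aa_entropies) if aa_entropies is not None else None,
        mean_nt,
        mean_aa,
    )


@dataclass(frozen=True)
class SnpCall:
    """One polymorphic alignment column."""

    column: int
    alleles: dict
    variation_frequency: float


def call_snps(
    aln: MosaicAlignment, vf_threshold: float = 0.25
) -> tuple[list[SnpCall], list[SnpCall]]:
    """Call polymorphic columns and filter by variation frequency.

    A column is a SNP iff at least two distinct non-gap symbols occur among
    the rows covering it; variation frequency is 1 minus the majority-symbol
    frequency over the non-gap denominator.  The filtered list keeps calls
    with variation frequency strictly above the threshold.
    """
    if len(aln) < 2:
        raise ContractError("SNP calling needs at least two rows")
    all_calls: list[SnpCall] = []
    for c in range(aln.ncols):
        counts = Counter(ch for ch in aln.column(c) if ch != "-")
        if len(counts) < 2:
            continue
        n = sum(counts.values())
        vf = 1.0 - max(counts.values()) / n
        all_calls.append(SnpCall(c, dict(counts), vf))
    filtered = [s for s in all_calls if s.variation_frequency > vf_threshold]
    return all_calls, filtered


class OrfStatus(str, Enum):
    FULL_ORF = "FULL_ORF"
    BROKEN = "BROKEN"


@dataclass(frozen=True)
class OrfReport:
    frame: int
    aa_length: int
    has_internal_stop: bool

    @property
    def status(self) -> OrfStatus:
        return OrfStatus.BROKEN if self.has_internal_stop else OrfStatus.FULL_ORF


def check_orf(seq: str, frame: int = 0) -> OrfReport:
    """Translate an amplicon in the given frame and test ORF integrity.

    FULL_ORF iff no stop codon occurs before the final complete codon; a
    stop in the final codon position is treated as terminal and excluded
    from the amino-acid length.
    """
    if frame not in (0, 1, 2):
        raise ContractError("frame must be 0, 1 or 2")
    seq = seq.upper().replace("-", "")
    if len(seq) < 3:
        raise ContractError("sequence shorter than one codon")
    coding = seq[frame:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    internal = "*" in aa[:-1]
    aa_length = len(aa) - (1 if aa.endswith("*") else 0)
    return OrfReport(frame, aa_length, internal)
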