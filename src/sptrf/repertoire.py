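"""Repertoire comparison between cell classes: amplicon profiles, shared and
unique sequence sets, and delta-delta-Ct (ddCt) relative copy numbers.

Sperm from one animal carry the germline gene repertoire; single immune
cells (coelomocytes) from the same animal can lack genes, carry extra
copies, or carry point-substituted variants.  The three views implemented
here mirror the three experimental read-outs: gel-like amplicon length
profiles from degenerate PCR primers, clone-sequence set comparison, and
qPCR copy-number ratios normalised to a single-copy reference gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ContractError, IntegrityError
from .io import CellClass, CqTable, SequenceRecord

__all__ = [
    "AmpliconProfile",
    "CopyRatioResult",
    "Repertoire",
    "RepertoireComparison",
    "compare_repertoires",
    "ddct_copy_ratio",
    "in_silico_pcr",
    "missing_band_report",
]

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _mismatches(window: str, primer: str) -> int:
    return sum(1 for b, p in zip(window, primer) if b not in _IUPAC_SETS[p])


def _best_site(seq: str, primer: str, start: int, max_mismatch: int, rightmost: bool) -> int | None:
    """Best primer placement at or after ``start``; ties go 5'-most.

    For a plus-strand (forward) primer that is the leftmost placement; for a
    reverse-complemented reverse-primer site the 5' end lies on the minus
    strand, so ties go rightmost on the plus strand.
    """
    best_pos, best_mm = None, max_mismatch + 1
    rng = range(start, len(seq) - len(primer) + 1)
    for pos in rng:
        mm = _mismatches(seq[pos:pos + len(primer)], primer)
        if mm < best_mm or (mm == best_mm and rightmost and best_pos is not None):
            best_pos, best_mm = pos, mm
    return best_pos if best_mm <= max_mismatch else None


def _merge_bands(lengths: list[int], resolution: int) -> list[tuple[int, int]]:
    """Chain-merge sorted lengths whose neighbours lie within ``resolution`` bp.

    Returns (band length, multiplicity) pairs sorted ascending; the band
    length is the rounded mean of its members.
    """
    bands: list[tuple[int, int]] = []
    cluster: list[int] = []
    for ln in sorted(lengths):
        if cluster and ln - cluster[-1] > resolution:
            bands.append((round(sum(cluster) / len(cluster)), len(cluster)))
            cluster = []
        cluster.append(ln)
    if cluster:
        bands.append((round(sum(cluster) / len(cluster)), len(cluster)))
    return bands


@dataclass(frozen=True)
class AmpliconProfile:
    """Predicted amplicon lengths plus their gel-resolution band summary."""

    lengths: tuple[int, ...]
    resolution: int
    bands: tuple[tuple[int, int], ...]  # (length, multiplicity), ascending

    def __post_init__(self) -> None:
        if any(ln <= 0 for ln in self.lengths):
            raise ContractError("amplicon lengths must be positive")

    @property
    def band_lengths(self) -> tuple[int, ...]:
        return tuple(b[0] for b in self.bands)


def in_silico_pcr(
    genes: list[SequenceRecord],
    fwd: str,
    rev: str,
    max_mismatch: int = 2,
    resolution: int = 30,
) -> AmpliconProfile:
    """Predict degenerate-primer amplicon lengths for a set of genes.

    Per gene, the best forward-primer site (IUPAC matching, at most
    ``max_mismatch`` mismatches, ties 5'-most) and the best downstream
    reverse-complement site of the reverse primer are located; the amplicon
    is their inclusive span.  Genes lacking either site contribute nothing.
    Lengths are merged into bands when within ``resolution`` bp, emulating
    gel discrimination.
    """
    fwd = fwd.upper()
    rev_rc = reverse_complement(rev)
    if not set(fwd) <= set(_IUPAC_SETS) or not set(rev_rc) <= set(_IUPAC_SETS):
        raise ContractError("primers must be over the IUPAC nucleotide alphabet")
    lengths: list[int] = []
    for gene in genes:
        seq = gene.ungapped
        f = _best_site(seq, fwd, 0, max_mismatch, rightmost=False)
        if f is None:
            continue
        r = _best_site(seq, rev_rc, f + len(fwd), max_mismatch, rightmost=True)
        if r is None:
            continue
        lengths.append(r + len(rev_rc) - f)
    return AmpliconProfile(tuple(lengths), resolution, tuple(_merge_bands(lengths, resolution)))


def missing_band_report(
    focal: AmpliconProfile, germline: AmpliconProfile
) -> tuple[list[int], list[int]]:
    """Bands absent from / extra in a focal cell relative to the germline.

    A germline band is *missing* when no focal band lies within the shared
    resolution; a focal band with no germline band within resolution is
    *novel*.  Profiles must share a resolution.
    """
    if focal.resolution != germline.resolution:
        raise ContractError("profiles were built at different resolutions")
    res = germline.resolution
    missing = [g for g in germline.band_lengths
               if all(abs(g - f) > res for f in focal.band_lengths)]
    novel = [f for f in focal.band_lengths
             if all(abs(f - g) > res for g in germline.band_lengths)]
    return missing, novel


@dataclass(frozen=True)
class Repertoire:
    """Gene sequence set of one cell (or pooled cell class) of one animal."""

    animal: int
    cell_class: CellClass
    members: frozenset  # of (pattern_name, variant, sequence)

    def __post_init__(self) -> None:
        seqs = [m[2] for m in self.members]
        if len(set(seqs)) != len(seqs):
            raise ContractError("repertoire members must be unique by sequence")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def patterns(self) -> frozenset:
        return frozenset(m[0] for m in self.members)

    @property
    def sequences(self) -> frozenset:
        return frozenset(m[2] for m in self.members)


@dataclass(frozen=True)
class RepertoireComparison:
    shared: frozenset
    unique_a: frozenset
    unique_b: frozenset
    patterns_only_in_a: frozenset
    patterns_only_in_b: frozenset


def compare_repertoires(
    a: Repertoire, b: Repertoire, allow_cross_animal: bool = False
) -> RepertoireComparison:
    """Partition two repertoires into shared and unique members.

    Membership is by exact sequence identity; pattern-level sharing is
    reported separately (patterns present in one repertoire and absent from
    the other, the stronger signal of whole-gene loss).  Comparing cells of
    different animals requires ``allow_cross_animal`` — across genotypes the
    expected sequence overlap is zero.
    """
    if a.animal != b.animal and not allow_cross_animal:
        raise ContractError(
            f"repertoires from animals {a.animal} and {b.animal}; "
            "pass allow_cross_animal=True to compare across genotypes"
        )
    shared_seqs = a.sequences & b.sequences
    shared = frozenset(m for m in a.members | b.members if m[2] in shared_seqs)
    unique_a = frozenset(m for m in a.members if m[2] not in shared_seqs)
    unique_b = frozenset(m for m in b.members if m[2] not in shared_seqs)
    return RepertoireComparison(
        shared, unique_a, unique_b,
        a.patterns - b.patterns, b.patterns - a.patterns,
    )


@dataclass(frozen=True)
class CopyRatioResult:
    """Relative copy number of one target between a focal and reference sample.

    ``ratio`` is efficiency^(-ddCt); None encodes ABSENT (the target gave no
    signal in the focal sample, rendered "X" in reports).
    """

    target: str
    ratio: float | None
    dct_focal: float | None
    dct_reference: float

    @property
    def absent(self) -> bool:
        return self.ratio is None

    def render(self, decimals: int = 3) -> str:
        return "X" if self.absent else f"{self.ratio:.{decimals}f}"


def ddct_copy_ratio(
    cq: CqTable,
    target: str,
    focal_sample: str,
    reference_sample: str,
    efficiency: float = 2.0,
) -> CopyRatioResult:
    """Relative copy number by the delta-delta-Ct method.

    dCt(x) = Cq(target, x) - Cq(reference gene, x); ddCt = dCt(focal) -
    dCt(reference sample); ratio = efficiency^(-ddCt).  An ABSENT target Cq
    in the focal sample yields an ABSENT result; an ABSENT reference-gene Cq
    anywhere is an integrity error because normalisation is impossible.
    """
    ref_gene = cq.reference_target
    for sample in (focal_sample, reference_sample):
        if math.isnan(cq.cq(sample, ref_gene)):
            raise IntegrityError(f"reference gene {ref_gene!r} absent in sample {sample!r}")
    cq_t_ref = cq.cq(reference_sample, target)
    if math.isnan(cq_t_ref):
        raise IntegrityError(
            f"target {target!r} absent in reference sample {reference_sample!r}"
        )
    dct_ref = cq_t_ref - cq.cq(reference_sample, ref_gene)
    cq_t_focal = cq.cq(focal_sample, target)
    if math.isnan(cq_t_focal):
        return CopyRatioResult(target, None, None, dct_ref)
    dct_focal = cq_t_focal - cq.cq(focal_sample, ref_gene)
    ratio = efficiency ** (-(dct_focal - dct_ref))
    return CopyRatioResult(target, ratio, dct_focal, dct_ref)
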