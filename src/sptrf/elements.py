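"""Element library, pattern typing, and element-anchored multiple alignment.

The second exon of every gene in the family is a mosaic of conserved
sequence blocks ("elements") that are present or absent in a fixed genomic
order; the presence/absence vector is the gene's *element pattern* and is
the primary classification axis for the whole analysis.

``decompose`` types an arbitrary nucleotide sequence against an element
library by semi-global alignment of each element consensus, followed by a
dynamic program that selects an ordered, non-overlapping set of placements.
``element_align`` then builds a deterministic multiple alignment anchored on
those placements: each present element's segment is pairwise-aligned to the
element consensus, absent elements become all-gap blocks, and unassigned
inter-element stretches are stacked left-justified.  The result reproduces
the familiar picture in which horizontal gap runs mark missing elements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import edlib
from Bio import Align

from .errors import ContractError, FormatError, LowConfidenceError
from .io import SequenceRecord

__all__ = [
    "NOVEL",
    "DecompositionResult",
    "Element",
    "ElementLibrary",
    "ElementPattern",
    "MosaicAlignment",
    "classify_pattern",
    "decompose",
    "default_library",
    "element_align",
    "variant_group",
]

#: Name returned for a presence vector matching no catalog entry.
NOVEL = "NOVEL"

# Fixed pairwise scoring so alignments are bit-reproducible across runs.
_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND = 1, -1, -4, -1


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = _MATCH
    a.mismatch_score = _MISMATCH
    a.open_gap_score = _GAP_OPEN
    a.extend_gap_score = _GAP_EXTEND
    return a


@dataclass(frozen=True)
class Element:
    """One conserved block of the mosaic exon."""

    index: int
    name: str
    consensus: str
    min_len: int | None = None
    max_len: int | None = None

    def __post_init__(self) -> None:
        if len(self.consensus) < 6:
            raise ContractError(f"element {self.name!r}: consensus shorter than 6 nt")


@dataclass(frozen=True)
class ElementLibrary:
    """Ordered reference elements composing all mosaic genes."""

    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        idx = [e.index for e in self.elements]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ContractError("element indices must be strictly increasing")
        names = [e.name for e in self.elements]
        if len(set(names)) != len(names):
            raise ContractError("element names must be unique")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, i: int) -> Element:
        return self.elements[i]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "elements": [
                {"index": e.index, "name": e.name, "consensus": e.consensus,
                 "min_len": e.min_len, "max_len": e.max_len}
                for e in self.elements
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "ElementLibrary":
        if isinstance(source, (str, Path)):
            source = json.loads(Path(source).read_text())
        try:
            elements = tuple(
                Element(d["index"], d["name"], d["consensus"].upper(),
                        d.get("min_len"), d.get("max_len"))
                for d in source["elements"]
            )
        except (KeyError, TypeError) as exc:
            raise FormatError(f"bad element library JSON: {exc}") from exc
        return cls(elements)


@dataclass(frozen=True)
class ElementPattern:
    """Presence/absence over the library plus a catalog name (or NOVEL)."""

    presence: tuple[bool, ...]
    name: str = NOVEL

    def __post_init__(self) -> None:
        # Catalog entries must contain at least one element; the all-absent
        # vector is tolerated only as the NOVEL outcome of typing a query
        # that matched nothing.
        if not any(self.presence) and self.name != NOVEL:
            raise ContractError("an element pattern must contain at least one element")


def load_catalog(source: str | Path | dict) -> list[ElementPattern]:
    """Load a named-pattern catalog from JSON ({"patterns": {name: [bool,...]}})."""
    if isinstance(source, (str, Path)):
        source = json.loads(Path(source).read_text())
    return [ElementPattern(tuple(bool(b) for b in vec), name)
            for name, vec in source.get("patterns", {}).items()]


def default_library() -> tuple[ElementLibrary, list[ElementPattern]]:
    """Packaged schematic element library and pattern catalog.

    The shipped asset is a synthetic stand-in shaped like the published
    element-pattern diagrams (ordered blocks, named patterns); real-data
    runs should supply a library built from reference alignments.
    """
    payload = json.loads(
        resources.files("sptrf.data").joinpath("default_library.json").read_text()
    )
    return ElementLibrary.from_json(payload), load_catalog(payload)


@dataclass(frozen=True)
class ElementCall:
    """Placement of one element consensus on the query."""

    element: Element
    start: int  # 0-based half-open on the query
    end: int
    identity: float


@dataclass(frozen=True)
class DecompositionResult:
    pattern: ElementPattern
    calls: tuple[ElementCall, ...]
    unassigned_fraction: float
    low_confidence: bool

    @property
    def presence(self) -> tuple[bool, ...]:
        return self.pattern.presence


def _edlib_stats(consensus: str, query: str) -> tuple[int, int, float, float] | None:
    """Best semi-global placement of consensus on query.

    Returns (start, end, identity, coverage) with end exclusive, or None if
    the consensus cannot be placed at all.  Identity is the fraction of
    consensus positions matched exactly; coverage the fraction aligned to a
    query base (as opposed to deleted).  Ties are resolved leftmost.
    """
    res = edlib.align(consensus, query, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end_incl = res["locations"][0]
    if start is None:
        start = 0
    matches = mismatches = deletions = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            matches += n
        elif ch == "X":
            mismatches += n
        elif ch == "D":  # consensus base unaligned (insertion in query is 'I')
            pass
        elif ch == "I":
            deletions += n
    clen = len(consensus)
    identity = matches / clen
    coverage = (matches + mismatches) / clen
    return start, end_incl + 1, identity, coverage


def decompose(
    seq: str,
    lib: ElementLibrary,
    min_identity: float = 0.70,
    min_coverage: float = 0.80,
) -> DecompositionResult:
    """Type a sequence by element presence/absence against the library.

    Each element consensus is placed semi-globally on the query; an element
    is a candidate iff its identity is at least ``min_identity`` over at
    least ``min_coverage`` of the consensus.  Candidates are then filtered
    to an ordered, non-overlapping chain (elements occur as ordered genomic
    blocks) maximising summed identity, ties broken leftmost.  A query with
    more than half its length unassigned is flagged low-confidence rather
    than rejected.
    """
    if len(lib) == 0:
        raise ContractError("empty element library")
    if not (0 < min_identity <= 1) or not (0 < min_coverage <= 1):
        raise ContractError("thresholds must be in (0, 1]")
    seq = seq.upper().replace("-", "")
    shortest = min(len(e.consensus) for e in lib)
    if len(seq) < shortest:
        raise ContractError("query shorter than the shortest element consensus")

    candidates: list[ElementCall] = []
    for elem in lib:
        hit = _edlib_stats(elem.consensus, seq)
        if hit is None:
            continue
        start, end, identity, coverage = hit
        if identity >= min_identity and coverage >= min_coverage:
            candidates.append(ElementCall(elem, start, end, identity))

    # Weighted chain selection: placements must respect library order and
    # must not overlap on the query.  Semi-global placement ends can wobble
    # by a few bases, so small overlaps are tolerated here and trimmed below.
    overlap_tol = 6
    n = len(candidates)
    best_score = [0.0] * n
    parent = [-1] * n
    for i, ci in enumerate(candidates):
        best_score[i] = ci.identity
        for j in range(i):
            cj = candidates[j]
            if cj.element.index < ci.element.index and cj.end <= ci.start + overlap_tol:
                cand = best_score[j] + ci.identity
                if cand > best_score[i] + 1e-12:
                    best_score[i] = cand
                    parent[i] = j
    chosen: list[ElementCall] = []
    if n:
        i = max(range(n), key=lambda k: (best_score[k], -candidates[k].start))
        while i != -1:
            chosen.append(candidates[i])
            i = parent[i]
        chosen.reverse()
    # trim residual overlaps so reported intervals partition cleanly
    trimmed: list[ElementCall] = []
    prev_end = 0
    for call in chosen:
        start = max(call.start, prev_end)
        if start >= call.end:
            continue
        if start != call.start:
            call = ElementCall(call.element, start, call.end, call.identity)
        trimmed.append(call)
        prev_end = call.end
    chosen = trimmed

    presence = [False] * len(lib)
    pos = {e.index: k for k, e in enumerate(lib)}
    covered = 0
    for call in chosen:
        presence[pos[call.element.index]] = True
        covered += call.end - call.start
    unassigned = 1.0 - covered / len(seq)
    return DecompositionResult(
        ElementPattern(tuple(presence)), tuple(chosen), unassigned,
        unassigned > 0.5 or not chosen,
    )


def classify_pattern(presence: Sequence[bool], catalog: Iterable[ElementPattern]) -> str:
    """Exact presence-vector lookup; anything else is NOVEL, never a guess."""
    key = tuple(bool(b) for b in presence)
    names = [p.name for p in catalog]
    if len(set(names)) != len(names):
        raise ContractError("catalog names must be unique")
    for pat in catalog:
        if pat.presence == key:
            return pat.name
    return NOVEL


@dataclass
class MosaicAlignment:
    """Gapped multiple alignment whose columns carry element classes.

    ``column_classes[c]`` is the library index of the element block column
    ``c`` belongs to, or None for inter-element / unassigned columns.
    Ungapping any row reproduces its input sequence exactly.
    """

    records: list[SequenceRecord]
    rows: list[str]
    column_classes: list[int | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ContractError("alignment rows differ in length")
        if self.rows and self.column_classes and len(self.column_classes) != len(self.rows[0]):
            raise ContractError("column_classes length mismatch")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def column(self, c: int) -> str:
        return "".join(row[c] for row in self.rows)

    def to_fasta(self, path: str | Path) -> None:
        from .io import write_fasta

        write_fasta(
            [SequenceRecord(r.id, row, r.description, aligned=True, iupac=True)
             for r, row in zip(self.records, self.rows)],
            path,
        )


def _align_segment_to_consensus(segment: str, consensus: str) -> tuple[list[str], list[str]]:
    """Needleman-Wunsch of segment against consensus.

    Returns (per_consensus, inserts): ``per_consensus[i]`` is the segment
    character aligned to consensus position i ('-' if deleted);
    ``inserts[i]`` collects segment characters inserted *before* consensus
    position i (index len(consensus) = after the last).
    """
    aln = _aligner().align(consensus, segment)[0]
    per_consensus = ["-"] * len(consensus)
    inserts = [""] * (len(consensus) + 1)
    t_blocks, q_blocks = aln.aligned
    prev_t_end = 0
    prev_q_end = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if qs > prev_q_end:  # segment bases skipped relative to consensus
            inserts[ts] += segment[prev_q_end:qs]
        for k in range(te - ts):
            per_consensus[ts + k] = segment[qs + k]
        prev_t_end, prev_q_end = te, qe
    if prev_q_end < len(segment):
        inserts[len(consensus)] += segment[prev_q_end:]
    return per_consensus, inserts


def element_align(
    seqs: list[SequenceRecord],
    lib: ElementLibrary,
    min_identity: float = 0.70,
    min_coverage: float = 0.80,
    force: bool = False,
) -> MosaicAlignment:
    """Deterministic element-anchored multiple alignment.

    Every sequence is decomposed; per element, the present sequences'
    segments are pairwise-aligned to that element's consensus and stacked
    (insertions relative to the consensus are merged left-justified), while
    sequences lacking the element receive an all-gap block.  Unassigned
    stretches between placements are stacked left-justified in inter-element
    blocks keyed by the next element in library order.
    """
    if not seqs:
        raise ContractError("no sequences to align")
    decomps = []
    for rec in seqs:
        d = decompose(rec.ungapped, lib, min_identity, min_coverage)
        if d.low_confidence and not force:
            raise LowConfidenceError(
                f"record {rec.id!r}: decomposition is low-confidence; pass force=True to align anyway"
            )
        decomps.append(d)

    lib_order = [e.index for e in lib]
    # Per row: element index -> segment; "pre" slot keyed by next element
    # index (library position), tail keyed by len(lib).
    seg_by_elem: list[dict[int, str]] = []
    pre_by_slot: list[dict[int, str]] = []
    for rec, d in zip(seqs, decomps):
        seq = rec.ungapped
        segs: dict[int, str] = {}
        pres: dict[int, str] = {}
        cursor = 0
        for call in d.calls:
            lib_pos = lib_order.index(call.element.index)
            if call.start > cursor:
                pres[lib_pos] = seq[cursor:call.start]
            segs[lib_pos] = seq[call.start:call.end]
            cursor = call.end
        if cursor < len(seq):
            pres[len(lib)] = seq[cursor:]
        seg_by_elem.append(segs)
        pre_by_slot.append(pres)

    rows = [""] * len(seqs)
    classes: list[int | None] = []

    def _stack_plain(slot: int) -> None:
        width = max((len(p.get(slot, "")) for p in pre_by_slot), default=0)
        if width == 0:
            return
        for i, p in enumerate(pre_by_slot):
            s = p.get(slot, "")
            rows[i] += s + "-" * (width - len(s))
        classes.extend([None] * width)

    for lib_pos, elem in enumerate(lib):
        _stack_plain(lib_pos)
        present = [i for i in range(len(seqs)) if lib_pos in seg_by_elem[i]]
        if not present:
            continue
        per_cons: dict[int, list[str]] = {}
        ins: dict[int, list[str]] = {}
        for i in present:
            pc, inserts = _align_segment_to_consensus(seg_by_elem[i][lib_pos], elem.consensus)
            per_cons[i] = pc
            ins[i] = inserts
        clen = len(elem.consensus)
        ins_width = [max(len(ins[i][g]) for i in present) for g in range(clen + 1)]
        block_cols = sum(ins_width) + clen
        for i in range(len(seqs)):
            if i not in per_cons:
                rows[i] += "-" * block_cols
                continue
            out = []
            for g in range(clen + 1):
                s = ins[i][g]
                out.append(s + "-" * (ins_width[g] - len(s)))
                if g < clen:
                    out.append(per_cons[i][g])
            rows[i] += "".join(out)
        for g in range(clen + 1):
            classes.extend([elem.index] * ins_width[g])
            if g < clen:
                classes.append(elem.index)
    _stack_plain(len(lib))

    aln = MosaicAlignment(list(seqs), rows, classes)
    for i, rec in enumerate(seqs):
        if aln.ungapped(i) != rec.ungapped:
            raise AssertionError(f"ungapping invariant broken for {rec.id!r}")
    return aln


def variant_group(seqs: list[SequenceRecord]) -> tuple[list[int], float]:
    """Assign variant numbers by exact sequence identity, in first-occurrence order.

    Returns the per-input variant numbers (1-based) and the redundancy,
    defined as 1 - unique/total: the fraction of inputs duplicating an
    already-seen sequence.
    """
    if not seqs:
        raise ContractError("no sequences to group")
    seen: dict[str, int] = {}
    numbers = []
    for rec in seqs:
        key = rec.ungapped
        if key not in seen:
            seen[key] = len(seen) + 1
        numbers.append(seen[key])
    redundancy = 1.0 - len(seen) / len(seqs)
    return numbers, redundancy
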