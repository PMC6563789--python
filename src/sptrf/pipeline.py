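"""End-to-end analysis steps that chain the per-module operations.

These are the entry points a study-level analysis actually runs: type a
clone library against an element library, collapse it to a repertoire,
contrast coelomocyte and sperm repertoires and copy numbers, and estimate
the per-gene somatic deletion probability from qPCR absent-gene calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .elements import (ElementLibrary, MosaicAlignment, classify_pattern,
                       decompose, element_align, variant_group)
from .errors import ContractError
from .io import CellClass, CqTable, SequenceRecord
from .phylogeny import CladePurityReport, clade_purity, jc_matrix, nj_tree
from .repertoire import Repertoire, ddct_copy_ratio

__all__ = [
    "TypedRecord",
    "build_repertoire",
    "estimate_deletion_rate",
    "pattern_purity_of_records",
    "type_records",
]


@dataclass(frozen=True)
class TypedRecord:
    record: SequenceRecord
    pattern_name: str
    variant: int
    low_confidence: bool


def type_records(
    records: list,
    lib: ElementLibrary,
    catalog: list,
    min_identity: float = 0.70,
    min_coverage: float = 0.80,
) -> list:
    """Decompose, classify and variant-number a set of sequences.

    Variant numbers are assigned within each pattern by first occurrence of
    each distinct sequence, mirroring the pattern-then-variant naming used
    for cloned amplicons.
    """
    typed: list[tuple[SequenceRecord, str, bool]] = []
    for rec in records:
        d = decompose(rec.ungapped, lib, min_identity, min_coverage)
        name = classify_pattern(d.presence, catalog)
        typed.append((rec, name, d.low_confidence))
    out: list[TypedRecord] = []
    by_pattern: dict[str, dict[str, int]] = {}
    for rec, name, low in typed:
        seen = by_pattern.setdefault(name, {})
        key = rec.ungapped
        if key not in seen:
            seen[key] = len(seen) + 1
        out.append(TypedRecord(rec, name, seen[key], low))
    return out


def build_repertoire(
    records: list,
    lib: ElementLibrary,
    catalog: list,
    animal: int,
    cell_class: CellClass,
) -> Repertoire:
    """Collapse a clone library to its unique-sequence repertoire."""
    typed = type_records(records, lib, catalog)
    members = {(t.pattern_name, t.variant, t.record.ungapped) for t in typed}
    return Repertoire(animal, cell_class, frozenset(members))


def estimate_deletion_rate(
    cq: CqTable,
    gene_targets: dict,
    focal_samples: dict,
    reference_samples: dict,
) -> tuple[float, dict]:
    """Estimate the per-gene somatic deletion probability from qPCR.

    For every focal (somatic) sample, each of its animal's germline gene
    targets is quantified against the animal's sperm reference sample with
    the delta-delta-Ct method; a gene is called deleted when the result is
    ABSENT.  Returns the fraction of (cell, gene) pairs called deleted —
    the point estimate of p_del — and the per-sample per-target ratios.

    Parameters map animal -> list of gene targets, animal -> list of focal
    sample ids, animal -> sperm reference sample id.
    """
    n = deleted = 0
    ratios: dict = {}
    for animal, targets in gene_targets.items():
        ref_sample = reference_samples[animal]
        for sample in focal_samples.get(animal, []):
            for target in targets:
                res = ddct_copy_ratio(cq, target, sample, ref_sample)
                ratios[(sample, target)] = res
                n += 1
                if res.absent:
                    deleted += 1
    if n == 0:
        raise ContractError("no (sample, target) pairs to evaluate")
    return deleted / n, ratios


def pattern_purity_of_records(
    records: list,
    lib: ElementLibrary,
    labels: dict,
    groups: list | None = None,
) -> tuple[CladePurityReport, MosaicAlignment]:
    """Align records, build the NJ tree and report element-pattern monophyly.

    ``labels`` maps record id -> pattern name; duplicate sequences should be
    collapsed beforehand (identical rows give zero distances, which NJ
    handles but which dilute the purity question).
    """
    if len(records) < 4:
        raise ContractError("purity analysis needs at least 4 sequences")
    aln = element_align(records, lib)
    tree = nj_tree(jc_matrix(aln, saturation="clamp"))
    return clade_purity(tree, labels, groups), aln
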