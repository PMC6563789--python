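"""Forward simulator: germline mosaic gene families and somatically
diversified single-cell genomes, with full ground truth.

The model mirrors the biology the pipeline is built to detect.  A shared
element library defines conserved blocks; named element patterns are
ordered presence subsets of the library, each with its own realisation of
every present element (patterns are old relative to genotypes, so
between-pattern divergence exceeds between-genotype divergence).  Each
animal (genotype) carries one gene per pattern slot, diverged from the
pattern realisation.  Sperm cells carry the germline unchanged; single
somatic immune cells undergo whole-gene deletion, whole-gene duplication
and point substitution, with an optional rejection step that keeps every
reading frame intact (matching the observed absence of pseudogenes).
Downstream measurements — clone libraries sampled with redundancy and qPCR
quantification cycles with Gaussian noise — are generated from the same
ground truth, so every analysis stage has a recoverable oracle.

All element lengths and primer sites are multiples of three and stop-free
in frame 0, so a full amplicon always translates cleanly from its first
base.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .elements import Element, ElementLibrary, ElementPattern
from .errors import ContractError
from .io import ABSENT, CellClass, CqTable, SequenceRecord

__all__ = [
    "CellGenome",
    "FWD_PRIMER",
    "REV_PRIMER",
    "SimulationConfig",
    "Study",
    "TruthRecord",
    "simulate_cell",
    "simulate_clones",
    "simulate_cq",
    "simulate_germline",
    "simulate_study",
]

#: Degenerate primer pair embedded at the amplicon boundaries of every
#: simulated gene (synthetic placeholders; real-data runs supply their own).
FWD_PRIMER = "GARGCWATGGGCACCCAYGAR"  # 21 nt, frame-0 stop-free realisations
REV_PRIMER = "YTCYTGRGTSCCCATWGCYTC"  # 21 nt on the minus strand

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}

_PATTERN_NAMES = ["A3", "C2", "D1", "C3", "D5", "B3", "E2", "01", "02",
                  "A4", "G2", "D2", "B8", "E3", "A1", "C5"]


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the forward simulator.

    Defaults are scaled to the published study: seven genes per genotype
    (matching the six-or-seven-band sperm amplicon profiles), three
    genotypes, a catalog of twelve element patterns, somatic deletion and
    duplication acting on whole genes, and ORF-preserving substitution.
    """

    n_elements: int = 15
    n_patterns: int = 12
    genes_per_genotype: int = 7
    n_genotypes: int = 3
    element_len_range: tuple[int, int] = (51, 120)
    pattern_divergence: float = 0.10
    germline_divergence: float = 0.03
    p_del: float = 0.2
    p_dup: float = 0.1
    mu: float = 0.002
    orf_preserving: bool = True
    n_cells: int = 3
    clones_per_cell: int = 60
    qpcr_noise_sd: float = 0.15
    cq_base: float = 20.0
    amplification_failure_p: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pattern_divergence", "germline_divergence", "p_del", "p_dup",
                     "amplification_failure_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"{name} must be in [0, 1], got {v}")
        if self.mu < 0 or self.qpcr_noise_sd < 0:
            raise ContractError("mu and qpcr_noise_sd must be non-negative")
        if self.n_patterns > 2 ** self.n_elements - 1:
            raise ContractError("more patterns requested than presence subsets exist")
        lo, hi = self.element_len_range
        if lo < 6 or hi < lo:
            raise ContractError("bad element length range")


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            return codon


def _stop_free_sequence(length: int, rng: np.random.Generator) -> str:
    assert length % 3 == 0
    return "".join(_random_codon(rng) for _ in range(length // 3))


def _realize_primer(primer: str, rng: np.random.Generator, revcomp: bool) -> str:
    """Concrete stop-free (frame 0, plus strand) realisation of a degenerate primer."""
    from .repertoire import reverse_complement

    for _ in range(100):
        site = "".join(rng.choice(list(_IUPAC[c])) for c in primer)
        plus = reverse_complement(site) if revcomp else site
        codons = {plus[i:i + 3] for i in range(0, len(plus), 3)}
        if not codons & _STOPS:
            return plus
    raise ContractError("could not realise a stop-free primer site")


def _mutate(seq: str, rate: float, rng: np.random.Generator, orf_preserving: bool) -> str:
    """Per-site substitution at the given rate; in ORF-preserving mode a
    substitution that would create an in-frame (frame 0) stop is resampled
    among the remaining bases, or skipped if none is viable."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for pos in hits:
        current = chars[pos]
        alternatives = [b for b in _BASES if b != current]
        rng.shuffle(alternatives)
        for alt in alternatives:
            if not orf_preserving:
                chars[pos] = alt
                break
            cstart = (pos // 3) * 3
            codon = chars[cstart:cstart + 3]
            codon[pos - cstart] = alt
            if "".join(codon) not in _STOPS:
                chars[pos] = alt
                break
    return "".join(chars)


@dataclass(frozen=True)
class GermlineGene:
    gene_id: str
    pattern_name: str
    sequence: str


@dataclass(frozen=True)
class Event:
    op: str  # DELETE | DUPLICATE | SUBSTITUTE
    gene_id: str
    detail: str = ""


@dataclass(frozen=True)
class CellGene:
    gene_id: str
    pattern_name: str
    sequence: str
    copy_number: int


@dataclass
class CellGenome:
    cell_id: str
    animal: int
    cell_class: CellClass
    genes: list  # of CellGene
    event_log: list = field(default_factory=list)  # of Event

    @property
    def gene_ids(self) -> set:
        return {g.gene_id for g in self.genes}


@dataclass
class TruthRecord:
    """Everything needed to recompute downstream expectations without
    re-simulation: germline content, per-cell events, true copy numbers."""

    germline: dict  # animal -> {gene_id: {"pattern":..., "sequence":...}}
    events: dict  # cell_id -> list of (op, gene_id, detail)
    copy_numbers: dict  # cell_id -> {gene_id: copies, 0 when deleted}
    clone_gene: dict = field(default_factory=dict)  # clone id -> gene_id

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


@dataclass
class GermlineSimulation:
    library: ElementLibrary
    catalog: list  # of ElementPattern
    pattern_realizations: dict  # pattern name -> {"elements": {idx: seq}, "fwd":..., "rev_rc":...}
    genotypes: dict  # animal -> list of GermlineGene


def _make_library(cfg: SimulationConfig, rng: np.random.Generator) -> ElementLibrary:
    lo, hi = cfg.element_len_range
    elements = []
    for i in range(cfg.n_elements):
        length = 3 * int(rng.integers(math.ceil(lo / 3), hi // 3 + 1))
        elements.append(Element(i, f"e{i + 1}", _stop_free_sequence(length, rng),
                                min_len=length, max_len=length))
    return ElementLibrary(tuple(elements))


def _make_catalog(cfg: SimulationConfig, rng: np.random.Generator) -> list:
    names = list(_PATTERN_NAMES)
    while len(names) < cfg.n_patterns:
        names.append(f"P{len(names) + 1}")
    seen: set = set()
    catalog = []
    for k in range(cfg.n_patterns):
        while True:
            presence = tuple(bool(b) for b in rng.random(cfg.n_elements) < 0.6)
            # the terminal element is the family's name-defining block and is
            # present in every pattern
            presence = presence[:-1] + (True,)
            if sum(presence) >= 3 and presence not in seen:
                seen.add(presence)
                break
        catalog.append(ElementPattern(presence, names[k]))
    return catalog


def simulate_germline(cfg: SimulationConfig, seed: int) -> GermlineSimulation:
    """Generate the element library, pattern catalog and genotype gene sets.

    Gene slots (one per pattern, shared across genotypes) diverge from the
    pattern realisation by ``germline_divergence`` per genotype, so exact
    cross-genotype sequence sharing has probability ~0 at the default
    divergence and genotypes are identical when divergence is 0.
    """
    rng = _rng(seed, 0)
    library = _make_library(cfg, rng)
    catalog = _make_catalog(cfg, rng)
    if cfg.genes_per_genotype > len(catalog):
        raise ContractError("genes_per_genotype exceeds the pattern catalog size")

    gene_patterns = [catalog[i] for i in
                     rng.choice(len(catalog), size=cfg.genes_per_genotype, replace=False)]
    realizations: dict = {}
    for pat in catalog:
        prng = _rng(seed, 1, catalog.index(pat))
        realizations[pat.name] = {
            "elements": {
                e.index: _mutate(e.consensus, cfg.pattern_divergence, prng, cfg.orf_preserving)
                for e, present in zip(library, pat.presence) if present
            },
            "fwd": _realize_primer(FWD_PRIMER, prng, revcomp=False),
            "rev_rc": _realize_primer(REV_PRIMER, prng, revcomp=True),
        }

    genotypes: dict = {}
    for animal in range(1, cfg.n_genotypes + 1):
        genes = []
        for slot, pat in enumerate(gene_patterns):
            grng = _rng(seed, 2, animal, slot)
            real = realizations[pat.name]
            body = "".join(real["elements"][e.index]
                           for e, present in zip(library, pat.presence) if present)
            body = _mutate(body, cfg.germline_divergence, grng, cfg.orf_preserving)
            seq = real["fwd"] + body + real["rev_rc"]
            genes.append(GermlineGene(f"A{animal}.{pat.name}", pat.name, seq))
        genotypes[animal] = genes
    return GermlineSimulation(library, catalog, realizations, genotypes)


def simulate_cell(
    germline: list,
    cfg: SimulationConfig,
    cell_class: CellClass,
    seed: int,
    cell_id: str,
    animal: int,
) -> CellGenome:
    """Apply per-cell somatic events to a germline gene list.

    Sperm are germline carriers: all somatic rates are forced to zero.  For
    somatic cells each gene is deleted with ``p_del``; each surviving gene
    gains one extra copy with ``p_dup`` and acquires per-site substitutions
    at rate ``mu`` (ORF-preserving by rejection when configured).
    """
    somatic = cell_class is not CellClass.SPERM
    p_del = cfg.p_del if somatic else 0.0
    p_dup = cfg.p_dup if somatic else 0.0
    mu = cfg.mu if somatic else 0.0
    genes: list[CellGene] = []
    events: list[Event] = []
    for slot, g in enumerate(germline):
        rng = _rng(seed, 3, animal, slot)
        if rng.random() < p_del:
            events.append(Event("DELETE", g.gene_id))
            continue
        copies = 1
        if rng.random() < p_dup:
            copies = 2
            events.append(Event("DUPLICATE", g.gene_id, "copy_number=2"))
        seq = _mutate(g.sequence, mu, rng, cfg.orf_preserving)
        nsub = sum(1 for a, b in zip(seq, g.sequence) if a != b)
        if nsub:
            events.append(Event("SUBSTITUTE", g.gene_id, f"n={nsub}"))
        genes.append(CellGene(g.gene_id, g.pattern_name, seq, copies))
    return CellGenome(cell_id, animal, cell_class, genes, events)


def simulate_clones(cell: CellGenome, clones_per_cell: int, seed: int) -> list:
    """Sample a clone library with replacement, proportional to copy number.

    Returns :class:`SequenceRecord` clones whose descriptions carry the true
    source gene id (the oracle for redundancy and typing checks).
    """
    if not cell.genes:
        raise ContractError(f"cell {cell.cell_id} has no genes to clone")
    rng = _rng(seed, 4)
    weights = np.array([g.copy_number for g in cell.genes], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(cell.genes), size=clones_per_cell, p=weights)
    records = []
    for i, k in enumerate(picks):
        g = cell.genes[k]
        records.append(SequenceRecord(
            f"{cell.cell_id}.clone{i + 1:03d}", g.sequence, f"source={g.gene_id}"
        ))
    return records


def simulate_cq(
    copy_numbers: dict,
    noise_sd: float,
    seed: int,
    base: float = 20.0,
) -> dict:
    """Quantification cycles from true copy numbers.

    Cq = base - log2(copies) + Normal(0, noise_sd); zero copies give the
    ABSENT sentinel (no amplification signal).
    """
    rng = _rng(seed, 5)
    out = {}
    for target in sorted(copy_numbers):
        copies = copy_numbers[target]
        if copies < 0:
            raise ContractError("copy numbers must be >= 0")
        if copies == 0:
            out[target] = ABSENT
        else:
            noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            out[target] = base - math.log2(copies) + noise
    return out


@dataclass
class Study:
    """One full simulated experiment with its ground truth."""

    cfg: SimulationConfig
    germline: GermlineSimulation
    cells: list  # of CellGenome (sperm first, then coelomocytes, per animal)
    clone_libraries: dict  # cell_id -> list of SequenceRecord
    cq: CqTable
    truth: TruthRecord

    def cells_of(self, animal: int, cell_class: CellClass) -> list:
        return [c for c in self.cells if c.animal == animal and c.cell_class is cell_class]


def simulate_study(cfg: SimulationConfig, seed: int) -> Study:
    """Simulate germline, cells, clone libraries and a Cq table end to end.

    Per genotype, ``n_cells`` sperm (identical by construction) and
    ``n_cells`` coelomocytes are generated.  The Cq table has one sample
    per cell with one target per germline gene plus the single-copy
    reference gene.  The RNG is split hierarchically by (stage, animal,
    cell), so adding cells does not perturb earlier cells' draws.
    """
    germ = simulate_germline(cfg, seed)
    cells: list[CellGenome] = []
    clone_libraries: dict = {}
    truth = TruthRecord(
        germline={
            a: {g.gene_id: {"pattern": g.pattern_name, "sequence": g.sequence}
                for g in genes}
            for a, genes in germ.genotypes.items()
        },
        events={},
        copy_numbers={},
    )
    cq_rows = []
    for animal, genes in germ.genotypes.items():
        for cls, code in ((CellClass.SPERM, "S"), (CellClass.COELOMOCYTE, "C")):
            for k in range(cfg.n_cells):
                cell_id = f"{code}{animal}c{k + 1}"
                cell_seed_key = (animal, 0 if cls is CellClass.SPERM else 1, k)
                cell = simulate_cell(
                    genes, cfg, cls,
                    int(_rng(seed, 6, *cell_seed_key).integers(2 ** 31)),
                    cell_id, animal,
                )
                cells.append(cell)
                truth.events[cell_id] = [(e.op, e.gene_id, e.detail) for e in cell.event_log]
                copies = {g.gene_id: 0 for g in genes}
                for cg in cell.genes:
                    copies[cg.gene_id] = cg.copy_number
                truth.copy_numbers[cell_id] = copies
                if cell.genes:
                    clones = simulate_clones(
                        cell, cfg.clones_per_cell,
                        int(_rng(seed, 7, *cell_seed_key).integers(2 ** 31)),
                    )
                    clone_libraries[cell_id] = clones
                    for rec in clones:
                        truth.clone_gene[rec.id] = rec.description.split("=", 1)[1]
                targets = dict(copies)
                targets["SpGAPDH"] = 1
                cqs = simulate_cq(
                    targets, cfg.qpcr_noise_sd,
                    int(_rng(seed, 8, *cell_seed_key).integers(2 ** 31)),
                    base=cfg.cq_base,
                )
                for target, value in cqs.items():
                    cq_rows.append({
                        "sample_id": cell_id,
                        "cell_class": cls.value,
                        "target": target,
                        "cq": value,
                    })
    import pandas as pd

    cq = CqTable(pd.DataFrame(cq_rows))
    return Study(cfg, germ, cells, clone_libraries, cq, truth)
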