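"""Reading and writing the external representations the pipeline touches.

Covers plain and aligned FASTA, the sequence-naming dialect that encodes
provenance (source cell class, animal, element pattern, variant), and CSV
tables of qPCR quantification cycles (Cq).

Naming dialect
--------------
``<S|C|M><animal>-<pattern>-<variant>`` where S = sperm, C = coelomocyte and
M = found in both cell classes, e.g. ``C3-E2-14`` is variant 14 of the E2
element pattern sequenced from a coelomocyte of animal 3.  Published figures
print names in this style without a rigid grammar; this package imposes one
so that names round-trip losslessly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError, IntegrityError, NameParseError

__all__ = [
    "ABSENT",
    "CellClass",
    "CqTable",
    "ProvenanceTag",
    "SequenceRecord",
    "format_name",
    "parse_name",
    "read_cq_table",
    "read_fasta",
    "write_fasta",
]

_STRICT_ALPHABET = frozenset("ACGT")
_IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: Sentinel Cq for a target undetected by qPCR (rendered "X" in reports).
ABSENT = math.nan


class CellClass(str, Enum):
    """Origin of a sequence or sample."""

    SPERM = "sperm"
    COELOMOCYTE = "coelomocyte"
    BOTH = "both"

    @property
    def code(self) -> str:
        return {"sperm": "S", "coelomocyte": "C", "both": "M"}[self.value]

    @classmethod
    def from_code(cls, code: str) -> "CellClass":
        try:
            return {"S": cls.SPERM, "C": cls.COELOMOCYTE, "M": cls.BOTH}[code]
        except KeyError:
            raise NameParseError(f"unknown cell-class code {code!r}") from None


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide sequence with free-text description.

    The sequence is canonicalised to upper case on construction.  By default
    only A/C/G/T are accepted; pass ``iupac=True`` to tolerate ambiguity
    codes and ``aligned=True`` to tolerate ``-`` gap characters.
    """

    id: str
    sequence: str
    description: str = ""
    iupac: bool = field(default=False, compare=False)
    aligned: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        allowed = _IUPAC_ALPHABET if self.iupac else _STRICT_ALPHABET
        if self.aligned:
            allowed = allowed | {"-"}
        bad = set(seq) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: disallowed symbols {sorted(bad)} "
                f"(iupac={self.iupac}, aligned={self.aligned})"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass(frozen=True)
class ProvenanceTag:
    """Decoded sequence name: cell class, animal, element pattern, variant."""

    source: CellClass
    animal: int
    pattern_name: str
    variant: int

    def __post_init__(self) -> None:
        if self.animal < 1:
            raise NameParseError(f"animal number must be >= 1, got {self.animal}")
        if self.variant < 1:
            raise NameParseError(f"variant number must be >= 1, got {self.variant}")


_NAME_RE = re.compile(r"^([SCM])([1-9]\d*)-([A-Za-z0-9]+)-([1-9]\d*)$")


def parse_name(name: str) -> ProvenanceTag:
    """Parse ``<S|C|M><animal>-<pattern>-<variant>`` into a :class:`ProvenanceTag`.

    Raises :class:`NameParseError` for any other shape; callers typically keep
    the record and leave its tag absent.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise NameParseError(f"id {name!r} does not match <S|C|M><animal>-<pattern>-<variant>")
    code, animal, pattern, variant = m.groups()
    return ProvenanceTag(CellClass.from_code(code), int(animal), pattern, int(variant))


def format_name(tag: ProvenanceTag) -> str:
    """Inverse of :func:`parse_name`."""
    return f"{tag.source.code}{tag.animal}-{tag.pattern_name}-{tag.variant}"


def read_fasta(path: str | Path, *, aligned: bool = False, iupac: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order, upper-cased.

    Gap characters are rejected unless ``aligned=True``; ambiguity codes are
    rejected unless ``iupac=True``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, seq, desc, iupac=iupac, aligned=aligned))
    if not records and path.stat().st_size > 0:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving id, description and sequence."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


@dataclass
class CqTable:
    """Long-format qPCR quantification cycles.

    One row per (sample, target); ``cq`` is in cycles, NaN encodes a target
    that produced no amplification signal (printed as ``X``).  The
    single-copy reference gene must be measured in every sample so that
    delta-delta-Ct normalisation is always possible.
    """

    data: pd.DataFrame
    reference_target: str = "SpGAPDH"

    def __post_init__(self) -> None:
        required = {"sample_id", "cell_class", "target", "cq"}
        missing = required - set(self.data.columns)
        if missing:
            raise IntegrityError(f"Cq table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["sample_id", "target"])
        if dup.any():
            pair = self.data.loc[dup.idxmax(), ["sample_id", "target"]].tolist()
            raise IntegrityError(f"duplicate (sample, target) pair: {pair}")
        for sample, grp in self.data.groupby("sample_id"):
            ref = grp[grp["target"] == self.reference_target]
            if ref.empty:
                raise IntegrityError(
                    f"sample {sample!r} lacks the reference target {self.reference_target!r}"
                )
            if ref["cq"].isna().any():
                raise IntegrityError(
                    f"sample {sample!r}: reference target {self.reference_target!r} is absent;"
                    " cannot normalise"
                )

    def cq(self, sample_id: str, target: str) -> float:
        """Cq in cycles, or NaN if the target was undetected."""
        sel = self.data[(self.data["sample_id"] == sample_id) & (self.data["target"] == target)]
        if sel.empty:
            raise KeyError(f"no row for sample {sample_id!r}, target {target!r}")
        return float(sel["cq"].iloc[0])

    def is_absent(self, sample_id: str, target: str) -> bool:
        return math.isnan(self.cq(sample_id, target))

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))

    @property
    def targets(self) -> list[str]:
        return list(dict.fromkeys(self.data["target"]))

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["cq"] = out["cq"].map(lambda v: "X" if (isinstance(v, float) and math.isnan(v)) else v)
        out.to_csv(path, index=False)


def read_cq_table(path: str | Path, reference_target: str = "SpGAPDH") -> CqTable:
    """Read a Cq CSV with columns sample_id, cell_class, target, cq.

    An empty cq cell or the literal ``X`` encodes an undetected target.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "cell_class": str, "target": str})
    required = {"sample_id", "cell_class", "target", "cq"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")

    def _parse_cq(v: object) -> float:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ABSENT
        s = str(v).strip()
        if s == "" or s.upper() == "X":
            return ABSENT
        try:
            cq = float(s)
        except ValueError:
            raise FormatError(f"{path}: unparsable cq value {v!r}") from None
        if cq <= 0:
            raise FormatError(f"{path}: non-positive cq value {cq}")
        return cq

    df["cq"] = df["cq"].map(_parse_cq)
    return CqTable(df, reference_target=reference_target)
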