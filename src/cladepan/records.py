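"""Core in-memory containers shared by every pipeline stage.

Coordinates follow the GFF3 convention (1-based, inclusive) at every file
boundary; internal region arithmetic converts to 0-based half-open and back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class CladepanError(ValueError):
    """Base class for all validation and computation errors in this package."""


@dataclass
class SequenceRecord:
    """A single named sequence (nucleotide or protein)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise CladepanError(f"sequence id must be a non-empty token, got {self.id!r}")
        if not self.residues:
            raise CladepanError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    def validate_alphabet(self, kind: str) -> None:
        alphabet = NUCLEOTIDE_ALPHABET if kind == "nucleotide" else PROTEIN_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in alphabet:
                raise CladepanError(
                    f"sequence {self.id!r}: character {ch!r} at position {pos + 1} "
                    f"is not in the {kind} alphabet"
                )


@dataclass
class GenomeAssembly:
    """A genome as an ordered list of contigs plus labels used downstream.

    ``species_label`` controls the intra/inter-species switch of the hybrid
    ANI distance; ``clade_label`` is the (optional) truth label used by the
    simulator and by clade-profile evaluation.
    """

    genome_id: str
    contigs: list[SequenceRecord]
    species_label: str = "unlabeled"
    clade_label: str | None = None

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise CladepanError(f"genome {self.genome_id!r}: duplicate contig ids")
        if self.total_length == 0:
            raise CladepanError(f"genome {self.genome_id!r} has zero total length")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig(self, contig_id: str) -> SequenceRecord:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise CladepanError(f"genome {self.genome_id!r}: no contig {contig_id!r}")


@dataclass
class GeneAnnotation:
    """A CDS feature: the atom of pangenome analysis.

    ``status`` distinguishes intact coding sequences from pseudogenized
    fragments (the fCDS of annotation pipelines); fragment-only families
    are the middle state of the ternary presence matrix.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    status: str
    protein: SequenceRecord
    product: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise CladepanError(
                f"gene {self.gene_id!r}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise CladepanError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.status not in ("intact", "fragment"):
            raise CladepanError(f"gene {self.gene_id!r}: bad status {self.status!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LabeledMatrix:
    """A labeled numeric matrix backed by a pandas DataFrame.

    Symmetric instances (distance / ANI matrices) additionally guarantee
    cells[i, j] == cells[j, i] and identical row/column label order.
    """

    df: pd.DataFrame
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.df.shape[0] == 0 or self.df.shape[1] == 0:
            raise CladepanError("matrix must be non-empty")
        if len(set(self.df.index)) != self.df.shape[0]:
            raise CladepanError("duplicate row labels")
        if len(set(self.df.columns)) != self.df.shape[1]:
            raise CladepanError("duplicate column labels")
        if self.symmetric:
            if list(self.df.index) != list(self.df.columns):
                raise CladepanError("symmetric matrix needs identical row/column labels")
            values = self.df.to_numpy(dtype=float)
            if not np.allclose(values, values.T, equal_nan=True):
                raise CladepanError("matrix flagged symmetric but cells differ from transpose")

    @property
    def row_labels(self) -> list[str]:
        return [str(x) for x in self.df.index]

    @property
    def col_labels(self) -> list[str]:
        return [str(x) for x in self.df.columns]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledMatrix):
            return NotImplemented
        return (
            self.symmetric == other.symmetric
            and self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.allclose(
                self.df.to_numpy(float), other.df.to_numpy(float), rtol=1e-11, atol=0.0,
                equal_nan=True,
            )
        )


#: ternary presence states
ABSENT, FRAGMENT, INTACT = 0, 1, 2


@dataclass
class TernaryMatrix:
    """Genomes x gene-families matrix with states absent(0)/fragment(1)/intact(2)."""

    df: pd.DataFrame  # rows = genomes, columns = families, dtype int8

    def __post_init__(self) -> None:
        values = self.df.to_numpy()
        if not np.isin(values, (ABSENT, FRAGMENT, INTACT)).all():
            raise CladepanError("ternary matrix cells must be 0, 1 or 2")

    @property
    def genomes(self) -> list[str]:
        return [str(x) for x in self.df.index]

    @property
    def families(self) -> list[str]:
        return [str(x) for x in self.df.columns]

    def state(self, genome: str, family: str) -> int:
        return int(self.df.at[genome, family])
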