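"""Core-gene alignment and SNP/indel supermatrix construction.

The tree-building character matrix is the concatenation, over single-copy
core families without any fragment member, of every alignment column that
is variable (at least two of {A,C,G,T,-}) and free of N in all genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align

from .families import FamilyTable
from .records import ABSENT, FRAGMENT, INTACT, CladepanError, GeneAnnotation, TernaryMatrix

_nt_aligner = Align.PairwiseAligner()
_nt_aligner.mode = "global"
_nt_aligner.match_score = 1.0
_nt_aligner.mismatch_score = -1.0
_nt_aligner.open_gap_score = -4.0
_nt_aligner.extend_gap_score = -1.0


@dataclass
class AlignmentBlock:
    """One aligned core family: genome_id -> equal-length aligned row."""

    family_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise CladepanError(f"family {self.family_id!r}: unequal row lengths")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass
class CharacterMatrix:
    """Concatenated variant columns with per-column provenance."""

    genomes: list[str]
    columns: np.ndarray  # shape (n_genomes, n_columns), dtype '<U1'
    provenance: list[tuple[str, int]]  # (family_id, column index in block)

    def __post_init__(self) -> None:
        if self.columns.shape[0] != len(self.genomes):
            raise CladepanError("row count does not match genome list")
        if self.columns.shape[1] != len(self.provenance):
            raise CladepanError("provenance length does not match column count")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]

    def row(self, genome: str) -> str:
        return "".join(self.columns[self.genomes.index(genome)])


def select_core_unfragmented(
    families: FamilyTable,
    matrix: TernaryMatrix,
    annotations: list[GeneAnnotation],
) -> list[str]:
    """Families intact in every genome, with no fragment member anywhere and
    exactly one (intact) member per genome."""
    counts: dict[str, dict[str, int]] = {}
    fragmented: set[str] = set()
    for a in annotations:
        fam = families.family_of.get(a.gene_id)
        if fam is None:
            raise CladepanError(f"gene {a.gene_id!r} has no family")
        counts.setdefault(fam, {}).setdefault(a.genome_id, 0)
        counts[fam][a.genome_id] += 1
        if a.status == "fragment":
            fragmented.add(fam)
    genomes = matrix.genomes
    values = matrix.df
    selected = []
    for fam in matrix.families:
        if fam in fragmented:
            continue
        if not (values[fam] == INTACT).all():
            continue
        per_genome = counts.get(fam, {})
        if len(per_genome) == len(genomes) and all(c == 1 for c in per_genome.values()):
            selected.append(fam)
    if not selected:
        raise CladepanError(
            "no single-copy unfragmented core families; review clustering thresholds"
        )
    return sorted(selected)


def align_family(sequences: dict[str, str], family_id: str = "") -> AlignmentBlock:
    """Center-star multiple alignment of one gene per genome.

    The center is the sequence minimizing total pairwise edit distance (ties
    to the smallest genome label); every other sequence is aligned to the
    center globally (match 1 / mismatch -1 / open -4 / extend -1) and the
    pairwise alignments are merged under "once a gap, always a gap".
    """
    if len(sequences) < 2:
        raise CladepanError("need at least 2 sequences to align")
    for g, s in sequences.items():
        if not s:
            raise CladepanError(f"empty sequence for genome {g!r}")
    labels = sorted(sequences)
    # choose center
    totals = {g: 0 for g in labels}
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            d = edlib.align(sequences[gi], sequences[gj], mode="NW")["editDistance"]
            totals[gi] += d
            totals[gj] += d
    center = min(labels, key=lambda g: (totals[g], g))
    center_seq = sequences[center]

    # pairwise alignments to the center
    pairs: dict[str, tuple[str, str]] = {}
    for g in labels:
        if g == center:
            continue
        aln = _nt_aligner.align(center_seq, sequences[g])[0]
        pairs[g] = (str(aln[0]), str(aln[1]))

    # gaps_before[i] = max gaps inserted before center residue i (i == len: after last)
    n = len(center_seq)
    gaps_before = [0] * (n + 1)
    per_seq_gaps: dict[str, list[int]] = {}
    for g, (c_row, _) in pairs.items():
        gaps = [0] * (n + 1)
        idx = 0
        run = 0
        for ch in c_row:
            if ch == "-":
                run += 1
            else:
                gaps[idx] = run
                run = 0
                idx += 1
        gaps[n] = run
        per_seq_gaps[g] = gaps
        for i in range(n + 1):
            gaps_before[i] = max(gaps_before[i], gaps[i])

    def expand(row_center: str, row_other: str, gaps: list[int]) -> str:
        """Re-pad one pairwise alignment row to the merged coordinate system."""
        out = []
        idx = 0  # center residue index
        col = 0
        pending = []  # other-row chars in the current inter-residue slot
        for c_ch, o_ch in zip(row_center, row_other):
            if c_ch == "-":
                pending.append(o_ch)
            else:
                out.append("-" * (gaps_before[idx] - len(pending)) + "".join(pending))
                out.append(o_ch)
                pending = []
                idx += 1
        out.append("-" * (gaps_before[n] - len(pending)) + "".join(pending))
        return "".join(out)

    rows: dict[str, str] = {}
    # center row in merged coordinates
    merged_center = []
    for i, ch in enumerate(center_seq):
        merged_center.append("-" * gaps_before[i])
        merged_center.append(ch)
    merged_center.append("-" * gaps_before[n])
    rows[center] = "".join(merged_center)
    for g, (c_row, o_row) in pairs.items():
        rows[g] = expand(c_row, o_row, per_seq_gaps[g])
    return AlignmentBlock(family_id=family_id, rows=rows)


def variant_columns(block: AlignmentBlock) -> list[tuple[int, str]]:
    """Columns with >= 2 distinct symbols from {A,C,G,T,-} and no N anywhere.

    Returns (column index in block, column string in sorted-genome order).
    """
    genomes = sorted(block.rows)
    arr = np.array([list(block.rows[g]) for g in genomes])
    out = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if (col == "N").any():
            continue
        if len(set(col)) >= 2:
            out.append((j, "".join(col)))
    return out


def build_supermatrix(
    blocks: list[AlignmentBlock], genome_order: list[str]
) -> CharacterMatrix:
    """Concatenate variant columns in deterministic family-id order."""
    for block in blocks:
        missing = set(genome_order) - set(block.rows)
        if missing:
            raise CladepanError(
                f"family {block.family_id!r} is missing genomes {sorted(missing)}"
            )
    column_chunks: list[np.ndarray] = []
    provenance: list[tuple[str, int]] = []
    for block in sorted(blocks, key=lambda b: b.family_id):
        sorted_genomes = sorted(block.rows)
        reorder = [sorted_genomes.index(g) for g in genome_order]
        for j, col in variant_columns(block):
            symbols = np.array(list(col))[reorder]
            column_chunks.append(symbols)
            provenance.append((block.family_id, j))
    if not column_chunks:
        warnings.warn("supermatrix has zero variant columns", stacklevel=2)
        columns = np.empty((len(genome_order), 0), dtype="<U1")
    else:
        columns = np.stack(column_chunks, axis=1)
    return CharacterMatrix(genomes=list(genome_order), columns=columns,
                           provenance=provenance)
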