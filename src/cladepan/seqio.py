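"""Readers and writers for FASTA, GFF3, Newick and TSV matrices.

All file coordinates are 1-based inclusive (GFF3 convention); FASTA residues
are uppercased and validated against the declared alphabet on read.
"""

from __future__ import annotations

import math
import os
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import CladepanError, GeneAnnotation, LabeledMatrix, SequenceRecord
from .tree import TreeNode, from_newick, to_newick


def read_fasta(path: str | os.PathLike, kind: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    ``kind`` is ``"nucleotide"`` (alphabet ACGTN) or ``"protein"`` (20 amino
    acids + X). Duplicate ids, empty sequences and out-of-alphabet characters
    are hard errors.
    """
    if kind not in ("nucleotide", "protein"):
        raise CladepanError(f"unknown sequence kind {kind!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise CladepanError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise CladepanError(f"empty sequence {rec.id!r} in {path}")
        description = rec.description[len(rec.id):].strip() if rec.description else ""
        out = SequenceRecord(id=rec.id, residues=residues, description=description)
        out.validate_alphabet(kind)
        records.append(out)
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike, width: int = 80) -> None:
    bio = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_gff3(path: str | os.PathLike, proteins: list[SequenceRecord]) -> list[GeneAnnotation]:
    """Read CDS features from a GFF3 file, joining protein translations by id.

    The pseudogene state is carried in a ``status=intact|fragment`` attribute;
    a missing attribute means intact. A CDS whose ID has no protein record is
    a hard error.
    """
    by_id = {p.id: p for p in proteins}
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    annotations: list[GeneAnnotation] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.end < feat.start:
            raise CladepanError(f"CDS {feat.id!r}: end {feat.end} < start {feat.start}")
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id not in by_id:
            raise CladepanError(f"CDS {gene_id!r} has no matching protein record")
        status = feat.attributes.get("status", ["intact"])[0]
        product = feat.attributes.get("product", [""])[0]
        annotations.append(
            GeneAnnotation(
                gene_id=gene_id,
                genome_id=feat.attributes.get("genome", [Path(path).stem])[0],
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                status=status,
                protein=by_id[gene_id],
                product=product,
            )
        )
    return annotations


def _escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(annotations: list[GeneAnnotation], path: str | os.PathLike) -> None:
    """Write CDS features (1-based inclusive coordinates, status attribute)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"ID={_escape(a.gene_id)};genome={_escape(a.genome_id)};status={a.status}"
            if a.product:
                attrs += f";product={_escape(a.product)}"
            fh.write(
                f"{a.contig_id}\tcladepan\tCDS\t{a.start}\t{a.end}\t.\t{a.strand}\t0\t{attrs}\n"
            )


def write_newick(tree: TreeNode, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def read_newick(path: str | os.PathLike) -> TreeNode:
    with open(path) as fh:
        return from_newick(fh.read())


def write_matrix_tsv(matrix: LabeledMatrix, path: str | os.PathLike) -> None:
    """Write a labeled matrix as TSV (row label first column, header row),
    values at 12 significant digits."""
    matrix.df.to_csv(path, sep="\t", float_format="%.12g", index_label="label")


def read_matrix_tsv(path: str | os.PathLike, symmetric: bool | None = None) -> LabeledMatrix:
    """Read a TSV matrix; ragged rows and empty matrices are hard errors.

    With ``symmetric=None`` the flag is auto-detected (identical row/column
    labels and numerically symmetric cells).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise CladepanError(f"ragged rows in matrix file {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise CladepanError(f"empty matrix in {path}")
    # pandas silently pads short rows with NaN; a fully-NaN trailing column or
    # per-row NaN count mismatch indicates raggedness only when the writer
    # never emits empty cells, so check raw field counts instead.
    with open(path) as fh:
        widths = {len(line.rstrip("\n").split("\t")) for line in fh if line.strip()}
    if len(widths) != 1:
        raise CladepanError(f"ragged rows in matrix file {path}")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if symmetric is None:
        symmetric = list(df.index) == list(df.columns) and _is_symmetric(df)
    return LabeledMatrix(df=df, symmetric=symmetric)


def _is_symmetric(df: pd.DataFrame) -> bool:
    values = df.to_numpy(dtype=float)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            a, b = values[i, j], values[j, i]
            if math.isnan(a) and math.isnan(b):
                continue
            if not math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-12):
                return False
    return True
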