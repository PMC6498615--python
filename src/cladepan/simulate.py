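"""Synthetic bacterial genome generator with planted population structure.

The generator emulates the statistical structure a clade-discovery pipeline
assumes: several clades of related strains diverging on a known tree under a
Kimura-2-parameter substitution process, gene families gained nowhere and
lost or pseudogenized independently per strain, and clade-specific operon
blocks inserted at a fixed gene boundary in every member of a clade.  Every
emitted gene is bookkept in a :class:`TruthSet` so downstream inferences
(families, trees, clade-specific content, variable regions) can be scored
against the generating process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .records import CladepanError, GeneAnnotation, GenomeAssembly, SequenceRecord
from .seqio import write_fasta, write_gff3, write_newick
from .tree import TreeNode

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASES = np.frombuffer(b"ACGT", dtype="S1")
# transitions: A<->G, C<->T (codes 0<->2, 1<->3)
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.int8)
_TV_TABLE = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror a 4-clade population of closely related strains with a
    divergent outgroup: inter-clade stem branches of 0.02 substitutions/site,
    within-clade tip branches of 0.002, transition/transversion rate ratio 4,
    3% gene loss and 2% pseudogenization per family per strain, and one
    planted 10-CDS clade-specific block per clade.
    """

    n_clades: int = 4
    strains_per_clade: list[int] | None = None  # default: 5 per clade
    n_ancestral_families: int = 300
    gene_length_range: tuple[int, int] = (300, 1500)
    intergenic_length: int = 50
    inter_clade_divergence: float = 0.02
    intra_clade_divergence: float = 0.002
    transition_bias: float = 4.0
    gene_loss_prob: float = 0.03
    pseudogenization_prob: float = 0.02
    blocks_per_clade: int = 1
    block_size_cds: int = 10
    outgroup: bool = True
    outgroup_divergence: float = 0.15
    split_contigs: int = 0  # extra contig breaks per genome, for I/O tests
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strains_per_clade is None:
            self.strains_per_clade = [5] * self.n_clades
        if len(self.strains_per_clade) != self.n_clades:
            raise CladepanError("strains_per_clade length must equal n_clades")
        if any(s < 1 for s in self.strains_per_clade):
            raise CladepanError("every clade needs at least one strain")
        for p in (self.gene_loss_prob, self.pseudogenization_prob):
            if not 0.0 <= p <= 1.0:
                raise CladepanError(f"probability {p} outside [0, 1]")
        for d in (
            self.inter_clade_divergence,
            self.intra_clade_divergence,
            self.outgroup_divergence,
        ):
            if d < 0:
                raise CladepanError("divergences must be >= 0")
        if self.n_ancestral_families + self.n_clades * self.blocks_per_clade * self.block_size_cds == 0:
            raise CladepanError("configuration yields zero genes")


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated dataset."""

    clade_of: dict[str, str]
    family_of_gene: dict[str, str]
    family_content: dict[str, dict[str, str]]  # genome -> family -> state
    clade_specific_families: dict[str, set[str]]
    planted_regions: dict[str, list[tuple[str, int, int, int]]]
    generating_tree: TreeNode
    families: list[str] = field(default_factory=list)


def mutate_sequence(
    residues: str,
    subst_per_site: float,
    transition_bias: float,
    rng: np.random.Generator,
) -> str:
    """Substitute bases under a Kimura-2-parameter-like process.

    Each site is substituted with probability ``subst_per_site``; a
    substitution is a transition with probability bias/(bias+2), otherwise one
    of the two transversions uniformly.  Length is preserved; ``N`` sites are
    left untouched.
    """
    if subst_per_site < 0:
        raise CladepanError("substitution rate must be >= 0")
    if subst_per_site == 0 or not residues:
        return residues
    raw = np.frombuffer(residues.encode(), dtype=np.uint8)
    codes = _CODE[raw]
    valid = codes >= 0
    hit = (rng.random(len(raw)) < subst_per_site) & valid
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return residues
    old = codes[idx]
    is_ts = rng.random(idx.size) < transition_bias / (transition_bias + 2.0)
    tv_pick = rng.integers(0, 2, idx.size)
    new = np.where(is_ts, _TS_PARTNER[old], _TV_TABLE[old, tv_pick])
    out = raw.copy()
    out[idx] = np.frombuffer(b"ACGT", dtype=np.uint8)[new]
    return out.tobytes().decode()


def translate_cds(nt: str) -> str:
    """Translate a CDS, mapping mutation-created internal stops to 'X'."""
    usable = nt[: len(nt) - len(nt) % 3]
    if not usable:
        return "X"
    return str(Seq(usable).translate()).replace("*", "X")


def pseudogenize_gene(
    gene: GeneAnnotation,
    gene_seq: str,
    rng: np.random.Generator,
) -> list[GeneAnnotation]:
    """Turn an intact gene into one truncated or two split fragments.

    A truncation keeps a 5' portion of at least 30% of the gene; a split
    yields two fragments separated by a short unannotated gap.  Genes shorter
    than 150 bp are returned unchanged with a warning.
    """
    length = gene.length
    if length < 150:
        warnings.warn(
            f"gene {gene.gene_id} is too short ({length} bp) to pseudogenize",
            stacklevel=2,
        )
        return [gene]
    n_codons = length // 3
    min_codons = max(1, int(np.ceil(0.3 * n_codons)))
    if rng.random() < 0.5 or n_codons < min_codons + 3:
        # internal-stop truncation: one 5' fragment
        keep = int(rng.integers(min_codons, n_codons + 1)) * 3
        frag = GeneAnnotation(
            gene_id=f"{gene.gene_id}_f1",
            genome_id=gene.genome_id,
            contig_id=gene.contig_id,
            start=gene.start,
            end=gene.start + keep - 1,
            strand=gene.strand,
            status="fragment",
            protein=SequenceRecord(
                id=f"{gene.gene_id}_f1", residues=translate_cds(gene_seq[:keep])
            ),
            product=gene.product,
        )
        return [frag]
    # split into two fragments with a small skipped region between them
    c1 = int(rng.integers(min_codons, n_codons - 2))
    c2 = int(rng.integers(c1 + 1, n_codons))
    parts = []
    for tag, lo_codon, hi_codon in (("_f1", 0, c1), ("_f2", c2, n_codons)):
        seq = gene_seq[lo_codon * 3: hi_codon * 3]
        parts.append(
            GeneAnnotation(
                gene_id=f"{gene.gene_id}{tag}",
                genome_id=gene.genome_id,
                contig_id=gene.contig_id,
                start=gene.start + lo_codon * 3,
                end=gene.start + hi_codon * 3 - 1,
                strand=gene.strand,
                status="fragment",
                protein=SequenceRecord(id=f"{gene.gene_id}{tag}", residues=translate_cds(seq)),
                product=gene.product,
            )
        )
    return parts


def plant_insert_region(
    assembly: GenomeAssembly,
    annotations: list[GeneAnnotation],
    block_genes: list[tuple[str, str]],
    position: int,
    intergenic_length: int = 50,
    spacer_rng: np.random.Generator | None = None,
) -> tuple[GenomeAssembly, list[GeneAnnotation], tuple[str, int, int, int] | None]:
    """Insert a contiguous run of CDS at a gene boundary of the first contig.

    ``block_genes`` is a list of ``(gene_id, sequence)``; ``position`` is the
    0-based offset (on the first contig) at which insertion happens and must
    not fall strictly inside an annotated gene.  A leading spacer separates
    the block from upstream sequence; genes within the block are separated by
    ``intergenic_length``-bp spacers.  Downstream annotations shift by the
    inserted length.  Returns the updated assembly, annotations, and the
    planted region as ``(contig, start, end, n_cds)`` (1-based inclusive).
    """
    if not block_genes:
        return assembly, annotations, None
    contig = assembly.contigs[0]
    if not 0 <= position <= len(contig):
        raise CladepanError(f"insert position {position} outside contig {contig.id!r}")
    for a in annotations:
        if a.contig_id == contig.id and a.start - 1 < position < a.end:
            raise CladepanError(
                f"insert position {position} overlaps gene {a.gene_id!r} "
                f"({a.start}..{a.end})"
            )
    if spacer_rng is None:
        spacer_rng = np.random.default_rng(0)
    spacer = lambda: "".join(  # noqa: E731
        np.array(list("ACGT"))[spacer_rng.integers(0, 4, intergenic_length)]
    )
    pieces = [spacer()]
    new_annotations: list[GeneAnnotation] = []
    offset = position + intergenic_length  # 0-based start of first block gene
    region_start = offset + 1
    for k, (gene_id, seq) in enumerate(block_genes):
        if k > 0:
            pieces.append(spacer())
            offset += intergenic_length
        pieces.append(seq)
        new_annotations.append(
            GeneAnnotation(
                gene_id=gene_id,
                genome_id=assembly.genome_id,
                contig_id=contig.id,
                start=offset + 1,
                end=offset + len(seq),
                strand="+",
                status="intact",
                protein=SequenceRecord(id=gene_id, residues=translate_cds(seq)),
            )
        )
        offset += len(seq)
    region_end = offset
    insert_seq = "".join(pieces)
    shift = len(insert_seq)
    new_residues = contig.residues[:position] + insert_seq + contig.residues[position:]
    shifted: list[GeneAnnotation] = []
    for a in annotations:
        if a.contig_id == contig.id and a.start - 1 >= position:
            a = GeneAnnotation(
                gene_id=a.gene_id, genome_id=a.genome_id, contig_id=a.contig_id,
                start=a.start + shift, end=a.end + shift, strand=a.strand,
                status=a.status, protein=a.protein, product=a.product,
            )
        shifted.append(a)
    shifted.extend(new_annotations)
    shifted.sort(key=lambda a: (a.contig_id, a.start))
    new_contig = SequenceRecord(id=contig.id, residues=new_residues,
                                description=contig.description)
    new_assembly = GenomeAssembly(
        genome_id=assembly.genome_id,
        contigs=[new_contig] + assembly.contigs[1:],
        species_label=assembly.species_label,
        clade_label=assembly.clade_label,
    )
    region = (contig.id, region_start, region_end, len(block_genes))
    return new_assembly, shifted, region


def _random_gene(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    lo, hi = length_range
    n_codons = int(rng.integers(max(1, lo // 3), hi // 3 + 1))
    picks = rng.integers(0, len(_NON_STOP_CODONS), n_codons)
    return "".join(_NON_STOP_CODONS[p] for p in picks)


def _random_spacer(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[GenomeAssembly], list[GeneAnnotation], TruthSet]:
    """Generate assemblies, annotations and truth labels under ``config``.

    Each ingroup genome is one contig of genes laid end-to-end with fixed
    intergenic spacers, evolved down a star-of-clades tree; the optional
    outgroup hangs off the root on a long stem.  Loss and pseudogenization
    are applied per family per strain at the leaves; planted clade blocks are
    exempt so they stay diagnostic of their clade.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    kappa = cfg.transition_bias

    n_fam = cfg.n_ancestral_families
    fam_ids = [f"F{i + 1:04d}" for i in range(n_fam)]
    ancestral_genes = {f: _random_gene(rng, cfg.gene_length_range) for f in fam_ids}
    ancestral_spacers = [_random_spacer(rng, cfg.intergenic_length)
                         for _ in range(n_fam + 1)]

    clade_names = [chr(ord("A") + i) for i in range(cfg.n_clades)]

    # generating tree
    root = TreeNode(name=None)
    clade_nodes: dict[str, TreeNode] = {}
    for clade, n_strains in zip(clade_names, cfg.strains_per_clade):
        mrca = TreeNode(name=None, length=cfg.inter_clade_divergence)
        for s in range(n_strains):
            mrca.children.append(
                TreeNode(name=f"{clade}{s + 1:02d}", length=cfg.intra_clade_divergence)
            )
        root.children.append(mrca)
        clade_nodes[clade] = mrca
    if cfg.outgroup:
        root.children.append(TreeNode(name="OUT", length=cfg.outgroup_divergence))

    # clade-ancestral sequences for shared families
    clade_seqs: dict[str, dict[str, str]] = {}
    for clade in clade_names:
        clade_seqs[clade] = {
            f: mutate_sequence(ancestral_genes[f], cfg.inter_clade_divergence, kappa, rng)
            for f in fam_ids
        }

    # planted clade-specific blocks, generated at the clade ancestor
    clade_blocks: dict[str, list[tuple[str, str]]] = {c: [] for c in clade_names}
    clade_specific: dict[str, set[str]] = {c: set() for c in clade_names}
    block_positions: dict[str, list[int]] = {}
    next_fam = n_fam
    all_family_ids = list(fam_ids)
    for clade in clade_names:
        for _b in range(cfg.blocks_per_clade):
            for _k in range(cfg.block_size_cds):
                next_fam += 1
                fid = f"F{next_fam:04d}"
                clade_blocks[clade].append((fid, _random_gene(rng, cfg.gene_length_range)))
                clade_specific[clade].add(fid)
                all_family_ids.append(fid)
        # one insertion point per block, expressed as "after ancestral gene g"
        block_positions[clade] = sorted(
            int(g) for g in rng.choice(n_fam, size=cfg.blocks_per_clade, replace=False)
        ) if cfg.blocks_per_clade else []

    clade_of: dict[str, str] = {}
    family_of_gene: dict[str, str] = {}
    family_content: dict[str, dict[str, str]] = {}
    planted_regions: dict[str, list[tuple[str, int, int, int]]] = {}
    assemblies: list[GenomeAssembly] = []
    annotations: list[GeneAnnotation] = []

    def build_leaf(
        genome_id: str,
        species: str,
        clade: str | None,
        gene_seqs: dict[str, str],
        events: bool,
        leaf_rng: np.random.Generator,
    ) -> tuple[GenomeAssembly, list[GeneAnnotation]]:
        content: dict[str, str] = {}
        pieces: list[str] = []
        leaf_annotations: list[GeneAnnotation] = []
        offset = 0
        gene_no = 0
        for i, fam in enumerate(fam_ids):
            spacer = ancestral_spacers[i]
            pieces.append(spacer)
            offset += len(spacer)
            seq = gene_seqs[fam]
            state = "intact"
            if events:
                u = leaf_rng.random()
                if u < cfg.gene_loss_prob:
                    state = "absent"
                elif u < cfg.gene_loss_prob + cfg.pseudogenization_prob:
                    state = "fragment"
            if state == "absent":
                content[fam] = "absent"
                continue
            pieces.append(seq)
            gene_no += 1
            gene_id = f"{genome_id}_g{gene_no:04d}"
            gene = GeneAnnotation(
                gene_id=gene_id,
                genome_id=genome_id,
                contig_id=f"{genome_id}_c1",
                start=offset + 1,
                end=offset + len(seq),
                strand="+",
                status="intact",
                protein=SequenceRecord(id=gene_id, residues=translate_cds(seq)),
            )
            offset += len(seq)
            if state == "fragment":
                frags = pseudogenize_gene(gene, seq, leaf_rng)
                if len(frags) == 1 and frags[0].status == "intact":
                    state = "intact"  # too short to pseudogenize
                for fr in frags:
                    family_of_gene[fr.gene_id] = fam
                leaf_annotations.extend(frags)
            else:
                family_of_gene[gene_id] = fam
                leaf_annotations.append(gene)
            content[fam] = state
        pieces.append(ancestral_spacers[n_fam])
        contig = SequenceRecord(id=f"{genome_id}_c1", residues="".join(pieces))
        assembly = GenomeAssembly(
            genome_id=genome_id, contigs=[contig],
            species_label=species, clade_label=clade,
        )
        family_content[genome_id] = content
        return assembly, leaf_annotations

    for clade, n_strains in zip(clade_names, cfg.strains_per_clade):
        block_list = clade_blocks[clade]
        per_block = cfg.block_size_cds
        for s in range(n_strains):
            genome_id = f"{clade}{s + 1:02d}"
            leaf_rng = np.random.default_rng(rng.integers(0, 2**31))
            gene_seqs = {
                f: mutate_sequence(clade_seqs[clade][f], cfg.intra_clade_divergence,
                                   kappa, leaf_rng)
                for f in fam_ids
            }
            assembly, leaf_ann = build_leaf(
                genome_id, "ingroup", clade, gene_seqs, events=True, leaf_rng=leaf_rng,
            )
            # plant the clade blocks (reverse gene order keeps positions valid)
            regions: list[tuple[str, int, int, int]] = []
            for b in range(cfg.blocks_per_clade - 1, -1, -1):
                genes = block_list[b * per_block: (b + 1) * per_block]
                leaf_genes = [
                    (f"{genome_id}_{fid}", mutate_sequence(seq, cfg.intra_clade_divergence,
                                                           kappa, leaf_rng))
                    for fid, seq in genes
                ]
                anchor_fam = fam_ids[block_positions[clade][b]]
                anchor = [a for a in leaf_ann
                          if family_of_gene.get(a.gene_id) == anchor_fam]
                if anchor:
                    position = max(a.end for a in anchor)
                else:  # anchor gene lost in this strain: append after the last gene
                    position = max((a.end for a in leaf_ann), default=0)
                assembly, leaf_ann, region = plant_insert_region(
                    assembly, leaf_ann, leaf_genes, position,
                    cfg.intergenic_length, spacer_rng=leaf_rng,
                )
                regions.append(region)
                for (fid, _), (gid, _) in zip(genes, leaf_genes):
                    family_of_gene[gid] = fid
                    family_content[genome_id][fid] = "intact"
            for fid in clade_specific[clade]:
                family_content[genome_id].setdefault(fid, "intact")
            for other_clade in clade_names:
                if other_clade != clade:
                    for fid in clade_specific[other_clade]:
                        family_content[genome_id][fid] = "absent"
            planted_regions[genome_id] = sorted(regions, key=lambda r: r[1])
            clade_of[genome_id] = clade
            assemblies.append(assembly)
            annotations.extend(leaf_ann)

    if cfg.outgroup:
        leaf_rng = np.random.default_rng(rng.integers(0, 2**31))
        out_seqs = {
            f: mutate_sequence(ancestral_genes[f], cfg.outgroup_divergence, kappa, leaf_rng)
            for f in fam_ids
        }
        assembly, leaf_ann = build_leaf(
            "OUT", "outgroup", None, out_seqs, events=False, leaf_rng=leaf_rng,
        )
        clade_of["OUT"] = "outgroup"
        planted_regions["OUT"] = []
        for clade in clade_names:
            for fid in clade_specific[clade]:
                family_content["OUT"][fid] = "absent"
        assemblies.append(assembly)
        annotations.extend(leaf_ann)

    if not annotations:
        raise CladepanError("configuration yielded zero genes")

    if cfg.split_contigs > 0:
        assemblies, annotations = _split_contigs(assemblies, annotations, cfg, rng)

    truth = TruthSet(
        clade_of=clade_of,
        family_of_gene=family_of_gene,
        family_content=family_content,
        clade_specific_families=clade_specific,
        planted_regions=planted_regions,
        generating_tree=root,
        families=all_family_ids,
    )
    return assemblies, annotations, truth


def _split_contigs(assemblies, annotations, cfg, rng):
    """Split each single-contig genome at random gene boundaries (I/O tests)."""
    ann_by_genome: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        ann_by_genome.setdefault(a.genome_id, []).append(a)
    new_assemblies = []
    new_annotations = []
    for asm in assemblies:
        contig = asm.contigs[0]
        genes = sorted(ann_by_genome.get(asm.genome_id, []), key=lambda a: a.start)
        boundaries = sorted(
            {int(genes[i].end) for i in
             rng.choice(len(genes) - 1, size=min(cfg.split_contigs, len(genes) - 1),
                        replace=False)}
        ) if len(genes) > 1 else []
        cuts = [0] + boundaries + [len(contig)]
        contigs = []
        out_ann = []
        for k in range(len(cuts) - 1):
            lo, hi = cuts[k], cuts[k + 1]
            cid = f"{asm.genome_id}_c{k + 1}"
            contigs.append(SequenceRecord(id=cid, residues=contig.residues[lo:hi]))
            for a in genes:
                if lo < a.start <= hi:
                    out_ann.append(
                        GeneAnnotation(
                            gene_id=a.gene_id, genome_id=a.genome_id, contig_id=cid,
                            start=a.start - lo, end=a.end - lo, strand=a.strand,
                            status=a.status, protein=a.protein, product=a.product,
                        )
                    )
        new_assemblies.append(
            GenomeAssembly(genome_id=asm.genome_id, contigs=contigs,
                           species_label=asm.species_label, clade_label=asm.clade_label)
        )
        new_annotations.extend(out_ann)
    return new_assemblies, new_annotations


def write_dataset(
    assemblies: list[GenomeAssembly],
    annotations: list[GeneAnnotation],
    truth: TruthSet,
    outdir: str | Path,
) -> None:
    """Write genomes, proteins, GFF3, truth tables and the generating tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_genome: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        by_genome.setdefault(a.genome_id, []).append(a)
    for asm in assemblies:
        write_fasta(asm.contigs, outdir / f"{asm.genome_id}.fna")
        anns = sorted(by_genome.get(asm.genome_id, []),
                      key=lambda a: (a.contig_id, a.start))
        write_gff3(anns, outdir / f"{asm.genome_id}.gff3")
        write_fasta([a.protein for a in anns], outdir / f"{asm.genome_id}.faa")
    with open(outdir / "clades.tsv", "w") as fh:
        fh.write("genome\tclade\n")
        for g in sorted(truth.clade_of):
            fh.write(f"{g}\t{truth.clade_of[g]}\n")
    with open(outdir / "species.tsv", "w") as fh:
        fh.write("genome\tspecies\n")
        for asm in assemblies:
            fh.write(f"{asm.genome_id}\t{asm.species_label}\n")
    with open(outdir / "truth_families.tsv", "w") as fh:
        fh.write("gene\tfamily\n")
        for g in sorted(truth.family_of_gene):
            fh.write(f"{g}\t{truth.family_of_gene[g]}\n")
    write_newick(truth.generating_tree, outdir / "generating_tree.nwk")
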