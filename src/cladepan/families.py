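"""Protein family clustering and pangenome presence/absence statistics.

Families are single-linkage components of the graph whose edges connect
protein pairs exceeding both an amino-acid identity and an alignment
coverage threshold (strictly greater than, 80%/80% by default).  The
genome x family matrix is ternary: a genome is intact (2) for a family when
it carries at least one intact member, fragment-only (1) when it carries
only pseudogene fragments, and absent (0) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .records import (
    ABSENT,
    FRAGMENT,
    INTACT,
    CladepanError,
    GeneAnnotation,
    SequenceRecord,
    TernaryMatrix,
)

_aligner = Align.PairwiseAligner()
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -11.0
_aligner.extend_gap_score = -1.0
_aligner.mode = "global"


@dataclass
class PairwiseHit:
    """Identity/coverage metrics of one aligned protein pair.

    Identity is identical residues over aligned columns with terminal gaps
    excluded (internal gap columns count against identity); coverage_x is the
    fraction of x's residues inside the terminal-gap-trimmed core.
    """

    a_id: str
    b_id: str
    identity: float
    coverage_a: float
    coverage_b: float


@dataclass
class FamilyTable:
    """A partition of genes into families, with both directions indexed."""

    members: dict[str, list[str]]  # family_id -> sorted gene ids
    family_of: dict[str, str]  # gene_id -> family_id

    def __len__(self) -> int:
        return len(self.members)


def pairwise_protein_metrics(a: SequenceRecord, b: SequenceRecord) -> PairwiseHit:
    """Globally align two proteins (BLOSUM62, affine gaps) and measure
    identity and mutual coverage."""
    alignment = _aligner.align(a.residues, b.residues)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    n_cols = len(row_a)
    # trim terminal gap columns: core runs from the first to the last column
    # in which both sequences have a residue
    lo = 0
    while lo < n_cols and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    hi = n_cols
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    core_a = row_a[lo:hi]
    core_b = row_b[lo:hi]
    columns = hi - lo
    if columns == 0:
        return PairwiseHit(a.id, b.id, 0.0, 0.0, 0.0)
    identical = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    res_a = sum(1 for x in core_a if x != "-")
    res_b = sum(1 for x in core_b if x != "-")
    return PairwiseHit(
        a_id=a.id,
        b_id=b.id,
        identity=identical / columns,
        coverage_a=res_a / len(a.residues),
        coverage_b=res_b / len(b.residues),
    )


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def connected(self, a, b):
        return self.find(a) == self.find(b)


def _protein_kmers(seq: str, k: int = 5) -> set[str]:
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


def _edit_bound_ok(a: str, b: str) -> bool:
    """Rigorous prune: any pair exceeding 80/80 has unit edit distance at most
    0.25*min(m,n) + 0.2*(m+n) (mismatch+gap columns within the core plus
    terminal overhangs), so pairs beyond that bound cannot form an edge."""
    m, n = len(a), len(b)
    bound = int(0.25 * min(m, n) + 0.2 * (m + n)) + 1
    d = edlib.align(a, b, mode="NW", k=bound)["editDistance"]
    return d >= 0


def build_families(
    proteins: list[SequenceRecord],
    id_threshold: float = 0.80,
    cov_threshold: float = 0.80,
) -> FamilyTable:
    """Cluster proteins into families by thresholded single linkage.

    An edge joins a and b iff identity > id_threshold and
    min(coverage_a, coverage_b) > cov_threshold (strict inequalities);
    families are the connected components.  Candidate pairs are pre-filtered
    by shared 5-mers, which cannot lose a true edge: identity above 0.8 over
    the aligned core forces a gapless run of at least 5 identical residues.
    Family ids are assigned deterministically from each family's smallest
    member id.
    """
    if not proteins:
        raise CladepanError("no proteins to cluster")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise CladepanError("duplicate protein ids")
    seq_of = {p.id: p for p in proteins}
    uf = _UnionFind(ids)

    # identical sequences are trivially one family
    by_seq: dict[str, list[str]] = defaultdict(list)
    for p in proteins:
        by_seq[p.residues].append(p.id)
    reps: list[str] = []
    for _, group in sorted(by_seq.items(), key=lambda kv: min(kv[1])):
        group.sort()
        for other in group[1:]:
            uf.union(other, group[0])
        reps.append(group[0])

    # shared-kmer candidate pairs among representatives
    kmer_index: dict[str, list[int]] = defaultdict(list)
    rep_kmers: list[set[str]] = []
    for ri, rid in enumerate(reps):
        kmers = _protein_kmers(seq_of[rid].residues)
        rep_kmers.append(kmers)
        for kmer in kmers:
            kmer_index[kmer].append(ri)
    pair_counts: dict[tuple[int, int], int] = defaultdict(int)
    for posting in kmer_index.values():
        if len(posting) < 2:
            continue
        for i in range(len(posting)):
            for j in range(i + 1, len(posting)):
                pair_counts[(posting[i], posting[j])] += 1

    # most-similar-first ordering lets union-find skip most within-family pairs
    ordered = sorted(pair_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    for (ri, rj), _count in ordered:
        a, b = reps[ri], reps[rj]
        if uf.connected(a, b):
            continue
        pa, pb = seq_of[a], seq_of[b]
        if not _edit_bound_ok(pa.residues, pb.residues):
            continue
        hit = pairwise_protein_metrics(pa, pb)
        if hit.identity > id_threshold and min(hit.coverage_a, hit.coverage_b) > cov_threshold:
            uf.union(a, b)

    components: dict[str, list[str]] = defaultdict(list)
    for gid in ids:
        components[uf.find(gid)].append(gid)
    members: dict[str, list[str]] = {}
    family_of: dict[str, str] = {}
    for group in components.values():
        group.sort()
        fam_id = f"FAM_{min(group)}"
        members[fam_id] = group
        for gid in group:
            family_of[gid] = fam_id
    return FamilyTable(members=dict(sorted(members.items())), family_of=family_of)


def ternary_presence(
    families: FamilyTable, annotations: list[GeneAnnotation]
) -> TernaryMatrix:
    """Genome x family matrix with states absent/fragment-only/intact.

    Multiple members in one genome collapse to one state; intact dominates
    fragment.
    """
    genomes = sorted({a.genome_id for a in annotations})
    fam_ids = sorted(families.members)
    g_index = {g: i for i, g in enumerate(genomes)}
    f_index = {f: j for j, f in enumerate(fam_ids)}
    cells = np.zeros((len(genomes), len(fam_ids)), dtype=np.int8)
    for a in annotations:
        fam = families.family_of.get(a.gene_id)
        if fam is None:
            raise CladepanError(f"gene {a.gene_id!r} has no family")
        state = INTACT if a.status == "intact" else FRAGMENT
        i, j = g_index[a.genome_id], f_index[fam]
        cells[i, j] = max(cells[i, j], state)
    return TernaryMatrix(df=pd.DataFrame(cells, index=genomes, columns=fam_ids))


def member_counts(
    families: FamilyTable, annotations: list[GeneAnnotation]
) -> pd.DataFrame:
    """Genome x family member counts (genes, including fragments)."""
    genomes = sorted({a.genome_id for a in annotations})
    fam_ids = sorted(families.members)
    counts = pd.DataFrame(0, index=genomes, columns=fam_ids, dtype=int)
    for a in annotations:
        counts.at[a.genome_id, families.family_of[a.gene_id]] += 1
    return counts


def partition_pangenome(
    matrix: TernaryMatrix,
    families: FamilyTable | None = None,
) -> tuple[set[str], set[str], set[str]]:
    """Split the pangenome into core, variable and singleton family sets.

    Core: present (state >= 1) in every genome.  Singleton: total member
    count across all genomes is one (requires ``families``; without it, a
    family present in exactly one genome counts as singleton).  Variable:
    everything else.  The three sets partition the pangenome.
    """
    present = matrix.df.to_numpy() >= FRAGMENT
    fam_ids = matrix.families
    core: set[str] = set()
    singleton: set[str] = set()
    variable: set[str] = set()
    n_genomes = len(matrix.genomes)
    for j, fam in enumerate(fam_ids):
        n_present = int(present[:, j].sum())
        if families is not None:
            total_members = len(families.members.get(fam, ()))
        else:
            total_members = n_present
        if n_present == n_genomes:
            core.add(fam)
        elif total_members == 1:
            singleton.add(fam)
        else:
            variable.add(fam)
    return core, variable, singleton


def rarefaction_curve(
    matrix: TernaryMatrix,
    reps: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pan- and core-genome sizes for growing random strain subsets.

    Each rep is a random permutation of the strains; the subset at step n is
    that permutation's first n strains, so every step sees ``reps`` random
    strain combinations while pan (families present in >= 1 sampled strain)
    is non-decreasing and core (present in all sampled strains) is
    non-increasing along every rep by construction.  Returns a long-format
    DataFrame with columns n_strains, rep, pan_size, core_size.
    """
    if reps < 1:
        raise CladepanError("reps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    present = matrix.df.to_numpy() >= FRAGMENT
    n_genomes = present.shape[0]
    rows = []
    for rep in range(reps):
        order = rng.permutation(n_genomes)
        pan = np.zeros(present.shape[1], dtype=bool)
        core = np.ones(present.shape[1], dtype=bool)
        for n, idx in enumerate(order, start=1):
            pan |= present[idx]
            core &= present[idx]
            rows.append(
                {
                    "n_strains": n,
                    "rep": rep,
                    "pan_size": int(pan.sum()),
                    "core_size": int(core.sum()),
                }
            )
    rows.sort(key=lambda r: (r["n_strains"], r["rep"]))
    return pd.DataFrame(rows)


def group_bootstrap_stats(
    matrix: TernaryMatrix,
    group_of: dict[str, str],
    families: FamilyTable | None = None,
    sample_n: int = 5,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
    replace: bool = False,
) -> pd.DataFrame:
    """Resampled per-group variable-genome MICFAM and singleton statistics.

    Per rep, ``sample_n`` strains are drawn from the group (without
    replacement by default); ``unique_*`` counts distinct families present in
    the sample, the non-unique statistics sum per-strain family counts.
    Returns one row per group with mean and sd over ``reps`` for the four
    statistics.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    core, variable, singleton = partition_pangenome(matrix, families)
    fam_ids = matrix.families
    var_mask = np.array([f in variable for f in fam_ids])
    sing_mask = np.array([f in singleton for f in fam_ids])
    present = matrix.df.to_numpy() >= FRAGMENT
    genomes = matrix.genomes
    groups: dict[str, list[int]] = defaultdict(list)
    for i, g in enumerate(genomes):
        if g in group_of:
            groups[group_of[g]].append(i)
    rows = []
    for group in sorted(groups):
        idx = np.array(groups[group])
        if not replace and len(idx) < sample_n:
            raise CladepanError(
                f"group {group!r} has {len(idx)} strains, fewer than sample_n={sample_n}"
            )
        stats = {key: np.empty(reps) for key in
                 ("unique_micfams", "unique_singletons", "micfams", "singletons")}
        for r in range(reps):
            pick = rng.choice(idx, size=sample_n, replace=replace)
            sub_var = present[np.ix_(pick, np.nonzero(var_mask)[0])]
            sub_sing = present[np.ix_(pick, np.nonzero(sing_mask)[0])]
            stats["unique_micfams"][r] = sub_var.any(axis=0).sum()
            stats["unique_singletons"][r] = sub_sing.any(axis=0).sum()
            stats["micfams"][r] = sub_var.sum()
            stats["singletons"][r] = sub_sing.sum()
        row = {"group": group, "n_strains": len(idx)}
        for key, values in stats.items():
            row[f"{key}_mean"] = float(values.mean())
            row[f"{key}_sd"] = float(values.std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
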