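"""Shared fixtures: one default synthetic dataset and its derived analyses.

The expensive session fixtures (family clustering, core-SNP supermatrix) are
computed once and shared by the cross-module property tests and the
acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import cladepan as cp

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """The default 4-clade, 5-strains-per-clade + outgroup dataset."""
    config = cp.SimulationConfig(seed=DEFAULT_SEED)
    return cp.simulate_dataset(config)


@pytest.fixture(scope="session")
def ingroup(default_dataset):
    assemblies, annotations, truth = default_dataset
    asm = [g for g in assemblies if g.genome_id != "OUT"]
    ann = [a for a in annotations if a.genome_id != "OUT"]
    return asm, ann, truth


@pytest.fixture(scope="session")
def family_analysis(ingroup):
    asm, ann, truth = ingroup
    table = cp.build_families([a.protein for a in ann])
    matrix = cp.ternary_presence(table, ann)
    return table, matrix


@pytest.fixture(scope="session")
def supermatrix(ingroup, family_analysis):
    asm, ann, truth = ingroup
    table, matrix = family_analysis
    selected = cp.select_core_unfragmented(table, matrix, ann)
    genomes = {g.genome_id: g for g in asm}
    ann_of = {a.gene_id: a for a in ann}
    blocks = []
    for fam in selected:
        seqs = {}
        for gene_id in table.members[fam]:
            a = ann_of[gene_id]
            contig = genomes[a.genome_id].contig(a.contig_id)
            seqs[a.genome_id] = contig.residues[a.start - 1: a.end]
        blocks.append(cp.align_family(seqs, family_id=fam))
    return cp.build_supermatrix(blocks, sorted(genomes)), selected


def random_protein(rng: np.random.Generator, length: int) -> str:
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(alphabet[rng.integers(0, 20, length)])


def perturb_protein(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False):
        current = chars[pos]
        options = [c for c in alphabet if c != current]
        chars[pos] = options[rng.integers(0, len(options))]
    return "".join(chars)


def random_protein_fixture(rng: np.random.Generator, n_proteins: int = 50):
    """A family-structured random protein set for clustering oracles."""
    proteins = []
    i = 0
    while len(proteins) < n_proteins:
        base_len = int(rng.integers(80, 300))
        base = random_protein(rng, base_len)
        family_size = int(rng.integers(1, 5))
        for _ in range(min(family_size, n_proteins - len(proteins))):
            n_subs = int(rng.integers(0, max(1, base_len // 8)))
            i += 1
            proteins.append(
                cp.SequenceRecord(id=f"p{i:03d}", residues=perturb_protein(base, n_subs, rng))
            )
    return proteins


def brute_force_families(proteins, id_threshold=0.80, cov_threshold=0.80):
    """Independent oracle: all-pairs metrics + networkx connected components."""
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(p.id for p in proteins)
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            hit = cp.pairwise_protein_metrics(proteins[i], proteins[j])
            if hit.identity > id_threshold and min(hit.coverage_a, hit.coverage_b) > cov_threshold:
                graph.add_edge(proteins[i].id, proteins[j].id)
    return {frozenset(c) for c in nx.connected_components(graph)}


def tree_path_distances(tree: cp.TreeNode) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path-length metric of a tree (independent of NJ)."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node):
        if node.is_leaf:
            return {node.name: 0.0}
        below: dict[str, float] = {}
        for child in node.children:
            sub = walk(child)
            sub = {k: v + child.length for k, v in sub.items()}
            for a, da in below.items():
                for b, db in sub.items():
                    dists[tuple(sorted((a, b)))] = da + db
            below.update(sub)
        return below

    walk(tree)
    return dists


def random_tree(labels: list[str], rng: np.random.Generator,
                min_len: float = 0.05, max_len: float = 1.0) -> cp.TreeNode:
    """Random unrooted binary topology with positive branch lengths."""
    nodes = [cp.TreeNode(name=lab, length=float(rng.uniform(min_len, max_len)))
             for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(
            cp.TreeNode(children=[a, b], length=float(rng.uniform(min_len, max_len)))
        )
    return cp.TreeNode(children=nodes)


def enumerate_unrooted_topologies(labels: list[str]):
    """All unrooted binary topologies by stepwise addition (3, 15, 105...)."""
    base = cp.TreeNode(children=[cp.TreeNode(name=lab) for lab in labels[:3]])
    trees = [base]
    for lab in labels[3:]:
        new_trees = []
        for t in trees:
            edges = []
            for node in t.walk():
                for child in node.children:
                    edges.append((node, child))
            for k in range(len(edges)):
                t2 = t.copy()
                edges2 = []
                for node in t2.walk():
                    for child in node.children:
                        edges2.append((node, child))
                parent, child = edges2[k]
                mid = cp.TreeNode(children=[child, cp.TreeNode(name=lab)])
                parent.children[parent.children.index(child)] = mid
                new_trees.append(t2)
        trees = new_trees
    return trees
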