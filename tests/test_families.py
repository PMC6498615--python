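"""Protein family clustering, ternary matrix and pangenome statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import cladepan as cp
from cladepan.records import CladepanError
from conftest import (
    brute_force_families,
    perturb_protein,
    random_protein,
    random_protein_fixture,
)


def _rec(pid, seq):
    return cp.SequenceRecord(id=pid, residues=seq)


class TestPairwiseMetrics:
    def test_identical_proteins(self):
        seq = random_protein(np.random.default_rng(0), 100)
        hit = cp.pairwise_protein_metrics(_rec("a", seq), _rec("b", seq))
        assert hit.identity == 1.0
        assert hit.coverage_a == hit.coverage_b == 1.0

    def test_prefix_coverage(self):
        seq = random_protein(np.random.default_rng(1), 100)
        hit = cp.pairwise_protein_metrics(_rec("a", seq[:50]), _rec("b", seq))
        assert hit.identity == 1.0
        assert hit.coverage_a == 1.0
        assert hit.coverage_b == 0.5

    def test_fifteen_substitutions_identity(self):
        rng = np.random.default_rng(2)
        seq = random_protein(rng, 100)
        other = perturb_protein(seq, 15, rng)
        hit = cp.pairwise_protein_metrics(_rec("a", seq), _rec("b", other))
        assert hit.identity == pytest.approx(0.85)
        assert hit.coverage_a == hit.coverage_b == 1.0


class TestBuildFamilies:
    def test_threshold_edge_rules(self):
        rng = np.random.default_rng(3)
        base = random_protein(rng, 100)
        sim85 = perturb_protein(base, 15, rng)  # identity 0.85 > 0.80 -> edge
        sim80 = perturb_protein(base, 20, rng)  # identity exactly 0.80 -> no edge
        short = perturb_protein(base, 5, rng)[:70]  # coverage 0.70 -> no edge
        proteins = [_rec("base", base), _rec("sim85", sim85),
                    _rec("sim80", sim80), _rec("short", short)]
        table = cp.build_families(proteins)
        fam = table.family_of
        assert fam["base"] == fam["sim85"]
        assert fam["base"] != fam["sim80"]
        assert fam["base"] != fam["short"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        proteins = random_protein_fixture(rng, n_proteins=30)
        table = cp.build_families(proteins)
        predicted = {frozenset(m) for m in table.members.values()}
        assert predicted == brute_force_families(proteins)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(7)
        proteins = random_protein_fixture(rng, n_proteins=20)
        table1 = cp.build_families(proteins)
        table2 = cp.build_families(proteins[::-1])
        assert table1.members == table2.members

    def test_empty_input_is_error(self):
        with pytest.raises(CladepanError):
            cp.build_families([])


def _annotation(gene_id, genome, status="intact"):
    return cp.GeneAnnotation(
        gene_id=gene_id, genome_id=genome, contig_id=f"{genome}_c1",
        start=1, end=30, strand="+", status=status,
        protein=cp.SequenceRecord(id=gene_id, residues="M"),
    )


def _family_table(mapping):
    members = {}
    for gene, fam in mapping.items():
        members.setdefault(fam, []).append(gene)
    return cp.FamilyTable(
        members={f: sorted(g) for f, g in sorted(members.items())},
        family_of=dict(mapping),
    )


class TestTernaryPresence:
    def test_collapse_rules(self):
        annotations = [
            _annotation("g1", "G1"),  # intact -> 2
            _annotation("g2", "G2", "fragment"),
            _annotation("g3", "G2", "fragment"),  # two fragments -> 1
            _annotation("g4", "G3"),
            _annotation("g5", "G3", "fragment"),  # intact dominates -> 2
        ]
        table = _family_table({g: "famA" for g in ("g1", "g2", "g3", "g4", "g5")})
        matrix = cp.ternary_presence(table, annotations)
        assert matrix.state("G1", "famA") == 2
        assert matrix.state("G2", "famA") == 1
        assert matrix.state("G3", "famA") == 2

    def test_gene_without_family_is_error(self):
        with pytest.raises(CladepanError, match="family"):
            cp.ternary_presence(_family_table({}), [_annotation("gx", "G1")])


class TestPartition:
    def test_three_genome_example(self):
        table = _family_table({"a1": "F1", "a2": "F1", "a3": "F1",
                               "b1": "F2", "b2": "F2", "c1": "F3"})
        annotations = [
            _annotation("a1", "G1"), _annotation("a2", "G2"), _annotation("a3", "G3"),
            _annotation("b1", "G1"), _annotation("b2", "G2"),
            _annotation("c1", "G3"),
        ]
        matrix = cp.ternary_presence(table, annotations)
        core, variable, singleton = cp.partition_pangenome(matrix, table)
        assert core == {"F1"}
        assert variable == {"F2"}
        assert singleton == {"F3"}

    def test_single_genome_no_variable(self):
        table = _family_table({"a1": "F1", "a2": "F1", "b1": "F2"})
        annotations = [_annotation("a1", "G1"), _annotation("a2", "G1"),
                       _annotation("b1", "G1")]
        matrix = cp.ternary_presence(table, annotations)
        core, variable, singleton = cp.partition_pangenome(matrix, table)
        assert not variable
        assert core | singleton == {"F1", "F2"}

    def test_partition_is_exhaustive_and_disjoint(self, family_analysis):
        table, matrix = family_analysis
        core, variable, singleton = cp.partition_pangenome(matrix, table)
        assert core | variable | singleton == set(matrix.families)
        assert not (core & variable or core & singleton or variable & singleton)


def _random_ternary(rng, n_genomes=6, n_families=25):
    cells = rng.integers(0, 3, size=(n_genomes, n_families)).astype("int8")
    return cp.TernaryMatrix(df=pd.DataFrame(
        cells,
        index=[f"G{i}" for i in range(n_genomes)],
        columns=[f"F{j}" for j in range(n_families)],
    ))


class TestRarefaction:
    def test_identical_genomes_flat_curves(self):
        df = pd.DataFrame(2, index=["G1", "G2", "G3"],
                          columns=["F1", "F2"], dtype="int8")
        curve = cp.rarefaction_curve(cp.TernaryMatrix(df=df), reps=3,
                                     rng=np.random.default_rng(0))
        assert (curve.pan_size == 2).all()
        assert (curve.core_size == 2).all()

    def test_full_sample_equals_pan_and_core(self):
        matrix = _random_ternary(np.random.default_rng(4))
        core, variable, singleton = cp.partition_pangenome(matrix)
        present = matrix.df.to_numpy() >= 1
        n = matrix.df.shape[0]
        curve = cp.rarefaction_curve(matrix, reps=5, rng=np.random.default_rng(1))
        last = curve[curve.n_strains == n]
        assert (last.pan_size == int(present.any(axis=0).sum())).all()
        assert (last.core_size == int(present.all(axis=0).sum())).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_curves_monotonic(self, seed):
        matrix = _random_ternary(np.random.default_rng(seed + 100))
        curve = cp.rarefaction_curve(matrix, reps=10,
                                     rng=np.random.default_rng(seed))
        means = curve.groupby("n_strains")[["pan_size", "core_size"]].mean()
        assert (means.pan_size.diff().dropna() >= -1e-9).all()
        assert (means.core_size.diff().dropna() <= 1e-9).all()


class TestGroupBootstrap:
    def _matrix_and_groups(self, rng, sizes):
        genomes = []
        group_of = {}
        for gi, size in enumerate(sizes):
            for s in range(size):
                gid = f"g{gi}_{s}"
                genomes.append(gid)
                group_of[gid] = f"grp{gi}"
        cells = rng.integers(0, 3, size=(len(genomes), 40)).astype("int8")
        matrix = cp.TernaryMatrix(df=pd.DataFrame(
            cells, index=genomes, columns=[f"F{j}" for j in range(40)]))
        return matrix, group_of

    def test_exhausted_group_has_zero_sd(self):
        matrix, group_of = self._matrix_and_groups(np.random.default_rng(2), [5, 6])
        stats = cp.group_bootstrap_stats(matrix, group_of, sample_n=5, reps=50,
                                         rng=np.random.default_rng(0))
        row = stats.loc["grp0"]
        for key in ("unique_micfams", "unique_singletons", "micfams", "singletons"):
            assert row[f"{key}_sd"] == 0.0

    def test_fixed_seed_reproducible(self):
        matrix, group_of = self._matrix_and_groups(np.random.default_rng(3), [6])
        s1 = cp.group_bootstrap_stats(matrix, group_of, sample_n=5, reps=1,
                                      rng=np.random.default_rng(5))
        s2 = cp.group_bootstrap_stats(matrix, group_of, sample_n=5, reps=1,
                                      rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(s1, s2)

    def test_six_strain_group_matches_exhaustive_enumeration(self):
        matrix, group_of = self._matrix_and_groups(np.random.default_rng(6), [6])
        core, variable, singleton = cp.partition_pangenome(matrix)
        present = matrix.df.to_numpy() >= 1
        var_cols = [j for j, f in enumerate(matrix.families) if f in variable]
        exact_values = []
        for subset in itertools.combinations(range(6), 5):
            sub = present[np.ix_(list(subset), var_cols)]
            exact_values.append(sub.any(axis=0).sum())
        exact_mean = np.mean(exact_values)
        reps = 10_000
        stats = cp.group_bootstrap_stats(matrix, group_of, sample_n=5, reps=reps,
                                         rng=np.random.default_rng(1))
        observed = stats.loc["grp0", "unique_micfams_mean"]
        sd = stats.loc["grp0", "unique_micfams_sd"]
        assert abs(observed - exact_mean) <= max(4 * sd / np.sqrt(reps), 1e-9)

    def test_group_smaller_than_sample_is_error(self):
        matrix, group_of = self._matrix_and_groups(np.random.default_rng(8), [3])
        with pytest.raises(CladepanError, match="grp0"):
            cp.group_bootstrap_stats(matrix, group_of, sample_n=5, reps=10)
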