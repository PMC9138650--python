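"""Simulator behaviour: determinism, rate calibration, ground-truth recovery."""
import numpy as np
import pytest
from scipy import stats as sps

from phyloepi import (
    SimConfig,
    SubstitutionModel,
    dinuc_divergence_stats,
    evolve_along_tree,
    five_taxon_primate_tree,
    generate_root_sequence,
    make_island_spec,
    p_distance_matrix,
    scan_dinuc_sites,
    summarize_divergence,
    three_taxon_caterpillar,
    topology_equal,
    upgma,
)
from phyloepi.cli import cpg_tree, snp_tree
from phyloepi.errors import DistanceError, ParameterError
from phyloepi.phylo import Tree, TreeNode


def _cg_start_density(seq, start=0, end=None):
    end = len(seq) if end is None else end
    region = seq[start:end]
    return region.count("CG") / max(len(region), 1)


class TestGenerateRootSequence:
    def test_length_zero(self):
        assert generate_root_sequence(0, seed=1) == ""

    def test_determinism(self):
        a = generate_root_sequence(2000, seed=5)
        b = generate_root_sequence(2000, seed=5)
        assert a == b
        assert a != generate_root_sequence(2000, seed=6)

    def test_density_infeasible(self):
        with pytest.raises(ParameterError):
            generate_root_sequence(100, cpg_density_out=0.6, seed=0)

    def test_in_must_exceed_out_with_islands(self):
        with pytest.raises(ParameterError):
            generate_root_sequence(
                1000, ((0, 100, False),), cpg_density_in=0.01,
                cpg_density_out=0.05, seed=0,
            )

    def test_island_density_within_three_standard_errors(self):
        L = 10000
        spec = ((2000, 5000, False),)
        seq = generate_root_sequence(
            L, spec, cpg_density_in=0.10, cpg_density_out=0.01, seed=17
        )
        assert len(seq) == L
        d_in = _cg_start_density(seq, 2000, 5000)
        d_out = _cg_start_density(seq, 5100, L)
        se_in = np.sqrt(0.10 * 0.90 / 3000)
        se_out = np.sqrt(0.01 * 0.99 / 4900)
        assert abs(d_in - 0.10) < 3 * se_in
        assert abs(d_out - 0.01) < 3 * se_out


class TestMakeIslandSpec:
    def test_layout_and_protection(self):
        spec = make_island_spec(10000, n_islands=10, island_length=200,
                                protected_fraction=0.5)
        assert len(spec) == 10
        assert all(e - s == 200 for s, e, _ in spec)
        assert sum(p for _, _, p in spec) == 5
        ends = [e for _, e, _ in spec]
        starts = [s for s, _, _ in spec]
        assert all(starts[i + 1] >= ends[i] for i in range(9))

    def test_infeasible(self):
        with pytest.raises(ParameterError):
            make_island_spec(100, n_islands=2, island_length=100)


class TestEvolveAlongTree:
    def test_determinism_byte_identical(self):
        cfg = SimConfig(tree=five_taxon_primate_tree(),
                        root_sequence_length=3000, seed=11,
                        island_spec=make_island_spec(3000, 5, 100))
        aln1, tr1 = evolve_along_tree(cfg)
        aln2, tr2 = evolve_along_tree(cfg)
        assert aln1 == aln2
        assert tr1.root_sequence == tr2.root_sequence
        assert tr1.mutations.equals(tr2.mutations)

    def test_zero_branch_lengths_copy_root(self):
        t = Tree(TreeNode(children=(
            TreeNode(label="a", height=0.0, length=0.0),
            TreeNode(label="b", height=0.0, length=0.0),
        ), height=0.0))
        cfg = SimConfig(tree=t, root_sequence_length=500, seed=2)
        aln, truth = evolve_along_tree(cfg)
        assert aln.rows == (truth.root_sequence,) * 2
        assert truth.n_substitutions == 0

    def test_tree_without_lengths_rejected(self):
        t = Tree(TreeNode(children=(
            TreeNode(label="a", height=0.0),
            TreeNode(label="b", height=0.0),
        ), height=0.0))
        with pytest.raises(DistanceError):
            SimConfig(tree=t, root_sequence_length=100, seed=0)

    def test_substitution_counts_poisson_under_null(self):
        # m=1, no islands: per-branch counts ~ Poisson(L * t); dispersion test
        t = Tree(TreeNode(children=(
            TreeNode(label="a", height=0.0, length=0.05),
            TreeNode(label="b", height=0.0, length=0.05),
        ), height=0.05))
        L, bl = 2000, 0.05
        counts = []
        for rep in range(50):
            cfg = SimConfig(
                tree=t, root_sequence_length=L, seed=1000 + rep,
                model=SubstitutionModel(cpg_multiplier=1.0),
            )
            _, truth = evolve_along_tree(cfg)
            counts.extend(
                truth.mutations.groupby("branch").size().reindex(
                    ["a", "b"], fill_value=0
                )
            )
        mu = L * bl
        statistic = float(np.sum((np.array(counts) - mu) ** 2 / mu))
        p = sps.chi2.sf(statistic, df=len(counts))
        assert 0.001 < p or sps.chi2.cdf(statistic, df=len(counts)) < 0.999

    def test_cpg_rate_elevation_matches_multiplier(self):
        # C->T events per ancestral CpG-C vs per ancestral non-CpG C: the
        # per-opportunity ratio must sit within 30% of the configured factor.
        m = 25.0
        t = Tree(TreeNode(children=(
            TreeNode(label="a", height=0.0, length=0.01),
            TreeNode(label="b", height=0.0, length=0.01),
        ), height=0.01))
        L = 100_000
        cfg = SimConfig(
            tree=t, root_sequence_length=L, seed=424242,
            model=SubstitutionModel(cpg_multiplier=m),
            island_spec=make_island_spec(L, 20, 500),
            cpg_density_in=0.10, cpg_density_out=0.01,
        )
        aln, truth = evolve_along_tree(cfg)
        root = truth.root_sequence
        cpg_c = {i for i in range(L - 1) if root[i : i + 2] == "CG"}
        all_c = {i for i in range(L) if root[i] == "C"}
        plain_c = all_c - cpg_c
        muts = truth.mutations
        ct = muts[(muts.ref_base == "C") & (muts.alt_base == "T")]
        n_cpg = int(ct.position.isin(cpg_c).sum())
        n_plain = int(ct.position.isin(plain_c).sum())
        ratio = (n_cpg / len(cpg_c)) / (n_plain / len(plain_c))
        assert m * 0.7 < ratio < m * 1.3

    def test_preserved_variable_fraction_monotone_in_multiplier(self):
        fractions = []
        for m in (1.0, 5.0, 25.0, 50.0):
            cfg = SimConfig(
                tree=five_taxon_primate_tree(), root_sequence_length=20_000,
                seed=7, model=SubstitutionModel(cpg_multiplier=m),
                island_spec=make_island_spec(20_000, 10, 200),
            )
            aln, _ = evolve_along_tree(cfg)
            st = dinuc_divergence_stats(aln, ("CG",))
            fractions.append(st.per_dinuc["CG"].preserved_variable_fraction)
        assert fractions == sorted(fractions)

    def test_protected_islands_erode_less(self):
        # half the islands protected: their CpG sites must stay more intact
        L = 20_000
        spec = make_island_spec(L, 10, 400, protected_fraction=0.5)
        cfg = SimConfig(
            tree=five_taxon_primate_tree(), root_sequence_length=L, seed=29,
            model=SubstitutionModel(cpg_multiplier=25.0, protected_fraction=0.5),
            island_spec=spec,
        )
        aln, truth = evolve_along_tree(cfg)
        sites = scan_dinuc_sites(aln, "CG", "majority")
        prot = truth.protected

        def variable_fraction(site_list):
            var = sum(s.site_class.value == "preserved_variable" for s in site_list)
            return var / max(len(site_list), 1)

        in_island = np.zeros(L, dtype=bool)
        for s, e, _ in spec:
            in_island[s:e] = True
        prot_sites = [s for s in sites if prot[s.column]]
        unprot_sites = [s for s in sites if in_island[s.column] and not prot[s.column]]
        assert len(prot_sites) > 20 and len(unprot_sites) > 20
        assert variable_fraction(prot_sites) < variable_fraction(unprot_sites)


class TestSummarizeDivergence:
    def test_table_shape_and_truth_columns(self):
        cfg = SimConfig(tree=three_taxon_caterpillar(),
                        root_sequence_length=2000, seed=3)
        aln, truth = evolve_along_tree(cfg)
        df = summarize_divergence(aln, truth)
        assert list(df["dinuc_type"]) == ["CG", "AG", "TG", "GG"]
        assert (df["n_true_substitutions"] == truth.n_substitutions).all()
        assert df["n_true_cpg_deaminations"].iloc[0] <= truth.n_substitutions

    def test_null_run_has_no_cpg_excess(self):
        # multiplier 1 on a uniform root: CG fraction comparable to AG/TG/GG
        rng = np.random.default_rng(55)
        root = "".join(rng.choice(list("ACGT"), 20_000))
        cfg = SimConfig(
            tree=five_taxon_primate_tree(), root_sequence_length=20_000,
            seed=5, model=SubstitutionModel(cpg_multiplier=1.0),
            root_sequence=root,
        )
        aln, truth = evolve_along_tree(cfg)
        df = summarize_divergence(aln, truth).set_index("dinuc_type")
        cg = df.loc["CG", "genome_fraction"]
        others = df.drop("CG")["genome_fraction"]
        assert cg < 3 * others.max() + 1e-9
        assert (truth.mutations["cpg_context"] == False).all()  # noqa: E712


class TestEndToEndRecovery:
    def test_three_taxon_both_pipelines(self):
        # caterpillar with well-separated heights: both the SNP-mode and the
        # CpG-mode pipeline must recover the true rooted topology
        true = three_taxon_caterpillar(h1=0.01, h2=0.03)
        n_ok_snp = n_ok_cpg = 0
        reps = 100
        for rep in range(reps):
            cfg = SimConfig(
                tree=true, root_sequence_length=10_000, seed=50_000 + rep,
                model=SubstitutionModel(cpg_multiplier=25.0),
                island_spec=make_island_spec(10_000, 10, 200),
            )
            aln, _ = evolve_along_tree(cfg)
            n_ok_snp += topology_equal(snp_tree(aln), true)
            n_ok_cpg += topology_equal(cpg_tree(aln), true)
        assert n_ok_snp >= 0.95 * reps
        assert n_ok_cpg >= 0.95 * reps
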