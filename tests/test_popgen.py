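"""Population genetics: diversity, distances, AMOVA vs brute-force oracle,
NJ tree, haplotype network."""

import io

import numpy as np
import pandas as pd
import pytest

import littorina as lt
from littorina.popgen import InputError
from conftest import make_dataset


# ---------------------------------------------------------------------------
# brute-force AMOVA oracle: plain-Python evaluation of the sums-of-squares
# identities and expected-mean-square coefficient equations
# ---------------------------------------------------------------------------


def oracle_components(sequences, pops, groups=None):
    n = len(sequences)
    d = [[sum(a != b for a, b in zip(sequences[i], sequences[j]))
          for j in range(n)] for i in range(n)]

    def ssd(members):
        return sum(d[i][j] for i in members for j in members) / (2 * len(members))

    everyone = list(range(n))
    ssd_total = ssd(everyone)
    pop_names = sorted(set(pops))
    pop_members = {p: [i for i in everyone if pops[i] == p] for p in pop_names}
    ssd_wp = sum(ssd(m) for m in pop_members.values())

    if groups is None:
        df_ap, df_wp = len(pop_names) - 1, n - len(pop_names)
        sigma_c = ssd_wp / df_wp
        sizes = [len(pop_members[p]) for p in pop_names]
        n_prime = (n - sum(s**2 for s in sizes) / n) / df_ap
        sigma_b = ((ssd_total - ssd_wp) / df_ap - sigma_c) / n_prime
        return 0.0, sigma_b, sigma_c

    grp_names = sorted(set(groups))
    grp_members = {g: [i for i in everyone if groups[i] == g] for g in grp_names}
    ssd_wg = sum(ssd(m) for m in grp_members.values())
    ssd_ag = ssd_total - ssd_wg
    ssd_ap_wg = ssd_wg - ssd_wp

    P, G = len(pop_names), len(grp_names)
    df_ag, df_ap, df_wp = G - 1, P - G, n - P
    sigma_c = ssd_wp / df_wp
    grp_of_pop = {p: groups[pop_members[p][0]] for p in pop_names}
    grp_size = {g: len(m) for g, m in grp_members.items()}
    A = sum(len(pop_members[p]) ** 2 / grp_size[grp_of_pop[p]] for p in pop_names)
    B = sum(len(pop_members[p]) ** 2 for p in pop_names) / n
    C = sum(s**2 for s in grp_size.values()) / n
    n1 = (n - A) / df_ap if df_ap > 0 else float("nan")
    n2 = (A - B) / df_ag
    n3 = (n - C) / df_ag
    sigma_b = ((ssd_ap_wg / df_ap) - sigma_c) / n1 if df_ap > 0 else 0.0
    sigma_a = ((ssd_ag / df_ag) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


class TestReadFasta:
    def test_mapped_records_loaded(self):
        fasta = io.StringIO(">a\nACGT\n>b\nACGA\n>c\nACGT\n>d\nACCT\n")
        mapping = pd.DataFrame(
            {"sample": list("abcd"), "population": ["p1", "p1", "p2", "p2"]}
        )
        ds = lt.read_fasta_with_labels(fasta, mapping)
        assert len(ds) == 4
        assert ds.populations == ["p1", "p1", "p2", "p2"]

    def test_unmapped_record_error_names_it(self):
        fasta = io.StringIO(">a\nACGT\n>mystery\nACGT\n")
        mapping = pd.DataFrame({"sample": ["a"], "population": ["p1"]})
        with pytest.raises(InputError, match="mystery"):
            lt.read_fasta_with_labels(fasta, mapping)

    def test_mixed_case_uppercased(self):
        fasta = io.StringIO(">a\nacgt\n>b\nAcGt\n")
        mapping = pd.DataFrame({"sample": ["a", "b"], "population": ["p", "p"]})
        ds = lt.read_fasta_with_labels(fasta, mapping)
        assert ds.sequences == ["ACGT", "ACGT"]

    def test_ragged_alignment_rejected(self):
        fasta = io.StringIO(">a\nACGT\n>b\nACG\n")
        mapping = pd.DataFrame({"sample": ["a", "b"], "population": ["p", "p"]})
        with pytest.raises(InputError):
            lt.read_fasta_with_labels(fasta, mapping)


class TestCollapse:
    def test_all_identical_single_private_haplotype(self):
        ds = make_dataset([("ACGT", "p1")] * 5)
        table = lt.collapse_haplotypes(ds)
        assert len(table) == 1
        assert table["count"].iloc[0] == 5
        assert bool(table["private"].iloc[0])

    def test_two_identical_pairs(self):
        ds = make_dataset(
            [("ACGT", "p1"), ("ACGA", "p2"), ("ACGT", "p1"), ("ACGA", "p1")]
        )
        table = lt.collapse_haplotypes(ds)
        assert sorted(table["count"]) == [2, 2]
        shared = table[table["sequence"] == "ACGA"].iloc[0]
        assert not shared["private"]

    def test_private_flag_requires_single_population(self):
        ds = make_dataset([("AAAA", "p1"), ("AAAA", "p2"), ("CCCC", "p2")])
        table = lt.collapse_haplotypes(ds).set_index("sequence")
        assert not table.loc["AAAA", "private"]
        assert table.loc["CCCC", "private"]


class TestDiversity:
    def test_all_distinct_haplotype_diversity_is_one(self):
        ds = make_dataset(
            [("AAAA", "p"), ("AAAC", "p"), ("AACC", "p"), ("ACCC", "p")]
        )
        assert lt.diversity(ds)["overall"].h_e == pytest.approx(1.0)

    def test_two_pairs_hand_value(self):
        ds = make_dataset(
            [("AAAA", "p"), ("AAAA", "p"), ("CCCC", "p"), ("CCCC", "p")]
        )
        # H_e = (4/3)(1 - 0.5) = 2/3
        assert lt.diversity(ds)["overall"].h_e == pytest.approx(2.0 / 3.0)

    def test_pi_two_sequences_two_diffs_of_598(self):
        base = "A" * 598
        other = "C" + base[1:597] + "G"
        ds = make_dataset([(base, "p"), (other, "p")])
        s = lt.diversity(ds)["overall"]
        assert s.pi == pytest.approx(2.0 / 598.0)
        assert s.mean_pairwise_diff == pytest.approx(2.0)
        assert s.n_ps == 2

    def test_order_invariance(self):
        seqs = [("AAAA", "p"), ("AACC", "p"), ("CCCC", "p"), ("AAAC", "p")]
        a = lt.diversity(make_dataset(seqs))["overall"]
        b = lt.diversity(make_dataset(seqs[::-1]))["overall"]
        assert (a.h_e, a.pi, a.n_hap) == (b.h_e, b.pi, b.n_hap)

    def test_single_sequence_rejected(self):
        with pytest.raises(InputError):
            lt.diversity(make_dataset([("ACGT", "p")]))


class TestPDistance:
    def test_identical_zero_and_hand_value(self):
        base = "A" * 598
        other = "CCC" + base[3:]
        m = lt.p_distance_matrix([base, base, other])
        assert m[0, 1] == 0.0
        assert m[0, 2] == pytest.approx(3.0 / 598.0)
        np.testing.assert_allclose(m, m.T)

    def test_ambiguous_sites_excluded_pairwise(self):
        m = lt.p_distance_matrix(["ACGT", "NCGA", "ACGA"])
        assert m[0, 1] == pytest.approx(1.0 / 3.0)  # N site dropped for this pair
        assert m[2, 1] == pytest.approx(0.0)

    def test_triangle_inequality_on_random_fixture(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)]
        m = lt.p_distance_matrix(seqs)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-12


class TestBaseComposition:
    def test_identical_sequences_chi2_zero(self):
        ds = make_dataset([("ACGTACGT", "p"), ("ACGTACGT", "p")])
        chi2, df, p = lt.base_composition_homogeneity(ds)
        assert chi2 == 0.0
        assert p == 1.0

    def test_hand_contingency_value(self):
        ds = make_dataset([("A" * 8 + "C" * 2, "p"), ("A" * 2 + "C" * 8, "p")])
        chi2, df, p = lt.base_composition_homogeneity(ds)
        assert chi2 == pytest.approx(7.2)
        assert df == 1

    def test_third_codon_class(self):
        ds = make_dataset([("AAAC" * 3, "p"), ("AAAC" * 3, "p")])
        chi2, _, p = lt.base_composition_homogeneity(
            ds, site_class="third-codon", codon_frame=0
        )
        assert chi2 == 0.0

    def test_overall_composition_percentages(self):
        ds = make_dataset([("AACG", "p"), ("TTTT", "p")])
        comp = lt.base_composition(ds)
        assert comp["T"] == pytest.approx(50.0)
        assert sum(comp.values()) == pytest.approx(100.0)


class TestAmova:
    def test_monomorphic_distinct_populations_phi_one(self):
        ds = make_dataset(
            [("AAAA", "X")] * 4 + [("CCCC", "Y")] * 4
        )
        res = lt.amova(ds, n_perm=0)
        assert res.phi_st == pytest.approx(1.0)

    def test_all_identical_degenerate_phi_zero(self):
        ds = make_dataset([("ACGT", "X")] * 3 + [("ACGT", "Y")] * 3)
        with pytest.warns(UserWarning):
            res = lt.amova(ds, n_perm=0)
        assert res.phi_st == 0.0
        assert res.degenerate

    def test_components_match_bruteforce_two_pops(self, two_pop_fixture):
        res = lt.amova(two_pop_fixture, n_perm=0)
        _, sb, sc = oracle_components(
            two_pop_fixture.sequences, two_pop_fixture.populations
        )
        assert res.sigma_b == pytest.approx(sb, abs=1e-10)
        assert res.sigma_c == pytest.approx(sc, abs=1e-10)

    def test_components_match_bruteforce_hierarchical(self, hierarchical_fixture):
        ds = hierarchical_fixture
        res = lt.amova(ds, n_perm=0)
        sa, sb, sc = oracle_components(ds.sequences, ds.populations, ds.groups)
        assert res.sigma_a == pytest.approx(sa, abs=1e-10)
        assert res.sigma_b == pytest.approx(sb, abs=1e-10)
        assert res.sigma_c == pytest.approx(sc, abs=1e-10)
        total = sa + sb + sc
        assert res.phi_st == pytest.approx((sa + sb) / total, abs=1e-10)
        assert res.phi_ct == pytest.approx(sa / total, abs=1e-10)
        assert res.phi_sc == pytest.approx(sb / (sb + sc), abs=1e-10)

    def test_permutation_pvalues_deterministic(self, hierarchical_fixture):
        r1 = lt.amova(hierarchical_fixture, n_perm=200, seed=5)
        r2 = lt.amova(hierarchical_fixture, n_perm=200, seed=5)
        assert (r1.p_phi_st, r1.p_phi_sc, r1.p_phi_ct) == (
            r2.p_phi_st, r2.p_phi_sc, r2.p_phi_ct
        )
        for p in (r1.p_phi_st, r1.p_phi_sc, r1.p_phi_ct):
            assert 0.0 <= p <= 1.0

    def test_strong_structure_has_small_p(self):
        ds = make_dataset(
            [("AAAAAAAA", "X")] * 6 + [("CCCCCCCC", "Y")] * 6
        )
        res = lt.amova(ds, n_perm=500, seed=1)
        assert res.p_phi_st < 0.05

    def test_phi_ct_recovers_generator_divergence_ordering(self):
        from littorina.studies import phi_ct_divergence_sweep

        means = phi_ct_divergence_sweep(between_levels=(0, 2, 6), n_replicates=20, seed=0)
        assert means[0] <= means[1] <= means[2]

    def test_phi_ct_type_one_error_controlled_under_null(self):
        """Zero between-region divergence: Phi_CT rejects at most ~5%."""
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            ds = lt.simulate_haplotypes(
                lt.SeqSimConfig(
                    between_group_mutations=0, within_pop_mutations=2,
                    n_per_pop=6, seed=int(rng.integers(2**31)),
                )
            )
            res = lt.amova(ds, n_perm=100, seed=int(rng.integers(2**31)))
            hits += (res.p_phi_ct is not None) and (res.p_phi_ct < 0.05)
        # exact binomial 97.5% upper bound for rate 0.05 at n=100; the
        # whole-population permutation scheme is discrete hence conservative
        assert hits <= 11


class TestPairwisePhist:
    def test_matches_single_pair_amova(self, two_pop_fixture):
        phi, pval = lt.pairwise_phist(two_pop_fixture, n_perm=100, seed=3)
        single = lt.amova(two_pop_fixture, n_perm=0)
        assert phi.loc["X", "Y"] == pytest.approx(single.phi_st, abs=1e-12)
        assert 0.0 <= pval.loc["X", "Y"] <= 1.0

    def test_duplicate_population_phi_small(self):
        """A population compared against its exact copy: the estimator's
        finite-sample value is -1/(m-1) (zero self-distances deflate the
        between-population average), vanishing as m grows."""
        rng = np.random.default_rng(2)
        m = 6
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(m)]
        ds = make_dataset(
            [(s, "X") for s in seqs] + [(s, "Y") for s in seqs]
        )
        phi, _ = lt.pairwise_phist(ds, n_perm=0, seed=0)
        assert phi.loc["X", "Y"] == pytest.approx(-1.0 / (m - 1), abs=1e-10)
        assert abs(phi.loc["X", "Y"]) < 0.25

    def test_fixed_seed_identical_pvalues(self, hierarchical_fixture):
        p1 = lt.pairwise_phist(hierarchical_fixture, n_perm=100, seed=7)[1]
        p2 = lt.pairwise_phist(hierarchical_fixture, n_perm=100, seed=7)[1]
        pd.testing.assert_frame_equal(p1, p2)


class TestDaDistance:
    def test_identical_monomorphic_populations_zero(self):
        ds = make_dataset(
            [("AAAA", "X"), ("AAAA", "X"), ("AAAA", "Y"), ("AAAA", "Y")]
        )
        da = lt.da_distance(ds)
        assert da.loc["X", "Y"] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_populations_net_divergence(self):
        # pi terms vanish; D_a = k/L with k=3 differences over L=12
        x = "AAAAAAAAAAAA"
        y = "CCCAAAAAAAAA"
        ds = make_dataset([(x, "X"), (x, "X"), (y, "Y"), (y, "Y")])
        da = lt.da_distance(ds)
        assert da.loc["X", "Y"] == pytest.approx(3.0 / 12.0)

    def test_mixed_fixture_hand_computed(self):
        ds = make_dataset(
            [("AAAA", "X"), ("AAAC", "X"), ("CCAA", "Y"), ("CCAC", "Y")]
        )
        # within-X pairs: 1/4; within-Y: 1/4 -> pi_X = pi_Y = 0.25
        # between pairs: d(AAAA,CCAA)=2, d(AAAA,CCAC)=3, d(AAAC,CCAA)=3,
        # d(AAAC,CCAC)=2 -> D_xy = 10/16 = 0.625; D_a = 0.625 - 0.25 = 0.375
        da = lt.da_distance(ds)
        assert da.loc["X", "Y"] == pytest.approx(0.375)


class TestNjTree:
    def three_taxon_matrix(self):
        return pd.DataFrame(
            [[0.0, 2.0, 3.0], [2.0, 0.0, 4.0], [3.0, 4.0, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )

    def test_three_taxa_closed_form_branch_lengths(self):
        import dendropy

        newick = lt.nj_tree(self.three_taxon_matrix())
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        # closed form: a=(2+3-4)/2=0.5, b=1.5, c=2.5; patristic = input
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(2.0)
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(3.0)
        assert pdm.distance(taxa["B"], taxa["C"]) == pytest.approx(4.0)

    def test_additive_four_taxon_matrix_recovered(self):
        import dendropy

        # tree ((A:1,B:2):1,C:3,D:4) with internal edge 1
        dist = pd.DataFrame(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ],
            index=list("ABCD"), columns=list("ABCD"),
        )
        newick = lt.nj_tree(dist)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in "ABCD":
            for j in "ABCD":
                if i != j:
                    assert pdm.distance(taxa[i], taxa[j]) == pytest.approx(
                        dist.loc[i, j]
                    )

    def test_newick_parses_with_expected_leaves(self):
        import dendropy

        newick = lt.nj_tree(self.three_taxon_matrix(), outgroup="C")
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == {"A", "B", "C"}

    def test_asymmetric_matrix_rejected(self):
        m = self.three_taxon_matrix()
        m.iloc[0, 1] = 99.0
        with pytest.raises(InputError):
            lt.nj_tree(m)


class TestHaplotypeNetwork:
    def test_two_haplotypes_single_edge(self):
        ds = make_dataset([("AAAA", "p"), ("AAAC", "p")])
        net = lt.haplotype_network(ds)
        assert len(net.edges) == 1
        assert net.edges["steps"].iloc[0] == 1.0

    def test_chain_keeps_only_short_edges(self):
        ds = make_dataset([("AAAA", "p"), ("AAAC", "p"), ("AAGC", "p")])
        net = lt.haplotype_network(ds)
        assert len(net.edges) == 2
        assert (net.edges["steps"] == 1.0).all()

    def test_connection_limit_disconnects(self):
        ds = make_dataset([("AAAA", "p"), ("CCCC", "q")])
        net = lt.haplotype_network(ds, connection_limit=3)
        assert len(net.edges) == 0
        assert len(net.nodes) == 2

    def test_equal_weight_ties_all_retained(self):
        # square: four haplotypes, four 1-step edges form a cycle; a pure
        # spanning tree would drop one, the network keeps all ties
        ds = make_dataset(
            [("AAAA", "p"), ("AACA", "p"), ("CAAA", "p"), ("CACA", "p")]
        )
        net = lt.haplotype_network(ds)
        assert len(net.edges) == 4
        assert (net.edges["steps"] == 1.0).all()

    def test_node_frequencies_per_population(self):
        ds = make_dataset(
            [("AAAA", "p1"), ("AAAA", "p2"), ("AAAC", "p2")]
        )
        net = lt.haplotype_network(ds)
        top = net.nodes.set_index("haplotype").loc["H1"]
        assert top["count"] == 2
        assert top["population_counts"] == "p1:1;p2:1"
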