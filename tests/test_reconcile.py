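"""Rooting enumeration, LCA reconciliation and duplication-timing classes."""

import numpy as np
import pytest

from paraclade.core_io import CladeScheme, FormatError, GeneTree, Node, parse_newick
from paraclade.reconcile import (
    _classify_rooted,
    best_rooting,
    classify_family,
    count_root_choices,
    diagnostic_columns,
    enumerate_rootings,
    lca_reconcile,
    min_cost_rootings,
    n_rootings,
    reroot_on_edge,
    unroot,
)
from paraclade.simulate import SimulationConfig, default_species_trees, simulate_family

PATTERN_SCHEME = CladeScheme({"B": "B", "Cn": "Cn", "Pl": "Pl", "Ct": "Ct",
                              "Po": "Po", "Cf": "Choanoflagellatea"})


def bipartitions(tree):
    allp = frozenset(tree.leaf_names())
    out = set()
    for n in tree.postorder():
        if n.parent is None or n.is_leaf:
            continue
        s = frozenset(l.name for l in n.leaves())
        if 2 <= len(s) <= len(allp) - 2:
            out.add(min(s, allp - s, key=sorted))
    return out


class TestRootingEnumeration:
    def test_four_leaves_give_five_rootings(self):
        u = unroot(parse_newick("((A|a:1,B|b:1):1,(C|c:1,D|d:1):1);"))
        assert len(enumerate_rootings(u)) == 5

    def test_ten_leaf_fixture_gives_seventeen_rootings(self, forced_fixture):
        u = unroot(forced_fixture["cteno_world_true"])
        assert n_rootings(u) == 2 * len(u) - 3 == 17
        assert len(enumerate_rootings(u)) == 17

    def test_every_rooting_unroots_back(self, forced_fixture):
        u = unroot(forced_fixture["cteno_world_true"])
        reference = bipartitions(u)
        for rooted in enumerate_rootings(u):
            assert len(rooted.root.children) == 2
            assert bipartitions(unroot(rooted)) == reference

    def test_rooted_input_rejected(self, forced_fixture):
        with pytest.raises(FormatError, match="unroot"):
            enumerate_rootings(forced_fixture["cteno_world_true"])

    def test_edge_lengths_preserved_by_rerooting(self, forced_fixture):
        u = unroot(forced_fixture["cteno_world_true"])
        total = u.total_length()
        for rooted in enumerate_rootings(u):
            assert rooted.total_length() == pytest.approx(total)


class TestLcaReconcile:
    def test_congruent_tree_costs_nothing(self, five_phyla):
        cfg = SimulationConfig(seed=1, include_choanoflagellate=True,
                               rate_asymmetry=(1.0, 1.0))
        h = simulate_family(cfg)
        summary = lca_reconcile(h.tree, five_phyla["ctenophore_early"])
        assert summary.cost == (0, 0)

    def test_fixture_true_rooting_single_duplication(self, forced_fixture):
        summary = lca_reconcile(forced_fixture["cteno_world_true"], forced_fixture["ctenophore_early"])
        assert summary.cost == (1, 0)

    def test_slow_clade_partition_one_ctenophore_loss(self, forced_fixture):
        summary = lca_reconcile(forced_fixture["slow_clade_partition"], forced_fixture["sponge_early"])
        assert summary.cost == (0, 1)
        assert summary.loss_edges() == ["Ct"]

    def test_unmapped_species_raises(self, forced_fixture):
        tree = parse_newick("('Zz|g1':1,('B|b1':1,'Cn|c1':1):1);")
        with pytest.raises(KeyError, match="Zz"):
            lca_reconcile(tree, forced_fixture["sponge_early"])

    def test_multifurcation_rejected(self, forced_fixture):
        tree = parse_newick("('B|a':1,'Cn|b':1,'Pl|c':1);")
        tree.root.add(Node("Po|d", 1.0))
        rooted = GeneTree(Node(children=[tree.root, Node("Ct|e", 1.0)]))
        with pytest.raises(FormatError, match="polytomies|multifurcat"):
            lca_reconcile(rooted, forced_fixture["sponge_early"])

    def test_losses_match_loss_edge_listing(self, five_phyla):
        for seed in range(10):
            cfg = SimulationConfig(seed=300 + seed, birth_rate=0.5,
                                   death_rate=0.3,
                                   include_choanoflagellate=True,
                                   rate_asymmetry=(1.0, 1.0))
            h = simulate_family(cfg)
            summary = lca_reconcile(h.tree, five_phyla["ctenophore_early"])
            assert len(summary.loss_edges()) == summary.losses

    def test_pure_birth_families_match_event_counts(self, five_phyla):
        # with no losses every duplication event survives and is visible
        for seed in range(60):
            cfg = SimulationConfig(seed=400 + seed, birth_rate=0.6,
                                   include_choanoflagellate=True,
                                   rate_asymmetry=(1.0, 1.0))
            h = simulate_family(cfg)
            summary = lca_reconcile(h.tree, five_phyla["ctenophore_early"])
            assert summary.duplications == h.n_events("duplication")
            assert summary.losses == 0

    def test_random_lossy_families_match_species_set_oracle(self, five_phyla):
        # independent per-node recomputation: map every node to the LCA of
        # its leaf species set, then recount duplications and depth gaps
        sp = five_phyla["ctenophore_early"]
        checked = 0
        for seed in range(200):
            cfg = SimulationConfig(seed=500 + seed, birth_rate=0.5,
                                   death_rate=0.25,
                                   include_choanoflagellate=True,
                                   rate_asymmetry=(1.0, 1.0))
            h = simulate_family(cfg)
            if len(h.tree.leaf_names()) > 20:
                continue
            summary = lca_reconcile(h.tree, sp)
            D = L = 0
            for node in h.tree.postorder():
                if node.is_leaf:
                    continue
                from paraclade.core_io import species_of

                mv = sp.lca_of_species(
                    {species_of(l.name) for l in node.leaves()})
                child_maps = [
                    sp.lca_of_species(
                        {species_of(l.name) for l in c.leaves()})
                    for c in node.children
                ]
                dup = any(m is mv for m in child_maps)
                D += dup
                for m in child_maps:
                    gap = sp.depth(m) - sp.depth(mv)
                    L += gap if dup else max(0, gap - 1)
            assert (summary.duplications, summary.losses) == (D, L)
            checked += 1
        assert checked >= 150


class TestCountRootChoices:
    def test_hand_enumerated_example(self):
        scheme = CladeScheme({"CtA": "Ct", "CtB": "Ct", "Po": "Po",
                              "Cn": "Cn", "B": "B"})
        tree = parse_newick("((CtA:1,CtB:1):1,(Po:1,(Cn:1,B:1):1):1);")
        report = count_root_choices(tree, scheme)
        assert report.n_edges == 7
        assert report.count("Ct") == 3  # two pendants plus their joining edge
        assert report.count("Po") == 1

    def test_fixture_two_and_two(self, forced_fixture):
        report = count_root_choices(unroot(forced_fixture["cteno_world_true"]), forced_fixture["scheme"])
        assert report.count("Ct") == 2
        assert report.count("Po") == 2

    def test_single_phylum_tree_every_edge(self):
        scheme = CladeScheme({"B": "B"})
        tree = parse_newick("('B|a':1,('B|b':1,('B|c':1,'B|d':1):1):1);")
        report = count_root_choices(tree, scheme)
        assert report.count("B") == report.n_edges == 5

    def test_cost_table_per_hypothesis(self, forced_fixture):
        u = unroot(forced_fixture["cteno_world_true"])
        report = count_root_choices(u, forced_fixture["scheme"],
                                    hypotheses={
                                        "ct": forced_fixture["ctenophore_early"],
                                        "po": forced_fixture["sponge_early"]})
        best_ct = min(e["costs"]["ct"] for e in report.per_edge)
        assert best_ct == (1, 0)


class TestBestRooting:
    def test_congruent_tree_recovers_true_root(self, five_phyla):
        cfg = SimulationConfig(seed=1, include_choanoflagellate=True,
                               rate_asymmetry=(1.0, 1.0))
        h = simulate_family(cfg)
        best = best_rooting(unroot(h.tree), five_phyla["ctenophore_early"])
        assert (best.duplications, best.losses) == (0, 0)
        sides = [frozenset(l.name for l in c.leaves())
                 for c in best.tree.root.children]
        assert frozenset({"Cf1|fam0_c1"}) in sides

    def test_fixture_under_true_hypothesis(self, forced_fixture):
        best = best_rooting(unroot(forced_fixture["cteno_world_true"]),
                            forced_fixture["ctenophore_early"])
        assert (best.duplications, best.losses) == (1, 0)
        sides = [frozenset(l.name for l in c.leaves())
                 for c in best.tree.root.children]
        clade_one = frozenset({"Ct|Ct1", "Po|Po1", "Pl|Pl1", "Cn|Cn1", "B|B1"})
        assert clade_one in sides

    def test_forced_sponge_rooting_pays_in_losses(self, forced_fixture):
        best = best_rooting(unroot(forced_fixture["cteno_world_true"]), forced_fixture["sponge_early"])
        assert (best.duplications, best.losses) > (1, 0)
        assert best.duplications > 1 or best.losses >= 1

    def test_weighted_mode_available(self, forced_fixture):
        best = best_rooting(unroot(forced_fixture["cteno_world_true"]),
                            forced_fixture["ctenophore_early"], weights=(1.0, 1.0))
        assert best.duplications + best.losses == 1


class TestCostSymmetry:
    def test_phylum_relabeling_leaves_costs_unchanged(self, forced_fixture):
        swap = {"Ct": "Po", "Po": "Ct"}

        def rename(text):
            return (text.replace("Ct|Ct", "@@|@@").replace("Po|Po", "Ct|Ct")
                        .replace("@@|@@", "Po|Po"))

        gene = parse_newick(rename(forced_fixture["cteno_world_true"].newick()))
        sp = parse_newick(
            forced_fixture["ctenophore_early"].newick().replace("Ct:", "@@:")
            .replace("Po:", "Ct:").replace("@@:", "Po:"), kind="species")
        base = lca_reconcile(forced_fixture["cteno_world_true"], forced_fixture["ctenophore_early"])
        swapped = lca_reconcile(gene, sp)
        assert base.cost == swapped.cost


MLX_PATTERN = (
    "('Cf|max':1,('Ct|maxlike':1,"
    "(('Po|mlx':1,('Pl|mlx':1,('Cn|mlx':1,'B|mlx':1):1):1):1,"
    "('Po|mlxip':1,('Pl|mlxip':1,('Cn|mlxip':1,'B|mlxip':1):1):1):1):1):1);"
)
STOMATIN_PATTERN = (
    "('Cf|out':1,"
    "(('Ct|stom':1,('Po|stom':1,('Pl|stom':1,('Cn|stom':1,'B|stom':1):1):1):1):1,"
    "('Ct|stoml':1,('Po|stoml':1,('Pl|stoml':1,('Cn|stoml':1,'B|stoml':1):1):1):1):1):1);"
)
TMC_PATTERN = (
    "('Cf|out':1,('Ct|tmcZ2':1,('Po|tmc48756':1,"
    "(('Pl|t487':1,('Cn|t487':1,'B|t487':1):1):1,"
    "('Pl|t56':1,('Cn|t56':1,'B|t56':1):1):1):1):1):1);"
)
AMX_PATTERN = (
    "((('Cf|amx':1,('Po|amx':1,'B|amx':1):1):1,"
    "('Cf|cg10795':1,('Po|cg10795':1,'B|cg10795':1):1):1):1,"
    "('Cf|cg11103':1,('Po|cg11103':1,'B|cg11103':1):1):1);"
)


class TestClassifyPatterns:
    def _hypo(self, forced_fixture):
        # same five-phylum hypotheses, extended with the choanoflagellate
        sponge = parse_newick(
            "(Cf:0.1,(Po:0.1,(Ct:0.1,(Pl:0.1,(Cn:0.1,B:0.1)Planulozoa:0.1)"
            "Eumetazoa:0.1)Neuralia:0.1)Metazoa:0.1)Choanozoa;", kind="species")
        cteno = parse_newick(
            "(Cf:0.1,(Ct:0.1,(Po:0.1,(Pl:0.1,(Cn:0.1,B:0.1)Planulozoa:0.1)"
            "Eumetazoa:0.1)Benthozoa:0.1)Metazoa:0.1)Choanozoa;", kind="species")
        return {"sponge_early": sponge, "ctenophore_early": cteno}

    def _scheme(self):
        return PATTERN_SCHEME

    def test_mlx_pattern_supports_benthozoa(self, forced_fixture):
        tree = unroot(parse_newick(MLX_PATTERN))
        res = classify_family(tree, self._scheme(), self._hypo(forced_fixture))
        assert res.category == "BENTHOZOA_SUPPORT"
        # the duplication's paralog clades each span sponge + eumetazoans
        label, s1, s2 = res.supporting_nodes[0]
        assert sorted(s1) == sorted(s2) == ["B", "Cn", "Pl", "Po"]

    def test_mlx_pattern_strictness_flag(self, forced_fixture):
        # with a duplicated ctenophore sister the strict rule abstains
        text = MLX_PATTERN.replace("'Ct|maxlike':1",
                                   "('Ct|maxlike':1,'Ct|maxlike2':1):1")
        tree = unroot(parse_newick(text))
        strict = classify_family(tree, self._scheme(), self._hypo(forced_fixture))
        relaxed = classify_family(tree, self._scheme(), self._hypo(forced_fixture),
                                  strict_sister_single_copy=False)
        assert relaxed.category == "BENTHOZOA_SUPPORT"
        assert strict.category != "BENTHOZOA_SUPPORT"

    def test_stomatin_pattern_ctenophore_shared(self, forced_fixture):
        tree = unroot(parse_newick(STOMATIN_PATTERN))
        res = classify_family(tree, self._scheme(), self._hypo(forced_fixture))
        assert res.category == "CTENOPHORE_SHARED_UNINFORMATIVE"

    def test_tmc_pattern_eumetazoa_duplication(self, forced_fixture):
        tree = unroot(parse_newick(TMC_PATTERN))
        res = classify_family(tree, self._scheme(), self._hypo(forced_fixture))
        assert res.category == "EUMETAZOA_DUPLICATION"

    def test_amx_pattern_pre_choanozoan(self, forced_fixture):
        tree = unroot(parse_newick(AMX_PATTERN))
        res = classify_family(tree, self._scheme(), self._hypo(forced_fixture))
        assert res.category == "PRE_CHOANOZOAN_UNINFORMATIVE"

    def test_no_duplication_family(self, forced_fixture):
        tree = unroot(parse_newick(
            "('Cf|g':1,('Ct|g':1,('Po|g':1,('Pl|g':1,('Cn|g':1,'B|g':1):1):1):1):1);"))
        res = classify_family(tree, self._scheme(), self._hypo(forced_fixture))
        assert res.category == "NO_DUPLICATION"


class TestBruteForceRerooting:
    @staticmethod
    def _brute_reroot(tree, index):
        from conftest import brute_reroot
        return brute_reroot(tree, index)

    def test_classification_identical_across_implementations(self, five_phyla):
        scheme = five_phyla["scheme"]
        count = 0
        for seed in range(40):
            cfg = SimulationConfig(seed=600 + seed, birth_rate=0.4,
                                   death_rate=0.2,
                                   include_choanoflagellate=True,
                                   rate_asymmetry=(1.0, 1.0))
            h = simulate_family(cfg)
            if not 4 <= len(h.tree.leaf_names()) <= 12:
                continue
            u = unroot(h.tree)
            for i in range(n_rootings(u)):
                ours = _classify_rooted(reroot_on_edge(u, i), scheme, True)
                brute = _classify_rooted(self._brute_reroot(u, i), scheme, True)
                assert ours[0] == brute[0], (seed, i)
            count += 1
        assert count >= 25


class TestScenarioRecovery:
    CASES = [
        ("Metazoa", 1, "CTENOPHORE_SHARED_UNINFORMATIVE"),
        ("Benthozoa", 1, "BENTHOZOA_SUPPORT"),
        ("Eumetazoa", 1, "EUMETAZOA_DUPLICATION"),
        ("Ctenophora", {"Ct": 2}, "PHYLUM_SPECIFIC"),
    ]

    @pytest.mark.parametrize("edge,spp,expected", CASES)
    def test_noiseless_true_trees_recover_scenario(self, edge, spp, expected):
        sponge, cteno, scheme = default_species_trees(
            spp, include_choanoflagellate=True)
        hypo = {"sponge_early": sponge, "ctenophore_early": cteno}
        for seed in range(25):
            cfg = SimulationConfig(seed=700 + seed,
                                   hypothesis="ctenophore_early",
                                   species_per_phylum=spp,
                                   include_choanoflagellate=True,
                                   planted_duplications=((edge, 0.5),),
                                   rate_asymmetry=(1.0, 1.0))
            h = simulate_family(cfg)
            res = classify_family(unroot(h.tree), scheme, hypo)
            assert res.category == expected

    @pytest.mark.parametrize("edge,spp,expected", CASES)
    def test_nj_trees_recover_over_90_percent(self, edge, spp, expected):
        from paraclade.nj_infer import neighbor_joining, p_distance
        from paraclade.simulate import evolve_sequences

        sponge, cteno, scheme = default_species_trees(
            spp, include_choanoflagellate=True)
        hypo = {"sponge_early": sponge, "ctenophore_early": cteno}
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            cfg = SimulationConfig(seed=800 + seed,
                                   hypothesis="ctenophore_early",
                                   species_per_phylum=spp,
                                   include_choanoflagellate=True,
                                   planted_duplications=((edge, 0.5),),
                                   rate_asymmetry=(1.5, 1.0),
                                   sequence_length=1000)
            h = simulate_family(cfg)
            aln = evolve_sequences(h, cfg)
            tree = neighbor_joining(p_distance(aln))
            res = classify_family(tree, scheme, hypo)
            hits += res.category == expected
        assert hits / n_rep > 0.9


class TestDiagnosticColumns:
    def _aln(self):
        return None

    def test_probe_matches_a_not_b(self):
        from paraclade.core_io import Alignment

        aln = Alignment(["a1", "a2", "b1", "b2", "p"],
                        ["AA", "AA", "CC", "CC", "AC"])
        res = diagnostic_columns(aln, ["a1", "a2"], ["b1", "b2"], ["p"])
        assert res.assignments == ["A-like", "B-like"]

    def test_probe_matching_both_is_neither(self):
        from paraclade.core_io import Alignment

        aln = Alignment(["a1", "b1", "p"], ["A", "A", "A"])
        res = diagnostic_columns(aln, ["a1"], ["b1"], ["p"])
        assert res.assignments == ["neither"]

    def test_empty_clade_errors(self):
        from paraclade.core_io import Alignment

        aln = Alignment(["a1", "p"], ["A", "A"])
        with pytest.raises(ValueError):
            diagnostic_columns(aln, [], ["a1"], ["p"])

    def test_simulated_labeled_columns_recovered(self):
        from paraclade.core_io import AMINO_ACIDS, Alignment

        rng = np.random.default_rng(12)
        L, mut = 300, 0.05
        res_a = rng.choice(list(AMINO_ACIDS), size=L)
        res_b = np.array([
            rng.choice([c for c in AMINO_ACIDS if c != a]) for a in res_a
        ])
        labels = rng.random(L) < 0.5  # True -> probe inherits clade A residue

        def noisy(base):
            out = base.copy()
            hit = rng.random(L) < mut
            out[hit] = rng.choice(list(AMINO_ACIDS), size=int(hit.sum()))
            return "".join(out)

        ids = ["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4", "probe"]
        rows = [noisy(res_a) for _ in range(4)] + \
               [noisy(res_b) for _ in range(4)] + \
               ["".join(np.where(labels, res_a, res_b))]
        aln = Alignment(ids, rows)
        res = diagnostic_columns(aln, ids[:4], ids[4:8], ["probe"])
        expected = np.where(labels, "A-like", "B-like")
        agree = np.mean([a == e for a, e in zip(res.assignments, expected)])
        assert agree >= 0.9
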