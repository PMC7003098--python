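"""Synthetic gene-family generator under competing early-animal hypotheses.

Gene families evolve down a rooted species tree under a birth--death process
(duplication rate ``birth_rate``, loss rate ``death_rate``, both per gene per
unit branch length), optionally with *planted* duplications at fixed positions
on named species-tree edges. The two subtrees descending from the first
planted duplication can evolve at different substitution-rate multipliers
(``r1``/``r2``), emulating the rate asymmetry that typically follows paralog
divergence. Amino-acid sequences evolve along the realized gene tree under a
Poisson (uniform replacement) model or an empirical rate matrix, with an
optional compositional bias mixed into the branches of one named phylum.

A noiseless homology table -- the table a perfect Compara-style pipeline
would produce -- is derived from the true gene tree, so downstream screens
and miscall experiments can be run against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .core_io import (
    AMINO_ACIDS,
    Alignment,
    CladeScheme,
    GeneTree,
    HomologyTable,
    Node,
    SpeciesTree,
    species_of,
)

_PHYLUM_NAMES = {
    "B": "Bilateria",
    "Cn": "Cnidaria",
    "Pl": "Placozoa",
    "Ct": "Ctenophora",
    "Po": "Porifera",
    "Choanoflagellatea": "Choanoflagellatea",
    "Outgroup": "Outgroup-clade",
}
_PREFIX = {
    "B": "B",
    "Cn": "Cn",
    "Pl": "Pl",
    "Ct": "Ct",
    "Po": "Po",
    "Choanoflagellatea": "Cf",
    "Outgroup": "Out",
}
_METAZOA = ("Ct", "Po", "Pl", "Cn", "B")


@dataclass(frozen=True)
class CompositionBias:
    """Target residue frequencies mixed into one phylum's branches.

    The replacement distribution on a biased branch is
    ``(1 - weight) * model + weight * target``.
    """

    phylum: str
    target: tuple
    weight: float

    def __post_init__(self):
        if len(self.target) != len(AMINO_ACIDS):
            raise ValueError("target must have 20 frequencies")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated gene family.

    ``planted_duplications`` is a list of ``(edge_name, relative_position)``
    pairs, where the edge is named by the species-tree node below it and the
    position is a fraction of that edge's length. ``rate_asymmetry`` gives the
    substitution-rate multipliers for the two clades descending from the
    first planted duplication (the depicted fast/slow paralog clades; the
    defaults are this package's knobs, not measured values).
    """

    seed: int
    hypothesis: str = "ctenophore_early"
    species_per_phylum: object = 1  # int, or mapping phylum -> count
    include_choanoflagellate: bool = False
    include_outgroup: bool = False
    planted_duplications: tuple = ()
    birth_rate: float = 0.0
    death_rate: float = 0.0
    rate_asymmetry: tuple = (3.0, 1.0)
    sequence_length: int = 300
    substitution_model: object = "poisson_uniform"  # or ("empirical", path)
    composition_bias: CompositionBias | None = None
    family_id: str = "fam0"
    edge_length: float = 0.1
    max_retries: int = 100

    def __post_init__(self):
        if self.hypothesis not in ("sponge_early", "ctenophore_early"):
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("birth and death rates must be non-negative")
        r1, r2 = self.rate_asymmetry
        if r1 <= 0 or r2 <= 0:
            raise ValueError("rate multipliers must be positive")
        if self.sequence_length < 1:
            raise ValueError("sequence length must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def counts(self) -> dict:
        if isinstance(self.species_per_phylum, int):
            return {ph: self.species_per_phylum for ph in _METAZOA}
        return {ph: int(self.species_per_phylum.get(ph, 1)) for ph in _METAZOA}


@dataclass
class TrueHistory:
    """Realized history of one simulated family.

    ``tree`` is the pruned true gene tree (surviving genes only); ``full_tree``
    retains loss events for truth-based oracles. Event records are
    ``(type, species_edge_name)`` tuples.
    """

    tree: GeneTree
    full_tree: GeneTree
    events: list
    species_tree: SpeciesTree
    scheme: CladeScheme
    config: SimulationConfig

    def n_events(self, kind: str) -> int:
        return sum(1 for t, _ in self.events if t == kind)

    def phylogram(self) -> GeneTree:
        """True gene tree with branch lengths scaled by realized rates."""
        out = self.tree.copy()
        for node in out.postorder():
            if node.length is not None:
                node.length *= node.rate
        return out


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def _phylum_subtree(phylum: str, count: int, edge_length: float) -> Node:
    """Ladder of a phylum's species; the clade's MRCA carries the phylum name."""
    prefix = _PREFIX[phylum]
    leaves = [Node(f"{prefix}{i + 1}", length=edge_length) for i in range(count)]
    node = leaves[0]
    for i, leaf in enumerate(leaves[1:], start=2):
        name = _PHYLUM_NAMES[phylum] if i == count else f"{_PHYLUM_NAMES[phylum]}_{i}"
        node = Node(name, length=edge_length, children=[node, leaf])
    return node


def default_species_trees(
    species_per_phylum=1,
    include_choanoflagellate: bool = False,
    include_outgroup: bool = False,
    edge_length: float = 0.1,
):
    """The two competing rooted species hypotheses over one species set.

    Returns ``(sponge_early, ctenophore_early, scheme)``. Both trees share the
    same leaves; internal nodes are named (Metazoa, Benthozoa or Neuralia,
    Eumetazoa, Planulozoa, per-phylum clades, Choanozoa/Holozoa when the
    outgroups are included).
    """
    if isinstance(species_per_phylum, int):
        counts = {ph: species_per_phylum for ph in _METAZOA}
    else:
        counts = {ph: int(species_per_phylum.get(ph, 1)) for ph in _METAZOA}

    def build(order_first: str, inner_name: str) -> SpeciesTree:
        sub = {ph: _phylum_subtree(ph, counts[ph], edge_length) for ph in _METAZOA}
        planulozoa = Node("Planulozoa", length=edge_length,
                          children=[sub["Cn"], sub["B"]])
        eumetazoa = Node("Eumetazoa", length=edge_length,
                         children=[sub["Pl"], planulozoa])
        second = "Po" if order_first == "Ct" else "Ct"
        inner = Node(inner_name, length=edge_length,
                     children=[sub[second], eumetazoa])
        metazoa = Node("Metazoa", children=[sub[order_first], inner])
        root = metazoa
        if include_choanoflagellate:
            metazoa.length = edge_length
            cf = _phylum_subtree("Choanoflagellatea", 1, edge_length)
            root = Node("Choanozoa", children=[cf, metazoa])
        if include_outgroup:
            root.length = edge_length
            out = _phylum_subtree("Outgroup", 1, edge_length)
            root = Node("Holozoa", children=[out, root])
        return SpeciesTree(root)

    sponge_early = build("Po", "Neuralia")
    ctenophore_early = build("Ct", "Benthozoa")

    phylum_of = {}
    for ph in _METAZOA:
        for i in range(counts[ph]):
            phylum_of[f"{_PREFIX[ph]}{i + 1}"] = ph
    if include_choanoflagellate:
        phylum_of["Cf1"] = "Choanoflagellatea"
    if include_outgroup:
        phylum_of["Out1"] = "Outgroup"
    scheme = CladeScheme(phylum_of)
    return sponge_early, ctenophore_early, scheme


def species_tree_for(cfg: SimulationConfig):
    """Species tree and scheme matching a config's hypothesis."""
    sponge, cteno, scheme = default_species_trees(
        cfg.species_per_phylum,
        include_choanoflagellate=cfg.include_choanoflagellate,
        include_outgroup=cfg.include_outgroup,
        edge_length=cfg.edge_length,
    )
    return (sponge if cfg.hypothesis == "sponge_early" else cteno), scheme


# ---------------------------------------------------------------------------
# Birth-death gene family simulation
# ---------------------------------------------------------------------------

def simulate_family(cfg: SimulationConfig, species_tree: SpeciesTree = None,
                    scheme: CladeScheme = None) -> TrueHistory:
    """Evolve one gene family down the species tree.

    Planted duplications occur deterministically at their stated positions
    and double every lineage alive at that point; stochastic duplications and
    losses follow a Poisson process. A family extinct in all species (or
    surviving as a single gene) is resampled with the generator state
    advanced, up to ``max_retries``.
    """
    if species_tree is None or scheme is None:
        species_tree, scheme = species_tree_for(cfg)
    planted = {}
    for edge_name, pos in cfg.planted_duplications:
        node = species_tree.node(edge_name)  # KeyError if absent
        if node.parent is None:
            raise ValueError(f"cannot plant a duplication on the root ({edge_name!r})")
        if not 0.0 < pos < 1.0:
            raise ValueError("planted positions must lie strictly inside the edge")
        planted.setdefault(edge_name, []).append(pos * (node.length or 0.0))
    for name, positions in planted.items():
        positions.sort()
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate planted positions on edge {name!r}")

    rng = np.random.default_rng((cfg.seed, 0))
    for _ in range(cfg.max_retries):
        full, planted_nodes = _grow(cfg, species_tree, planted, rng)
        _name_leaves(full, cfg.family_id)
        _assign_rates(full, planted_nodes, cfg.rate_asymmetry)
        pruned_root = _prune(full)
        if pruned_root is not None and len(pruned_root.children) >= 1 \
                and len(pruned_root.leaves()) >= 2:
            pruned_root.length = None
            events = [
                (n.event, n.species.name if n.species is not None else "")
                for n in full.postorder()
                if n.event in ("speciation", "duplication", "loss")
            ]
            full_tree = GeneTree(full)
            return TrueHistory(GeneTree(pruned_root), full_tree, events,
                               species_tree, scheme, cfg)
    raise RuntimeError(
        f"family extinct in all retries (max_retries={cfg.max_retries}); "
        "lower death_rate or raise max_retries"
    )


def _grow(cfg, species_tree, planted, rng):
    birth, death = cfg.birth_rate, cfg.death_rate
    total = birth + death
    planted_nodes = []

    def lineage(species_node: Node, t0: float) -> Node:
        T = species_node.length or 0.0
        # marks strictly after t0: a lineage restarted at a mark's own time
        # does not re-trigger it
        marks = [p for p in planted.get(species_node.name or "", []) if p > t0]
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        t_stoch = t0 + wait
        t_mark = marks[0] if marks else math.inf
        if min(t_stoch, t_mark) < T:
            if t_mark <= t_stoch:
                node = Node(length=t_mark - t0)
                node.event, node.species = "duplication", species_node
                planted_nodes.append(node)
                node.add(lineage(species_node, t_mark))
                node.add(lineage(species_node, t_mark))
                return node
            node = Node(length=t_stoch - t0)
            node.species = species_node
            if rng.random() < birth / total:
                node.event = "duplication"
                node.add(lineage(species_node, t_stoch))
                node.add(lineage(species_node, t_stoch))
            else:
                node.event = "loss"
            return node
        if species_node.is_leaf:
            node = Node(length=T - t0)
            node.event, node.species = "leaf", species_node
            return node
        node = Node(length=T - t0)
        node.event, node.species = "speciation", species_node
        for child in species_node.children:
            node.add(lineage(child, 0.0))
        return node

    return lineage(species_tree.root, 0.0), planted_nodes


def _name_leaves(root: Node, family_id: str) -> None:
    counters = {}
    for node in root.postorder():
        if node.event == "leaf":
            sp = node.species.name
            counters[sp] = counters.get(sp, 0) + 1
            node.name = f"{sp}|{family_id}_c{counters[sp]}"


def _assign_rates(root: Node, planted_nodes, rate_asymmetry) -> None:
    """Attach r1/r2 to the two clades of the first planted duplication."""
    r1, r2 = rate_asymmetry
    for node in root.postorder():
        node.rate = 1.0
    if not planted_nodes:
        return
    focal = planted_nodes[0]
    for child, mult in zip(focal.children, (r1, r2)):
        for node in child.preorder():
            node.rate = mult


def _prune(node: Node):
    """Drop lost subtrees and suppress the resulting unary nodes."""
    if node.event == "loss":
        return None
    if node.event == "leaf":
        return node.copy()
    kept = [p for p in (_prune(c) for c in node.children) if p is not None]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.length = (child.length or 0.0) + (node.length or 0.0)
        child.parent = None
        return child
    new = Node(node.name, node.length, node.support)
    new.event, new.species, new.rate = node.event, node.species, node.rate
    for child in kept:
        new.add(child)
    return new


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def read_paml_matrix(path):
    """Read an empirical exchangeability matrix in PAML format.

    Expects 19 lower-triangle rows of exchangeabilities followed by a line of
    20 equilibrium frequencies. Returns the rate matrix ``Q`` (scaled to one
    expected substitution per unit length) and the frequency vector.
    """
    values = []
    with open(path) as fh:
        for line in fh:
            values.extend(float(tok) for tok in line.split())
    need = 19 * 20 // 2 + 20
    if len(values) < need:
        raise ValueError(
            f"malformed PAML matrix: expected at least {need} numbers, got {len(values)}"
        )
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.array(values[k:k + 20])
    if not math.isclose(pi.sum(), 1.0, rel_tol=1e-3):
        pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return Q / scale, pi


def _phylum_map(species_tree: SpeciesTree, scheme: CladeScheme) -> dict:
    """Species-tree node id -> phylum, when the node's species are one phylum."""
    out = {}
    for node in species_tree.postorder():
        phyla = {scheme.clade(leaf.name) for leaf in node.leaves()}
        out[id(node)] = next(iter(phyla)) if len(phyla) == 1 else None
    return out


def evolve_sequences(history: TrueHistory, cfg: SimulationConfig = None,
                     rng=None) -> Alignment:
    """Evolve an ungapped true alignment along the pruned gene tree.

    Branch lengths are multiplied by realized rate multipliers; expected
    substitutions per site on a branch equal ``length * rate``. Under the
    Poisson-uniform model each substitution event replaces the residue with a
    uniform draw from the 20 amino acids, so the probability a site differs
    from its ancestor after ``d`` expected events is ``(19/20)(1 - e^-d)``.
    """
    cfg = cfg or history.config
    if rng is None:
        rng = np.random.default_rng((cfg.seed, 1))
    L = cfg.sequence_length
    model = cfg.substitution_model
    if model == "poisson_uniform":
        Q, pi = None, np.full(20, 0.05)
    elif isinstance(model, tuple) and model[0] == "empirical":
        Q, pi = read_paml_matrix(model[1])
        if cfg.composition_bias is not None:
            raise ValueError("composition bias is only supported under poisson_uniform")
    else:
        raise ValueError(f"unknown substitution model {model!r}")

    bias = cfg.composition_bias
    phylum_of_node = _phylum_map(history.species_tree, history.scheme)

    def replacement_dist(node: Node) -> np.ndarray:
        if bias is None:
            return pi
        sp_node = node.species
        ph = phylum_of_node.get(id(sp_node)) if sp_node is not None else None
        if ph == bias.phylum:
            return (1 - bias.weight) * pi + bias.weight * np.asarray(bias.target)
        return pi

    tree = history.tree
    seqs = {}
    root_seq = rng.choice(20, size=L, p=pi)

    def down(node: Node, parent_seq: np.ndarray):
        d = (node.length or 0.0) * (node.rate or 1.0)
        seq = parent_seq.copy()
        if d > 0:
            hit = rng.poisson(d, size=L) > 0
            n_hit = int(hit.sum())
            if n_hit:
                if Q is None:
                    seq[hit] = rng.choice(20, size=n_hit, p=replacement_dist(node))
                else:
                    P = expm(Q * d)
                    for state in np.unique(parent_seq[hit]):
                        mask = hit & (parent_seq == state)
                        seq[mask] = rng.choice(20, size=int(mask.sum()), p=P[state])
        if node.is_leaf:
            seqs[node.name] = seq
        else:
            for child in node.children:
                down(child, seq)

    for child in tree.root.children:
        down(child, root_seq)
    if not tree.root.children:  # single-node tree (not produced in practice)
        seqs[tree.root.name] = root_seq
    ids = tree.leaf_names()
    rows = ["".join(AMINO_ACIDS[i] for i in seqs[name]) for name in ids]
    return Alignment(ids, rows)


# ---------------------------------------------------------------------------
# Truth-derived homology tables
# ---------------------------------------------------------------------------

def _leaf_lca_events(tree: GeneTree) -> dict:
    """Map unordered leaf-name pairs to their LCA node (event carrier)."""
    ancestors = {}
    for leaf in tree.leaves():
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent
        ancestors[leaf.name] = path
    out = {}
    names = list(ancestors)
    for i, a in enumerate(names):
        seen = {id(n): n for n in ancestors[a]}
        for b in names[i + 1:]:
            for node in ancestors[b]:
                if id(node) in seen:
                    out[frozenset((a, b))] = node
                    break
    return out


def table_from_events(tree: GeneTree, event_of, level_of) -> HomologyTable:
    """Build a Compara-style table from a gene tree with labeled nodes.

    ``event_of(node)`` gives ``"speciation"`` or ``"duplication"`` for each
    internal node, ``level_of(node)`` the taxon level of a duplication. A
    cross-species pair is an ortholog exactly when its LCA is a speciation;
    within-species pairs are paralogs at their LCA's duplication level.
    One-to-one/one-to-many/many-to-many come from reciprocal ortholog counts.
    Cross-species pairs descending from a duplication receive no record,
    mirroring the ortholog-centric view of Compara exports.
    """
    lca = _leaf_lca_events(tree)
    leaves = tree.leaf_names()
    sp = {name: species_of(name) for name in leaves}

    ortho_partners = {name: {} for name in leaves}  # gene -> species -> count
    for pair, node in lca.items():
        a, b = sorted(pair)
        if sp[a] != sp[b] and event_of(node) == "speciation":
            ortho_partners[a][sp[b]] = ortho_partners[a].get(sp[b], 0) + 1
            ortho_partners[b][sp[a]] = ortho_partners[b].get(sp[a], 0) + 1

    records = []
    for pair, node in sorted(lca.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        if sp[a] == sp[b]:
            records.append((a, sp[a], b, sp[b], "within_species_paralog",
                            level_of(node) or "<unknown>"))
        elif event_of(node) == "speciation":
            n_ab = ortho_partners[a].get(sp[b], 0)
            n_ba = ortho_partners[b].get(sp[a], 0)
            if n_ab == 1 and n_ba == 1:
                relation = "ortholog_one2one"
            elif n_ab == 1 or n_ba == 1:
                relation = "ortholog_one2many"
            else:
                relation = "ortholog_many2many"
            records.append((a, sp[a], b, sp[b], relation, ""))
    return HomologyTable.from_records(records)


def homology_table_from_truth(history: TrueHistory,
                              species_tree: SpeciesTree = None) -> HomologyTable:
    """Noiseless Compara-style table derived from the true gene tree."""
    return table_from_events(
        history.tree,
        event_of=lambda n: n.event,
        level_of=lambda n: n.species.name if n.species is not None else "",
    )


# ---------------------------------------------------------------------------
# Forced-rooting thought-experiment fixture
# ---------------------------------------------------------------------------

def make_forced_rooting_fixture() -> dict:
    """Deterministic fixture of the forced-rooting thought experiment.

    Returns the two true gene trees for a stem-metazoan duplication under the
    sponge-early and ctenophore-early worlds (one species per phylum; fast
    paralog clade one at rate 3, slow clade two at rate 1), the sponge-early
    re-rooting of the ctenophore-early truth, and the two resulting
    "single-copy" partitions: the slow clade missing the Ct2 gene and the
    fast clade uniting both ctenophore genes.
    """
    from .core_io import parse_newick
    from .reconcile import reroot_on_edge, unroot  # local import; no cycle

    def clade(i: int, order, rate: float) -> str:
        e = 0.1 * rate
        inner = f"('Pl|Pl{i}':{e},('Cn|Cn{i}':{e},'B|B{i}':{e}):{e}):{e}"
        first, second = order
        return (f"('{first}|{first}{i}':{e},('{second}|{second}{i}':{e},{inner}):{e})"
                f":{0.05 * rate}")

    sponge_clades = [clade(1, ("Po", "Ct"), 3.0), clade(2, ("Po", "Ct"), 1.0)]
    cteno_clades = [clade(1, ("Ct", "Po"), 3.0), clade(2, ("Ct", "Po"), 1.0)]

    sponge_world = parse_newick(f"({sponge_clades[0]},{sponge_clades[1]});", kind="gene")
    cteno_world = parse_newick(f"({cteno_clades[0]},{cteno_clades[1]});", kind="gene")

    # Sponge-early re-rooting of the ctenophore-early truth: place the root on
    # the edge that isolates (Po2,(Pl2,(Cn2,B2))), i.e. the slow clade with the
    # sponge gene basal -- exactly the edge a sponge-early prior selects.
    unrooted = unroot(cteno_world)
    target = {"Po|Po2", "Pl|Pl2", "Cn|Cn2", "B|B2"}
    forced_rerooted = None
    for rooted in (reroot_on_edge(unrooted, i)
                   for i in range(2 * len(unrooted) - 3)):
        sides = [frozenset(l.name for l in child.leaves())
                 for child in rooted.root.children]
        if frozenset(target) in sides:
            forced_rerooted = rooted
            break
    clade_two_side = next(c for c in forced_rerooted.root.children
                          if {l.name for l in c.leaves()} == target)
    other_side = next(c for c in forced_rerooted.root.children
                      if c is not clade_two_side)
    slow_clade_partition = GeneTree(clade_two_side.copy())
    slow_clade_partition.root.length = None

    # The sponge-early model applied to the remaining genes: root the
    # remainder on the Po1 pendant edge, uniting Ct1 and Ct2.
    remainder = GeneTree(other_side.copy())
    remainder.root.length = None
    un_rem = unroot(remainder)
    fast_clade_partition = None
    for i in range(2 * len(un_rem) - 3):
        rooted = reroot_on_edge(un_rem, i)
        sides = [{l.name for l in child.leaves()} for child in rooted.root.children]
        if {"Po|Po1"} in sides:
            fast_clade_partition = rooted
            break
    return {
        "sponge_world_true": sponge_world,
        "cteno_world_true": cteno_world,
        "forced_rerooted": forced_rerooted,
        "slow_clade_partition": slow_clade_partition,
        "fast_clade_partition": fast_clade_partition,
        "scheme": CladeScheme({"B": "B", "Cn": "Cn", "Pl": "Pl",
                               "Ct": "Ct", "Po": "Po"}),
        "sponge_early": parse_newick(
            "(Po:0.1,(Ct:0.1,(Pl:0.1,(Cn:0.1,B:0.1)Planulozoa:0.1)"
            "Eumetazoa:0.1)Neuralia:0.1)Metazoa;", kind="species"),
        "ctenophore_early": parse_newick(
            "(Ct:0.1,(Po:0.1,(Pl:0.1,(Cn:0.1,B:0.1)Planulozoa:0.1)"
            "Eumetazoa:0.1)Benthozoa:0.1)Metazoa;", kind="species"),
    }


def simulate_dataset(cfg: SimulationConfig, species_tree=None, scheme=None):
    """Convenience: one family's ``(history, alignment, homology table)``."""
    history = simulate_family(cfg, species_tree, scheme)
    alignment = evolve_sequences(history, cfg)
    table = homology_table_from_truth(history)
    return history, alignment, table
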