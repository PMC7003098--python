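"""Rooting enumeration, duplication/loss reconciliation, and family timing.

An unrooted binary gene tree with ``n`` leaves admits ``2n - 3`` rootings,
one per edge. Each rooted candidate is reconciled against a rooted species
hypothesis by last-common-ancestor (LCA) mapping: a gene-tree node mapping to
the same species-tree node as one of its children is a duplication, and gaps
in the mapping along an edge imply gene losses. Minimizing the
(duplications, losses) cost over rootings formalizes the "forced rooting"
that an assumed species hypothesis imposes on a gene family, which is how
apparent (possibly false-positive) gene losses arise.

On top of the reconciliation engine this module classifies a family's
duplication timing -- pre-choanozoan, ctenophore-shared, Benthozoa- or
Neuralia-supporting, Eumetazoa-defining, or phylum-specific -- from the
phylum content of each duplication node's two paralog clades, and computes
the diagnostic-residue partition used to ask whether a single outgroup-like
sequence resembles one paralog clade more than the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import (
    CladeScheme,
    FormatError,
    GeneTree,
    Node,
    SpeciesTree,
    species_of,
)

CATEGORIES = (
    "NO_DUPLICATION",
    "PRE_CHOANOZOAN_UNINFORMATIVE",
    "CTENOPHORE_SHARED_UNINFORMATIVE",
    "BENTHOZOA_SUPPORT",
    "NEURALIA_SUPPORT",
    "EUMETAZOA_DUPLICATION",
    "PHYLUM_SPECIFIC",
    "AMBIGUOUS_ROOT",
)

_OUTGROUP_LABELS = ("Outgroup", "Choanoflagellatea")

#: Family-level precedence: an informative duplication outranks coexisting
#: uninformative or phylum-specific ones (a family keeping pre-metazoan and
#: lineage-specific duplications can still carry one decisive early-metazoan
#: duplication).
_FAMILY_PRECEDENCE = (
    "BENTHOZOA_SUPPORT",
    "NEURALIA_SUPPORT",
    "EUMETAZOA_DUPLICATION",
    "PRE_CHOANOZOAN_UNINFORMATIVE",
    "CTENOPHORE_SHARED_UNINFORMATIVE",
    "PHYLUM_SPECIFIC",
)


# ---------------------------------------------------------------------------
# Unrooting and rooting enumeration
# ---------------------------------------------------------------------------

def unroot(tree: GeneTree) -> GeneTree:
    """Canonical unrooted form: the root becomes a trifurcation.

    The two root edges merge into one (lengths summed); supports on the
    merged edge are preserved.
    """
    t = tree.copy()
    root = t.root
    if len(root.children) == 3:
        return t
    if len(root.children) != 2:
        raise FormatError("unroot expects a binary tree")
    a, b = root.children
    keep = a if not a.is_leaf else b
    if keep.is_leaf:
        raise FormatError("cannot unroot a two-leaf tree")
    other = b if keep is a else a
    other.length = (a.length or 0.0) + (b.length or 0.0)
    if other.support is None:
        other.support = keep.support
    new_root = Node()
    for child in list(keep.children):
        new_root.add(child)
    new_root.add(other)
    return GeneTree(new_root)


def _edge_list(tree: GeneTree):
    """Edges as (parent, child) pairs in preorder; 2n - 3 on an unrooted tree."""
    return [(n.parent, n) for n in tree.preorder() if n.parent is not None]


def n_rootings(tree: GeneTree) -> int:
    return len(_edge_list(tree))


def reroot_on_edge(tree: GeneTree, index: int) -> GeneTree:
    """Root an unrooted tree on its ``index``-th edge (preorder order).

    The chosen edge's length is split evenly between the two root children.
    """
    t = tree.copy()
    edges = _edge_list(t)
    parent, child = edges[index]
    length = child.length or 0.0
    support = child.support

    parent.children.remove(child)
    child.parent = None

    # Reverse the path from `parent` up to the old root.
    path = [parent]
    while path[-1].parent is not None:
        path.append(path[-1].parent)
    orig = {id(n): (n.length, n.support) for n in path}
    for upper in path[1:]:
        upper.children.remove(path[path.index(upper) - 1])
    for lower, upper in zip(path[:-1], path[1:]):
        lower.add(upper)
        upper.length, upper.support = orig[id(lower)]
    top = parent
    _suppress_unary(top)

    child.length = length / 2.0
    top.length, top.support = length / 2.0, support
    root = Node(children=[child, top])
    return GeneTree(root)


def _suppress_unary(node: Node) -> None:
    """Collapse any single-child descendants created by rerooting."""
    for n in list(node.postorder()):
        if not n.is_leaf and len(n.children) == 1 and n.parent is not None:
            child = n.children[0]
            child.length = (child.length or 0.0) + (n.length or 0.0)
            if child.support is None:
                child.support = n.support
            parent = n.parent
            parent.children[parent.children.index(n)] = child
            child.parent = parent


def enumerate_rootings(tree: GeneTree):
    """All rooted trees obtained by placing the root on each edge.

    Requires the canonical unrooted form (trifurcating root); a rooted input
    raises, since its root placement would silently bias the enumeration.
    """
    if tree.is_rooted:
        raise FormatError("tree is rooted; call unroot() first")
    return [reroot_on_edge(tree, i) for i in range(n_rootings(tree))]


# ---------------------------------------------------------------------------
# LCA reconciliation
# ---------------------------------------------------------------------------

@dataclass
class ReconciliationSummary:
    """Duplication/loss counts and per-node annotation of one reconciliation."""

    duplications: int
    losses: int
    node_events: dict      # id(gene node) -> "speciation" | "duplication"
    node_map: dict         # id(gene node) -> species-tree Node
    gene_tree: GeneTree
    species_tree: SpeciesTree
    root_edge: object = None

    @property
    def cost(self):
        return (self.duplications, self.losses)

    def event_of(self, node: Node) -> str:
        return self.node_events[id(node)]

    def map_of(self, node: Node) -> Node:
        return self.node_map[id(node)]

    def loss_edges(self):
        """Species-tree branches on which a loss is implied, with multiplicity."""
        losses = []
        for node in self.gene_tree.postorder():
            if node.is_leaf:
                continue
            mv = self.map_of(node)
            for child in node.children:
                mc = self.map_of(child)
                walk = mc
                skip_first = self.event_of(node) == "speciation"
                path = []
                while walk is not mv:
                    path.append(walk)
                    walk = walk.parent
                if skip_first and path:
                    path = path[:-1]
                for missing_top in path:
                    # a loss on the sibling branch at each skipped speciation
                    for sib in missing_top.parent.children:
                        if sib is not missing_top:
                            losses.append(sib.name or "<unnamed>")
        return losses


def lca_reconcile(gene_tree: GeneTree, species_tree: SpeciesTree,
                  root_edge=None) -> ReconciliationSummary:
    """LCA-map a rooted binary gene tree onto a rooted species tree.

    Each leaf maps to its species; an internal node maps to the LCA of its
    children's images and is a duplication exactly when it maps to the same
    species-tree node as one of its children. Losses per child edge are the
    number of species-tree edges skipped by the mapping (one fewer for
    speciation nodes).
    """
    if not gene_tree.is_rooted:
        raise FormatError("gene tree must be rooted (got a trifurcating root)")
    node_map, node_events = {}, {}
    D = L = 0
    for node in gene_tree.postorder():
        if node.is_leaf:
            sp = species_of(node.name)
            if not species_tree.has_node(sp):
                raise KeyError(f"species {sp!r} (leaf {node.name!r}) missing "
                               "from the species tree")
            node_map[id(node)] = species_tree.node(sp)
            continue
        if len(node.children) != 2:
            raise FormatError("multifurcating gene trees are not supported; "
                              "resolve polytomies upstream")
        m1, m2 = (node_map[id(c)] for c in node.children)
        mv = species_tree.lca(m1, m2)
        node_map[id(node)] = mv
        is_dup = mv is m1 or mv is m2
        node_events[id(node)] = "duplication" if is_dup else "speciation"
        if is_dup:
            D += 1
        for mc in (m1, m2):
            gap = species_tree.depth(mc) - species_tree.depth(mv)
            L += gap if is_dup else max(0, gap - 1)
    return ReconciliationSummary(D, L, node_events, node_map,
                                 gene_tree, species_tree, root_edge)


# ---------------------------------------------------------------------------
# Root-choice evaluation
# ---------------------------------------------------------------------------

@dataclass
class RootChoiceReport:
    """Per-edge root-choice bookkeeping on one unrooted gene tree."""

    n_edges: int
    simple_counts: dict            # phylum -> number of simple X-early edges
    per_edge: list                 # dicts: index, side_leaves, simple_phyla, costs

    def count(self, phylum: str) -> int:
        return self.simple_counts.get(phylum, 0)


def count_root_choices(tree: GeneTree, scheme: CladeScheme,
                       hypotheses: dict = None) -> RootChoiceReport:
    """Evaluate every root edge of an unrooted gene tree.

    An edge is a *simple X-early* choice when one of its sides contains only
    genes from phylum X. When species hypotheses are supplied (name ->
    SpeciesTree), the (duplications, losses) reconciliation cost of rooting
    on each edge is reported per hypothesis — the cost-based generalization
    covering root choices that imply additional gene losses.
    """
    u = tree if not tree.is_rooted else unroot(tree)
    all_leaves = frozenset(u.leaf_names())
    per_edge = []
    simple_counts = {}
    for i, (_, child) in enumerate(_edge_list(u)):
        side = frozenset(l.name for l in child.leaves())
        other = all_leaves - side
        simple_phyla = set()
        for leaves in (side, other):
            phyla = scheme.clades_of_leaves(leaves)
            if len(phyla) == 1:
                simple_phyla.add(next(iter(phyla)))
        for ph in simple_phyla:
            simple_counts[ph] = simple_counts.get(ph, 0) + 1
        costs = {}
        if hypotheses:
            rooted = reroot_on_edge(u, i)
            for name, sp_tree in hypotheses.items():
                summary = lca_reconcile(rooted, sp_tree, root_edge=i)
                costs[name] = summary.cost
        per_edge.append({"index": i, "side_leaves": side,
                         "simple_phyla": sorted(simple_phyla), "costs": costs})
    return RootChoiceReport(len(per_edge), simple_counts, per_edge)


@dataclass
class BestRooting:
    tree: GeneTree
    edge_index: int
    duplications: int
    losses: int
    tie_indices: list


def best_rooting(tree: GeneTree, species_tree: SpeciesTree,
                 weights=None) -> BestRooting:
    """Minimum-cost rooting of an unrooted gene tree under one hypothesis.

    Cost is (duplications, losses) compared lexicographically — losses are
    never traded against duplications silently — or, when ``weights=(wd, wl)``
    is given, the weighted sum. Ties break toward the longest root edge,
    then the lexicographically smallest leaf-name set below the edge.
    """
    u = tree if not tree.is_rooted else unroot(tree)
    edges = _edge_list(u)
    scored = []
    for i, (_, child) in enumerate(edges):
        rooted = reroot_on_edge(u, i)
        summary = lca_reconcile(rooted, species_tree, root_edge=i)
        if weights is None:
            cost = summary.cost
        else:
            cost = (weights[0] * summary.duplications
                    + weights[1] * summary.losses,)
        names = tuple(sorted(l.name for l in child.leaves()))
        scored.append((cost, -(child.length or 0.0), names, i, rooted, summary))
    scored.sort(key=lambda s: s[:3])
    best = scored[0]
    ties = [s[3] for s in scored if s[0] == best[0]]
    return BestRooting(best[4], best[3], best[5].duplications,
                       best[5].losses, ties)


def min_cost_rootings(tree: GeneTree, species_tree: SpeciesTree):
    """Edge indices of every minimum-(D, L) rooting."""
    u = tree if not tree.is_rooted else unroot(tree)
    costs = []
    for i in range(n_rootings(u)):
        summary = lca_reconcile(reroot_on_edge(u, i), species_tree, root_edge=i)
        costs.append((summary.cost, i))
    best = min(c for c, _ in costs)
    return [i for c, i in costs if c == best]


# ---------------------------------------------------------------------------
# Family classification
# ---------------------------------------------------------------------------

@dataclass
class FamilyClassification:
    category: str
    rootings_used: list            # edge indices (or ["outgroup"]) evaluated
    per_rooting: dict              # edge index -> category
    supporting_nodes: list         # (label, sorted(S1), sorted(S2)) triples
    apparent_losses: list          # (clade description, missing phyla) pairs


def _phyla_of(node: Node, scheme: CladeScheme) -> frozenset:
    return frozenset(scheme.clade(species_of(l.name)) for l in node.leaves())


def _species_overlap_duplications(root: Node):
    """Duplication nodes by the species-overlap criterion (model-agnostic)."""
    species_sets = {}
    dups = []
    for node in root.postorder():
        if node.is_leaf:
            species_sets[id(node)] = frozenset({species_of(node.name)})
            continue
        sets = [species_sets[id(c)] for c in node.children]
        species_sets[id(node)] = frozenset().union(*sets)
        if len(node.children) == 2 and sets[0] & sets[1]:
            dups.append(node)
    return dups


def _single_copy(node: Node) -> bool:
    leaves = node.leaves()
    return len(leaves) == len({species_of(l.name) for l in leaves})


def _label_duplication(node: Node, scheme: CladeScheme,
                       strict_sister_single_copy: bool) -> str:
    """Timing label for one duplication node from its paralog clades.

    Support patterns (a sponge- or ctenophore-shared duplication with the
    other candidate sister lineage branching immediately outside) are tested
    before the shared-uninformative patterns, otherwise a duplication shared
    by ctenophores could never be read as Neuralia support. A duplication
    that fits no pattern can only be timed by invoking gene loss and is
    binned with the pre-choanozoan uninformative class (the equivocal
    cornichon-type situation).
    """
    eum = scheme.eumetazoa_set
    s1, s2 = (_phyla_of(c, scheme) for c in node.children)
    union, inter = s1 | s2, s1 & s2
    non_metazoan = set(_OUTGROUP_LABELS)

    if len(union) == 1:
        return "PHYLUM_SPECIFIC"
    if "Choanoflagellatea" in inter or "Outgroup" in inter:
        return "PRE_CHOANOZOAN_UNINFORMATIVE"

    def sister_is(phylum: str) -> bool:
        parent = node.parent
        if parent is None:
            return False
        sibling = next(c for c in parent.children if c is not node)
        if _phyla_of(sibling, scheme) != {phylum}:
            return False
        return _single_copy(sibling) if strict_sister_single_copy else True

    clean = not (union & non_metazoan)
    if (clean and "Po" in inter and (s1 & eum) and (s2 & eum)
            and "Ct" not in union and sister_is("Ct")):
        return "BENTHOZOA_SUPPORT"
    if (clean and "Ct" in inter and (s1 & eum) and (s2 & eum)
            and "Po" not in union and sister_is("Po")):
        return "NEURALIA_SUPPORT"
    if "Ct" in inter:
        return "CTENOPHORE_SHARED_UNINFORMATIVE"
    if union <= eum and len(s1) >= 2 and len(s2) >= 2:
        return "EUMETAZOA_DUPLICATION"
    return "PRE_CHOANOZOAN_UNINFORMATIVE"


def _classify_rooted(rooted: GeneTree, scheme: CladeScheme,
                     strict: bool):
    dups = _species_overlap_duplications(rooted.root)
    if not dups:
        return "NO_DUPLICATION", [], []
    labeled = [(n, _label_duplication(n, scheme, strict)) for n in dups]
    for category in _FAMILY_PRECEDENCE:
        winners = [(n, lab) for n, lab in labeled if lab == category]
        if winners:
            nodes = [(lab,
                      sorted(_phyla_of(n.children[0], scheme)),
                      sorted(_phyla_of(n.children[1], scheme)))
                     for n, lab in winners]
            losses = []
            for n, lab in winners:
                s1, s2 = (_phyla_of(c, scheme) for c in n.children)
                union = s1 | s2
                for k, side in enumerate((s1, s2)):
                    missing = sorted(union - side)
                    if missing:
                        losses.append((f"paralog clade {k + 1} "
                                       f"({','.join(sorted(side))})", missing))
            return category, nodes, losses
    raise AssertionError("unreachable: every duplication receives a label")


def classify_family(tree: GeneTree, scheme: CladeScheme, hypotheses,
                    strict_sister_single_copy: bool = True) -> FamilyClassification:
    """Duplication-timing category of one gene family.

    When the tree carries non-metazoan genes that form a clean unrooted
    split, that split roots the tree. Otherwise every minimum-(D, L) rooting
    under each supplied hypothesis (name -> SpeciesTree) is evaluated; if the
    admissible rootings disagree on the category the family is
    ``AMBIGUOUS_ROOT``. Duplication nodes are detected by species overlap,
    so the per-rooting category itself never assumes either hypothesis.
    """
    if isinstance(hypotheses, SpeciesTree):
        hypotheses = {"hypothesis": hypotheses}
    u = tree if not tree.is_rooted else unroot(tree)
    for leaf in u.leaves():  # fail early on unmapped species
        scheme.clade(species_of(leaf.name))

    outgroup_leaves = frozenset(
        l.name for l in u.leaves()
        if scheme.clade(species_of(l.name)) in _OUTGROUP_LABELS
    )
    admissible = []
    if outgroup_leaves:
        all_leaves = frozenset(u.leaf_names())
        for i, (_, child) in enumerate(_edge_list(u)):
            side = frozenset(l.name for l in child.leaves())
            if side == outgroup_leaves or (all_leaves - side) == outgroup_leaves:
                admissible = [i]
                break
    if not admissible:
        seen = set()
        for sp_tree in (hypotheses.values() if hypotheses else []):
            for i in min_cost_rootings(u, sp_tree):
                if i not in seen:
                    seen.add(i)
                    admissible.append(i)
    if not admissible:
        raise ValueError("no admissible rooting: supply hypotheses or outgroups")

    per_rooting, details = {}, {}
    for i in sorted(admissible):
        rooted = reroot_on_edge(u, i)
        category, nodes, losses = _classify_rooted(rooted, scheme,
                                                   strict_sister_single_copy)
        per_rooting[i] = category
        details[i] = (nodes, losses)
    categories = set(per_rooting.values())
    if len(categories) > 1:
        return FamilyClassification("AMBIGUOUS_ROOT", sorted(admissible),
                                    per_rooting, [], [])
    category = categories.pop()
    first = sorted(admissible)[0]
    nodes, losses = details[first]
    return FamilyClassification(category, sorted(admissible), per_rooting,
                                nodes, losses)


# ---------------------------------------------------------------------------
# Diagnostic residue partition
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticColumns:
    assignments: list              # per column: "A-like" | "B-like" | "neither"
    n_a_like: int
    n_b_like: int

    def a_like_columns(self):
        """1-based column positions resembling clade A."""
        return [i + 1 for i, a in enumerate(self.assignments) if a == "A-like"]

    def b_like_columns(self):
        return [i + 1 for i, a in enumerate(self.assignments) if a == "B-like"]


def _consensus(rows, col: int):
    counts = {}
    for row in rows:
        ch = row[col]
        if ch not in ("-", "X"):
            counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return None
    total = sum(counts.values())
    best = max(counts, key=lambda c: (counts[c], c))
    if counts[best] * 2 < total:
        return None
    if sum(1 for c in counts if counts[c] == counts[best]) > 1:
        return None
    return best


def diagnostic_columns(aln, cladeA_rows, cladeB_rows, probe_rows) -> DiagnosticColumns:
    """Assign each column by whether the probe matches clade A's or B's
    consensus residue (majority, at least half the counted residues) but not
    the other's. Gaps and unknowns never form or match a consensus.
    """
    for name, ids in (("cladeA", cladeA_rows), ("cladeB", cladeB_rows),
                      ("probe", probe_rows)):
        if not ids:
            raise ValueError(f"{name} row set is empty")
    if (set(cladeA_rows) & set(cladeB_rows)) or (set(cladeA_rows) & set(probe_rows)) \
            or (set(cladeB_rows) & set(probe_rows)):
        raise ValueError("clade and probe row sets must be disjoint")
    a = [aln.row(i) for i in cladeA_rows]
    b = [aln.row(i) for i in cladeB_rows]
    p = [aln.row(i) for i in probe_rows]
    assignments = []
    for col in range(aln.n_columns):
        cons_a, cons_b = _consensus(a, col), _consensus(b, col)
        probe = _consensus(p, col)
        if probe is not None and probe == cons_a and probe != cons_b:
            assignments.append("A-like")
        elif probe is not None and probe == cons_b and probe != cons_a:
            assignments.append("B-like")
        else:
            assignments.append("neither")
    return DiagnosticColumns(assignments,
                             assignments.count("A-like"),
                             assignments.count("B-like"))
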