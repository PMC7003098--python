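import numpy as np
import pytest

from paraclade.core_io import GeneTree, Node
from paraclade.simulate import default_species_trees, make_forced_rooting_fixture


def random_additive_instance(rng, n):
    """Random binary tree (as merge records) plus its exact path-length
    matrix and internal splits — an oracle independent of any tree code."""
    nodes = [(f"L{i}",) for i in range(n)]
    children, lengths = {}, {}
    for i in range(n):
        lengths[(f"L{i}",)] = rng.uniform(0.1, 2.0)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = tuple(sorted(a + b))
        children[merged] = (a, b)
        lengths[merged] = rng.uniform(0.1, 2.0)
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    root = nodes[0]

    depth = {}

    def assign(group, acc):
        if group in children:
            for child in children[group]:
                assign(child, acc + lengths[child])
        else:
            depth[group[0]] = acc

    for child in children.get(root, ()):
        assign(child, lengths[child])

    names = sorted(depth)
    idx = {nm: k for k, nm in enumerate(names)}
    d = np.zeros((n, n))
    groups_small_first = sorted(children, key=len)

    def node_depth(group, target, acc):
        if group == target:
            return acc
        for child in children.get(group, ()):
            if set(target) <= set(child):
                return node_depth(child, target, acc + lengths[child])
        return None

    for a in names:
        for b in names:
            if a >= b:
                continue
            host = next(g for g in groups_small_first if a in g and b in g)
            lca_depth = 0.0 if host == root else node_depth(root, host, 0.0)
            d[idx[a], idx[b]] = d[idx[b], idx[a]] = \
                depth[a] + depth[b] - 2 * lca_depth

    splits = set()
    all_names = frozenset(names)
    for g in children:
        s = frozenset(g)
        if 2 <= len(s) <= n - 2:
            splits.add(min(s, all_names - s, key=sorted))
    return names, d, splits


def tree_splits(tree):
    all_names = frozenset(tree.leaf_names())
    out = set()
    for node in tree.postorder():
        if node.is_leaf or node.parent is None:
            continue
        s = frozenset(l.name for l in node.leaves())
        if 2 <= len(s) <= len(all_names) - 2:
            out.add(min(s, all_names - s, key=sorted))
    return out


def brute_reroot(tree, index):
    """Independent rerooting via an adjacency map and directed recursion."""
    nodes = list(tree.preorder())
    adj = {id(n): [] for n in nodes}
    payload = {id(n): n.name for n in nodes}
    edges = []
    for n in nodes:
        if n.parent is not None:
            edges.append((n.parent, n, n.length or 0.0))
            adj[id(n.parent)].append((n, n.length or 0.0))
            adj[id(n)].append((n.parent, n.length or 0.0))

    def build(node, banned):
        new = Node(payload[id(node)])
        for c, l in adj[id(node)]:
            if id(c) == id(banned):
                continue
            child = build(c, node)
            child.length = l
            new.add(child)
        return new

    parent, child, length = edges[index]
    top_a = build(child, parent)
    top_a.length = length / 2
    top_b = build(parent, child)
    top_b.length = length / 2
    for side in (top_a, top_b):
        stack = [side]
        while stack:
            n = stack.pop()
            for k, c in enumerate(list(n.children)):
                if not c.is_leaf and len(c.children) == 1:
                    g = c.children[0]
                    g.length = (g.length or 0) + (c.length or 0)
                    n.children[k] = g
                    g.parent = n
                stack.append(n.children[k])
    return GeneTree(Node(children=[top_a, top_b]))


@pytest.fixture(scope="session")
def forced_fixture():
    return make_forced_rooting_fixture()


@pytest.fixture(scope="session")
def five_phyla():
    """One species per phylum plus a choanoflagellate outgroup."""
    sponge, cteno, scheme = default_species_trees(
        1, include_choanoflagellate=True)
    return {"sponge_early": sponge, "ctenophore_early": cteno,
            "scheme": scheme}
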