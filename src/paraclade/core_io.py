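"""Domain types and file I/O shared by every pipeline stage.

This module defines the in-memory containers used throughout the package --
phylogenetic trees (gene trees and species trees), rectangular amino-acid
alignments, Compara-style pairwise homology tables, and the clade scheme that
maps species to the major early-animal lineages -- together with readers and
writers for the standard text formats (FASTA, NEXUS, Newick, TSV) and the
elementary alignment statistics the screen relies on.

Conventions
-----------
* Gene-tree leaves embed their species as ``"Species|gene_id"``; a leaf
  without ``"|"`` is treated as a gene whose id equals its species name,
  which keeps toy trees readable.
* Internal Newick labels are taxon names on species trees and bootstrap
  supports on gene trees (the two uses are never mixed on one tree).
* Alignment columns are 0-based half-open internally; human-readable output
  reports them 1-based.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
_VALID_CHARS = set(AMINO_ACIDS) | {GAP, UNKNOWN}

#: Phylum labels for the major lineages: Bilateria, Cnidaria, Placozoa,
#: Ctenophora, Porifera, plus the choanoflagellate and more distant outgroups.
PHYLA = ("B", "Cn", "Pl", "Ct", "Po", "Choanoflagellatea", "Outgroup")
EUMETAZOA = frozenset({"B", "Cn", "Pl"})


class FormatError(ValueError):
    """Malformed input file (ragged alignment, bad Newick, invalid table)."""


class UndefinedValueError(ValueError):
    """A statistic whose denominator is empty (e.g. no shared columns)."""


# ---------------------------------------------------------------------------
# Clade scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeScheme:
    """Maps species names to early-animal phylum labels.

    ``eumetazoa_set`` names the labels counted as Eumetazoa
    (Bilateria + Cnidaria + Placozoa by default).
    """

    phylum_of: dict
    eumetazoa_set: frozenset = EUMETAZOA

    def __post_init__(self):
        bad = set(self.phylum_of.values()) - set(PHYLA)
        if bad:
            raise ValueError(f"unknown clade labels: {sorted(bad)}")

    def clade(self, species: str) -> str:
        try:
            return self.phylum_of[species]
        except KeyError:
            raise KeyError(f"species {species!r} not covered by the clade scheme") from None

    def clades_of_leaves(self, leaf_names) -> set:
        return {self.clade(species_of(name)) for name in leaf_names}

    @classmethod
    def from_tsv(cls, path) -> "CladeScheme":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["species"], df["phylum"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"species": list(self.phylum_of), "phylum": list(self.phylum_of.values())}
        ).to_csv(path, sep="\t", index=False)


def species_of(leaf_name: str) -> str:
    """Species component of a gene-tree leaf name (``"Species|gene"``)."""
    return leaf_name.split("|", 1)[0]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """A node of a (gene or species) tree.

    ``name`` is the leaf name or internal taxon label; ``support`` holds a
    bootstrap value on gene-tree internal nodes; ``length`` is the length of
    the edge above the node (``None`` on the root when absent).

    ``event`` / ``species`` / ``rate`` are annotation slots used by the
    simulator (true event type, hosting species-tree node, realized
    substitution-rate multiplier of the branch above the node).
    """

    __slots__ = ("name", "length", "support", "children", "parent",
                 "event", "species", "rate")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name = name
        self.length = length
        self.support = support
        self.children = []
        self.parent = None
        self.event = None
        self.species = None
        self.rate = 1.0
        for child in children or ():
            self.add(child)

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        dup = Node(self.name, self.length, self.support)
        dup.event, dup.species, dup.rate = self.event, self.species, self.rate
        for child in self.children:
            dup.add(child.copy())
        return dup

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, n_children={len(self.children)})"


class Tree:
    """Rooted or unrooted tree.

    A root with two children is a rooted tree; a root with three children is
    the canonical representation of an unrooted binary tree.
    """

    def __init__(self, root: Node):
        self.root = root

    # -- basic structure ---------------------------------------------------
    def postorder(self):
        return self.root.postorder()

    def preorder(self):
        return self.root.preorder()

    def leaves(self):
        return self.root.leaves()

    def leaf_names(self):
        return [leaf.name for leaf in self.leaves()]

    def __len__(self):
        return len(self.leaves())

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def is_binary(self) -> bool:
        for node in self.postorder():
            if node.is_leaf:
                continue
            limit = 3 if node is self.root and not self.is_rooted else 2
            if len(node.children) != limit:
                return False
        return True

    def copy(self):
        return type(self)(self.root.copy())

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    # -- serialization -----------------------------------------------------
    def newick(self, support_as_label: bool = True) -> str:
        return _serialize(self.root, support_as_label) + ";"

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({len(self)} leaves)"


class GeneTree(Tree):
    """Gene tree whose leaves carry ``Species|gene`` ids."""

    def leaf_species(self) -> dict:
        return {leaf.name: species_of(leaf.name) for leaf in self.leaves()}


class SpeciesTree(Tree):
    """Rooted species tree with uniquely named internal taxon levels."""

    def __init__(self, root: Node):
        super().__init__(root)
        self._index = None

    def _build_index(self):
        by_name, depth, order = {}, {}, {}
        for i, node in enumerate(self.root.preorder()):
            depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1
            order[id(node)] = i
            if node.name is not None:
                if node.name in by_name:
                    raise FormatError(f"duplicate species-tree node name {node.name!r}")
                by_name[node.name] = node
        self._index = (by_name, depth, order)

    @property
    def _maps(self):
        if self._index is None:
            self._build_index()
        return self._index

    def node(self, name: str) -> Node:
        by_name, _, _ = self._maps
        try:
            return by_name[name]
        except KeyError:
            raise KeyError(f"no species-tree node named {name!r}") from None

    def has_node(self, name: str) -> bool:
        return name in self._maps[0]

    def depth(self, node: Node) -> int:
        return self._maps[1][id(node)]

    def lca(self, a: Node, b: Node) -> Node:
        depth = self._maps[1]
        while a is not b:
            if depth[id(a)] >= depth[id(b)]:
                a = a.parent
            else:
                b = b.parent
        return a

    def lca_of_species(self, species_names) -> Node:
        nodes = [self.node(s) for s in species_names]
        out = nodes[0]
        for other in nodes[1:]:
            out = self.lca(out, other)
        return out

    def species(self) -> list:
        return self.leaf_names()


# -- Newick ----------------------------------------------------------------

_QUOTE_NEEDED = re.compile(r"[\s()\[\]{}:;,']")


def _format_label(name) -> str:
    text = str(name)
    if _QUOTE_NEEDED.search(text):
        return "'" + text.replace("'", "''") + "'"
    return text


def _format_length(length) -> str:
    return "" if length is None else f":{length:.10g}"


def _serialize(node: Node, support_as_label: bool) -> str:
    if node.is_leaf:
        return _format_label(node.name) + _format_length(node.length)
    inner = ",".join(_serialize(c, support_as_label) for c in node.children)
    if node.name is not None:
        label = _format_label(node.name)
    elif support_as_label and node.support is not None:
        label = f"{node.support:.10g}"
    else:
        label = ""
    return f"({inner}){label}" + _format_length(node.length)


def _from_dendropy(dnode, kind: str) -> Node:
    if dnode.is_leaf():
        name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return Node(name=name, length=dnode.edge.length)
    node = Node(length=dnode.edge.length)
    label = dnode.label
    if label is not None:
        if kind == "species":
            node.name = label
        else:
            try:
                node.support = float(label)
            except ValueError:
                node.name = label
    for child in dnode.child_nodes():
        node.add(_from_dendropy(child, kind))
    return node


def parse_newick(text: str, kind: str = "gene"):
    """Parse one Newick tree from a string.

    ``kind`` selects how internal labels are read: taxon names for
    ``"species"`` trees, bootstrap supports for ``"gene"`` trees.
    """
    if kind not in ("gene", "species"):
        raise ValueError("kind must be 'gene' or 'species'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise FormatError(f"Newick parse error: {exc}") from None
    root = _from_dendropy(dtree.seed_node, kind)
    cls = SpeciesTree if kind == "species" else GeneTree
    tree = cls(root)
    names = tree.leaf_names()
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf names in Newick input: {sorted(dupes)}")
    return tree


def read_newick(path, kind: str = "gene"):
    return parse_newick(Path(path).read_text(), kind=kind)


def write_newick(tree: Tree, path=None) -> str:
    text = tree.newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Rectangular amino-acid alignment over the 20-letter alphabet plus
    gap ``-`` and unknown ``X``."""

    ids: list
    rows: list

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate sequence ids in alignment")
        if self.rows:
            width = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != width:
                    raise FormatError(
                        f"ragged alignment: row {sid!r} has length {len(row)}, "
                        f"expected {width}"
                    )
                bad = set(row.upper()) - _VALID_CHARS
                if bad:
                    raise FormatError(
                        f"row {sid!r} contains invalid residue symbols: {sorted(bad)}"
                    )
        self.rows = [row.upper() for row in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)]

    def subset(self, ids) -> "Alignment":
        return Alignment(list(ids), [self.row(i) for i in ids])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a FASTA or NEXUS alignment into a rectangular :class:`Alignment`.

    The NEXUS reader accepts both interleaved and sequential matrices.
    Ragged input raises :class:`FormatError` naming the offending row.
    """
    path = Path(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise FormatError(f"no sequences found in {path}")
        return Alignment([r.id for r in records], [str(r.seq) for r in records])
    if format == "nexus":
        try:
            msa = AlignIO.read(str(path), "nexus")
        except Exception as exc:
            detail = _nexus_length_report(path.read_text())
            raise FormatError(f"NEXUS parse error in {path}: {exc}{detail}") from None
        return Alignment([r.id for r in msa], [str(r.seq) for r in msa])
    raise ValueError(f"unsupported alignment format {format!r}")


def _nexus_length_report(text: str) -> str:
    """Best-effort per-row length diagnostic for a broken NEXUS matrix."""
    m = re.search(r"matrix(.*?);", text, flags=re.IGNORECASE | re.DOTALL)
    if not m:
        return ""
    lengths = {}
    for line in m.group(1).splitlines():
        parts = line.split()
        if len(parts) >= 2:
            lengths[parts[0]] = lengths.get(parts[0], 0) + len("".join(parts[1:]))
    if len(set(lengths.values())) > 1:
        rows = ", ".join(f"{k}={v}" for k, v in sorted(lengths.items()))
        return f" (row lengths: {rows})"
    return ""


def alignment_columns(aln: Alignment) -> int:
    """Number of columns (the length of every row)."""
    return aln.n_columns


def gap_normalized_identity(row_a: str, row_b: str, denominator: str = "shared") -> float:
    """Gap-normalized percent identity between two aligned rows.

    ``100 * identical / comparable`` where, under the default ``"shared"``
    denominator, comparable columns are those where neither row has a gap.
    Columns where either residue is unknown (``X``) never count as matches
    or mismatches. ``denominator="all"`` divides by the full column count
    instead (the alternative reading of "gap-normalized").
    """
    if len(row_a) != len(row_b):
        raise FormatError("rows differ in length")
    row_a, row_b = row_a.upper(), row_b.upper()
    identical = comparable = 0
    for a, b in zip(row_a, row_b):
        if a == UNKNOWN or b == UNKNOWN:
            continue
        if a == GAP or b == GAP:
            continue
        comparable += 1
        if a == b:
            identical += 1
    if denominator == "all":
        comparable = sum(
            1 for a, b in zip(row_a, row_b) if a != UNKNOWN and b != UNKNOWN
        )
    if comparable == 0:
        raise UndefinedValueError("no comparable (shared non-gap) columns")
    return 100.0 * identical / comparable


def aa_composition(rows) -> np.ndarray:
    """Residue frequencies over ``AMINO_ACIDS`` pooled across rows.

    Gaps and unknowns are excluded; the result sums to 1.
    """
    counts = np.zeros(len(AMINO_ACIDS))
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for row in rows:
        for ch in row.upper():
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise UndefinedValueError("no residues observed (all-gap input)")
    return counts / total


def aa_counts(rows) -> np.ndarray:
    """Raw residue counts over ``AMINO_ACIDS`` pooled across rows."""
    counts = np.zeros(len(AMINO_ACIDS), dtype=int)
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for row in rows:
        for ch in row.upper():
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# Homology tables
# ---------------------------------------------------------------------------

RELATIONS = (
    "ortholog_one2one",
    "ortholog_one2many",
    "ortholog_many2many",
    "within_species_paralog",
)

_HOMOLOGY_COLUMNS = [
    "gene_a",
    "species_a",
    "gene_b",
    "species_b",
    "relation",
    "duplication_level",
]


class HomologyTable:
    """Pairwise homology records emulating Compara/BioMart output.

    Each record relates two genes with a relation from :data:`RELATIONS`;
    ``duplication_level`` names the species-tree level of the duplication and
    is non-empty exactly for ``within_species_paralog`` records. Records are
    stored once per unordered pair; :meth:`directed` doubles them for
    per-gene queries.
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(_HOMOLOGY_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"homology table missing columns: {sorted(missing)}")
        df = df[_HOMOLOGY_COLUMNS].copy()
        df["duplication_level"] = df["duplication_level"].fillna("")
        bad = set(df["relation"]) - set(RELATIONS)
        if bad:
            raise FormatError(f"unknown homology relations: {sorted(bad)}")
        paralog = df["relation"] == "within_species_paralog"
        if (df.loc[paralog, "duplication_level"] == "").any():
            raise FormatError("within_species_paralog records need a duplication_level")
        if (df.loc[~paralog, "duplication_level"] != "").any():
            raise FormatError("only within_species_paralog records carry a duplication_level")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "HomologyTable":
        return cls(pd.DataFrame(list(records), columns=_HOMOLOGY_COLUMNS))

    @classmethod
    def read_tsv(cls, path) -> "HomologyTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def __len__(self):
        return len(self.df)

    def species(self) -> set:
        return set(self.df["species_a"]) | set(self.df["species_b"])

    def genes(self) -> set:
        return set(self.df["gene_a"]) | set(self.df["gene_b"])

    def directed(self) -> pd.DataFrame:
        """Both orientations of every record (symmetric closure)."""
        fwd = self.df
        rev = fwd.rename(
            columns={
                "gene_a": "gene_b",
                "gene_b": "gene_a",
                "species_a": "species_b",
                "species_b": "species_a",
            }
        )[_HOMOLOGY_COLUMNS]
        return pd.concat([fwd, rev], ignore_index=True)

    def ortholog_pairs(self) -> pd.DataFrame:
        return self.df[self.df["relation"] != "within_species_paralog"]

    def paralog_pairs(self) -> pd.DataFrame:
        return self.df[self.df["relation"] == "within_species_paralog"]

    def genes_of(self, species: str) -> set:
        d = self.directed()
        return set(d.loc[d["species_a"] == species, "gene_a"])

    def ortholog_partners(self, gene: str) -> pd.DataFrame:
        d = self.directed()
        return d[(d["gene_a"] == gene) & (d["relation"] != "within_species_paralog")]

    def has_ortholog_in(self, gene: str, species: str) -> bool:
        partners = self.ortholog_partners(gene)
        return bool((partners["species_b"] == species).any())
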