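"""Model-agnostic paralogy screen over Compara-style homology tables.

The cascade mirrors a genome-scale candidate hunt for early-animal gene
duplications: start from a focal species' genes, keep those in within-species
paralogous relationships, require orthologs in a panel of taxa spanning the
bilaterian/placozoan backbone, discard paralogy relationships that arose at
recent taxonomic levels, group the survivors into paralogy groups (connected
components of the remaining paralogy edges), keep the small groups (two to
three genes), and sample a deterministic fraction for tree building.
Crucially, the candidate sponge-like and ctenophore-like species are *never*
used as filters — their presence or absence is only annotated afterwards, so
the screen does not presuppose either branching hypothesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core_io import HomologyTable


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of one screen cascade.

    ``excluded_duplication_levels`` lists taxon levels whose within-species
    paralogy edges are severed (recent duplications irrelevant to early
    branching). ``annotate_species`` are flagged, never filtered on.
    """

    focal_species: str
    required_ortholog_taxa: tuple = ()
    excluded_duplication_levels: tuple = ()
    keep_size_range: tuple = (2, 3)
    sample_fraction: float = 1.0
    seed: int = 0
    annotate_species: tuple = ()
    discard_mode: str = "sever"        # "sever" edges or "drop" genes
    ortholog_requirement: str = "per_gene"  # or "per_group"

    def __post_init__(self):
        lo, hi = self.keep_size_range
        if lo < 2:
            raise ValueError("keep_size_range minimum must be >= 2")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must be in (0, 1]")
        overlap = set(self.annotate_species) & set(self.required_ortholog_taxa)
        if overlap:
            raise ValueError(
                f"annotate_species may never act as filters: {sorted(overlap)}"
            )


@dataclass
class ScreenReport:
    """Cascade bookkeeping: per-stage gene counts and the retained groups."""

    stage_counts: dict                 # stage name -> number of genes
    groups: list                       # kept groups (sorted gene tuples)
    set_aside: list                    # (group, size) for groups outside range
    sampled: list                      # sampled subset of `groups`
    annotations: dict                  # group -> {species: bool}
    config: ScreenConfig = None

    def apparent_loss_candidates(self):
        """Sampled groups lacking at least one annotated species."""
        return [g for g in self.sampled
                if not all(self.annotations[g].values())]


def _paralogy_edges(table: HomologyTable, focal_species: str,
                    excluded_levels=()):
    df = table.paralog_pairs()
    df = df[df["species_a"] == focal_species]
    df = df[df["species_b"] == focal_species]
    if excluded_levels:
        df = df[~df["duplication_level"].isin(set(excluded_levels))]
    return list(zip(df["gene_a"], df["gene_b"]))


def _components(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return [tuple(sorted(c)) for c in nx.connected_components(g) if len(c) >= 2]


def paralogy_groups(table: HomologyTable, focal_species: str,
                    excluded_levels=(), discard_mode: str = "sever"):
    """Paralogy groups of the focal species after level filtering.

    ``sever`` (default) removes only the paralogy edges at excluded levels
    and regroups; ``drop`` removes every gene participating in an
    excluded-level relationship outright. Groups are connected components of
    the surviving edges; singletons are discarded.
    """
    edges = _paralogy_edges(table, focal_species, excluded_levels)
    if discard_mode == "drop":
        banned = set()
        for a, b in _paralogy_edges(table, focal_species):
            if (a, b) not in set(edges) and (b, a) not in set(edges):
                banned.update((a, b))
        edges = [(a, b) for a, b in edges if a not in banned and b not in banned]
    elif discard_mode != "sever":
        raise ValueError(f"unknown discard_mode {discard_mode!r}")
    return sorted(_components(edges))


def require_orthologs(groups, table: HomologyTable, required_taxa,
                      paralogy_edges=None, mode: str = "per_gene"):
    """Keep genes with at least one ortholog call in *every* required taxon.

    ``per_gene`` (default) filters genes then rebuilds groups from the
    surviving paralogy edges; ``per_group`` keeps a whole group when each
    required taxon is hit by at least one of its members.
    """
    required = list(required_taxa)
    if not required:
        return list(groups)
    universe = table.species()
    missing = set(required) - universe
    if missing:
        raise ValueError(f"required taxa absent from the table: {sorted(missing)}")

    directed = table.directed()
    ortho = directed[directed["relation"] != "within_species_paralog"]
    hits = {
        taxon: set(ortho.loc[ortho["species_b"] == taxon, "gene_a"])
        for taxon in required
    }

    def gene_ok(gene):
        return all(gene in hits[t] for t in required)

    if mode == "per_group":
        return sorted(
            g for g in groups
            if all(any(gene in hits[t] for gene in g) for t in required)
        )
    if mode != "per_gene":
        raise ValueError(f"unknown mode {mode!r}")
    surviving = {gene for g in groups for gene in g if gene_ok(gene)}
    if paralogy_edges is None:
        # fall back to every within-species paralogy edge in the table
        df = table.paralog_pairs()
        paralogy_edges = list(zip(df["gene_a"], df["gene_b"]))
    edges = [(a, b) for a, b in paralogy_edges
             if a in surviving and b in surviving]
    return sorted(_components(edges))


def bin_by_size(groups, keep_range=(2, 3)):
    """Split groups into (kept, set_aside) by member count."""
    lo, hi = keep_range
    kept = sorted(g for g in groups if lo <= len(g) <= hi)
    set_aside = sorted((g, len(g)) for g in groups if not lo <= len(g) <= hi)
    return kept, set_aside


def sample_groups(kept, fraction: float, seed: int):
    """Seeded sample of ``floor(fraction * count)`` groups, no replacement."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    kept = sorted(kept)
    k = math.floor(fraction * len(kept))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(kept))
    return sorted(kept[i] for i in order[:k])


def annotate_presence(sample, table: HomologyTable, annotate_species):
    """Flag, per sampled group, which annotate species have >= 1 ortholog call.

    Flags only — groups are never filtered here. A group lacking a flagged
    species is an apparent-loss candidate (true loss or a false-positive
    loss from paralog miscalling).
    """
    directed = table.directed()
    ortho = directed[directed["relation"] != "within_species_paralog"]
    out = {}
    for group in sample:
        members = set(group)
        flags = {}
        for sp in annotate_species:
            called = set(ortho.loc[ortho["species_b"] == sp, "gene_a"])
            flags[sp] = bool(members & called)
        out[group] = flags
    return out


def run_screen(table: HomologyTable, config: ScreenConfig) -> ScreenReport:
    """Execute the full cascade and record per-stage gene counts."""
    focal_genes = table.genes_of(config.focal_species)
    counts = {"focal_genes": len(focal_genes)}

    all_edges = _paralogy_edges(table, config.focal_species)
    in_paralogy = {g for e in all_edges for g in e}
    counts["in_paralogy"] = len(in_paralogy)

    groups0 = _components(all_edges)
    groups1 = require_orthologs(groups0, table, config.required_ortholog_taxa,
                                paralogy_edges=all_edges,
                                mode=config.ortholog_requirement)
    counts["with_required_orthologs"] = sum(len(g) for g in groups1)

    surviving = {g for grp in groups1 for g in grp}
    filtered_edges = [
        (a, b)
        for a, b in _paralogy_edges(table, config.focal_species,
                                    config.excluded_duplication_levels)
        if a in surviving and b in surviving
    ]
    if config.discard_mode == "drop":
        df = table.paralog_pairs()
        df = df[(df["species_a"] == config.focal_species)
                & (df["duplication_level"]
                   .isin(set(config.excluded_duplication_levels)))]
        banned = set(df["gene_a"]) | set(df["gene_b"])
        filtered_edges = [e for e in filtered_edges
                          if e[0] not in banned and e[1] not in banned]
    groups2 = sorted(_components(filtered_edges))
    counts["after_level_filter"] = sum(len(g) for g in groups2)

    kept, set_aside = bin_by_size(groups2, config.keep_size_range)
    counts["small_groups_genes"] = sum(len(g) for g in kept)
    sampled = sample_groups(kept, config.sample_fraction, config.seed)
    counts["sampled_genes"] = sum(len(g) for g in sampled)

    annotations = annotate_presence(sampled, table, config.annotate_species)
    return ScreenReport(counts, kept, set_aside, sampled, annotations, config)


def trichoplax_anchor_config() -> ScreenConfig:
    """The placozoan-anchored variant of the screen.

    Anchors on Trichoplax adhaerens genes that group into paralogy groups and
    have homologs in a cnidarian (Nematostella vectensis), a lophotrochozoan
    (Lottia gigantea), an ecdysozoan (Drosophila melanogaster), and a sponge
    (Amphimedon queenslandica). Note the sponge is a *required* taxon in this
    variant, unlike the model-agnostic default; the ctenophore is still only
    annotated.
    """
    return ScreenConfig(
        focal_species="Trichoplax_adhaerens",
        required_ortholog_taxa=(
            "Nematostella_vectensis",
            "Lottia_gigantea",
            "Drosophila_melanogaster",
            "Amphimedon_queenslandica",
        ),
        excluded_duplication_levels=(),
        keep_size_range=(2, 3),
        sample_fraction=1.0,
        seed=0,
        annotate_species=("Mnemiopsis_leidyi",),
    )
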