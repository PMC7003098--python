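"""The ortholog-miscall experiment: forcing trees into an assumed hypothesis.

If gene trees that truly evolved under a ctenophore-early world are rooted
under a sponge-early prior, ancient paralogs get partitioned into the wrong
"single-copy" clades. The slowly evolving paralog clade then shows a
false-positive gene loss for the ctenophore, while the fast clade unites
both ctenophore paralogs and manifests false-positive rate and amino-acid
composition heterogeneity. This module operationalizes that argument:
tree-based ortholog calling from a (possibly mis-rooted) reconciliation,
per-lineage ortholog-coverage percentages and the ctenophore coverage
deficit, per-phylum false-loss rates against the simulator's truth, and the
rate/composition heterogeneity statistics of the two paralog clades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .core_io import (
    Alignment,
    GeneTree,
    HomologyTable,
    SpeciesTree,
    aa_counts,
    species_of,
)
from .nj_infer import neighbor_joining, p_distance
from .reconcile import best_rooting, lca_reconcile, unroot
from .simulate import (
    SimulationConfig,
    default_species_trees,
    evolve_sequences,
    homology_table_from_truth,
    simulate_family,
    table_from_events,
)

logger = logging.getLogger(__name__)


def call_orthologs(gene_tree: GeneTree, species_tree: SpeciesTree) -> HomologyTable:
    """Tree-based ortholog calling from a rooted gene tree.

    Internal nodes are labeled speciation/duplication by LCA reconciliation
    against the species hypothesis; a cross-species pair is called an
    ortholog exactly when its LCA is a speciation node. This emulates a
    Compara-style pipeline run on an inferred — and possibly mis-rooted —
    gene tree.
    """
    summary = lca_reconcile(gene_tree, species_tree)
    return table_from_events(
        gene_tree,
        event_of=summary.event_of,
        level_of=lambda n: summary.map_of(n).name or "<unnamed>",
    )


def ortholog_coverage(tables, focal_species: str, reference_species: str,
                      universe=None) -> float:
    """Percentage of the focal species' genes with >= 1 ortholog call in the
    reference species, pooled over family tables.

    ``universe`` optionally supplies the full focal gene set (a gene absent
    from every table — e.g. one that received no calls at all — still counts
    in the denominator when listed there).
    """
    tables = list(tables)
    if universe is None:
        universe = set()
        for t in tables:
            universe |= t.genes_of(focal_species)
    universe = set(universe)
    if not universe:
        raise ValueError(f"focal species {focal_species!r} has no genes")
    covered = set()
    for t in tables:
        d = t.directed()
        hit = d[(d["species_a"] == focal_species)
                & (d["species_b"] == reference_species)
                & (d["relation"] != "within_species_paralog")]
        covered |= set(hit["gene_a"])
    return 100.0 * len(covered & universe) / len(universe)


def rate_heterogeneity(gene_tree: GeneTree, clade_partition) -> float:
    """Mean root-to-tip path length of clade 1 over clade 2.

    ``clade_partition`` is a pair of leaf-name collections; paths are summed
    from the root of the given (rooted) tree.
    """
    depths = {}

    def walk(node, acc):
        here = acc + (node.length or 0.0)
        if node.is_leaf:
            depths[node.name] = here
        for child in node.children:
            walk(child, here)

    walk(gene_tree.root, -(gene_tree.root.length or 0.0))
    means = []
    for names in clade_partition:
        names = list(names)
        if not names:
            raise ValueError("empty clade in partition")
        means.append(sum(depths[n] for n in names) / len(names))
    if means[1] == 0:
        raise ZeroDivisionError("clade 2 has zero mean root-to-tip length")
    return means[0] / means[1]


def composition_heterogeneity(aln: Alignment, group_rows, rest_rows):
    """Pearson chi-square of pooled residue counts, group vs rest.

    Only residues with a nonzero pooled count enter the table;
    ``df = residues - 1``. Returns ``(statistic, df)``.
    """
    if not group_rows or not rest_rows:
        raise ValueError("both row groups must be nonempty")
    g = aa_counts([aln.row(i) for i in group_rows])
    r = aa_counts([aln.row(i) for i in rest_rows])
    keep = (g + r) > 0
    if keep.sum() < 2:
        raise ValueError("degenerate composition: fewer than two residues observed")
    table = np.vstack([g[keep], r[keep]])
    stat, _, df, _ = chi2_contingency(table, correction=False)
    return float(stat), int(df)


# ---------------------------------------------------------------------------
# The forced-rooting experiment
# ---------------------------------------------------------------------------

@dataclass
class MiscallExperimentResult:
    """Aggregate outcome of one forced-rooting simulation experiment."""

    coverage: dict          # reference species -> {focal species -> pct}
    deficit_gap: dict       # reference species -> min(others) - focal pct
    false_loss_rate: dict   # phylum -> fraction of families
    rate_ratio_mean: float  # mean fast/slow root-clade path-length ratio
    composition_chi2_mean: float
    focal_min_fraction: dict  # reference -> fraction of families where the
                              # focal phylum's coverage is the minimum
    n_families: int
    n_failed: int
    seed: int
    focal_phylum: str
    per_family: pd.DataFrame = None

    def coverage_rank_ok(self, reference: str) -> bool:
        """True when the focal phylum's pooled coverage is the minimum."""
        cov = self.coverage[reference]
        focal = [v for s, v in cov.items() if s.startswith("Ct")]
        others = [v for s, v in cov.items() if not s.startswith("Ct")]
        return bool(focal) and min(focal) <= min(others)


def _true_ortholog_sets(truth: HomologyTable) -> dict:
    out = {}
    d = truth.directed()
    ortho = d[d["relation"] != "within_species_paralog"]
    for gene, partner in zip(ortho["gene_a"], ortho["gene_b"]):
        out.setdefault(gene, set()).add(partner)
    return out


def false_losses(true_tree: GeneTree, truth: HomologyTable,
                 called: HomologyTable, scheme) -> set:
    """Phyla with a gene cut off from a paralog group it truly belongs to.

    For every duplication in the true tree, each child clade is one true
    paralog group. A gene is falsely lost from its group when the called
    table links it to none of its true orthologs *within that group* — the
    situation where a mis-rooted paralog is flipped out of its clade. An
    outgroup gene that is truly ortholog to both paralog clades can
    therefore never mask the loss.
    """
    true_sets = _true_ortholog_sets(truth)
    called_sets = _true_ortholog_sets(called)
    flagged = set()
    for node in true_tree.postorder():
        if node.event != "duplication":
            continue
        for child in node.children:
            clade = {l.name for l in child.leaves()}
            for gene in clade:
                partners = true_sets.get(gene, set()) & clade
                if partners and not (called_sets.get(gene, set()) & partners):
                    flagged.add(scheme.clade(species_of(gene)))
    return flagged


def run_experiment(cfg: SimulationConfig, assumed_hypothesis: str,
                   n_families: int, seed: int, use_nj: bool = True,
                   reference_species=None, keep_per_family: bool = True
                   ) -> MiscallExperimentResult:
    """Simulate families under the TRUE hypothesis, force them into the
    ASSUMED hypothesis, and measure the resulting miscall artifacts.

    Per family: simulate the true history, optionally evolve sequences and
    infer an NJ tree (otherwise the true phylogram is used), take the
    minimum-(D, L) rooting under the assumed hypothesis, call orthologs from
    that reconciliation, and compare with the truth-derived table. Families
    whose inference degenerates (fewer than three surviving genes) are
    logged, skipped, and counted in ``n_failed``.
    """
    sponge, cteno, scheme = default_species_trees(
        cfg.species_per_phylum,
        include_choanoflagellate=cfg.include_choanoflagellate,
        include_outgroup=cfg.include_outgroup,
        edge_length=cfg.edge_length,
    )
    trees = {"sponge_early": sponge, "ctenophore_early": cteno}
    true_sp = trees[cfg.hypothesis]
    assumed_sp = trees[assumed_hypothesis]
    if reference_species is None:
        reference_species = ("Cn1", "Po1")
    metazoan_species = [s for s, ph in scheme.phylum_of.items()
                        if ph in ("B", "Cn", "Pl", "Ct", "Po")]

    rng = np.random.default_rng(seed)
    fam_seeds = rng.integers(0, 2**31 - 1, size=n_families)

    called_tables, universes = [], {s: set() for s in metazoan_species}
    false_loss_families = {ph: 0 for ph in ("B", "Cn", "Pl", "Ct", "Po")}
    rate_ratios, chi2s, rows, focal_min_counts = [], [], [], []
    n_failed = 0

    for i in range(n_families):
        fam_cfg = replace(cfg, seed=int(fam_seeds[i]), family_id=f"fam{i:04d}")
        history = simulate_family(fam_cfg, true_sp, scheme)
        truth = homology_table_from_truth(history)
        for leaf in history.tree.leaf_names():
            sp = species_of(leaf)
            if sp in universes:
                universes[sp].add(leaf)
        try:
            if use_nj:
                aln = evolve_sequences(history, fam_cfg)
                tree = neighbor_joining(p_distance(aln))
            else:
                tree = unroot(history.phylogram())
            best = best_rooting(tree, assumed_sp)
        except Exception as exc:  # degenerate family: log, skip, count
            logger.warning("family %s skipped: %s", fam_cfg.family_id, exc)
            n_failed += 1
            continue
        called = call_orthologs(best.tree, assumed_sp)
        called_tables.append(called)

        flagged = false_losses(history.tree, truth, called, scheme)
        for ph in flagged:
            if ph in false_loss_families:
                false_loss_families[ph] += 1

        # Per-family coverage rank: is the focal (ctenophore) fraction of
        # genes with an ortholog call in the reference the minimum?
        fam_genes = {}
        for leaf in history.tree.leaf_names():
            sp = species_of(leaf)
            if sp in universes:
                fam_genes.setdefault(sp, set()).add(leaf)
        d = called.directed()
        ortho = d[d["relation"] != "within_species_paralog"]
        fam_min = {}
        for ref in reference_species:
            hit = set(ortho.loc[ortho["species_b"] == ref, "gene_a"])
            fracs = {sp: len(genes & hit) / len(genes)
                     for sp, genes in fam_genes.items() if sp != ref and genes}
            ct = [v for sp, v in fracs.items() if scheme.clade(sp) == "Ct"]
            rest = [v for sp, v in fracs.items() if scheme.clade(sp) != "Ct"]
            if ct and rest:
                fam_min[ref] = min(ct) <= min(rest)
        focal_min_counts.append(fam_min)

        clades = [[l.name for l in c.leaves()] for c in best.tree.root.children]
        ratio = chi2 = float("nan")
        if all(clades):
            try:
                r = rate_heterogeneity(best.tree, clades)
                ratio = max(r, 1.0 / r) if r > 0 else float("nan")
            except ZeroDivisionError:
                pass
            if use_nj:
                try:
                    chi2, _ = composition_heterogeneity(aln, clades[0], clades[1])
                except ValueError:
                    pass
        if not np.isnan(ratio):
            rate_ratios.append(ratio)
        if not np.isnan(chi2):
            chi2s.append(chi2)
        if keep_per_family:
            rows.append({
                "family": fam_cfg.family_id,
                "n_genes": len(history.tree.leaf_names()),
                "duplications": best.duplications,
                "losses": best.losses,
                "false_loss_phyla": ",".join(sorted(flagged)),
                "rate_ratio": ratio,
                "composition_chi2": chi2,
                **{f"focal_min_vs_{ref}": fam_min.get(ref)
                   for ref in reference_species},
            })

    n_used = n_families - n_failed
    coverage, deficit = {}, {}
    for ref in reference_species:
        cov = {}
        for sp in metazoan_species:
            if sp == ref or not universes[sp]:
                continue
            cov[sp] = ortholog_coverage(called_tables, sp, ref,
                                        universe=universes[sp])
        coverage[ref] = cov
        focal_vals = [v for s, v in cov.items() if scheme.clade(s) == "Ct"]
        other_vals = [v for s, v in cov.items() if scheme.clade(s) != "Ct"]
        if focal_vals and other_vals:
            deficit[ref] = min(other_vals) - min(focal_vals)

    focal_min_fraction = {}
    for ref in reference_species:
        flags = [fm[ref] for fm in focal_min_counts if ref in fm]
        if flags:
            focal_min_fraction[ref] = sum(flags) / len(flags)

    return MiscallExperimentResult(
        coverage=coverage,
        deficit_gap=deficit,
        false_loss_rate={ph: (c / n_used if n_used else float("nan"))
                         for ph, c in false_loss_families.items()},
        rate_ratio_mean=float(np.mean(rate_ratios)) if rate_ratios else float("nan"),
        composition_chi2_mean=float(np.mean(chi2s)) if chi2s else float("nan"),
        focal_min_fraction=focal_min_fraction,
        n_families=n_used,
        n_failed=n_failed,
        seed=seed,
        focal_phylum="Ct",
        per_family=pd.DataFrame(rows) if keep_per_family else None,
    )
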