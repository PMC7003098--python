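# Methods

## The model and its assumptions

`paraclade` treats early-animal branching as a gene-duplication inference
problem. A rooted species hypothesis is a binary tree over representatives
of Bilateria (B), Cnidaria (Cn), Placozoa (Pl), Ctenophora (Ct) and
Porifera (Po), optionally with a choanoflagellate and a more distant
outgroup; the two competing hypotheses differ only in whether Ct or Po is
sister to the rest of Metazoa (the Po + Eumetazoa clade of the
ctenophore-early tree is called Benthozoa, the Ct + Eumetazoa clade of the
sponge-early tree Neuralia; Eumetazoa is Pl + Cn + B throughout).

Gene families evolve down the species tree under a linear birth–death
process: each gene lineage independently duplicates at rate λ and dies at
rate μ per unit branch length, every speciation splits every live lineage,
and a loss prunes the lineage at the event point. *Planted* duplications are
deterministic events at a fixed relative position on a named species-tree
edge; they double every lineage alive at that instant. This is the device
used to construct controlled scenarios (a stem-metazoan, stem-benthozoan,
stem-eumetazoan, or within-ctenophore duplication) whose correct
duplication-timing category is known by construction.

Amino-acid sequences evolve by a Poisson process: substitution events
arrive at `length × rate-multiplier` expected events per site, and each
event replaces the residue with a draw from a replacement distribution
(uniform over the 20 residues by default, or the equilibrium of an
empirical PAML-format rate matrix via its matrix exponential). Under the
uniform model the probability that a site differs from its ancestor after
`d` expected events is `(19/20)(1 − e^{−d})`; this closed form is the
oracle the sequence layer is tested against. The two clades descending from
the first planted duplication may carry different rate multipliers (r1,
r2), emulating the rate asymmetry that follows divergent
functionalization. Composition bias mixes a target frequency vector into
the replacement distribution on the branches of one named phylum — the
simplest mechanism that produces the compositional-heterogeneity artifact
in the mixed "fast" clade; a branch is attributed to a phylum by the
species-tree position of its lower end.

## Reconciliation and forced rooting

LCA reconciliation maps each gene-tree leaf to its species and each
internal node to the species-tree LCA of its children's images; a node
mapping onto one of its children's images is a duplication. Losses are the
species-tree edges skipped along each child mapping (one fewer for
speciation nodes); `ReconciliationSummary.loss_edges()` names the species
branch of each implied loss, and its length always equals the loss count.

An unrooted binary tree with n leaves has exactly 2n − 3 edges, each a
candidate root. Forcing a family into an assumed hypothesis means taking
the rooting of minimum (duplications, losses), compared lexicographically —
losses, the central artifact, are never traded silently against
duplications (a weighted-sum mode exists for sensitivity checks). Cost ties
break toward the longest root edge (the natural phylogram choice), then the
lexicographically smallest leaf set, making the procedure fully
deterministic. A split edge's length is divided evenly between the two new
root children; this convention does not affect costs.

"X-early root choices" are formalized two ways, because arrowhead-style
counts on published trees follow no stated rule: the *simple* rule (an edge
one of whose sides contains only phylum-X genes) and the cost-based
generalization (the per-edge (D, L) table under each hypothesis). Both are
reported by `count_root_choices`.

## Duplication-timing classification

Classification never assumes either hypothesis at the node level:
duplication nodes are detected by species overlap between the two child
clades. For a duplication with child phylum-sets S1, S2 the rules are
applied in this order:

1. single-phylum union → `PHYLUM_SPECIFIC`;
2. choanoflagellate (or deeper outgroup) in S1 ∩ S2 →
   `PRE_CHOANOZOAN_UNINFORMATIVE`;
3. Po in S1 ∩ S2, at least one eumetazoan phylum on each side, no
   ctenophore or outgroup genes inside, and a ctenophore lineage branching
   immediately outside → `BENTHOZOA_SUPPORT` (mirrored with Po ↔ Ct →
   `NEURALIA_SUPPORT`);
4. Ct in S1 ∩ S2 → `CTENOPHORE_SHARED_UNINFORMATIVE`;
5. S1 ∪ S2 within Eumetazoa with ≥ 2 phyla per side →
   `EUMETAZOA_DUPLICATION`;
6. anything else can only be timed by invoking gene loss and is binned with
   the pre-choanozoan uninformative class (the equivocal cornichon-type
   situation: a sponge + eumetazoan duplication with no ctenophore sister
   could equally be an older duplication with losses).

The support patterns are tested *before* the shared-uninformative patterns;
otherwise a duplication whose clades both contain ctenophores could never
be read as Neuralia support and that category would be unreachable.
"Immediately outside" means the duplication's sibling subtree contains only
the candidate phylum — by default restricted to a single-copy sister
(one gene per species), with a relaxed flag, because a multi-copy sister
weakens the case that the duplication postdates that lineage's divergence.

Family-level category takes the highest-precedence node label in the order
Benthozoa > Neuralia > Eumetazoa > pre-choanozoan > ctenophore-shared >
phylum-specific: an informative duplication outranks coexisting
uninformative ones, since a family can retain pre-metazoan and
lineage-specific duplications and still carry one decisive early-metazoan
duplication (the TMC situation). Choanoflagellate exclusion inside the
support patterns is what prevents a mis-rooted pre-choanozoan family from
masquerading as support — the reason outgroup retention is decisive.

Rootings evaluated: when non-metazoan outgroup genes form a clean unrooted
split, that split roots the tree; otherwise every minimum-cost rooting
under each supplied hypothesis is evaluated, and disagreement between them
yields `AMBIGUOUS_ROOT`. Multifurcating gene trees are rejected rather than
resolved silently.

## The screen

The cascade over homology tables runs: focal genes → genes in
within-species paralogy → genes with ≥ 1 ortholog call in every required
taxon → severing of paralogy edges whose duplication level is in the
excluded list (a `drop` mode removes such genes outright) → connected-
component grouping (transitive closure being the weakest consistent
grouping rule; singletons discarded) → size binning (default keep 2–3-gene
groups) → seeded sampling of ⌊fraction × count⌋ groups via a documented
shuffle. Stage gene counts are recorded and are non-increasing by
construction. The ortholog requirement is applied per gene with groups
rebuilt afterwards (per-group mode available). The sponge-like and
ctenophore-like species are barred from every filtering stage by
construction (`ScreenConfig` rejects overlap between annotate and filter
species) and only flagged at the end; a unit test poisons their records to
verify the retained groups cannot change. A placozoan-anchored
configuration (`trichoplax_anchor_config`) encodes the alternative
five-criteria variant with a cnidarian, lophotrochozoan, ecdysozoan and
sponge requirement.

## The miscall experiment

Per family: simulate the true history under the TRUE hypothesis → evolve
sequences → NJ tree (or the true phylogram, for controls) → minimum-cost
rooting under the ASSUMED hypothesis → label nodes by reconciliation → call
a cross-species pair orthologous iff its LCA is a speciation node. Against
the truth-derived table the experiment reports:

- per-species ortholog-coverage percentages versus a cnidarian and a sponge
  reference, and the deficit gap (minimum over other lineages minus the
  ctenophore; positive = deficit);
- per-phylum false-loss rates. A gene is falsely lost when the called table
  links it to none of its true orthologs *within a paralog group it truly
  belongs to* (a child clade of a true duplication). The group restriction
  matters: an outgroup gene is truly orthologous to both paralog clades, so
  a surviving outgroup call must not mask the loss of a gene's entire
  clade;
- the fast/slow root-clade path-length ratio (reported as max/min, since a
  rooted tree's child order is arbitrary) and the Pearson chi-square of
  pooled residue counts between the two clades (df = residues − 1).

Correctly specified runs (true = assumed, symmetric rates, true trees) are
the negative control and must give exactly zero false losses and 100%
coverage. Degenerate families (fewer than three surviving genes) are
logged, skipped and counted.

## Parameters and defaults

| parameter | default | units / meaning |
|---|---|---|
| species-tree edge length | 0.1 | expected substitutions/site per branch; keeps pairwise distances well below saturation |
| λ (birth), μ (death) | 0 | events per gene per unit branch length; scenario runs use 0 (noiseless) or λ ≈ 0.3–0.5, μ ≈ λ/2 for lossy families |
| r1, r2 | 3, 1 | rate multipliers of the two planted-duplication clades; arbitrary knobs for the depicted asymmetry, not measured values |
| sequence length | 300 | residues; 1000 for tree-inference recovery runs |
| keep_size_range | [2, 3] | smallest informative paralogy groups |
| sample_fraction | 1.0 | seeded sampling; ⌊fraction × count⌋ groups |
| bootstrap replicates | caller-set | column resampling with replacement, seeded |

Every stochastic component takes a mandatory integer seed; the pipeline
derives per-stage and per-family seeds from one global seed, so identical
configs reproduce artifacts byte for byte.

## What the generator does and does not emulate

It emulates: competing rooted hypotheses over one species set, planted and
stochastic duplications/losses, clade-specific rate asymmetry, lineage
composition bias, and noiseless Compara-style homology tables. It does
not emulate: insertions/deletions (true alignments are ungapped, so
alignment error is outside every test), rate variation across sites,
annotation/curation error in homology tables, genome-scale gene counts, or
real ctenophore substitution processes. Passing tests therefore demonstrate
the internal logic of the screen/reconciliation/miscall argument under its
own model, not the empirical magnitudes of any real ortholog database.

## Numerical and degenerate-input choices

Newick round-trips are exact on topology and labels and stable to 1e-9 on
lengths; distance-matrix symmetry is enforced to 1e-12. Negative NJ branch
lengths are clamped to zero with the deficit logged. Bootstrap supports are
percentages of successful replicates containing each internal bipartition
of the point-estimate tree (not a consensus), matching how supports
annotate a single drawn tree. Gap-normalized identity divides by shared
non-gap columns, with the total-column alternative exposed as an option,
since "gap-normalized" admits both readings; unknown (X) residues never
count as match or mismatch anywhere. Zero-denominator statistics (no
shared columns, no comparable columns for a pair, all-gap composition,
single-residue chi-square) raise explicit errors naming the offender.
Alignment coordinates are 0-based half-open internally and 1-based in
human-readable output.

## Problem sizes used in the shipped checks

The self-contained acceptance checks run at desk scale by choice: 100
random additive matrices (n ≤ 12) for NJ recovery, 200 random lossy
families for the reconciliation oracle, 500 (tests) / 200 (script)
replicates per planted scenario on noiseless trees and 30–50 on NJ trees at
sequence length 1000, 50-family negative controls and 200-family positive
controls. Genome-scale screen counts depend on a specific external database
release and are covered by the cascade's structural properties (monotone
counts, partition invariants, toy-table oracles) rather than by absolute
numbers.

## Known limitations

Reconciliation is parsimony-based and binary-only; probabilistic
reconciliation, transfers and polytomies are out of scope. Duplication
detection by species overlap misses duplications whose descendant species
sets were made disjoint by loss (hidden paralogy — precisely the artifact
the miscall experiment quantifies from the other direction). The
classification of loss-equivocal duplications into the pre-choanozoan
uninformative bin is a conservative convention, not a claim about their
true timing. Bootstrap supports on very gappy alignments can be computed
over fewer than the requested replicates (failed replicates are excluded
from the denominator and the count is logged).
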