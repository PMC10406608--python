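# Methods

`genecontent` reimplements, as a tested and reusable library, the standard
inference chain of comparative gene-content phylogenomics: homologous-group
(HG) construction from a protein similarity network, mapping of gene gains,
duplications and losses onto a rooted species tree by Dollo parsimony, a
suite of rule-based repertoire classifiers (conservation classes,
transcription factors, transporters, secretome), and gene-content
ordination with GO term enrichment. Every stage is exercised end-to-end on
synthetic data with known truth; no external search tools (MMSeqs2, HMMER,
InterProScan, SignalP, TMHMM, WoLFPSORT, dbCAN, MEROPS) are run — their
outputs enter as tabular inputs.

## Homologous-group construction

The raw all-vs-all similarity edge list (query, subject, score, e-value,
coverage of the longer and of the shorter protein) is processed in five
steps:

1. **Filtering.** Edges are kept when coverage of the longer protein
   ≥ 20%, coverage of the shorter ≥ 80% and e-value ≤ 1e-4 (all
   boundaries inclusive).
2. **Markov clustering (MCL)** with inflation 2.0. The transition matrix
   is column-stochastic with self-loops set to each node's maximum
   incident edge weight; near-zero entries are pruned at 1e-8. These are
   standard MCL practices needed for convergence. Clusters are read off
   the converged matrix as attractor systems; isolated proteins become
   singleton clusters. Non-convergence after `max_iter` raises a warning
   and interprets the current matrix.
3. **Cluster network.** Clusters are joined by edges weighted by the
   number of crossing protein-level edges, normalised to cluster size.
   We normalise by `min(|A|, |B|)` so that a small cluster strongly
   attached to a large one ranks as a strong link; mean-size
   normalisation is available via the `norm` argument.
4. **Diameter pruning.** While any connected component of the cluster
   network has unweighted diameter > 3, its minimum-weight edge is
   removed (ties broken by the lexicographic cluster-id pair). We prune
   *edges*: a diameter criterion over a cluster network is only
   meaningful under edge removal, and the "weakest" elements ranked by
   normalised connection counts are edges.
5. **Merging.** Each cluster pair still connected after pruning is merged
   iff a profile comparison reports e-value ≤ 1e-10, profile-side
   coverage ≥ 75%, consensus-side coverage ≥ 20% *and* a match score of
   at least 75% of the self-match. Merging is transitive (union–find), so
   the output is a coarsening of the MCL partition. The merge test is
   applied in the single (profile → consensus) direction; requiring both
   directions is a plausible alternative reading and can be emulated with
   a symmetric scorer.

Profile scoring is a pluggable contract (`evalue, coverage_profile,
coverage_consensus, score, self_score` per cluster pair). The bundled
`GraphProfileScorer` aggregates raw similarity-edge statistics (mean
crossing score, minimum crossing e-value, mean coverages, mean self-match
score). It is a desk-scale stand-in that preserves the shape of the
contract and is **not** equivalent to an HMM-vs-consensus search.

An optional species-composition sanity filter can flag HGs dominated
> 90% by a single species; taxonomic contamination screening proper is out
of scope.

## Marker filters

Four pure screens applied to candidate single-copy marker families:
terminal (same-species) clade collapse on gene trees, keeping the leaf
with the smallest mean distance to other species' leaves when distances
are given (lexicographic fallback — the choice is not critical and is
logged in the output); a mean pairwise amino-acid-distance ceiling
(pass iff mean < 1.5); an ancestral-paralogue screen; and the alignment
size rule (pass iff length ≥ 60 aa and ≥ 30 species).

The ancestral-paralogue screen clusters the distance matrix
hierarchically and fails a family when both sides of the root split share
at least 2 species — the signature of a duplication predating the
family's deepest divergence. The "first split" criterion is not
operationally defined in the literature this follows; the shared-species
rule is one plausible reading and is documented as such. The linkage
method is a parameter (default `average`; `complete` matches R's
`hclust` default). A Poisson-corrected distance (−ln(1−p)) is bundled as
a convenient default when no maximum-likelihood distances are supplied.

## Reconciliation and Dollo mapping

Gene trees are reconciled against the species tree by LCA mapping: each
internal node maps to the LCA of its children's mappings and is a
duplication if a child co-maps with it or — for polytomies, which arise
from collapsing edges with support < 80 — if two children co-map to the
same species-tree node (the conservative reading: duplication only when
forced). Losses on a gene-tree branch are the species-tree edges skipped
between the parent's and the child's mapping, minus one when the parent
is a speciation. Rooting places the root on the unrooted edge minimising
duplications + losses, with ties broken by fewer duplications and then by
the lexicographically smallest leaf bipartition, making the choice
deterministic.

Orthogroups are the maximal speciation-only subtrees obtained by cutting
the gene tree at every duplication node's child edges; each is mapped to
the species tree by Dollo parsimony: a single gain at the MRCA of its
species, and one loss on the root edge of every maximal member-free
subtree below the gain. Species absent from a gene tree contribute losses
only below the gain node, never "unsampled" states — that is what Dollo
semantics require.

Within a family, ancestral copy numbers are reconstructed on the Dollo
"present" skeleton by a Sankoff-style dynamic programme over integer
states 1..max(tip count), minimising the summed |Δcopies| along branches.
Traceback ties are resolved toward the parent's value, then toward the
smaller state, which avoids introducing spurious duplication + loss
pairs. Copy-number changes along a branch are booked as duplications
(increase) or losses (decrease); a full loss books the parent's copies.
Aggregation over families yields per-node totals satisfying exactly

    copies(node) = copies(parent) + gains + duplications − losses,

which is asserted (`EventMap.check_bookkeeping`) on every pipeline run.
Both per-copy (`counts`) and presence-only (`presence`) modes are
provided, since gain/loss bookkeeping can be read either per orthogroup
or per gene copy; the default is `counts`.

Node identity: nodes carry stable postorder integers (every id larger
than all ids in its subtree; root = n−1). The numbering is a pure
function of topology and child order, so exported node labels are
reproducible across serialisation.

## Repertoire classifiers

All classifiers are exact rules over the annotation table, and all are
order-independent. Boundary conventions follow the wording of each rule:
"> 50%" (majority annotation) is strict; the 70% (conservation), 75%
(fungal-domain HGs, self-match fraction), and 99% (fungal-specific
domains) thresholds are inclusive.

* **Conservation** of an HG in a species group = |present ∩ group| /
  |group|.
* **Protist-conserved/lost** HGs: present at the Holomycota ancestor per
  the Dollo reconstruction, absent from every Dikarya species, and either
  ≥ 70% conserved in at least one named group or gained at/before the
  Holomycota node.
* **Novel-core** HGs: gained strictly below a reference ancestor and
  ≥ 70% conserved among all descendant tips of their own gain node.
* **Fungal-specific domains**: ≥ 99% of occurrences in the Holomycota
  column of the domain × supergroup table; an HG carries the flag when
  ≥ 75% of its members have such a domain.
* **Transcription factors**: strict majority of members carrying a
  DNA-binding domain, vetoed if any exclusion domain (ribonucleases,
  metallopeptidases, chromatin remodelling, splicing, ...) itself passes
  the majority rule; the family is that of the most frequent DBD (ties:
  lexicographic).
* **Transporters**: strict majority of transporter-specific domains and
  plasma membrane as the modal member localization (ties fail) with
  median score strictly > 15. The aggregation side (median over the
  members carrying the modal label) is our choice; mode-plus-median is
  not uniquely pinned down by the rule's usual statement.
* **Small secreted proteins**: length < 300 aa, signal peptide present,
  no transmembrane helix.
* **Dynamics ranking**: per HG, the sum over a root-to-descendant chain
  of ancestors of (copies(child) − copies(parent)) / max(copies(parent),
  1). The denominator clamp means a family newly gained on the path
  contributes its copy count. The chain is supplied explicitly (it is a
  figure-defined set of nodes in the original analyses); we treat "over
  eight nodes" as the eight branches between nine successive ancestors.
* **Shannon diversity** of a TF repertoire uses the natural logarithm.

## Ordination and enrichment

HGs entering the ordination have ≥ 4 member proteins and ≥ 50%
conservation in at least one supplied clade. The species × HG
presence/absence matrix is turned into a Jaccard-complement ("binary")
distance, d = (b+c)/(a+b+c); two all-absent profiles are at distance 0.
PCoA is classical scaling (double-centre −D²/2, eigendecompose,
coordinates = eigenvectors × √eigenvalues). Negative eigenvalues are
reported but never used for coordinates, and no Cailliez-type correction
is applied by default. The minimum spanning tree is Kruskal's algorithm
with ties broken by lexicographic edge order.

Enrichment p-values are one-sided hypergeometric tails
(`scipy.stats.hypergeom`). The `elim` mode walks the GO DAG from the most
specific terms upward, removing a significant term's genes from its
ancestors before testing them; this approximates — but is not identical
to — weight-based decorrelation algorithms, and rankings may differ.
Raw p-values with a P < 0.05 significance flag are the default output; a
Benjamini–Hochberg column is optional.

## Synthetic data: what it emulates and what it does not

The generative model is the package's own construction — the analysis it
validates only infers histories and defines no forward process — and all
distributional choices are stand-ins:

* **Species trees** are pure-birth (Yule) trees; branch lengths are in
  arbitrary pure-birth units.
* **Gene families** originate exactly once at a node (uniform over nodes
  by default; root-only and branch-length-weighted modes exist — the
  root-only mode gives the cleanest Dollo tests). On each branch,
  duplication and loss counts are Poisson with mean
  rate × copies × branch length (length 1 when absent), losses capped so
  copies stay non-negative; the origin node starts at 1 plus the
  duplications drawn on its incoming branch. This mirrors the per-branch
  event counts the inference reconstructs. Default rates (duplication
  0.1, loss 0.1 per copy per branch, 150 families on a 12-tip tree in
  the pipeline default) produce moderate-turnover histories in which
  presence patterns are informative but losses are common enough to
  exercise the Dollo machinery.
* **Similarity graphs** are planted partitions: within-family pairs get
  edges with probability 0.9, strong scores and tiny e-values;
  between-family pairs with probability 0.02 and weak scores; 10% of
  edges receive coverages that fail the asymmetric coverage filter.
  Real similarity networks have heavy-tailed degree and score
  distributions, domain-level chaining and shared-domain cross-family
  edges; none of that is emulated, so clustering recovery here
  demonstrates correctness of the chain, not expected accuracy on real
  proteomes.
* **Annotation tables** are drawn from per-family generating
  probabilities, which makes exact planted positives (a family that is
  100% TF, transporter, SSP or extracellular by construction)
  constructible — classifier tests assert precision = recall = 1.0
  because the rules are exact, not statistical.

Consequently, passing tests show that the inference and the rules are
implemented correctly under the stated model; they say nothing about
annotation error, alignment artefacts, contamination or model violations
in real data.

## Numerical and degenerate-input conventions

MCL: convergence tolerance 1e-8 (max-entry change), entry pruning 1e-8,
maximum 200 iterations. PCoA: eigenvalues below 1e-12 × the spectral
radius are treated as zero. Sankoff traceback: ties toward the parent's
state, then the smaller state. Empty homologous groups, empty study
sets, empty species patterns and empty groups are rejected with
`ValueError` rather than given a default. Globally extinct simulated
families are excluded from the emitted matrix (real data never shows
them) but retained, flagged, in the truth record.

## Verification problem sizes

The acceptance script and test suite use exhaustive checks where the
space is small (every presence pattern on every rooted binary shape with
≤ 6 tips; every hypergeometric table with margins ≤ 50) and simulation
elsewhere (1,000-family bookkeeping and origin-recovery runs and a
10,000-family no-ancestral-inference run on a 20-tip tree; 20 seeds of
the 10-family × 8-protein planted-partition design; 100 random graphs
for the pruning bound and MST cross-checks). These sizes make every
guarantee checkable in seconds while covering the regimes — exhaustive
where provable, stochastic where not — that the guarantees are stated
over.

## Known limitations

* The MCL implementation is dense; it is intended for desk-scale graphs
  (up to a few thousand proteins), not proteome-scale runs.
* `GraphProfileScorer` is not an HMM profile comparison; merge decisions
  on real data should use a scorer backed by a profile search.
* The elim enrichment mode approximates, but does not reproduce,
  weight01-style rankings.
* NOTUNG-style rearrangement of weakly supported regions is not
  reproduced; weak edges are collapsed and polytomies reconciled
  conservatively instead.
* Horizontal transfer is not modelled as a distinct event type; as in
  the analyses this follows, it is folded into origination.
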