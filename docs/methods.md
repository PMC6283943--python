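# Methods

## The inference

`palaeopsin` answers one question: *what is the smallest set of paralogues a
lineage can be credited with at the base of its stem?*  Two dated trees are
compared purely through their 95% credibility intervals (CIs), never through
point estimates:

- **Precedence rule.** A duplication with CI `(dup.young, dup.old)` precedes a
  species divergence with CI `(div.young, div.old)` iff `div.old < dup.young`
  (strict).  Boundary equality counts as overlap.  Ternary logic is collapsed
  to `{precedes, ambiguous}`: anything short of unambiguous precedence keeps
  the ancestral gene, so the inference errs, by construction, toward *fewer,
  more ancestral* genes.
- **Frontier cut.** Starting at the root gene of the dated duplication chain,
  a gene is expanded into its two daughters iff its duplication precedes the
  divergence; the unexpanded frontier is the inferred complement.  A daughter
  duplication is never evaluated unless its parent was expanded, so the
  output is well-defined even when sampled CIs are imperfectly nested.
- **Bracketing.** For a node whose sampled descendants are all extant, gene
  presence is instead inferred by Dollo bracketing on a presence/absence
  table: a single origin at the MRCA of the possessing tips, unlimited loss.
  A tip carrying a derived paralogue also evidences its ancestral composites
  (component sets are nested: `UV` ⊂ `UV/SWS`), and only the most-derived
  frontier is reported.  Nodes with fossil descendants are refused and routed
  to the interval comparison — a fossil is always younger than the clade it
  belongs to, so comparing two timetrees avoids invalid comparisons against
  raw fossil ages.
- **Chromacy.** The visual-pigment count is the complement size minus one if
  the standalone `Rh7` gene is present (its characterised role is circadian
  entrainment, not vision); composites *containing* Rh7 still count as
  visual.  0 → none, 1 → monochromat, 2 → dichromat, 3 → trichromat,
  more → polychromat.  A flag (`rh7_nonvisual=False`,
  `--no-rh7-nonvisual`) disables the Rh7 discount.

Assumptions worth keeping in mind: verdicts are per-comparison (the 95% level
is not propagated into a joint probability over whole complements); no
lineage-specific loss or gain after the focal divergence is modelled, so a
complement is a statement about what was *inherited*, not what was retained;
intervals are treated as opaque (no HPD vs equal-tailed distinction).

## Reconciliation

Duplications are placed on the species tree by standard LCA (parsimony)
reconciliation: each gene node maps to the lowest species node containing its
descendant copies; a node is a duplication iff it maps to the same species
node as one of its children.  This attains the parsimony minimum number of
duplications (verified in the tests against exhaustive enumeration of all
valid mappings on trees of up to 7 gene tips) and reproduces exactly what the
downstream inference consumes — the placement of duplications on a fixed
rooted topology.  Probabilistic, gene-tree-aware reconciliation is out of
scope.  Losses are not reconstructed: `copies_at` counts gene lineages whose
origin the reconciliation places at or above a species node and which retain
at least one sampled descendant below it, so secondary loss shows up as
reduced counts rather than as explicit events.  Polytomies are handled by the
same LCA semantics without arbitrary binarisation.

## Nomenclature

Ancestral genes are named by slash-concatenating their terminal descendants in
a fixed precedence order (default `Rh7, UV, SWS, MWS, LWS`).  Published
spellings permute the components, so name identity is defined on the
component *set* (`same_gene`), and every constructed tree re-derives each
internal name from its subtree — a self-consistency check that runs on
construction.  Duplication events are supplied as bipartitions of leaf sets
and must form a laminar family; chain ages must be monotone (a daughter
duplication may not be entirely older than its parent; tolerance 1e-9 Ma).

## The synthetic generator

The generator emulates the *outputs* of the two dating analyses, not their
likelihoods:

- **Species tree.** Forward birth–death simulation from a root split, root age
  drawn from Gamma(mean 600 Ma, sd 26 Ma).  Fossilisation events fall as a
  Poisson process with rate ψ per lineage per Ma on all branches, extinct
  subtrees included; each event becomes a dated tip of the sampled tree, and
  a lineage with no sampled descendants is truncated at its youngest fossil —
  the structure of a fossilised-birth–death sampled tree.  Extant lineages
  are sampled with probability ρ; the simulation is conditioned on at least
  two sampled extant tips and an observed root split.
- **Defaults.** birth 0.011, death 0.008, ψ 0.015 /lineage/Ma, ρ 1.0.  These
  were chosen once to reproduce the *scale* of the empirical design this
  package was built around — on the order of ten extant and fifty fossil tips
  under a ~600 Ma root.  In the empirical analyses the sampling parameters
  are priors of an inverse problem (an extant sampling fraction of 1e-5
  reflects sampling ~10 of ~10⁷ living arthropod species, and the fossil rate
  carried an exponential prior with rate 10, i.e. mean 0.1/Ma); literal
  forward simulation at those values would require millions of lineages and
  would not yield comparable trees, so the generator uses ρ and ψ as direct
  generative rates and leaves both fully configurable.
- **Posterior ages.** For a true age *t*, a posterior centre is drawn
  lognormally around *t* with relative sd σ (default 0.01, giving ~20–25 Ma
  wide CIs at ~550 Ma, comparable to the published focal intervals); posterior
  draws (default 500) are then taken lognormally around that centre and
  summarised as an equal-tailed 95% interval.  Drawing the centre is what
  makes the intervals *calibrated* — the truth lands inside the 95% CI ~95%
  of the time, which the tests verify — rather than trivially containing the
  truth always.  Draws are truncated sample-wise to respect parent/child
  ordering and clamped below by the oldest tip in the subtree; σ = 0 yields
  degenerate CIs for exact-recovery tests.  Duplication and divergence ages
  are perturbed independently, mirroring the fact that they come from two
  separate analyses.
- **Default scenario.** Four duplications on the backbone lineage (the extant
  tip with the most ancestors), each placed midway between consecutive focal
  divergences; five foci chosen along the backbone with a minimum spacing of
  20 Ma.  Each focus therefore truly inherits one more paralogue than the one
  above it.
- **Recovery metrics.** Against the exact time-cut truth (degenerate CIs at
  the true times), an inferred complement *overclaims* when it contains
  paralogues whose true duplication postdates the true divergence, and
  *underclaims* when an ancestral gene is kept although its duplication truly
  precedes.  The one-sided rule bounds overclaims (≲2.5% per comparison under
  calibrated CIs; tested against a 5% ceiling over 1000 replicates), while
  underclaims are the price of conservatism and grow with CI width — the
  tests check they shrink monotonically as intervals narrow and vanish at
  zero width.

What the generator does **not** emulate: autocorrelated-clock behaviour,
topological uncertainty, correlated errors between the two dating analyses,
morphological or sequence data of any kind.  Passing the recovery tests shows
the *comparison step* is conservative and consistent under honest interval
uncertainty; it says nothing about errors upstream in tree inference or
dating.

## Numerical and design choices

- Ages are floats in Ma before present; "older" = larger.  Age comparisons
  use an absolute tolerance of 1e-9 Ma; intervals are normalised to
  `young ≤ old` on input regardless of written order.
- Zero-length branches are legal (fossil tips attach at exactly their age);
  validation enforces only non-negativity and parent ≥ child.
- The annotated Newick dialect is `[&age=x,ci={young,old}]` node comments;
  NEXUS is supported through the same machinery (dendropy underneath).  Trees
  without ages round-trip via stored branch lengths.
- The bundled species tree's focal-node CIs and the duplication intervals are
  published values; unlabelled internal point ages and fossil tip ages in
  that file are representative placeholders that only keep the chronology
  consistent — the inference never reads them.
- Bracketing reports the most-derived frontier (dropping ancestral composites
  whose descendants are present) so that its output is directly comparable to
  a frontier cut.
- Random experiments derive per-replicate generators from
  `numpy.random.SeedSequence(seed).spawn`, so every figure the package
  produces is reproducible from a single integer seed.

## Known limitations

- The conservative rule cannot distinguish "duplication after divergence"
  from "not enough dating resolution"; both read as ambiguous, and with wide
  intervals the inferred complements collapse toward the root gene.
- LCA reconciliation assigns each duplication to the lowest consistent node;
  genuinely older duplications followed by losses will be placed too low
  (this is the parsimony trade-off, and it biases complements in the same
  conservative direction).
- `copies_at` trusts the Dollo single-origin convention for the family root;
  gene families with multiple independent origins are outside the model.
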