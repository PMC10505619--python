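# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not emulate. It is the design record for
maintainers; the README covers usage.

## Orthogroup preparation

The analysis set is the orthogroups containing at least one protein
from every species of the configured panel (order of the input table
preserved). Where a species contributes several isoforms the longest
is kept; length ties break to the lexicographically smallest gene ID so
reruns are reproducible. Codon alignments are produced by threading
each gene's CDS through its aligned protein row (gap → `---`, residue →
codon), after stripping one terminal stop codon if present; any
length or translation disagreement is a hard error naming the gene and
residue. The standard genetic code with 61 sense codons is assumed
throughout. Back-translation from the protein alignment is the single
supported route to a nucleotide alignment: it guarantees column
compatibility between the protein-level and codon-level analyses.

## Root-to-tip divergence

Maximum-likelihood gene trees are unrooted, so rooting precedes the
distance computation. Three methods are supported:

- `midpoint` (default for unrooted inputs) — root at the midpoint of
  the longest tip-to-tip path;
- `outgroup` — root on a configured outgroup tip's branch, split 50/50;
- `input` — keep the rooting the tree came with (requires a
  bifurcating root).

One interaction deserves emphasis, because it shaped the defaults: a
midpoint root is by construction equidistant from the two ends of the
tree diameter, so under midpoint rooting the maximum root-to-tip
distance is always attained by at least two tips. The parameter-free
`strict_max` rule ("focal strictly exceeds every other tip") therefore
cannot fire on the very trees where the focal tip is genuinely the most
divergent — the signal is halved and handed to the opposite diameter
end. When gene trees carry a meaningful root (e.g. they were derived
from, or reconciled with, a rooted species tree) `input` rooting should
be used, and the synthetic cohort's generated configuration does so.
With midpoint rooting, prefer the `zscore` rule (focal exceeds the
background mean by k standard deviations, default k = 2).

Ties under `strict_max` are not flagged (strict inequality); both rules
are invariant to rescaling all branch lengths by a positive constant.
Absent branch lengths are an error, never treated as zero.

## Unique amino acid substitutions

A hit is an alignment column where all background rows carry one
identical non-gap residue and the focal row carries a different non-gap
residue. Columns within `window` (default 10) alignment columns of any
column containing a gap in any row are excluded: alignment quality near
indels is too poor to support single-column inference. The window is
applied in alignment-column coordinates, triggered by a gap in any row,
because the scan itself is column-wise; per-sequence coordinates would
give each row a different mask. A focal-row gap is never a hit (a
deletion is not a substitution). Background identity is strict; a
configurable minimum background-row count (default 2) guards degenerate
alignments.

Functional impact: offline, deleteriousness is proxied by the BLOSUM62
exchange score of background → focal (score < 0 ⇒ deleterious) —
negative BLOSUM scores mark exchanges observed less often than chance
between related proteins. Genuine SIFT output can be imported
(`gene`, `position`, `prediction`, `score` TSV); imported rows override
the proxy and use SIFT's own convention (deleterious when predicted so
or score ≤ 0.05). The `source` field records which route annotated
each hit.

## Branch-site selection test

Model A as described in the README. Numerical choices:

- **Codon frequencies**: F3x4 with a pseudocount of 0.5 per nucleotide
  per codon position, so every sense codon has positive frequency even
  in short alignments.
- **Rate scaling**: each class's rate matrix is divided by the
  proportion-weighted mean substitution rate of the *background* class
  ωs, so branch lengths keep expected-substitutions-per-codon-site
  units at the mixture level; the foreground branch shares the same
  scale factor.
- **Likelihood**: Felsenstein pruning over 61 states with per-pattern
  scaling (site patterns are compressed first). The traversal is rooted
  at the focal tip's parent; by reversibility the likelihood is
  root-invariant, and this choice lets the four site classes share the
  two background prunings (ω₀ and 1) and differ only in the foreground
  edge factor — the single biggest speed lever in the package.
  Codons containing gaps or ambiguity are treated as missing data.
- **Branch lengths**: estimated once under the single-ω model (M0) and
  held fixed for both mixture fits. The default M0 mode (`scale`)
  estimates one global rescaling of the input tree's relative branch
  lengths together with κ and ω — input gene trees already carry ML
  relative lengths, and re-estimating only their overall rate in codon
  units is both faster and more stable at alignment sizes of a few
  hundred codons. A `full` mode frees every branch length individually
  for trees whose relative lengths are not trusted.
- **Optimisation**: L-BFGS-B with bounds κ ∈ [0.05, 50],
  ω₀ ∈ [10⁻⁴, 1], ω₂ ∈ [1, 50], proportions through an additive
  log-ratio transform; deterministic multi-start (default 3: fixed
  defaults plus seeded perturbations). Relative function tolerance
  10⁻⁷; with log-likelihoods of order 10³ this resolves the LRT
  statistic to ~10⁻³, far below any decision boundary. If the
  alternative optimum falls below the null's (a boundary artifact),
  the null optimum is reused for the alternative, since the models are
  nested.
- **LRT**: 2Δℓ against χ²₁ (conservative for this boundary null); the
  50:50 mixture of a point mass at zero and χ²₁ is available
  (`lrt_convention="mixture"`). Under the null roughly half the fitted
  statistics are exactly zero, so p-values pile up near 1 — this is a
  property of boundary LRTs, not a bug; calibration checks should test
  for anti-conservatism (excess small p-values), not uniformity.
- **FDR**: Benjamini–Hochberg across orthogroups (via statsmodels,
  validated against a step-up oracle in the tests). Non-converged fits
  are excluded from the correction and flagged, not silently kept.
- **BEB**: posterior probability of the foreground classes (2a + 2b)
  per site, integrating over a uniform grid prior — 10 interval
  midpoints for ω₀ on (0, 1) and for ω₂ on (1, 11), and the midpoints
  of a 10-per-axis triangular grid over the (p₀, p₁) simplex, all
  cells equally weighted; κ and branch lengths stay at their estimates,
  as does the mixture rate scaling. Sites with posterior > 0.95 are
  reported (1-based codon positions). NEB (plugging in the MLEs) is
  available as a cheaper mode, documented as less reliable for small
  alignments. BEB runs only for genes passing the FDR threshold.

## Gene-family birth–death analysis

Equal birth and death rates λ per gene per million years on an
ultrametric species tree (ultrametricity is validated, tolerance 10⁻⁶
relative; it is an input property, not computed here). The transition
probability is the closed form given in the README; parameter bounds
keep α = λt/(1+λt) < ½ on every branch. Family likelihoods use pruning
over copy-number states 0..N_max with N_max = max observed count + 20
(the state space must be capped; results are insensitive to the
headroom because the transition mass above observed counts decays
geometrically). The root prior is uniform on 1..N_max — a family
observed in the tips existed at the root. The two-λ partition is the
focal terminal branch vs all other branches; a one-λ fit is available
and is always nested within the two-λ fit.

Filters before fitting, applied per family: any species with more than
100 copies (annotation and clustering artifacts dominate such
families), and families whose members all fall within a single child
clade of the root, whose birth cannot be placed on the tree
(alternative rule: present in exactly one species). Ancestral counts
are joint-ML states from a max-product pruning pass with ties resolved
to the smaller count; Δ is the focal tip count minus its parent's
state. "Highly" expanded/contracted defaults to the most literal
reading of the size rule — a changed family whose focal count exceeds
10 — with an |Δ| > 10 alternative exposed, because the size-vs-change
ambiguity cannot be resolved from the rule's phrasing alone. Per-family
Monte-Carlo significance p-values are deliberately not computed; the
reported output is expansion/contraction direction and the size-based
"highly" flag.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline reads, with recorded
ground truth and bit-reproducible output under a fixed seed. They avoid
the analyzers' numerical machinery where sharing it would make checks
self-confirming: the family simulator is an exact event-driven jump
process (the analyzer uses the closed-form law — the agreement of the
two is itself an acceptance test), and the codon simulator draws states
through matrix exponentials rather than the pruning code.

The default cohort mirrors the target analysis at desk scale: 19
species with one focal lineage, 50 orthogroups of 100 codons, a
species tree of height 0.5 substitutions per codon site, 200 gene
families on a 120-My ultrametric tree with λ = 0.002 (background) and
0.004 (focal). Three orthogroups are planted with two signatures each
(an elongated focal branch and three deleterious focal-unique
substitutions, Gly→Trp); the rest evolve under the branch-site null.
Design choices that make the planted ground truth identifiable, chosen
a priori and then frozen:

- Per-orthogroup gene trees are one shared clock-like species topology
  (a Kingman coalescent) with lognormal per-gene and per-edge rate
  jitter, not independent random trees. With independent trees, a null
  orthogroup whose focal branch happens to be longest genuinely carries
  the divergence signature and, being focal-fast, is enriched for
  focal-unique substitutions — no correct implementation could then
  recover "exactly the planted genes". Rate-jittered species trees are
  also closer to real orthogroup data.
- The focal species sits on the shortest terminal branch of the base
  tree (a label swap, valid by coalescent exchangeability) — like a
  real focal lineage with close relatives in the panel — so elevated
  focal divergence in a null orthogroup is rare rather than a
  1-in-n_taxa coin flip. Measured over six cohort seeds: planted genes
  recovered 18/18, zero joint (divergence ∧ substitution) false
  positives in 282 null orthogroups.
- Planting is constructive: the planted focal branch is extended until
  its root-to-tip distance exceeds every background tip by a 1.2
  margin, and planted substitution columns are overwritten in the codon
  alignment (background GGG, focal TGG) so protein alignment, CDS and
  codon alignment stay mutually consistent.

What the synthetic data do **not** emulate: indel evolution (gap blocks
are planted, not evolved), among-site rate variation beyond the
branch-site classes, alignment error, annotation noise, isoform
structure beyond a single planted decoy per orthogroup, and gene-tree
discordance (the jitter changes rates, not topology). Passing the
planted-cohort test therefore demonstrates that the pipeline's
inference and bookkeeping are correct under the stated models, not that
the signatures are robust to misalignment or orthology error in real
data.

## Problem sizes and runtime

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own working sizes: oracle comparisons at ≤ 4
taxa and ≤ 5 codons (exhaustive enumeration over 61³ internal-state
assignments), null calibration at 50 replicates of 6 taxa × 100 codons,
power and recovery checks at 500 codons / 500 families, and the
end-to-end cohort at 19 taxa × 50 orthogroups with one optimizer start
per model (multi-start matters for ridge-shaped alternative fits on
large alignments; on 100-codon simulated data the default start is
reliable, and the acceptance checks exercise exactly that regime).

## Known limitations

- The branch-site fit holds branch lengths at their M0 estimates;
  joint re-estimation under the mixture is available only through the
  `full` M0 mode, not within the mixture fit itself.
- Synonymous rate variation, site models (M1a/M2a/M7/M8) and branch
  models are out of scope.
- The BLOSUM62 impact proxy is a coarse stand-in for a
  conservation-based predictor: it knows the exchange, not the site's
  evolutionary context.
- The birth–death model assumes equal birth and death rates; families
  are independent; no rate variation across families.
- `strict_max` divergence calls are sensitive to the rooting method,
  as discussed above; reports record the rule used.
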