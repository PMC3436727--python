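# Methods

This note records the model behind `compositemap`, the tunable parameters,
the numerical conventions, and the design decisions taken where the
procedure was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The merge model and its assumptions

A composite map is built by *marker merging*, not by joint segregation
analysis: the inputs are finished linkage maps (ordered markers at cM
positions), and the only information used to align them is the set of
markers they share. The method assumes:

- **Synteny and colinearity.** Homologous linkage groups exist across maps
  and, after screening, agree in marker order up to local noise. Markers
  shared between two homologous LGs estimate a common underlying order.
- **Approximately affine distortion.** Within one LG, a component map's
  positions relate to the building composite's positions by roughly a
  straight line `p_c = m·p_i + c`. The slope absorbs pedigree-specific map
  expansion/contraction (different recombination rates, marker densities);
  the intercept absorbs the arbitrary LG origin. This is a first-order
  assumption — regional recombination-rate differences make the true
  relation only piecewise-linear, which is one reason merged-in positions
  carry more uncertainty than backbone positions.
- **A trustworthy backbone.** The seed map's orders and distances are taken
  as fixed; everything else is expressed in the seed's coordinate system.
  The seed is chosen as the densest map (tie-break: largest pedigree, then
  lexical map id) because merge error accumulates in projected markers, and
  the densest map leaves the least to project.

Merging is greedy: at each round the component LG with the highest fit value
`|ρ|·log(n)` is merged. The magnitude of ρ is used because LG orientation is
arbitrary across independently built maps; a reversed but perfectly
colinear LG is as informative as a forward one, and its positions are
flipped (`p_i ← max(p_i) − p_i`) before regression. Later rounds anchor on
previously projected markers as well as seed markers, which lets a map that
shares little with the seed still be merged through intermediate maps.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_anchors` | 3 | minimum shared markers for a merge or homology call; below this a regression line is unfalsifiable |
| `min_rho` | 0.50 | minimum \|ρ\| for a component LG to contribute its markers |
| `screen_rho` | 0.90 | pre-screen threshold: a component LG whose best \|ρ\| against all overlapping reference LGs falls below this is flagged discordant |
| `trim_gap_cm` | 5.0 cM | distal gap at or above which a poorly supported end marker is trimmed |
| `trim_min_support` | 2 | end markers supported by fewer component maps than this are trim candidates |
| `log_base` | 10 | base of the fit-value logarithm; selection is provably base-invariant (a positive rescaling of all scores), asserted in tests |

The eligibility thresholds (3 anchors, ρ ≥ 0.50, 5 cM trim) are the
reference behavior for this kind of merge and are all overridable on the
CLI. The screening threshold 0.90 is our own quantification of "substantial
non-colinearity": in practice, component LGs whose order is usable correlate
≥ ~0.92 with the composite while wholesale-discordant ones fall far below;
screening is advisory by default (report, don't drop) because the decision
is traditionally made by visual inspection — `--auto-exclude` applies it.

## Numerical conventions

- Positions are carried at full floating precision internally and rendered
  at 0.1 cM in reports; the TSV writer's full-precision mode round-trips
  exactly.
- Spearman ρ uses mean ranks for ties (scipy). Fewer than two shared
  markers, or zero rank variance on either side, make ρ undefined; such
  comparisons are flagged, never coerced to 0.
- The anchor regression is unweighted ordinary least squares; a fit is
  degenerate (error) when anchors have no usable position spread.
- Projected positions may fall below 0 or beyond the current LG ends during
  building; each LG is rigidly shifted to start at 0 at the end (and again
  after trimming). Backbone immutability therefore means: seed positions
  change only by one rigid per-LG translation.
- Fit-value ties break by larger anchor count, then component input order —
  builds are deterministic.
- Markers projected to identical positions are kept as distinct co-located
  loci (no jitter); "unique loci" in the summary collapses co-location at
  the 0.1 cM reporting granularity.
- A component LG is consumed at most once per building LG; one component
  map may contribute different LGs to different composite LGs independently.
- Composite LGs exist only for seed LGs: an LG absent from the seed map has
  no backbone coordinate system and is not invented.

## QC surface

- **Correlation table**: signed Spearman ρ between each composite LG and the
  best-matching LG of each component map, with flags for pairs whose order
  actually entered the build and pairs excluded by screening. Averages are
  over defined cells only.
- **Summary table**: per-LG length (max position), marker positions by type,
  unique loci, average interval = length / (unique loci − 1); the totals row
  uses total length / (total unique loci − number of LGs). The per-LG
  interval denominator convention varies between studies; ours is stated
  here and used consistently.
- **Multicopy χ² test**: expected multicopy DArT positions per LG are
  allocated proportionally to DArT positions,
  `E_i = (Σ multicopy / Σ DArT) · DArT_i`, with `χ² = Σ(O−E)²/E`,
  `df = LGs − 1`. Only DArT positions enter either side. Per-LG multicopy
  percentages are reported against both the DArT-position and the
  total-position denominators, since both conventions appear in the
  literature.
- **Accounting identity**: total positions = distinct markers + Σ(copies−1)
  over multicopy markers; checked on every composite the engine produces.
- **Redundant candidates**: markers co-locating (within a tolerance,
  default exact) on every LG where both occur are grouped as putative
  identical clones; sequence-level confirmation is out of scope.

## The synthetic generator

The generator emulates the statistical structure of a seven-pedigree
mapping study so the whole pipeline can be validated against known truth:
a true map (11 LGs, 400 markers/LG, lengths uniform on 80–140 cM, marker
types 95% DArT / 4.8% SSR / 0.2% gene) is drawn once; each component map
retains each marker independently (default per-map retentions 0.45, 0.44,
0.27, 0.14, 0.10, 0.21, 0.18 — mirroring how the share of polymorphic
markers varies across pedigrees), scales positions by a per-map factor
(1.00, 1.11, 1.04, 0.93, 1.03, 0.95, 1.14 — map-length inflation), adds
Gaussian position noise (sd 1 cM) and adjacent-order swaps (rate 0.02 per
neighbouring pair — order uncertainty among tightly linked markers), and
shifts each LG to start at 0. About 2% of mapped DArT markers are
duplicated under the same name onto a second LG in one map (multicopy
injection); two redundant clone pairs are created at identical true
positions; and five LGs among the three sparsest maps get their order
randomly permuted (wholesale discordance). A single seeded RNG drives
everything, so identical config + seed gives byte-identical files.

What the generator does **not** emulate: pedigree-driven marker sharing
(real marker polymorphism is correlated across related pedigrees, not
i.i.d.), genotyping error and segregation distortion (noise is applied in
map-distance space, not re-estimated from genotypes), piecewise
recombination-rate variation (the per-map distortion is globally affine),
and clustering of duplicated loci. Passing the recovery tests therefore
shows the merge machinery is correct under the stated error structure; it
does not certify performance on maps whose errors violate the affine or
independence assumptions.

Problem sizes used in the shipped validation runs — 11 LGs × 400 markers ×
7 maps, 20 replicates for the noisy-recovery statistics — match the scale
of the motivating study while keeping a full validation run to a few
seconds.

## Known limitations

- Projected (non-backbone) positions inherit regression extrapolation error
  at LG ends; the distal trim removes the worst cases but sub-cM order
  among tightly linked markers is not statistically resolvable by any
  merge method.
- Homology assignment is by maximum shared-marker count; a map whose LG is
  split across two reference LGs will be routed wholly to one of them
  (ties are flagged unassigned rather than guessed).
- When a pedigree supplies alternative framework/comprehensive versions of
  an LG, choosing between them is user configuration (build with the files
  you prefer); no automatic rule is applied.
- Merging maps with different chromosome numbers, and re-estimating orders
  from segregation data, are out of scope.
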