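# Methods

This note records the model, its assumptions, the parameter choices, and the
design decisions taken where the problem left the design open.

## Temporal graph model

Input is a time series of peak tables: per snapshot (1-based, consecutive
integers) a map from molecular formula to normalized peak intensity. A
formula with zero or missing intensity is *not detected* at that snapshot —
no node is created; negative intensities are rejected. Nodes carry
`(formula, snapshot, intensity)` and are unique per (formula, snapshot).
Edges only ever connect consecutive snapshots:

* `SAME_AS` — same formula at t and t+1, property `intensity_trend` =
  I(t+1)/I(t);
* `POTENTIAL_TRANSFORMATION` — product(t+1) = educt(t) + unit delta for a
  unit in the table; several units linking the same pair give parallel
  edges;
* `PREDICTED_TRANSFORMATION` — the TPA-selected subset (below).

After potential edges are computed, nodes without any potential edge are
pruned together with their incident SAME_AS edges; the omitted fraction is
reported. **Pruning is graph hygiene, not data removal**: the graph keeps
the full detection series, and everything that represents a *measurement* —
intensity trends for the TPA predicate, losses/gains for the edge weights,
per-snapshot molecule counts, trend partitions and intensity-weighted
descriptors — is computed from the series. Only structural edge counts
(potential/predicted) refer to the pruned graph. Without this separation
the prediction of a transformation could depend on whether its product
happened to have other potential edges, which has no chemical
justification.

## Transformation units

A transformation unit is a named, signed, integer element delta
(e.g. `-CO2` = ΔC −1, ΔO −2). Matching is exact formula arithmetic — never
a mass tolerance — because upstream formula assignment has already resolved
masses. The group is determined by the sign of the monoisotopic mass delta:
*photo addition* (> 0) or *photo elimination* (< 0); note that `-H2+O`
(oxidation of an alcohol/aldehyde to an acid) is a photo addition by this
rule. Reverse reactions must be listed as separate units; delta vectors are
unique within a table.

The packaged default table has 22 units. Nine are the photochemically
prominent units discussed throughout the DOM photolysis literature
(`-CO2`, `-H2O`, `-SO3`, `-CO`, `+O`, `+O2`, `-H2+O`, `+NO2-H`, `+O-NH`);
the remaining 13 (hydrogenations, hydration/dehydration counterparts,
small CHO-fragment eliminations, `-NH3`, `-H2S`, `-O`) are a reconstruction
of the standard photochemical reaction compilations, since no authoritative
machine-readable source was available when the table was frozen. Users with
a curated set should pass their own CSV (`name,dC,dH,dN,dO,dS[,dP]`).

## The Transformation Prediction Algorithm

A potential edge A@t → B@t+1 becomes predicted iff A's trend is decreasing
and B's trend is increasing. Choices:

* **Margin semantics.** The error margin m (default 0.05, matching a 5%
  measurement error) applies to the intensity *ratio*: trends in
  [1−m, 1+m] inclusive are *consistent*; a change must be strictly larger
  than the margin to count. Ratio rather than absolute difference was
  chosen because the trend property itself is a ratio.
* **Appearing/disappearing formulas.** `strict` (default) requires a trend
  on both ends, so such formulas never participate. `zero_fill` treats a
  formula absent at t but detected at t+1 as increasing (transient
  photoproduct) and one detected at t but absent at t+1 as decreasing
  (fully consumed). The policy is a config flag and is recorded in every
  run report.
* **Order independence.** The predicate is edge-local, so the result does
  not depend on iteration order; the implementation iterates potential
  edges per transition with memoized trend classes.

### Edge weights

The exact reference weighting was not specified beyond its ingredients
(trends and node intensities), so the package adopts equal apportionment:
with loss(A) = I_A(t) − I_A(t+1) (I_A(t) if A disappears) and gain(B) =
I_B(t+1) − I_B(t) (I_B(t+1) if B appears),

    w(A→B) = ½ ( loss(A)/outdeg_pred(A) + gain(B)/indeg_pred(B) ),

where degrees count predicted edges on that transition, parallel unit edges
separately. This is symmetric in educt/product, uses exactly the stated
ingredients, and satisfies a testable conservation law: per transition,
Σ w = ½ (Σ participating losses + Σ participating gains), asserted to
1e-12 relative in the suite.

## Light graph and clustering

The light graph has one node per unique formula (with its full intensity
series of surviving nodes) and one edge per ordered formula pair holding a
record `(transition, unit, predicted?, weight)` per potential/predicted
occurrence — at most one record per (transition, unit). Conversion back
reconstructs nodes, recomputes SAME_AS from the series, and re-materializes
potential and predicted edges; `from_light(to_light(g))` is structurally
identical to `g` (property-tested). The detection series of formulas whose
nodes were pruned is not carried through the light graph.

Label propagation is asynchronous and weighted: the clustering weight of a
formula pair is the **count of predicted records between them, summed over
both directions** (edges are treated as undirected for clustering;
community structure here is not direction-sensitive, and the choice is
switchable). Every node starts with a unique label; per sweep, nodes are
visited in a seed-shuffled order and adopt the neighboring label with the
largest summed incident weight, ties broken by the smallest label. The run
stops when a sweep changes nothing (a converged assignment is a fixed
point) or after `max_iter` sweeps (default 100; non-convergence returns the
current assignment with a warning). Determinism given the seed is a hard
contract. Nodes with only zero-weight (potential-only) edges remain
singletons unless zero-weight adoption is enabled (off by default).

## Analytics

* `transition_stats` — detected-molecule counts, SAME_AS count with its
  increasing/decreasing/consistent partition at the margin, potential and
  predicted counts, and predicted edges per molecule; counts of
  measurements use the detection series (see pruning note above).
* `unit_shares` — share(t, u) among predicted edges per transition; unit
  averages across transitions with predictions; the grand mean over a full
  K-unit tabulation is 1/K by construction. "Relative change first→last"
  is implemented first→last *transition* (shares are per-transition
  quantities); units with zero share in the first transition are flagged
  undefined rather than divided by zero.
* `unit_importance` — per-transition normalized sums of TPA weights per
  unit ("contribution to intensity change"); zero-weight transitions report
  zeros.
* `group_shares` — roll-up of the share matrix into photo addition vs photo
  elimination.
* `weighted_descriptors` — intensity-weighted means of MW, H/C, O/C, DBE,
  AImod, NOSC per snapshot over all detected molecules.
* `cluster_report` — per cluster: size, element-class composition (CHO /
  CHNO / CHOS / CHNOS / other), descriptor means, within-cluster unit
  shares counting only records internal to the cluster (boundary records
  are tallied separately), and the mean of educt+product trends over
  internal predicted records, which is ≈1 when clusters mix educts and
  products symmetrically.

### Descriptor conventions

DBE = 1 + C − H/2 + N/2. NOSC = 4 − (4C + H − 3N − 2O − 2S)/C. The
aromaticity index defaults to the modified variant
AImod = (1 + C − 0.5·O − S − 0.5·H)/(C − 0.5·O − N − S − P), with the plain
variant (full oxygen weight) behind a flag; a non-positive denominator or
numerator maps to 0 so descriptor tables never contain undefined or
negative aromaticity entries. Monoisotopic masses come from one constants
table (standard IUPAC values, ≥ 6 decimals).

## Synthetic data generator

The generator emulates a multi-day natural-sunlight photolysis series: 300
seed CHNOS formulas (C 6–30, H/C 0.6–1.8, O/C 0.1–0.8, 25% N-containing,
12% S-containing), log-uniform initial intensities over three decades, 13
snapshots with a 12-transition dose schedule that ramps over mornings,
peaks at midday, and contains one zero-dose overnight transition. Per
transition, each formula's feasible reactions (active units with rate
constants; decarboxylation and dehydration fast, oxidations intermediate,
heteroatom losses slow) compete first-order: the fraction
1 − exp(−dose·Σk) of the educt's intensity leaves and is split across the
reactions ∝ k, each transfer recorded as ground truth. Noise is
multiplicative log-normal (σ default 0.05, the scale of the 5% error
margin) applied to observed tables only; the true ledger conserves total
intensity exactly unless the optional mineralization sink is enabled.

The reaction cascade is depth-bounded (`max_chain`, default 2): seeds react
and their products react once more, but second-generation products are
terminal. An unbounded cascade grows the formula pool exponentially with
the number of transitions, which neither real DOM (a bounded assignment
space) nor any fixed memory budget resembles.

What the generator does **not** emulate: real DOM's mass- and
structure-dependent reactivity, isomers, ionization competition, detection
limits, or non-conserving intensity normalization. A green recovery test
therefore establishes that the TPA recovers the transformations its
predicate describes — not that it recovers chemistry from real
measurements.

## Numerical and degenerate-input choices

* Boundary trends exactly at 1 ± m classify as consistent (strict
  inequality required to act).
* Structural graph equality rounds floats to 12 decimals, below any
  tolerance used in the suite.
* Empty degenerate cases: a graph with no predicted edges yields zeros in
  `transition_stats`, an error in `unit_shares` (shares would be 0/0), an
  empty weight map, and empty-but-valid exports. `evaluate_recovery`
  defines precision = 1 with no predictions and recall = 1 with empty
  truth.
* All randomness flows from explicit integer seeds (label propagation
  order, simulation); run reports record seeds, margin, policy, and the
  unit-table checksum.

## Known limitations

* Only net reactivity between consecutive snapshots is modeled; multi-step
  pathways within one transition are invisible.
* The predicate treats every intensity change as composition change;
  matrix/ionization effects are out of scope.
* The default unit table's 13 non-named entries are a literature-informed
  reconstruction (see above), not a transcription of a single published
  list.
* Isomers are not resolved: a formula is the identity level throughout.
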