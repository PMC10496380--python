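# Methods

## Scope and model

phytonet implements the computational chain of an affinity-ultrafiltration
ligand-fishing study: accurate-mass annotation of extract constituents, the
enrichment screen that separates receptor binders from the rest, and a
multiplex-network analysis of the binders' predicted targets and annotated
pathways. Target prediction (SEA-style chemical-similarity search) and
pathway enrichment (DAVID/KEGG) are *inputs*, consumed as two-column
mapping tables; the package never re-implements them.

## Annotation arithmetic

Monoisotopic masses are sums of most-abundant-isotope masses (C 12 exactly,
H 1.00782503, N 14.0030740, O 15.9949146, S 31.9720707, P 30.9737615 Da;
the table is a plain dict and extensible). The [M+H]⁺ ion adds the proton
mass 1.00727646 Da, not the hydrogen-atom mass: the cation is short one
electron, and this convention reproduces the reference library's printed
[M+H]⁺ values exactly on the 0.0-ppm rows. Formula parsing accepts plain
Hill notation, underscore-decorated dialects, whitespace, and dot-separated
multi-part formulas (`C14H20O7.NH3`), whose parts are summed; adduct text in
compound *names* is never interpreted — callers supply the effective
formula.

Annotation is a pure ±ppm window test against the library's theoretical
[M+H]⁺ values (default 5 ppm). A peak inside several windows yields several
hits, all flagged ambiguous; resolving isomers (e.g. luteolin vs
scutellarein, identical formula) requires MS/MS and is out of scope. The
enrichment screen keeps hits with area_sample > θ·area_control, strict
inequality, θ = 1 by default and exposed because "larger area" is the only
published rule; a zero control with positive sample area counts as
enriched.

Two caveats about the embedded reference library: recomputing the printed
molecular-weight column reproduces 32 of 34 values exactly at 4 dp, while
two rows were evidently truncated rather than rounded in print (agreement
is within one unit of the 4th decimal for all 34); and the printed 1-dp ppm
errors follow an unstated rounding convention — direct recomputation agrees
to within ~0.35 ppm, and the package always reports the directly computed
value.

## Network construction

Node identity is the raw id string (normalization is the reader's job).
Edges are unweighted and simple; the multiplicity of shared targets is
discarded. Targets referenced by the ingredient map but absent from the
pathway map are tolerated with a warning and contribute no edges — this is
the normal situation for predicted targets that fail pathway enrichment.
Isolated nodes are kept by default so node budgets remain auditable; an
explicit `prune_isolated` step (and `--prune` flag) drops them on request.
The ingredient–pathway edge rule is pure shared-target membership, exactly
as the construction rule states; no per-ingredient significance filter is
applied.

## Statistics

* Average path length on disconnected graphs averages finite distances
  (ordered pairs within components); the diameter is the largest finite
  distance; an edgeless network has no finite distances and raises an
  error rather than returning a sentinel.
* Betweenness uses Brandes' dependency accumulation; the raw pair-sum
  Σ_{j<k} g_jk(i)/g_jk is kept alongside the value normalized by
  (N−1)(N−2)/2. The normalized form is the headline number because
  reference centrality values of this kind (e.g. ≈0.03 on a dense
  90-node pathway network) are only attainable on the normalized scale.
* Closeness uses the Wasserman–Faust correction,
  (r/(N−1)) · (r/Σd), with r the number of reachable nodes, so values on
  disconnected graphs stay in [0,1] and match the connected-graph formula
  when the graph is connected. Isolated nodes get closeness 0 with a
  warning. On a complete graph closeness is analytically 1 and the package
  reports 1 (a reference table printing 0 there is treated as a
  typesetting artifact).
* The power-law exponent γ of the clustering spectrum C(k) ∝ k^γ is an
  ordinary least-squares slope on log C(k) vs log k restricted to
  k ≥ k_min (k_min is a parameter; the reference analysis used 72). OLS on
  binned spectra is the convention this mirrors; MLE power-law fitting is
  deliberately out of scope. The same fit can be applied to P(k).
* Key-node ranking sorts descending by degree, C_d, C_b, C_c or a
  composite (mean of min-max-scaled centralities), with lexicographic
  tie-break for reproducibility.

Correctness of the hand-written graph algorithms is established two ways in
the test suite: an explicit geodesic-enumeration oracle (Floyd–Warshall
distances plus recursive path listing) on 200+ random graphs of ≤ 12 nodes,
and networkx as an independent library cross-check on larger random graphs.

## Synthetic-data generator

`GeneratorConfig` defaults define the emulated study conditions: 6
ingredients, 160 targets, 90 pathways. Pathway annotation uses a
broad/narrow target mixture — each target is "broad" with probability 0.10
(per-pathway inclusion 0.30) or "narrow" (0.02), and the first ~2% of
pathways are "hubs" whose inclusion probability is boosted 2.5×. The
mixture exists because a single independent-Bernoulli probability cannot
jointly produce the reference aggregates: ~479 ingredient–pathway edges
*and* pathway–pathway density ~0.77 (dense pathway co-membership is driven
by a minority of promiscuous signaling proteins). Ingredient→target links
are Bernoulli with p = 0.25. Defaults were calibrated once, by the
closed-form expectations in `expected_edge_counts`, against the published
aggregate counts (160/90/479/3099); Monte-Carlo means over 50 seeds land at
~491 IPB edges and PPI density ~0.79. Per-seed spread is substantial (PPI
density sd ≈ 0.08), as expected for a 90-node graph driven by ~16 broad
targets.

Post-processing: a `hub_fraction` of ingredients (default 2/6, mirroring
the two main active ingredients) is forced to cover all pathways by adding
targets; every pathway keeps ≥ 1 annotated target so full coverage is
attainable; targets with an empty pathway draw are re-drawn once, then
dropped from the pathway map with a log line (they may persist as predicted
targets). The closed-form expectations account for the re-draw and are
exact when both post-processing steps are disabled.

The peak-table generator draws distinct formulas from a built-in set of 38
plausible phytochemical compositions (flavones, coumarins, phenolic acids,
terpenes, alkaloids; pairwise mass gaps > 10 ppm, so ±5 ppm annotation is
unambiguous), perturbs each theoretical [M+H]⁺ by uniform noise within
±noise_ppm (default 2 ppm, matching the reference library's observed error
range of −1.0…+1.0 ppm), and plants exactly `n_enriched` compounds with
sample/control ratio in U(1.5, 5) against U(0.2, 0.95) for the rest.

What the generator does *not* emulate: correlated target sets between
chemically similar ingredients, pathway-size distributions beyond the
two-point mixture, retention-time structure, isotope patterns, and
chromatographic artifacts. Passing tests therefore demonstrate the
correctness of the arithmetic and construction rules and the recoverability
of planted structure — not that real SEA/DAVID output has this statistical
shape.

## Pipeline and formats

The end-to-end run is deterministic given the config and seed (byte-equal
outputs, verified in tests). If the enrichment screen keeps nothing, the
network stages are skipped with a warning. In synthetic mode the screened
compound names become the network's ingredient ids. Networks are written as
Pajek `.net` (1-based indices over lexicographically sorted ids, quoted
labels) and GraphML (node type as a node attribute); both round-trip through
the package's own readers. Every count a run produces (hits, screen
survivors, nodes, edges, dropped targets) is logged at INFO so a run can be
audited against an external report.

## Problem sizes in tests and the acceptance script

Tests run random-graph oracles at ≤ 12 nodes (exhaustive geodesic
enumeration is exponential in the worst case), generator bands at the full
6×160×90 condition over 50 seeds, and the acceptance script reconstructs
the reference-sized networks (96/3593, 90/3099) directly, which the metrics
suite handles in well under a second. Reference-scale statistics that
depend on the unpublished per-ingredient annotation detail (exact edge
counts, clustering coefficients, the specific critical pathway's centrality
triple, γ = −0.95 on the real spectrum) are checked structurally — via the
additivity/consistency invariants, planted-structure recovery and
calibration bands — rather than numerically.
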