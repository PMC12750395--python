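# Methods

This note records the models, parameter choices and numerical conventions
behind `pbnet`, and what the synthetic benchmark does and does not
demonstrate.

## Modified-cosine similarity

Spectra are preprocessed before scoring: peaks within 17 Th of the
precursor are removed (they carry no structural information and inflate
self-similarity), peaks below 0.1% of the base peak are dropped,
intensities are raised to the power 0.5 and the vector is scaled to unit
Euclidean norm. Square-root weighting tempers base-peak dominance and is
the classic molecular-networking convention; the exponent is configurable
in (0, 1]. A spectrum with fewer than `min_peaks_per_spectrum` (default 2)
surviving peaks is flagged unusable: it scores 0 against everything but
remains a network node.

Candidate fragment pairs match directly within `fragment_tol` (default
0.02 Th) or shifted by the precursor mass difference when
`allow_precursor_shift` is on; a pair satisfying both counts once, as
direct. The one-to-one assignment is greedy by descending intensity
product, with ties broken by smaller |Δm/z|, then lower peak indices —
the tie-break makes results deterministic and the score symmetric in
practice. The greedy sum of products of unit-norm vectors is the score,
clipped at 1.

The greedy assignment is not guaranteed optimal. The test suite carries an
exhaustive-assignment oracle (recursive enumeration over candidate pairs,
feasible for ≤ 8-peak spectra): on conflict-free candidate sets greedy and
optimum coincide exactly, and on random small spectra greedy stays within
95% of the optimum. `matchms.similarity.ModifiedCosine` serves as an
independent implementation cross-check; it is never used in the pipeline
itself.

## Network topology

Edges require cosine ≥ `min_cosine` (0.7) and ≥ `min_matched_peaks` (6)
matched pairs. The mutual top-K rule (K = 10) keeps an edge only if each
endpoint ranks the other within its K best neighbours by cosine (ties
ranked by node id). Oversized connected components (> 100 nodes) lose
their weakest edge repeatedly — ties broken toward the lexicographically
smallest (id, id) pair — until the cap holds. These are widely used FBMN
defaults; all four are exposed in configuration, since published networks
are often built with tuned values. Singletons (degree 0) are counted
inside node totals, matching how network sizes are conventionally
reported.

Determinism is a contract: node and edge insertion is sorted everywhere,
and GraphML export re-sorts before writing, so identical inputs produce
byte-identical files.

## Mass conventions

All ion species are treated as [M+H]⁺; other charge states are rejected
explicitly rather than silently mishandled. Proton mass 1.007276 Da.
Modification deltas ship as data (`data/modification_deltas.csv`):
malonylation +86.0004 (C₃H₂O₃), hydrogenation +2.0157, dehydrogenation
−2.0157, oxygenation +15.9949, and glycosylation +162.0528 (disabled by
default — glucoside loss is plausible for this compound class but not part
of the core vocabulary). Each exact mass is verified in the tests against
a sum-of-monoisotopic-atomic-masses oracle. The built-in PB reference
table contains only masses derivable from the [M+H]⁺ ion at m/z 643.2754
(neutral 642.2681 Da and its malonylated analog 728.2685 Da); a real
screen should supply a full reference table.

ppm error is signed, `1e6 × (observed − theoretical)/theoretical`. The
MS¹ and analog-delta tolerance defaults to 5 ppm; whether an analog search
should use a wider tolerance than MS¹ matching (the measured-minus-measured
difference carries √2× the single-measurement error) is left to the user —
one configurable value is used for both, which is the conservative choice.

## Annotation layers

Analog propagation extends one edge out from each MS¹-matched anchor. The
neutral-mass difference to the neighbour is compared against every enabled
delta, tolerance applied on the neighbour's absolute neutral mass; the
best (smallest-deviation) delta wins, and when both spectra are available
the fragment-shift check records how many analog peaks are explained as
parent + Δ (shifted) or parent ± tol (conserved). Conserved takes
precedence, so a zero delta counts identical peaks once. Propagation is
deliberately not chained transitively: each analog call is anchored to a
directly connected reference match, keeping the evidence interpretable.

In-source flagging requires a 1 ppm precursor-to-fragment coincidence plus
co-elution within `rt_tol` (0.1 min; chromatographic peaks in this kind of
gradient are a few seconds wide). The flag never removes a node: an
apparent artifact can be a genuine metabolite at a different retention
time, and only the retention-time comparison distinguishes the two.

Isomer groups above four nodes per compound are flagged rather than
collapsed: four is the stereochemical expectation (cis/trans at C15 ×
C8² epimers), and exceedances usually indicate broad chromatographic
peaks or on-column hydrolysis, which deserve inspection, not deletion.

## Informed overlays

The 420 nm filter takes the maximum trace absorbance in ± `rt_window`
(0.1 min) around each feature's RT (plus a signed detector-to-MS offset,
default 0 — the plumbing delay is instrument-specific and should be
measured, not guessed). The default threshold is 5× the trace median, a
robust baseline floor; any fixed mAU value can be supplied. Border weight
is min–max-scaled RT with the all-equal case pinned at 0.5. Pie shares
are intensity fractions (zero vector when a feature has zero total), and
the activity score is the share-weighted mean of the four ordinal FRAP
classes, hence invariant to uniform intensity rescaling and bounded by
[0, 3]. Cluster prioritization ranks components by (count of nodes with
score ≥ 2.5, mean score, size); 2.5 sits between "very active" and
"highly active", so the count tracks nodes dominated by the top activity
classes. A second assay table (e.g. cellular ROS) can be overlaid in
parallel; scores are kept separate, never averaged, because the two
assays can rank fractions differently.

## Synthetic benchmark

The generator emulates the structures the method exploits, with truth
defined by its manifest rather than by chemistry — scaffold masses are
fixed arbitrary constants:

- Each PB family has a core [M+H]⁺ (643.2754 for the first family), six
  shiftable fragments (losses 18.0106, 32.0262, 76.0160, 104.0473,
  146.0579, 188.0685 Da — the first three are the real small-molecule
  losses, so the signature detector is exercised genuinely) and two
  conserved ring-A-side fragments (losses 108.0211, 126.0317 Da).
  Modification analogs shift the precursor and the shiftable fragments by
  the delta; conserved fragments keep their absolute m/z.
- Three stereoisomer copies of each anchor elute 0.3 min apart; analogs
  occupy subsequent 0.3 min slots from 5.0 min. All families share the
  slot grid, so 420 nm bands (PxB-class features only) never bleed into
  the windows of colourless analogs.
- One in-source artifact per family: its precursor is the parent's
  measured ring-A-loss fragment with ~0.2 ppm residual error (same-run
  ion), co-eluting within 0.02 min, with sub-fragments of the same
  scaffold so it joins the family cluster.
- m/z jitter is 2 ppm (1 s.d.) everywhere else — inside the 5 ppm
  matching tolerance for typical draws, outside the 1 ppm co-elution
  window for uncorrelated ions, so both code paths run. Intensities get
  10% log-normal noise plus three low-intensity random peaks per
  spectrum.
- Decoys (48 by default) come in families of four sharing a random-walk
  scaffold and precursor, forming background clusters with no PB deltas.
  Decoy RTs avoid the 420 nm bands so the UV truth stays exact.
- Per-fraction intensities put 60% of a feature's signal into the
  fraction its RT maps to and 20% into each neighbour (a 20 min run over
  13 fractions). Fraction activity classes default to the published
  four-class FRAP pattern of a 13-fraction polarity separation (F4/F5
  highest), and PB families elute into the highest-activity fractions.

Everything derives from one integer seed through a single `numpy`
generator; equal seeds give byte-identical files.

What passing the benchmark shows: the pipeline recovers planted cluster
membership, modification identities, in-source artifacts and the UV/
bioactivity prioritization under realistic mass error and intensity
noise. What it does not show: performance on real chromatography (peak
shape, coelution of unrelated compounds), isotope envelopes and adduct
series (not modelled), true fragmentation chemistry, or library-scale
false-discovery behaviour. One stochastic caveat is inherent to the
conditions: with 2 ppm (1 s.d.) mass error and a 5 ppm gate, an analog
occasionally draws a > 2.5 σ error and is correctly rejected by the
tolerance — at such seeds the analog naming accuracy drops below 100%
(e.g. 7/8) even though the method behaves as specified.

## Problem sizes

The default benchmark (64 features, ~10 peaks per spectrum) keeps the
full O(n²) pair scan, annotation and overlay pipeline under two seconds;
the oracle-equivalence checks use 1000 random ≤ 8-peak pairs and ~25
random ≤ 30-node graphs, sizes at which exhaustive enumeration is exact
and fast. These sizes were chosen so that every property is checked
against a brute-force oracle rather than a sampled approximation.

## Known limitations

- Only [M+H]⁺ species; ion-identity networking (collapsing adduct
  series) is out of scope.
- The deposited-data comparison (cosine 0.9 between two published
  phylloxanthobilin spectra) needs the zenodo archive
  (10.5281/zenodo.17243849); the corresponding test fails with
  instructions until the file is supplied locally.
- Quantification-table column layouts vary between export tools; the
  reader auto-detects the common feature-table convention and accepts a
  column map for anything else.
- Ring-loss masses for the signature detector are configuration, not
  constants: published values differ by PB substitution pattern.
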