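# Methods

This note records the models, conventions, parameter defaults, and numerical
choices behind each `mitocomp` module, and states explicitly what the package
does and does not compute.

## Coordinates and annotation arithmetic (`genome`, `annotation`)

* Coordinates are 1-based inclusive on a circular molecule; a feature with
  `stop < start` wraps the origin. `FeatureRecord.size` accounts for wrapping.
* The signed intergenic value between adjacent features is
  `IN = start(downstream) − stop(upstream) − 1` (positive = spacer,
  negative = overlap), evaluated over all 38 adjacencies including the wrap
  from the last feature back to the first. The closure identity
  `Σ sizes + Σ signed IN = genome length` is checked exactly.
* Stop-codon classes: `complete` (TAA/TAG/AGA/AGG of the vertebrate
  mitochondrial code), `incomplete:TA-` (size ≡ 2 mod 3), `incomplete:T--`
  (size ≡ 1 mod 3); anything else is `irregular`. Minus-strand genes are read
  on their coding strand.
* Gene-order comparison uses circular unordered adjacency sets
  (breakpoint distance), so rotations of the same order compare equal.

## Composition (`composition`)

* Percentages use the ACGT count as denominator; skews are
  `(A−T)/(A+T)` and `(G−C)/(G+C)` and return NaN on zero denominators.
* Per-class composition concatenates features *per feature* by default, so
  overlap positions count once per overlapping gene — this matches how
  published annotation tables total gene sizes (PCG total 11,425 bp includes
  the 14 shared bp). `dedupe=True` uses the union of positions instead.
* Report rounding: percentages to 2 dp, skews to 3 dp, rounded last.

## Codon usage (`codons`)

* Vertebrate mitochondrial code (NCBI translation table 2) throughout; 60
  sense codons. Counting reads each CDS in frame from position 1, drops a
  trailing partial codon, excludes one terminal complete stop, and warns on
  (and skips) internal stops.
* RSCU(c) = count(c) × family size / family total; zero-usage families give
  NaN (undefined), not 0. CDspT is per-mille of total sense codons.
  "Low usage" defaults to RSCU ≤ 0.5 with NaN excluded.

## Ka/Ks (`kaks`)

* Nei–Gojobori (1986): per-codon synonymous site fraction over *non-stop*
  single-nucleotide neighbors (S + N = 3 per codon), equal pathway weighting
  for multi-difference codons with stop-traversing paths excluded (falling
  back to all paths when every path hits a stop), sites averaged over the two
  sequences, Jukes–Cantor correction `d = −¾ ln(1 − 4p/3)` (NaN with a warning
  at p ≥ ¾). Codons containing gaps, ambiguity codes, or stops are skipped
  pairwise. Ratio is NaN when Ks = 0.
* **Estimator bias**: the ratio of two JC-corrected proportions is a ratio
  estimator and is biased upward at finite length (Jensen's inequality).
  Measured on this package's own generator at 300 codons, divergence t = 1.0
  expected neutral substitutions per codon: mean Ka/Ks at true ω = 1 is
  **1.022 ± 0.006** (1,000 replicates). The bias grows as divergence falls
  (≈1.05 at t = 0.3). Tests at ω = 1 therefore sit close to the 1.96·SEM
  boundary by the nature of the estimator, not because of an implementation
  error; the acceptance script reports mean and SEM so the reader can judge.
* Gene ranking is ascending by ratio, ties (and NaN) broken alphabetically.

## tRNA cloverleaf (`trna`)

* Folding is a bounded grid search over layout segment lengths (leader 0–1,
  acceptor stem 6–7, connectors, DHU stem 0 or 2–4 with its loop, anticodon
  stem 4–5 with a fixed 7-nt loop and the anticodon at its center, variable
  region 2–12, TψC stem 4–5 with loop 4–8, 3′ tail 1–4), maximizing the number
  of Watson–Crick + G·U pairs. Input length 55–95 nt. Ties are broken
  deterministically by enumeration order; an optional `anticodon=` constraint
  restricts the anticodon-loop placement (with unconstrained fallback).
* G·U (wobble) pairs are tallied per stem; `dhu_present` requires ≥ 2 DHU
  pairs; a structure scoring < 12 pairs is flagged unfoldable, not an error.
* This is a geometry search, not thermodynamics: no energy model, no
  pseudoknots, no modified bases.

## Control region blocks (`control_region`)

* Each consensus motif (bundled: ETAS 30 nt, CSB-D 27, CSB-I 41, CSB-II 49,
  CSB-III 34) slides over the alignment; the window with maximal mean identity
  wins (leftmost on ties) and must reach ≥ 60% identity to count as found.
  The canonical order ETAS < CSB-D < CSB-I < CSB-II < CSB-III is enforced by
  starting each search after the previous found block.
* A column is conserved iff all rows carry the same non-gap base; percentages
  are computed from integer counts and rounded last (27 columns with 12
  variable → 44.44%).

## Phylogenetics (`phylo`)

* Supermatrix concatenation with a 1-based partition map; `union` policy
  gap-fills missing taxa with a warning.
* Neighbor joining is the Saitou–Nei algorithm; negative branch lengths are
  clamped to 0 with a warning.
* Likelihood is Felsenstein pruning with site-pattern compression and
  per-node scaling. GTR-family matrices are diagonalized via the symmetrized
  form `B = D^½ Q D^-½` (valid for reversible models), normalized to mean
  rate 1 at the stationary frequencies. +Γ uses Yang's four discrete
  categories (mean category rates), +I a simple invariant-site mixture.
* Free-parameter counts for BIC (k): 2n−3 branch lengths plus 0 (JC69),
  1 (K2P), 4 (HKY85: 3 frequencies + κ), 8 (GTR: 3 + 5 exchangeabilities),
  +1 for α, +1 for p_inv; BIC = −2 lnL + k ln(sites). Branch lengths are
  optimized by coordinate descent with Brent's method (bounds 1e−8 to 10),
  with a global tree-scale pass after each model-parameter step to avoid the
  α/length ridge.
* Bootstrap is column resampling with splits canonicalized as the side
  excluding the first taxon; supports are percentages over B replicates.
* Problem sizes are the package's own choice for desk-scale verification:
  tests use 3–10 taxa and hundreds to thousands of sites, where NJ on
  additive matrices and pruning-vs-exhaustive-sum checks are exact.

## Divergence dating (`timetree`)

* RelTime-style relative-rate scaling: relative node heights are computed
  bottom-up with geometric-mean reconciliation of sibling subtree rates, ages
  propagate top-down, and the whole tree is scaled so the MRCA of the
  calibration taxa equals the calibration point (default: interval midpoint;
  a point estimate must lie inside [lo, hi]). Output trees are ultrametric to
  machine precision; calibrations on leaves and non-bifurcating roots are
  rejected.
* On strict-clock branch lengths the transform recovers all true node ages
  exactly (well within the 5% tolerance the tests assert). Recovery from
  *sequence-estimated* distances is noise-limited: at 500–20,000 sites the
  young-node relative errors routinely exceed 5%, so the sequence-level
  pipeline is verified for topology, ultrametricity, and calibration
  consistency rather than a 5% age bound.

## Synthetic generators (`simulate`)

* `gen_mitogenome` realizes the bundled reference geometry (or any closed
  spec): background bases from the target composition, designed cloverleaf
  tRNAs (loops drawn from {A, C} so the planted layout is the unique maximal
  pairing), CDSs with the requested start codon and stop class, planted CR
  motifs, a locked-position repair pass that removes accidental in-frame
  stops, and a whole-genome composition rebalance over unlocked positions
  (skipping any change that would create an in-frame stop) so realized base
  percentages land within a fraction of a percent of the target. A final
  verification pass re-checks every planted constraint.
* `evolve_codon_pair` is a Gillespie simulation per codon: each non-stop
  single-nucleotide neighbor is reached at rate μ·1 (synonymous) or μ·ω
  (nonsynonymous), μ = 1/9, for total time t (expected neutral substitutions
  per codon). Stops are never created.
* `sim_alignment_on_tree` draws root states from the stationary distribution
  and evolves sites independently down the tree (+Γ/+I honored);
  `clock_tree`/`random_tree` return trees (and, for clock trees, true node
  ages keyed by leaf-label sets).
* All generators are deterministic given their seed.

## Scope and limitations

* No empirical result is asserted anywhere in the test suite that the code
  does not itself compute from the bundled annotation table or from synthetic
  data with planted ground truth. Results that require external accessions
  and the original third-party tools (real per-gene Ka/Ks values, real wobble
  counts, real CSB windows, a specific model-selection outcome and dated
  topology) are out of scope and are replaced by oracle-equivalence and
  recovery properties.
* Alignment construction is out of scope: codon alignments and CR alignments
  are inputs (the generators provide aligned data).
* The likelihood machinery covers reversible 4-state DNA models only; no
  codon or amino-acid models, no ML dN/dS (codeml-style), no topology search
  beyond NJ, no Bayesian dating.
* The tRNA folder scores pair counts, not free energy; the CR block finder is
  consensus-identity based, not an HMM.
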