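# Methods

This note documents the models and procedures implemented in `hoxscan`,
the defaults and why they were chosen, and what the synthetic benchmark
does and does not demonstrate.

## Generalised profiles

A profile for homology group *g* is built from a multiple alignment of
that group's homeodomains. Columns whose gap fraction exceeds
`max_gap_fraction` (default 0.5) are dropped; the remaining match
columns define the profile length (≈60 for homeodomain alignments).
Scores use the average-score (substitution-matrix extrapolation)
construction:

    M[i][a] = Σ_b f(b, i) · S(a, b)

where the column frequencies are smoothed with pseudo-observations of
the background composition,

    f(b, i) = (c(b, i) + w · bg_b) / (n_i + w),

`c(b, i)` being gap-excluded counts, `n_i` the column's observed count,
and `w` the `pseudocount_weight` (default 1.0, i.e. one background-
distributed pseudo-sequence per column). The background defaults to the
overall composition of the training alignment itself. `S` defaults to
BLOSUM62 (via Biopython). Unknown residues ('X' and other ambiguity
codes) are excluded from the counts and contribute score 0 when they
appear in queries.

This construction guarantees the extrapolation property: every match
position assigns a finite score to all 20 residues, graded by
substitutability with the observed column (a G-only column scores A
above W).

Design note: position-specific gap weighting, as used by some profile
suites, is not implemented. Gap penalties are position-uniform affine
(default open 11, extend 1, the common protein-search defaults). On
nearly gapless 60-residue homeodomain alignments position-specific gap
weighting has almost nothing to act on, and uniform penalties keep the
scorer exactly checkable against an enumeration oracle.

## Scoring

Queries are scored by affine-gap dynamic programming (Gotoh three-state
recurrences, vectorised row-wise; query-consuming gaps within a row are
resolved with a running-maximum transform of the affine penalty).

* **local** (default): cell scores are floored at 0 and the maximal
  scoring segment is reported, so full-length proteins can be scored
  without excising the homeodomain first. Ties are broken
  deterministically: earliest query start, then shortest segment.
* **semiglobal**: the full profile must align; query overhangs are
  free. Useful when queries are pre-excised domains.

The affine convention `gap_open ≥ gap_extend` is enforced on profiles:
below it, the per-run cost `open + extend·(len−1)` is no longer the
cost of an optimal gap decomposition and the model is not well defined.
Scores are used raw — not converted to E-values or probabilities —
because the discriminant layer is trained directly on score vectors.
For tiny instances the DP is verified against an independent
brute-force enumeration of all gapped alignments (exact equality).

## Discriminant layer

Classification is Gaussian linear discriminant analysis on the score
vectors: per-class means, one pooled covariance, configurable priors.
Posteriors are computed in log space with a log-sum-exp normalisation.
On 2-class problems this reduces to the closed-form Bayes ratio, which
the tests check to 1e-9; on multi-class data the implementation is
cross-checked against scikit-learn's LDA (which is never used as the
implementation).

* **Priors.** The control class carries a deliberately high prior —
  default 0.90, the remainder spread equally over the groups — so
  borderline sequences are rejected into CTL rather than assigned to a
  group. The exact value is configurable per classifier version.
  Raising the CTL prior can only move calls toward CTL (the non-CTL
  log-posterior differences are unchanged), a monotonicity the tests
  assert.
* **Shrinkage.** The pooled covariance may be shrunk toward its
  diagonal: `Σ(λ) = (1−λ)·S + λ·diag(S)`. With `shrinkage="auto"` the
  intensity λ is the Ledoit–Wolf estimate computed on the within-class
  centred data. The diagonal target (rather than Ledoit–Wolf's scaled
  identity) preserves the very different variance scales of profile
  score columns; the LW intensity is kept because it adapts to the
  sample size. With `shrinkage=0` a singular pooled covariance is an
  error that names the remedy.
* **Ties.** Exact posterior ties go to CTL when CTL is involved,
  otherwise to the lexicographically first class. This is implemented
  structurally: classes are ordered CTL-first then lexicographically,
  and the first argmax wins — conservatism by construction.
* **Variable selection.** Greedy forward selection: starting from the
  empty set, repeatedly add the profile that most improves LOOCV
  geometric accuracy; stop when no candidate improves it by more than
  1e-6. Additions must strictly improve, so fewer features win ties by
  construction; at least one profile is always selected.

## Evaluation

* **Geometric accuracy** is the geometric mean of per-reference-class
  sensitivities, `(Π_k TP_k/n_k)^(1/K)`. One dead class drives it to
  zero, which is the point: a classifier cannot buy headline accuracy
  on large classes while abandoning small ones. The defining reference
  for this statistic in the profile-classification literature does not
  reprint the formula; the geometric mean of sensitivities is adopted
  here and stated prominently as this package's definition. For
  relaxed versions — which by design misroute non-Hox homeobox genes —
  the accuracy is computed restricted to the Hox classes
  (`restrict_to`), which underestimates the global accuracy.
* **LOOCV** refits the discriminant with each sequence held out and
  aggregates the held-out calls. Profile construction and variable
  selection are *not* nested inside the folds by default (scores are
  fixed once), which is mildly optimistic; selection can be re-run on
  any fold subset by the caller for a stricter protocol. The reports
  state exactly what was cross-validated.
* **Permutation tests** recompute the LOOCV geometric accuracy under
  uniformly random label permutations and report the add-one-corrected
  p-value `(1 + #{null ≥ observed}) / (1 + n_perm)`, which can never be
  exactly zero. With 99 permutations the resolution floor is p = 0.01.

## Synthetic benchmark

The generator emulates the structure of the real task. A single
proto-consensus (length 60, drawn from a BLOSUM62-style average protein
composition) is mutated into six group consensuses — labelled after the
real broad classes ANT/CENT/POST and the ParaHox groups GSX/XLOX/CDX —
with per-consensus divergence `1 − √0.70`, so pairwise consensus
identity is ≈70%, mimicking closely related homology groups. Group
members are per-site mutated copies (default substitution rate 0.15,
indel rate 0.01 applied after the substitution step, so each group also
yields an ungapped true alignment for profile training). The default
set has 20 members per group plus 100 random decoys labelled CTL.

A seventh, optional "HOMEO-like" consensus models non-Hox homeodomain
proteins: related to every group but belonging to none. Its members
mutate at `homeo_divergence = 0.20` — only modestly above the group
rate. This value matters: such decoys must be domain-like enough that a
control class trained on random sequences alone fails to absorb them
(the relaxed behaviour), while adding them to the control class makes
rejection near-perfect (the non-relaxed behaviour). At much higher
divergence the decoys drift into the random-score region and both
versions trivially reject them, which is not what real non-Hox
homeodomains do.

What passing the synthetic suite shows: the full pipeline — profile
construction, DP scoring, discriminant training, LOOCV — recovers
planted family structure at realistic within-family divergence, rejects
random sequences at the stated rate, degrades monotonically with
divergence, and is calibrated under label permutation. What it does not
show: performance on real proteomes. Real homeodomain families have
position-specific conservation structure (helix 3 is far more conserved
than the N-terminal arm), insertion hotspots, and non-i.i.d. residue
correlations that the per-site mutation model does not reproduce; the
synthetic consensus-cloud geometry is also more homogeneous than real
group score distributions.

## Versions and screening

`build_version` assembles a classifier from per-group alignments:
profiles, labelled training scores (alignment rows plus generated
RANDOM sequences — count `max(200, 2 × largest group)` by default,
drawn from the training-set composition so the control class occupies
the realistic score region — plus HOMEO decoys for non-relaxed
versions), the trained discriminant, and a candidate-filter threshold
set to the 95th percentile of the RANDOM best-score null distribution.
Every bundle records seeds, input hashes and the package version, and
rebuilding with the same config and seed is byte-identical.

`scan_proteome` filters candidates by best profile score, classifies
them, and joins non-CTL calls to gene coordinates into per-scaffold
layouts ordered by start, with strand and inter-gene distance. No
automatic "clustered / not clustered" call is made — real cluster
descriptions are qualitative, and inventing a distance threshold would
suggest precision the method does not have.

## Problem sizes and numerical choices

The test suite and the acceptance script run the synthetic suite at its
default size (220 sequences, 6 profiles), 5 replicates per divergence
level on the grid {0.05, 0.15, 0.30, 0.45}, 99 permutations for the
informative permutation test and 19 for each of the 20 null-calibration
replicates — sizes chosen so the whole stack re-runs from scratch in a
few minutes on one core while leaving the measured contrasts far from
their decision boundaries. All randomness flows from explicit seeds
through `numpy.random.default_rng`; derived seeds stay below 2^31.
Posterior maps are asserted to sum to 1 within 1e-9; DP/oracle equality
is exact to 1e-9; model and profile JSON round to 10 decimals, which is
below every decision tolerance in the package.

## Known limitations

* Published profile sets cannot be reproduced bit-for-bit: the original
  training alignments are distributed as accession lists, and the exact
  profile-construction parameters used upstream are not printed.
  Raw scores are therefore version-specific; trained bundles are
  self-contained and comparisons should stay within one bundle.
* Whether to score full proteins (local mode) or pre-excised domains
  (semiglobal) is left to the caller; both are provided, local is the
  default.
* LOOCV reuses globally computed scores and the globally selected
  variable set, as noted above.
* The vertebrate fine-grained PG1–14 sub-classification with nested
  orthologous groups is representable in the config format (group
  labels are arbitrary strings) but no published sub-group training
  data ships with the package.
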