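# Methods

## The predictor contract

Every analysis in this package runs against a *predictor*: an object with
`predict(sequence, fold) -> (log_counts, profile)` returning the natural-log
total accessibility counts and a non-negative per-base count profile over the
central window, and `contributions(sequence, fold)` returning per-base
attribution scores.  Defaults mirror the common base-resolution accessibility
model setup: a 2,114-bp input window, a 1,000-bp central profile window, and
an ensemble of five cross-validation folds whose mean is reported.  Profiles
are counts (i.e. softmax-normalized shape already scaled by the exponentiated
log counts), so downstream code never needs the model's logits.  Trained deep
models satisfy this contract in production; here a planted-effect oracle
stands in so that every statistic has a known ground truth.

## The planted synthetic oracle

`PlantedModel` computes, for a sequence:

    y = baseline + sum(marginal effects of exact consensus matches, both strands)
      + sum(interaction terms over co-occurring match pairs)
      + fold jitter

* **Marginal effects** are per-consensus signed constants in natural-log
  counts; negative values model motifs that reduce accessibility.
* **Hard interactions** add their magnitude only when the realized
  orientation and edge-to-edge gap match the rule exactly; orientations are
  canonicalized modulo reverse complement of the whole insert (3 codes for
  an identical pair, 4 for a distinct pair), using the same conventions as
  the marginalization engine so the planted optimum is recoverable by
  construction.
* **Soft interactions** are orientation-agnostic and multiply the magnitude
  by a logistic gap kernel `1 / (1 + exp((gap - 60) / 15))`: ~1 at contact,
  ~0.5 at 60 bp, below 0.07 past 100 bp, effectively zero by 150 bp.  The
  midpoint and scale were fixed once to make soft synergy detectable across
  a 20–150 bp separation band while decaying to additivity beyond ~100 bp,
  the behaviour expected of nucleosome-mediated cooperativity.
* **Fold jitter** is an additive Gaussian keyed deterministically on
  (sequence content, fold, seed) via a splitmix64 hash and Box–Muller, so
  predictions are reproducible across platforms without carrying RNG state.
  Default sd is 0.05 log counts, a realistic scale of fold-to-fold spread
  for an ensemble of well-trained models.

Contribution scores place each match's realized effect (marginal plus half
of any firing pair term) across its span — proportionally to |CWM| when one
is registered, else uniformly — with sub-1e-3 noise elsewhere.  Hypothetical
(counterfactual) scores carry the actual-base contribution in the observed
base's row and near-zero values in the alternates, which is what neutral-base
ablation consumes.

What the oracle does **not** emulate: saturation and sub-additivity of real
models, sequence-soft matching (it requires exact consensus matches), Tn5
sequence bias, and receptive-field edge effects.  Passing tests therefore
validate the *analysis machinery* — editing, bookkeeping, statistics,
classification logic — not any property of trained models.  One honest
artifact of exact-match planting: substituting a block next to background
bases can occasionally spell a new match across the junction, perturbing a
single background/arrangement cell; at the study scale (100 backgrounds)
this shifts arrangement means by ≲0.01 log counts and does not affect
classification.

## Background libraries

Backgrounds are sampled base-wise at a target GC fraction (default 0.5 ±
0.02), with occurrences of any planted consensus or its reverse complement
locally resampled and the sequence rejected if constraints cannot be met.
This emulates GC-matched, motif-free non-accessible regions; it does not
model genomic repeat structure or dinucleotide composition.

## Marginalization

A motif's marginal effect is the mean over backgrounds and folds of the
change in predicted log counts after substituting its consensus into the
window centre.  For pairs, the two oriented blocks are centred as a whole
with `gap` background bases left intact between them (each insertion is an
independent substitution; 0 = abutting).  "Distance" throughout is the
edge-to-edge gap, with the centre-to-centre distance
(`gap + (lenA + lenB)/2`) reported alongside.  Per (background, fold,
arrangement) the table records y0, yA, yB, yJ and the derived dA, dB, dJ and
dS = dA + dB, the log-additive (multiplicative-in-counts) expectation for
independent effects.  dA/dB are computed once per (background, fold) and
shared across arrangements.  Iteration order is fixed (orientation in
canonical order, ascending gap, background, fold) so tables are
byte-reproducible.

## Synergy calling and syntax classification

* **Optimum**: the arrangement with the greatest mean dJ; ties break to the
  smallest gap, then canonical orientation order.
* **Test**: one-sided Wilcoxon signed-rank on the per-background
  (fold-averaged) differences dJ − dS at the optimum, BH-corrected across
  the batch of composites screened together.  Synergistic requires adjusted
  P < 0.001 **and** mean dJ − dS > 0.15 log counts.
* **Hard**: any arrangement whose mean dJ lies more than 4 standard
  deviations above the across-arrangement mean (z computed over all
  per-arrangement means, optimum included, sample sd).
* **Soft**: mean dJ − dS > 0.15 at any arrangement whose gap lies in
  [20, 150] bp (edge-to-edge; configurable, since separation could also be
  read centre-to-centre).
* Composites that are both are reported hard-dominant.  By default syntax
  labels are only attached to synergistic composites; a flag reports them
  unconditionally.
* **Abstention**: the interpretation guard computes the mean fraction of
  total |contribution| mass falling inside the inserted-base mask of edited
  sequences and abstains below 0.5.  This check is traditionally done by
  eye; making the threshold explicit keeps it reproducible, and it is
  configurable and logged.

Wilcoxon details: zeros are dropped before ranking; the exact null
distribution is used for n ≤ 25 without ties, otherwise the normal
approximation with tie correction and no continuity correction.  With the
default conditions (100 backgrounds) the normal path is the one exercised.
Because the optimum is selected as a maximum over many noisy arrangement
means, null composites have systematically sub-uniform raw P values
(selection bias); the minimum-effect gate (0.15, far above the selection
bias of ~3 standard errors) is what keeps the null calibration clean, and
the seeded null battery verifies zero synergistic calls across 50 additive
pairs.

## Study conditions used by the validation batteries

The synthetic batteries fix: 100 background sequences of 2,114 bp, five
folds, jitter sd 0.05, marginal effects U(0.3, 0.6), interaction magnitudes
U(0.3, 0.5), hard gaps in {0, 5, 10, 15} (protein–protein interaction
length scales), random distinct non-palindromic 8-mers as consensi, and a
gap grid of 0–200 bp in steps of 5 (recovery battery) or 10 (null battery).
The step-5 grid contains every planted hard gap, so grid reduction cannot
displace a planted optimum; it only reduces compute relative to the
exhaustive 0–200 single-bp scan.

## Instance processing

* The **greedy hit caller** is matching pursuit on a 4×N contribution
  track: repeatedly select the (motif, offset, strand) with the highest
  Pearson correlation to the residual, record a hit at or above the
  similarity threshold, subtract the least-squares-scaled CWM, and stop
  when nothing qualifies.  This replaces sparse-regression hit calling with
  a procedure verifiable against brute-force scanning on small tracks; the
  downstream filters are implemented exactly as specified: motifs whose
  strand-aligned mean instance-CWM correlates < 0.9 with the input CWM are
  dropped wholesale, and same-label instances overlapping by > 3 bp are
  deduplicated keeping the highest hit correlation (ties: leftmost, then
  first in input — input-order invariant).
* **Context annotation** is evaluated at the instance centre with
  precedence promoter (± 2 kb of a TSS) > exonic > intronic > distal; the
  precedence order is a choice since an instance can satisfy several.
* **Distance binning** uses half-open 10-bp bins over [0, 250); distances
  of exactly 250 are excluded; z-scores are computed across bins within
  each motif (constant non-zero rows give z = 0; empty rows are flagged
  undefined).
* **Co-occurrence** uses one-sided Fisher exact tests on peak×motif 2×2
  tables, BH-corrected across all pairs in a context, significant at
  adjusted P < 0.05.
* **Footprints** sum insertion counts over 500-bp windows centred at
  instances and divide by the mean of the outer 10% of positions on each
  side (the local background accessibility); zero flank mass is an error,
  truncated windows are skipped with a warning.

## Tn5 coordinate conventions

The Tn5 homodimer duplicates a 9-base span: with the event centre at c, the
first duplicated base is c−4 on the plus strand and c+4 on the minus
strand.  Fragments run from one event's plus insertion to the next event's
minus insertion, stored half-open, so a fragment's plus insertion is its
`start` and its minus insertion is `end − 1`.  Under this bookkeeping the
+4/−4 scheme maps both mates of a shared event to the consensus coordinate
c exactly, while the legacy +4/−5 scheme (correct only under an
end-inclusive reading) leaves a constant 1-bp mismatch — per event, not
merely on average.  The simulator and the offset corrector share this one
convention so the claim is checkable event by event.

## eQTL enrichment

Variant-gene pairs are deduplicated keeping the higher fine-mapping PIP.  A
variant overlaps an instance iff `start ≤ pos < end`.  Enrichment shuffles
permute the signed aFC values across variants without replacement
(positions fixed, direction margin preserved), recounting per (motif,
direction); 100,000 shuffles per context at production scale, 10,000 in the
desk-scale recovery fixture.  The enrichment score is observed over mean
shuffled count; the empirical P uses the strict inequality with a +1
pseudo-count on numerator and denominator so sampled P never reaches zero
(the exhaustive-enumeration mode reports the plain proportion, which is the
quantity the sampling estimates).  Significance requires BH FDR < 0.05 and
the observed count above the empirical 97.5th percentile of shuffled counts
(the "95% CI" is percentile-based; a normal approximation was the
alternative).  The strict inequality makes P values anti-conservative by
one discreteness step when counts are small; the percentile gate absorbs
this, and the calibration test uses fixtures with enough overlapping
variants that the step is negligible.  Degenerate cells are explicit: zero
observed gives score 0; zero mean shuffled with positive observed flags an
infinite score (P still finite), matching the convention of reporting
OR = ∞ in the Fisher meta-test when a zero cell forces it.

## Numerical and degenerate-input policy

All coordinates are 0-based half-open.  Consensus ties break to the earlier
base in A<C<G<T.  CWM similarity is the maximum Pearson correlation over
ungapped offsets with at least 50% overlap of the shorter matrix
(zero-padded outside), optionally over the reverse complement; constant
matrices are flagged degenerate with similarity 0.  Trimming keeps the
contiguous span between the first and last position at or above 30% of the
maximum per-position |contribution| total (flank trimming; interior dips are
retained so motifs stay gapless), and is idempotent.  All-zero CWMs,
empty libraries, empty instance sets, unknown offset schemes and
out-of-range parameters raise typed errors rather than returning silently.

## Problem sizes in the shipped validation suite

The test batteries use 60 pairs (20 hard / 20 soft / 20 null) for syntax
recovery and 50 additive pairs for null calibration, 1,000 shared
transposition events for the offset check, 10,000 shuffles for eQTL
recovery, and 150,000 simulated events / 10,000 anchors for footprint
flatness — sizes chosen so the whole suite completes in a few minutes on
one CPU while keeping every statistical margin wide (the recovery battery
passes at 100%, against a 95% requirement).
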