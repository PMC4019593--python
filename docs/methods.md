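# Methods

## Encodings

A pairwise alignment column is one of 16 ungapped base combinations;
identifying each with its complement leaves 8 equivalence classes,
written `a`–`h` (species-1-major order: `a` = A/A ≡ T/T, …, `f` = C/C ≡
G/G).  A three-way column reduces likewise from 64 to 32 classes,
`a`–`z`,`U`–`Z`.  The identification makes the encoding strand-
symmetric, which is verified exhaustively at import time and again in
the test suite.  Useful derived statistics are linear in the symbol
frequencies: conservation is the frequency of `{a, f}` (pair) or
`{a, v}` (triple); species-1 GC content is the frequency of `{e..h}`
(pair) or of the 16 C-major symbols (triple); the pairwise
transition/transversion ratio is `freq{c, h} / freq{b, d, e, g}`.

Columns containing a gap or any IUPAC ambiguity code are excluded from
the encoding; ambiguity codes are treated exactly like indels because
keeping the alphabet closed matters more than the handful of columns
lost.  The coordinate map (chromosome, species-1 position, strand per
retained symbol; 0-based half-open throughout) records what was
dropped, so segment calls can be projected back to the genome and runs
are never allowed to bridge a coordinate discontinuity.

Concatenating encoded blocks (successive 3′ UTRs, exons, MAF blocks)
inserts a *fixed boundary* between blocks.  Fixed boundaries are
structural: they are present in every segmentation state, contribute no
likelihood term, are reported separately (`Nfixed`) from the free
change-point count k, and split posterior segment calls.  No separator
symbol is ever emitted, so the alphabet stays exactly A = 8/32/2.

## The change-point model

Symbols within a segment are exchangeable multinomial draws; the
segment's parameter vector comes from one of K Dirichlet classes.  The
multinomial parameter is integrated out analytically, leaving the
Dirichlet-multinomial marginal per segment.  Collapsing θ removes a
layer of latent variables and substantially improves mixing; θ
therefore appears nowhere in the state.

Priors and defaults:

| quantity | prior / default | why |
|---|---|---|
| boundary inclusion ρ | Bernoulli per eligible boundary, ρ = 0.01 | closed-form prior ratio for birth/death; mean prior segment length 1/ρ = 100 symbols, the scale of interest |
| class weights π | symmetric Dirichlet(1) | uniform on the simplex; conjugate |
| hyperparameters α_ca | Gamma(shape 1, scale 10) | weakly informative, positive; mean 10 per component allows both tight (large Σα) and diffuse classes |
| iterations | 20,000 (library default) | long-run default; the bundled experiments use 1,200–2,000 where the sequences are shorter |
| burn-in | first 50% of iterations | conservative; overridable, diagnosable from the blob plots |
| thinning of stored states | every 10th iteration | memory control; summaries are kept every iteration |

One sweep of the sampler performs: (i) Metropolis toggle proposals
(birth/death) on ~n·ρ randomly chosen eligible boundaries with the
class labels summed out of the acceptance ratio; (ii) ±1 shift
proposals on ~20% as many active free boundaries; (iii) an exact Gibbs
draw of every segment label; (iv) a conjugate Gibbs draw of π; (v) a
componentwise random-walk Metropolis update of log α (step 0.25, with
the Jacobian folded into the acceptance ratio).  Steps (i)–(iii) form a
partially collapsed Gibbs scheme — boundaries are updated under the
label-marginalised posterior and labels are then re-instantiated from
their exact conditional — which leaves the joint posterior invariant.
Correctness is pinned to an exhaustive-enumeration oracle
(`brute_force_posterior`) on instances small enough to sum over all
2^(n−1) segmentations: with α and π held fixed, sampled boundary and
class marginals must match enumeration within Monte-Carlo error.  Each
run uses a single seeded generator; the seed is recorded in the trace
and identical seeds give bitwise-identical traces.

Numerical notes: segment scores use log-Gamma throughout; label draws
use a max-shifted softmax; the inner loop is compiled with numba and
uses prefix-sum symbol counts so a boundary proposal costs O(A·K)
independent of segment length.

## Model selection

`DICV = −2·mean(logL) + 2·var(logL)` with the unbiased sample variance
over post-burn-in log-likelihoods.  The "V" penalty (twice the
half-deviance-variance, Gelman-style p_D) was fixed as a design choice;
selection depends only on the curve's shape, and the simulation suite
validates the selection behaviour rather than the absolute value.

Procedure 1 walks K upward and stops at the first K whose successor
does not improve DICV beyond a noise tolerance.  Two refinements
codify what is otherwise a subjective reading of the curve:

* **Noise tolerance.**  DICV is a Monte-Carlo estimate; its standard
  error is estimated by contiguous batch means over the post-burn-in
  logL chain (20 batches).  A successor must improve by more than
  2·√(se_K² + se_{K+1}²) to keep the walk going, so ties and sub-noise
  dips resolve toward the smaller model.
* **Continuation rule.**  If the curve beyond the stopping point later
  drops below it by more than `continue_threshold` (default 0.10) of
  the curve's range *and* beyond the noise tolerance, the walk
  continues to the next minimum — the codified version of "the values
  obviously keep decreasing".

Finally the empty-class veto steps K down while the chosen model
contains a class whose mean mixture proportion is below
`empty_threshold` (default 0.005): a model with an empty class is
over-fitted regardless of its DICV.

Procedure 2 selects the largest K at which every class is stable.
Per class, the post-burn-in conservation and GC series (computed from
the per-iteration class-aggregate symbol frequencies, after
relabelling) must have standard deviation at most `var_threshold`
(default 0.05), and the mixture proportion must clear
`empty_threshold`.  A class that holds no segments in some iteration
contributes its prior-driven α-mean frequencies there, which is what
makes spurious classes visibly unstable.  Both thresholds are exposed
in the API and CLI; the defaults encode "varies by more than a few
percent" and "holds well under a percent of the mixture", the scales at
which a class stops being interpretable.

Label switching is controlled by aligning each iteration's class
frequency vectors to running reference means with an optimal
(Hungarian) assignment — deterministic given the trace, and at least as
good as greedy matching at undoing switches.  Stability series,
profiles and summaries all use the relabelled classes.

## Profiles, calls, enrichment

A position's class probability is the fraction of stored post-burn-in
states whose covering segment carries that class.  Calls are maximal
runs of at least 8 positions whose most probable class reaches
probability τ = 0.5 (inclusive); 0.5 makes "called" coincide with "most
probable", calls from different classes disjoint, and is the natural
compromise between false positive and false negative allocation.  Runs
split at fixed boundaries and coordinate gaps, and short leftovers are
discarded.

Enrichment of an annotation type across classes uses expected counts
proportional to the fraction of the reference sequence each class's
calls cover (plus an unassigned/background category so observed and
expected totals match).  Instances are assigned by majority overlap
(> 50% of the instance length), with the instance midpoint breaking
exact ties.  The statistic is the multinomial log-likelihood ratio
G = 2·Σ O_j log(O_j/E_j); its exact tail probability is computed by a
dictionary dynamic program over (count, statistic) states when the
composition count allows (≲ 5·10^5 states), by a quantized-grid
convolution DP for N ≤ 500, and by ≥ 10^5 Monte-Carlo draws beyond.
Types with fewer than two matches inside the classes are not tested;
Bonferroni divides by the number of types actually tested.  A
zero-coverage category with observations receives a pseudo-expected
floor of half a count (with a warning); zero-coverage, zero-observation
categories are dropped exactly.

## Synthetic data

The generators are pure functions of (parameters, seed) and define the
package's benchmark conditions:

* `single_class_control` — same length and fixed-boundary layout as a
  template (or an explicit layout; the bundled experiments use ~300-
  symbol geometric spacing, emulating concatenated UTR blocks), every
  segment's θ drawn from one Dirichlet centred on the template
  frequencies with concentration 100.  The shipped frequency preset
  (`DROSOPHILA_UTR_PAIR8_FREQS`: conservation 0.95, GC 0.38, Ts/Tv
  ≈ 1.2) reflects a 3′ UTR alignment of closely related Drosophila
  species.  Any structure found beyond one class in this control is
  spurious.
* `multiclass` — planted K-class sequences: Bernoulli change-points
  (all *free*, so recovery is honest), i.i.d. labels, i.i.d. symbols
  per segment.
* `alignment_pair` — raw two-species alignments with per-segment GC,
  identity and transition:transversion odds κ (each transversion
  half-weighted), so the pair8 encoding of the output has planted
  classes and measured Ts/Tv ≈ κ.
* `motif_control_classes` — 100 replicates per observed class with the
  length multiset preserved exactly and bases i.i.d. at the observed
  composition, for motif-discovery null controls.

What the simulations do *not* emulate: indel evolution, within-segment
autocorrelation, phylogenetic dependence beyond the pair/triple column
process, and genome-scale sequence length.  Passing the recovery suite
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to real-data misspecification.

## Problem sizes in the bundled experiments

The packaged experiments are sized for a single CPU: the control
experiment in `scripts/acceptance.py` uses a 100 kb control with
K = 1..5 at 2,000 iterations; the test suite uses 20–40 kb sequences
with 800–1,500 iterations, a ten-dataset selection suite at 30 kb, and
enumeration oracles on ≤ 12-symbol instances.  At these sizes the
selection procedures behave as at larger scale because the number of
segments (several hundred) — not the raw length — drives both the DICV
noise level and the empty-class threshold.

## Known limitations

* Selection on sequences with only tens of segments is noisy: the
  empty-class veto loses power when 1/(number of segments) approaches
  `empty_threshold`, and DICV differences drown in Monte-Carlo noise.
* The sampler updates α one component at a time; for very large K the
  α updates dominate runtime.
* Segment likelihoods assume exchangeable symbols within segments;
  Markov-dependent alternatives and HMM formulations are out of scope.
* The enrichment test conditions on the called segmentation; it does
  not propagate segmentation uncertainty into the p-values.
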