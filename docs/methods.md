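# Methods

## The scoring model

`diaxic` scores one precursor at one candidate retention time by a
representative spectral matrix (RSM): 170 XIC rows × 12 acquisition cycles.
All XICs are sums of centroid intensities within an m/z tolerance window,
per cycle; the window is ±r ppm (basic resolution, default 30 ppm, suitable
for TOF-class data) or the narrower 0.2·r and 0.45·r for the extra library
resolutions. The time axis is the acquisition cycle throughout; the RT in
seconds is kept as metadata and used only for reporting and for
quantification areas.

Row blocks and their ordering rules:

* **library@r / library@0.2r / library@0.45r** (20 rows each). The 20
  most intense library fragments (library intensity, ties by row order).
  Rows at r are sorted descending by the sum of their Pearson correlations
  with the *other* library@r rows, computed over the 12-cycle window;
  rows with zero variance (zero-filled padding, or flat traces) take
  correlation 0 by convention, making the sort deterministic. The two
  narrow-resolution blocks, and the iso/light blocks, follow the same
  fragment order, so row i always refers to the same fragment across
  library-aligned blocks.
* **self** (50 rows). All theoretical b/y ions — charge 1 for precursor
  charge ≤ 2, charges 1 and 2 otherwise — extracted at r, filtered to the
  50 most intense in the window when more exist, sorted by Pearson
  correlation with the first library@r row, zero-filled otherwise.
* **qt3** (10 rows). Unfragmented precursor and its (M+1)/q…(M+4)/q
  isotopologues extracted from the MS2 spectra of the precursor's isolation
  window: 5 enumerated traces, zero-padded to 10.
* **ms1** (10 rows). Precursor at the three resolutions plus
  (M+1)/q…(M+4)/q and (M−1)/q at r, from MS1: 8 traces, zero-padded to 10.
* **iso / light** (20 rows each). (M+1)/q and (M−1)/q traces of the 20
  library fragments, in library@r order.

The enumerated qt3/ms1 traces do not fill their blocks; both are
zero-padded to 10 rows so that the default total is exactly 170 and the
part-exclusion series (dropping light, iso, qt3, ms1, self, library@0.45r,
library@0.2r in turn) yields 150/130/120/110/60/40/20 rows. Isotope
spacing uses the ¹³C–¹²C mass difference (1.0033548 Da) divided by the ion
charge. Windows at the run edges are zero-padded rather than re-centered,
so the candidate apex always sits at the same column (index 5 of 12).

Each RSM is conditioned for the model by global-max scaling (all entries in
[0, 1]; all-zero matrices pass through).

## The representation network

Two stacked LSTM layers (128 and 64 units by default) run along the cycle
axis with the 170 XIC values per step as input; dropout is variational
(one mask per sequence): input dropout 0.4 and recurrent dropout 0.3 on
both layers. The last hidden state feeds a 16-unit ReLU layer — the deep
representation features — and a single sigmoid unit, the deep discriminant
score (dds). Training minimizes binary cross-entropy, targets = 1,
decoys = 0.

Because no deep-learning framework is part of the runtime, the network is
implemented directly on NumPy: the forward pass, backpropagation through
time and the Adam update are written out in `deep_rep.py` and are verified
against central finite differences in the test suite (relative error
≲ 1e-4 across all parameter tensors). Gate order is (input, forget, cell,
output); forget-gate bias starts at 1; input weights are Glorot-uniform
and recurrent weights orthogonal per gate. Defaults: Adam with learning
rate 1e-3, batch size 256, a 7:3 train/validation split grouped by
precursor (a precursor's RSMs never straddle the split; a decoy shares its
source target's group), early stopping on validation loss with patience 10
and best-weight restore. Inference disables dropout and is deterministic;
batched and single-item embedding agree.

Two model sizes appear in practice: the full 128/64 architecture, and a
compact 32/16 variant used by the pipeline-level tests, which preserves
the architecture while keeping repeated end-to-end runs cheap. Both emit
16 features; checkpoints store the architecture and refuse RSMs of a
different shape.

## RT calibration

A seeded random sample of target precursors (default 500) is scanned at
every cycle of the gradient; the representation model's dds marks the best
RSM. The dds of a true peptide plateaus over the handful of adjacent
windows that still contain the peak, so within the near-maximal plateau
(dds ≥ max − 0.02) the anchor takes the cycle whose center column carries
the greatest library-block intensity — for a Gaussian elution profile that
column is maximal exactly at the apex. Anchors below dds 0.5 are dropped.

The library-RT → run-RT map is then fitted robustly: the linear model by
RANSAC (residual threshold 2.5 × MAD of a preliminary least-squares fit,
100 trials, seeded; the final fit is ordinary least squares on the inlier
set) and the nonlinear model by LOWESS (span 0.3, 2 robustness iterations)
after removing points with residuals beyond 3 × MAD. Linear predictions
extrapolate; LOWESS predictions clamp at the anchor range. Predicted
seconds map to the nearest cycle. Minimum anchor counts: 10 (linear),
30 (LOWESS).

## Positive-unlabeled rescoring and FDR

For every target and decoy, RSMs are assembled at each cycle within ±25
cycles of the predicted RT; those with dds ≥ 0.5 become candidates
(test-time augmentation), with the single max-dds window as a fallback so
every precursor stays scoreable. Each candidate carries 23 features: dds,
the 16 deep features, and six auxiliary values (precursor m/z, charge,
peptide length, |candidate − predicted RT| in cycles, log1p of the summed
library-block intensity, and the count of non-zero library@r rows).

The discriminant classifier is XGBoost (depth 6, 100 trees) or a random
forest (depth 12, 200 trees), trained on all candidates with decoys as
confirmed negatives and targets as the unlabeled positive class. Scoring
is 2-fold cross-fitted by default: precursors are split into folds, and
each fold is scored by the classifier trained on the other. This was a
deliberate design choice: with a single train/score pass the booster can
effectively memorize individual precursors through high-cardinality
features such as precursor m/z, which inflates the scores of absent
targets relative to decoys and destroys FDR calibration (measured realized
false-discovery proportions of 0.17–0.23 at nominal q of 0.01–0.10 on
synthetic data). Cross-fitting removes the self-scoring bias; the
single-pass scheme remains available (`pu_folds=1`).

Per precursor, the highest-scoring candidate is kept (ties: smaller RT
deviation, then earlier cycle). q-values use the standard target-decoy
estimator FDR(c) = #decoys(≥ c) / max(1, #targets(≥ c)), monotonized from
the bottom of the score list; protein-level q-values apply the same
estimator to per-protein best scores.

**Known conservatism.** The estimator treats every decoy as a stand-in for
a false target, i.e. it implicitly assumes all targets are absent. When a
fraction π₀ of the library is actually absent, the realized false-target
fraction at reported q is approximately π₀ · q. On synthetic runs with 30%
of precursors absent this is measured at ≈ 0.000/0.014/0.029 for nominal
0.01/0.05/0.10 — conservative by the factor π₀ ≈ 0.3, the textbook
behavior of the uncorrected estimator. No π₀ correction is applied; error
control is safe in the conservative direction. The two-species proxy FDR
(foreign identifications / all identifications) shows the same scaling on
the same data, as expected since both measure the identical quantity.

## Quantification

Q(precursor) = Σᵢ Σⱼ Corr(Cᵢ, Cⱼ) · Area(Cᵢ) over the top library
fragments of the best candidate's RSM — the first six rows of the sorted
library@r block, unnormalized. The double sum includes i = j, so each
fragment's weight is 1 plus the sum of its cross-correlations; weights can
go negative under anti-correlated interference and are deliberately not
clipped. Areas are trapezoidal integrals over the fixed 12-cycle window
using the run's cycle spacing in seconds; no peak-boundary detection is
performed. Q is linear in signal intensity (correlations are
scale-invariant), which is what makes two-condition ratio recovery exact
on noiseless data. The optional self-fragment mode adds
Corr(selfᵢ, library₁) · Area(selfᵢ) for the top k (3–15) self rows.
Protein quantities are the sum of the three largest precursor quantities.

## The synthetic-data generator

`synth` emulates the data structure the method assumes: tryptic-like
peptides (length 7–20, C-terminal K or R, 6–15 annotated b/y fragments
with log-normal relative intensities), a cycle-structured run (default 100
cycles at 3 s; 64 fixed-width isolation windows over 400–1200 Th), Gaussian
elution peaks (σ = 6 s ± 20% per-precursor jitter) whose apexes follow the
linear map seconds = 2.0 · libraryRT + 30, fragment heights proportional to
library intensities × a log-normal abundance (median 500, σ = 0.8 ln
units), five-peak MS1 isotope envelopes (relative heights
1/0.8/0.4/0.15/0.05), fragment M+1 isotopes at half height, co-eluting
interference peptides at rate 0.1, a Poisson noise floor (mean 30 peaks per
spectrum at mean intensity 5 ≈ 1% of the median peak height, i.e. high
SNR), and centroid m/z jitter of 2 ppm. A configurable fraction of library
precursors is entirely absent; a present-mask override supports
two-species designs. Two-condition mode multiplies abundances by per-group
ratios while sharing the library, apexes and presence pattern.

Runs are written as minimal centroided mzML 1.1 and mzXML 3.2 (64-bit
float arrays); mzML parsing is handled by a small namespace-agnostic
reader inside `raw_io` and mzXML by pyteomics, and equality of both
round-trips is a test.

What the generator does not model — and hence what passing tests cannot
show about real data: profile peak shapes and centroiding artifacts,
detector saturation and dynamic-range compression, chimeric precursors
sharing fragment m/z, charge-state cross-talk, RT drift/nonlinearity
beyond the planted map, and ion mobility. In particular the generator's
absent precursors are *pure* nulls, which is exactly the regime where the
π₀ conservatism above is most visible.

## Problem sizes used in the tests

Pipeline-level tests train the compact 32/16 model on 2000 generator RSMs
(8 epochs) and analyze runs of 120–2000 precursors; the FDR/recall surface
uses three seeded 2000-precursor runs with 30% absent; the representation
benchmark trains the full 128/64 model on 2000 RSMs for 10 epochs and
evaluates on 600 held-out RSMs; ratio recovery uses 600 precursors in
three planted groups (log2 ratios 0, 1, −2) under noiseless conditions.
These sizes were chosen so the entire suite completes in minutes while
keeping ≥ 600 precursors per statistical estimate.

## Degenerate inputs and tie-breaks

Zero-variance XICs correlate 0 with everything; all-zero RSMs normalize to
themselves and embed to finite features; every sort is a stable descending
sort so ties keep original order; precursors falling into two overlapping
isolation windows are assigned to the window whose center is nearest;
libraries without decoys trigger decoy generation inside the pipeline;
homopolymeric sequences that cannot produce a distinct shuffled decoy are
skipped with a warning after 10 retries.
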