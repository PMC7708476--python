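# Methods

## The latent ensemble recruitment (LER) model

The model assumes a local network of N cells organized into K fixed, hidden
ensembles. Once per network, each ensemble's cell-association vector σ_k is
drawn from a Dirichlet with concentration β; σ_k is a probability vector
over cells, so ensembles are soft, possibly overlapping memberships. Per
event i (an interictal discharge or other synchronous network event), a
recruitment vector θ_i over ensembles is drawn from a Dirichlet(α); small α
makes each event recruit a sparse mixture of ensembles. Per (event, cell),
a binary recruitment indicator z_ij is drawn from a Bernoulli whose
parameter is proportional to Σ_k θ_ik σ_kj, and for recruited cells the
source ensemble ζ_ij is drawn with probability θ_ik σ_kj / Σ_k θ_ik σ_kj.
The observed responsiveness Δ_ij then comes from N(μ_on, σ_on²) if z_ij = 1
and N(μ_off, σ_off²) otherwise.

Because σ rows are simplexes over cells, the raw Bernoulli parameter
Σ_k θ_ik σ_kj averages 1/N and vanishes as the population grows. The
generator therefore applies a documented gain g = r·N, with r the target
expected fraction of cells recruited per event (default r = 0.1), and clips
the product to [0, 1]. The clip matters for small ensembles: cells of an
11-cell ensemble saturate near probability 1 when their ensemble is
strongly recruited, making such cells hyperactive. This is a known,
accepted distortion of the gain design.

Inference reduces to Latent Dirichlet Allocation: after the responsiveness
matrix is binarized (below), each event is a "document" whose "words" are
its active cells (each once — z′ is binary, so no repeat counts exist), and
ensembles are "topics". Fitting uses scikit-learn's batch variational Bayes
with symmetric priors α = 1/K, β = 1/N, multiple restarts (default 10), and
the best evidence lower bound kept. Two determinism measures are built in:
restart seeds derive from one seed via `SeedSequence`, and the solver runs
on a canonical (lexicographically sorted) row ordering so that event order
cannot leak into the fit through the solver's per-document random
initialization — permuting event rows permutes θ rows exactly and leaves σ
bit-identical. Lineage labels are never an input to the fit; they enter
only the post-hoc tests.

### What the fit can and cannot recover

On binarized recruitment data at the default emission signal-to-noise
(μ_on − μ_off = 1.0 ΔF/F against σ_on = 0.25, σ_off = 0.1), the K* = 6 fit
recovers the planted ensembles with Hungarian-matched Pearson correlation
0.97–0.99. Through the full signal chain — rendered traces, 3-s
responsiveness windows, trigger-bootstrap binarization at ~1.1 events/s —
binarization recall drops to roughly 0.25 (overlapping windows contaminate
both the estimates and the null), and the K = K* fit then loses one of the
two small abGC ensembles on roughly a third of dataset seeds: a mode that
splits a large mGC ensemble instead can win the variational bound, and
restart selection by bound does not reliably discriminate (fits at K = K*+1
recover all planted ensembles, so the information survives binarization).
The acceptance checks therefore measure parameter recovery at the
binarized-recruitment level and treat full-chain recovery as
characterization, not a guarantee.

## Binarization (activation variable z′)

The responsiveness of a cell to an event is Δ = mean ΔF/F in a fixed
window (default 3 s) after the event minus the same window before, both
windows abutting but excluding the event frame. Events whose windows do not
fit the recording are dropped and logged. Per cell, a null distribution is
built by drawing 10,000 trigger frames with replacement from the eligible
pool and computing Δ at each; an event activates the cell (z′ = 1) when its
observed Δ strictly exceeds the null's 95th percentile (one-sided, α =
0.05). Excluded frames (detected events, seizures) are removed from the
trigger pool; the exclusion margin around each excluded frame is a
parameter with default 0 — at ~1.1 events/s with 3-s windows, any margin of
a full window would exclude every frame. Under an exchangeable null the
activation rate is α ± 0.01 by construction; this is verified on iid
Gaussian traces.

For responsiveness matrices available without a trace (model-level data),
`mixture_activation` binarizes by a two-component Gaussian mixture on the
pooled Δ values, assigning the higher-mean component as active — an
unsupervised use of the on/off emission separability (with
μ_on − μ_off ≥ 3·max(σ_on, σ_off) the optimal single threshold errs < 1%).

## Event detection

**IEDs.** The LFP is segmented into per-frame snippets (rectangular window,
equal lengths); each snippet's FFT magnitude spectrum (DC dropped) is the
frame's feature vector — magnitudes, not complex spectra, so detection is
invariant to where the event falls within the frame. Features are z-scored
per frequency bin across frames. An online kernelized perceptron (Gaussian
RBF, σ = 1, misclassified examples added with ±1 coefficients, 5 passes in
frame order, ties to the negative class) is trained from a small labeled
set and optionally refined over rounds of corrections — in tests and the
pipeline, an oracle callback stands in for the annotator. Runs of
consecutive positive frames merge to one event at the frame of maximal
broadband (20–500 Hz) power. On synthetic sessions with transients at 8×
the pink-noise SD and 30 labeled frames, precision and recall exceed 0.9
(events are credited within ±1 frame: a transient near a frame boundary
legitimately peaks in the neighbouring frame).

**Sharp-wave ripples.** Ripple-band power is the per-sample maximum squared
magnitude over a Gabor filter bank (centers 100–225 Hz, 25 Hz spacing,
7-cycle atoms). Candidates are contiguous regions strictly above
median + 12·MAD that last at least 20 ms; each is reported at its power
peak and kept only if the peak falls in an immobility epoch (speed <
1 cm/s sustained ≥ 3 s). The 20-ms minimum duration is essential: without
it, single-sample crossings of the heavy-tailed power envelope produce
~1.6 false events/min on pure pink noise; with it the false-positive rate
is below 0.2/min while injected bursts ≥ 8× amplitude are fully recovered.

## Lineage decoding and informative events

Each cell's fingerprint is its row of Δ (response to every event),
z-scored per event. A logistic regression (positive score ↔ mGC) is
cross-validated over repeated 80–20 splits by cell; test sets are balanced
by subsampling the majority class so population size does not inflate
accuracy. Regularization strength defaults to nested 5-fold selection over
C ∈ {0.01…100} by balanced accuracy. On generator defaults
(lineage-structured ensembles, 11% abGC) the L2 decoder reaches ~0.9
balanced accuracy; L1 trades a few points of accuracy for sparsity.

Events with L1 weight > +0.1 are pro-mGC, < −0.1 anti-mGC. Support
recovery has an intrinsic caveat: with heavily imbalanced populations a
sparse classifier can reach high accuracy from one population's events
alone (non-responders default to the other class), so redundant planted
events are dropped no matter how informative. The planted-event recovery
check therefore uses a balanced population and partial-coverage events
(each planted event informs a different subset of cells), with the
solver-default C = 1 — the property under test is support recovery, not
accuracy. A two-way ANOVA (population × event class, interaction; per-cell
mean Δ over each informative-event class) verifies the crossover: it
matches a closed-form balanced 2×2 oracle to 1e-9.

## Dominance and synchrony statistics

Ensemble membership is σ weight strictly > 3/N (three times the uniform
prior). The dominance test fixes the fitted ensemble sizes, permutes the
lineage labels (10,000 iterations, counts preserved), and calls an ensemble
abGC- or mGC-dominated when its observed count strictly exceeds the
size-matched null's 95th percentile. On discrete hypergeometric counts this
test is conservative: its exact type-I rate oscillates with ensemble size
(0.01–0.05) and only approaches the nominal 0.05 where the count
distribution is nearly continuous (large ensembles in large populations).
The calibration fixture uses sizes chosen — from the hypergeometric, before
running anything — where the exact rate is 0.042–0.05.

Synchrony is the Kendall tau between the abGC and mGC populations' median
event-activation vectors (tau tolerates small temporal displacements,
penalizing desynchronization continuously). On sparse binary z′ the median
of a small population is almost surely constant zero and tau is undefined
(reported as missing, not an error); session-level synchrony comparisons
use the real-valued responsiveness matrix, where lineage-structured
sessions are reliably less synchronous (tau ≈ −0.12) than mixed-membership
sessions (tau ≈ 0), and a two-sided Mann–Whitney U (exact for small,
tie-free samples) compares groups of sessions.

Decoding the most active ensemble (argmax θ, ties to the lowest index)
from the event's own LFP spectrum uses a 100-tree random forest on
1/f-corrected, per-bin-standardized power spectra over stratified 80–20
splits; stratification keeps chance-level accuracy binomial around the
empirical class frequency (unstratified splits induce below-chance
anti-correlation under shuffled targets). Significance is an exact binomial
test of pooled test hits against the empirical majority-class frequency;
1/K is reported alongside.

## The synthetic generator: what it emulates, what it does not

Defaults are fixed as the package's reference study conditions: 15 Hz
imaging, 1250 Hz LFP, 11% abGC, event spacing averaging ~1.15 events/s,
K = 6 ensembles with round(0.25·K) abGC-pure (disjoint pools partitioning
each lineage), recruitment fraction 0.1, μ_on = 1.0, σ_on = 0.25,
μ_off = 0, σ_off = 0.1 ΔF/F, trace noise 0.05 ΔF/F, calcium kernel rise
50 ms / decay 500 ms (max-normalized double exponential; a box kernel
option spans exactly one responsiveness window so measured Δ equals the
planted amplitude), IED transients as derivatives of a Gaussian (10 ms
deflection scale, ~50–60 ms events, amplitude 8× the unit-SD 1/f
background), and Gaussian-windowed ripple bursts with an immobility mask.

The generator does not emulate: slow ΔF/F drift or neuropil contamination;
non-Poisson temporal clustering of events (real IED trains are temporally
coherent — the model's exchangeability makes this irrelevant to the fit but
it does affect window contamination statistics); electrode artifacts or
line noise; movement-locked imaging artifacts; within-ensemble amplitude
correlations. Passing tests on this generator therefore demonstrate the
statistical machinery under the planted model, not robustness to every
failure mode of real recordings.

## Numerical and reproducibility choices

All randomness flows through per-call `numpy.random.default_rng` seeds; the
pipeline derives independent per-stage seeds from one global seed via
`SeedSequence.spawn` and records them, with content hashes, in a manifest —
re-running a config reproduces every numeric output byte for byte (stage
timings are logged separately, never in the manifest). Simplex rows are
normalized to 1 within 1e-6 after every fit; constant traces yield
undefined (NaN) correlations that are reported as missing; empty events are
dropped with a log line; empty ensembles are "mixed" by definition in the
dominance test. Problem sizes in tests and the acceptance script (e.g.
M = 2000 events at N = 200 cells for recovery, 25 cross-validation splits,
2–3 model realizations per K in the dominance sweep) were chosen to keep a
full run in the minutes range on a single core while leaving the measured
quantities' Monte-Carlo error well inside the tolerances they are checked
against.
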