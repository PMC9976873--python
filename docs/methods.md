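# Methods

`g4fret` quantifies the folding of consecutive G-quadruplexes (G4s) in
long human-telomeric DNA from single-molecule FRET (smFRET) time traces,
and models that folding with a kinetic scheme in which randomly nucleated
G4s can block full condensation of the strand. This note records the
models, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## The off-path folding model

An eight-repeat telomeric strand (Tel8) can accommodate two G4s. The
first G4 can nucleate at any of five repeat positions; only the two
terminal positions leave enough free repeats for a second G4. The model
is a continuous-time Markov chain over seven states — unfolded `U`, one
G4 at position 2..6 (`P2..P6`), and fully folded `F` (two consecutive
G4s) — with four rate constants:

| rate  | meaning                               | units |
|-------|---------------------------------------|-------|
| `k_f` | total nucleation rate out of `U`      | 1/s   |
| `k_u` | unfolding of a single G4              | 1/s   |
| `k_f2`| folding of the second G4 (on-path only)| 1/s  |
| `k_u2`| unfolding of the second G4            | 1/s   |

`k_f` is the *total* exit rate from `U`, split across positions by
`nucleation_weights` (uniform by default). This makes the unfolded-state
dwell lifetime exactly `1/k_f`, matching how the unfolded-state lifetime
is measured from segmented traces. All one-G4 states share one `k_u`
(equal stability irrespective of position). `F` unfolds only back to
on-path states, with `k_u2` split over them by renormalized nucleation
weights; off-path states reach `F` only through `U` (tree topology — a
mid-strand G4 must unfold before the strand can fully fold). Under
kinetic equipartitioning (uniform nucleation), the terminal on-path
share is 2/5 = 40% and the off-path share 60%, which is why a fast
nucleation burst from `U` with negligible unfolding traps the long-time
fully folded fraction at 40%.

Two fully folded conformations with distinct FRET signatures (E ≈ 0.8
and ≈ 0.6) are merged into the single kinetic state `F`; the emission
map, not the topology, differentiates them, because the rate model does
not assign them separate rates.

The chain is a tree, so detailed balance holds and the stationary
distribution has the closed form (unnormalized)

    pi_U = 1,   pi_Pi = k_f w_i / k_u,   pi_F = k_f k_f2 W / (k_u k_u2)

with `W` the on-path weight sum. `equilibrium(model, "nullspace")`
computes the same vector from the null space of the generator; the two
agree to ~1e-15 and the comparison is exercised in the tests.

Deterministic time courses use the matrix exponential of the fixed
generator (via one eigendecomposition, with `expm` as fallback);
the stochastic twin is an exact Gillespie simulation vectorized across
molecules. The two agree within binomial Monte-Carlo error by
construction, which the tests verify state-by-state.

### Rate fitting and identifiability

`fit_rates`/`RateFitter` fit rate constants to a folded-fraction time
course by weighted least squares (weights 1/sd²), log-parameterized,
with bounded multi-start local search (20 starts by default, fixed
seed). An important structural fact, discovered while validating the
fitter and now asserted by a test: the folded-fraction curve from an
all-unfolded start **cannot identify all four rates** — it is invariant
under exchanging the roles of the first and second folding steps
(`k_f` ↔ `k_f2`, with a compensating `k_u2`). The fitter detects the
flat objective (near-optimal solutions far apart in parameter space) and
reports it. The supported workflow, mirroring how such rates are
actually determined, is to fix `k_f` to the independently measured
unfolded-state rate (1/lifetime of the lowest-FRET state from dwell
analysis) and fit the remaining rates; recovery is then exact on
noiseless data, and at 5% observation noise the median relative error on
`k_f2` is a few percent while `k_u2` remains poorly constrained (its
influence on the curve is weak on the observed time scales).

Free energies follow from the rate ratio, ΔG = −RT ln(k_fold/k_unfold),
in kJ/mol.

## Trace quantification

Per-frame transfer efficiencies come from the two donor-excitation
channels after the standard alternating-laser-excitation (ALEX)
corrections: background subtraction per channel, donor leakage
α·F_DD′ and acceptor direct excitation δ·F_AA′ removed from the
acceptor channel, then

    E = F_AD' / (F_AD' + γ F_DD')

with defaults α = 0.15, δ = 0.05, γ = 1.2 (sample-averaged factors
applied uniformly). E is not clipped; frames with a non-positive
denominator are flagged invalid and dropped, never imputed. Histograms
count one entry per usable frame over a fixed range [−0.1, 1.1]
(corrected E exceeds [0, 1] under noise) with a default bin width of
0.025, which places a bin edge exactly at the E = 0.6 threshold
separating fully folded from partially folded molecules; `folded_fraction`
refuses thresholds that do not fall on a bin edge. Uncertainty on the
folded fraction comes from randomly dealing the trace pool round-robin
into three near-equal groups and taking the spread of per-group
fractions (sample sd, ddof = 1).

## Trace selection

Only traces with clean single-step photobleaching are analyzed.
Acceptor bleaching is detected as downward mean steps in the direct
acceptor-excitation channel F_AA (recursive binary segmentation with a
two-segment mean fit; minimum step 3× the robust per-frame noise from
successive differences). Donor bleaching is detected in the summed
donor-excitation signal F_DD + F_AD, with the additional requirement
that the step remove at least 25% of the local signal — a donor bleach
collapses the whole donor-excitation signal to background, whereas
conformational transitions move it only a few percent. More than one
step in either channel (aggregates, colocalized doublets) rejects the
trace. Traces with no bleach inside the record are accepted at full
length; accepted traces get their usable range truncated at the first
bleach frame. On synthetic data the detected cut is compared against
the generator's ground-truth bleach annotations.

## HMM segmentation and dwell kinetics

Corrected traces are segmented with a Gaussian-emission hidden Markov
model. For k = 1..`max_states` the model is fitted by
expectation-maximization with five seeded restarts — the first restart
starts from evenly spaced quantile means with a sticky transition matrix
(diagonal 0.95; smFRET dwells span many frames), the rest from k-means —
and k is selected by the Bayesian information criterion. The sticky,
quantile-spread initialization matters: plain k-means starts frequently
miss one of four well-separated states and the BIC then prefers a wrong
k. Decoding is Viterbi; states are relabeled in ascending mean order.
Zero-variance traces short-circuit to a one-state result.

Maximal constant-state runs become dwells; the first and last dwell of a
path are flagged censored and excluded from lifetime fits. Lifetimes are
estimated two ways: the maximum-likelihood mean of uncensored dwells
(default; standard error mean/√n) and a binned-histogram exponential fit
(bin width one frame, bins centred on frame multiples, empty bins
retained, unweighted least squares — calibration against simulated truth
showed observed-count Poisson weighting biases the lifetime low by ~3%
while the unweighted fit is the least biased variant). The histogram
fit's standard error is a seeded bootstrap over dwells, because the fit
covariance understates the sampling spread of heteroskedastic bin
counts. Frame quantization biases the plain mean upward by about half a
frame; at the lifetimes of interest (seconds against a 0.2 s frame) this
is 2–5% and inside every tolerance used.

Traces are classified into a low-FRET group (every visited state mean
below 0.6: unfolded and partially folded only) and a high-FRET group (at
least one state mean ≥ 0.6: fully folded conformations present). Rare
direct transitions between the lowest and highest bands are flagged when
consecutive dwells jump between a state mean ≤ 0.25 and one ≥ 0.6; the
0.25 bound is this package's operationalization of "lowest FRET state"
(the source analyses describe but do not quantify these events).

## Synthetic data generator

The generator is the testing stand-in for the microscope. A molecule's
conformational path is an exact CTMC simulation of a kinetic model; the
renderer converts it into the three ALEX channels per 200 ms frame over
a 500 s record:

    F_AD = I·E + α·I(1−E)/γ + δ·I + bg + noise
    F_DD = I(1−E)/γ + bg + noise
    F_AA = I + bg + noise

with per-frame true E the time-weighted mixture of state emission means
over the frame interval (motion blur — fast exchange produces genuinely
intermediate frames, as real 200 ms integration does) plus
emission-width noise. Inverting these expressions is exactly the
correction stage, which is what makes the zero-noise round trip an
identity to machine precision.

Defaults, and their provenance: frame time 0.2 s, record 500 s, α =
0.15, δ = 0.05, γ = 1.2 (the imaging conditions the correction stage is
designed for); state emission means 0.2 (unfolded), 0.4 (every one-G4
intermediate, the partially folded band) and 0.8 (fully folded, the
dominant high-FRET state). Emission width 0.05 and total intensity 1000
counts/frame with channel noise sd 30 and background 100/channel are
declared defaults, not inferred values — the source data's widths and
intensities are unpublished — chosen so the state means are separable
but overlapping, as real histograms are. Bleaching uses independent
exponential clocks per dye (defaults 0.002/s donor, 0.004/s acceptor,
i.e. mean bleach times of ~250–500 s against a 500 s record). Truth
annotations record the per-frame state (with frames spanning a jump
labelled `mix`, so a zero-width frame is labelled `F` exactly when its
true E equals the F mean), the true blurred E, and bleach times/frames.

Simplifications a user should know about: noise is additive Gaussian,
not shot noise (a deliberate, analytically invertible choice); after the
acceptor bleaches, F_AD drops all the way to background rather than
retaining the donor-leakage pedestal; there is no camera physics,
blinking, drift or spot-detection stage. Consequently, passing tests
demonstrate correctness of the analysis pipeline's logic and statistics,
not robustness to every artifact of real EMCCD data. The
doublet-artifact mode (`n_fluorophore_pairs > 1`) superimposes
independent dye pairs to produce the multi-step bleaching that the
selection stage must reject.

`simulate_discrete_trace` additionally provides frame-aligned dynamics
(geometric dwells, no sub-frame blur) for segmentation benchmarks, where
blur frames would constitute genuine extra emission components and make
"true k" ill-defined.

Time-course ensembles emulate a buffer exchange into folding conditions
at t = 0: every molecule starts unfolded, observation windows open at
the requested time points, and the empirical state distribution at each
instant is stored as ground truth.

## Distance → FRET

Structural ensembles are mapped to the FRET axis by
E = 1/(1 + (d/R₀)⁶) with R₀ = 52 Å; orientation effects are folded into
the fixed R₀. Ensembles are summarized either in the dynamic convention
(mean of per-sample efficiencies; the default, since dye motion is fast
relative to a 200 ms frame) or static (efficiency of the mean distance),
with box-plot statistics (quartiles, 1.5×IQR whiskers).

## Numerical choices and problem sizes

Tolerances: generator rows sum to zero to 1e-12; occupancies normalized
to 1e-8; closed-form vs null-space equilibrium to 1e-10; zero-noise
correction round trip to 1e-9. Statistical checks run at sizes chosen to
make their error bars decisive while keeping the default suite fast:
10⁴ molecules × 25 random models for the ODE–Gillespie comparison, 50
seeded replicates for HMM state-count selection and for noisy rate
recovery, 10³ dwells for lifetime estimation. `scripts/acceptance.py`
re-runs the same computations end to end and writes the resulting
numbers as JSON.

## Known limitations

- The four-rate time-course fit is structurally non-identifiable (see
  above); fixing `k_f` is required for unique recovery.
- The HMM treats frames as conditionally independent given the state; no
  blur-aware emission model, so very fast exchange inflates the state
  count — which is physically real for time-integrated detection.
- Censored dwells are excluded rather than modelled; lifetimes much
  longer than the record are therefore underrepresented.
- The selection stage's step detector assumes steps are large against
  frame noise; it is a reproducible proxy for what is, in practice, a
  visual criterion.
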