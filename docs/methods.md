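# Methods

## The single-compartment T4 model

The core object is a passive, capacitance-free conductance model. Five
presynaptic voltage traces are min–max normalized per input class —
jointly across all stimulus conditions of that class, so amplitude
ratios between conditions are retained — and converted to relative
conductances by a rectilinear transfer function with a per-class
threshold and gain. The membrane potential is then the
conductance-weighted mean of the reversal potentials (see README for
the equation), which makes V_m a convex combination of
{E_Glu, E_ACh, E_GABA, E_leak} at every instant. Two consequences are
used throughout:

- **Boundedness.** V_m can never leave the interval spanned by the
  reversal potentials.
- **Scale degeneracy.** Multiplying all gains *and* g_leak by a common
  positive factor leaves V_m exactly unchanged. Only ratios to g_leak,
  the thresholds and E_leak are identifiable; fitting and posterior
  summaries report those combinations.

Neglecting capacitance is justified quantitatively: a dynamic
single-compartment cable run with the same synaptic conductances
settles to within 0.1 mV of the algebraic V_m after about five membrane
time constants (tested).

The transfer function defaults to the continuous form
`g = gain·max(0, v − thld)`; a discontinuous `gain·v·1[v > thld]`
variant is available (`form="jump"`). The continuous form was chosen as
the default because it keeps the least-squares loss piecewise smooth,
which bounded quasi-Newton fitting relies on.

Direction is emulated rather than re-measured: for a stimulus at angle
φ relative to the PD, the Mi9 conductance is advanced and the Mi4/C3
conductances delayed by Δt = θ·cos φ/v (θ = 4.8°, v = 30°/s). The sign
convention places Mi9 one column *upstream* of PD motion, so its
release from tonic activity leads the cholinergic drive during PD
motion — this is what makes the disinhibition coincident and the PD
response maximal, and the synthetic detector geometry uses the same
convention (Mi9 at −4.8° along the PD axis, Mi4/C3 at +4.8°).

### Linearity analysis

`linearity_index` compares the depolarization of the coincident event
(excitation + release from a tonic inhibitory conductance) with the sum
of the two events alone, all measured from the tonic baseline. On a
50×50 grid over g_exc, g_inh ∈ (0, 5] with E_exc = −21, E_inh = −68,
E_leak = −65 mV the index is positive everywhere; sublinear cells
appear only when the excitatory reversal moves to within a few mV of
E_leak — then "excitation" barely drives current at baseline, and the
release interaction can lose to it.

## The cable model

An SWC morphology is mapped one-to-one to cylindrical compartments
(compartment = sample point; its cable runs to the parent point, with
the child point's diameter). The root has no parent edge and therefore
contributes no membrane area when read from SWC; directly constructed
morphologies may assign it a length. Axial conductance per edge is
(π d²/4)/(R_a L), membrane leak π d L/R_m and capacitance C_m π d L,
assembled into a sparse symmetric system solved with SuperLU. The
dynamic update is backward Euler at Δt = 0.1 ms (unconditionally
stable); steady states drop the capacitive diagonal. Defaults:
R_a = 150 Ω·cm, R_m = 28 kΩ·cm², C_m = 1 µF·cm⁻², E_leak = −65 mV,
giving the textbook τ_m = R_m·C_m = 28 ms and, for a 100 µm × 1 µm
cylinder, R_in = R_m/(π d L) ≈ 8.9 GΩ. Units are SI internally with
mV/pA/GΩ/µm at the interfaces.

### Voltage-clamp emulation

A proportional-integral controller injects
I(t) = K_p·(V_cmd − V_site(t)) + K_i·I(t−1) at the clamped compartment,
with V_site read at the *current* step: K_p joins the matrix diagonal
and K_p·V_cmd + K_i·I(t−1) the right-hand side. This implicit coupling
is stable for arbitrarily stiff K_p, whereas feeding back the previous
step's voltage diverges for any gain large enough to clamp well; with
K_i = 1 the integral action makes the steady-state error exactly zero.
The injected current is recovered from the node-balance residual
because at K_p = 2×10⁹ S the product K_p·(V_cmd − V) underflows double
precision.

### Space clamp and reversal potentials

`iv_reversal` reproduces the experimental protocol: settle the clamp at
each command voltage, step a synaptic conductance, measure the
leak-subtracted peak evoked current and regress it on V_cmd. For a
synapse at the clamped compartment the zero crossing recovers E_syn
exactly. For a distal synapse the evoked somatic current vanishes only
when the *attenuated* local potential reaches E_syn, so the apparent
reversal is E_leak + (E_syn − E_leak)/A with dendrite-to-soma
steady-state attenuation A < 1 — the estimate overshoots E_syn, away
from E_leak. The tests assert this closed form; it is the quantitative
form of the space-clamp artefact the multi-compartment model exists to
assess.

## Receptive-field analysis

The reverse-correlation kernel is K(x, τ) = Σ_t S(x, t − τ)·V_m(t)·Δt
for τ ∈ [−0.5, 3.0] s at the stimulus frame rate; membrane traces
recorded faster are frame-averaged onto the stimulus clock first, which
makes K independent of the physiological sampling rate. Drift is
removed beforehand by subtracting a 60 s-σ Gaussian low-pass.
Kernels are z-scored over the whole kernel (the reference region is
configurable); cells are screened by the extremum criterion (|z| ≥ 4 by
default) and by a 22.48° screen-edge margin, and accepted kernels are
recentred on the extremum.

A caveat the implementation makes explicit: the peak criterion is a
maximum over all kernel bins, so its false-acceptance probability under
the null grows roughly as 6.3×10⁻⁵ per effectively independent bin. For
kernels of realistic size (tens of pixels × 211 lags) a stimulus-
unrelated cell therefore *passes* the 4 s.d. cut more often than not;
with ~30,000 bins the measured null rejection rate is ≈ 28%. The
default remains 4 s.d. for fidelity to standard practice; users who
need family-wise control should raise `peak_sd` to about
√(2·ln n_bins).

Directional statistics follow the standard vector conventions: the
preferred direction is the angle of the resultant of |v(φ)| vectors
(a typed `UndefinedPD` outcome when the resultant vanishes), and
L_dir = |Σ v(φ)|/Σ|v(φ)| ∈ [0, 1]. Tuning amplitudes are the maxima of
Voigt profiles fitted (lmfit) in a 700 ms window around each raw peak,
with the raw peak as fallback on non-convergence.

## Synthetic data

The generator emulates the *statistical structure* of the in vivo
recordings, not their biophysics. Each input class filters the
luminance inside a Gaussian receptive field through a latency-shifted
difference-of-exponentials kernel with unit DC gain, scaled by a
per-class amplitude and signed by polarity; Mi9 is ON-hyperpolarizing
with a tonic depolarized dark level, all others ON-depolarizing, Mi4/C3
delayed (latencies 30/30/30/150/150 ms for Mi9/Mi1/Tm3/Mi4/C3).
Within the cholinergic and GABAergic pairs the kernel time constants
and field widths differ (Tm3 faster and wider than Mi1, C3 faster than
Mi4) so that each class carries a distinct temporal fingerprint — with
identical pair members only the pair *sums* would be identifiable and
parameter recovery would be ill-posed by construction. Amplitudes and
time constants are free choices of the generator, not calibrated
claims.

T4 episodes are forward simulations of the point model on these drives,
plus I_hold × R_in(t) (R_in scaled so the dark value matches the 5.28 GΩ
wild-type mean used as ground truth) and additive white Gaussian
voltage noise (default 0.5–1 mV). Because the noise is white and the
presynaptic nonlinearities are absent, passing recovery tests shows the
*estimators* are correct under the assumed noise model; it does not
certify performance under correlated biological noise, adaptation or
spiking, which the generator deliberately omits.

The fitting dataset comprises the four edge conditions (ON/OFF × PD/ND,
30°/s, 2.8° pixels, 0.3 s pre-roll, ~2.3 s each at 1 kHz); its
normalized drives are shared between generation and fitting so the
printed parameter set is exactly the data-generating truth.

## Inference

Twelve free parameters (5 gains, 5 thresholds, E_leak, g_leak) are fit
by L-BFGS-B within the printed bounds (thresholds [0,1], gains [0,2],
E_leak [−80,−45] mV, g_leak [0,3], floored at 10⁻⁶ to keep the model
defined), from Latin-hypercube multi-starts plus an optional
initializer; the returned loss never exceeds the initializer's.
Equal per-sample weight across the four conditions (their durations are
equal anyway). Uncertainty uses rejection sampling in place of a
trained neural density estimator: 20,000 uniform prior draws ranked by
RMS voltage error, keeping the closest set. This preserves the priors
and simulation budget of the original procedure and exhibits its
qualitative conclusions — the truth lies in regions of high acceptance,
and the scale-degenerate direction stays as broad as the prior —
without any learned component.

Measured under the defaults (20 seeds, 1 mV noise, 4 starts): pooled
median relative error of the identifiable quantities ≈ 1–2%; a few
seeds end in local minima where one small-conductance class is dropped,
which the median absorbs.

## Pipeline

`t4 run --config pipeline.yaml` executes synth → rf → simulate → fit →
posterior → report with one global seed expanded per stage through
`SeedSequence(seed, stage_index)`, validates the config (including path
resolvability) before any stage runs, and writes a manifest with the
config hash and the SHA-256 of every artifact along with the hashes of
its inputs. Reruns of the same config are byte-identical (the output
directory is excluded from the config hash for that reason).

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script
each complete in about a minute on one core: 12–20 px screens and
90–120 s noise movies for receptive-field work, 25–50-compartment trees
for cable oracles, 20 fitting seeds and a 20,000-draw posterior budget.
All of these scale up by argument without code changes.

## Known limitations

- No active conductances, adaptation, synaptic dynamics or correlated
  noise anywhere.
- The generator's presynaptic kernels are phenomenological; recovery
  results are statements about the estimators, not about fly neurons.
- The 4 s.d. receptive-field screen does not control the family-wise
  error for large kernels (see above).
- Derivative-based alignment is limited by transition width over SNR,
  a few ms at amplitude SNR 10 — not by the 1 kHz sample clock.
- The multi-compartment model treats the SWC root like any other
  compartment; no spherical soma special-casing.
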