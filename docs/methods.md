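# Methods

## Spike temporal encoding

Frames are grayscale, normalized to [0, 1] (8-bit inputs are divided by 255).
Each pixel maps to one input neuron in row-major order from the top-left
corner (fixed so checkpoints are portable), and each neuron emits exactly one
spike per frame window at

    T_i = round((1 − I_i) · T_max),   T_max = 256 by default.

The time axis is discrete, {0, …, T_max}: the rounding makes decoding exact to
half a step (max round-trip error ≤ 1/(2·T_max)), the code is monotone
(brighter never fires later), and a real-valued axis would buy nothing
downstream because layer simulation proceeds in integer steps. A neuron with
zero intensity — and, downstream, any neuron that never crosses threshold —
is assigned the terminal step T_max as a forced, minimal-information spike.
This keeps every spike train a dense integer vector and, importantly, gives
the learning rule a defined spike time for silent neurons (see below).
Decoding inverts the code: value = 1 − T/T_max.

## Integrate-and-fire dynamics with a dynamic threshold

Neurons integrate weighted presynaptic spikes with no leak. The firing
threshold grows linearly with the simulation step,

    D_th(t) = V_th + θ·t,   defaults V_th = 0 mV, V_reset = 0 mV, θ = 0.5,

which privileges early spikes: late input must overcome an ever-higher bar.
θ is interpreted against the current simulation step t (the candidate firing
time), not a per-neuron time fixed by past activity — the alternative is
undefined on the first frame. The threshold test runs after input
integration at the same step, and firing additionally requires the potential
to exceed the resting potential strictly. Without that guard the whole layer
would fire vacuously at t = 0, where the default threshold is zero; with it,
a layer with all-zero weights emits only forced terminal spikes, as it
should. Comparison uses ≥ (not >) against the threshold itself. Each neuron
fires at most once per frame window; firing resets the potential to V_reset
and freezes it; membranes are reset after every frame, making the forward
pass stateless across frames. There is no refractory mechanism beyond the
single-spike window and no leak term.

The vectorized layer simulation exploits the no-leak, single-spike structure:
a neuron's potential at step t is the running sum of weighted inputs
delivered up to t, and crossings can only happen at arrival steps, so the
whole layer reduces to a sparse matrix product, a cumulative sum and a first
`argmax`. A step-by-step reference (`run_layer_stepwise`) and a scalar
pure-Python oracle in the tests pin the semantics; the three agree exactly on
randomized instances.

## Network

Two dense layers: input (one neuron per pixel) → hidden IF layer → output IF
layer, with both weight matrices initialized i.i.d. uniform on [−1, 1] from a
caller-supplied seed. The hidden size defaults to the input size (12,000 per
layer at the reference 120×100 geometry; experiments here run at reduced
geometry, see "Study conditions"). Training consumes 3-frame sliding
windows; since membranes reset per frame, the first two frames of a window
cannot influence its output, so the implementation forwards only the last
frame — the multi-frame motion history enters through the label, which is
computed from the preceding frames. Checkpoints are HDF5 files holding both
matrices plus the full configuration as attributes.

## The magnocellular label generator

The saliency label for frame t is produced by a four-stage filter chain over
the clip history:

| stage | operation | parameter, default | why |
|---|---|---|---|
| photoreceptor adaptation | I′ = I / (I_pool + a), Gaussian pool σ = 5 px | a = 0.1 | compresses dark regions more than bright ones; output approximately invariant to global illumination |
| outer-plexiform low-pass | Gaussian blur | σ_opl = 1 px | denoises before temporal differencing |
| temporal high-pass | EMA background B_t = (1−1/τ)B_{t−1} + (1/τ)F_t; response \|F_t − B_{t−1}\| | τ = 2 frames | responds to change, nulls static structure exactly; ON/OFF channels collapsed into the absolute difference, since the target label is a single nonnegative map |
| ganglion stage | Gaussian blur then x/(x+c) | σ_g = 2 px, c = 0.1 | extracts low-frequency motion contours; compression near-saturates the response of a 1 px/frame small target |

The result is min-max normalized per frame (a constant map normalizes to all
zeros) and, when building training labels, restricted to the content inside
the ground-truth boxes before normalization — the tight box, not a dilated
one: dilation combined with the ganglion smoothing halo makes detection boxes
derived even from the label itself several times larger than small targets,
which destroys IoU against tight ground truth. The constants are not
identifiable from any published description of this filter class; the
defaults above were fixed once so that a 1 px/frame target of drone-like size
yields a near-saturated response while static clutter is nulled, and all of
them are configurable. Fidelity is claimed to the stage sequence and its
qualitative properties (exact static suppression, translation equivariance up
to borders, illumination invariance), not to any particular reference
implementation's output.

## Learning rule

The loss per window is a mean squared spike-time error between the output
train and the latency-encoded label,

    L = ½ Σ_j μ (T_out,j − T_label,j)² / T_max²,   μ = 0.02.

The surrogate for differentiation is the standard one for latency-coded IF
networks: the membrane approximates a ReLU activation, the activation relates
to the firing time as y ≈ T_max − t (so ∂t/∂V = −1 where the neuron fires),
and the ReLU derivative is 1 for neurons that fired before T_max, else 0.
This yields the output error term

    δ_j = −μ (T_out,j − T_label,j) / T_max²  = −∂L/∂T_out,j,

hidden error terms δ_i = (Σ_j w2[i,j] δ_j)·g_i with g_i the early-spike
indicator, and an STDP sign factor

    ε_j = +1 if T_label,j > T_out,j, −1 if T_label,j < T_out,j,
          0 if they agree or either is the forced spike at T_max.

Three update modes are implemented; the rule composed exactly as printed
above — Δw_ji = β·δ_j·S_i·ε_j with S_i the presynaptic early-spike indicator
— has two structural properties worth stating plainly:

1. sign(ε_j) = sign(δ_j) whenever ε_j ≠ 0, so the active update β·δ·S·ε is
   always nonnegative: it can only potentiate, never depress;
2. the ε = 0 branch freezes every synapse whose label **or** output spike
   sits at T_max — under realistic saliency labels that is the overwhelming
   majority of neurons (static background), so neither spurious early firing
   nor silent-but-salient outputs can ever be corrected.

Consequently the `"literal"` mode (and the `"magnitude"` variant |δ|·ε, which
is algebraically β·δ·S under the gate) cannot decrease the loss it is
derived from; in our experiments both leave the held-out MAE flat to slightly
increasing. The default mode, `"descent"`, is the exact SGD direction under
the stated surrogate,

    Δw_ji = −β · δ_j · S_i            (both layers, no gate),

with the forced terminal spike treated as a valid spike time — which is
precisely what forcing it is for: every neuron has a defined time, so silent
outputs under early labels are recruited (Δw > 0) and early outputs under
silent labels are suppressed (Δw < 0), and the unique fixed point is
T_out = T_label. The gated modes remain available and unit-tested for
comparison. Hidden-layer updates in the gated modes fold the output gate
into the backpropagated sum (δ_i uses δ_j·ε_j); in descent mode they use the
plain chain rule. S_i is binarized presence-of-an-early-spike rather than
the raw spike time, matching the spike-indicator convention of
backpropagation-through-STDP schemes and the minimal-information status of
the forced spike. The optimizer is plain SGD — no momentum, no weight
clipping beyond finiteness checks; window order is reshuffled each epoch from
the training seed.

A grid-search helper for θ (`search_theta`) is provided because the optimal
threshold slope depends on input statistics; 0.5 stays the default
everywhere.

## Synthetic data

The generator emulates the intended operating conditions: 120×100 px
grayscale at 20 fps (defaults), clips of 5–10 s, one or more Gaussian-profile
targets of 2–10 px (full width at half maximum; the binary mask is the
half-intensity support and the box bounds it tightly), photometric contrast
sampled in [0.2, 0.8] with polarity chosen against the local background, and
piecewise-linear motion with reflection at the frame margins so the target
never leaves the frame. Backgrounds cover four scene classes: constant
gray; low-spatial-frequency value noise advected at ≤ 0.5 px/frame (drifting
clouds); a static high-frequency pattern of rectangles (urban clutter); and a
slow global gain ramp (exposure drift). Frames are written as 8-bit PNGs
(values quantized to a 255 gray-level maximum); generation is bitwise
deterministic given the seed.

What it does not emulate: real sensor noise, camera shake, motion blur,
compression artifacts, occlusion, or textured targets. Passing tests on this
data demonstrates the pipeline's mechanics — encoding, dynamics, learning,
label quality, metrics — under controlled conditions, not detection
performance on real footage.

## Study conditions for the training experiments

The scaled training study (tests and `scripts/acceptance.py`) uses 20 clips
at 40×30 px, 5 s at 20 fps, split 15 train / 5 held-out (the 500:150
proportion of the full-scale design), T_max = 256, θ = 0.5, μ = 0.02,
20 epochs. The geometry keeps the dense 1,200² weight matrices and the
~1,470 windows per epoch tractable on one CPU; the reference 12,000² network
is functionally identical but ~100× heavier per layer.

The learning rate for this configuration is β = 1. The reference value
β = 10⁻⁶ is kept as the `TrainParams` default, but with δ ~ μ·Δt/T_max² ≈
3·10⁻⁵ it moves weights by ~10⁻¹¹ per update — no spike time can change
within 20 epochs at any feasible dataset size, so a per-configuration rate
choice is unavoidable (consistent with training under "a learning rate
strategy" rather than a fixed constant). β = 1 comes from requiring that one
epoch of updates can move a threshold crossing by tens of steps:
β·μ·Δt/T_max² per synapse per window, times k ≈ 300 active presynaptic
neurons and U ≈ 1.5·10³ windows, should match the needed potential change
θ·Δt — giving β ≈ 1. A stability scan of the training curve (β ∈ {1, 2, 4,
8, 16}, all smooth, all reaching the same plateau) confirmed the choice is
not critical.

## Evaluation conventions

Spike-time MAE is (1/N) Σ |T_i − T̂_i| in time steps, averaged over windows.
Boxes are half-open pixel rectangles (x, y, w, h), 0-based, top-left origin.
Motion maps become detections by thresholding and 4-connected component
labeling; each component's tight box is scored by its maximum map value.
Matching is greedy in descending score (ties broken by ascending detection
index, deterministic), one detection per ground-truth box, counting a true
positive when IoU strictly exceeds the threshold (default 0.25 — appropriate
at low resolution where targets span few pixels). Average precision uses
all-point interpolation (area under the precision envelope), pooled over all
frames rather than averaged per clip. Undefined precision or recall (zero
denominator) is reported as NaN, never silently as 0.

## Known limitations

- Because membranes reset per frame, the forward pass sees a single frame;
  all temporal context lives in the label. The trained network is therefore
  a learned *frame-to-saliency* map, not a temporal filter. On the scaled
  study it converges to strong static suppression (static clips decode to a
  mean map intensity below 0.05) with only a weak, speckled response at the
  target: the saliency labels are ≈ 93% silent, so silence is close to the
  loss minimizer, and 15 clips × 20 epochs do not recruit a contiguous
  target response. Thresholded boxes from the raw maps consequently localize
  poorly at IoU > 0.25 against tight small-target boxes; the maps are a
  guidance channel for a downstream detector, not a detector.
- The literal gated update modes are retained for study but do not learn;
  see "Learning rule".
- The label generator's constants are design choices, not fitted values; its
  outputs define the supervision, so systematic changes to them change what
  the network learns.
- Video containers (AVI/MP4) are not read directly; clips must be exported
  to per-frame PNG/TIFF directories first.
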