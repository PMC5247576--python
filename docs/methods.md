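# Methods

This package models and analyses a bacterial electrogenetic device: an
electrode sets the redox state of a diffusible mediator (the
ferri/ferrocyanide couple, Fcn(O)/Fcn(R)), the oxidized mediator amplifies
pyocyanin-driven SoxR activation of the PsoxS promoter, and the promoter
drives an output — a short-lived fluorescent reporter, the motility effector
CheZ, or a quorum-sensing signal synthase. Every stage of the signal chain
(potential → charge → expression; video → velocities; events → population
summaries) is implemented as a tested library function, exercised by the
numbered drivers in `analysis/` on synthetic data with ground truth.

## Electrochemistry (`electrogenetics.electrochem`)

The mediator pool (default: 3 ml of 5 mM, 37 °C) is treated as well stirred
and lumped. The oxidized fraction `f` relaxes first-order toward the Nernst
equilibrium of the applied potential,

    df/dt = k_e (f_eq(E) − f) − k_cell · OD · f,
    f_eq(E) = 1 / (1 + exp(−nF(E − E0)/RT)),

with `E0 = +0.2 V` vs Ag/AgCl and `n = 1` (the standard one-electron
hexacyanoferrate couple). The emitted current is the electrode term only,
`I = −nFVC · k_e (f_eq − f)`; by convention oxidation gives negative current
and charge. Charge is the trapezoidal integral of `I(t)`; because the
current jumps at a potential step, the simulator records an extra sample a
microsecond after each switch so the quadrature sees the discontinuity
(without it, charge conservation degrades by ~1% per switch).

Parameters and rationale:

- `k_e = ln(100)/900 s⁻¹` — lumped electrode rate; makes a full bulk
  interconversion 99% complete in 15 min, the device's observed conversion
  time. No Butler–Volmer kinetics: the device operates at strongly over- or
  under-potential, where the relaxation form suffices.
- `k_cell` (per-OD mediator re-reduction by respiring cells) — the
  phenomenon is real but no rate is available; default 0, exposed as a
  parameter. The protocol helpers `duration_for_charge` /
  `potential_for_charge` assume `k_cell = 0`.
- Integration: fixed-step RK4, default `dt = 1 s` (the per-segment step is
  shortened to land exactly on boundaries). Halving `dt` changes endpoints
  by < 10⁻⁸, and integrated charge matches the Faraday charge `nF·Δmoles`
  of the net conversion to a few 10⁻⁴ %.

## Reporter circuit (`electrogenetics.circuit`)

Reporter protein (≡ fluorescence, arbitrary units) follows

    dP/dt = s(f) − k_deg P,
    s(f) = pyo/(K_pyo + pyo) · (s0 + s_max · f/(K_fcn + f)).

The saturable `f` term lumps intracellular pyocyanin redox cycling and SoxR
oxidation; no mRNA stage or growth dilution is modelled. Calibration
defaults (the study reports no fitted constants, so these are the package's
own choices, fixed once):

| parameter | default | reason |
|---|---|---|
| `s0` | 0.17 au/s | basal plateau ≈ 300 au above baseline at 5 µM pyocyanin |
| `s_max` | 5.44 au/s | fully amplified plateau ≈ 17× basal, the observed fold amplification |
| `K_fcn` | 1.0 | keeps synthesis-vs-charge near-linear up to ≈ −0.5 C of the 5 mM pool, as observed |
| `pyo`, `K_pyo` | 5 µM, 1 µM | working inducer concentration, near-saturating |
| `k_deg` | ln 2 / 1500 s⁻¹ | 25-min ssrA half-life; visible decay well inside 45 min |
| `maturation_lag` | 0 s | the flavin-based reporter needs no O₂-dependent maturation |

'ON' is +0.5 V (oxidizing), 'OFF' is −0.3 V (reducing); OFF is purely the
removal of the amplified synthesis term — degradation is never actively
enhanced.

**Deconvolution.** Because degradation is first-order, cumulative
degradation-free synthesis is recoverable from a fluorescence series alone:

    S(t) = P(t) − P(0) + k_deg ∫₀ᵗ P dτ   (trapezoid rule).

This identity is exact (round-trip error < 10⁻⁸ against the simulator's
internal accumulator at 1-s sampling). Measured data carry the noise of
`P(t)` straight into `S(t)`, so `integrated_synthesis` accepts an optional
centred moving-average pre-filter (`smooth_window` samples); the analysis
uses 9 samples (4.5 min at 30-s sampling), the conventional moving-window
time average for such series. `fit_degradation_rate` is log-linear least
squares on the post-OFF decay; zero-residual fits report a zero standard
error (the underlying regression returns NaN there).

## Motility video analysis (`electrogenetics.tracking`)

Per frame: min–max rescale to 8 bits, 256-bin histogram, Otsu threshold
(ties toward the lower level), 8-connected components, centroids as
unweighted member-pixel means, `min_area = 4 px`. Because fluorescent cells
cover a tiny fraction of the field, a single Otsu pass can land inside the
background noise at extreme class imbalance; `frame_threshold` re-derives
the threshold from the upper histogram (iterated Otsu) whenever the
foreground fraction exceeds 20%. Thresholds are per-frame.

**Linking.** Cost per candidate pair: `w_d·dist/gate + w_s·Δarea/max_area +
w_i·Δintensity/max_intensity` with defaults `(1.0, 0.5, 0.25)` and a 10-px
gate; pairs beyond the gate are forbidden. The assignment is solved exactly
(minimum-cost maximum-cardinality matching via the Hungarian algorithm with
penalty costs for forbidden pairs) rather than greedily: exact matching is
deterministic, coincides with exhaustive enumeration on small instances by
construction, and avoids the pathological swaps greedy ordering can commit.
Tracks bridge up to `max_gap = 1` missing frame (gate scaled by the gap);
chains shorter than 10 detections are dropped.

**Background flow.** A swimming cell displaces by a full step every frame
whatever its tumble rate, so only passively carried objects (stuck cells,
debris) produce displacements near the true flow vector. The estimator
anchors on that passive cluster: video-wide mean displacement, shrunk onto
the cluster by trimmed means of radii 2.5/1.2/0.6 px, then per-frame-pair
means of links within 1 px of the anchor, smoothed over 15 frames. Two
guards: (i) a cluster moving faster than half the typical displacement with
under 40% of all links is rejected (a persistent straight swimmer is
formally indistinguishable from a stuck cell in fast flow — flow above
~50% of swimming speed is declared unidentifiable); (ii) with no passive
links at all, drift falls back to zero, flagged. The estimator is
shift-equivariant, which is what makes drift-corrected speeds invariant
(< 2%) under a uniform field translation.

**Stuck cells.** A trajectory is stuck when its drift-corrected net
displacement over its whole span is < 2 µm, or when every 3-s window along
it is sub-threshold (robust to slow residual drift error). Sub-threshold
windows on otherwise motile tracks mark partial sticking; those frame pairs
are excluded from the speed. The 3-s window targets surface-attachment
episodes — 1-s windows start flagging transient loitering of healthy
swimmers and make speeds sensitive to borderline windows.

**Velocity.** Mean over consecutive detection pairs of |drift-corrected
displacement| × pixel size × fps, gaps using elapsed frames; stuck tracks
are excluded (requesting their velocity raises). Trajectory roses translate
the first 3 s of each track to the origin. Group statistics: mean, s.e.m.,
and a two-tailed pooled-variance Student's t-test.

## Cytometry (`electrogenetics.cytometry`)

Rectangular scatter gating (strictly inside; empty gates warn, not raise),
arithmetic mean of the green channel, and a subpopulation split: Otsu on a
256-bin histogram of log₁₀ fluorescence, scored by between-class /
total variance. A unimodal Gaussian-like distribution cannot exceed 2/π ≈
0.637 on that score (the analytic optimum of a half-split normal), so the
bimodality cutoff is 0.70 — above the unimodal ceiling, far below the
≈ 0.85+ of 10×-separated mixtures. Nonpositive fluorescence gets shifted-log
handling with a warning.

## Synthetic data (`electrogenetics.synth`)

- **Expression traces**: piecewise-constant synthesis programs integrated
  with the exact per-segment closed form (no discretization error), then
  multiplicative (CV) and/or additive Gaussian noise; ground truth is the
  noiseless cumulative synthesis. Default sampling 30 s.
- **Motility videos**: run-and-tumble kinematics — exponential tumble
  waiting times, uniform redirection (no persistence), constant swim speed,
  tumbles resolved at frame boundaries so a swimmer's path speed equals the
  nominal speed exactly. Stuck cells are stationary in world coordinates.
  Background drift is a rigid stage/camera pan added at render time; cell
  kinematics are simulated pan-free in a box inset by the total pan, so
  stuck cells translate rigidly with the field for the whole video and
  adding a pan leaves cell paths bitwise identical. Swimmers scatter off
  the border (overshoot folded, heading flipped). Cells render as Gaussian
  blobs (σ = 2 px, amplitudes 140–220) on a noisy background (level 20,
  σ = 4) in 8 bits. Default geometry 680 × 512 px at 0.32 µm/px, 10 fps,
  100 frames — a standard camera field at 20×; fps and pixel size are not
  reported for the original videos and are declared assumptions. Emitted
  ground-truth speeds are the *realized* drift-corrected path speeds
  (border folds make the nominal speed unattainable by any tracker).
- **Cytometry events**: log-normal fluorescence mixtures with Gaussian
  scatter clusters; default 50,000 events, 1:1 two-population design with
  10× median separation and σ = 0.2 decades.
- **Current traces**: the electrolysis simulator plus additive Gaussian
  noise; truth is the noiseless charge.

All generators are bitwise seed-deterministic.

`evaluate_tracking` scores a tracking result against truth: a ground-truth
link counts as recovered if some trajectory holds detections within 3 px of
the cell at both frames; per-cell speed errors are computed over
identity-consistent tracks (within 2 px of their majority cell for ≥ 95% of
samples) against the cell's realized speed over the same frames. Tracks that
fail consistency are almost always prolonged close-proximity pairs — two
cells travelling within a blob diameter, where no appearance-based tracker
can keep identities — and those errors are already charged to the
link-recovery metric.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the real measurements (noise
models, acquisition sizes, imbalance, drift, sticking) but not their full
messiness: no photobleaching, depth-of-field or illumination gradients in
the videos; no cell growth, division or plasmid-loss heterogeneity in the
expression traces; no instrument compensation artifacts in cytometry; and
the circuit model's parameters are calibrated to reported fold-changes, not
fitted to data. Passing tests therefore demonstrate that the algorithms are
correct and well-conditioned under realistic synthetic conditions — not
that the biological constants are right.

## Numerical conventions and degenerate inputs

Trapezoid rule for all integrals; RK4 with `dt = 1 s` for ODEs; image
coordinates (x = column, y = row), origin top-left, pixel centres at
integers; CSV with mandatory headers, `%.17g` floats and round-trip parsing;
TIFF stacks round-trip bit-exact. Degenerate cases: single-valued frames
yield no detections; Otsu on fewer than two occupied bins raises; empty
linking inputs return empty assignments; frame pairs without links get zero
drift and a flag; constant traces fit `k_deg = 0 ± 0`.

## Known limitations

- Flow faster than ~50% of the swimming speed without stuck cells is
  declared unidentifiable rather than estimated.
- Heavily tumbling slow cells (CheZ-null at low speed) sit near the
  stuck/swimming boundary; a few are conservatively flagged stuck.
- The cell-mediated mediator re-reduction rate is a free parameter with no
  literature value; analyses run with it at zero.
- The counter chamber, electrode geometry and diffusion layers are ignored;
  cyclic voltammetry is out of scope (only its peak potentials enter, as
  the ±ON/OFF operating points).
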