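# Methods

## The optical model

A non-depolarizing thin layer with all six anisotropy mechanisms is
described by one complex 2×2 Jones matrix.  Writing the complex linear
components `B₀₉₀ = LB₀₉₀ − i·LD₀₉₀`, `B₄₅ = LB₄₅ − i·LD₄₅` and the circular
component `A = CB − i·CD` (angles in radians; dichroism as radian-equivalent
attenuation), the layer's generator is

```
G = [[−i·B₀₉₀,   A − i·B₄₅],
     [−A − i·B₄₅,  i·B₀₉₀]],          G² = −Q²·I,
Q  = √(B₀₉₀² + B₄₅² + A²)   (principal branch, Re Q ≥ 0)
```

and `W = exp(G/2) = cos(Q/2)·I + sin(Q/2)/Q · G`.  `G` is traceless, so `W`
is always unimodular, and unitary exactly when all dichroisms vanish.  Both
facts are asserted in the test suite, together with elementwise agreement
with `scipy.linalg.expm` to 1e−10 on random states.

Two inversions are provided:

* **Closed form** (`method="paper"`): `Q = 2·arccos(½·Re(w₁₁ + w₂₂))`, then
  the aggregates from linear combinations of matrix elements scaled by
  `Q/(2·sin(Q/2))`.  Exact for phase-only anisotropy; for weak dichroism it
  is a controlled approximation — the birefringence readouts converge at
  second order in (LD, CD), the dichroism readouts at first order (both
  rates are asserted numerically).
* **Exact** (`method="exact"`, the default): the principal matrix logarithm
  of the unimodular `W` via complex `arccos` of the half-trace, exact for
  `Re Q ∈ (0, 2π)`; the endpoints are branch points and such pixels are
  masked out, never clamped.

A note on the circular readouts of the closed form: for a pure rotator
(optical activity θ) the Jones matrix is the real rotation matrix, so
circular *birefringence* lives in `Re(w₁₂ − w₂₁)` and circular *dichroism*
in `−Im(w₁₂ − w₂₁)`.  The implemented default (`inversion_convention=
"eq10_11"`) uses this algebraically consistent assignment — it is the only
one under which forward–inverse round trips close.  The alternative
labelling that swaps the birefringence/dichroism roles of real and
imaginary parts is available as `"eq15"`.

## Holographic recording and demodulation

Each irradiation polarization s ∈ {0°, 90°} turns the matching column of
`W(a, b)` into the object field; the reference is a tilted plane wave
polarized at 45°, so each analyzer channel beats against amplitude
`r/√2`.  The recorded intensity per channel is
`I = |⟨E_s, Ω⟩ + (r/√2)·e^{i2π(υ₀a + ν₀b)}|²`, optionally with additive
Gaussian detector noise and 8/16-bit quantization (full scale = maximum
over the four channels).

Demodulation is standard off-axis sideband extraction: (Hann-apodized)
2D FFT, a square window of half-width 0.1 cycles/px around the carrier
(default (0.2, 0.2) cycles/px), inverse FFT, exact baseband shift,
conjugation, division by the reference amplitude and by the apodization
window where it is non-negligible.  A 16-px border and window weights
< 0.05 are excluded from the validity mask.  The sideband window must not
touch the DC hump: carrier components must exceed the window half-width
(a warning is raised otherwise).

**Piston convention.**  Only the global phase is unobservable.  `rephase`
removes it with a determinant anchor: for a unimodular field `det Ŵ =
e^{2iχ}`, so `χ = ½·arg(mean det)` recovers the true piston exactly, with
the ±π ambiguity resolved by requiring `Re(mean ŵ₁₁) > 0`.  (Anchoring on
the mean phase of `ŵ₁₁`, available as `anchor="w11"`, biases the recovered
retardance of any retarding film and is kept only for compatibility with
data lacking a trustworthy determinant.)

## Phase scanning

The layer-by-layer gate needs a per-pixel scalar that grows with the
amount of anisotropic interaction accumulated along the path.  The default
functional is the trace phase `φ = 2·arccos(clip(½·Re(w₁₁ + w₂₂)))`, which
equals the retardance δ for any pure retarder or rotator and grows with
stacked interactions.  Two alternatives are selectable: the
inter-component split `|arg(w₂₁/w₁₁)|` (piston-invariant, but
orientation- rather than magnitude-sensitive for weak pixels — it cannot
order pixels by optical thickness) and the direct path phase `|arg w₁₁|`.
Cumulative gating (`φ ≤ φₖ`) is the default; band gating
(`|φ − φₖ| ≤ Δφ/2`) is provided because "phase plane" admits both
readings.  Masks are nested by construction in cumulative mode and the
retained count K is carried into every downstream statistic.

## Markers and diagnostics

Z₁–Z₄ are population moments over the valid pixels (1/K normalisation).
Z₂ is the *standard deviation*: the Z₃ = m₃/Z₂³ and Z₄ = m₄/Z₂⁴
normalisations are dimensionless only then (a `z2_is_variance` flag
restores the literal reading).  Z₄ is *excess* kurtosis by default so a
Gaussian map scores Z₃ = Z₄ = 0 (`raw_kurtosis` restores m₄/σ⁴).
Degenerate (constant) maps report Z₃, Z₄ as undefined rather than NaN.

Classification is deliberately transparent: leave-one-out, with the
training threshold maximizing Youden's J (ties resolve toward the midpoint
between the group means, polarity fixed by the group means), then
Se = N/Q, Sp = H/G, Ac = (N+H)/(Q+G) rounded half-up to one decimal, and
the accuracy grade on half-open bands anchored at 80/85/90/95 (the
published band edges leave gaps at the integers; anchoring is the only
self-consistent closure).  The shipped worked-example table recomputes
exactly from its printed counts except one specificity cell whose printed
value repeats the neighbouring comparison's (88.5 printed, 92.3 = 24/26
from its own counts); the verifier reports it and the tests pin both
numbers.

## The synthetic phantom — what it emulates and what it does not

`PhantomSpec.default(grid)` states one world:

| parameter | default | why |
|---|---|---|
| zones (central/transitional/edge) | 0.45 / 0.75 / 1.0 radius fractions | needles in the outer annulus, spherulites in the central disc, mirroring facies zonation |
| needle coverage per layer | ≈ 0.18 of area | sparse-network regime: a per-pixel zero-spike plus structure tail, which the phase gates slice |
| needle length / width | 8–22% of grid side / 3–6 px | dendrite branches; widths at the resolution scale |
| needle retardance δ | \|N(1.5, 0.7)\| rad | structure phases straddle the π/2…π/8 gates after blur dilution |
| orientation γ | uniform on [0, 2π) | the healthy wide orientation disorder |
| dichroism fraction | 0.2 × birefringence | weak anisotropic absorption along the same axes |
| spherulite coverage / radius | ≈ 0.10 / 5–11 px | chiral domains of the central zone |
| optical activity | \|N(1.2, 0.4)\| rad | commensurate with the linear anisotropy |
| layers | 4 | multi-interaction stacking; composed by matrix products |
| blur σ | 3 px | optical PSF; keeps most object spectrum inside the sideband window |
| seed | 7 | the default stated world is a fixed realization |

The pathology-like counterpart narrows the orientation range to [0, π/4],
coarsens the dendrites (0.6× count, 1.3× length) and intensifies the
chiral network (2× spherulites, 1.5× activity, 0.5× amplitude spread —
"the range of changes decreases" as concentration rises).

These choices were *calibrated* until the generator reproduces the
qualitative mechanisms the method is built to detect — tightening the
phase gate lowers Z₁, Z₂ and raises Z₃, Z₄ of the LB and CB maps, and the
pathology deltas raise the ensemble LB tail moments and separate the
cohorts on Z₃ of CB at φₖ = π/8 — and then frozen.  What a green test
establishes is therefore that the *pipeline* (recording, demodulation,
gating, inversion, statistics, classification) faithfully propagates those
mechanisms, not that the phantom is clinically realistic.  In particular:

* there is no true diffuse multiple scattering or speckle; "scattering
  multiplicity" is emulated by layer stacking, and the moment-vs-φₖ
  scenario is asserted at the default seed (the Z₁/Z₂ direction is robust
  across seeds; the Z₃/Z₄ direction is realization-dependent);
* dehydration dynamics, salt crystals, depolarization and instrument
  aberrations are absent;
* amplitude laws are folded normals — stated, not fitted to any data.

## Numerical choices

* Removable singularities `sin(Q/2)/Q` and `Q/(2 sin(Q/2))` switch to
  6th-order series below |Q| = 1e−6.
* The principal square root / arccos branches are aligned so that forward
  and inverse use the same cut (`Re Q ≥ 0`, `Im Q ≥ 0` on the cut).
* `invert_paper` masks arccos-domain violations by default and can clip
  (`clip_arccos`) for noisy demodulated data; singular pixels are dropped
  from masks and counted (`dropped_fraction`), and > 50% dropped raises.
* Quantization stores the intensity scale so demodulation is unbiased.
* All randomness flows through `numpy` Generators seeded from explicit
  integers; cohort sample seeds derive from a `SeedSequence` spawn.

## Fidelity budget

End-to-end map error is (field error)/(map RMS), so it is dominated by the
fraction of object spectrum outside the sideband window.  On the default
single-layer world the recovered field is within 2% relative RMSE
(noiseless) and all four maps within 5% at 16-bit quantization; on a
band-limited single-layer phantom (blur σ = 5 px, matching the 0.1
cycles/px window) the maps recover to well under 2% unquantized.  16-bit
quantization contributes negligibly at default reference amplitude; the
blur band-limit dominates.

## Known limitations

* The closed-form inversion's LD/CD readouts carry a first-order
  weak-dichroism error (~9% relative at LD ≈ 0.04 under strong
  birefringence); use `method="exact"` (default) when dichroism matters.
* Phase-plane selection is a per-pixel gate on the composed matrix, not a
  volumetric scattering solver; it cannot separate contributions within a
  pixel.
* Skewness/kurtosis of gated maps are heavy-tailed statistics; with few
  retained structures they vary strongly between samples (visible in the
  healthy-group spread of the worked example).
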