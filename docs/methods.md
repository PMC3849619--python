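# Methods

This note documents the model, the numerical design choices, and what the
synthetic tests do and do not demonstrate.

## Atoms and discretization

A real Gabor atom is `K · exp(−π((t−u)/s)²) · cos(ω(t−u) + φ)` with time
center `u` (samples), angular frequency `ω ∈ (0, π]` (radians/sample),
scale `s > 0` (samples) and phase `φ`.  Four families populate a
dictionary: Gabor atoms, pure harmonics (`cos(ωt + φ)` over the whole
epoch), Kronecker deltas (one per sample), and pure Gaussians (the
envelope without a carrier).  Only Gabor atoms are enabled by default;
harmonics, deltas and Gaussians are opt-in via
`DictionaryConfig.include_families`, because they triple bookkeeping for
signals that are typically well served by Gabors alone.

**Discrete normalization.** Atoms handed to the engines are normalized by
the Euclidean norm of their *sampled* vector, not by the continuous-time
factor `K(γ)`.  The continuous normalization and the closed-form
continuous inner product are kept for screening and for oracle tests; they
track the discrete quantities only in the well-sampled regime.  Atoms
clipped by the epoch border are renormalized on the clipped support, so
the unit-norm contract (`‖g‖ = 1` to 1e−12) holds everywhere.

**Support cutoff.** Envelope samples below 1e−16 of the peak are exact
zeros.  This makes far-apart atoms *exactly* orthogonal in discrete time,
bounds every window to ~6.85·s samples, and is the discrete counterpart of
truncating the product integrals to a finite interval.

**Recurrence tables.** Carrier and envelope samples are generated by
one-step recurrences (a complex rotation for cos/sin, a multiplicative
update for the Gaussian), i.e. cumulative products seeded by a handful of
transcendental calls.  Tables are generated left-to-right across the
support window; the mirror-symmetry saving of C-era implementations is
omitted as irrelevant to vectorized generation.  Recurrence output matches
direct library evaluation to better than 1e−9 over 4096 samples (tested).

**Minimum scale: 4 samples.** Below `s ≈ 4` the discrete atom is an
aliased rendition of its continuous parent: near Nyquist, the `2ω` term of
the discrete products no longer averages out (its alias distance from 2π
is small while the envelope bandwidth is large), and the ε bound on
neighbor distances — which the continuous closed forms satisfy everywhere —
fails by up to a few times 1e−3.  A numerical survey of adjacent-pair
distances across scales shows the bound restored to within 1e−6 for
`s ≥ 4`, so the scale grid starts at the first `aʲ ≥ 4`.  This replaces a
looser "envelope narrower than 2 samples" representability rule, which
the survey showed to be insufficient.

## The metric and the optimal sampling

`d₀(g₀,g₁) = √(1 − ⟨g₀|g₁⟩)` on unit-norm atoms; on phase classes,
`d = √(1 − ⟨G₀|G₁⟩_max)` with the product maximized over both phases.  The
discrete class product is computed *exactly*: each class spans the 2-D
space `{C, S}` (envelope×cosine, envelope×sine), and the maximum
normalized product is the largest singular value of the whitened 2×2
cross-Gram.  No iteration, no phase grid.

Adjacent-atom maximal products have closed forms in the three directions
(scale, frequency, position); the position case needs an inner
maximization over phase which is solved via its stationary-point equation
(`R·sin(θ+ψ) = rhs`), not a grid.  Setting the three Nyquist-limit
products equal to `1 − ε²` gives

- dilation factor: the root `> 1` of `2a/(a²+1) = (1−ε²)²`,
- `Δω(s) = (1/s)·√(−8π·log(1−ε²))`,
- `Δu(s) = s·√(−(2/π)·log(1−ε²))`.

Steps are chosen at the Nyquist end of the band, where they are tightest;
at lower frequencies the realized neighbor distances are smaller.  ε is
restricted to (0, 1) with a warning above 0.5.

**FFT-bin snapping.** Within each scale, the frequency grid must consist
of exact DFT bins for the windowed-FFT product machinery.  The transform
length is the next power of two ≥ max(2π/Δω, window width), and the
realized step `2π/L ≤ Δω` replaces Δω.  Snapping *down* only increases
density, so the ε bound is preserved (audited in tests at N = 512 for
ε ∈ {0.05, 0.1, 0.2}).  Position grids keep the exact real-valued Δu(s),
anchored at 0 for every scale.

**Stochastic dictionaries** remove `(100 − percentage_chosen)%` of the
atoms of the dense dictionary, drawn uniformly without replacement from a
seeded generator; parameters are never jittered.  Equal seeds give
bit-identical dictionaries (and books).

**Enumeration order** — family (gabor, harmonic, delta, gaussian), then
scale ascending, position ascending, frequency ascending — is part of the
stable API; the pursuit breaks argmax ties toward this order.

## Products, optimal phase, and the fast engine

All products against a whole scale are computed as one batched real FFT of
the Gauss-windowed signal (one row per position), rotated to the atom
center.  Per atom, five scalar moments `(xc, xs, cc, ss, cs)` determine
both the optimal phase and the maximal product.  Because `⟨C,S⟩ ≠ 0` in
discrete time, the solver uses the exact 2×2 Gram system
(`w* ∝ G⁻¹v`, product² = `vᵀG⁻¹v`); it reduces to the classical
`φ = arctan[(xs/ss)/(xc/cc)]` form when `cs = 0`.  Degenerate classes
(`ss ≤ 1e−12·cc`, e.g. Nyquist atoms centered on integer samples where S
is pure rounding noise, or `det(G)` below 1e−10 of `cc·ss`) fall back to
the φ = 0 branch; without the absolute `ss` guard the Gram solve amplifies
rounding noise into spurious products.  Reported weights are non-negative
for phase-carrying families, with sign absorbed into φ; delta and Gaussian
atoms have no phase and keep signed weights.

The **fast monochannel engine** maintains the per-atom product tables
across iterations with the update formula
`⟨Rⁿ⁺¹x, C_i⟩ = ⟨Rⁿx, C_i⟩ − w·⟨gₙ, C_i⟩`, evaluating the cross-products
by scanning the selected atom's waveform over only those positions whose
windows overlap its support and which are not flagged orthogonal by the
analytic factorization bound `(2√2/ε²)·Z < η` (η = 1e−16, the double
precision limit; `Z = ½·√(s₀s₁/(s₀²+s₁²))·e^C` is the envelope-overlap
factor).  A naive engine recomputing every product from the residual each
iteration is kept as the in-tree reference; the two agree atom-for-atom
with weights to 1e−8 over 20 iterations on noise (tested).  The fast
engine also maintains the residual explicitly and checks table/residual
drift at one atom every 10 iterations at 1e−6.

The truncated-integration half-width for pair products was re-derived from
the two-sided tail condition using `erfc(x) ≤ exp(−x²)` and the
dictionary bound on the normalization product, giving
`Δ′ = √((C − log(ηε²/2 · √(s₀/s₁ + s₁/s₀)))/A)` — the square root on the
scale ratio makes Δ′ conservative, and the truncation-error guarantee is
verified against full-support products in tests.

**Stopping.** `max_iterations` (default 50) and `energy_percent` (default
99) act in logical conjunction: the pursuit continues only while both the
iteration budget remains and the explained energy is below target.

## Multivariate engines

MMP1 (common phase, max Σ|products|), MMP2 (selection on the channel
average), MMP3 (free phase per channel, max Σ products²), and the MMPXY
compositions on channels×trials matrices.  A "2" digit averages its
dimension before selection; the remaining digit sets the selection
objective; any "3" frees the phase per channel/trial at the weighting
stage (for MMP23/MMP32 the selection on averages uses one free phase per
averaged signal, and the per-signal phases are refit at weighting — the
one-line catalog definitions leave this interleaving open, and this
implementation documents rather than guesses the original intent).
Weights are always exact dot products of the *unaveraged* residua with the
selected waveform, so per-channel energy conservation is structural.
MMP13 and MMP31 are rejected.

The common phase of MMP1 has no closed form; it is found per candidate
atom by maximizing the 1-D objective `Σᵢ|xcᵢ·cosφ − xsᵢ·sinφ|/‖g_φ‖` on a
64-point grid, then refining by golden section to 1e−10.  To keep the
grid from misranking atoms, every atom whose upper bound
`Σᵢ√(vᵢᵀG⁻¹vᵢ)` could beat the coarse winner is refined before the final
choice.  MMP2 refuses data whose channel mean is numerically zero (average
reference) and warns when the mean carries less than 1e−10 of the mean
channel energy.

The multivariate engines recompute product tables from the explicit
residuals each iteration rather than reusing the update formula across
channels.  This is a deliberate simplicity/correctness trade: for the
free-phase XY variants the averaged-signal tables are not rank-1
updatable, and the rescan cost is negligible at the epoch sizes these
engines target.  The update-formula machinery remains fully exercised (and
cross-checked against the naive engine) in the monochannel pursuit.

## Maps, physical parameters, filtering

Each Gabor atom renders on the time-frequency map as the unit-integral 2-D
Gaussian `∝ exp(−2π((t−u)/s)² − s²(ω−ω₀)²/(2π))`, scaled by its squared
weight; cross-terms are omitted by construction, so the map is additive
and non-negative and its integral equals Σw² for blobs contained in the
epoch×band window.  The negative-frequency mirror of the real cosine is
omitted, consistently with dropping cross-terms; for the zero-frequency
Gaussian family the mirror half is folded back so the blob keeps unit
integral.  Deltas render as one-column time lines, harmonics as one-row
frequency lines.  Atoms near the frequency edges (ω₀ → 0 or Nyquist) and
wide atoms near epoch borders leak blob mass outside the grid; the
integral identity is exact only up to that leakage.

Physical parameters follow EEG conventions: peak amplitude =
|weight|·max|waveform|·calibration (µV), peak-to-peak = twice that,
frequency `f = ω·fs/2π` (Hz), width `s/fs` (s).  Filters are conjunctions
of bounds on these; the SWA preset is ≥ 50 µV p2p, ≥ 0.5 s, 0.5–4 Hz and
the spindle preset 11–15 Hz, 0.5–2 s, ≥ 15 µV p2p.  Epoch occupancy — used
in sleep-stage rules (20–50% SWA for stage III, > 50% for stage IV) — is
the interval union of per-atom supports `[u − s/2, u + s/2]` (one scale
unit by default, configurable multiplier).

## Synthetic data

The generator plants Gabor atoms with *mathematical* (peak) amplitudes in
µV — so peak-to-peak, the EEG convention, is about twice the parameter —
plus white Gaussian noise at a seeded σ, optionally calibrated to a target
epoch-level SNR.  The sleep preset is an 8 s epoch at 128 Hz: one 1.5 Hz /
60 µV / 1.2 s slow wave and two 0.8 s / 20 µV spindles at 12 and 14 Hz.
The two spindle frequencies are distinct within the 11–15 Hz band,
mirroring the situation where the pursuit separates superimposed spindles
that visual scoring marks as one; equal-frequency coherent spindles 2 s
apart would instead be (correctly, in the greedy-ℓ² sense) merged into one
wide atom.  Parameter-recovery tests run this preset at 20 dB SNR with
ε = 0.05 and require each planted atom within one grid step and 5% in
amplitude; the pipeline smoke tests use 10–15 dB.

What the generator does *not* emulate: 1/f background spectra, artifacts,
non-stationary noise, inter-channel correlation structure, or volume
conduction.  Passing tests demonstrate correctness of the algorithms and
the advertised resolution on compact transients in white noise — not
detection performance on clinical EEG.

## Known limitations

- The one-step error bound is an a-priori worst case for a *single*
  iteration; MP is nonlinear and no claim is made about M-step optimality.
- The continuous closed-form product is used only for screening; exact
  discrete Gabor–Gabor products via theta-function series are not
  implemented (direct numerical products are used instead).
- Dictionaries at ε = 0.05 and epochs of ~1000 samples hold tens of
  millions of atoms; scan tables occupy a few hundred MB per signal, and
  problem sizes in the examples and tests (N = 256–1024, ε ≥ 0.05, tens of
  iterations) were chosen to keep single runs in seconds to tens of
  seconds on one core.
- Text epoch files are single-trial; multitrial blocks use the binary
  format with a JSON sidecar.
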