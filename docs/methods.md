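# Methods

## Physical model

The simulated experiment is Davies ENDOR with a frequency-swept RF pulse.
The microwave part of the sequence is idealized: a perfectly selective
inversion of one electron-spin transition prepares longitudinal two-spin
order, the traceless deviation operator `2IzSz` (diagonal
`(+1/2, −1/2, −1/2, +1/2)` in the `|αα⟩, |αβ⟩, |βα⟩, |ββ⟩` basis, electron
label first). During the RF pulse the relevant Hamiltonian in linear
frequency units is

    H(t) = ν_n Iz + A IzSz + ν₂(t) Ix

with `ν_n` the nuclear Larmor frequency (default 14.1 MHz, a proton at
X band), `A` the isotropic hyperfine coupling, and `ν₂(t)` the real RF drive
including its carrier oscillation. The echo observable after the RF pulse is
the population difference between `|αα⟩` and `|βα⟩`; it equals 1 for the
untouched initial state and 0 when one nuclear transition has been fully
inverted. Relaxation is absent, and the electron appears only through `Sz`,
so the four-level problem factorizes into two spin-1/2 problems with
effective nuclear frequencies `ν_n ± A/2` — one per electron manifold. The
ENDOR signal is then

    I(A, ν_RF) = 1 − E_α − E_β

where `E_α/β` are the inversion efficiencies of the pulse at the two
transition frequencies. An inhomogeneous sample is a Gaussian distribution
of couplings, and the spectrum is the probability-weighted sum of
`I(A_i, ν_RF)` over a discretized coupling grid, scanned over the chirp
center frequency `ν_RF`. The baseline is exactly 1; the "effect" channel
`1 − I` has positive peaks.

## Pulses and conventions

Chirp pulses sweep linearly from `ν_RF − Δν/2` to `ν_RF + Δν/2` over the
full pulse duration (edges included) with a quarter-sine amplitude envelope
over the first and last `t_e` (default 0.2 µs); the carrier phase is the
closed-form integral of the instantaneous frequency. Waveforms are real with
an explicit cosine carrier sampled at the AWG period (default 1 ns; a guard
rejects periods above 5 ns for carriers up to 100 MHz).

Amplitudes follow the linear-polarization convention: a drive of peak
amplitude `ν₂,max` nutates an on-resonance spin at `ν₂,max/2`. The
"100 kHz RF amplitude" of the simulated chirps and the "50 kHz" amplitude
that makes a 10 µs rectangular pulse a π pulse are the same setting —
`peak_amplitude = 0.1 MHz` here. Callers holding pre-halved rotating-frame
amplitudes pass `amplitude_convention="rotating"`; the flag is explicit
everywhere, never guessed.

Inversion efficiency (not transverse magnetization) defines the excitation
profile `E(ν − ν_RF) = (⟨Iz⟩_i − ⟨Iz⟩_f)/(2⟨Iz⟩_i) ∈ [0, 1]`, because the RF
pulse's job in Davies ENDOR is population inversion across one nuclear
transition.

## Numerics

Propagation is piecewise-constant: `ρ ← U_k ρ U_k†` with
`U_k = exp(−i2πH_k Δt)` per waveform sample. Three routes exist:

- **full** — 4×4 propagation with `U_k` from exact diagonalization of the
  instantaneous Hamiltonian; the reference for cross-checks.
- **blocks** — the two electron-manifold 2×2 blocks accumulated with the
  closed-form SU(2) rotation per sample (lab frame, carrier explicit).
  Agrees with the full route to machine precision; this is an exact
  consequence of `[H, Sz] = 0`, not an approximation.
- **fast** (default for spectra and profiles) — rotating-frame propagation:
  in a frame co-rotating with each spin the drive is a transverse field of
  magnitude `envelope/2` whose azimuth is the pulse phase relative to the
  spin; the counter-rotating component is dropped. The step starts at 50 ns
  and is halved until two successive results agree to 1e-4 in efficiency
  (floor 1 ns). Because the result depends on the spin frequency only
  through its offset from the chirp center, a whole (coupling × scan-point)
  table collapses into one vectorized profile evaluation.

The lab-frame routes carry the physical Bloch–Siegert shift of a linearly
polarized drive (~ν₁²/4ν₀, about 1e-4 MHz at a 14.1 MHz carrier), so they
differ from the rotating-wave closed form by up to ~1e-3 in efficiency at
X-band carriers; the test suite pins the rotating route to the closed-form
Rabi oracle at 1e-3 and the two routes to each other at 2e-3.

Other numerical choices: the coupling distribution is discretized on 81
points over ±4σ with renormalized weights (tests use 41 or 21 points; the
spectra are insensitive at the 1e-3 level); scan grids default to 0.05 MHz
steps covering `ν_n ± (Ā/2 + 4σ/2 + Δν/2 + 1)`; FWHM uses linear
interpolation between grid points with ties broken by the outermost
half-maximum crossings and rejects maxima on the grid boundary; convolution
zero-pads outside the single-frequency spectrum's range (its flanks are
baseline) and refuses mismatched grid steps rather than silently
resampling; spectrum normalization divides by the maximum and rejects
non-positive input.

## Linewidths and the coupling axis

The transitions sit at `ν_n ± A/2`, so a coupling spread σ appears halved on
the RF-frequency axis: the Gaussian distribution with σ = 0.5 MHz gives an
RF-axis FWHM of 2.355·σ/2 ≈ 0.59 MHz. Linewidths of ENDOR peaks are
therefore quoted in hyperfine-coupling units — twice the RF-axis width, here
2.355·σ ≈ 1.18 MHz — which compares directly with the width of the coupling
distribution itself. The intrinsic-linewidth measurement probes the line
with the narrowest useful chirp (0.1 MHz bandwidth, 40 µs, 100 kHz drive)
and lands a few percent above the distribution limit (~1.23 MHz): the
probe's own excitation width has a floor of roughly 0.1–0.2 MHz set by power
broadening of the 50 kHz effective nutation, and bandwidths at or below that
floor distort the profile (the 40 µs drive is a 4π rotation when barely
swept) rather than sharpening it further.

## Bandwidth phenomenology reproduced by the simulation

With 100 kHz drive and 40 µs pulses: bandwidths well below the intrinsic
width intensify the lines at essentially constant width (<10% FWHM change
from 0.1 to 0.25 MHz); near and above the intrinsic width the lines broaden
markedly (the swept window convolves into the line) and the peak effect
rises through ~1 MHz bandwidth before falling at 2 MHz and beyond, where the
spectral power density is too low for full inversion. A tenfold stronger
drive (1 MHz) removes that decline up to 8 MHz bandwidth. An 8 MHz sweep
covers both nuclear transitions when centered between them, giving a
two-step spectrum whose inner plateau is twice the outer one and whose
maximum lies between the two lines. At still-moderate bandwidths the
directly simulated chirp spectrum and the convolution prediction
(single-frequency spectrum ⊗ chirp profile, both normalized) agree to ~2%
RMS of peak for bandwidths up to 2 MHz.

## Synthetic spectra

The synthetic single-frequency generator stands in for a measured
Cu(II)-tetraphenylporphyrin spectrum: Gaussian (optionally Lorentzian) lines
at 13.4/15.6 MHz (¹H, 0.3 MHz wide), 21.6/23.8 MHz (¹⁴N, 1.5 MHz),
49.0 MHz (⁶³,⁶⁵Cu, 6 MHz), amplitudes 1.0/0.8/0.5/0.6/0.25, on an 8–95 MHz
grid at 0.1 MHz with seeded Gaussian noise and a line-free 92–95 MHz window
for offset correction. Positions follow the real peak pattern; the widths,
amplitudes and shapes are plausible stand-ins, not fits. What the synthetic
route does not emulate: hyperfine enhancement and the 1/ν_RF RF-field
dependence (real π-pulse lengths vary across the spectrum), quadrupole
structure and multi-transition interference of ¹⁴N (I = 1), orientation
selection in powders, amplifier overtones, and relaxation — so tests passing
on synthetic data validate the algorithms, not instrument-specific line
shapes.

## Gain bookkeeping

Gains are ratios of offset-corrected peak heights (not integrals) at
requested positions; the peak is located as the grid maximum of the test
spectrum within ±0.5 MHz (narrower for narrow lines — the window should be
the local half-linewidth). A table of gains is summarized by its arithmetic
mean over non-missing cells; the equivalent measurement-time reduction
squares the mean after rounding it to one decimal, reproducing the printed
arithmetic of the benchmark table (5.7 → 32.5); squaring the unrounded mean
(→ 32.7) is available behind a flag.

## Known limitations

Single I = 1/2 nucleus only: no I ≥ 1, no multiple nuclei, no TRIPLE
(two-RF-pulse) propagation, no Mims preparation gratings, no relaxation, no
finite microwave pulses, no hyperfine enhancement, no powder averaging.
Deconvolution is deliberately absent: resolution lost to a wide sweep cannot
be recovered afterward. The convolution predictor inherits the three caveats
above (constant profile amplitude across the spectrum, no multi-transition
interference, residual broadening already inside the single-frequency
spectrum).
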