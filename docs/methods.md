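# Methods

## Physical model

`pbisim` models propagation-based phase-contrast radiography in the
projection (thin-object) approximation with scalar wave optics:

1. **Projection.** A scene is a homogeneous background slab (lung
   parenchyma, default 100 mm) containing non-overlapping analytic objects
   (cylindrical airways with concentric walls, spheres). Each ray's
   per-material path length is the exact circle-chord expression; objects
   displace background along their chord, so Σ_m t_m(x) equals the slab
   thickness for every ray to machine precision. This replaces voxelized
   anatomy with closed-form geometry: it is exact for the isolated-object
   questions the package answers, and it is the reason a simulation runs in
   milliseconds instead of days.

2. **Transmission.** At energy E (wavelength λ = hc/E, hc = 1.23984193
   eV·μm) the exit wavefront of a unit plane wave is
   T(x) = exp(−Σ_m μ_m t_m/2) · exp(iφ), φ = −(2π/λ) Σ_m δ_m t_m.
   Attenuation is always included; for the thin airway wall its effect is
   small against the phase term (δ/μ·(2π/λ) ≫ 1 at 60 keV) but it supplies
   the correct absolute detector counts.

3. **Free-space propagation.** Single-distance Fresnel propagation is done
   spectrally: multiply the FFT of the field by
   H(ν) = exp(−iπλz|ν|²), dropping the global exp(ikz) phase. The sign
   pair (φ negative as above, H as above) is self-consistent and is
   validated against a direct O(N²) quadrature of the Fresnel convolution
   integral with kernel exp(+iπ(x−x′)²/(λz)) · e^{−iπ/4}/√(λz).
   A parallel beam (M = 1) is assumed in the propagation core; divergent
   geometries are mapped to an effective distance z_eff = d/M by the design
   module rather than by a divergent propagator.

4. **Detection.** The intensity |u|², normalized to a declared
   background-only region (I/I₀), is optionally blurred with a Gaussian
   σ_det, area-averaged onto square detector pixels (an idealized
   photon-counting detector with single-pixel PSF), scaled to expected
   counts = fluence · pitch² · T_background · (I/I₀), and Poisson-sampled.
   Detector absorption efficiency is 1 and there is no scatter background
   (ideal scatter rejection); the CdTe sensor material and 0.75-mm
   thickness are carried as metadata only.

## Default study conditions

The defaults reproduce the canonical monochromatic airway scenario:
60 keV; z = 12 m; lumen diameter D = 2 mm; wall thickness d ∈ 0.1–0.4 mm
(muscle-like wall, air lumen, parenchyma background at densities 1.05,
0.0012, 0.53 g/cm³; δ at 60 keV 6.66·10⁻⁸, 6.91·10⁻¹¹, 3.37·10⁻⁸);
50-μm detector pixels; incident fluence 3.6·10⁶ photons/mm² for the
monochromatic settings and 4·10⁶ for the tungsten spectrum. The wave-optics
grid default is 5 μm, below the sampling bound √(λz)/2 ≈ 7.9 μm at
z = 12 m (the bound is enforced; 2-m studies need ≤ 3.2 μm and use a
2.5-μm grid in the tests). The background slab thickness (100 mm) is a
configurable stand-in: intensities are normalized to the parenchyma-only
region, so it only sets overall transmission.

## Materials data

δ values for the three tissues are anchored at 60 keV and extended in
energy with the far-from-edge scaling δ(E) = δ(E₀)(E₀/E)²; linear
attenuation tables are bundled reference data (μ/ρ from standard photon
mass-attenuation compilations for dry air, skeletal muscle — reused for
parenchyma composition at 0.53 g/cm³ — aluminum, and approximate CdTe),
log-linearly interpolated in energy. μ values are not part of the
scientific claim being reproduced; they set absolute count levels and the
small attenuation contrast, both insensitive to percent-level table error.
User files override any entry.

## The tungsten spectrum

The conventional-radiography setting uses a bundled 120-kVp tungsten table:
a Kramers thick-target continuum hardened by 3 mm aluminum-equivalent
inherent filtration, tungsten K lines at ~8% of the continuum fluence, and
the stated 4.3 mm external aluminum filtration
(`scripts/make_tungsten_spectrum.py` regenerates it). Its fluence-weighted
mean energy is 59.8 keV, matching the rationale for choosing 60 keV as the
monochromatic energy. Polychromatic images are incoherent,
detected-fluence-weighted sums of per-energy coherent images with unity
photon weighting (counting detector); at z = 0 this reduces exactly to
polychromatic Beer–Lambert transmission. Per-bin propagation at z > 0 is
supported but experimental — the canonical phase-contrast setting is
monochromatic.

## Measurement operators

* **Edge width.** Deviations from a declared parenchyma baseline are
  thresholded at 25% of the peak deviation; the fringe-pair width is the
  span of the contiguous above-threshold runs containing the principal
  overshoot and undershoot. Fringes count as absent when the peak deviation
  is under 3 baseline standard deviations *or* under an absolute floor
  (default 0.05), which rejects the few-percent attenuation plateaus of an
  unpropagated image. A peak and trough separated by more than a quarter of
  the window triggers a refusal (two interfaces in the window). All
  thresholds are arguments.

* **Wall thickness.** At these geometries each interface's strongly
  refracting tangent ray casts a sharp intensity minimum essentially at the
  interface, flanked by bright lobes. The estimator finds candidate minima
  (prominence- and depth-filtered) and selects the quadruple
  p₁ < p₂ < p₃ < p₄ maximizing total shadow depth subject to airway
  structure (lumen gap ≥ 0.5 mm, walls within 0.06–1.0 mm); the wall is the
  mean of p₂−p₁ and p₄−p₃. A fringe-center (midpoint of
  overshoot/undershoot pair) method was evaluated and rejected: the bright
  lobes sit asymmetrically about the interface, giving a systematic
  ≈ +20 μm bias, and lobe pairing is unstable under coarse binning. The
  shadow minima are cusp-like, so sub-sample parabolic refinement is off by
  default. When the two shadows of a side merge (wall at the separation
  limit), the quarter-depth extent of the merged dark complex is reported
  and flagged. Averaged over sub-pixel airway placements the mean absolute
  error is non-increasing as the pixel shrinks (≈ 31–38 μm at 50 μm pixels,
  ≈ 4–6 μm at 5–10 μm), i.e. recovery is detector-resolution limited down
  to a few-μm refractive-displacement floor.

* **Visibility.** Michelson contrast (I_max − I_min)/(I_max + I_min) over a
  window after baseline normalization.

## Design formulas and the coherence criterion

σ_FZ = √(λz); sampling bound x_s ≤ σ_FZ/2; transverse coherence
l_t = Rλ/σ_src; magnification M = (R+d)/R with z_eff = d/M and the inverse
d = R·z_eff/(R−z_eff). The coherence pass criterion is l_t ≥ σ_FZ/√2,
chosen because it is algebraically identical to the source-requirement
ratio R/σ_src ≥ √(z/(2λ)) used for the numerical requirements (3.8·10⁵ at
60 keV, z = 6 m; R ≥ 19.05 m ≈ 20 m for σ_src = 50 μm); the often-quoted
l_t ≥ σ_FZ/2 differs from that ratio by √2 and cannot satisfy both at
once. The detector-regime label is "ideal" when σ_det ≤ σ_FZ/2 (Nyquist
sampling of the first Fresnel zone); a single-pixel-PSF detector is
assigned the effective resolution σ_det = 2 × pixel pitch.

## Numerical choices

* Grids are even-sized, centered, samples at pitch·(i − n/2). Binned-pixel
  coordinates inherit the left edge of each footprint; all difference-based
  measurements are invariant to that convention.
* Edge-replication padding with factor ≥ 2 before the FFT, cropped back
  after; this suppresses wrap-around from the circular convolution for the
  non-periodic slab borders. Complex128 storage throughout — the
  energy-conservation and unitarity contracts (≤ 1e-9, 1e-6) leave no
  headroom for single precision.
* The direct Fresnel quadrature is a *test oracle only*: it is trustworthy
  when the sampled chirp is unaliased over the grid (N·pitch² ≲ λz) and the
  field is compactly supported within the aperture; tests choose such
  regimes deliberately. The propagator's validity needs only band-limited
  fields, which the sampling guard enforces.
* The sampling guard refuses propagation when pitch > √(λz)/2; z = 0 is an
  exact identity; back-propagation requires an explicit inverse flag.
* Gaussian detector blur truncates at 8σ so the semigroup property
  (σ₁ then σ₂ equals √(σ₁²+σ₂²)) holds to ~1e-7.

## What the synthetic scenes do and do not show

The analytic scenes isolate interface physics: fringe formation, the
z-dependence of edge enhancement, detector-resolution limits on fringe
visibility and wall measurement. They contain no parenchymal texture,
vasculature, anatomical overlap, alveolar speckle, or scatter background —
so passing tests demonstrate the imaging-chain physics and the measurement
operators, not clinical detectability in a structured background. Nodule
scenes provide attenuation-contrast context only. Full-thorax radiography,
reader statistics, Monte-Carlo dose calibration and vendor post-processing
are explicitly out of scope (the generic unsharp-mask display operator is
labelled non-reproducing).

## Problem sizes

Default 1D airway runs use 2000 samples at 5 μm (10-mm field), padded to
4096 for the FFT — milliseconds per run. The z-sweep tests use 4000 samples
at 2.5 μm. 2D nodule runs are kept to ≤ ~1000² at 5–10 μm as
attenuation-contrast checks. Noise statistics use 10⁵ pixels.
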