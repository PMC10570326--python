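# Methods

This note documents the models, conventions and numerical choices behind
natsad, in the order a dataset flows through the package.

## Spectral conversions and scattering coefficients

Energy–wavelength conversion uses hc = 12.3984 keV·Å (CODATA value rounded
to the precision relevant for beamline work; the relative error against the
full-precision constant is < 2·10⁻⁶, far below any printed wavelength).

Anomalous scattering coefficients are bundled as per-element plain-text
grids (`src/natsad/data/scattering/*.dat`, columns energy eV / f′ / f″)
computed with the Cromer–Liberman relativistic algorithm, covering
1.7–16.5 keV for P, S, Cl, K, Ca, V, Se, Zn, Cd and I. Each file also
declares its labelled K/L absorption edges. Grid points are placed
log-uniformly plus densely (±0.5, ±2, ±8, ±25 eV) around each edge, so the
discontinuity is bracketed within ±0.5 eV.

Lookups interpolate f″ in log(E)–log(f″) space — f″ follows approximate
power laws between edges, so log–log interpolation is exact in the limit
and accurate to well under 1% on this grid density — and f′ (which changes
sign) linearly in log E. Queries at exact grid energies return the stored
value unmodified. Interpolation never crosses a labelled edge: when the
bracketing grid interval contains an edge, the value from the query's own
side is used. White-line features near edges are not modelled; tabulated
coefficients underestimate the signal attainable very close to an edge.

## Bijvoet ratio

The expected relative Bijvoet difference is estimated as
√(N_anom/2N_protein)·2f″/Z_eff with the standard protein-average constants
Z_eff = 6.7 e⁻ and 7.7 non-hydrogen atoms per residue. These constants are
the conventional choice for this estimator; the 0.6% lower limit for SAD
feasibility is an empirical rule of thumb, exposed as a plain number rather
than a hard-coded verdict.

## Unique-reflection counting

d-spacings come from the full triclinic reciprocal metric tensor, so every
crystal system is handled uniformly. Enumeration bounds each index by
⌈axis/d_min⌉ (complete because |h| = |a·s| ≤ a/d), then applies the exact
d ≥ d_min test.

Reduction to unique reflections partitions indices into orbits under the
space-group operators (h′ = hᵀR), plus inversion when Friedel mates are
merged, and keeps the lexicographically greatest triple of each orbit as
its canonical representative — a deterministic, convention-free choice.
Systematic absences use the phase-restriction test (some operator fixes h
with non-integral translation phase h·t); centric reflections are those
whose rotation orbit contains −h. Absent reflections stay in the reduced
set, flagged, but are excluded from the unique count. The implementation is
vectorised by encoding index triples into single integers whose ordering
matches lexicographic order, so counting remains fast for millions of
reflections.

Operator sets for the common macromolecular groups are bundled as triplet
files; any group can be supplied as an explicit operator file in
`-x,y+1/2,-z` notation. The operator list must contain the identity and be
closed under composition modulo lattice translations. Note that the
hexagonal (obverse) setting of rhombohedral groups has operator counts
(9, 18) outside the divisors of 192; the plausibility check admits them via
the factor 3. One subtlety worth recording: in purely rotational groups of
222 type, zone reflections such as (hk0) genuinely are centric — their
rotation orbit contains −h — so "no improper operators" does not imply "no
centrics".

**Dialect.** "Unique reflections" means Friedel-merged, absence-excluded,
centrics counted once. Deposited reflection counts in public archives mix
merged and unmerged conventions, so the unmerged count is available via a
flag; merged is the default and the dialect used by the feasibility ratio.

## Feasibility statistic and required resolution

The ratio is exactly N_unique/N_anom, with N_anom counted per asymmetric
unit — the same normalisation as the numerator, making the statistic
invariant under cell multiplicity. The verdict uses a strict ratio > 1000
by default; the threshold is a parameter. Only sulfur has a sequence-based
counter (Cys + Met, case-insensitive, with positions of illegal letters
reported); other scatterers are supplied as explicit counts. Whether
partial-occupancy or solvent sites should count is a judgement call left to
the caller.

The inverse predictor works on a 0.01 Å grid over [0.5, 10] Å. Because the
ratio is a non-increasing step function of d_min, bisection over the grid
is exact: the answer d satisfies ratio(d) > threshold and
ratio(d + 0.01) ≤ threshold, and "unreachable" is reported when even 0.5 Å
fails. The grid makes the inverse well defined despite plateaus in the step
function.

## Sulfur-content statistics and the synthetic proteome

Content = 100·(n_Cys + n_Met)/length per sequence; collection summaries are
unweighted per-sequence means and medians with a 0.5%-bin histogram.
Ambiguity codes (B, Z, X, U, O) are tolerated, counted as non-sulfur and
reported in an ambiguity tally — real proteome files contain them, and
rejecting whole records would bias the statistics.

The generator draws per-sequence lengths from a log-normal law (median 300
residues, σ = 0.45, floor 30 — a realistic protein length distribution) and
per-sequence target content from a Gamma law (shape 4, truncated at 30%)
whose mean is configurable; presets at 3.5% and 4.4% mirror the
bacteria/archaea-like and eukaryote-like regimes. Residues are drawn
per-position with the target fraction split equally between C and M and the
remainder uniform over the other 18 amino acids. Realized content is
therefore binomial around the target and the collection mean is unbiased
for the configured mean, which is what the parameter-recovery tests check.
What the generator does not emulate: residue-composition correlations,
taxonomic structure, disulfide-rich extracellular domains, or any database
snapshot — so passing tests validate the statistics pipeline, not any
claim about real proteomes.

## Synthetic anomalous-diffraction pipeline

Structure factors use direct summation,
F(h) = Σ occ·(f0(s) + f′ + i f″)·exp(−B s²)·exp(2πi h·x) with
s = sinθ/λ = 1/2d, evaluated independently for +h and −h. Normal form
factors f0 are the bundled 4-Gaussian-plus-constant fits (International
Tables parameterisation) for H, C, N, O, S, P, Ca, K, Cl, Zn, Cd, I, V.
Friedel's law (|F(h)| = |F(−h)| when f″ = 0) holds to rounding and is
asserted at 1e-10 relative.

The default toy crystal is a deterministic 18 Å cubic P1 cell with 40
pseudo-randomly packed C/N/O atoms (fixed internal seed — the crystal is a
reproducible object, not a random variable) and 2 sulfur atoms at separated
sites, B = 15 Å², simulated at λ = 2.75 Å to d_min = 2.2 Å (≈1150 Bijvoet
pairs). Its Bijvoet ratio (~5%) is deliberately healthy so that peak
heights are well above map noise and rate effects are resolvable with 10
seeds.

**Noise model.** The experiment of injecting Poisson background into
detector images and re-integrating is emulated at the statistic that
matters, the integrated intensity and its σ: true intensities |F|² are
scaled so their mean is 2000 counts (I/σI ≈ 36 at the lowest rate — the
regime of a well-measured dataset), then
observed = Poisson(I_true) + Poisson(rate·B_ref) with the reference
background B_ref fixed at 10% of the mean true intensity, σ =
√(observed + rate·B_ref), and reported net intensity = observed − expected
background (floored at 0). The rate grid {0.25, 0.5, 1, 2, 4} is preserved
exactly; only relative rates are meaningful because absolute image-level
background units do not transfer to reflection space. All draws derive
from `SeedSequence(seed, spawn_key=(100·rate,))`, so results are
bit-reproducible given (seed, rate).

**Difference map.** Coefficients (|F⁺| − |F⁻|)·exp(i(φ_model − 90°)) at +h
with the conjugate at −h (the standard phased anomalous difference
synthesis; the −90° shift puts positive peaks at anomalous sites), with
phases from the noise-free model playing the role of external phases — no
phasing program is reimplemented. The map is synthesized by FFT on a grid
of spacing d_min/3 (validation rejects anything coarser than d_min/2);
omitting F(000) makes the map mean zero by construction. FFT values agree
with direct single-point summation to 1e-6 relative (tested at ~1e-13).
Peak height = trilinearly interpolated map value at the site divided by the
standard deviation of all grid values.

The experiment computes structure factors once, then per (rate, seed)
injects noise, synthesizes the map and averages peak heights over the
anomalous sites; per-rate means over ≥10 seeds decrease monotonically
across the rate grid, and a weak-occupancy variant of the toy crystal loses
a larger height fraction between the lowest and highest rate than the
full-occupancy one — the weakly-diffracting-crystal effect.

## Problem sizes and determinism

Default problem sizes (toy crystal ~1150 pairs, 5000-sequence proteomes,
randomized symmetry cells kept below ~5000 reflections) were chosen so the
full validation suite represents each scientific claim at comfortable
statistical resolution while remaining desk-scale. All stochastic
components take explicit integer seeds; nothing reads global RNG state.

## Known limitations

* f′/f″ tables carry no white-line or fine-structure effects near edges.
* No absorption, radiation-damage or dose modelling anywhere; the noise
  pipeline isolates background noise only.
* The detector model is a single 2θ_max cut (default 100°); corner effects
  of real panel layouts are not modelled, so quoted limits are meridian
  limits.
* The feasibility threshold is an empirical rule calibrated on
  long-wavelength S-SAD projects; it is not a guarantee, and centric/
  acentric composition is not factored into the ratio.
* Toy crystals are P1 only; the noise experiment does not model symmetry-
  related redundancy or merging.
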