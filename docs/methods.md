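# Methods

This note records the models implemented in `nirtransfer`, their
assumptions, the defaults and why they were chosen, what the simulator does
and does not emulate, and the numerical conventions a maintainer needs.

## The transfer problem

Two spectrometers observe the same samples. Their spectra differ in
wavelength range, number of grid points, resolution and systematic
absorbance level, so a PLS calibration built on one instrument mispredicts
spectra from the other. Both transfer methods here estimate a *linear* map
between the instruments' response spaces from n_t paired transfer
standards; both assume the instruments are linear in the underlying
chemistry (Beer–Lambert regime) and that the transfer standards span the
composition space the map will be used on. Spectra being transferred far
outside that span are flagged with a `LeverageWarning` (median out-of-span
energy fraction > 0.5) but never blocked.

## Score-space PCA transfer

`IPCATransfer.fit(X_src, Y_dest)` factorizes the destination transfer set
by thin SVD, Y = TPᵀ + E with T = U_kΣ_k, P = V_k, then solves
F = X_src⁺ T. `transform(X)` returns X F Pᵀ on the destination grid.

* **No centring inside the transfer.** The SVD acts on raw absorbance and
  the default preprocessing is "none"; the map is linear through the
  origin. Centring or derivatives, if wanted, are applied identically to
  both instruments upstream via `PreprocessSpec`.
* **nPC (`n_components`)** controls how much of the destination spectral
  structure is retained. Too few components cannot carry the analyte
  signal (the RMSEP surface stays high for nPC below the chemical rank);
  too many chase noise. Default 5; the intended selection route is the
  minimum-RMSEP grid search (`grid_search`), which is also how the
  end-to-end runs choose it.
* **Generalized inverse.** SVD-based pseudo-inverse with relative cutoff
  `rcond = 1e-12·σ_max`. A near-rank-deficient source transfer matrix
  (σ_min < 1e-10·σ_max) emits a `ConditioningWarning` and proceeds — the
  cutoff truncates the unstable directions rather than failing.
* **Sign convention.** The SVD leaves each component's sign free; each is
  flipped so the largest-magnitude loading entry is positive, making
  fitted models and their JSON serializations reproducible bit for bit.
* **Transfer-set size.** Warnings below 10 samples (map unreliable) and
  below 30 (short of quantitative practice); never a hard error, since
  screening uses legitimately run smaller.

Key identities, all enforced by tests: transferring the transfer set
itself equals the rank-k SVD reconstruction of the destination set
(exactly when the destination scores lie in the source column space, which
holds automatically for p_src ≥ n_t and for shared low-rank chemistry
otherwise); with identical instruments and full rank the map is the
identity; reconstruction error is non-increasing in nPC; the output grid
length always equals the destination's regardless of the input's — the
property that separates this method from PDS.

## Piecewise direct standardization

`PDSTransfer.fit` regresses each destination wavelength j on the source
window [j−(W−1)/2, j+(W−1)/2] (clipped at the axis ends, never padded —
padding would invent absorbance) with a PLS1 of `n_components` latent
variables, mean-centred per window.

* **Intercepts.** The window regressions retain their intercepts. A pure
  formulation without them cannot remove additive absorbance offsets
  between instruments, and offsets of ~0.1 AU are exactly what
  bench/handheld pairs show; with intercepts, PDS removes them.
* **Edge behaviour.** Clipped windows shrink, and the per-window LV count
  is capped at the shrunk width. Consequence: the "window = p equals
  global direct standardization" degeneration is exact at the centre
  wavelength (whose window spans the whole axis) and approximate toward
  the edges — a deliberate trade against inventing data.
* **Unequal grids.** PDS requires equal point counts. The pipeline
  resamples the lower-resolution instrument onto the overlap of the two
  axes (linear interpolation, no extrapolation ever) and runs PDS and its
  comparison model there. This is this package's documented alignment
  choice for mixed-grid pairs.
* Defaults W = 17, n_components = 2: W = 17 is the standard tuned window
  for NIR standardization tasks of this kind.

## PLS engine

`NIPALSPLS` is a from-scratch NIPALS PLS1: X and y are mean-centred (no
variable scaling — absorbance units are homogeneous across the axis),
components are extracted by w = Xᵀy/‖Xᵀy‖, t = Xw, with X- and
y-deflation, and the regression vector is b = W(PᵀW)⁻¹q. NIPALS for a
univariate response is deterministic — no random initialisation — so every
downstream result is bit-reproducible. At n_components = rank(X) it
coincides with least squares (tested against the pseudo-inverse and
against scikit-learn's PLS implementation, which serves only as a
cross-check, never as the engine).

`loo_select_nlv` runs leave-one-out cross-validation over 1..max_lv,
refitting per fold once at max depth and reading the coefficient sequence
for all shallower models (algebraically identical to naive per-depth
refits; a test asserts equality to 1e-10). Ties break toward the smallest
nLV (parsimony). Transfer-stage and model-stage component counts are
always explicit parameters; nothing re-selects silently.

## Sample-set division

`kennard_stone` is the classical maximin algorithm on raw absorbance with
Euclidean distance (preprocessing before selection is the caller's
choice): seed with the most distant pair, then repeatedly add the sample
maximizing its minimum distance to the selected set. Ties break to the
lowest original index, which makes the selection deterministic, nested in
the selection count, and permutation-invariant on tie-free data. Above
3000 samples the seed pair is found blockwise to avoid materializing the
full distance matrix.

`make_split` composes Kennard–Stone calibration selection with a seeded
random subdivision of the remainder into transfer and validation sets;
`transfer_from="calibration"` instead draws the transfer standards from
the KS selection (removing them from calibration — the three sets stay
disjoint). The RNG is a locally constructed `numpy` generator from the
recorded seed; no global state. `remove_outliers` drops caller-specified
0-based indices — outlier *detection* is out of scope.

## Evaluation

RMSEP = √(mean(pred − ref)²), in reference units. The paired t-test
(two-sided, via `scipy.stats.ttest_rel`) compares two prediction series on
the same validation samples; p > 0.05 at CI 95 % reads as "no significant
difference". Degenerate conventions: all differences exactly zero → (t=0,
p=1) — a defined answer beats an exception inside pipelines; zero-variance
nonzero differences → (±∞, 0). `grid_search` is exhaustive over the
nPC × nLV grid (PLS fits cached per nLV, which cannot change results);
argmin ties break to smaller nPC, then smaller nLV, independent of grid
enumeration order.

## Simulator

`generate_pair` draws, per seed: 3 latent chemical factors, each a sum of
4 Gaussian bands (centres across the union of both axes, widths 30–120 nm,
heights 0.3–1.0, amplitude scale 0.02 AU per concentration unit — broad
overlapping NIR-like overtone bands giving absorbances of order 1);
concentrations uniform in 20–60 mg/mL (uniform, not Gaussian, to give
Kennard–Stone clear extremes); then both instruments sample the *same*
continuous pure-component functions on their own grids — the essential
assumption of the transfer problem. The low-resolution instrument's blur
is applied analytically (a Gaussian band convolved with a Gaussian kernel
stays Gaussian, widths adding in quadrature, area conserved), so the truth
carries no discretization artefacts. The target instrument additionally
gets a wavelength-constant +0.1 AU offset (a sloped-baseline option exists,
default off) and its own iid noise.

Default conditions: 162 samples split 90/30/42; source grid 1557 points
over 1000–2500 nm, target grid 125 points over 908–1676 nm; offset
0.1 AU; spectral noise 0.002 AU per instrument; blur 10 nm; reference-assay
error 1.0 mg/mL (≈2.5 % CV at mid-range — an automated protein assay's
scale; it floors every scenario's RMSEP alike, as real reference methods
do). These sizes keep the full study and its grid search to seconds on one
CPU.

What the simulator does *not* emulate: detector nonlinearity, stray light,
multiplicative scatter, wavelength-registration drift, batch structure and
temperature effects. Passing tests therefore demonstrate correctness of
the algorithms and the qualitative transfer behaviour (transfer restores
accuracy that the raw instrument change destroys; the RMSEP surface drops
once nPC reaches the chemical rank) — not performance claims on any real
instrument pair.

## Numerical and interface conventions

* Wavelengths in nm, strictly increasing, inclusive interval selection;
  wavenumber (cm⁻¹) input is converted by the caller
  (`wavenumber_to_wavelength`; the CLI exposes `--wavenumber`).
* `first_derivative` uses central differences along the (possibly
  non-uniform) nm axis — exact on linear ramps, same-length output;
  Savitzky–Golay is provided separately for smoothing. Resampling is
  linear interpolation and never extrapolates.
* File dialect: delimited text, header = wavelengths, first column =
  sample ID, optional trailing `reference` column. Floats are written with
  shortest-round-trip `repr`, so write→read→write is byte-identical.
  Model files are JSON with a `method` tag (`ipca`, `pds`, `pls1-nipals`);
  JSON float round-tripping is exact, so serialization preserves every
  invariant bit for bit.
* End-to-end runs hash their configuration (SHA-256 over the canonical
  config JSON, output path excluded); the hash is embedded in every JSON
  output, and `manifest.json` carries it for the flat CSV outputs, whose
  dialect has no comment field.
* CLI exit codes: 0 success, 2 parameter error, 3 data-format error,
  4 shape/pairing error.

## Known limitations

Both transfer maps are linear and standard-dependent: a paired transfer
set is mandatory, and extrapolation beyond its span is flagged, not
corrected. The score-space method inherits SVD noise sensitivity when the
transfer set is small or ill-conditioned (hence the warnings). The
reported study sizes are simulation-scale; applying the package to the
public tablet/corn benchmarks requires downloading those sets and choosing
splits, which is deliberately outside the tested surface.
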