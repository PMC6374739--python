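# Methods

## The measurement problem

A photoreceptor that shuttles between a homodimer and a signaling-active
monomer can be assayed in vivo by Förster resonance energy transfer (FRET)
between a GFP donor and an mCherry acceptor fused to the protein. `uvrfret`
implements the two standard readouts on multi-channel confocal images:

1. **Sensitized-emission ratio.** Under 488 nm excitation the acceptor
   fluoresces only through energy transfer (plus artifacts), so the ratio of
   acceptor-band to donor-band intensity, `fret_488 / donor_488`, rises with
   the mean transfer efficiency.
2. **Acceptor photobleaching.** Destroying the acceptor with intense 552 nm
   light removes the transfer pathway and *dequenches* the donor; the percent
   rise of donor fluorescence, `100*(I_pb - I_pre)/I_pre`, measures the energy
   previously lost to FRET.

Two labelling schemes are modelled. In the **NcCg** scheme one polypeptide
carries the acceptor at its N-terminus and the donor at its C-terminus: a
donor in a dimer can transfer intramolecularly and across the dimer
interface, a monomer only intramolecularly. In the **2in1** scheme donor-only
(GFP-X-GFP) and acceptor-only (mCherry-X-mCherry) homotagged proteins are
co-expressed 1:1; monomers are FRET-silent and random assortment yields
donor/donor, mixed, and acceptor/acceptor dimers of which only the mixed
dimer transfers. The 2in1 readout therefore isolates the inter-monomer
signal.

## Forward model (`fret_physics`)

* **Distance law.** `E = R0^6 / (R0^6 + r^6)`; efficiencies may be given
  directly or derived from effective distances.
* **Multiple acceptors.** A donor facing several acceptors is treated as one
  excited state with competing depopulation pathways: path *i* contributes a
  transfer rate `o_i = e_i/(1-e_i)` relative to unit radiative decay, giving
  the combined efficiency `sum(o)/(1+sum(o))`. This rate-additive rule is
  exact for independent exponential pathways (verified in the tests against a
  kinetic Monte-Carlo race); a probabilistic-OR rule is available via
  `combine_rule="or"` for sensitivity analysis only.
* **Species mixtures.** A population is decomposed into assemblies (dimers
  and monomers) with per-donor path lists. The NcCg dimer donor carries two
  paths (`E_intra`, `E_inter`: one cross-interface path per donor, the
  simplest symmetric geometry); the 2in1 mixed dimer one (`E_inter`); all
  other species none. The population mean efficiency is donor-weighted,
  assuming equal donor brightness per molecule.
* **Channel expectations.** The donor channel reports the *quenched* donor
  (`∝ 1-E` — what is measured under donor excitation is the post-FRET
  signal). The FRET channel stacks sensitized emission (`∝ E`) on two
  artifacts: spectral bleed-through of donor emission into the acceptor band
  (`beta_bleed` of the donor signal) and direct acceptor excitation by the
  488 nm line (`alpha_direct` of the full acceptor signal). Single-tag
  control populations make these artifacts observable in isolation.
* **Photobleaching.** The bleach removes each discrete acceptor independently
  with probability `bleach_completeness`; the post-bleach per-donor
  efficiency is the exact expectation over path-survival patterns. At
  complete bleach the donor recovery reduces to the algebraic identity
  `100*E/(1-E)`. We model survival binomially rather than scaling all
  transfer rates continuously because acceptors are discrete chromophores;
  the two pictures coincide at complete bleach and for single-path species
  they differ only at second order.

### Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `R0` | 5.0 nm | typical GFP–mCherry Förster radius |
| `E_intra` | 0.15 | intramolecular N↔C transfer; free parameter (not measurable from the study design), magnitude chosen to reproduce the qualitative orderings |
| `E_inter` | 0.30 | cross-interface transfer in the dimer; free parameter, larger than `E_intra` so monomerization dominates the signal change |
| `beta_bleed` | 0.05 | donor emission collected in the acceptor band; typical GFP tail beyond 590 nm at these band settings |
| `alpha_direct` | 0.02 | acceptor excitation by the 488 nm line |
| `g_donor`, `g_acceptor` | 1.0 | detector gain scale (intensity units/fluorophore); opaque scale factors, never interpreted |
| dimer fraction: WT −UV / +UV | 0.90 / 0.25 | photo-equilibrium: mostly dimeric in darkness; partial monomerization with ongoing re-dimerization under UV-B |
| dimer fraction: constitutive dimer | 0.95 | UV-blind dimer-locked mutant |
| dimer fraction: constitutive monomer | 0.05 | UV-blind monomer-locked mutant; the small residual models weak transient monomer–monomer contacts and is configurable down to 0 |

Whether UV-B changes `E_intra` (a conformational change altering the N–C
distance) is left open by the data this design produces; the default is no
change, and an alternative `FretParams` can be supplied per condition to
explore it.

## Synthetic image generator (`image_synth`)

The generator emulates lower-epidermis fields of transiently transformed
cells in which fluorescence concentrates in a 2–4 px band along each cell
periphery:

* **Geometry.** Voronoi tessellation of jittered-grid seed points; each
  region is eroded by a 2 px wall and the outermost 3 px of the remainder is
  the periphery band. Defaults: 192×192 px, 6 cells (a size chosen so a full
  study renders in seconds; all estimators operate per-pixel and are
  insensitive to the field size).
* **Expression.** Per-cell molecule density is log-normal with mean 200
  molecules/px on the band and CV 0.4, modelling the strong
  cell-to-cell variability of transient transformation.
* **Noise chain.** Per-scan illumination/gain factor `N(1, 0.015)` — the
  donor and FRET channels share one 488 nm scan and hence one factor, while
  every scan of a photobleaching series draws its own (laser output and focus
  are only ~1–2% stable over the minute-long bleach protocol) — then Poisson
  shot noise on the expected counts, then Gaussian read noise (sd 2), clipped
  at 0. Clipping keeps intensities non-negative but gives blank background a
  small positive mean (`sd/sqrt(2π)` ≈ 0.8), the familiar camera-offset
  effect; ratios on dim regions inherit a floor of order 0.01.
* **Replicate variability.** Each independent experiment/replicate redraws
  the dimer fraction on the logit scale (sd 0.4), modelling day-to-day
  variation of the photo-equilibrium (UV dose, leaf age, expression timing).
* **Photobleaching series.** Five pre-bleach donor scans, an instantaneous
  bleach of completeness 0.95 confined to a rectangular region, five
  post-bleach scans. The bleach and control rectangles are placed
  automatically: the bleach box encloses the periphery of the largest cell,
  the control box covers unbleached periphery in the image strip beside it,
  making disjointness structural.
* **I/O.** Multi-page TIFF (uint16 by default, with saturation warnings;
  float32 for lossless work) plus a YAML sidecar naming every page, its
  excitation line (488/552 nm), collection band and gain tag; ground-truth
  efficiency/label/expression maps travel in a separate float TIFF that the
  quantification stage never reads.

**What the generator does not emulate:** point-spread-function blur,
z-sectioning, chromatic shifts, stage drift, donor photobleaching during
scanning (a linear fade hook exists conceptually but the controls here are
flat by construction), photoswitching, or lifetime (FLIM) information.
Passing tests therefore demonstrate correctness of the estimators under an
idealized but noise-faithful image model, not robustness to optical
artifacts absent from the model.

## Quantification (`quantify`)

* **Region sampling.** Square patches (16 px side) drawn uniformly among
  positions whose donor patch-mean exceeds a threshold (Otsu of the
  patch-mean image by default, logged; `min_signal=0` disables the
  constraint), with pairwise overlap capped at 50% of the patch area.
  Saturated pixels are included (flagged upstream at write time).
* **Ratio aggregation.** Per-region ratio of channel means, averaged region →
  image → experiment; the standard error is taken across independent
  experiments, never pooled pixels. A pooled-means alternative
  (`pooled=True`) is provided. Regions with zero donor mean are excluded
  with a logged warning; no background subtraction is applied by default.
* **Periphery tracing.** Otsu threshold on the log intensity within the
  region of interest (log because cells differ multiplicatively in
  expression), longest *closed* iso-contour of the foreground (open contours
  are clipped fragments of neighbouring cells), arc-length resampling to
  ~100 ordered points, intensity as the 3×3 neighbourhood mean per point.
* **Percent increase.** Means over the 5 pre- and 5 post-bleach scans at the
  traced points; `100*(I_pb - I_pre)/I_pre`; the same statistic on the
  unbleached control mask is always reported alongside.

Coordinates are 0-based, row-major, pixel-centred; regions are half-open
rectangles rasterized to pixel sets.

## Inference (`stats`)

Fixed-effects two-way ANOVA (genotype × UV-B) with interaction, Type II sums
of squares (robust to mild imbalance), fitted via statsmodels. Pairwise cell
comparisons use t statistics on the residual mean square with Šídák
adjustment `p_adj = 1-(1-p)^m`; the default family (m=6) is the three
within-genotype ±UV pairs plus the three −UV between-genotype pairs — the
contrasts conventionally annotated on the bar figures. Summaries report
mean ± SE across experiments with significance stars (ratio figures,
α=0.05) or a greedy compact letter display (photobleach figures, α=0.01).
Constant-response tables are reported with zero sums of squares and undefined
F ratios rather than float noise.

**Testing "essentially no FRET".** For the 2in1 constitutive monomer the
natural question is whether any donor dequenching occurred. A literal
one-sample test of the percent increase against zero is confounded: the pre
and post stacks are acquired a minute apart, and the shared illumination
drift between them shifts the percent of *every* region coherently. The
unbleached control region exists precisely to absorb this common mode, so
the package's analyses compare the bleach-region percent against the
control-region percent (Welch two-sample t at the photobleach threshold
α=0.01). With the default 5% residual dimer fraction the monomer's true
recovery is ~0.75%, well inside the control-referenced noise and an order of
magnitude below the dimeric signal.

## Reproducibility and problem sizes

Every stochastic step flows from one seed through `numpy` `SeedSequence`
spawning, making full pipeline runs bit-for-bit reproducible; run manifests
record the resolved configuration, seed and file checksums. The default
study grid is the full protocol — 2 constructs × 3 genotypes × ±UV × 5
experiments × 10 images × 20 regions, and 6 photobleaching replicates per
condition with 5+5 scans and 100 periphery points. The type-I-error
property test uses a reduced field (64 px, 2 cells, 1 image and 10 regions
per experiment) across 500 simulated null studies; the reduction affects
only rendering cost, not the inferential unit (experiment means), which is
what the error rate depends on.

## Known limitations

* Efficiencies `E_intra`/`E_inter` are free parameters, not inferred values;
  the design cannot decompose the NcCg dimer signal into its intramolecular
  and inter-monomer components (the 2in1 scheme exists for that reason).
* The mixed-effects structure (regions within images within experiments) is
  collapsed to experiment means rather than modelled hierarchically.
* No spectral unmixing or bleed-through correction is applied; artifacts are
  modelled, measured via single-tag controls, and otherwise left in the
  ratios, as in standard practice for this assay.
* The 16-bit export quantizes intensities; estimator-exactness guarantees
  hold for in-memory (or float32-exported) data.
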