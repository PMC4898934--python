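# Methods

## Scope

The package quantifies live two-channel movies (kinetochore marker +
geminin/chromatin reporter) and fixed karyotype spreads from cells dividing
after genome reduplication, and ships a synthetic generator that emulates
those data with planted ground truth so every detector can be validated by
parameter recovery. All detectors operate on the real-data path (TIFF +
YAML calibration in, CSV out); the generator is only ever an input source.

## Forward model (synthetic movies)

A movie is T×2×Y×X (default 96×96 px at 0.2 µm/px; 1-min frames for
first-division timing presets, 2-min frames otherwise).

**Kinetochore channel.** Every kinetochore is an isotropic Gaussian spot
(psf σ = 1.0 px in movies, peak 60 counts per kinetochore; a sister-pair
focus is 120). Before NEBD the pairs are aggregated into clusters — one per
polytene/diplochromosome group — placed with ≥ 6 px spacing in a nucleus
whose radius grows with cluster count (≥ 8 px). At NEBD each cluster splits
into its sister-pair foci; child intensities sum exactly to the parent's,
so total flux is conserved until anaphase (verified to < 1e-6 relative).
Split delays are exponential (mean 0.5 min): separation bursts at NEBD,
matching the observed synchrony between the clusteredness and geminin
declines. Split foci scatter ±2.5 px around the parent with a 30% drift
toward their eventual plate site; in a 2-minute congression window ending
at t_plate they move linearly onto the plate (axial jitter σ = 1.0 px,
lateral ± 14 px). At anaphase each pair splits into two kinetochores of
half intensity moving along a uniformly oriented division axis at
6 px/min (1.2 µm/min) per pole, capped at 30 px.

Event times are continuous: t_NEBD and the NEBD→anaphase duration are
drawn per preset (durations truncated-normal; wild type 17.1 ± 2.5 min on
[10, 26], mad2 14.0 ± 2.0 on [8, 22]); anaphase is snapped to the nearest
frame and the onset frame already shows poleward displacement (the
operational meaning of "first frame with poleward movement"). Metaphase
length is drawn per preset (wild-type-like 6 ± 1 min; diplochromosome
divisions 12 ± 2 min, twice the baseline) and fixes
t_plate = t_anaphase − metaphase.

**Geminin/chromatin channel.** A nuclear Gaussian blob (σ = 12 px) carries
the geminin-like brightness: flat at 1 before NEBD, linear to 0 across two
frames, half-maximal exactly at t_NEBD — so the half-max detector is
unbiased by construction and NEBD is *defined* operationally as that
crossing. Two DNA masses (σ = 5 px) sit at the plate and segregate with the
kinetochores. Planted errors: a bridge is a strand of Gaussians (σ = 2 px,
60% of mass brightness) connecting the mass centers; a lagging chromatid is
one kinetochore (plus a small chromatin blob) left within ±2 px of the
spindle equator. In mad2-like presets 30% of cells keep a fixed fraction
(25%, ≥ 1) of clusters unsplit; an unsplit clump congresses to an off-plate
axial offset of 4–8 px (failed biorientation) and always produces a bridge.
Error probabilities per preset: diplochromosome divisions 0.80, mad2
diplochromosome 1.0, separated tetraploid 0.10 (planted modes: bridge or
lagging with equal probability).

**Noise.** Poisson shot noise on (signal + background) plus Gaussian read
noise, background 5% and read σ 2% of the canonical object's peak — the
sister-pair focus for movies — so single post-anaphase kinetochores remain
several σ above background, as in usable real footage. Noise is the last
step; noise-free renders are exactly additive.

**Spreads** are 200×200 two-channel single frames: chromosome bodies as
blurred capsules (sister-pair 14×4.5 px, diplochromosome 16×7, polytene
24×10) and centromere marks as psf-σ 1 px spots 4 px apart (2 per pair
body; 4 in a square for diplochromosomes — "conjoined"; 8 for polytene).
Haploid number 4 (female) / 5 (male). Classes: euploid diploid (2N
bodies), tetraploid separated (4N), diplo-tetraploid (2N bodies × 4
conjoined marks), aneuploid (4N ± 1–2), polytene (N giant bodies), clumped
(4N bodies in groups of four 8 px apart). The `hs10_metaphase` preset mixes
diplo-tetraploid 0.96 / separated 0.04.

## Detectors and numerical choices

- **Foci**: per-frame auto-threshold (Otsu default; Li, mean, and a robust
  background threshold median + 5·1.4826·MAD are available), 8-connectivity,
  min area 4 px, regions sorted row-major. A constant frame yields zero
  regions; "resolvable" deliberately means one connected component — no
  watershed splitting.
- **Clusteredness**: mean over the *union* of focus pixels divided by total
  focus area (only the union statistic is scale-invariant after the per-cell
  min–max normalization to [0, 1]). Frames with no focus pixels carry NaN; a
  constant series normalizes to zeros with a warning.
- **NEBD**: first downward half-max crossing of B_t that stays below 0.5 for
  ≥ 2 frames, interpolated linearly between the bracketing frames.
- **Anaphase**: project focus centroids on the principal axis of the
  final-frame centroid set; d(t) = distance between the two centers of an
  exact 1-D 2-means split; onset = first frame with d above
  median + max(2·MAD, 1 px) of the preceding frames and d rising for the
  next two frames. The 1-px floor guards against MAD collapsing to
  segmentation jitter on stable traces. Frames with < 2 centroids are
  skipped; ≥ 5 valid preceding frames are required.
- **Metaphase plate**: per-frame axial spread of the segmented focus *mask
  pixels* (component centroids wash out when neighbouring foci merge, so
  the pixel spread is used whenever FociSet input is available; bare
  centroid arrays are still accepted). Plate level = median spread of the
  last three pre-onset frames, dropping the final frame if its spread
  doubles (onset detected one frame late); t_plate = the frame after the
  spread last exceeded 1.5× the plate level. No collapse by ≥ 1.5× →
  NoMetaphase.
- **Profiles**: kinetochore frame immediately before onset, rotated so the
  division axis is horizontal (bilinear), cropped to the Otsu mask bounding
  box + 2 px, column-summed, resampled to 100 bins, unit-sum normalized,
  flipped so the center of mass is in the left half (removes the axis-sign
  ambiguity). The variability statistic `sd` is the intensity-weighted
  spatial spread in *pixels* along the axis, computed before resampling —
  a bin-wise standard deviation is insensitive to off-plate clumps after
  the unit-sum resampling, whereas the spatial spread separates clumped
  mad2 plates from wild type decisively. A flat profile gets mirror
  correlation 1 by convention and a degenerate flag. Aggregates use a
  seeded percentile bootstrap (1000 resamples, 95%).
- **Bridge**: chromatin frame at onset + 4 min (configurable), Otsu mask,
  flagged iff one connected component has pixels in both outer-25% regions
  of the mask's pole-to-pole extent along the division axis.
- **Lagging**: kinetochore frame at the same offset, robust background
  threshold and no minimum area (a single lagging kinetochore is a 1–2 px
  object whose peak can fall below a bimodal threshold dominated by bright
  merged pole clumps), flagged iff any focus lies in the middle third of
  the pole-to-pole axis.
- **Karyotype**: bodies by Otsu + components (min 30 px²); marks by local
  maxima of the lightly smoothed (σ 0.5) centromere channel above Otsu,
  assigned to the containing body (stray marks logged). Diplochromosome
  body = 3–4 mutually close marks (< 7 px; three allowed because two of
  four marks occasionally merge into one peak). Polytene = haploid count of
  giant (≥ 150 px²) bodies. Clumped vs separated: median nearest-neighbour
  body distance below vs above one median body equivalent diameter. The
  catch-all is `unclassified` — never an error.
- **Statistics**: pooled two-sided t, one-way ANOVA with Bonferroni over
  all pairwise contrasts, Kruskal–Wallis, chi-squared without continuity
  correction; fold change = ratio of group means with a seeded bootstrap
  CI; α = 0.05 throughout.

## Validation design and problem sizes

Every recovery test regenerates its cohort from named presets with fixed
seeds: 500 fixed cells per foci cohort, 200 movies per timing genotype,
200 diplochromosome divisions and 50 mad2-diplo divisions for error rates,
200 spreads plus 50 noiseless spreads per class for the karyotype
classifier; property suites (flux conservation, bounds, rotation
invariance, byte determinism) run on handfuls of movies. These sizes give
standard errors several times smaller than the planted effects while the
whole suite and the acceptance script each finish in a few minutes on one
CPU. Empirically the pipeline recovers NEBD within one frame in 100% and
anaphase in ~98% of default-noise movies, and the mean durations to about
±0.2 min of the planted 17.1/14.0 min.

## What passing does and does not show

The generator plants punctate, flux-conserving foci, a clean geminin step,
rigid linear anaphase movement and a single cell per movie. Passing
recovery therefore demonstrates the *procedures* are implemented correctly
and are unbiased under the stated forward model — not that they are robust
to focus drift, photobleaching, 3-D defocus, cell crowding or migration,
segmentation of touching cells, or non-Gaussian camera artifacts, none of
which are modelled (2-D only, no drift, no bleaching by design). Karyotype
classification likewise assumes non-overlapping chromosome bodies; real
spreads with touching chromosomes would need manual curation. The t_plate
definition (collapse of axial spread) is an operationalization chosen here;
metaphase lengths are comparable within this package but not necessarily
with other software's definitions.

## Known limitations

- Anaphase time is frame-resolved while NEBD is sub-frame; durations carry
  up to half a frame of quantization noise per cell (unbiased on average).
- t_plate detection is biased early by a fraction of the congression window
  (threshold crossing happens mid-collapse); at 2-min frames this puts
  detected metaphase fold changes slightly above the planted ratio.
- The lagging detector assesses a single offset frame; transient lagging
  resolved before +4 min is invisible, as in the original protocol.
- Bridges dimmer than roughly the Otsu threshold of the chromatin frame
  would be missed; the robust background threshold is available for such
  data via configuration.
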