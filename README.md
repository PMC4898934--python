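# sirs-quant

Quantification of mitosis after genome reduplication, for cell biologists
studying polyploid divisions (e.g. *Drosophila* rectal papillar cells or
wing-disc cells induced to re-replicate their genome). When a cell enters
mitosis after extra S-phases without division, its chromosomes are polytene
or diplochromosomes: the kinetochores start out clustered into about the
haploid number of foci and must separate into recent-sister pairs before
anaphase (SIRS — separation into recent sisters). This package implements
the image-quantification procedures used to characterize such divisions:

- **Resolvable kinetochore foci** — threshold (Otsu by default) + 8-connected
  components on the Cenp-C-like channel; a focus is one connected component,
  F_t per frame.
- **Kinetochore clusteredness** — S_t = (mean intensity over all focus
  pixels) / (total focus area), min-max normalized per cell to K_t ∈ [0, 1];
  drops as clusters disperse into sister pairs.
- **Mitotic timing** — NEBD as the half-maximal downward crossing of the
  normalized nuclear geminin trace B_t (linear interpolation, 2-frame
  persistence); anaphase as the first frame with sustained poleward movement,
  d(t) > median + max(2·MAD, 1 px) of its history, where d(t) is the
  separation of the two 1-D 2-means groups of focus projections on the
  division axis; duration = t_anaphase − t_NEBD. Metaphase length from
  plate formation (collapse of the axial signal spread) to anaphase.
- **Metaphase-plate profiles** — 100-bin unit-sum line profile along the
  division axis plus the spatial spread of the signal (plate variability),
  with seeded-bootstrap aggregate plots.
- **Anaphase-error scoring** at +4 min after onset — DNA bridge: a chromatin
  component spanning both outer-25% pole regions; lagging chromosome: any
  kinetochore focus in the middle third of the pole-to-pole axis.
- **Karyotype-spread classification** — chromosome bodies + per-body
  centromere marks → euploid diploid / tetraploid / diplo-tetraploid /
  aneuploid-tetraploid and polytene / clumped / separated configurations.

Because real movies of this kind are rarely shareable, the package ships a
first-class synthetic generator (`sirs_quant.synthetic`) producing
two-channel TIFF movies and karyotype spreads with planted ground truth —
cluster counts, event times, segregation errors, spread classes — under
named presets (`wt_timing`, `mad2_timing`, `diplo_division`,
`hs10_metaphase`, ...) calibrated to the biological conditions. Every
quantification stage is validated by parameter recovery against that truth.

## Worked example

```bash
python analysis/02_time_divisions.py 1
```

prints

```
wt_timing: mean NEBD->anaphase 17.13 min (n=60, 0 undetected)
mad2_timing: mean NEBD->anaphase 13.90 min (n=60, 0 undetected)
t-test: t=7.24, p=4.99e-11
```

i.e. checkpoint-compromised (*mad2*-like) divisions enter anaphase about
3 minutes earlier than wild type, recovering the planted condition means
(17.1 and 14.0 min). The other numbered drivers quantify foci counts
(`01`, means 4.10 and 15.12 foci before/after the first division), plate
variability (`03`, clumped mad2 plates spread 3.61 px vs 2.33 px wild type,
ANOVA p = 9.3e-05), anaphase-error rates and the metaphase fold change
(`04`: 78.8% / 100% / 10.0% of divisions with lagging or bridge; fold
change 1.88 [1.75–2.02]), and karyotype calls (`05`, 99% of tetraploid
spreads called diplo-tetraploid; all seven planted classes recovered
20/20 noiseless). Each writes its table under `results/`.

The same machinery is scriptable from the shell:

```bash
sirs-quant simulate --preset wt_timing --n 5 --seed 1 --outdir movies/
sirs-quant quantify --indir movies/ --out cells.csv
sirs-quant run --config configs/demo.yaml
```

Library use mirrors the CLI: `generate_movie(preset, seed)` →
`segment_movie` → `detect_nebd` / `detect_anaphase` / `metaphase_length` →
`orient_and_profile` / `score_errors`, with `quantify_movie` composing all
stages with per-stage failure codes.

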