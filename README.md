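# revfiber

Quantification and statistical analysis of dystrophin-positive *revertant
fibers* (RFs) in transverse muscle sections, plus a synthetic-cohort
simulator so the whole pipeline runs without external data.

The package implements:

- **core** — domain types (`FiberRecord`, `SectionGraph`, `StudyKey`), the
  whole-circumference positivity rule (`call_revertant`), and adjacency-graph
  construction from edge lists or 2D integer label maps
  (`graph_from_labelmap`, background never mediates adjacency).
- **quantify** — per-section RF statistics: density (RF/mm²), clusters as
  connected components of adjacent revertant fibers, size classes
  (singleton / small 2–4 / medium 5–8 / large 9–17 / very large ≥18),
  percent clustered, and *isolated* fibers (singletons separated from every
  other RF by at least 2 negative fibers, i.e. graph distance ≥ 3), plus
  mouse/group/study aggregation.
- **stats** — repeated-measures mixed-effects analysis:
  `value ~ muscle * age_group` with a random intercept per mouse (REML via
  statsmodels `MixedLM`), Wald group contrasts with between-within degrees
  of freedom, optional Holm adjustment, and a likelihood-ratio factor
  screen (muscle, age group, mouse random effect, section order).
- **simulate** — a clonal-expansion generator: Poisson founder reversion at
  birth, per-cycle annexation of adjacent fibers, continued de-novo
  reversion, longitudinal extents of 100–300 µm (tail up to 900 µm), and
  10–12 sections ~120 µm apart, so one fiber's positive segment can appear
  in several sections. Emits the exact CSVs the quantify stage consumes,
  with per-section ground-truth cluster histograms.
- **io / reports / cli** — CSV/TIFF readers with row-level validation, run
  manifests, and report grids (mean±sd density table, per-group cluster
  maxima, per-muscle trends, contrast summaries).

## Command line

```sh
revfiber simulate --out-dir cohort/ --seed 17 [--config sim.json] [--mice-per-group 10]
revfiber quantify --fibers cohort/fibers.csv --edges cohort/edges.csv \
    --design cohort/design.csv --out traits.csv [--min-separation 2] \
    [--empty-section-policy zero|drop]
revfiber analyze --traits traits.csv --trait rf_per_mm2 \
    --contrasts 1-4,1-3,2-4 --alpha 0.05 --out contrasts.csv [--adjust holm]
revfiber report --traits traits.csv --contrasts contrasts.csv --out-dir reports/
```

Every run writes a `run_manifest.json` (config hash, seed, versions) for
exact replay.

### CSV schemas

- `fibers.csv`: `section_id,fiber_id,x_um,y_um,csa_um2,stain_fraction,revertant`
- `edges.csv`: `section_id,fiber_a,fiber_b`
- `design.csv`: `mouse_id,age_group,muscle,section_id,section_area_mm2[,z_position_um]`

Decimal commas in numeric fields are accepted on input and normalized to
points.

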