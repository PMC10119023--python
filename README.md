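# cambiokit

Quantitative tools for the vascular cambium of *Arabidopsis* roots in
cross-section: how gibberellin (GA) shifts the cambial auxin-signalling
maximum and, through it, the fate of the bifacial stem cell's daughters.

The package is for plant developmental biologists quantifying confocal or
stained cross-sections of secondary tissue, and for anyone who wants a
fully testable, synthetic-data-backed re-implementation of that analysis
chain. It provides:

* **`synthetic_cambium`** — generators for radial cell files, renderable
  multichannel section images and annotations, with per-condition presets
  and ground truth attached, so the whole pipeline runs without any
  microscopy.
* **`polar_projection`** — rotate a section to the primary-xylem axis,
  unwrap it into an angle × radius map by ray sampling from the root
  centre, align every angular column to the cambial landmark (the
  thinnest, most recent division wall), and aggregate aligned maps into
  per-treatment mean ± sd stacks.
* **`positional_quant`** — the scoring rules: signed cell positions
  around the landmark (−1 | 1, no 0), marker gradient-end ("reach"),
  stem-cell-marker spread over the daughters, EdU placement relative to
  the marker domain, cell-type counts, control normalization, and a
  Pearson chi-square test for categorical position tables.
* **`lineage_sectors`** — clonal (GUS) sector extents relative to the
  landmark, classification (bifacial / xylem-only / phloem-only /
  stem-regain) and landmark-aligned bar-plot tables.
* **`fate_simulator`** — a stochastic model of repeated stem-cell
  divisions where GA sets the per-division outcome probabilities
  (xylem gain `q_x`, phloem gain `q_p`, double-xylem with
  respecification of the adjacent phloem cell `q_d`), emitting
  lineage-labelled sectors.
* **`cli_io` / `cambiokit` CLI** — TIFF + JSON section IO, CSV/YAML/JSON
  tables and configs, and an umbrella pipeline command.

## The core quantities

All positions are signed indices around the most recent periclinal
division wall: … −2, −1 | 1, 2 … with negative values toward the xylem.
For a marker channel with per-cell intensities, the *gradient end* is the
most phloem-ward position of the contiguous supra-threshold run
(threshold = 0.25 × file maximum) containing the channel maximum. The
headline statistic per condition is the fraction of cell files whose
gradient end falls at a stem-cell daughter, P(end ∈ {−1, 1}).

One stem-cell division resolves as xylem gain, phloem gain or — rarely,
under high GA — double xylem, with probabilities (q_x, q_p, q_d),
q_x + q_p + q_d = 1. In the double event both daughters differentiate
and the adjacent phloem cell respecifies as the new stem cell, which is
how a phloem-origin clone can re-acquire stemness. The high-GA preset
fixes q_p = 0.33 and calibrates q_d by exact enumeration of outcome
sequences against the observed 21% sector-class rates (see
`docs/methods.md`).

## Worked example

```python
from cambiokit import (load_preset, make_cell_files, score_files,
                       fraction_reaching, chi_square)
from cambiokit.cli_io import _contingency
from cambiokit.fate_simulator import cohort

col0 = make_cell_files(load_preset("col0_mock"), 500, rng_seed=1)
ga1  = make_cell_files(load_preset("ga1_mock"), 500, rng_seed=2)
d_col0 = score_files(col0, "DR5", condition="col0_mock")
d_ga1  = score_files(ga1, "DR5", condition="ga1_mock")
print(fraction_reaching(d_col0, {-1, 1}), fraction_reaching(d_ga1, {-1, 1}))
tab, bins = _contingency(d_col0, d_ga1)
print(chi_square(tab))
sectors, summary = cohort("ant_stem_cell",
                          load_preset("fate_highGA").fate, 1000, rng_seed=9)
print(summary["class_fractions"])
```

prints

```
0.468 0.326
ChiSquareResult(statistic=31.409228949874276, df=5, p=7.776133804693111e-06)
{'bifacial': 0.797, 'xylem_only': 0.203, 'phloem_only': 0.0, 'stem_regain': 0.0}
```

46.8% of wild-type mock files versus 32.6% of GA-deficient files have the
auxin-reporter gradient reaching a stem-cell daughter (the presets encode
48% and 29%; both recoveries are within sampling error at n = 500), the
position distributions differ strongly (χ², df = 5, p ≈ 8 × 10⁻⁶), and
under the high-GA fate regime 20.3% of stem-cell-origin clones were
pushed entirely into the xylem — the signature of both daughters
differentiating and the stem cell being replaced by respecification.

The same chain runs from the shell:

```sh
cambiokit simulate --preset col0_mock --n-files 2000 --seed 1 --out files.csv
cambiokit render   --files files.csv --out section.tif
cambiokit unwrap   --section section.tif --annotation section.json --out polar.tif
cambiokit quantify --files files.csv --channel DR5 --out dist.csv
cambiokit fate     --preset fate_highGA --origin ant_stem_cell --n 1000 --seed 7 --out sectors.csv
cambiokit sectors  --in sectors.csv --summary summary.json --plot-table bars.csv
```

or end to end from a YAML config with `cambiokit run --config run.yaml
--out outdir` (every artefact carries provenance metadata and an
exclusions report; identical config + seed gives byte-identical tables).

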