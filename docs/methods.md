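# Methods

`cambiokit` models and measures one biological setting: the vascular
cambium of the *Arabidopsis* root during early secondary growth, viewed in
cross-section. The cambium is a bifacial stem-cell niche — a ring of
dividing cells that produces xylem inward and phloem outward. The most
recent periclinal division in each radial cell file is recognizable as the
thinnest cell wall, and every quantity in this package is anchored to that
wall (the *landmark*): the cell just inward of it is position −1, the cell
just outward is position 1, and there is no position 0. Gibberellin (GA)
shifts the position and width of the cambial auxin-signalling maximum and
thereby the fate of the two stem-cell daughters; the package provides the
machinery to quantify that shift and to simulate its consequences for
clonal lineages.

## Synthetic data model

Because the quantification rules operate on manually annotated
micrographs, the package ships a generator that emulates annotated data
with ground truth attached.

A synthetic **cell file** holds `n_xylem` cells inward of the landmark,
`n_phloem` cells outward, and one outermost periderm cell (defaults 5 + 5
+ 1; typical of young secondary tissue where a radial file spans a handful
of cells each side of the cambium). Channels are painted at two levels:
"on" = 1000 a.u. and "off" = 50 a.u., with additive Gaussian noise of
sd 20 a.u. (clipped at 0). The >10:1 separation makes thresholding
unambiguous anywhere in a threshold-fraction range of roughly 0.1–0.6,
while the noise still exercises robustness of the scoring code.

Per-condition presets encode the observed frequencies as categorical
distributions:

* **gradient end** (auxin-reporter channel, `DR5`): the position where
  expression stops, over bins {≤−3, −2, −1, 1, ≥2}. The aggregate
  P(end ∈ {−1, 1}) is 0.48 / 0.29 for wild-type / GA-deficient mock and
  0.83 / 0.57 after 48 h GA. Only the aggregates were observed; the
  split inside {−1, 1} and over the tails is a documented package
  convention (mock remainder uniform over the xylem-side bins; GA
  remainder uniform over {−2, ≥2}), and no downstream statistic depends
  on it. Tail bins resolve to a concrete position uniformly at random
  within the available cells.
* **spread** (stem-cell marker channel, `ANT`): on at both daughters
  {−1, 1} (mock: 0.68) or only at the phloem-side daughter {1} (GA:
  0.43 phloem-only).
* **EdU placement**: one S-phase-labelled nucleus per file, either inside
  the ANT domain (mock: 0.80) or inward of it (GA: 0.36).
* **fate parameters** for the division simulator (below).

Rendering rasterizes files as annular sectors of a concentric wedge
lattice — one file per equal angular wedge, one cell per radial ring —
with a wall channel marking ring boundaries, flat per-cell marker paint,
and i.i.d. Gaussian noise. This is deliberately *not* a growth or optics
model: no cell-shape variation, no point-spread function, no depth
attenuation, no segmentation errors. Tests passing on these images show
the projection and scoring machinery is self-consistent; they do not show
robustness to the geometric and optical variability of real confocal
data, where centre placement and landmark annotation are manual and
imperfect.

All randomness is explicit: every generator takes a seed or NumPy
`SeedSequence`, batch helpers fan one root seed out into per-item child
sequences, and equal seeds give bit-identical output.

## Polar projection

`rotate_section` turns the image about the annotated root centre until
the primary-xylem axis is vertical (bilinear interpolation).
`unwrap` samples each channel along rays from the centre (default 360
angular bins, 1 px radial step — pixel-scale fidelity for typical
512–2048 px sections) with bilinear interpolation; rays are truncated and
masked at the image border, never extrapolated. Angles are degrees
counter-clockwise from the vertical axis; image coordinates are 0-based,
x rightward, y downward. `align_to_landmark` interpolates the annotated
landmark polyline across angular gaps (linear in angle–radius, periodic
over 360°) and shifts each column by a whole number of radial bins so the
landmark sits on a common reference row (default: the largest landmark
bin, so no column loses inner samples). Integer shifts preserve raw
intensities; landmark annotation is only cell-accurate anyway. Masked
bins are carried, counted, and reported — never dropped silently.
`aggregate` computes per-bin mean, population sd (0 where n = 1) and n
across maps; values are sorted per bin before reduction so the result is
bit-identical under input reordering.

The choice of resampling scheme and bin counts is this package's own;
self-consistency (round trips, an independent nearest-neighbour sampling
oracle, area-weighted intensity conservation within 3%) is tested, but
equivalence with any particular prior implementation is not claimed.

## Quantification rules

`gradient_end` thresholds a channel at a fraction of the file's maximum
(default 0.25) and returns the most phloem-ward position of the
contiguous above-threshold run containing the maximum. Contiguity is the
conservative reading for markers that can be patchy around the cambium;
an `contiguous=False` mode scores the outermost above-threshold cell
anywhere instead. A channel with no positive signal yields a
`no_expression` sentinel that stays in the denominator of downstream
fractions. `classify_spread` and `classify_edu` apply the same threshold
to the stem-cell marker; EdU-positive cells phloem-ward of the marker
domain are labelled `excluded` and dropped from the two-class denominator
(only in-domain and xylem-side nuclei were scored classes), with the
exclusion tally reported. `count_cell_types` splits at the landmark:
everything inward is xylem (vessels only where labelled as such, the rest
parenchyma, including the inner stem-cell daughter), everything outward
up to the periderm is phloem. Files without a recognizable landmark are
excluded and counted, mirroring scoring on real sections.
`normalize_by_control` rescales per experiment batch so the control-group
mean is exactly 1. The chi-square test is the plain Pearson statistic
with df = (r−1)(c−1) and no continuity correction by default (a Yates
flag exists); zero expected counts raise with advice to merge bins.

## Fate simulator

The simulator is an abstraction of the cartoon model, not a transport
model: the auxin maximum's position is collapsed into three per-division
outcome probabilities. One radial file holds exactly one stem cell. Each
cycle it divides into daughters at −1/1 and the division resolves:

* `xylem_gain` (probability `q_x`): −1 daughter → xylem;
* `phloem_gain` (`q_p`): +1 daughter → phloem;
* `double_xylem` (`q_d`): both daughters → xylem and the phloem cell
  adjacent to the cambium respecifies as the new stem cell. If no phloem
  cell remains the file terminates with a flag.

Cell number grows by exactly one per division; respecification relabels,
it does not add. Lineage labels are inherited, so clones stay contiguous
and can be read out as sectors with xylem/phloem extents relative to the
final landmark.

Presets: `fate_mock` = (0.5, 0.5, 0) — balanced bifacial output;
`fate_lowGA` = (0.33, 0.67, 0) — the mirrored phloem bias;
`fate_highGA` fixes `q_p` = 0.33 (a third of divisions produce phloem
under high GA) and calibrates `q_d` against the sector-level
observations: 21% of stem-cell-origin (ANT) clones end entirely on the
xylem side, and 21% of phloem-origin (PEAR1) clones contain a stem cell.
Both events are first-passage events — a double-xylem division counts
only if no phloem-gain happened earlier in that clone, because otherwise
the respecified cell is the clone's own phloem and stem identity stays
inside the clone — so neither equals `1 − (1 − q_d)^n`. The calibration
enumerates all 3^`n_cycles` outcome sequences through the simulator
itself (exact, no sampling), and picks the `q_d` minimizing the summed
squared deviation of the two enumerated class probabilities from 0.21; a
single `q_d` cannot satisfy both exactly (resulting expectations ≈ 21.6%
and 20.2%, both inside the sampling error of 1,000-sector cohorts). With
`q_p` fixed this gives `q_d` ≈ 0.100, `q_x` ≈ 0.570.

`n_cycles` defaults to 5 for a 6-day tracing window (~one division per
1.2 days); it is a free parameter, and the calibration is re-run for any
other value. The tracing origins are: `ant_stem_cell` labels the stem
cell, `pear1_phloem` the innermost phloem cell, `random_cambium` either
recent daughter with equal probability.

Sector classification: bifacial (both extents positive, landmark within
or at the clone boundary), xylem-only (clone entirely inward of the
landmark), phloem-only, and — for phloem-origin clones — stem-regain when
the clone contains a stem cell or spans the landmark. The
`contains_stem` field exists because a clone respecified on the final
cycle is a single stem cell sitting just outside the newest wall; by
span alone it would be indistinguishable from a plain phloem sector.
Clones truncated on dead xylem vessels (a real-data phenomenon: staining
is invisible in dead cells) carry a flag and their xylem extent is a
lower bound; the synthetic simulator never truncates.

Cohort summaries report mean ± sd extents and class fractions. For real
lineage data only proliferating sectors are informative; the summary's
`min_size` defaults to 3 cells, this package's operationalization of
"proliferated" (the original cut-off is not stated anywhere; simulated
cohorts are summarized with `min_size=1` since every window is observed).

## Problem sizes and checks

The test and acceptance workloads are sized for a laptop-class single
CPU: 2,000 files per gradient-end condition, 1,000 files per
spread/EdU condition, 1,000 sectors per origin, 10,000 division
outcomes — matching the recovery tolerance of three binomial standard
errors used throughout. The whole suite runs in well under a minute.

Known limitations: no automatic centre/landmark detection (annotations
are inputs by design); no segmentation of real images into cells; the
wedge-lattice renderer cannot probe robustness to real tissue geometry;
the fate model has no spatial auxin field, so questions about transport
or signalling dynamics are outside its scope; and division rate and
window length are folded into the single `n_cycles` parameter.
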