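"""Synthetic cambium cross-section data with attached ground truth.

Generates the three kinds of object every downstream stage consumes, so the
whole pipeline is testable without microscopy:

* :class:`CellFile` -- an ordered radial file of cells (innermost first)
  with identities, per-channel marker intensities, EdU flags and the
  landmark index of the thinnest (most recent) division wall.  Marker
  expression ends at a position drawn from a preset categorical
  distribution; the draw is recorded as ground truth.
* :class:`RadialSection` -- a renderable multichannel raster of concentric
  cell wedges built from cell files, with centre, xylem-axis angle and a
  per-wedge landmark polyline, i.e. exactly the annotation a human would
  supply for a real confocal section.
* lineage sectors, via the presets' fate parameters and
  :mod:`cambiokit.fate_simulator`.

Preset frequencies encode the observed condition-specific statistics:
fractions of files whose auxin-reporter (DR5v2-like) gradient ends at the
stem-cell daughters, the spread of the stem-cell marker (ANT-like) over
the daughters, the placement of EdU-positive nuclei relative to the ANT
domain, and GA-regime fate parameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fate_simulator import FateParams, calibrate_double_xylem

__all__ = [
    "ON_INTENSITY",
    "OFF_INTENSITY",
    "DEFAULT_NOISE_SD",
    "GeneratorPreset",
    "CellFile",
    "RadialSection",
    "available_presets",
    "load_preset",
    "make_cell_file",
    "make_cell_files",
    "render_section",
    "spawn_seeds",
]

# Synthetic intensity levels, arbitrary fluorescence units.  The >10:1
# on/off separation makes thresholding unambiguous at any threshold
# fraction in 0.1-0.6 while noise still exercises robustness.
ON_INTENSITY = 1000.0
OFF_INTENSITY = 50.0
DEFAULT_NOISE_SD = 20.0

#: Categorical bins for the gradient-end position.  Tail bins pool
#: everything at or beyond +/-2/3 because per-position tail frequencies
#: were not reported, only aggregates.
END_BINS = ("<=-3", "-2", "-1", "1", ">=2")
SPREAD_CLASSES = ("both_daughters", "phloem_only")
EDU_CLASSES = ("overlap_ant", "xylem_side")

IDENTITIES = (
    "vessel",
    "xylem_parenchyma",
    "stem_daughter",
    "phloem",
    "sieve_element",
    "periderm",
)


def _validated(probs: dict, keys: tuple) -> dict:
    out = {k: float(probs.get(k, 0.0)) for k in keys}
    if any(v < 0 for v in out.values()):
        raise ValueError("negative probability")
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {total}, not 1")
    return out


@dataclass(frozen=True)
class GeneratorPreset:
    """One named synthetic condition.

    ``end_position_probs`` is a categorical distribution over
    ``END_BINS`` for where the gradient-marker expression ends;
    ``spread_probs`` over ``SPREAD_CLASSES`` for the ANT-like domain;
    ``edu_probs`` over ``EDU_CLASSES`` for EdU nucleus placement;
    ``fate`` holds the division-outcome probabilities for sector
    simulation.  All probability vectors must sum to 1 within 1e-9.
    """

    name: str
    end_position_probs: dict
    spread_probs: dict
    edu_probs: dict
    fate: FateParams
    noise_sd: float = DEFAULT_NOISE_SD
    n_files_per_section: int = 16
    marker_channel: str = "DR5"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "end_position_probs", _validated(self.end_position_probs, END_BINS)
        )
        object.__setattr__(
            self, "spread_probs", _validated(self.spread_probs, SPREAD_CLASSES)
        )
        object.__setattr__(self, "edu_probs", _validated(self.edu_probs, EDU_CLASSES))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_files_per_section < 1:
            raise ValueError("n_files_per_section must be >= 1")


@dataclass
class CellFile:
    """An ordered radial file of cells, innermost (index 0) first.

    ``landmark_index`` is a boundary index: the thinnest wall sits between
    cells ``landmark_index - 1`` (position -1) and ``landmark_index``
    (position +1).  ``intensities`` maps channel name to one value per
    cell.  ``ground_truth`` records the generator draws (``end_position``,
    ``spread_class``, ``edu_class``) for round-trip testing.
    """

    identities: list
    intensities: dict
    landmark_index: int
    edu_positive: np.ndarray
    apl_positive: np.ndarray
    ground_truth: dict = field(default_factory=dict)
    file_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.identities)
        if not 1 <= self.landmark_index <= n - 1:
            raise ValueError("landmark must lie strictly between two cells")
        for ch, vals in self.intensities.items():
            if len(vals) != n:
                raise ValueError(f"channel {ch!r} length mismatch")
        if len(self.edu_positive) != n or len(self.apl_positive) != n:
            raise ValueError("flag array length mismatch")
        peri = [i for i, ident in enumerate(self.identities) if ident == "periderm"]
        if peri and peri != list(range(peri[0], n)):
            raise ValueError("periderm cells must be outermost")

    @property
    def n_cells(self) -> int:
        return len(self.identities)

    @property
    def channels(self) -> list:
        return list(self.intensities)


@dataclass
class RadialSection:
    """A multichannel raster section plus its annotations.

    ``image`` has shape (n_channels, H, W); ``channels`` names each page.
    ``centre`` is (x, y) in pixel coordinates (x rightward, y downward,
    0-based).  ``xylem_axis_angle`` is degrees counter-clockwise from the
    vertical (up) axis.  ``landmark_polyline`` is a (n, 2) array of
    (angle_deg, radius_px) samples of the cambial landmark.
    """

    image: np.ndarray
    channels: list
    centre: tuple
    xylem_axis_angle: float
    landmark_polyline: np.ndarray
    pixel_size: float = 1.0
    files: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.image.ndim != 3:
            raise ValueError("image must be (channels, H, W)")
        if len(self.channels) != self.image.shape[0]:
            raise ValueError("channel names do not match image pages")
        h, w = self.image.shape[1:]
        x, y = self.centre
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError("centre lies outside the image")
        poly = np.asarray(self.landmark_polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2:
            raise ValueError("landmark_polyline must be (n, 2) [angle_deg, radius_px]")
        half = min(h, w) / 2
        if np.any(poly[:, 1] <= 0) or np.any(poly[:, 1] >= half):
            raise ValueError("landmark radius must be in (0, image half-extent)")
        self.landmark_polyline = poly


def _build_presets() -> dict:
    """Construct the named preset registry.

    Gradient-end aggregates over {-1, 1} follow the observed per-condition
    fractions; the remaining mass is split uniformly over the xylem-side
    bins for mock conditions (expression typically retreats into the
    xylem) and over {-2, >=2} for GA-treated conditions (expression
    spread varies in both directions after treatment).  Within {-1, 1},
    mock mass sits mostly at -1 (phloem-side daughter expression is rare
    without GA) and shifts towards 1 under GA.
    """
    fate_mock = FateParams(q_x=0.5, q_p=0.5, q_d=0.0, name="fate_mock")
    fate_low = FateParams(q_x=0.33, q_p=0.67, q_d=0.0, name="fate_lowGA")
    fate_high = calibrate_double_xylem()

    # spread/edu defaults for conditions where those channels are not the
    # measured quantity
    spread_mock = {"both_daughters": 0.68, "phloem_only": 0.32}
    spread_ga = {"both_daughters": 0.57, "phloem_only": 0.43}
    edu_mock = {"overlap_ant": 0.80, "xylem_side": 0.20}
    edu_ga = {"overlap_ant": 0.64, "xylem_side": 0.36}

    def ends(m3, m2, m1, p1, p2):
        return {"<=-3": m3, "-2": m2, "-1": m1, "1": p1, ">=2": p2}

    presets = {}

    def add(name, end, spread, edu, fate):
        presets[name] = GeneratorPreset(
            name=name,
            end_position_probs=end,
            spread_probs=spread,
            edu_probs=edu,
            fate=fate,
        )

    # Auxin-reporter gradient-end conditions: P(end in {-1,1}) =
    # 0.48 / 0.29 (mock Col-0 / ga1), 0.83 / 0.57 (48 h GA).
    add("col0_mock", ends(0.26, 0.26, 0.40, 0.08, 0.00), spread_mock, edu_mock, fate_mock)
    add("ga1_mock", ends(0.355, 0.355, 0.25, 0.04, 0.00), spread_mock, edu_mock, fate_low)
    add("col0_ga48h", ends(0.00, 0.085, 0.50, 0.33, 0.085), spread_ga, edu_ga, fate_high)
    add("ga1_ga48h", ends(0.00, 0.215, 0.37, 0.20, 0.215), spread_ga, edu_ga, fate_high)

    # Stem-cell-marker spread conditions (both daughters 68% mock, phloem
    # only 43% after GA).
    add("ant_mock", ends(0.26, 0.26, 0.40, 0.08, 0.00), spread_mock, edu_mock, fate_mock)
    add("ant_ga", ends(0.00, 0.085, 0.50, 0.33, 0.085), spread_ga, edu_ga, fate_high)

    # EdU placement conditions (in ANT domain 80% mock; xylem side 36% GA).
    add("edu_mock", ends(0.26, 0.26, 0.40, 0.08, 0.00), spread_mock, edu_mock, fate_mock)
    add("edu_ga", ends(0.00, 0.085, 0.50, 0.33, 0.085), spread_ga, edu_ga, fate_high)

    # Fate-only conditions.
    add("fate_mock", ends(0.26, 0.26, 0.40, 0.08, 0.00), spread_mock, edu_mock, fate_mock)
    add("fate_lowGA", ends(0.355, 0.355, 0.25, 0.04, 0.00), spread_mock, edu_mock, fate_low)
    add("fate_highGA", ends(0.00, 0.085, 0.50, 0.33, 0.085), spread_ga, edu_ga, fate_high)
    return presets


_PRESETS: Optional[dict] = None


def available_presets() -> list:
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _build_presets()
    return sorted(_PRESETS)


def load_preset(name: str) -> GeneratorPreset:
    """Return a named, validated preset.

    Raises ``KeyError`` listing the valid names when ``name`` is unknown.
    """
    names = available_presets()
    if name not in names:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(names)}")
    return _PRESETS[name]


def spawn_seeds(root_seed: int, n: int) -> list:
    """Derive ``n`` independent child seed sequences from one root seed."""
    return np.random.SeedSequence(root_seed).spawn(n)


def _draw_category(rng: np.random.Generator, probs: dict) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=[probs[k] for k in keys])]


def _end_bin_to_position(
    bin_name: str, rng: np.random.Generator, n_xylem: int, n_phloem: int
) -> int:
    if bin_name == "-2":
        return -2
    if bin_name == "-1":
        return -1
    if bin_name == "1":
        return 1
    if bin_name == "<=-3":
        if n_xylem < 3:
            raise ValueError("n_xylem must be >= 3 when the <=-3 bin has mass")
        return -int(rng.integers(3, n_xylem + 1))
    if bin_name == ">=2":
        if n_phloem < 2:
            raise ValueError("n_phloem must be >= 2 when the >=2 bin has mass")
        return int(rng.integers(2, n_phloem + 1))
    raise ValueError(f"unknown end bin {bin_name!r}")


def make_cell_file(
    preset: GeneratorPreset,
    n_xylem: int = 5,
    n_phloem: int = 5,
    rng_seed=None,
    file_id: str = "",
    add_periderm: bool = True,
) -> CellFile:
    """Draw one synthetic radial cell file from a preset.

    The file holds ``n_xylem`` cells inward of the landmark (positions
    ``-n_xylem .. -1``), ``n_phloem`` cells outward (``1 .. n_phloem``)
    and, when ``add_periderm``, one periderm cell outermost.  The
    gradient channel (``preset.marker_channel``) is ON from the innermost
    cell up to the drawn end position and OFF (noise only) beyond; the
    ANT channel is ON at positions {-1, 1} or {1} per the drawn spread
    class; one EdU-positive nucleus is placed per the drawn EdU class.
    All draws are recorded in ``ground_truth``.
    """
    if n_xylem < 2 or n_phloem < 2:
        raise ValueError("need n_xylem >= 2 and n_phloem >= 2")
    rng = np.random.default_rng(rng_seed)

    end_bin = _draw_category(rng, preset.end_position_probs)
    end_pos = _end_bin_to_position(end_bin, rng, n_xylem, n_phloem)
    spread = _draw_category(rng, preset.spread_probs)
    edu_class = _draw_category(rng, preset.edu_probs)

    n = n_xylem + n_phloem + (1 if add_periderm else 0)
    landmark_index = n_xylem

    def pos_to_index(p: int) -> int:
        return landmark_index + p + (0 if p < 0 else -1)

    positions = [i - landmark_index if i < landmark_index else i - landmark_index + 1
                 for i in range(n)]

    identities = []
    for i, p in enumerate(positions):
        if add_periderm and i == n - 1:
            identities.append("periderm")
        elif p in (-1, 1):
            identities.append("stem_daughter")
        elif p < 0:
            identities.append("vessel" if rng.random() < 0.4 else "xylem_parenchyma")
        else:
            identities.append("sieve_element" if rng.random() < 0.3 else "phloem")

    apl = np.zeros(n, dtype=bool)
    for i, ident in enumerate(identities):
        if ident == "sieve_element":
            apl[i] = True
        elif positions[i] > 0 and ident != "periderm" and rng.random() < 0.3:
            apl[i] = True

    noise = lambda: rng.normal(0.0, preset.noise_sd, size=n)  # noqa: E731

    grad = np.full(n, OFF_INTENSITY)
    grad[: pos_to_index(end_pos) + 1] = ON_INTENSITY
    grad = np.clip(grad + noise(), 0.0, None)

    ant = np.full(n, OFF_INTENSITY)
    ant_positions = (-1, 1) if spread == "both_daughters" else (1,)
    for p in ant_positions:
        ant[pos_to_index(p)] = ON_INTENSITY
    ant = np.clip(ant + noise(), 0.0, None)

    edu = np.zeros(n, dtype=bool)
    if edu_class == "overlap_ant":
        edu[pos_to_index(int(rng.choice(ant_positions)))] = True
    else:  # xylem_side of the ANT domain
        inner_limit = min(ant_positions)  # -1 or 1
        candidates = [p for p in positions if p < inner_limit and p < 0]
        edu[pos_to_index(int(rng.choice(candidates)))] = True

    intensities = {preset.marker_channel: grad}
    if "ANT" not in intensities:
        intensities["ANT"] = ant

    return CellFile(
        identities=identities,
        intensities=intensities,
        landmark_index=landmark_index,
        edu_positive=edu,
        apl_positive=apl,
        ground_truth={
            "end_bin": end_bin,
            "end_position": end_pos,
            "spread_class": spread,
            "edu_class": edu_class,
        },
        file_id=file_id,
    )


def make_cell_files(
    preset: GeneratorPreset,
    n_files: int,
    rng_seed,
    n_xylem: int = 5,
    n_phloem: int = 5,
) -> list:
    """Generate ``n_files`` independent cell files from one root seed."""
    seeds = spawn_seeds(rng_seed, n_files) if not isinstance(
        rng_seed, np.random.SeedSequence
    ) else rng_seed.spawn(n_files)
    return [
        make_cell_file(preset, n_xylem, n_phloem, rng_seed=s, file_id=f"file{i:05d}")
        for i, s in enumerate(seeds)
    ]


def render_section(
    files: Sequence[CellFile],
    radii: Optional[np.ndarray] = None,
    pixel_size: float = 1.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng_seed=None,
    wall_width: float = 1.0,
    margin: int = 8,
    xylem_axis_angle: float = 90.0,
) -> RadialSection:
    """Rasterize cell files into a concentric wedge-lattice section.

    Each file occupies one equal angular wedge; cell ``j`` of a file fills
    the annulus between ``radii[j]`` and ``radii[j + 1]``.  The wall
    channel marks ring boundaries (bright lines of ``wall_width`` px);
    marker channels are painted flat per cell from the file intensities;
    i.i.d. Gaussian noise of ``noise_sd`` is added to every channel.  The
    landmark polyline samples each wedge's landmark radius at the wedge
    centre angle.  Angles are counter-clockwise from the vertical (up)
    axis; the wedge for file 0 starts at 0 deg.
    """
    files = list(files)
    if len(files) < 8:
        raise ValueError("need at least 8 files (angular wedges)")
    n_cells_max = max(f.n_cells for f in files)
    if radii is None:
        radii = np.arange(n_cells_max + 1, dtype=float) * 6.0 + 10.0
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or len(radii) < n_cells_max + 1:
        raise ValueError("radii must provide one boundary per cell plus one")
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")

    channels = ["wall"]
    for f in files:
        for ch in f.channels:
            if ch not in channels:
                channels.append(ch)
    has_edu = any(f.edu_positive.any() for f in files)
    if has_edu:
        channels.append("EdU")

    rng = np.random.default_rng(rng_seed)
    r_max = radii[-1]
    half = int(np.ceil(r_max)) + margin
    size = 2 * half + 1
    cx = cy = float(half)

    yy, xx = np.mgrid[0:size, 0:size]
    dx = xx - cx
    dy = yy - cy
    r = np.hypot(dx, dy)
    # angle CCW from the vertical (up) axis, in [0, 360)
    theta = np.degrees(np.arctan2(-dx, -dy)) % 360.0

    n_wedges = len(files)
    wedge = np.floor(theta / (360.0 / n_wedges)).astype(int) % n_wedges
    ring = np.searchsorted(radii, r, side="right") - 1  # -1 before radii[0]

    image = np.zeros((len(channels), size, size), dtype=float)
    ch_index = {ch: k for k, ch in enumerate(channels)}

    # wall channel: ring boundaries
    wall = np.zeros((size, size))
    for rb in radii:
        wall[np.abs(r - rb) <= wall_width / 2] = ON_INTENSITY
    image[ch_index["wall"]] = wall

    inside = (ring >= 0) & (r < r_max)
    for w, f in enumerate(files):
        sel_w = inside & (wedge == w) & (ring < f.n_cells)
        for ch in f.channels:
            vals = f.intensities[ch]
            image[ch_index[ch]][sel_w] = vals[ring[sel_w]]
        if has_edu:
            edu_img = np.where(f.edu_positive[np.clip(ring, 0, f.n_cells - 1)],
                               ON_INTENSITY, OFF_INTENSITY)
            image[ch_index["EdU"]][sel_w] = edu_img[sel_w]

    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
        image = np.clip(image, 0.0, None)

    wedge_step = 360.0 / n_wedges
    poly = np.array(
        [
            [(w + 0.5) * wedge_step, radii[f.landmark_index]]
            for w, f in enumerate(files)
        ]
    )

    return RadialSection(
        image=image,
        channels=channels,
        centre=(cx, cy),
        xylem_axis_angle=xylem_axis_angle,
        landmark_polyline=poly,
        pixel_size=pixel_size,
        files=list(files),
    )
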