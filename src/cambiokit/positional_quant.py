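"""Positional quantification rules for annotated radial cell files.

All rules anchor to the cambial landmark, the most recent (thinnest)
periclinal division wall.  Cells are indexed by signed position: the cell
just inward (xylem side) of the wall is -1, the cell just outward
(phloem side) is 1, and there is no position 0 -- the wall itself
separates -1 from 1.

The quantifications mirror how annotated cross-sections are scored:

* the *reach* of a gradient marker (auxin-reporter or PIN1-like): the
  most phloem-ward position at which expression is still seen
  (:func:`gradient_end`);
* the *spread* of the stem-cell marker over the two daughters
  (:func:`classify_spread`);
* EdU-positive nuclei relative to the stem-cell marker domain
  (:func:`classify_edu`);
* cell-type counts with the xylem/phloem split at the landmark
  (:func:`count_cell_types`), the conductive-phloem ratio
  (:func:`apl_ratio`), and per-batch normalization to a control
  (:func:`normalize_by_control`);
* a Pearson chi-square comparison of categorical position tables
  (:func:`chi_square`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .synthetic_cambium import CellFile

__all__ = [
    "NO_EXPRESSION",
    "PositionIndex",
    "PositionDistribution",
    "CellTypeCounts",
    "ChiSquareResult",
    "index_positions",
    "gradient_end",
    "score_files",
    "fraction_reaching",
    "classify_spread",
    "classify_edu",
    "count_cell_types",
    "apl_ratio",
    "normalize_by_control",
    "chi_square",
]

#: Sentinel for files with no supra-threshold expression; such files are
#: tallied separately, never silently dropped.
NO_EXPRESSION = "no_expression"

DEFAULT_THRESHOLD_FRACTION = 0.25


@dataclass(frozen=True)
class PositionIndex:
    """Mapping cell index -> signed position (never 0)."""

    positions: tuple
    landmark_index: int

    def __getitem__(self, cell_index: int) -> int:
        return self.positions[cell_index]

    def index_of(self, position: int) -> int:
        if position == 0:
            raise ValueError("position 0 does not exist")
        return self.positions.index(position)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class PositionDistribution:
    """Counts of a categorical outcome (e.g. gradient end) per position.

    ``counts`` maps position (int) or a tail/sentinel label (str) to a
    count; ``n`` is the number of scored cell files.
    """

    counts: dict
    condition: str = ""

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "PositionDistribution") -> "PositionDistribution":
        merged = Counter(self.counts) + Counter(other.counts)
        return PositionDistribution(dict(merged), condition=self.condition)


@dataclass(frozen=True)
class CellTypeCounts:
    vessels: int
    xylem_parenchyma: int
    xylem_total: int
    phloem_total: int
    sieve_elements: int
    apl_positive: int
    periderm_found: bool = True

    def __post_init__(self) -> None:
        if self.xylem_total != self.vessels + self.xylem_parenchyma:
            raise ValueError("xylem_total must equal vessels + parenchyma")
        if self.sieve_elements > self.phloem_total:
            raise ValueError("sieve_elements cannot exceed phloem_total")
        if self.apl_positive > self.phloem_total:
            raise ValueError("apl_positive cannot exceed phloem_total")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def index_positions(file: CellFile) -> PositionIndex:
    """Signed positions around the landmark: ..., -2, -1 | 1, 2, ...

    The cell just inward of the landmark wall is -1, just outward is 1;
    positions are consecutive with no 0.
    """
    lm = file.landmark_index
    if lm is None:
        raise ValueError("file has no landmark")
    positions = tuple(
        i - lm if i < lm else i - lm + 1 for i in range(file.n_cells)
    )
    return PositionIndex(positions=positions, landmark_index=lm)


def _above_threshold(
    file: CellFile, channel: str, threshold_fraction: float
) -> np.ndarray:
    vals = np.asarray(file.intensities[channel], dtype=float)
    if vals.max() <= 0:
        return np.zeros(len(vals), dtype=bool)
    return vals >= threshold_fraction * vals.max()


def _expression_run(
    file: CellFile, channel: str, threshold_fraction: float, contiguous: bool
) -> Optional[np.ndarray]:
    """Cell indices of the scored expression domain, or None if empty.

    With ``contiguous`` (default behaviour of the callers), the domain is
    the contiguous above-threshold run containing the channel maximum --
    the conservative reading when expression is patchy.  Otherwise every
    above-threshold cell counts.
    """
    vals = np.asarray(file.intensities[channel], dtype=float)
    if vals.max() <= 0:  # no signal anywhere -> nothing to score
        return None
    on = vals >= threshold_fraction * vals.max()
    if not on.any():
        return None
    if not contiguous:
        return np.flatnonzero(on)
    peak = int(np.argmax(vals))
    lo = peak
    while lo > 0 and on[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(on) - 1 and on[hi + 1]:
        hi += 1
    return np.arange(lo, hi + 1)


def gradient_end(
    file: CellFile,
    channel: str,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    contiguous: bool = True,
):
    """Most phloem-ward position at which marker expression is seen.

    The threshold is ``threshold_fraction`` of the file's maximum for the
    channel.  By default the scored domain is the contiguous
    above-threshold run containing the maximum; ``contiguous=False``
    scores the outermost above-threshold cell anywhere (for markers with
    patchy expression).  Returns :data:`NO_EXPRESSION` when no cell
    passes the threshold.
    """
    run = _expression_run(file, channel, threshold_fraction, contiguous)
    if run is None:
        return NO_EXPRESSION
    return index_positions(file)[int(run[-1])]


def score_files(
    files: Iterable[CellFile],
    channel: str,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    condition: str = "",
    contiguous: bool = True,
) -> PositionDistribution:
    """Score many files with :func:`gradient_end` into a distribution."""
    counts: Counter = Counter()
    for f in files:
        counts[gradient_end(f, channel, threshold_fraction, contiguous)] += 1
    return PositionDistribution(dict(counts), condition=condition)


def fraction_reaching(
    dist: PositionDistribution, target_positions: Iterable[int]
) -> float:
    """Fraction of scored files whose outcome is in ``target_positions``.

    Exact rational arithmetic until the final conversion to float.
    """
    if dist.n == 0:
        raise ValueError("empty distribution")
    targets = set(target_positions)
    hit = sum(c for pos, c in dist.counts.items() if pos in targets)
    return float(Fraction(hit, dist.n))


def classify_spread(
    file: CellFile,
    channel: str = "ANT",
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> str:
    """Spread of a marker over the stem-cell daughters.

    ``both_daughters`` when positions -1 and 1 are both above threshold,
    ``phloem_only`` when only 1 is, ``other`` otherwise.
    """
    on = _above_threshold(file, channel, threshold_fraction)
    pidx = index_positions(file)
    on_m1 = bool(on[pidx.index_of(-1)])
    on_p1 = bool(on[pidx.index_of(1)])
    if on_m1 and on_p1:
        return "both_daughters"
    if on_p1:
        return "phloem_only"
    return "other"


def classify_edu(
    file: CellFile,
    ant_channel: str = "ANT",
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> list:
    """Classify each EdU-positive cell against the stem-cell marker domain.

    Returns one label per EdU-positive cell: ``overlap_ant`` when the
    cell lies within the supra-threshold marker domain, ``xylem_side``
    when it lies inward of it.  Cells phloem-ward of the domain are
    labelled ``excluded`` (they were not part of the scored classes) so
    the caller can drop them from the denominator without losing count.
    An empty list (no EdU-positive cells) is the flagged empty result.
    """
    edu_idx = np.flatnonzero(file.edu_positive)
    if edu_idx.size == 0:
        return []
    run = _expression_run(file, ant_channel, threshold_fraction, contiguous=True)
    if run is None:
        raise ValueError("no supra-threshold marker domain to classify against")
    lo, hi = int(run[0]), int(run[-1])
    labels = []
    for i in edu_idx:
        if lo <= i <= hi:
            labels.append("overlap_ant")
        elif i < lo:
            labels.append("xylem_side")
        else:
            labels.append("excluded")
    return labels


def count_cell_types(file: CellFile) -> CellTypeCounts:
    """Count cell types with the xylem/phloem split at the landmark.

    Xylem cells are all cells inward of the most recent division
    (including stem-cell daughters on that side); only cells labelled
    ``vessel`` count as vessels (mature secondary vessels), everything
    else inward is parenchyma.  Phloem cells are all cells outward of the
    division up to the periderm border.  When no periderm is labelled the
    phloem extends to the file end and the result is flagged.
    """
    pidx = index_positions(file)
    vessels = parenchyma = phloem = sieve = apl = 0
    periderm_found = False
    for i, ident in enumerate(file.identities):
        if ident == "periderm":
            periderm_found = True
            continue
        if pidx[i] < 0:
            if ident == "vessel":
                vessels += 1
            else:
                parenchyma += 1
        else:
            phloem += 1
            if ident == "sieve_element":
                sieve += 1
            if bool(file.apl_positive[i]):
                apl += 1
    return CellTypeCounts(
        vessels=vessels,
        xylem_parenchyma=parenchyma,
        xylem_total=vessels + parenchyma,
        phloem_total=phloem,
        sieve_elements=sieve,
        apl_positive=apl,
        periderm_found=periderm_found,
    )


def apl_ratio(counts: CellTypeCounts) -> float:
    """Conductive-phloem ratio: APL-positive cells / all phloem cells."""
    if counts.phloem_total == 0:
        raise ValueError("phloem_total is 0; ratio undefined")
    return counts.apl_positive / counts.phloem_total


def normalize_by_control(
    values_by_group: Mapping[str, Sequence[float]],
    control_group: str,
) -> dict:
    """Scale every value by the control-group mean (control mean -> 1).

    Used to pool experiments run in separate batches: apply per batch,
    with the control genotype as ``control_group``.
    """
    if control_group not in values_by_group:
        raise KeyError(f"control group {control_group!r} not present")
    ctrl = np.asarray(values_by_group[control_group], dtype=float)
    if ctrl.size == 0:
        raise ValueError("control group is empty")
    m = ctrl.mean()
    if m == 0:
        raise ValueError("control group mean is zero")
    return {
        g: np.asarray(v, dtype=float) / m for g, v in values_by_group.items()
    }


def chi_square(
    table, yates: bool = False
) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    X^2 = sum (O - E)^2 / E with E from the row/column margins,
    df = (r - 1)(c - 1), two-tailed p from the chi-square survival
    function.  No continuity correction by default; ``yates=True``
    applies the Yates correction (2 x 2 tables).
    Zero expected counts raise (merge sparse bins first).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = row @ col / total
    if np.any(expected == 0):
        raise ValueError(
            "zero expected count; merge rows/columns with empty margins"
        )
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_chi2_dist.sf(stat, df))
    return ChiSquareResult(statistic=stat, df=df, p=p)
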