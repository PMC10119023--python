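"""Clonal lineage-sector analysis for the vascular cambium.

A *sector* is the contiguous radial span of cells descended from a single
clonally marked progenitor (for example a GUS-stained CRE/lox clone).
Sectors are described relative to the cambial landmark -- the most recent
periclinal division wall, recognizable in micrographs as the thinnest cell
wall -- with an extent towards the xylem (inward) and an extent towards the
phloem (outward).  Classifying those extents distinguishes bifacial clones
(the progenitor behaved as a stem cell, producing both tissues), clones
pushed entirely into the xylem (both stem-cell daughters differentiated),
and phloem-origin clones that re-acquired stem-cell identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Sector",
    "SECTOR_CLASSES",
    "sector_extents",
    "classify_sector",
    "sector_plot_table",
    "cohort_summary",
]

#: Valid clone origins.
ORIGINS = ("random_cambium", "ant_stem_cell", "pear1_phloem")

#: Exhaustive, mutually exclusive sector classes.
SECTOR_CLASSES = ("bifacial", "xylem_only", "phloem_only", "stem_regain")

#: Colour key used by :func:`sector_plot_table` (one colour per class).
CLASS_COLOURS = {
    "bifacial": "#666666",
    "xylem_only": "#7fc8e8",
    "phloem_only": "#c9a0dc",
    "stem_regain": "#7fc8e8",
}


@dataclass(frozen=True)
class Sector:
    """A clonal lineage span, positioned relative to the cambial landmark.

    Parameters
    ----------
    origin
        Promoter used to induce the clone: ``ant_stem_cell`` labels the
        cambial stem cell, ``pear1_phloem`` the early-phloem cell adjacent
        to the cambium, ``random_cambium`` either recent daughter.
    n_xylem, n_phloem
        Number of clone cells inward / outward of the landmark.
    landmark_within
        True when the clone spans or touches the landmark wall.
    contains_stem
        True when the clone holds a stem-identity cell at observation
        time (a phloem-origin clone with this flag re-acquired stemness).
    truncated_on_vessel
        True when the inward end of the clone abuts a differentiated
        vessel, making ``n_xylem`` a lower bound: GUS staining cannot be
        seen in dead vessels, so such clones are under-measured.
    """

    origin: str
    n_xylem: int
    n_phloem: int
    landmark_within: bool = False
    contains_stem: bool = False
    truncated_on_vessel: bool = False
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}; valid: {ORIGINS}")
        if self.n_xylem < 0 or self.n_phloem < 0:
            raise ValueError("extents must be non-negative")
        if self.n_xylem + self.n_phloem < 1:
            raise ValueError("a sector holds at least one cell")

    @property
    def size(self) -> int:
        return self.n_xylem + self.n_phloem


def sector_extents(
    clone_cell_indices: Sequence[int], landmark_index: int
) -> tuple[int, int]:
    """Split a contiguous clone at the landmark and count each side.

    Parameters
    ----------
    clone_cell_indices
        Cell indices (innermost = 0) belonging to one clone.  Must form a
        contiguous run -- clones are contiguous by construction because
        only radial (periclinal) divisions occur.
    landmark_index
        Boundary index of the landmark wall: the wall sits between cells
        ``landmark_index - 1`` and ``landmark_index``.

    Returns
    -------
    (n_xylem, n_phloem)
        Counts of clone cells inward (< landmark) and outward (>=).
    """
    idx = sorted(clone_cell_indices)
    if not idx:
        raise ValueError("empty clone")
    if idx[-1] - idx[0] != len(idx) - 1:
        raise ValueError("clone cells are not contiguous")
    n_xylem = sum(1 for i in idx if i < landmark_index)
    return n_xylem, len(idx) - n_xylem


def classify_sector(sector: Sector) -> str:
    """Assign one of ``SECTOR_CLASSES`` to a sector.

    Rules:

    * ``pear1_phloem`` origin: ``stem_regain`` when the clone contains a
      stem cell or straddles the landmark (a phloem-origin clone that
      produced both tissues); ``xylem_only`` when it was pushed fully into
      the xylem; ``phloem_only`` otherwise.
    * other origins: ``bifacial`` when both extents are positive and the
      landmark is within or adjacent to the clone; ``xylem_only`` when the
      clone lies entirely inward of the landmark; ``phloem_only`` when
      entirely outward.
    """
    both = sector.n_xylem > 0 and sector.n_phloem > 0
    if sector.origin == "pear1_phloem":
        if sector.contains_stem or both:
            return "stem_regain"
        if sector.n_phloem == 0:
            return "xylem_only"
        return "phloem_only"
    if both and (sector.landmark_within or sector.contains_stem):
        return "bifacial"
    if sector.n_phloem == 0 and not sector.landmark_within:
        return "xylem_only"
    if sector.n_xylem == 0 and not sector.landmark_within:
        return "phloem_only"
    # Contiguity means a clone with cells on both sides always straddles
    # the wall; reaching here implies inconsistent flags.
    return "bifacial" if both else ("xylem_only" if sector.n_phloem == 0 else "phloem_only")


def sector_plot_table(sectors: Iterable[Sector]) -> pd.DataFrame:
    """Tabulate sectors as landmark-aligned horizontal bars.

    Each sector becomes one bar from ``-n_xylem`` to ``+n_phloem`` in
    landmark-relative cell units (landmark at 0), mirroring the aligned
    sector-bar plots used for lineage-tracing cohorts.  Rows are sorted by
    treatment, then descending total extent, and carry the class colour key.
    """
    sectors = list(sectors)
    if not sectors:
        raise ValueError("need at least one sector")
    rows = []
    for s in sectors:
        cls = classify_sector(s)
        rows.append(
            {
                "treatment": s.treatment,
                "origin": s.origin,
                "start": -s.n_xylem,
                "end": s.n_phloem,
                "n_xylem": s.n_xylem,
                "n_phloem": s.n_phloem,
                "sector_class": cls,
                "colour": CLASS_COLOURS[cls],
                "truncated_on_vessel": s.truncated_on_vessel,
            }
        )
    df = pd.DataFrame(rows)
    df["_extent"] = df["n_xylem"] + df["n_phloem"]
    df = (
        df.sort_values(["treatment", "_extent"], ascending=[True, False])
        .drop(columns="_extent")
        .reset_index(drop=True)
    )
    df.insert(0, "bar", range(len(df)))
    return df


def cohort_summary(
    sectors: Iterable[Sector], min_size: int = 3
) -> dict:
    """Summarize a sector cohort: mean +/- sd extents and class fractions.

    Only proliferating sectors (``size >= min_size``, default 3 cells)
    enter the summary, because non-proliferating clones carry no fate
    information.  Sectors truncated on a vessel are tallied separately;
    their xylem extents are lower bounds.

    Returns a dict with keys ``n``, ``n_excluded_small``, ``n_truncated``,
    ``xylem_mean``, ``xylem_sd``, ``phloem_mean``, ``phloem_sd``,
    ``class_fractions`` (summing to 1 over included sectors) and
    ``sd_defined`` (False when n < 2).
    """
    sectors = list(sectors)
    included = [s for s in sectors if s.size >= min_size]
    n = len(included)
    if n < 2:
        # sd undefined; still report what can be reported
        summary: dict = {"sd_defined": False}
    else:
        summary = {"sd_defined": True}
    xyl = [s.n_xylem for s in included]
    phl = [s.n_phloem for s in included]
    classes = [classify_sector(s) for s in included]
    summary.update(
        n=n,
        n_excluded_small=len(sectors) - n,
        n_truncated=sum(s.truncated_on_vessel for s in included),
        xylem_mean=float(sum(xyl) / n) if n else math.nan,
        phloem_mean=float(sum(phl) / n) if n else math.nan,
    )
    if n >= 2:
        mx, mp = summary["xylem_mean"], summary["phloem_mean"]
        summary["xylem_sd"] = math.sqrt(sum((x - mx) ** 2 for x in xyl) / (n - 1))
        summary["phloem_sd"] = math.sqrt(sum((p - mp) ** 2 for p in phl) / (n - 1))
    else:
        summary["xylem_sd"] = math.nan
        summary["phloem_sd"] = math.nan
    summary["class_fractions"] = {
        c: (classes.count(c) / n if n else math.nan) for c in SECTOR_CLASSES
    }
    return summary
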