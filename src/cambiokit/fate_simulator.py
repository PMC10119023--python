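"""Stochastic bifacial stem-cell fate simulator for the cambium.

Models a single radial cell file containing one cambial stem cell flanked
by xylem (inward) and phloem (outward).  Each division cycle the stem cell
divides periclinally into an inner (-1) and an outer (+1) daughter and the
division resolves into one of three outcomes, with probabilities set by the
gibberellin (GA) regime through the position of the cambial auxin maximum:

``xylem_gain``
    the inner daughter differentiates as xylem, the outer daughter remains
    the stem cell (auxin maximum covers position -1 only);
``phloem_gain``
    the outer daughter differentiates as phloem, the inner daughter remains
    the stem cell (auxin maximum short of the stem-cell daughters);
``double_xylem``
    both daughters differentiate as xylem and the phloem-identity cell
    adjacent to the cambium respecifies as the new stem cell (auxin maximum
    spread over both daughters) -- the rare event by which a phloem-origin
    clone can re-acquire stem-cell identity.

Low GA biases divisions towards ``phloem_gain``, high GA towards
``xylem_gain`` with occasional ``double_xylem``.  Lineage labels are
propagated through divisions so that clone spans can be read out as
:class:`~cambiokit.lineage_sectors.Sector` objects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .lineage_sectors import Sector, classify_sector, cohort_summary

__all__ = [
    "OUTCOMES",
    "FateParams",
    "FileState",
    "initial_state",
    "step",
    "simulate_sector",
    "cohort",
    "outcome_fractions",
    "expected_class_fraction",
    "calibrate_double_xylem",
]

OUTCOMES = ("xylem_gain", "phloem_gain", "double_xylem")


@dataclass(frozen=True)
class FateParams:
    """Per-division outcome probabilities for one GA regime.

    q_x + q_p + q_d must equal 1 (within 1e-9).  ``n_cycles`` is the
    number of divisions in one lineage-tracing window (default 5 for a
    6-day window, roughly one division per 1.2 days).
    """

    q_x: float
    q_p: float
    q_d: float = 0.0
    n_cycles: int = 5
    name: str = ""

    def __post_init__(self) -> None:
        for q in (self.q_x, self.q_p, self.q_d):
            if not 0.0 <= q <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.q_x + self.q_p + self.q_d - 1.0) > 1e-9:
            raise ValueError("q_x + q_p + q_d must sum to 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def probs(self) -> tuple[float, float, float]:
        return (self.q_x, self.q_p, self.q_d)


@dataclass
class FileState:
    """Radial cell file during a simulation.

    ``identities[i]`` is ``xylem``/``stem``/``phloem`` for the cell at
    index ``i`` (0 = innermost).  ``labels[i]`` carries the clone label or
    None.  ``landmark_index`` is the boundary index of the newest division
    wall (wall between cells ``landmark_index - 1`` and ``landmark_index``).
    """

    identities: list
    labels: list
    landmark_index: int
    cycle: int = 0
    terminated: bool = False
    events: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.identities)

    @property
    def stem_index(self) -> Optional[int]:
        idx = [i for i, ident in enumerate(self.identities) if ident == "stem"]
        if len(idx) > 1:
            raise AssertionError("more than one stem cell in file")
        return idx[0] if idx else None


def initial_state(n_xylem: int = 4, n_phloem: int = 6) -> FileState:
    """Build a fresh file: ``n_xylem`` xylem | stem | ``n_phloem`` phloem."""
    identities = ["xylem"] * n_xylem + ["stem"] + ["phloem"] * n_phloem
    return FileState(
        identities=identities,
        labels=[None] * len(identities),
        landmark_index=n_xylem,  # wall of the (pre-window) last division
    )


def step(
    state: FileState,
    params: FateParams,
    rng: Optional[np.random.Generator] = None,
    outcome: Optional[str] = None,
) -> FileState:
    """Advance the file by one stem-cell division (in place, returns state).

    The outcome is drawn from ``params`` unless ``outcome`` forces one
    (used for exact enumeration and tests).  A ``double_xylem`` with no
    phloem cell left to respecify terminates the file with a flag rather
    than failing silently.
    """
    if state.terminated:
        raise RuntimeError("file is terminated; no stem cell to divide")
    s = state.stem_index
    if s is None:
        raise RuntimeError("no stem cell in file")
    if outcome is None:
        if rng is None:
            raise ValueError("either rng or a forced outcome is required")
        outcome = OUTCOMES[rng.choice(3, p=list(params.probs))]
    elif outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")

    # Periclinal division: stem -> inner (-1) + outer (+1) daughter; the
    # new wall between them becomes the landmark.
    lab = state.labels[s]
    state.identities[s : s + 1] = ["stem", "stem"]
    state.labels[s : s + 1] = [lab, lab]
    state.landmark_index = s + 1
    state.cycle += 1

    if outcome == "xylem_gain":
        state.identities[s] = "xylem"
    elif outcome == "phloem_gain":
        state.identities[s + 1] = "phloem"
    else:  # double_xylem
        state.identities[s] = "xylem"
        state.identities[s + 1] = "xylem"
        nearest = next(
            (i for i in range(s + 2, state.n_cells) if state.identities[i] == "phloem"),
            None,
        )
        if nearest is None:
            state.terminated = True
        else:
            state.identities[nearest] = "stem"

    state.events.append(
        {
            "cycle": state.cycle,
            "outcome": outcome,
            "stem_index_before": s,
            "landmark_index": state.landmark_index,
            "terminated": state.terminated,
        }
    )
    return state


def _label_origin(state: FileState, origin: str, rng: Optional[np.random.Generator]) -> None:
    s = state.stem_index
    if origin == "ant_stem_cell":
        state.labels[s] = "clone"
    elif origin == "pear1_phloem":
        state.labels[s + 1] = "clone"  # phloem cell adjacent to the cambium
    elif origin == "random_cambium":
        # either daughter of the pre-window division: the stem or its
        # inward sibling, with equal probability
        if rng is None:
            raise ValueError("random_cambium origin needs an rng")
        state.labels[s if rng.random() < 0.5 else s - 1] = "clone"
    else:
        raise ValueError(f"unknown origin {origin!r}")


def _extract_sector(state: FileState, origin: str, treatment: str) -> Sector:
    idx = [i for i, lab in enumerate(state.labels) if lab == "clone"]
    if not idx:
        raise RuntimeError("clone label lost from file")
    if idx[-1] - idx[0] != len(idx) - 1:
        raise AssertionError("clone became non-contiguous")
    lm = state.landmark_index
    n_x = sum(1 for i in idx if i < lm)
    n_p = len(idx) - n_x
    # landmark within or at either clone boundary
    landmark_within = idx[0] <= lm <= idx[-1] + 1
    contains_stem = any(state.identities[i] == "stem" for i in idx)
    return Sector(
        origin=origin,
        n_xylem=n_x,
        n_phloem=n_p,
        landmark_within=landmark_within,
        contains_stem=contains_stem,
        treatment=treatment,
    )


def simulate_sector(
    origin: str,
    params: FateParams,
    rng: Optional[np.random.Generator] = None,
    treatment: str = "",
    n_xylem0: int = 4,
    n_phloem0: Optional[int] = None,
    _forced_outcomes: Optional[Sequence[str]] = None,
) -> Sector:
    """Run one lineage-tracing window and extract the labelled clone.

    The initial file has ``n_phloem0`` phloem cells (default
    ``params.n_cycles + 1``, enough that respecification can never run out
    of phloem within the window).
    """
    if n_phloem0 is None:
        n_phloem0 = params.n_cycles + 1
    state = initial_state(n_xylem=n_xylem0, n_phloem=n_phloem0)
    _label_origin(state, origin, rng)
    for k in range(params.n_cycles):
        if state.terminated:
            break
        forced = _forced_outcomes[k] if _forced_outcomes is not None else None
        step(state, params, rng=rng, outcome=forced)
    return _extract_sector(state, origin, treatment or params.name)


def cohort(
    origin: str,
    params: FateParams,
    n_sectors: int,
    rng_seed,
    treatment: str = "",
) -> tuple[list[Sector], dict]:
    """Simulate ``n_sectors`` independent clones; summarize the cohort.

    ``rng_seed`` may be an int, a ``SeedSequence`` or a ``Generator``.
    Proliferation filtering is disabled in the summary (``min_size=1``)
    because every simulated window is observed in full.
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    sectors = [
        simulate_sector(origin, params, rng=rng, treatment=treatment)
        for _ in range(n_sectors)
    ]
    return sectors, cohort_summary(sectors, min_size=1)


def outcome_fractions(events: Sequence[dict]) -> dict:
    """Empirical outcome frequencies from one or more event logs."""
    n = len(events)
    if n == 0:
        raise ValueError("empty event log")
    return {o: sum(e["outcome"] == o for e in events) / n for o in OUTCOMES}


def expected_class_fraction(
    params: FateParams, origin: str, sector_class: str
) -> float:
    """Exact probability of a sector class by enumerating outcome sequences.

    Walks all ``3 ** n_cycles`` forced outcome sequences through the
    simulator, classifies each final clone, and sums sequence
    probabilities.  Exact (no sampling); used for calibration and as an
    oracle for the stochastic path.
    """
    probs = dict(zip(OUTCOMES, params.probs))
    total = 0.0
    for seq in itertools.product(OUTCOMES, repeat=params.n_cycles):
        p = 1.0
        for o in seq:
            p *= probs[o]
        if p == 0.0:
            continue
        sector = simulate_sector(origin, params, _forced_outcomes=seq)
        if classify_sector(sector) == sector_class:
            total += p
    return total


@lru_cache(maxsize=None)
def calibrate_double_xylem(
    target_xylem_only: float = 0.21,
    target_stem_regain: float = 0.21,
    q_p: float = 0.33,
    n_cycles: int = 5,
) -> FateParams:
    """Choose ``q_d`` to match the observed sector-class rates.

    With the phloem-gain probability fixed, picks the double-xylem
    probability whose exact (enumerated) expected sector-class
    probabilities best match, in least squares, the observed rates of
    stem-cell-origin clones ending ``xylem_only`` and phloem-origin
    clones ending ``stem_regain``.  Both events hinge on a double-xylem
    division occurring before any phloem-gain in the clone (otherwise the
    respecified cell belongs to the clone and stem identity stays inside
    it), so each sector-level rate is a first-passage probability, not
    ``1 - (1 - q_d) ** n_cycles``; a single ``q_d`` cannot satisfy both
    observed rates exactly because the two first-passage corrections
    differ slightly.
    """

    def loss(q_d: float) -> float:
        params = FateParams(q_x=1.0 - q_p - q_d, q_p=q_p, q_d=q_d, n_cycles=n_cycles)
        a = expected_class_fraction(params, "ant_stem_cell", "xylem_only")
        r = expected_class_fraction(params, "pear1_phloem", "stem_regain")
        return (a - target_xylem_only) ** 2 + (r - target_stem_regain) ** 2

    res = minimize_scalar(
        loss, bounds=(1e-6, 1.0 - q_p - 1e-6), method="bounded",
        options={"xatol": 1e-10},
    )
    q_d = float(res.x)
    return FateParams(
        q_x=1.0 - q_p - q_d, q_p=q_p, q_d=q_d, n_cycles=n_cycles, name="fate_highGA"
    )
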