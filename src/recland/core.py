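"""Domain types shared across the package.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open.  A conversion tract ``(start, n)``
covers positions ``start .. start + n - 1``.  Marker positions are integer
base-pair coordinates on a chromosome arm.  Parental identity is encoded as
0 (P1) and 1 (P2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

P1, P2 = 0, 1
PARENT_LABELS = {0: "P1", 1: "P2"}


# ---------------------------------------------------------------------------
# simulation-side types
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeSpec:
    """Physical and genetic description of one chromosome arm.

    ``map_length_cM`` is the per-gamete expectation of crossover events per
    female meiosis times 100.  ``co_landscape`` is an optional array of
    relative crossover intensities over equal-width bins spanning the arm
    (uniform when omitted).  ``inheritance`` distinguishes autosomes from the
    X (transmitted to sons by the mother only) and the mitochondrion
    (maternal, clonal).
    """

    arm_id: str
    length_bp: int
    map_length_cM: float
    co_landscape: Optional[np.ndarray] = None
    has_co: bool = True
    inheritance: str = "autosome"  # autosome | X | mito

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.map_length_cM < 0:
            raise ValueError("map_length_cM must be non-negative")
        if not self.has_co and self.map_length_cM != 0:
            raise ValueError("map_length_cM must be 0 when has_co is False")
        if self.inheritance not in ("autosome", "X", "mito"):
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        if self.co_landscape is not None:
            lnd = np.asarray(self.co_landscape, dtype=float)
            if lnd.ndim != 1 or lnd.size == 0 or np.any(lnd < 0) or lnd.sum() <= 0:
                raise ValueError("co_landscape must be non-negative and normalizable")
            self.co_landscape = lnd


@dataclass
class GCParams:
    """Gene-conversion model: initiation rate and geometric tract lengths.

    ``gamma`` is the rate of GC initiations per bp per female meiosis.
    ``phi`` is the per-nucleotide tract-extension probability; tract length N
    has P(N = n) = (1 - phi) * phi**(n-1) for n >= 1, so the mean tract
    length is L_GC = 1 / (1 - phi).
    """

    gamma: float
    phi: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0.0 <= self.phi < 1.0):
            raise ValueError("phi must lie in [0, 1)")

    @property
    def mean_tract_length(self) -> float:
        return 1.0 / (1.0 - self.phi)

    @classmethod
    def from_mean_length(cls, gamma: float, l_gc: float) -> "GCParams":
        if l_gc < 1:
            raise ValueError("mean tract length must be >= 1 bp")
        return cls(gamma=gamma, phi=1.0 - 1.0 / l_gc)


@dataclass
class CrossDesign:
    """Mating scheme of a recombinant advanced intercross line (RAIL).

    ``n_bottles_schedule`` gives the number of bottles for each generation;
    every bottle holds ``males_per_bottle`` males and ``females_per_bottle``
    females (20/20 in the study design).  Flies are randomly redistributed
    across bottles between generations.
    """

    cross_id: str
    n_generations: int
    n_bottles_schedule: Sequence[int]
    chromosomes: Sequence[ChromosomeSpec]
    males_per_bottle: int = 20
    females_per_bottle: int = 20
    offspring_sampled: int = 100

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if len(self.n_bottles_schedule) != self.n_generations:
            raise ValueError("schedule length must equal n_generations")
        counts = [self.males_per_bottle, self.females_per_bottle,
                  self.offspring_sampled, *self.n_bottles_schedule]
        if any(c <= 0 for c in counts):
            raise ValueError("all design counts must be positive")
        if not self.chromosomes:
            raise ValueError("design needs at least one chromosome")


@dataclass
class SimTruth:
    """Ground truth for one transmitted chromosome.

    ``seg_starts``/``seg_parents`` encode the parental mosaic as a
    piecewise-constant function: segment i spans
    ``[seg_starts[i], seg_starts[i+1])`` (last segment to ``length_bp``).
    ``co_positions`` are the detectable crossover junctions accumulated along
    the lineage; ``gc_tracts`` are ``(start, length, donor_parent)`` tuples
    for visible conversion tracts.
    """

    arm_id: str
    length_bp: int
    seg_starts: np.ndarray
    seg_parents: np.ndarray
    co_positions: np.ndarray
    gc_tracts: list

    def __post_init__(self) -> None:
        self.seg_starts = np.asarray(self.seg_starts, dtype=np.int64)
        self.seg_parents = np.asarray(self.seg_parents, dtype=np.int8)
        self.co_positions = np.asarray(self.co_positions, dtype=np.int64)
        if self.seg_starts.size == 0 or self.seg_starts[0] != 0:
            raise ValueError("segments must start at 0 and partition the arm")
        if self.seg_starts.size != self.seg_parents.size:
            raise ValueError("seg_starts and seg_parents must align")
        if np.any(np.diff(self.seg_starts) <= 0):
            raise ValueError("segment starts must be strictly increasing")
        for start, n, _donor in self.gc_tracts:
            if n < 1 or start < 0 or start + n > self.length_bp:
                raise ValueError("GC tract outside chromosome bounds")

    def parent_at(self, positions: np.ndarray) -> np.ndarray:
        """Parental identity of the segment covering each position."""
        positions = np.asarray(positions)
        idx = np.searchsorted(self.seg_starts, positions, side="right") - 1
        return self.seg_parents[idx]


@dataclass
class MarkerPanel:
    """Informative-marker positions along one arm."""

    arm_id: str
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if self.positions.size and self.positions[0] < 0:
            raise ValueError("marker positions must be non-negative")

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)


# ---------------------------------------------------------------------------
# detection-side types
# ---------------------------------------------------------------------------

@dataclass
class MarkerHaplotype:
    """One offspring chromosome observed through a marker panel."""

    arm_id: str
    positions: np.ndarray
    parents: np.ndarray
    source_cross: str = ""
    source_individual: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.parents = np.asarray(self.parents, dtype=np.int8)
        if self.positions.shape != self.parents.shape:
            raise ValueError("positions and parents must align")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        bad = np.setdiff1d(np.unique(self.parents), [P1, P2])
        if bad.size:
            raise ValueError("parent calls must be binary (0/1)")

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)


@dataclass
class RecEvent:
    """A classified crossover (CO) or gene-conversion (GC) event.

    For a GC event the converted run spans ``first_conv_pos ..
    last_conv_pos``; ``gap_left``/``gap_right`` are the marker distances from
    the outermost converted markers to the nearest uninvolved flanking
    markers.  ``L_min = last_conv_pos - first_conv_pos + 1`` is the minimum
    true tract length, ``m_gc`` the mean flanking gap, and
    ``L_max = L_min + 2 * m_gc`` the reported maximum tract length.  For a CO
    the breakpoint lies in ``(left_flank_pos, right_flank_pos)``.
    """

    kind: str  # "CO" | "GC"
    arm_id: str
    left_flank_pos: int
    right_flank_pos: int
    first_conv_pos: Optional[int] = None
    last_conv_pos: Optional[int] = None
    source_cross: str = ""
    source_individual: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("CO", "GC"):
            raise ValueError("kind must be 'CO' or 'GC'")
        if self.kind == "GC":
            if self.first_conv_pos is None or self.last_conv_pos is None:
                raise ValueError("GC event needs converted-run coordinates")
            if not (self.left_flank_pos < self.first_conv_pos
                    <= self.last_conv_pos < self.right_flank_pos):
                raise ValueError("flanking markers must lie outside the converted run")
        elif self.right_flank_pos <= self.left_flank_pos:
            raise ValueError("CO breakpoint interval must be non-empty")

    # -- GC geometry -------------------------------------------------------
    @property
    def L_min(self) -> int:
        if self.kind != "GC":
            raise AttributeError("L_min is defined for GC events only")
        return self.last_conv_pos - self.first_conv_pos + 1

    @property
    def gap_left(self) -> int:
        return self.first_conv_pos - self.left_flank_pos

    @property
    def gap_right(self) -> int:
        return self.right_flank_pos - self.last_conv_pos

    @property
    def m_gc(self) -> float:
        return 0.5 * (self.gap_left + self.gap_right)

    @property
    def L_max(self) -> float:
        return self.L_min + 2.0 * self.m_gc

    # -- shared geometry ---------------------------------------------------
    @property
    def midpoint(self) -> float:
        if self.kind == "GC":
            return 0.5 * (self.first_conv_pos + self.last_conv_pos)
        return 0.5 * (self.left_flank_pos + self.right_flank_pos)

    @property
    def delim_span(self) -> int:
        """Width of the delimiting marker interval (basis of the *_500 sets)."""
        if self.kind == "GC":
            return self.right_flank_pos - self.left_flank_pos - self.L_min + 1
        return self.right_flank_pos - self.left_flank_pos


@dataclass
class WindowMap:
    """Per-window event counts and rates along one arm.

    ``table`` is a DataFrame with columns ``start, end, n_CO, n_GC, c,
    gamma_naive, ci_low, ci_high``; ``c`` is in cM/Mb per female meiosis and
    ``gamma_naive`` is the naive (detection-limited) GC rate per bp per
    meiosis.
    """

    arm_id: str
    window_size: int
    step: int
    n_meioses: float
    ci_level: float
    table: "object" = field(repr=False, default=None)
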