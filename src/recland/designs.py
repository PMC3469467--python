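"""Study-design constants for the *D. melanogaster* RAIL mapping experiment.

Eight crosses between inbred strains were propagated as recombinant advanced
intercross lines (RAILs) by sib mating in bottles of twenty males and twenty
females, with the bottle count ramped from five up to ten across generations.
The tables below carry the per-cross female-meiosis totals, the per-arm
genetic map lengths, and the centromere/telomere regions excluded from
heterogeneity analyses.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .core import ChromosomeSpec, CrossDesign, GCParams

#: r5 reference physical lengths of the chromosome arms (bp).
ARM_LENGTHS_BP: Dict[str, int] = {
    "X": 22_422_827,
    "2L": 23_011_544,
    "2R": 21_146_708,
    "3L": 24_543_557,
    "3R": 27_905_053,
    "4": 1_351_857,
}

#: Equivalent female meioses per cross (crosses 1..8).
CROSS_MEIOSES: Dict[int, float] = {
    1: 762.5, 2: 1522.0, 3: 493.5, 4: 720.0,
    5: 752.5, 6: 627.0, 7: 499.5, 8: 483.0,
}

#: Genetic map length (cM per female meiosis) per chromosome arm and cross.
#: Crosses 7 and 8 carry fixed 3R inversions and are excluded for that arm.
CROSS_MAP_LENGTHS_CM: Dict[int, Dict[str, float]] = {
    1: {"X": 71.8, "2L": 49.8, "2R": 45.8, "3L": 54.9, "3R": 47.6},
    2: {"X": 66.2, "2L": 55.8, "2R": 53.8, "3L": 52.7, "3R": 60.8},
    3: {"X": 56.4, "2L": 64.9, "2R": 60.0, "3L": 49.9, "3R": 56.7},
    4: {"X": 63.4, "2L": 62.5, "2R": 51.4, "3L": 51.8, "3R": 61.3},
    5: {"X": 67.5, "2L": 55.6, "2R": 49.0, "3L": 55.9, "3R": 56.2},
    6: {"X": 66.6, "2L": 52.4, "2R": 55.0, "3L": 50.3, "3R": 66.5},
    7: {"X": 73.0, "2L": 55.9, "2R": 58.6, "3L": 53.4},
    8: {"X": 57.7, "2L": 57.5, "2R": 59.3, "3L": 53.9},
}

#: Regions retained after trimming centromeric/telomeric low-CO stretches
#: (start_bp, end_bp per arm); everything outside is excluded.
INCLUDED_REGIONS: Dict[str, tuple] = {
    "X": (2_300_000, 20_800_000),
    "2L": (500_000, 17_400_000),
    "2R": (5_200_000, 20_800_000),
    "3L": (700_000, 19_900_000),
    "3R": (9_700_000, 26_900_000),
}

#: Sib-mating generations per cross.  The study reports only that crosses
#: ranged from 1 to 10 generations and the per-cross meiosis totals above;
#: assuming an equal split of the 2,829 genotyped genomes across crosses,
#: per-genome equivalent meioses are CROSS_MEIOSES[i] / (2829 / 8).
#: Junction accumulation with female-only recombination and ~1/2
#: heterozygosity (which halves both the detectability of new crossovers
#: and the transmission survival of existing junctions) gives
#: Eq(g) ~= 1 + (g - 2)/4 for g >= 2; inverting and capping at the study's
#: stated maximum of 10 generations gives the counts below.
CROSS_GENERATIONS: Dict[int, int] = {
    1: 7, 2: 10, 3: 4, 4: 6, 5: 7, 6: 5, 7: 4, 8: 4,
}

#: Genome-wide gene-conversion model reported by the study.
DEFAULT_GC = GCParams.from_mean_length(gamma=1.25e-7, l_gc=518.0)

#: Median distance to the nearest informative SNP (bp).
DEFAULT_MARKER_SPACING = 1830.0


def equivalent_meioses_approx(n_generations: int) -> float:
    """Junction-accumulation approximation of equivalent meioses.

    With female-only recombination and ~1/2 heterozygosity after the F1
    generation, each extra generation adds about a quarter of a meiosis of
    detectable junctions: Eq(1) = 1, Eq(g) ~= 1 + (g - 2)/4 for g >= 2.
    ``recland.detect.estimate_equivalent_meioses`` gives the simulation
    estimate this approximates.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if n_generations == 1:
        return 1.0
    return 1.0 + (n_generations - 2) / 4.0


def bottle_schedule(n_generations: int, start: int = 5, stop: int = 10) -> list:
    """Bottle counts ramped linearly from ``start`` up to ``stop``."""
    if n_generations == 1:
        return [start]
    t = np.linspace(0.0, 1.0, n_generations)
    return [int(round(start + (stop - start) * x)) for x in t]


def study_chromosomes(cross: int = 2, arms: Optional[Sequence[str]] = None,
                      include_dot: bool = False) -> list:
    """ChromosomeSpecs for one cross using its tabulated map lengths."""
    maps = CROSS_MAP_LENGTHS_CM[cross]
    arms = list(arms) if arms is not None else list(maps)
    specs = []
    for arm in arms:
        specs.append(ChromosomeSpec(
            arm_id=arm,
            length_bp=ARM_LENGTHS_BP[arm],
            map_length_cM=maps[arm],
            inheritance="X" if arm == "X" else "autosome",
        ))
    if include_dot:
        specs.append(ChromosomeSpec(
            arm_id="4", length_bp=ARM_LENGTHS_BP["4"],
            map_length_cM=0.0, has_co=False,
        ))
    return specs


def study_cross_design(cross: int, n_generations: Optional[int] = None,
                       offspring_sampled: int = 100,
                       arms: Optional[Sequence[str]] = None,
                       include_dot: bool = False) -> CrossDesign:
    """The study's mating design for one of the eight crosses."""
    if n_generations is None:
        n_generations = CROSS_GENERATIONS[cross]
    return CrossDesign(
        cross_id=f"cross{cross}",
        n_generations=n_generations,
        n_bottles_schedule=bottle_schedule(n_generations),
        chromosomes=study_chromosomes(cross, arms=arms, include_dot=include_dot),
        offspring_sampled=offspring_sampled,
    )
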