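"""Forward simulator of the RAIL mapping experiment.

Simulates female meioses with crossovers (CO) and gene-conversion (GC)
tracts, propagates recombinant advanced intercross lines (RAILs) through
bottles of sib-mated flies with drift, and projects transmitted chromosomes
onto an informative-marker panel.

Model assumptions
-----------------
* CO count per gamete is Poisson with mean ``map_length_cM / 100`` (no
  interference); an obligate fixed-count mode is available but off by
  default.
* GC initiations per gamete are Poisson with mean ``gamma * length_bp``;
  tract lengths are geometric with extension probability ``phi`` (support
  n >= 1, mean ``1/(1-phi)``).  A tract copies the homologous haplotype's
  content, so tracts in homozygous regions are invisible.
* Male *Drosophila* meiosis is achiasmatic: paternally transmitted
  chromosomes carry no new CO or GC.  The X is transmitted to sons by the
  mother only; the mitochondrion is maternal and clonal.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from .core import (P1, P2, ChromosomeSpec, CrossDesign, GCParams,
                   MarkerHaplotype, MarkerPanel, SimTruth)


# ---------------------------------------------------------------------------
# haplotype machinery
# ---------------------------------------------------------------------------

class Haplotype:
    """Piecewise-constant parental mosaic plus accumulated-event bookkeeping."""

    __slots__ = ("starts", "parents", "junctions", "gc_tracts")

    def __init__(self, starts, parents, junctions=(), gc_tracts=()):
        self.starts = np.asarray(starts, dtype=np.int64)
        self.parents = np.asarray(parents, dtype=np.int8)
        self.junctions = np.asarray(junctions, dtype=np.int64)
        self.gc_tracts = list(gc_tracts)  # (start, length, donor)

    @classmethod
    def uniform(cls, parent: int) -> "Haplotype":
        return cls([0], [parent])

    def parent_at(self, x) -> np.ndarray:
        idx = np.searchsorted(self.starts, x, side="right") - 1
        return self.parents[idx]


def _compact(starts: np.ndarray, parents: np.ndarray):
    """Merge adjacent segments with equal parent."""
    if parents.size <= 1:
        return starts, parents
    keep = np.empty(parents.size, dtype=bool)
    keep[0] = True
    keep[1:] = parents[1:] != parents[:-1]
    return starts[keep], parents[keep]


def _slice(starts, parents, lo, hi):
    """Segment arrays restricted to [lo, hi); first start clamped to lo."""
    i = np.searchsorted(starts, lo, side="right") - 1
    j = np.searchsorted(starts, hi, side="left")
    s = starts[i:j].copy()
    s[0] = lo
    return s, parents[i:j].copy()


def _replace(starts, parents, lo, hi, src_starts, src_parents, length_bp):
    """Overwrite [lo, hi) with the content of the source haplotype."""
    left_s, left_p = (_slice(starts, parents, 0, lo) if lo > 0
                      else (np.empty(0, np.int64), np.empty(0, np.int8)))
    mid_s, mid_p = _slice(src_starts, src_parents, lo, hi)
    if hi < length_bp:
        right_s, right_p = _slice(starts, parents, hi, length_bp)
    else:
        right_s = np.empty(0, np.int64)
        right_p = np.empty(0, np.int8)
    return (np.concatenate([left_s, mid_s, right_s]),
            np.concatenate([left_p, mid_p, right_p]))


def draw_co_positions(chrom: ChromosomeSpec, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Distinct CO breakpoints drawn from the arm's CO landscape."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    L = chrom.length_bp
    for _ in range(64):
        if chrom.co_landscape is None:
            pos = rng.integers(1, L, size=n)
        else:
            w = chrom.co_landscape / chrom.co_landscape.sum()
            bins = rng.choice(w.size, size=n, p=w)
            width = L / w.size
            pos = np.floor(bins * width + rng.random(n) * width).astype(np.int64)
            pos = np.clip(pos, 1, L - 1)
        pos = np.unique(pos)
        if pos.size == n:
            return pos
    raise RuntimeError("could not draw distinct CO positions")


def _draw_tracts(chrom: ChromosomeSpec, gc: GCParams, rng: np.random.Generator):
    n_gc = rng.poisson(gc.gamma * chrom.length_bp) if gc.gamma > 0 else 0
    if n_gc == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    starts = rng.integers(0, chrom.length_bp, size=n_gc)
    lengths = rng.geometric(1.0 - gc.phi, size=n_gc).astype(np.int64)
    return starts.astype(np.int64), lengths


def _meiosis_arm(hapA: Haplotype, hapB: Haplotype, chrom: ChromosomeSpec,
                 gc: GCParams, rng: np.random.Generator,
                 co_count_mode: str = "poisson", fixed_co_count: int = 1,
                 record_all_tracts: bool = False):
    """One female meiosis on one arm; returns the transmitted gamete.

    The gamete alternates between the mother's two haplotypes at the drawn
    CO breakpoints; each GC tract copies the other (non-contributing)
    haplotype's content over the tract interval.
    """
    L = chrom.length_bp
    if chrom.has_co and chrom.map_length_cM > 0:
        if co_count_mode == "poisson":
            n_co = rng.poisson(chrom.map_length_cM / 100.0)
        elif co_count_mode == "fixed":
            n_co = fixed_co_count
        else:
            raise ValueError(f"unknown co_count_mode {co_count_mode!r}")
    else:
        n_co = 0
    xs = draw_co_positions(chrom, n_co, rng)

    haps = (hapA, hapB)
    first = int(rng.integers(2))
    cuts = np.concatenate([[0], xs, [L]])
    sources = (first + np.arange(cuts.size - 1)) % 2

    seg_s: List[np.ndarray] = []
    seg_p: List[np.ndarray] = []
    junctions: List[int] = []
    tracts: List[tuple] = []
    for i, src in enumerate(sources):
        lo, hi = int(cuts[i]), int(cuts[i + 1])
        h = haps[src]
        s, p = _slice(h.starts, h.parents, lo, hi)
        seg_s.append(s)
        seg_p.append(p)
        inner = h.junctions[(h.junctions > lo) & (h.junctions < hi)]
        junctions.extend(int(j) for j in inner)
        tracts.extend(t for t in h.gc_tracts if lo <= t[0] and t[0] + t[1] <= hi)
    for x in xs:
        junctions.append(int(x))
    starts, parents = _compact(np.concatenate(seg_s), np.concatenate(seg_p))

    # gene-conversion overlay: copy homolog content over each tract
    t_starts, t_lens = _draw_tracts(chrom, gc, rng)
    for s0, n in zip(t_starts, t_lens):
        s0 = int(s0)
        hi = min(int(s0 + n), L)
        src = sources[np.searchsorted(cuts, s0, side="right") - 1]
        donor_hap = haps[1 - src]
        cur_s, cur_p = _slice(starts, parents, s0, hi)
        don_s, don_p = _slice(donor_hap.starts, donor_hap.parents, s0, hi)
        visible = not (cur_s.size == don_s.size
                       and np.array_equal(cur_s, don_s)
                       and np.array_equal(cur_p, don_p))
        if visible:
            starts, parents = _replace(starts, parents, s0, hi,
                                       donor_hap.starts, donor_hap.parents, L)
            starts, parents = _compact(starts, parents)
        if visible or record_all_tracts:
            donor = int(donor_hap.parent_at(s0))
            tracts.append((s0, hi - s0, donor))  # clipped at the arm end

    # keep only junctions still backed by a parental switch in the structure
    if junctions:
        jarr = np.unique(np.asarray(junctions, dtype=np.int64))
        jarr = jarr[(jarr > 0) & (jarr < L)]
        if record_all_tracts:
            kept = jarr
        else:
            left = parents[np.searchsorted(starts, jarr - 1, side="right") - 1]
            right = parents[np.searchsorted(starts, jarr, side="right") - 1]
            kept = jarr[left != right]
    else:
        kept = np.empty(0, np.int64)
    return Haplotype(starts, parents, kept, tracts)


def _to_truth(gamete: Haplotype, chrom: ChromosomeSpec) -> SimTruth:
    return SimTruth(
        arm_id=chrom.arm_id,
        length_bp=chrom.length_bp,
        seg_starts=gamete.starts,
        seg_parents=gamete.parents,
        co_positions=np.sort(gamete.junctions),
        gc_tracts=list(gamete.gc_tracts),
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_meiosis(chrom: ChromosomeSpec, gc: GCParams,
                     rng: np.random.Generator | int,
                     co_count_mode: str = "poisson",
                     fixed_co_count: int = 1) -> SimTruth:
    """One gamete from a fully heterozygous (F1) mother.

    The returned truth records every drawn CO position and every initiated
    GC tract (all are visible on an F1 background), alongside the resulting
    parental mosaic.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    hapA, hapB = Haplotype.uniform(P1), Haplotype.uniform(P2)
    gamete = _meiosis_arm(hapA, hapB, chrom, gc, rng,
                          co_count_mode=co_count_mode,
                          fixed_co_count=fixed_co_count,
                          record_all_tracts=True)
    return _to_truth(gamete, chrom)


def observe_haplotypes(truth: SimTruth, panel: MarkerPanel,
                       source_cross: str = "", source_individual: str = "") -> MarkerHaplotype:
    """Project a transmitted chromosome onto an informative-marker panel."""
    if panel.n_markers == 0:
        raise ValueError("empty marker panel")
    if panel.positions[-1] >= truth.length_bp:
        raise ValueError("panel extends beyond chromosome bounds")
    return MarkerHaplotype(
        arm_id=truth.arm_id,
        positions=panel.positions,
        parents=truth.parent_at(panel.positions),
        source_cross=source_cross,
        source_individual=source_individual,
    )


def make_marker_panel(arm_id: str, length_bp: int, mean_spacing: float = 1830.0,
                      rng: np.random.Generator | int = 0,
                      density_weights: Optional[np.ndarray] = None) -> MarkerPanel:
    """Marker positions from a (possibly inhomogeneous) Poisson process.

    ``density_weights``, when given, modulate the local marker intensity
    over equal-width bins spanning the arm (clustered panels).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = rng.poisson(length_bp / mean_spacing)
    n = max(n, 2)
    if density_weights is None:
        pos = rng.integers(0, length_bp, size=n)
    else:
        w = np.asarray(density_weights, dtype=float)
        w = w / w.sum()
        bins = rng.choice(w.size, size=n, p=w)
        width = length_bp / w.size
        pos = np.floor(bins * width + rng.random(n) * width).astype(np.int64)
    pos = np.unique(pos)
    while pos.size < 2:
        pos = np.unique(np.concatenate([pos, rng.integers(0, length_bp, size=2)]))
    return MarkerPanel(arm_id=arm_id, positions=pos)


# ---------------------------------------------------------------------------
# RAIL propagation
# ---------------------------------------------------------------------------

class _Fly:
    __slots__ = ("sex", "arms")

    def __init__(self, sex: str, arms: Dict[str, tuple]):
        self.sex = sex
        self.arms = arms  # arm_id -> (hapA, hapB-or-None)


def _founder(sex: str, design: CrossDesign, rng: np.random.Generator) -> _Fly:
    arms = {}
    for chrom in design.chromosomes:
        if chrom.inheritance == "mito":
            arms[chrom.arm_id] = (Haplotype.uniform(int(rng.integers(2))), None)
        elif chrom.inheritance == "X" and sex == "M":
            arms[chrom.arm_id] = (Haplotype.uniform(int(rng.integers(2))), None)
        else:
            arms[chrom.arm_id] = (Haplotype.uniform(P1), Haplotype.uniform(P2))
    return _Fly(sex, arms)


def _offspring(mother: _Fly, father: _Fly, sex: str, design: CrossDesign,
               gc: GCParams, rng: np.random.Generator,
               co_count_mode: str) -> _Fly:
    arms = {}
    for chrom in design.chromosomes:
        aid = chrom.arm_id
        if chrom.inheritance == "mito":
            arms[aid] = (mother.arms[aid][0], None)
            continue
        mat = _meiosis_arm(mother.arms[aid][0], mother.arms[aid][1], chrom,
                           gc, rng, co_count_mode=co_count_mode)
        if chrom.inheritance == "X":
            if sex == "M":
                arms[aid] = (mat, None)
            else:
                arms[aid] = (mat, father.arms[aid][0])
        else:
            pat = father.arms[aid][int(rng.integers(2))]
            arms[aid] = (mat, pat)
    return _Fly(sex, arms)


def _propagate(design: CrossDesign, gc: GCParams,
               rng: np.random.Generator, co_count_mode: str) -> List[_Fly]:
    """Run the mating design; returns the final generation."""
    nb0 = design.n_bottles_schedule[0]
    males = [_founder("M", design, rng) for _ in range(nb0 * design.males_per_bottle)]
    females = [_founder("F", design, rng) for _ in range(nb0 * design.females_per_bottle)]
    for gen in range(1, design.n_generations):
        if not males or not females:
            raise RuntimeError(f"design {design.cross_id} extinct at generation {gen}")
        nb_parent = design.n_bottles_schedule[gen - 1]
        nb_next = design.n_bottles_schedule[gen]
        # flies from all bottles are randomly mixed into the parent bottles
        m_bottle = rng.integers(0, nb_parent, size=len(males))
        f_bottle = rng.integers(0, nb_parent, size=len(females))
        bottles_m = [[] for _ in range(nb_parent)]
        bottles_f = [[] for _ in range(nb_parent)]
        for fly, b in zip(males, m_bottle):
            bottles_m[b].append(fly)
        for fly, b in zip(females, f_bottle):
            bottles_f[b].append(fly)
        n_m = nb_next * design.males_per_bottle
        n_f = nb_next * design.females_per_bottle
        new_m, new_f = [], []
        for i in range(n_m + n_f):
            sex = "M" if i < n_m else "F"
            for _ in range(64):
                b = int(rng.integers(nb_parent))
                if bottles_m[b] and bottles_f[b]:
                    break
            mother = bottles_f[b][int(rng.integers(len(bottles_f[b])))]
            father = bottles_m[b][int(rng.integers(len(bottles_m[b])))]
            child = _offspring(mother, father, sex, design, gc, rng, co_count_mode)
            (new_m if sex == "M" else new_f).append(child)
        males, females = new_m, new_f
    return males + females


def simulate_rail(design: CrossDesign, gc: GCParams,
                  rng: np.random.Generator | int,
                  co_count_mode: str = "poisson",
                  n_sampled: Optional[int] = None) -> List[Dict[str, SimTruth]]:
    """Transmitted genomes of sampled final-generation RAIL females.

    Each sampled female contributes one female meiosis per chromosome (the
    meiosis analyzed in the genotyped hybrid).  Accumulated detectable CO
    junctions and visible GC tracts are carried in each arm's truth record;
    events in regions driven to homozygosity by drift are invisible and are
    not recorded.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    final = _propagate(design, gc, rng, co_count_mode)
    females = [f for f in final if f.sex == "F"]
    if not females:
        raise RuntimeError("no females in final generation")
    n = design.offspring_sampled if n_sampled is None else n_sampled
    genomes = []
    for _ in range(n):
        mother = females[int(rng.integers(len(females)))]
        genome = {}
        for chrom in design.chromosomes:
            aid = chrom.arm_id
            if chrom.inheritance == "mito":
                genome[aid] = _to_truth(mother.arms[aid][0], chrom)
                continue
            gamete = _meiosis_arm(mother.arms[aid][0], mother.arms[aid][1],
                                  chrom, gc, rng, co_count_mode=co_count_mode)
            genome[aid] = _to_truth(gamete, chrom)
        genomes.append(genome)
    return genomes


# ---------------------------------------------------------------------------
# bulk GC-observation generator (single-meiosis panels, MLE experiments)
# ---------------------------------------------------------------------------

def simulate_gc_observations(panel: MarkerPanel, length_bp: int, gc: GCParams,
                             n_meioses: int, rng: np.random.Generator | int,
                             tracts=None):
    """Vectorized draw of detected GC events over many single meioses.

    Returns ``(events, intervals)`` where ``events`` is an integer array of
    rows ``(L_min, gap_left, gap_right)`` for every tract covering at least
    one non-terminal marker, and ``intervals`` is ``(m, multiplicity)`` rows
    for uninvolved adjacent-marker gaps aggregated over all meioses.  Tracts
    in the same meiosis are treated independently (overlap is negligible at
    the study's rates).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pos = panel.positions
    n_gaps = pos.size - 1
    gap_m = np.diff(pos)
    if tracts is None:
        k_tot = rng.poisson(gc.gamma * length_bp * n_meioses) if gc.gamma > 0 else 0
        starts = rng.integers(0, length_bp, size=k_tot)
        lens = rng.geometric(1.0 - gc.phi, size=k_tot).astype(np.int64)
    else:
        starts, lens = tracts
        k_tot = len(starts)
    involved = np.zeros(n_gaps + 1, dtype=np.int64)  # diff-accumulator
    rows = []
    if k_tot:
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, starts + lens, side="left") - 1
        hit = i1 >= i0
        interior = hit & (i0 > 0) & (i1 < pos.size - 1)
        for a, b in zip(i0[interior], i1[interior]):
            rows.append((pos[b] - pos[a] + 1,
                         pos[a] - pos[a - 1],
                         pos[b + 1] - pos[b]))
            involved[a - 1] += 1
            involved[b + 1] -= 1
    involved = np.cumsum(involved)[:n_gaps]
    mult = np.maximum(n_meioses - involved, 0).astype(float)
    events = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
    # aggregate identical gap widths
    uniq, inv = np.unique(gap_m, return_inverse=True)
    agg = np.zeros(uniq.size)
    np.add.at(agg, inv, mult)
    intervals = np.column_stack([uniq.astype(float), agg])
    return events, intervals
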