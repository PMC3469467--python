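"""Classification of marker-haplotype switches into CO and GC events,
windowed recombination-rate maps, and equivalent-meioses estimation.

A maximal run of one parental identity flanked on both sides by the other
parent is a gene-conversion (GC) candidate; it is called GC when the span of
its outermost converted markers does not exceed the tract-length cutoff
(15 kb by default), and otherwise resolves into two crossovers (CO).
Persistent switches are COs.  Runs touching the first or last marker of the
panel have one-sided evidence only and are classified CO.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ChromosomeSpec, CrossDesign, GCParams, MarkerHaplotype, RecEvent, WindowMap
from .simulate import simulate_rail

DEFAULT_GC_CUTOFF = 15_000


def _runs(parents: np.ndarray):
    """Indices of maximal constant-parent runs: (first_idx, last_idx) pairs."""
    change = np.flatnonzero(parents[1:] != parents[:-1]) + 1
    firsts = np.concatenate([[0], change])
    lasts = np.concatenate([change - 1, [parents.size - 1]])
    return firsts, lasts


def detect_events(hap: MarkerHaplotype, max_gc_span_bp: int = DEFAULT_GC_CUTOFF,
                  span_metric: str = "lmin") -> List[RecEvent]:
    """Classify parental switches in one haplotype into CO and GC events.

    ``span_metric`` selects the quantity compared against the cutoff:
    ``"lmin"`` (span of the outermost converted markers, default) or
    ``"lmax"`` (L_min plus both flanking gaps).
    """
    if hap.n_markers < 2:
        raise ValueError("need at least two markers")
    if span_metric not in ("lmin", "lmax"):
        raise ValueError(f"unknown span_metric {span_metric!r}")
    pos, par = hap.positions, hap.parents
    firsts, lasts = _runs(par)
    n_runs = firsts.size
    if n_runs == 1:
        return []

    events: List[RecEvent] = []
    meta = dict(arm_id=hap.arm_id, source_cross=hap.source_cross,
                source_individual=hap.source_individual)
    is_gc = np.zeros(n_runs, dtype=bool)
    for r in range(1, n_runs - 1):
        i, j = firsts[r], lasts[r]
        l_min = pos[j] - pos[i] + 1
        span = l_min
        if span_metric == "lmax":
            span = l_min + (pos[i] - pos[i - 1]) + (pos[j + 1] - pos[j])
        if span <= max_gc_span_bp:
            is_gc[r] = True
            events.append(RecEvent(
                kind="GC",
                left_flank_pos=int(pos[i - 1]),
                right_flank_pos=int(pos[j + 1]),
                first_conv_pos=int(pos[i]),
                last_conv_pos=int(pos[j]),
                **meta,
            ))
    # COs: junctions between consecutive non-GC runs with differing parents
    keep = np.flatnonzero(~is_gc)
    for a, b in zip(keep[:-1], keep[1:]):
        if par[firsts[a]] != par[firsts[b]]:
            events.append(RecEvent(
                kind="CO",
                left_flank_pos=int(pos[lasts[a]]),
                right_flank_pos=int(pos[firsts[b]]),
                **meta,
            ))
    events.sort(key=lambda e: e.midpoint)
    return events


def window_rates(events: Iterable[RecEvent], chrom: ChromosomeSpec,
                 window_size: int, step: Optional[int] = None,
                 n_meioses: float = 1.0, ci_level: float = 0.90) -> WindowMap:
    """Windowed CO/GC counts and rates (events assigned by midpoint).

    ``c`` is in cM per Mb per female meiosis; its confidence bounds come
    from an exact binomial (Clopper-Pearson) interval on the CO count out of
    ``n_meioses`` trials, rescaled to cM/Mb.  ``gamma_naive`` is the
    detected-GC rate per bp per meiosis (no tract-length correction).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    step = window_size if step is None else step
    starts = np.arange(0, max(chrom.length_bp - window_size, 0) + 1, step, dtype=np.int64)
    if starts.size == 0:
        starts = np.array([0], dtype=np.int64)
    ends = np.minimum(starts + window_size, chrom.length_bp)

    events = list(events) if not isinstance(events, list) else events
    mids_co = np.array([e.midpoint for e in events if e.kind == "CO"], dtype=float)
    mids_gc = np.array([e.midpoint for e in events if e.kind == "GC"], dtype=float)

    n_co = np.array([(mids_co >= s) & (mids_co < e) for s, e in zip(starts, ends)]).sum(axis=1) \
        if mids_co.size else np.zeros(starts.size, dtype=int)
    n_gc = np.array([(mids_gc >= s) & (mids_gc < e) for s, e in zip(starts, ends)]).sum(axis=1) \
        if mids_gc.size else np.zeros(starts.size, dtype=int)

    width_mb = (ends - starts) / 1e6
    c = 100.0 * n_co / (n_meioses * width_mb)
    gamma_naive = n_gc / (n_meioses * (ends - starts).astype(float))

    n_trials = max(int(round(n_meioses)), 1)
    alpha = 1.0 - ci_level
    k = np.minimum(n_co, n_trials)
    p_lo = np.where(k > 0, stats.beta.ppf(alpha / 2, k, n_trials - k + 1), 0.0)
    p_hi = np.where(k < n_trials,
                    stats.beta.ppf(1 - alpha / 2, k + 1, np.maximum(n_trials - k, 1)),
                    1.0)
    scale = 100.0 * n_trials / (n_meioses * width_mb)
    table = pd.DataFrame({
        "start": starts, "end": ends, "n_CO": n_co, "n_GC": n_gc,
        "c": c, "gamma_naive": gamma_naive,
        "ci_low": p_lo * scale, "ci_high": p_hi * scale,
    })
    return WindowMap(arm_id=chrom.arm_id, window_size=window_size, step=step,
                     n_meioses=n_meioses, ci_level=ci_level, table=table)


def genome_map_length(events_by_arm: Dict[str, Sequence[RecEvent]],
                      n_meioses: float) -> Dict[str, float]:
    """Per-arm and total genetic map length in cM (100 * CO / meioses)."""
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    out = {}
    for arm, events in events_by_arm.items():
        n_co = sum(1 for e in events if e.kind == "CO")
        out[arm] = 100.0 * n_co / n_meioses
    out["total"] = float(sum(v for k, v in out.items() if k != "total"))
    return out


def estimate_equivalent_meioses(design: CrossDesign, n_reps: int = 1000,
                                rng: np.random.Generator | int = 0,
                                n_pedigrees: Optional[int] = None) -> float:
    """Effective number of single female meioses per sampled RAIL genome.

    Estimated as E[detectable CO junctions per transmitted genome] divided
    by the single-meiosis expectation (sum of map lengths / 100), averaged
    over ``n_reps`` sampled genomes spread across independently simulated
    pedigrees.  A one-generation design is a single maternal meiosis by
    construction and returns exactly 1.0.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if design.n_generations == 1:
        return 1.0
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    co_arms = [c for c in design.chromosomes if c.has_co and c.map_length_cM > 0]
    if not co_arms:
        raise ValueError("design has no CO-bearing chromosome")
    per_meiosis = sum(c.map_length_cM for c in co_arms) / 100.0
    gc_off = GCParams(gamma=0.0, phi=0.0)
    if n_pedigrees is None:
        n_pedigrees = int(np.clip(n_reps // 500, 1, 16))
    per_pedigree = int(math.ceil(n_reps / n_pedigrees))
    total_junctions = 0
    total_genomes = 0
    for _ in range(n_pedigrees):
        genomes = simulate_rail(design, gc_off, rng, n_sampled=per_pedigree)
        for genome in genomes:
            total_junctions += sum(genome[c.arm_id].co_positions.size for c in co_arms)
        total_genomes += len(genomes)
    return total_junctions / (total_genomes * per_meiosis)
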