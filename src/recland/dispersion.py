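"""Among-cross and along-chromosome variation in crossover landscapes.

The Index of Dispersion ``R_CO`` is the variance-to-mean ratio of
lineage-corrected per-region CO counts across crosses; under a Poisson null
its expectation is ~1, and values significantly above 1 indicate
polymorphic hot- or coldspots.  Lineage weights remove genome-wide
differences between crosses (total CO per chromosome) before comparing
regional counts.  Along-chromosome heterogeneity is measured by the
coefficient of variation of per-window counts against a uniform-placement
null.  All significance levels come from Monte-Carlo replication with the
add-one estimator p = (1 + #{stat* >= stat}) / (reps + 1).
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .core import ChromosomeSpec


def lineage_weights(m: Sequence[float]) -> np.ndarray:
    """Per-cross lineage weights: w_i = m_i / mean(m); mean weight is 1."""
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError(
            "zero-CO chromosome in a cross: exclude that cross/chromosome "
            "before weighting")
    return m / m.mean()


def index_of_dispersion(x_r: Sequence[float], w: Sequence[float]) -> float:
    """Variance-to-mean ratio of lineage-corrected counts for one region.

    Corrected counts are y_i = x_i / w_i; R_CO = s^2(y) / mean(y) with the
    unbiased (n-1) variance.  Returns NaN when the regional mean is 0.
    """
    x_r = np.asarray(x_r, dtype=float)
    w = np.asarray(w, dtype=float)
    if x_r.shape != w.shape:
        raise ValueError("counts and weights must align")
    y = x_r / w
    ybar = y.mean()
    if ybar == 0:
        return float("nan")
    return float(y.var(ddof=1) / ybar)


def _r_co_matrix(y: np.ndarray) -> np.ndarray:
    """Vectorized R_CO along the last axis (NaN where the mean is 0)."""
    ybar = y.mean(axis=-1)
    s2 = y.var(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = s2 / ybar
    r[ybar == 0] = np.nan
    return r


def dispersion_pvalue(x: np.ndarray, w: Sequence[float], reps: int = 100_000,
                      rng: np.random.Generator | int = 0,
                      chunk: int = 2_000) -> Tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo p-values for regional R_CO against a Poisson null.

    ``x`` is a (regions x crosses) CO count matrix for one chromosome.
    Null replicates draw a Poisson total for the chromosome and place
    events multinomially among crosses proportionally to the lineage
    weights and among regions proportionally to the observed aggregate
    regional intensity.  Returns (R_CO per region, p per region); ties
    count as exceedances (conservative).
    """
    if reps < 10_000:
        raise ValueError("reps must be >= 10^4")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(x, dtype=float)
    n_regions, n_crosses = x.shape
    w = np.asarray(w, dtype=float)
    if w.size != n_crosses:
        raise ValueError("weights must match the number of crosses")

    r_obs = _r_co_matrix(x / w)
    total = x.sum()
    region_p = x.sum(axis=1)
    if region_p.sum() == 0:
        return r_obs, np.ones(n_regions)
    # Poisson total split multinomially over cells == independent Poisson
    # cells with matching intensities (Poissonization), sampled directly.
    lam = np.outer(region_p / region_p.sum(), w / w.sum()) * total

    chunk = max(1, min(chunk, int(5e6 // (n_regions * n_crosses)) + 1))
    exceed = np.zeros(n_regions, dtype=np.int64)
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        counts = rng.poisson(lam=lam, size=(b, n_regions, n_crosses))
        r_rep = _r_co_matrix(counts / w)
        finite = np.isfinite(r_rep)
        cmp = np.where(finite, r_rep, -np.inf) >= r_obs[None, :]
        exceed += np.where(np.isnan(r_obs)[None, :], 0, cmp).sum(axis=0)
        done += b
    p = (1.0 + exceed) / (reps + 1.0)
    p[np.isnan(r_obs)] = np.nan
    return r_obs, p


def cv_heterogeneity(event_positions: Sequence[float], chrom: ChromosomeSpec,
                     window_size: int, reps: int = 10_000,
                     rng: np.random.Generator | int = 0,
                     include_region: Optional[Tuple[int, int]] = None) -> Tuple[float, float]:
    """CV of per-window event counts and its uniform-null p-value.

    Non-overlapping windows of ``window_size`` tile the included region
    (whole arm by default; pass ``include_region`` to drop centromeric/
    telomeric stretches).  The null redistributes the observed total
    uniformly at random over the included windows.
    """
    if reps < 1_000:
        raise ValueError("reps must be >= 10^3")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo, hi = (0, chrom.length_bp) if include_region is None else include_region
    edges = np.arange(lo, hi + 1, window_size, dtype=np.int64)
    if edges.size < 3:
        raise ValueError("need at least two windows")
    pos = np.asarray(event_positions, dtype=float)
    pos = pos[(pos >= lo) & (pos < edges[-1])]
    counts, _ = np.histogram(pos, bins=edges)
    n_windows = counts.size
    total = int(counts.sum())
    if total == 0:
        import warnings
        warnings.warn("no events in included region; CV undefined, p = 1")
        return float("nan"), 1.0
    cv_obs = counts.std(ddof=1) / counts.mean()
    null = rng.multinomial(total, np.full(n_windows, 1.0 / n_windows), size=reps)
    cv_rep = null.std(axis=1, ddof=1) / null.mean(axis=1)
    p = (1.0 + int(np.sum(cv_rep >= cv_obs))) / (reps + 1.0)
    return float(cv_obs), float(p)


def genomewide_threshold(n_windows: int, alpha: float = 0.05) -> float:
    """Bonferroni-style whole-genome significance threshold: alpha / windows."""
    if n_windows < 1:
        raise ValueError("need at least one window")
    return alpha / n_windows
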