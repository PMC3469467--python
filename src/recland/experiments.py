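"""Reference experiments at desk scale.

Each function recomputes one of the package's headline quantities from
scratch by running the simulator and estimators end to end.  They are used
by the acceptance script and by the test suite; all randomness flows from
the single seed argument through spawned child generators.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from . import designs
from .core import ChromosomeSpec, GCParams
from .detect import detect_events
from .dispersion import index_of_dispersion
from .gc_mle import build_likelihood_data, fit_gc_mle
from .simulate import (make_marker_panel, observe_haplotypes, simulate_meiosis,
                       simulate_rail)


def mle_recovery_experiment(seed: int, gamma: float = 1.25e-7,
                            l_gc: float = 518.0, n_meioses: int = 5_000,
                            length_bp: int = 2_000_000,
                            marker_spacing: float = 1_830.0,
                            n_replicates: int = 9) -> Dict[str, float]:
    """Recover (gamma, L_GC) from simulated single meioses on a 2-Mb arm.

    Each replicate simulates ``n_meioses`` female meioses, projects the
    transmitted chromosomes onto a fresh marker panel at the study's median
    spacing, detects GC events, and fits the joint MLE.  The reported
    estimates are medians over ``n_replicates`` independent replicates,
    which suppresses the single-replicate Monte-Carlo noise of the strongly
    anti-correlated (gamma, L_GC) likelihood ridge without changing the
    per-replicate experimental scale.
    """
    gc = GCParams.from_mean_length(gamma=gamma, l_gc=l_gc)
    chrom = ChromosomeSpec("arm", length_bp, map_length_cM=0.0, has_co=False)
    g_hats, l_hats, ks = [], [], []
    for child in np.random.SeedSequence(seed).spawn(n_replicates):
        rng = np.random.default_rng(child)
        panel = make_marker_panel("arm", length_bp, marker_spacing, rng)
        haps_events = []
        for _ in range(n_meioses):
            truth = simulate_meiosis(chrom, gc, rng)
            evs = detect_events(observe_haplotypes(truth, panel))
            haps_events.append((panel.positions, evs))
        data = build_likelihood_data(haps_events)
        fit = fit_gc_mle(data, seed=int(rng.integers(2**31)))
        if not fit.converged:
            continue
        g_hats.append(fit.gamma_hat)
        l_hats.append(fit.L_GC_hat)
        ks.append(fit.n_events)
    return {
        "gamma_hat": float(np.median(g_hats)),
        "l_gc_hat": float(np.median(l_hats)),
        "n_events_total": int(np.sum(ks)),
        "n_replicates": len(g_hats),
        "n_meioses": n_meioses,
    }


def misassignment_experiment(seed: int, n_genomes: int = 10_000,
                             max_gc_span_bp: int = 15_000,
                             marker_spacing: float = 1_830.0,
                             crosses: Optional[Sequence[int]] = None,
                             pedigrees_per_cross: int = 5
                             ) -> Dict[str, object]:
    """Fraction of CO-derived events erroneously called GC by the cutoff.

    Simulates the study's eight RAIL crossing designs (their per-arm map
    lengths and derived sib-mating generation counts, up to 10 generations)
    with uniformly placed crossovers, no interference, and no gene
    conversion, then classifies the transmitted haplotypes through a
    marker panel at the study's median spacing.  Every GC call is therefore
    a misclassified close double crossover; the headline number is
    100 * (#GC calls) / (#true detectable CO junctions), pooled over arms
    and crosses, with per-arm maxima reported alongside.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if crosses is None:
        crosses = list(designs.CROSS_MEIOSES)
    arms = ["X", "2L", "2R", "3L", "3R"]
    panels = {arm: make_marker_panel(arm, designs.ARM_LENGTHS_BP[arm],
                                     marker_spacing, rng) for arm in arms}
    gc0 = GCParams(gamma=0.0, phi=0.0)
    per_pedigree = int(np.ceil(n_genomes / (len(crosses) * pedigrees_per_cross)))
    true_co = {arm: 0 for arm in arms}
    spurious = {arm: 0 for arm in arms}
    for cross in crosses:
        design = designs.study_cross_design(
            cross, offspring_sampled=per_pedigree,
            arms=[a for a in arms if a in designs.CROSS_MAP_LENGTHS_CM[cross]])
        genomes = []
        # independent pedigrees per cross: sampled genomes from a single
        # pedigree share ancestral junctions, which would otherwise make
        # the spurious-GC count strongly overdispersed
        for _ in range(pedigrees_per_cross):
            genomes.extend(simulate_rail(design, gc0, rng))
        for genome in genomes:
            for arm, truth in genome.items():
                true_co[arm] += int(truth.co_positions.size)
                evs = detect_events(observe_haplotypes(truth, panels[arm]),
                                    max_gc_span_bp)
                spurious[arm] += sum(1 for e in evs if e.kind == "GC")
    pct_by_arm = {arm: 100.0 * spurious[arm] / true_co[arm]
                  for arm in arms if true_co[arm]}
    tot_co = sum(true_co.values())
    tot_sp = sum(spurious.values())
    return {
        "pct_misassigned": 100.0 * tot_sp / tot_co,
        "pct_by_arm": pct_by_arm,
        "pct_max_arm": max(pct_by_arm.values()),
        "n_true_co": tot_co,
        "n_spurious_gc": tot_sp,
        "n_genomes": per_pedigree * pedigrees_per_cross * len(crosses),
    }


def r_co_null_experiment(seed: int, n_regions: int = 10_000,
                         n_crosses: int = 8,
                         mean_count: float = 10.0) -> Dict[str, float]:
    """Mean Index of Dispersion under an i.i.d. Poisson null.

    Draws per-region CO counts for ``n_crosses`` crosses with equal lineage
    totals (unit weights) and returns the mean R_CO across regions with its
    Monte-Carlo standard error; the Poisson expectation is ~1.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    x = rng.poisson(mean_count, size=(n_regions, n_crosses)).astype(float)
    w = np.ones(n_crosses)
    r = np.array([index_of_dispersion(row, w) for row in x])
    return {
        "mean_r_co": float(r.mean()),
        "se": float(r.std(ddof=1) / np.sqrt(n_regions)),
        "n_regions": n_regions,
    }
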