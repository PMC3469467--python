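"""End-to-end orchestration: simulate -> detect -> estimate -> statistics.

Also houses the small closed-form computations tying the map-level results
together: the fraction of double-strand breaks resolved as gene conversion,
the locally predicted gamma from a GC:CO ratio, and windowed correlations
between rate maps.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import designs, io
from .core import ChromosomeSpec, CrossDesign, GCParams, WindowMap
from .detect import detect_events, genome_map_length, window_rates
from .dispersion import dispersion_pvalue, cv_heterogeneity, genomewide_threshold, lineage_weights
from .enrichment import AnnotationSet, enrichment_test, expected_genic_frequency, tss_relative_positions
from .gc_mle import build_likelihood_data, fit_gc_mle
from .simulate import make_marker_panel, observe_haplotypes, simulate_rail


# ---------------------------------------------------------------------------
# closed-form report quantities
# ---------------------------------------------------------------------------

def gc_fraction_of_dsb(map_length_cM: float, dsb_per_meiosis: float,
                       per_gamete: bool = False) -> float:
    """Percentage of meiotic DSBs resolved as gene conversion.

    CO per female meiosis is counted at the bivalent level: each crossover
    exchanges two of the four chromatids, so a per-gamete map of
    ``map_length_cM`` corresponds to ``2 * map_length_cM / 100`` COs per
    meiosis (``per_gamete=True`` drops the factor of 2).
    """
    if dsb_per_meiosis <= 0:
        raise ValueError("dsb_per_meiosis must be positive")
    co_per_meiosis = (1.0 if per_gamete else 2.0) * map_length_cM / 100.0
    if co_per_meiosis > dsb_per_meiosis:
        raise ValueError("more COs per meiosis than DSBs: inconsistent inputs")
    return 100.0 * (1.0 - co_per_meiosis / dsb_per_meiosis)


def predicted_gamma_from_ratio(c_local: float, gc_per_co: float) -> float:
    """Local GC initiation rate predicted from a per-bp CO rate and GC:CO ratio."""
    if c_local < 0 or gc_per_co < 0:
        raise ValueError("rates must be non-negative")
    return gc_per_co * c_local


def windowed_correlations(map_a: WindowMap, map_b: WindowMap,
                          column: str = "c", method: str = "spearman",
                          control: Optional[WindowMap] = None) -> Dict[str, float]:
    """Rank correlation between two aligned window maps.

    With ``control`` given, also reports the semi-partial coefficient:
    the correlation of map_a with the rank residuals of map_b after
    removing the control map.
    """
    a = map_a.table[["start", column]].rename(columns={column: "a"})
    b = map_b.table[["start", column]].rename(columns={column: "b"})
    merged = a.merge(b, on="start").dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 paired windows")
    if method != "spearman":
        raise ValueError("only Spearman rank correlation is supported")
    r, p = stats.spearmanr(merged["a"], merged["b"])
    out = {"r": float(r), "p": float(p), "n_windows": int(len(merged))}
    if control is not None:
        c = control.table[["start", column]].rename(columns={column: "ctrl"})
        m3 = merged.merge(c, on="start").dropna()
        ra = stats.rankdata(m3["a"])
        rb = stats.rankdata(m3["b"])
        rc = stats.rankdata(m3["ctrl"])
        X = np.column_stack([np.ones(rc.size), rc])
        resid_b = rb - X @ np.linalg.lstsq(X, rb, rcond=None)[0]
        out["semi_partial_r"] = float(np.corrcoef(ra, resid_b)[0, 1])
    return out


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration for one end-to-end synthetic run.

    The default scale is a desk-size emulation of the study: a handful of
    crosses on one arm, with the study's per-meiosis rates.
    """

    seed: int = 0
    out_dir: str = "recland_out"
    arm_id: str = "2L"
    length_bp: int = 5_000_000
    map_length_cM: float = 12.0      # scaled with arm length (~55 cM / 23 Mb)
    gamma: float = 1.25e-7
    l_gc: float = 518.0
    marker_spacing: float = 1830.0
    n_crosses: int = 2
    n_generations: int = 2
    genomes_per_cross: int = 150
    max_gc_span_bp: int = 15_000
    window_size: int = 250_000
    window_step: int = 250_000
    ci_level: float = 0.90
    reps_dispersion: int = 10_000
    reps_cv: int = 2_000
    reps_enrichment: int = 10_000
    genic_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**io.load_yaml(path))

    def config_hash(self) -> str:
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = repr(sorted(fields.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _synthetic_annotation(length_bp: int, genic_fraction: float,
                          rng: np.random.Generator,
                          mean_gene_bp: float = 3_000.0) -> AnnotationSet:
    """Synthetic gene annotation: alternating genic/intergenic stretches."""
    genic, transcripts = [], []
    x = 0
    mean_gap = mean_gene_bp * (1 - genic_fraction) / max(genic_fraction, 1e-9)
    while x < length_bp:
        gap = int(rng.exponential(mean_gap)) + 1
        glen = int(rng.exponential(mean_gene_bp)) + 200
        s = x + gap
        e = min(s + glen, length_bp)
        if s >= length_bp:
            break
        genic.append((s, e))
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append({"tss": s if strand == "+" else e,
                            "length": e - s, "strand": strand})
        x = e
    return AnnotationSet(genic=np.array(genic),
                         transcripts=pd.DataFrame(transcripts))


def run_pipeline(config: RunConfig) -> Dict:
    """Execute simulate -> detect -> window -> gc-fit -> dispersion -> enrichment.

    Writes all intermediate TSV/BED artifacts under ``config.out_dir`` and
    returns the report dictionary (also written as report.json / report.txt).
    """
    rng = np.random.default_rng(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom = ChromosomeSpec(arm_id=config.arm_id, length_bp=config.length_bp,
                           map_length_cM=config.map_length_cM)
    gc = GCParams.from_mean_length(gamma=config.gamma, l_gc=config.l_gc)
    panel = make_marker_panel(config.arm_id, config.length_bp,
                              config.marker_spacing, rng)
    io.write_panel_bed(panel, out / "panel.bed")

    per_cross_events: List[list] = []
    all_events: List = []
    haps_events = []
    eq_meioses = designs.equivalent_meioses_approx(config.n_generations)
    for ci in range(config.n_crosses):
        design = CrossDesign(
            cross_id=f"sim{ci + 1}", n_generations=config.n_generations,
            n_bottles_schedule=designs.bottle_schedule(config.n_generations),
            chromosomes=[chrom], males_per_bottle=10, females_per_bottle=10,
            offspring_sampled=config.genomes_per_cross)
        genomes = simulate_rail(design, gc, rng)
        cross_events = []
        for gi, genome in enumerate(genomes):
            hap = observe_haplotypes(genome[config.arm_id], panel,
                                     source_cross=design.cross_id,
                                     source_individual=f"g{gi}")
            evs = detect_events(hap, config.max_gc_span_bp)
            cross_events.extend(evs)
            haps_events.append((panel.positions, evs))
        per_cross_events.append(cross_events)
        all_events.extend(cross_events)
    io.write_events_tsv(all_events, out / "events.tsv")
    io.write_events_bed(all_events, out / "events.bed")

    n_meioses_total = eq_meioses * config.n_crosses * config.genomes_per_cross
    wmap = window_rates(all_events, chrom, config.window_size,
                        config.window_step, n_meioses_total, config.ci_level)
    io.write_window_map_tsv(wmap, out / "windows.tsv")
    io.write_window_map_bedgraph(wmap, out / "c.bedgraph")

    map_len = genome_map_length({config.arm_id: all_events}, n_meioses_total)

    weights = [eq_meioses] * len(haps_events)
    lik_data = build_likelihood_data(haps_events, weights=weights)
    fit = fit_gc_mle(lik_data, seed=config.seed)
    gc_events = [e for e in all_events if e.kind == "GC"]
    co_events = [e for e in all_events if e.kind == "CO"]

    report: Dict = {
        "provenance": {"seed": config.seed, "config_hash": config.config_hash(),
                       "config": asdict(config)},
        "map_length_cM": map_len,
        "gc_fit": {"gamma_hat": fit.gamma_hat, "L_GC_hat": fit.L_GC_hat,
                   "phi_hat": fit.phi_hat, "converged": fit.converged,
                   "n_events": fit.n_events, "max_loglik": fit.max_loglik},
        "event_summary": {"n_CO": len(co_events), "n_GC": len(gc_events),
                          "gc_per_co": (len(gc_events) / len(co_events)
                                        if co_events else float("nan"))},
        "equivalent_meioses": eq_meioses,
    }
    if fit.n_events and fit.converged:
        report["gc_fraction_of_dsb_pct"] = gc_fraction_of_dsb(
            map_len["total"],
            dsb_per_meiosis=2 * (map_len["total"] / 100.0)
            * (1.0 + report["event_summary"]["gc_per_co"]))

    # among-cross dispersion (needs >= 2 crosses with CO events)
    totals = [sum(1 for e in evs if e.kind == "CO") for evs in per_cross_events]
    if len(per_cross_events) >= 2 and all(t > 0 for t in totals):
        edges = np.arange(0, config.length_bp + 1, config.window_size)
        x = np.stack([
            np.histogram([e.midpoint for e in evs if e.kind == "CO"], bins=edges)[0]
            for evs in per_cross_events], axis=1)
        w = lineage_weights(totals)
        r_co, pvals = dispersion_pvalue(x, w, reps=config.reps_dispersion,
                                        rng=rng)
        thr = genomewide_threshold(x.shape[0])
        disp = pd.DataFrame({"start": edges[:-1], "end": edges[1:],
                             "R_CO": r_co, "p": pvals,
                             "flagged": pvals < thr})
        disp.to_csv(out / "dispersion.tsv", sep="\t", index=False)
        report["dispersion"] = {"threshold": thr,
                                "n_flagged": int(np.nansum(pvals < thr)),
                                "n_regions": int(x.shape[0])}

    cv, cv_p = cv_heterogeneity([e.midpoint for e in co_events], chrom,
                                config.window_size, reps=config.reps_cv, rng=rng)
    report["cv_heterogeneity"] = {"CV": cv, "p": cv_p}

    ann = _synthetic_annotation(config.length_bp, config.genic_fraction, rng)
    try:
        enr = enrichment_test(all_events, ann, panel,
                              reps=config.reps_enrichment, rng=rng)
        report["enrichment"] = enr
        report["expected_genic_freq"] = expected_genic_frequency(ann, panel)
        gc500 = [e for e in gc_events if e.delim_span <= 500]
        if gc500:
            tss = tss_relative_positions(gc500, ann)
            report["tss"] = {"median_abs_tss_distance": tss["median_abs_tss_distance"],
                             "n_assigned": tss["n_assigned"]}
    except ValueError as exc:
        report["enrichment"] = {"skipped": str(exc)}

    io.write_report(report, out / "report")
    return report
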