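"""Readers and writers for the package's tabular formats.

Events travel as an extended TSV (all event fields) and as BED6; window
maps as TSV and BEDGRAPH; marker panels as BED.  Everything round-trips
through the functions here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import MarkerHaplotype, MarkerPanel, RecEvent, WindowMap

EVENT_COLUMNS = ["arm_id", "kind", "left_flank_pos", "right_flank_pos",
                 "first_conv_pos", "last_conv_pos", "L_min", "gap_left",
                 "gap_right", "m_gc", "L_max", "midpoint", "delim_span",
                 "source_cross", "source_individual"]


def events_to_frame(events: Sequence[RecEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        gc = e.kind == "GC"
        rows.append({
            "arm_id": e.arm_id, "kind": e.kind,
            "left_flank_pos": e.left_flank_pos,
            "right_flank_pos": e.right_flank_pos,
            "first_conv_pos": e.first_conv_pos if gc else "",
            "last_conv_pos": e.last_conv_pos if gc else "",
            "L_min": e.L_min if gc else "",
            "gap_left": e.gap_left if gc else "",
            "gap_right": e.gap_right if gc else "",
            "m_gc": e.m_gc if gc else "",
            "L_max": e.L_max if gc else "",
            "midpoint": e.midpoint,
            "delim_span": e.delim_span,
            "source_cross": e.source_cross,
            "source_individual": e.source_individual,
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_tsv(events: Sequence[RecEvent], path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> List[RecEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"source_cross": str,
                                            "source_individual": str},
                     keep_default_na=False, na_values=[""])
    out = []
    for _, r in df.iterrows():
        gc = r["kind"] == "GC"
        out.append(RecEvent(
            kind=r["kind"], arm_id=r["arm_id"],
            left_flank_pos=int(r["left_flank_pos"]),
            right_flank_pos=int(r["right_flank_pos"]),
            first_conv_pos=int(r["first_conv_pos"]) if gc else None,
            last_conv_pos=int(r["last_conv_pos"]) if gc else None,
            source_cross=str(r.get("source_cross", "") or ""),
            source_individual=str(r.get("source_individual", "") or ""),
        ))
    return out


def write_events_bed(events: Sequence[RecEvent], path) -> None:
    """BED6: chrom, start, end, name = kind, score = L_min for GC, strand '.'."""
    with open(path, "w") as fh:
        for e in events:
            if e.kind == "GC":
                start, end, score = e.first_conv_pos, e.last_conv_pos + 1, e.L_min
            else:
                start, end, score = e.left_flank_pos, e.right_flank_pos, 0
            fh.write(f"{e.arm_id}\t{start}\t{end}\t{e.kind}\t{score}\t.\n")


def write_window_map_tsv(wmap: WindowMap, path) -> None:
    df = wmap.table.copy()
    df.insert(0, "arm_id", wmap.arm_id)
    df.to_csv(path, sep="\t", index=False)


def read_window_map_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_window_map_bedgraph(wmap: WindowMap, path, column: str = "c") -> None:
    with open(path, "w") as fh:
        for _, r in wmap.table.iterrows():
            fh.write(f"{wmap.arm_id}\t{int(r['start'])}\t{int(r['end'])}\t{r[column]:.6g}\n")


def write_panel_bed(panel: MarkerPanel, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(panel.positions):
            fh.write(f"{panel.arm_id}\t{p}\t{p + 1}\tmarker{i}\n")


def read_panel_bed(path) -> MarkerPanel:
    rows = [ln.split("\t") for ln in Path(path).read_text().splitlines() if ln.strip()]
    arm = rows[0][0]
    positions = np.array(sorted(int(r[1]) for r in rows), dtype=np.int64)
    return MarkerPanel(arm_id=arm, positions=positions)


def write_haplotype_tsv(hap: MarkerHaplotype, path) -> None:
    pd.DataFrame({"arm_id": hap.arm_id, "position": hap.positions,
                  "parent": np.where(hap.parents == 0, "P1", "P2")}
                 ).to_csv(path, sep="\t", index=False)


def read_haplotype_tsv(path) -> MarkerHaplotype:
    df = pd.read_csv(path, sep="\t")
    return MarkerHaplotype(
        arm_id=str(df["arm_id"].iloc[0]),
        positions=df["position"].to_numpy(),
        parents=(df["parent"] == "P2").to_numpy().astype(np.int8),
    )


def write_truth_tsv(truth, path) -> None:
    """Ground-truth events and segments, one row per record."""
    rows = []
    for x in truth.co_positions:
        rows.append({"arm_id": truth.arm_id, "record": "CO", "start": int(x),
                     "length": "", "parent": ""})
    for s, n, donor in truth.gc_tracts:
        rows.append({"arm_id": truth.arm_id, "record": "GC", "start": int(s),
                     "length": int(n), "parent": f"P{donor + 1}"})
    for s, p in zip(truth.seg_starts, truth.seg_parents):
        rows.append({"arm_id": truth.arm_id, "record": "SEG", "start": int(s),
                     "length": "", "parent": f"P{p + 1}"})
    pd.DataFrame(rows, columns=["arm_id", "record", "start", "length", "parent"]
                 ).to_csv(path, sep="\t", index=False)


def read_design_yaml(path):
    """CrossDesign plus GCParams from a structured config file.

    Schema: top-level keys ``cross_id, n_generations, n_bottles_schedule,
    males_per_bottle, females_per_bottle, offspring_sampled, gamma, l_gc``
    and a ``chromosomes`` list of ``{arm_id, length_bp, map_length_cM,
    has_co, inheritance}`` entries.
    """
    from .core import ChromosomeSpec, CrossDesign, GCParams

    cfg = load_yaml(path)
    chroms = [ChromosomeSpec(
        arm_id=c["arm_id"], length_bp=int(c["length_bp"]),
        map_length_cM=float(c.get("map_length_cM", 0.0)),
        has_co=bool(c.get("has_co", True)),
        inheritance=c.get("inheritance", "autosome"),
    ) for c in cfg["chromosomes"]]
    design = CrossDesign(
        cross_id=str(cfg["cross_id"]),
        n_generations=int(cfg["n_generations"]),
        n_bottles_schedule=list(cfg["n_bottles_schedule"]),
        chromosomes=chroms,
        males_per_bottle=int(cfg.get("males_per_bottle", 20)),
        females_per_bottle=int(cfg.get("females_per_bottle", 20)),
        offspring_sampled=int(cfg.get("offspring_sampled", 100)),
    )
    gc = GCParams.from_mean_length(gamma=float(cfg.get("gamma", 0.0)),
                                   l_gc=float(cfg.get("l_gc", 1.0)))
    return design, gc


def load_yaml(path) -> Dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: Dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def write_report(report: Dict, path_prefix) -> None:
    """Machine-readable JSON plus a plain-text key/value rendering."""
    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
    with open(prefix.with_suffix(".txt"), "w") as fh:
        for line in _flatten(report):
            fh.write(line + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _flatten(obj, prefix=""):
    if isinstance(obj, dict):
        for k in sorted(obj, key=str):
            yield from _flatten(obj[k], f"{prefix}{k}.")
    elif isinstance(obj, pd.DataFrame):
        yield f"{prefix.rstrip('.')}\t<table {len(obj)} rows>"
    elif isinstance(obj, (list, tuple, np.ndarray)):
        yield f"{prefix.rstrip('.')}\t{json.dumps(np.asarray(obj).tolist())}"
    else:
        yield f"{prefix.rstrip('.')}\t{obj}"
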