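"""Readers and writers: subject tables, cluster tables, GeoJSON ellipses.

All writers are deterministic given identical inputs (stable row order, fixed
number formatting), so identical runs produce byte-identical files.
Coordinates are synthetic planar meters; GeoJSON carries a ``crs_note``
property instead of a CRS, since the synthetic data has no geodetic datum.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ROLES, WINDOWS
from .cohort import RECORD_COLUMNS, Cohort
from .pipeline import StudyResult

log = logging.getLogger("transgen_scan")

_GEOJSON_SEGMENTS = 64


def read_subjects_csv(path) -> pd.DataFrame:
    """Read and validate a subjects table (one row per ancestor per window).

    Required columns: subject_id, family_id, role, window, x, y, year,
    is_case. Raises with offending column names / row numbers on schema
    violations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty file")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | ~np.isfinite(vals)].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric {col} at rows {bad[:5]}")
        df[col] = vals.astype(float)
    years = pd.to_numeric(df["year"], errors="coerce")
    bad = df.index[years.isna()].tolist()
    if bad:
        raise ValueError(f"{path}: non-numeric year at rows {bad[:5]}")
    df["year"] = years.astype(int)
    bad = df.index[~df["role"].isin(ROLES)].tolist()
    if bad:
        raise ValueError(
            f"{path}: unknown role {df.loc[bad[0], 'role']!r} at rows {bad[:5]}"
        )
    bad = df.index[~df["window"].isin(WINDOWS)].tolist()
    if bad:
        raise ValueError(
            f"{path}: unknown window {df.loc[bad[0], 'window']!r} at rows {bad[:5]}"
        )
    df["is_case"] = df["is_case"].map(
        {True: True, False: False, "True": True, "False": False, 1: True, 0: False,
         "1": True, "0": False}
    )
    if df["is_case"].isna().any():
        bad = df.index[df["is_case"].isna()].tolist()
        raise ValueError(f"{path}: non-boolean is_case at rows {bad[:5]}")
    df["is_case"] = df["is_case"].astype(bool)
    df["subject_id"] = df["subject_id"].astype(str)
    df["family_id"] = df["family_id"].astype(str)
    return df[list(RECORD_COLUMNS)]


def write_subjects_csv(records: pd.DataFrame, path) -> None:
    """Write the subjects table; round-trips through read_subjects_csv."""
    records.to_csv(path, index=False, columns=list(RECORD_COLUMNS), float_format="%.3f")


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write a generated cohort: subjects CSV + ground-truth JSON sidecar."""
    from .config import planted_to_dict, RunConfig  # local to avoid cycle
    import dataclasses

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = out / "subjects.csv"
    write_subjects_csv(cohort.records, subjects)
    truth = out / "ground_truth.json"
    cfg = dataclasses.asdict(cohort.config)
    cfg["bbox"] = list(cfg["bbox"])
    cfg["urban_centers"] = [dict(u) if isinstance(u, dict) else u for u in cfg["urban_centers"]]
    with open(truth, "w") as fh:
        json.dump(
            {
                "config": _plain(cfg),
                "planted": planted_to_dict(cohort.planted),
                "seed": cohort.seed,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    log.info("wrote cohort: %d records -> %s", len(cohort.records), subjects)
    return {"subjects": subjects, "ground_truth": truth}


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _fmt_float(v, nd: int) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and (v != v):  # NaN
        return "nan"
    if v == float("inf"):
        return "inf"
    return f"{v:.{nd}f}"


def clusters_tsv_text(result: StudyResult) -> str:
    """Render the combined cluster table as TSV text with fixed precision."""
    header = [
        "cluster_id", "role", "window", "year_start", "year_end", "observed",
        "expected", "rr", "llr", "direction", "p_mc", "p_bonf", "area_km2",
        "n_members",
    ]
    lines = ["\t".join(header)]
    for r in result.clusters:
        lines.append(
            "\t".join(
                [
                    r.cluster_id or "",
                    r.role or "",
                    r.window or "",
                    str(r.cylinder.year_start),
                    str(r.cylinder.year_end),
                    str(r.c),
                    _fmt_float(r.e, 2),
                    _fmt_float(r.rr, 2),
                    _fmt_float(r.llr, 4),
                    r.direction,
                    repr(r.p_mc),
                    repr(r.p_bonf) if r.p_bonf is not None else "",
                    _fmt_float(r.area_km2, 2),
                    str(r.n),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def study_geojson(result: StudyResult) -> dict:
    """Cluster ellipses as a GeoJSON FeatureCollection (planar meters)."""
    features = []
    for r in result.clusters:
        poly = r.cylinder.polygon(_GEOJSON_SEGMENTS)
        coords = [[list(pt) for pt in poly.exterior.coords]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": coords},
                "properties": {
                    "cluster_id": r.cluster_id,
                    "role": r.role,
                    "window": r.window,
                    "year_start": r.cylinder.year_start,
                    "year_end": r.cylinder.year_end,
                    "observed": r.c,
                    "expected": round(r.e, 2),
                    "rr": None if r.rr == float("inf") else round(r.rr, 2),
                    "llr": round(r.llr, 4),
                    "direction": r.direction,
                    "p_mc": r.p_mc,
                    "p_bonf": r.p_bonf,
                    "area_km2": round(r.area_km2, 2),
                    "n_members": r.n,
                    "crs_note": "synthetic planar meters",
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_cluster_outputs(result: StudyResult, out_dir) -> dict[str, Path]:
    """Write the combined TSV, member CSV, GeoJSON and run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = out / "clusters.tsv"
    tsv.write_text(clusters_tsv_text(result))
    members = out / "cluster_members.csv"
    with open(members, "w") as fh:
        fh.write("cluster_id,subject_id\n")
        for r in result.clusters:
            for m in r.member_ids:
                fh.write(f"{r.cluster_id},{m}\n")
    geo = out / "clusters.geojson"
    with open(geo, "w") as fh:
        json.dump(study_geojson(result), fh, indent=1, sort_keys=True)
        fh.write("\n")
    meta = out / "run_metadata.json"
    with open(meta, "w") as fh:
        json.dump(
            {
                "master_seed": result.master_seed,
                "bonferroni_m": result.bonferroni_m,
                "stratum_seeds": {
                    f"{role}/{window}": s
                    for (role, window), s in sorted(result.seeds.items())
                },
                "stratum_counts": {
                    f"{role}/{window}": c
                    for (role, window), c in sorted(result.stratum_counts.items())
                },
                "skipped": {
                    f"{role}/{window}": reason
                    for (role, window), reason in sorted(result.skipped.items())
                },
                "n_clusters": len(result.clusters),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    log.info("wrote %d clusters -> %s", len(result.clusters), tsv)
    return {"clusters": tsv, "members": members, "geojson": geo, "metadata": meta}
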