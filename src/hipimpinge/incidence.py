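"""Impingement incidence tables and cohort summaries.

Incidence of a region = (number of the 12 protocol conditions contacting
that region) / 12 x 100.  The long-format table -- one row per
(patient, tilt, region in {A, B, C, total}) with anatomical covariates --
is the contract between the simulation half and the statistics half of
the package and round-trips through CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rom import ImpingementRecord

N_CONDITIONS = 12
REGIONS = ("A", "B", "C")

TABLE_COLUMNS = [
    "patient_id", "tilt_deg", "region", "incidence_pct", "n_conditions",
    "aiis_type", "lcea", "femoral_version", "acetabular_version",
]

#: subgroup class edges used in cohort summaries
FV_CLASSES = {"low": (-np.inf, 5.0), "normal": (5.0, 19.0), "high": (19.0, np.inf)}
LCEA_CLASSES = {"low": (-np.inf, 25.0), "normal": (25.0, 40.0), "high": (40.0, np.inf)}


def compute_incidence(records: list[ImpingementRecord]) -> dict[str, float]:
    """Per-region and total incidence (%) from one 12-condition run."""
    ids = sorted(r.condition_id for r in records)
    if ids != list(range(1, N_CONDITIONS + 1)):
        raise ValueError(f"expected condition ids 1..12 exactly once, got {ids}")
    counts = {r: 0 for r in REGIONS}
    total = 0
    for rec in records:
        if rec.impinged:
            total += 1
            if rec.region is not None:
                counts[rec.region] += 1
    out = {r: counts[r] / N_CONDITIONS * 100.0 for r in REGIONS}
    out["total"] = total / N_CONDITIONS * 100.0
    return out


def incidence_table(
    records: list[ImpingementRecord], covariates: dict[str, dict]
) -> pd.DataFrame:
    """Assemble the long-format incidence table from protocol records.

    ``covariates`` maps patient_id to a record holding at least
    aiis_type, lcea, femoral_version and acetabular_version (the
    *measured* anatomy from cohort sampling).
    """
    rows = []
    df = pd.DataFrame(
        [(r.patient_id, r.tilt_deg, r) for r in records],
        columns=["patient_id", "tilt_deg", "rec"],
    )
    for (pid, tilt), grp in df.groupby(["patient_id", "tilt_deg"], sort=True):
        inc = compute_incidence(list(grp["rec"]))
        cov = covariates[pid]
        for region in (*REGIONS, "total"):
            rows.append(
                {
                    "patient_id": pid,
                    "tilt_deg": float(tilt),
                    "region": region,
                    "incidence_pct": inc[region],
                    "n_conditions": N_CONDITIONS,
                    "aiis_type": cov["aiis_type"],
                    "lcea": cov["lcea"],
                    "femoral_version": cov["femoral_version"],
                    "acetabular_version": cov["acetabular_version"],
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _classify(value: float, classes: dict) -> str:
    # low: value < lo-edge; normal: closed interval; high: value > hi-edge
    lo_hi = classes["normal"]
    if value < lo_hi[0]:
        return "low"
    if value > lo_hi[1]:
        return "high"
    return "normal"


def summarize_cohort(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cohort means +/- sample SD per (tilt, region), plus subgroup means.

    Returns ``{"by_tilt_region": ..., "subgroups": ...}``.  Subgroups
    follow the usual clinical cuts: femoral version low < 5, normal 5-19,
    high > 19 deg; LCEA low < 25, normal 25-40, high > 40 deg; AIIS
    morphotype.  Subgroup rows use the *total* incidence.  SD is reported
    as NaN (not 0) for single-member groups; empty classes are omitted.
    """
    if table.empty:
        raise ValueError("empty incidence table")

    def sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else np.nan

    by = (
        table.groupby(["tilt_deg", "region"])["incidence_pct"]
        .agg(mean="mean", sd=sd, n="count")
        .reset_index()
    )

    tot = table[table["region"] == "total"].copy()
    tot["fv_class"] = [ _classify(v, FV_CLASSES) for v in tot["femoral_version"] ]
    tot["lcea_class"] = [ _classify(v, LCEA_CLASSES) for v in tot["lcea"] ]
    sub_rows = []
    for factor, col in (("aiis_type", "aiis_type"), ("fv", "fv_class"), ("lcea", "lcea_class")):
        for (level, tilt), grp in tot.groupby([col, "tilt_deg"]):
            sub_rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "tilt_deg": float(tilt),
                    "n": len(grp),
                    "mean": float(grp["incidence_pct"].mean()),
                    "sd": sd(grp["incidence_pct"]),
                }
            )
    return {"by_tilt_region": by, "subgroups": pd.DataFrame(sub_rows)}


def write_incidence_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_incidence_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns and c != "n_conditions"]
    if missing:
        raise ValueError(f"incidence CSV missing columns: {missing}")
    return df
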