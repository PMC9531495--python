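"""The full 18-model study: six ancestor roles x three developmental windows.

Each (role, window) stratum is scanned independently with its own
deterministic seed derived from the master seed; every reported cluster's
Monte Carlo p-value receives a Bonferroni adjustment for the m = 18 models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ROLES, WINDOWS, ScanConfig
from .scan import AncestorStratum, ClusterResult, scan_stratum


def build_strata(records: pd.DataFrame) -> dict[tuple[str, str], AncestorStratum]:
    """Partition the record table into the 18 (role, window) strata.

    Subjects missing a record for a window (linkage missingness) are simply
    absent from that stratum. Unknown role/window labels raise, naming the
    offending rows.
    """
    bad_role = ~records["role"].isin(ROLES)
    if bad_role.any():
        rows = records.index[bad_role][:5].tolist()
        raise ValueError(
            f"unknown role {records.loc[rows[0], 'role']!r} at rows {rows}"
        )
    bad_window = ~records["window"].isin(WINDOWS)
    if bad_window.any():
        rows = records.index[bad_window][:5].tolist()
        raise ValueError(
            f"unknown window {records.loc[rows[0], 'window']!r} at rows {rows}"
        )
    return {
        (role, window): AncestorStratum.from_records(records, role, window)
        for role in ROLES
        for window in WINDOWS
    }


def bonferroni_adjust(p: float, m: int = 18) -> float:
    """Textbook Bonferroni correction: min(1, m * p)."""
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def stratum_seed(master_seed: int, role: str, window: str) -> int:
    """Deterministic per-stratum scan seed derived from the master seed."""
    ss = np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF, ROLES.index(role), WINDOWS.index(window)]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class StudyResult:
    """Outcome of a full study run across all 18 strata."""

    clusters: list[ClusterResult]
    stratum_counts: dict[tuple[str, str], dict]  # N, C per stratum
    skipped: dict[tuple[str, str], str]  # stratum -> reason
    seeds: dict[tuple[str, str], int]
    master_seed: int
    bonferroni_m: int
    scan_config: ScanConfig = None

    def clusters_frame(self) -> pd.DataFrame:
        """Combined cluster table, one row per reported cluster."""
        rows = []
        for r in self.clusters:
            rows.append(
                {
                    "cluster_id": r.cluster_id,
                    "role": r.role,
                    "window": r.window,
                    "year_start": r.cylinder.year_start,
                    "year_end": r.cylinder.year_end,
                    "observed": r.c,
                    "expected": r.e,
                    "rr": r.rr,
                    "llr": r.llr,
                    "direction": r.direction,
                    "p_mc": r.p_mc,
                    "p_bonf": r.p_bonf,
                    "area_km2": r.area_km2,
                    "n_members": r.n,
                }
            )
        cols = [
            "cluster_id", "role", "window", "year_start", "year_end",
            "observed", "expected", "rr", "llr", "direction", "p_mc",
            "p_bonf", "area_km2", "n_members",
        ]
        return pd.DataFrame(rows, columns=cols)


def run_study(
    records: pd.DataFrame,
    scan_config: ScanConfig,
    seed: int,
    bonferroni_m: int = 18,
) -> StudyResult:
    """Scan every non-degenerate stratum; attach Bonferroni-adjusted p-values.

    Strata failing scan preconditions (no cases, no controls, fewer than two
    records or years) are recorded as skipped with the reason. Raises if all
    18 strata are degenerate.
    """
    strata = build_strata(records)
    clusters: list[ClusterResult] = []
    skipped: dict[tuple[str, str], str] = {}
    seeds: dict[tuple[str, str], int] = {}
    counts: dict[tuple[str, str], dict] = {}
    for (role, window), stratum in strata.items():
        counts[(role, window)] = {"N": stratum.N, "C": stratum.C}
        s = stratum_seed(seed, role, window)
        seeds[(role, window)] = s
        try:
            found = scan_stratum(stratum, scan_config, seed=s)
        except ValueError as err:
            skipped[(role, window)] = str(err)
            continue
        for k, r in enumerate(found, start=1):
            r.p_bonf = bonferroni_adjust(r.p_mc, bonferroni_m)
            r.cluster_id = f"{role}:{window}:{k}"
        clusters.extend(found)
    if len(skipped) == len(strata):
        raise ValueError("all strata degenerate; nothing to scan")
    clusters.sort(
        key=lambda r: (ROLES.index(r.role), WINDOWS.index(r.window), -r.llr)
    )
    return StudyResult(
        clusters=clusters,
        stratum_counts=counts,
        skipped=skipped,
        seeds=seeds,
        master_seed=seed,
        bonferroni_m=bonferroni_m,
        scan_config=scan_config,
    )
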