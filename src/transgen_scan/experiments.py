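"""Simulation experiments: calibration, planted-cluster recovery, jitter.

These drive the generator and the scan end to end under the study's
conditions (2:1 matching, six ancestor roles, three windows, ~90% linkage)
at desk-scale problem sizes, and are what both the test suite and
``scripts/acceptance.py`` execute. Candidate grids are deterministically
thinned (see ``ScanConfig``); Monte Carlo p-values remain valid for any
fixed grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import empirical_risk_ratio, generate_cohort, in_planted_cylinder
from .config import CohortConfig, PlantedCluster, ScanConfig
from .pipeline import run_study, stratum_seed
from .postprocess import jitter_rerun
from .scan import AncestorStratum, point_in_cylinder, scan_stratum

#: Reduced candidate grid used by the simulation experiments: circular
#: windows on a thinned center/size/time grid, R = 99 label permutations.
FAST_SCAN = ScanConfig(
    shapes=(1.0,),
    angles_per_shape=(1,),
    n_replicates=99,
    max_centers=60,
    n_size_steps=10,
    time_agg_years=8,
    max_reported=5,
)

#: Same grid at higher spatial resolution, for single-stratum recovery runs.
RECOVERY_SCAN = ScanConfig(
    shapes=(1.0,),
    angles_per_shape=(1,),
    n_replicates=99,
    max_centers=150,
    n_size_steps=12,
    time_agg_years=5,
    max_reported=5,
)

#: Planted high-rate cluster on the mid-density urban center, 1940s-50s,
#: attraction set so the inside/outside risk ratio lands near 2.9 (the
#: magnitude of the strongest clusters the method is meant to find).
PLANT_HIGH = PlantedCluster(
    target_role="paternal_grandmother",
    target_window="birth",
    center=(70_000.0, 140_000.0),
    semi_major=12_000.0,
    shape=1.5,
    angle=math.pi / 6,
    year_start=1945,
    year_end=1955,
    attraction=0.24,
)

#: Planted low-rate (case-depleted) region: controls attracted instead,
#: calibrated toward an inside/outside risk ratio near 0.3.
PLANT_LOW = PlantedCluster(
    target_role="paternal_grandmother",
    target_window="birth",
    center=(70_000.0, 140_000.0),
    semi_major=12_000.0,
    shape=1.5,
    angle=math.pi / 6,
    year_start=1945,
    year_end=1955,
    attraction=0.12,
    attract_label="control",
)


def _sub_seed(seed: int, tag: int, k: int) -> int:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag, k])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# type-I calibration
# ---------------------------------------------------------------------------


def type1_calibration(
    n_cohorts: int = 200,
    n_case_children: int = 100,
    seed: int = 0,
    scan_config: ScanConfig = FAST_SCAN,
    bonferroni_m: int = 18,
) -> dict:
    """Null calibration: no planted clusters, so case labels are exchangeable.

    Runs the full 18-model study on ``n_cohorts`` independent null cohorts
    (stratum sizes ~ 3 * n_case_children * p_link) and reports the fraction
    of scanned strata whose most-likely cluster has p_mc <= 0.05, plus the
    familywise fraction of cohorts with any Bonferroni-adjusted p < 0.05.
    """
    frac_sig = 0
    n_strata = 0
    cohorts_with_fw_hit = 0
    for k in range(n_cohorts):
        cfg = CohortConfig(n_case_children=n_case_children)
        cohort = generate_cohort(cfg, seed=_sub_seed(seed, 1, k))
        res = run_study(
            cohort.records, scan_config, seed=_sub_seed(seed, 2, k),
            bonferroni_m=bonferroni_m,
        )
        best_p: dict[tuple, float] = {}
        for cl in res.clusters:
            key = (cl.role, cl.window)
            best_p[key] = min(best_p.get(key, 1.0), cl.p_mc)
        scanned = [
            key for key in res.stratum_counts if key not in res.skipped
        ]
        n_strata += len(scanned)
        frac_sig += sum(1 for key in scanned if best_p.get(key, 1.0) <= 0.05)
        if any(cl.p_bonf is not None and cl.p_bonf < 0.05 for cl in res.clusters):
            cohorts_with_fw_hit += 1
    return {
        "n_cohorts": n_cohorts,
        "n_strata": n_strata,
        "frac_strata_sig": frac_sig / n_strata,
        "frac_cohorts_familywise": cohorts_with_fw_hit / n_cohorts,
    }


# ---------------------------------------------------------------------------
# planted-cluster recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryRun:
    detected: bool
    empirical_ratio: float
    recovered_rr: float | None
    recovered_direction: str | None
    p_mc: float | None


def _detects(cluster, planted: PlantedCluster) -> bool:
    """Significant-cluster match: ellipse contains the planted center and the
    year intervals overlap."""
    cyl = cluster.cylinder
    years_overlap = (
        cyl.year_start <= planted.year_end and planted.year_start <= cyl.year_end
    )
    return years_overlap and point_in_cylinder(
        planted.center[0], planted.center[1], cyl.year_start, cyl
    )


def recovery_run(
    planted: PlantedCluster,
    n_case_children: int,
    seed: int,
    scan_config: ScanConfig = RECOVERY_SCAN,
    direction: str = "high",
    alpha: float = 0.05,
) -> RecoveryRun:
    """One seeded generation + single-stratum scan of the planted stratum."""
    cfg = CohortConfig(n_case_children=n_case_children)
    cohort = generate_cohort(cfg, planted=[planted], seed=_sub_seed(seed, 3, 0))
    truth = empirical_risk_ratio(cohort.records, planted)
    stratum = AncestorStratum.from_records(
        cohort.records, planted.target_role, planted.target_window
    )
    clusters = scan_stratum(stratum, scan_config, seed=_sub_seed(seed, 4, 0))
    for cl in clusters:
        if cl.p_mc <= alpha and cl.direction == direction and _detects(cl, planted):
            return RecoveryRun(
                detected=True,
                empirical_ratio=truth["risk_ratio"],
                recovered_rr=cl.rr,
                recovered_direction=cl.direction,
                p_mc=cl.p_mc,
            )
    return RecoveryRun(
        detected=False,
        empirical_ratio=truth["risk_ratio"],
        recovered_rr=None,
        recovered_direction=None,
        p_mc=clusters[0].p_mc if clusters else None,
    )


def recovery_experiment(
    n_runs: int = 50,
    n_case_children: int = 600,
    seed: int = 0,
    planted: PlantedCluster = PLANT_HIGH,
    scan_config: ScanConfig = RECOVERY_SCAN,
    direction: str = "high",
) -> dict:
    """Repeated seeded recovery runs of a planted cluster.

    Reports the detection rate and, among detections, the ratio of the
    scan's estimated cluster RR to the empirical inside/outside risk ratio
    counted directly from the generated labels.
    """
    runs = [
        recovery_run(
            planted, n_case_children, _sub_seed(seed, 5, k), scan_config, direction
        )
        for k in range(n_runs)
    ]
    detected = [r for r in runs if r.detected]
    rr_ratios = [
        r.recovered_rr / r.empirical_ratio
        for r in detected
        if r.empirical_ratio and np.isfinite(r.recovered_rr)
    ]
    return {
        "n_runs": n_runs,
        "detection_rate": len(detected) / n_runs,
        "median_empirical_ratio": float(
            np.median([r.empirical_ratio for r in runs])
        ),
        "median_recovered_rr": float(np.median([r.recovered_rr for r in detected]))
        if detected
        else float("nan"),
        "median_rr_ratio": float(np.median(rr_ratios)) if rr_ratios else float("nan"),
        "rr_ratios": rr_ratios,
    }


# ---------------------------------------------------------------------------
# jitter sensitivity
# ---------------------------------------------------------------------------


def jitter_experiment(
    n_case_children: int = 300,
    seed: int = 0,
    d: float = 10.0,
    planted: PlantedCluster = None,
    scan_config: ScanConfig = RECOVERY_SCAN,
) -> dict:
    """Plant a strong km-scale cluster, run the study, jitter by d meters,
    re-run, and check the planted stratum's significant cluster persists."""
    if planted is None:
        planted = PLANT_HIGH
    cfg = CohortConfig(n_case_children=n_case_children)
    cohort = generate_cohort(cfg, planted=[planted], seed=_sub_seed(seed, 6, 0))
    records = cohort.records[
        (cohort.records["role"] == planted.target_role)
        & (cohort.records["window"] == planted.target_window)
    ].reset_index(drop=True)
    result = run_study(records, scan_config, seed=_sub_seed(seed, 7, 0))
    significant = [
        cl for cl in result.clusters if cl.p_mc <= 0.05 and _detects(cl, planted)
    ]
    report = jitter_rerun(
        records, scan_config, result, d=d, seed=_sub_seed(seed, 8, 0)
    )
    persisted = [
        cl
        for cl in significant
        if report.persistence.get(cl.cluster_id)
        and report.p_after.get(cl.cluster_id) is not None
        and report.p_after[cl.cluster_id] <= 0.05
    ]
    return {
        "displacement_m": d,
        "n_significant_before": len(significant),
        "n_persisting_significant": len(persisted),
        "all_persist": bool(significant) and len(persisted) == len(significant),
    }


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def determinism_check(n_case_children: int = 50, seed: int = 0) -> bool:
    """Same master seed twice -> byte-identical cluster TSV."""
    from .io import clusters_tsv_text

    texts = []
    for _ in range(2):
        cfg = CohortConfig(n_case_children=n_case_children)
        cohort = generate_cohort(cfg, planted=[PLANT_HIGH], seed=_sub_seed(seed, 9, 0))
        res = run_study(cohort.records, FAST_SCAN, seed=_sub_seed(seed, 10, 0))
        texts.append(clusters_tsv_text(res))
    return texts[0] == texts[1]
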