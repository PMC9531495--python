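"""Post-hoc analyses: cluster membership overlap, geocoding-jitter
sensitivity, and a Moran's I spatial-autocorrelation diagnostic.

Overlap quantifies "cohort effects": the same families produce clusters in
consecutive developmental windows because they did not move, so a birth-window
cluster's members reappear inside a childhood-window cluster's ellipse.

The jitter analysis displaces every residential point by a fixed distance in
an independent uniform direction and re-runs the whole study, mimicking a
robustness check against geocoding error (e.g. rural PO-box addresses); a
cluster "persists" when the rerun reports a cluster in the same stratum whose
ellipse contains the original center and whose years overlap the original.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScanConfig
from .pipeline import StudyResult, run_study
from .scan import ClusterResult, point_in_cylinder


@dataclass
class OverlapReport:
    """Directional spatial overlap: members of a inside b's ellipse."""

    cluster_a: str
    cluster_b: str
    n_shared: int
    fraction_shared: float


def overlap_membership(
    cluster_a: ClusterResult,
    cluster_b: ClusterResult,
    records: pd.DataFrame,
) -> OverlapReport:
    """Count cluster_a members whose location falls in cluster_b's ellipse.

    Space only (time is deliberately ignored): the question is whether the
    same people occupy the space of the other cluster. Not symmetric.
    """
    if not cluster_a.member_ids:
        raise ValueError("cluster_a has no members")
    sub = records
    if cluster_a.role is not None and cluster_a.window is not None:
        sub = records[
            (records["role"] == cluster_a.role)
            & (records["window"] == cluster_a.window)
        ]
    locs = sub.drop_duplicates("subject_id").set_index("subject_id")
    missing = [m for m in cluster_a.member_ids if m not in locs.index]
    if missing:
        raise ValueError(f"member ids missing from records: {missing[:5]}")
    # time-free copy of b's cylinder: test space only
    cyl = cluster_b.cylinder
    n_shared = 0
    for m in cluster_a.member_ids:
        row = locs.loc[m]
        dx, dy = float(row["x"]) - cyl.center[0], float(row["y"]) - cyl.center[1]
        ca, sa = np.cos(cyl.angle), np.sin(cyl.angle)
        u = dx * ca + dy * sa
        v = -dx * sa + dy * ca
        if cyl.semi_major > 0 and (
            (u / cyl.semi_major) ** 2 + (v / cyl.semi_minor) ** 2 <= 1.0 + 1e-9
        ):
            n_shared += 1
    return OverlapReport(
        cluster_a=cluster_a.cluster_id or "a",
        cluster_b=cluster_b.cluster_id or "b",
        n_shared=n_shared,
        fraction_shared=n_shared / len(cluster_a.member_ids),
    )


def overlap_table(result: StudyResult, records: pd.DataFrame) -> pd.DataFrame:
    """All ordered cluster pairs' overlap (both directions), as a table."""
    rows = []
    for a in result.clusters:
        for b in result.clusters:
            if a is b:
                continue
            rep = overlap_membership(a, b, records)
            rows.append(
                {
                    "cluster_a": rep.cluster_a,
                    "cluster_b": rep.cluster_b,
                    "n_shared": rep.n_shared,
                    "fraction_shared": rep.fraction_shared,
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster_a", "cluster_b", "n_shared", "fraction_shared"]
    )


@dataclass
class JitterReport:
    """Outcome of the displacement sensitivity analysis."""

    displacement: float
    persistence: dict[str, bool]  # original cluster_id -> persisted
    p_before: dict[str, float]
    p_after: dict[str, float | None]  # p of the matching rerun cluster
    rerun: StudyResult


def jitter_records(
    records: pd.DataFrame, d: float, seed: int | None = None
) -> pd.DataFrame:
    """Displace every record by exactly d meters in a uniform random direction."""
    if d <= 0:
        raise ValueError("displacement d must be > 0")
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * np.pi, len(records))
    out = records.copy()
    out["x"] = out["x"].to_numpy() + d * np.cos(phi)
    out["y"] = out["y"].to_numpy() + d * np.sin(phi)
    return out


def _persists(original: ClusterResult, rerun: StudyResult) -> ClusterResult | None:
    """Rerun cluster in the same stratum containing the original center with
    overlapping years, or None."""
    ox, oy = original.cylinder.center
    for r in rerun.clusters:
        if (r.role, r.window) != (original.role, original.window):
            continue
        years_overlap = (
            r.cylinder.year_start <= original.cylinder.year_end
            and original.cylinder.year_start <= r.cylinder.year_end
        )
        if years_overlap and point_in_cylinder(
            ox, oy, r.cylinder.year_start, r.cylinder
        ):
            return r
    return None


def jitter_rerun(
    records: pd.DataFrame,
    scan_config: ScanConfig,
    original: StudyResult,
    d: float = 10.0,
    seed: int = 0,
    bonferroni_m: int = 18,
) -> JitterReport:
    """Displace all points by d meters and re-run the full study."""
    moved = jitter_records(records, d, seed=seed)
    rerun = run_study(moved, scan_config, seed=original.master_seed, bonferroni_m=bonferroni_m)
    persistence, p_before, p_after = {}, {}, {}
    for cl in original.clusters:
        match = _persists(cl, rerun)
        persistence[cl.cluster_id] = match is not None
        p_before[cl.cluster_id] = cl.p_mc
        p_after[cl.cluster_id] = match.p_mc if match is not None else None
    return JitterReport(
        displacement=d,
        persistence=persistence,
        p_before=p_before,
        p_after=p_after,
        rerun=rerun,
    )


def morans_i_diagnostic(
    records: pd.DataFrame,
    cell_size: float = 1000.0,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Moran's I of gridded case fractions with rook contiguity weights.

    Records are aggregated to square cells of ``cell_size`` meters; each
    non-empty cell's value is its case fraction. I = (n/W) * sum_ij w_ij z_i
    z_j / sum_i z_i^2 on centered values; the permutation p-value shuffles
    cell values over the grid and is two-sided around E[I] = -1/(n-1).

    This is a diagnostic stand-in for the (unnamed) autocorrelation check a
    practitioner would run before trusting point-density-driven clusters.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    gx = np.floor(records["x"].to_numpy() / cell_size).astype(int)
    gy = np.floor(records["y"].to_numpy() / cell_size).astype(int)
    df = pd.DataFrame({"gx": gx, "gy": gy, "is_case": records["is_case"].to_numpy()})
    cells = df.groupby(["gx", "gy"])["is_case"].mean()
    if len(cells) < 2:
        raise ValueError("need at least 2 non-empty cells")
    values = cells.to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        raise ValueError("all cells identical: Moran's I undefined")
    coords = {key: i for i, key in enumerate(cells.index)}
    pairs = []
    for (cx, cy), i in coords.items():
        for nb in ((cx + 1, cy), (cx, cy + 1)):  # rook neighbors, undirected
            j = coords.get(nb)
            if j is not None:
                pairs.append((i, j))
    if not pairs:
        raise ValueError("no contiguous cells: Moran's I undefined")
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    n = len(values)
    W = 2 * len(pairs)  # symmetric weights, w_ij = w_ji = 1

    def moran(vals: np.ndarray) -> float:
        z = vals - vals.mean()
        num = 2.0 * float((z[ii] * z[jj]).sum())
        return (n / W) * num / float((z * z).sum())

    i_obs = moran(values)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    dev_obs = abs(i_obs - expected)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(values)
        if abs(moran(perm) - expected) >= dev_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return i_obs, p
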