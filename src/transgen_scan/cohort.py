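"""Synthetic multigenerational case-control cohort generator.

Emulates the structure of a statewide registry cohort used for
transgenerational space-time cluster analysis: case children born in a fixed
study period, controls matched 2:1 on exact (birth year, sex), six ancestors
per child (parents and both sets of grandparents), and one dated residential
point per ancestor per developmental window (birth 0-1 y, childhood 2-11 y,
adolescence 12-17 y). Locations are drawn from a mixture of Gaussian urban
centers and a uniform rural background; consecutive windows reuse the previous
location with probability ``p_stay``; each (ancestor, window) record survives
record linkage independently with probability ``p_link``.

Ground-truth space-time risk regions ("planted clusters") relocate case (or
control) ancestors of one role/window into an ellipse and a year range, which
is what the scan engine is later asked to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    ROLES,
    WINDOWS,
    WINDOW_AGE_SPANS,
    CohortConfig,
    PlantedCluster,
)

RECORD_COLUMNS = (
    "subject_id",
    "family_id",
    "role",
    "window",
    "x",
    "y",
    "year",
    "is_case",
)

#: role -> (anchor, "parent"|"grandparent") used to lay down birth years.
_ROLE_PARENT = {
    "mother": None,
    "father": None,
    "maternal_grandmother": "mother",
    "maternal_grandfather": "mother",
    "paternal_grandmother": "father",
    "paternal_grandfather": "father",
}


@dataclass
class Cohort:
    """Generated cohort: children, ancestors, and residential records."""

    children: pd.DataFrame  # child_id, family_id, birth_year, sex, is_case
    ancestors: pd.DataFrame  # subject_id, family_id, role, birth_year, is_case
    records: pd.DataFrame  # RECORD_COLUMNS
    config: CohortConfig
    planted: tuple[PlantedCluster, ...]
    seed: int | None


def match_controls(
    case_children: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int,
) -> dict[str, list[str]]:
    """Assign exactly ``ratio`` controls per case, matched on (birth_year, sex).

    Pool members are consumed in order and never reused. Raises ``ValueError``
    naming the (birth_year, sex) stratum when the pool is insufficient.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    used = set(case_children["child_id"]) & set(pool["child_id"])
    if used:
        raise ValueError(f"pool must be disjoint from cases, shared ids: {sorted(used)[:5]}")
    by_stratum: dict[tuple[int, str], list[str]] = {}
    for row in pool.itertuples(index=False):
        by_stratum.setdefault((row.birth_year, row.sex), []).append(row.child_id)
    assignment: dict[str, list[str]] = {}
    for row in case_children.itertuples(index=False):
        key = (row.birth_year, row.sex)
        avail = by_stratum.get(key, [])
        if len(avail) < ratio:
            raise ValueError(
                f"insufficient controls for stratum (birth_year={key[0]}, sex={key[1]}): "
                f"need {ratio}, have {len(avail)}"
            )
        assignment[row.child_id] = [avail.pop(0) for _ in range(ratio)]
    return assignment


def _draw_locations(n: int, config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """n locations from p_urban * (Gaussian mixture) + (1-p_urban) * uniform.

    Urban draws falling outside the bounding box are redrawn (truncation);
    a final clip guards against pathological spread/bbox combinations.
    """
    xmin, ymin, xmax, ymax = config.bbox
    xy = np.empty((n, 2))
    urban = rng.random(n) < config.p_urban
    n_bg = int((~urban).sum())
    xy[~urban, 0] = rng.uniform(xmin, xmax, n_bg)
    xy[~urban, 1] = rng.uniform(ymin, ymax, n_bg)
    n_urb = int(urban.sum())
    if n_urb:
        centers = config.urban_centers
        w = np.array([c.weight for c in centers], dtype=float)
        w /= w.sum()
        which = rng.choice(len(centers), size=n_urb, p=w)
        mu = np.array([[c.x, c.y] for c in centers])
        sd = np.array([c.spread for c in centers])
        pts = mu[which] + rng.standard_normal((n_urb, 2)) * sd[which, None]
        inside = (
            (pts[:, 0] >= xmin) & (pts[:, 0] <= xmax)
            & (pts[:, 1] >= ymin) & (pts[:, 1] <= ymax)
        )
        for _ in range(64):
            if inside.all():
                break
            bad = ~inside
            nb = int(bad.sum())
            which_b = rng.choice(len(centers), size=nb, p=w)
            pts[bad] = mu[which_b] + rng.standard_normal((nb, 2)) * sd[which_b, None]
            inside[bad] = (
                (pts[bad, 0] >= xmin) & (pts[bad, 0] <= xmax)
                & (pts[bad, 1] >= ymin) & (pts[bad, 1] <= ymax)
            )
        pts[:, 0] = np.clip(pts[:, 0], xmin, xmax)
        pts[:, 1] = np.clip(pts[:, 1], ymin, ymax)
        xy[urban] = pts
    return xy


def sample_in_ellipse(
    n: int,
    center: tuple[float, float],
    semi_major: float,
    shape: float,
    angle: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """n points uniform on a closed ellipse (area-uniform disc mapping)."""
    r = np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    u = r * np.cos(phi) * semi_major
    v = r * np.sin(phi) * (semi_major / shape)
    ca, sa = np.cos(angle), np.sin(angle)
    return np.column_stack(
        (center[0] + u * ca - v * sa, center[1] + u * sa + v * ca)
    )


def generate_cohort(
    config: CohortConfig,
    planted: Sequence[PlantedCluster] = (),
    seed: int | None = None,
) -> Cohort:
    """Generate the full cohort; see the module docstring for the model.

    ``seed`` overrides ``config.seed``. Output is bit-identical for a fixed
    seed. Controls are generated constructively (cloning each case child's
    (birth_year, sex)), so the 2:1 exact matching can never fail.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    for p in planted:
        _validate_planted(p, config)

    n_case = config.n_case_children
    ratio = config.control_ratio
    case_by = rng.integers(config.study_start, config.study_end + 1, n_case)
    case_sex = np.where(rng.random(n_case) < config.sex_ratio_male, "M", "F")

    # children: each case followed by its matched controls (same by, sex)
    child_rows = []
    fam = 0
    for i in range(n_case):
        child_rows.append((f"C{i:06d}", f"F{fam:06d}", int(case_by[i]), case_sex[i], True))
        fam += 1
        for j in range(ratio):
            child_rows.append(
                (f"K{i:06d}_{j}", f"F{fam:06d}", int(case_by[i]), case_sex[i], False)
            )
            fam += 1
    children = pd.DataFrame(
        child_rows, columns=["child_id", "family_id", "birth_year", "sex", "is_case"]
    )
    n_children = len(children)
    child_by = children["birth_year"].to_numpy()

    # ancestor birth years: uniform integer generation gaps
    gap = lambda n: rng.integers(config.min_gen_gap, config.max_gen_gap + 1, n)
    by: dict[str, np.ndarray] = {}
    by["mother"] = child_by - gap(n_children)
    by["father"] = child_by - gap(n_children)
    for role in ROLES:
        parent = _ROLE_PARENT[role]
        if parent is not None:
            by[role] = by[parent] - gap(n_children)

    anc_rows = []
    for role in ROLES:
        for i in range(n_children):
            anc_rows.append(
                (
                    f"{children['family_id'].iat[i]}:{role}",
                    children["family_id"].iat[i],
                    role,
                    int(by[role][i]),
                    bool(children["is_case"].iat[i]),
                )
            )
    ancestors = pd.DataFrame(
        anc_rows, columns=["subject_id", "family_id", "role", "birth_year", "is_case"]
    )

    # residential records: per role, chain locations across the 3 windows
    rec_frames = []
    for role in ROLES:
        locs = _draw_locations(n_children, config, rng)
        years = {}
        xy = {}
        for w_idx, window in enumerate(WINDOWS):
            lo, hi = WINDOW_AGE_SPANS[window]
            years[window] = by[role] + rng.integers(lo, hi + 1, n_children)
            if w_idx > 0:
                stay = rng.random(n_children) < config.p_stay
                fresh = _draw_locations(n_children, config, rng)
                locs = np.where(stay[:, None], locs, fresh)
            xy[window] = locs.copy()
        for window in WINDOWS:
            linked = rng.random(n_children) < config.p_link
            df = pd.DataFrame(
                {
                    "subject_id": ancestors.loc[
                        ancestors["role"] == role, "subject_id"
                    ].to_numpy(),
                    "family_id": children["family_id"].to_numpy(),
                    "role": role,
                    "window": window,
                    "x": xy[window][:, 0],
                    "y": xy[window][:, 1],
                    "year": years[window].astype(int),
                    "is_case": children["is_case"].to_numpy(),
                }
            )
            rec_frames.append(df[linked])
    records = pd.concat(rec_frames, ignore_index=True)

    for p in planted:
        records = _apply_planted(records, p, rng)

    records = records.sort_values(
        ["role", "window", "subject_id"], kind="stable"
    ).reset_index(drop=True)
    return Cohort(
        children=children,
        ancestors=ancestors,
        records=records,
        config=config,
        planted=tuple(planted),
        seed=seed,
    )


def _validate_planted(p: PlantedCluster, config: CohortConfig) -> None:
    xmin, ymin, xmax, ymax = config.bbox
    cx, cy = p.center
    if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
        raise ValueError(f"planted cluster center {p.center} outside bounding box")


def _apply_planted(
    records: pd.DataFrame, p: PlantedCluster, rng: np.random.Generator
) -> pd.DataFrame:
    want_case = p.attract_label == "case"
    mask = (
        (records["role"] == p.target_role)
        & (records["window"] == p.target_window)
        & (records["is_case"] == want_case)
    )
    idx = records.index[mask]
    if len(idx) == 0:
        return records
    hit = idx[rng.random(len(idx)) < p.attraction]
    if len(hit) == 0:
        return records
    pts = sample_in_ellipse(len(hit), p.center, p.semi_major, p.shape, p.angle, rng)
    records = records.copy()
    records.loc[hit, "x"] = pts[:, 0]
    records.loc[hit, "y"] = pts[:, 1]
    records.loc[hit, "year"] = rng.integers(p.year_start, p.year_end + 1, len(hit))
    return records


def in_planted_cylinder(records: pd.DataFrame, p: PlantedCluster) -> np.ndarray:
    """Boolean mask over ``records`` rows: inside the planted space-time region."""
    dx = records["x"].to_numpy() - p.center[0]
    dy = records["y"].to_numpy() - p.center[1]
    ca, sa = np.cos(p.angle), np.sin(p.angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    spatial = (u / p.semi_major) ** 2 + (v / p.semi_minor) ** 2 <= 1.0 + 1e-9
    yr = records["year"].to_numpy()
    return spatial & (yr >= p.year_start) & (yr <= p.year_end)


def empirical_risk_ratio(records: pd.DataFrame, p: PlantedCluster) -> dict:
    """Inside/outside case-risk ratio of the planted cylinder, counted directly.

    Restricted to the planted (role, window) stratum; this is the ground-truth
    quantity the scan's estimated cluster RR should approximate.
    """
    stratum = records[
        (records["role"] == p.target_role) & (records["window"] == p.target_window)
    ]
    inside = in_planted_cylinder(stratum, p)
    n_in = int(inside.sum())
    n_out = int((~inside).sum())
    c_in = int(stratum.loc[inside, "is_case"].sum())
    c_out = int(stratum.loc[~inside, "is_case"].sum())
    if n_in == 0 or n_out == 0 or c_out == 0:
        ratio = float("nan")
    else:
        risk_in = c_in / n_in
        risk_out = c_out / n_out
        ratio = risk_in / risk_out
    return {
        "risk_ratio": ratio,
        "cases_inside": c_in,
        "n_inside": n_in,
        "cases_outside": c_out,
        "n_outside": n_out,
    }
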