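"""Bernoulli space-time scan statistic over elliptic cylinder windows.

The scan tests, within one ancestor stratum (role x developmental window),
whether any elliptical spatial window crossed with a calendar-year interval
contains an excess (or deficit) of case ancestors relative to the Bernoulli
null in which the C case labels are exchangeable over the N fixed
(location, year) points.

For a cylinder holding n of the N subjects and c of the C cases, the
log-likelihood ratio is

    LLR = c ln(c/n) + (n-c) ln((n-c)/n)
        + (C-c) ln((C-c)/(N-n)) + (N-n-C+c) ln((N-n-C+c)/(N-n))
        - [C ln(C/N) + (N-C) ln((N-C)/N)],          0 ln 0 := 0,

maximized over all candidate cylinders; inference is by Monte Carlo: the
maximum is recomputed under R uniform permutations of the case labels and
p = (1 + #{replicate max >= observed}) / (1 + R).

Candidate spatial windows are centered on distinct subject locations and grow
through the inter-point distances in each ellipse's metric, as in elliptic
scan statistics; secondary clusters are reported greedily down the LLR
ranking provided their ellipse does not spatially intersect a better one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import xlogy
from shapely.geometry import Polygon

from .config import ROLES, WINDOWS, ScanConfig

#: Relative slack on the ellipse boundary so that the defining boundary point
#: of a window (whose distance equals the semi-major axis) tests inside under
#: re-derived arithmetic.
_BOUNDARY_RTOL = 1e-9

#: LLR values below this are treated as exactly 0 (proportional windows).
_LLR_SNAP = 1e-10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateCylinder:
    """An elliptical spatial window crossed with an inclusive year interval."""

    center: tuple[float, float]
    semi_major: float
    shape: float
    angle: float
    year_start: int
    year_end: int

    def __post_init__(self) -> None:
        if self.shape < 1:
            raise ValueError("shape must be >= 1")
        if self.semi_major < 0:
            raise ValueError("semi_major must be >= 0")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")

    @property
    def semi_minor(self) -> float:
        return self.semi_major / self.shape

    @property
    def area_km2(self) -> float:
        return math.pi * self.semi_major * self.semi_minor / 1e6

    def polygon(self, n_segments: int = 64) -> Polygon:
        """Closed polygonal approximation of the spatial ellipse."""
        t = np.linspace(0.0, 2.0 * np.pi, n_segments, endpoint=False)
        u = self.semi_major * np.cos(t)
        v = self.semi_minor * np.sin(t)
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        xs = self.center[0] + u * ca - v * sa
        ys = self.center[1] + u * sa + v * ca
        return Polygon(np.column_stack((xs, ys)))


@dataclass
class AncestorStratum:
    """All residential records for one (role, window): the unit a scan runs on."""

    role: str
    window: str
    subject_ids: np.ndarray  # object / str
    x: np.ndarray
    y: np.ndarray
    year: np.ndarray  # int
    is_case: np.ndarray  # bool

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        for name in ("x", "y", "year", "is_case"):
            if len(getattr(self, name)) != n:
                raise ValueError("stratum arrays must share length")
        if len(np.unique(self.subject_ids)) != n:
            raise ValueError("each subject_id may appear at most once per stratum")

    @property
    def N(self) -> int:
        return len(self.subject_ids)

    @property
    def C(self) -> int:
        return int(self.is_case.sum())

    @classmethod
    def from_records(cls, records: pd.DataFrame, role: str, window: str) -> "AncestorStratum":
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        if window not in WINDOWS:
            raise ValueError(f"unknown window {window!r}")
        sub = records[(records["role"] == role) & (records["window"] == window)]
        sub = sub.sort_values("subject_id", kind="stable")
        return cls(
            role=role,
            window=window,
            subject_ids=sub["subject_id"].to_numpy(),
            x=sub["x"].to_numpy(dtype=float),
            y=sub["y"].to_numpy(dtype=float),
            year=sub["year"].to_numpy(dtype=int),
            is_case=sub["is_case"].to_numpy(dtype=bool),
        )


@dataclass
class ClusterResult:
    """A reported cluster with its counts, statistics and membership."""

    cylinder: CandidateCylinder
    c: int  # cases inside
    n: int  # subjects inside
    e: float  # expected cases n*C/N
    llr: float
    direction: str  # high | low
    rr: float  # may be math.inf when c == C
    p_mc: float
    member_ids: list[str]
    area_km2: float
    p_bonf: float | None = None
    role: str | None = None
    window: str | None = None
    cluster_id: str | None = None


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def _check_counts(c: int, n: int, C: int, N: int) -> None:
    if not (0 <= c <= n <= N):
        raise ValueError(f"require 0 <= c <= n <= N, got c={c} n={n} N={N}")
    if not (c <= C <= N):
        raise ValueError(f"require c <= C <= N, got c={c} C={C} N={N}")
    if n < 1 or N - n < 1:
        raise ValueError("require n >= 1 and N - n >= 1")
    if C - c > N - n:
        raise ValueError("more cases outside than subjects outside")


def bernoulli_llr(c: int, n: int, C: int, N: int) -> tuple[float, str]:
    """Bernoulli scan log-likelihood ratio and rate direction for one window.

    Returns ``(llr, direction)`` with llr >= 0 and direction ``"high"`` iff
    the inside case proportion strictly exceeds the outside proportion.
    """
    _check_counts(c, n, C, N)
    llr = float(
        xlogy(c, c / n)
        + xlogy(n - c, (n - c) / n)
        + xlogy(C - c, (C - c) / (N - n))
        + xlogy(N - n - C + c, (N - n - C + c) / (N - n))
        - xlogy(C, C / N)
        - xlogy(N - C, (N - C) / N)
    )
    direction = "high" if c * (N - n) > n * (C - c) else "low"
    if llr < _LLR_SNAP:  # float noise around the proportional case
        llr = 0.0
    return llr, direction


def relative_risk(c: int, n: int, C: int, N: int) -> float:
    """Estimated risk inside the window over estimated risk outside.

    rr = (c/e) / ((C-c)/(C-e)) with e = n*C/N; equals
    (c/n) / ((C-c)/(N-n)). Returns 0 when c = 0 and ``math.inf`` when c = C.
    """
    _check_counts(c, n, C, N)
    if C == 0:
        raise ValueError("no cases in stratum")
    if c == 0:
        return 0.0
    if c == C:
        return math.inf
    e = n * C / N
    return (c / e) / ((C - c) / (C - e))


def monte_carlo_pvalue(observed_llr: float, replicate_max_llrs: Sequence[float]) -> float:
    """Monte Carlo rank p-value: (1 + #{replicate >= observed}) / (1 + R)."""
    reps = np.asarray(replicate_max_llrs, dtype=float)
    if reps.size < 1:
        raise ValueError("need at least one replicate")
    return float((1 + int((reps >= observed_llr).sum())) / (1 + reps.size))


def point_in_cylinder(x: float, y: float, year: int, cyl: CandidateCylinder) -> bool:
    """Closed-boundary membership test of one record in a cylinder."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("coordinates must be finite")
    if not (cyl.year_start <= year <= cyl.year_end):
        return False
    dx, dy = x - cyl.center[0], y - cyl.center[1]
    ca, sa = math.cos(cyl.angle), math.sin(cyl.angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    if cyl.semi_major == 0:
        return u == 0 and v == 0
    return (u / cyl.semi_major) ** 2 + (v / cyl.semi_minor) ** 2 <= 1.0 + _BOUNDARY_RTOL


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------


@dataclass
class _SpatialWindow:
    members: np.ndarray  # sorted record indices
    center: tuple[float, float]
    semi_major: float
    shape: float
    angle: float


def _orientations(config: ScanConfig) -> list[tuple[float, float]]:
    pairs = []
    for s, k in zip(config.shapes, config.angles_per_shape):
        for j in range(k):
            pairs.append((float(s), math.pi * j / k))
    return pairs


def _select_centers(x: np.ndarray, y: np.ndarray, config: ScanConfig) -> np.ndarray:
    """Distinct locations, deterministically thinned to ``max_centers``."""
    pts = np.unique(np.column_stack((x, y)), axis=0)
    if config.max_centers is not None and len(pts) > config.max_centers:
        idx = np.linspace(0, len(pts) - 1, config.max_centers).round().astype(int)
        pts = pts[np.unique(idx)]
    return pts


def _spatial_windows(stratum: AncestorStratum, config: ScanConfig) -> list[_SpatialWindow]:
    """Deduplicated growing windows around every center and orientation."""
    N = stratum.N
    kmax = max(1, int(math.floor(config.max_spatial_fraction * N)))
    centers = _select_centers(stratum.x, stratum.y, config)
    windows: list[_SpatialWindow] = []
    seen: set[bytes] = set()
    x, y = stratum.x, stratum.y
    for cx, cy in centers:
        dx = x - cx
        dy = y - cy
        for s, theta in _orientations(config):
            ca, sa = math.cos(theta), math.sin(theta)
            u = dx * ca + dy * sa
            v = -dx * sa + dy * ca
            r2 = u * u + (s * v) * (s * v)  # = a^2 on the ellipse boundary
            order = np.argsort(r2, kind="stable")
            r2s = r2[order]
            # prefix sizes at distinct distance values, ties enter together
            boundaries = np.flatnonzero(np.diff(r2s) > 0) + 1
            sizes = np.append(boundaries, N)
            sizes = sizes[sizes <= kmax]
            if sizes.size == 0:
                continue
            if config.n_size_steps is not None and sizes.size > config.n_size_steps:
                pick = np.linspace(0, sizes.size - 1, config.n_size_steps)
                sizes = sizes[np.unique(pick.round().astype(int))]
            for nk in sizes:
                members = np.sort(order[:nk])
                key = members.tobytes()
                if key in seen:
                    continue
                seen.add(key)
                windows.append(
                    _SpatialWindow(
                        members=members,
                        center=(float(cx), float(cy)),
                        semi_major=float(math.sqrt(r2s[nk - 1])),
                        shape=s,
                        angle=theta,
                    )
                )
    return windows


def _time_grid(stratum: AncestorStratum, config: ScanConfig):
    """Year bins (width time_agg_years) and admissible inclusive bin intervals.

    Returns (bin_index per record, bin->year range mapping, interval list of
    (b1, b2)). Interval length in bins is capped at
    max(1, floor(max_temporal_fraction * n_bins)).
    """
    ymin = int(stratum.year.min())
    ymax = int(stratum.year.max())
    agg = config.time_agg_years
    n_bins = (ymax - ymin) // agg + 1
    bin_idx = (stratum.year - ymin) // agg
    bin_years = [
        (ymin + b * agg, min(ymin + (b + 1) * agg - 1, ymax)) for b in range(n_bins)
    ]
    lmax = max(1, int(math.floor(config.max_temporal_fraction * n_bins)))
    intervals = [
        (b1, b2)
        for b1 in range(n_bins)
        for b2 in range(b1, min(b1 + lmax, n_bins))
    ]
    return bin_idx.astype(int), bin_years, intervals


def enumerate_cylinders(
    stratum: AncestorStratum, config: ScanConfig
) -> Iterator[CandidateCylinder]:
    """Yield every candidate cylinder (deduplicated spatial windows crossed
    with every admissible year interval)."""
    if stratum.N == 0:
        raise ValueError("empty stratum")
    if stratum.N < 2:
        raise ValueError("need at least 2 records to scan")
    if len(np.unique(stratum.year)) < 2:
        raise ValueError("need at least 2 distinct years")
    windows = _spatial_windows(stratum, config)
    _, bin_years, intervals = _time_grid(stratum, config)
    for w in windows:
        for b1, b2 in intervals:
            yield CandidateCylinder(
                center=w.center,
                semi_major=w.semi_major,
                shape=w.shape,
                angle=w.angle,
                year_start=bin_years[b1][0],
                year_end=bin_years[b2][1],
            )


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


def _membership_matrix(windows: list[_SpatialWindow], N: int) -> sparse.csr_matrix:
    indptr = np.zeros(len(windows) + 1, dtype=np.int64)
    for i, w in enumerate(windows):
        indptr[i + 1] = indptr[i] + len(w.members)
    indices = np.concatenate([w.members for w in windows]) if windows else np.array([], dtype=int)
    data = np.ones(len(indices), dtype=np.float64)
    return sparse.csr_matrix((data, indices, indptr), shape=(len(windows), N))


def _interval_counts(per_bin: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    """per_bin: (W, n_bins[, B]) counts -> (W, n_intervals[, B]) prefix sums."""
    pad = np.zeros((per_bin.shape[0], 1) + per_bin.shape[2:])
    cum = np.concatenate([pad, np.cumsum(per_bin, axis=1)], axis=1)
    b1 = np.array([i[0] for i in intervals])
    b2 = np.array([i[1] for i in intervals])
    return cum[:, b2 + 1] - cum[:, b1]


def _xlogx_table(N: int) -> np.ndarray:
    """T[k] = k ln k for k = 0..N (T[0] = 0), the only primitive the LLR needs:

    LLR = T[c] + T[n-c] + T[C-c] + T[N-n-C+c] - T[n] - T[N-n]
          - (T[C] + T[N-C] - T[N]).
    """
    k = np.arange(N + 1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = k * np.log(k)
    t[0] = 0.0
    return t


class _LlrLookup:
    """LLR as a (N+1) x (C+1) table over (subjects inside, cases inside).

    The permutation null re-evaluates the LLR for every candidate under every
    replicate; with counts being small integers a precomputed table turns
    that into a single fancy-indexed gather. Validity (1 <= n <= N-1,
    c <= min(n, C), n - c <= N - C) and the rate-direction filter are baked
    in as zeros, matching ``bernoulli_llr`` exactly elsewhere.
    """

    def __init__(self, C: int, N: int, rates: str):
        T = _xlogx_table(N)
        n = np.arange(N + 1, dtype=np.int64)[:, None]
        c = np.arange(C + 1, dtype=np.int64)[None, :]
        valid = (c <= n) & (n - c <= N - C) & (n >= 1) & (n <= N - 1)
        cs = np.where(valid, c, 0)
        ns = np.where(valid, n, 1)
        llr = (
            T[cs] + T[ns - cs] + T[C - cs] + T[N - ns - C + cs]
            - T[ns] - T[N - ns]
            - (T[C] + T[N - C] - T[N])
        )
        high = cs * (N - ns) > ns * (C - cs)
        if rates == "high":
            keep = high
        elif rates == "low":
            keep = ~high
        else:
            keep = np.ones_like(high)
        self._flat = np.where(valid & keep & (llr >= _LLR_SNAP), llr, 0.0).ravel()
        self._stride = C + 1

    def base(self, n_int: np.ndarray) -> np.ndarray:
        """Precompute the n-part of the flat index (counts are exact floats)."""
        return n_int.astype(np.int64) * self._stride

    def __call__(self, base: np.ndarray, c_int: np.ndarray) -> np.ndarray:
        if c_int.ndim == base.ndim + 1:
            base = base[..., None]
        return self._flat[base + c_int.astype(np.int64)]


def select_secondary_clusters(
    candidates: Sequence[tuple[CandidateCylinder, float, int]],
    max_reported: int | None = None,
) -> list[int]:
    """Greedy non-overlapping cluster selection down the LLR ranking.

    ``candidates`` are (cylinder, llr, n) triples. Scanning in order of
    decreasing llr (ties: smaller n, then lexicographic center), a candidate
    is reported iff its spatial ellipse does not intersect the ellipse of any
    already-reported cluster; temporal overlap is allowed. Candidates with
    llr <= 0 are never reported. Returns indices in report order.
    """
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            -candidates[i][1],
            candidates[i][2],
            candidates[i][0].center,
            candidates[i][0].semi_major,
        ),
    )
    reported: list[int] = []
    polys: list[Polygon] = []
    for i in order:
        cyl, llr, _n = candidates[i]
        if llr <= 0.0:
            break
        if max_reported is not None and len(reported) >= max_reported:
            break
        poly = None
        clash = False
        for j, rep in enumerate(reported):
            rcyl = candidates[rep][0]
            d = math.hypot(
                cyl.center[0] - rcyl.center[0], cyl.center[1] - rcyl.center[1]
            )
            if d > cyl.semi_major + rcyl.semi_major:
                continue  # bounding circles disjoint
            if poly is None:
                poly = cyl.polygon()
            if polys[j].intersects(poly):
                clash = True
                break
        if clash:
            continue
        reported.append(i)
        polys.append(poly if poly is not None else cyl.polygon())
    return reported


def scan_stratum(
    stratum: AncestorStratum,
    config: ScanConfig,
    seed: int | None = None,
) -> list[ClusterResult]:
    """Scan one stratum; returns reported clusters sorted by decreasing LLR.

    The most-likely cluster is the global LLR maximizer; secondary clusters
    are added greedily down the ranking when their spatial ellipse does not
    intersect any already-reported one. Every reported cluster receives a
    Monte Carlo p-value against the permutation distribution of the maximum
    LLR (same candidate grid and rate directions).
    """
    N, C = stratum.N, stratum.C
    if C == 0 or C == N:
        raise ValueError(
            f"degenerate stratum ({stratum.role}/{stratum.window}): C={C} of N={N}"
        )
    if N < 2:
        raise ValueError("need at least 2 records to scan")
    if len(np.unique(stratum.year)) < 2:
        raise ValueError("need at least 2 distinct years")
    if seed is None:
        seed = config.seed if config.seed is not None else 0

    windows = _spatial_windows(stratum, config)
    bin_idx, bin_years, intervals = _time_grid(stratum, config)
    n_bins = len(bin_years)
    W = len(windows)
    M = _membership_matrix(windows, N)

    # per-bin column blocks of the membership matrix, reused by every replicate
    bin_members = [np.flatnonzero(bin_idx == b) for b in range(n_bins)]
    M_csc = M.tocsc()
    M_bins = [M_csc[:, idx].tocsr() for idx in bin_members]

    def per_bin_counts(label_cols: np.ndarray) -> np.ndarray:
        """label_cols: (N, B) -> counts (W, n_bins, B)."""
        B = label_cols.shape[1]
        out = np.empty((W, n_bins, B))
        for b in range(n_bins):
            out[:, b, :] = M_bins[b] @ label_cols[bin_members[b], :]
        return out

    n_per_bin = per_bin_counts(np.ones((N, 1)))[:, :, 0]
    n_int = _interval_counts(n_per_bin, intervals)

    lut = _LlrLookup(C, N, config.rates)
    lut_base = lut.base(n_int)
    labels = stratum.is_case.astype(np.float64)
    c_per_bin = per_bin_counts(labels[:, None])[:, :, 0]
    c_int = _interval_counts(c_per_bin, intervals)
    llr_obs = lut(lut_base, c_int)

    # --- greedy secondary-cluster selection on per-window best candidates ---
    # All intervals of one spatial window share its ellipse, so greedy over
    # every (window, interval) pair reduces to greedy over each window's
    # best interval.
    best_interval = np.argmax(llr_obs, axis=1) if W else np.array([], dtype=int)
    best_llr = llr_obs[np.arange(W), best_interval] if W else np.array([])
    candidates = []
    for i, w in enumerate(windows):
        b1, b2 = intervals[int(best_interval[i])]
        candidates.append(
            (
                CandidateCylinder(
                    center=w.center,
                    semi_major=w.semi_major,
                    shape=w.shape,
                    angle=w.angle,
                    year_start=bin_years[b1][0],
                    year_end=bin_years[b2][1],
                ),
                float(best_llr[i]),
                int(n_int[i, int(best_interval[i])]),
            )
        )
    reported_idx = select_secondary_clusters(candidates, config.max_reported)

    # --- Monte Carlo permutation null of the max LLR ---
    # Replicate label streams are derived from (seed, replicate index), so
    # serial and any parallel/blocked execution agree bit for bit.
    R = config.n_replicates
    rep_max = np.empty(R)
    block = max(1, min(R, int(4e6 // max(1, W * len(intervals)))))
    for start in range(0, R, block):
        stop = min(start + block, R)
        L = np.zeros((N, stop - start))
        for r in range(start, stop):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed) & 0x7FFFFFFF, r])
            )
            L[rng.permutation(N)[:C], r - start] = 1.0
        c_i = _interval_counts(per_bin_counts(L), intervals)
        llr_rep = lut(lut_base, c_i)
        rep_max[start:stop] = (
            llr_rep.max(axis=(0, 1)) if llr_rep.size else 0.0
        )

    # --- build results ---
    results: list[ClusterResult] = []
    for i in reported_idx:
        w = windows[i]
        k = int(best_interval[i])
        b1, b2 = intervals[k]
        cyl = CandidateCylinder(
            center=w.center,
            semi_major=w.semi_major,
            shape=w.shape,
            angle=w.angle,
            year_start=bin_years[b1][0],
            year_end=bin_years[b2][1],
        )
        c = int(round(c_int[i, k]))
        n = int(round(n_int[i, k]))
        # the table value is used for both the report and the p-value so that
        # ties against replicate maxima (same arithmetic path) compare exact
        llr = float(llr_obs[i, k])
        _, direction = bernoulli_llr(c, n, C, N)
        in_time = (bin_idx >= b1) & (bin_idx <= b2)
        member_mask = np.zeros(N, dtype=bool)
        member_mask[w.members] = True
        member_mask &= in_time
        results.append(
            ClusterResult(
                cylinder=cyl,
                c=c,
                n=n,
                e=n * C / N,
                llr=llr,
                direction=direction,
                rr=relative_risk(c, n, C, N),
                p_mc=monte_carlo_pvalue(llr, rep_max),
                member_ids=sorted(stratum.subject_ids[member_mask].tolist()),
                area_km2=cyl.area_km2,
                role=stratum.role,
                window=stratum.window,
            )
        )
    results.sort(key=lambda r: (-r.llr, r.n, r.cylinder.center))
    return results
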