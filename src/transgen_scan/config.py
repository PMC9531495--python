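"""Configuration dataclasses for cohort generation, scanning and full runs.

All configurations round-trip through plain dicts (and hence YAML/JSON):
``RunConfig.from_dict(cfg.to_dict()) == cfg``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: Canonical ancestor roles, in reporting order. One scan "model" is run per
#: (role, developmental window) pair, 6 x 3 = 18 models.
ROLES: tuple[str, ...] = (
    "mother",
    "father",
    "maternal_grandmother",
    "maternal_grandfather",
    "paternal_grandmother",
    "paternal_grandfather",
)

#: Vulnerable developmental windows with inclusive age spans (years).
WINDOWS: tuple[str, ...] = ("birth", "childhood", "adolescence")
WINDOW_AGE_SPANS: dict[str, tuple[int, int]] = {
    "birth": (0, 1),
    "childhood": (2, 11),
    "adolescence": (12, 17),
}

GRANDPARENT_ROLES = frozenset(r for r in ROLES if "grand" in r)


def _check_prob(name: str, p: float) -> None:
    if not (isinstance(p, (int, float)) and math.isfinite(p) and 0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {p!r}")


@dataclass(frozen=True)
class UrbanCenter:
    """A Gaussian population center: locations ~ N(center, spread^2 I)."""

    x: float
    y: float
    weight: float
    spread: float  # meters (isotropic s.d.)

    def __post_init__(self) -> None:
        if self.weight < 0 or not math.isfinite(self.weight):
            raise ValueError(f"urban center weight must be >= 0, got {self.weight}")
        if self.spread <= 0 or not math.isfinite(self.spread):
            raise ValueError(f"urban center spread must be > 0, got {self.spread}")


# An intermountain-corridor-like line of population centers in the default
# 200 km x 300 km box, plus one smaller southwestern center.
DEFAULT_URBAN_CENTERS: tuple[UrbanCenter, ...] = (
    UrbanCenter(60_000.0, 220_000.0, 0.45, 7_000.0),
    UrbanCenter(65_000.0, 180_000.0, 0.25, 6_000.0),
    UrbanCenter(70_000.0, 140_000.0, 0.20, 6_000.0),
    UrbanCenter(120_000.0, 60_000.0, 0.10, 5_000.0),
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic multigenerational case-control cohort.

    The generator emulates the statistical structure of a statewide autism
    registry cohort: case children born in a fixed study period with 2:1
    age/sex-matched controls, six ancestor roles per child, one residential
    record per ancestor per developmental window, ~90% record linkage, and
    residential persistence between consecutive windows.
    """

    n_case_children: int
    control_ratio: int = 2
    study_start: int = 1989
    study_end: int = 2014
    #: (xmin, ymin, xmax, ymax) in synthetic planar meters.
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 200_000.0, 300_000.0)
    urban_centers: tuple[UrbanCenter, ...] = DEFAULT_URBAN_CENTERS
    p_urban: float = 0.8
    p_stay: float = 0.6
    p_link: float = 0.9
    sex_ratio_male: float = 0.8
    #: Parent-child (and grandparent-parent) birth-year gap, uniform integer.
    min_gen_gap: int = 18
    max_gen_gap: int = 40
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_case_children < 1:
            raise ValueError("n_case_children must be >= 1")
        if self.control_ratio < 0:
            raise ValueError("control_ratio must be >= 0")
        if self.study_end < self.study_start:
            raise ValueError("study_end must be >= study_start")
        for name in ("p_urban", "p_stay", "p_link", "sex_ratio_male"):
            _check_prob(name, getattr(self, name))
        xmin, ymin, xmax, ymax = self.bbox
        if not (xmax > xmin and ymax > ymin) or not all(
            math.isfinite(v) for v in self.bbox
        ):
            raise ValueError(f"invalid bounding box {self.bbox}")
        if self.p_urban > 0 and not self.urban_centers:
            raise ValueError("p_urban > 0 requires at least one urban center")
        if not (15 <= self.min_gen_gap <= self.max_gen_gap):
            raise ValueError("generation gaps must satisfy 15 <= min <= max")


@dataclass(frozen=True)
class PlantedCluster:
    """Ground-truth space-time risk region used by the generator.

    With probability ``attraction`` each ancestor of the target role/window
    carrying the target label is relocated uniformly inside the ellipse and
    its record year redrawn uniformly in [year_start, year_end]. Attracting
    cases creates a high-rate cluster; attracting controls a case-depleted
    (low-rate) one. ``attraction = 0`` reduces generation to the null model.
    """

    target_role: str
    target_window: str
    center: tuple[float, float]
    semi_major: float
    year_start: int
    year_end: int
    attraction: float
    shape: float = 1.0  # semi_major / semi_minor >= 1
    angle: float = 0.0  # radians in [0, pi)
    attract_label: str = "case"

    def __post_init__(self) -> None:
        if self.target_role not in ROLES:
            raise ValueError(f"unknown role {self.target_role!r}")
        if self.target_window not in WINDOWS:
            raise ValueError(f"unknown window {self.target_window!r}")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        _check_prob("attraction", self.attraction)
        if self.semi_major <= 0:
            raise ValueError("semi_major must be > 0")
        if self.shape < 1:
            raise ValueError("shape (semi_major/semi_minor) must be >= 1")
        if not (0.0 <= self.angle < math.pi):
            raise ValueError("angle must lie in [0, pi)")
        if self.attract_label not in ("case", "control"):
            raise ValueError("attract_label must be 'case' or 'control'")

    @property
    def semi_minor(self) -> float:
        return self.semi_major / self.shape


@dataclass(frozen=True)
class ScanConfig:
    """Settings of the elliptic-cylinder Bernoulli scan.

    ``shapes`` and ``angles_per_shape`` are aligned: shape s is scanned at
    that many evenly spaced orientations in [0, pi). The spatial window grows
    around each distinct location through the inter-point distances (in the
    ellipse metric) until it would hold more than ``max_spatial_fraction`` of
    subjects; every such window is crossed with every year interval no longer
    than ``max_temporal_fraction`` of the stratum's year span.

    ``max_centers``, ``n_size_steps`` and ``time_agg_years`` thin the
    candidate grid for large strata (deterministically); the defaults keep
    the full enumeration. Monte Carlo p-values are valid for any fixed
    candidate grid, so thinning trades detection resolution, not validity.
    """

    shapes: tuple[float, ...] = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
    angles_per_shape: tuple[int, ...] = (1, 4, 6, 9, 12, 15)
    max_spatial_fraction: float = 0.5
    max_temporal_fraction: float = 0.5
    n_replicates: int = 999
    alpha: float = 0.05
    rates: str = "both"  # {high, low, both}
    seed: int | None = None
    max_centers: int | None = None
    n_size_steps: int | None = None
    time_agg_years: int = 1
    max_reported: int = 10

    def __post_init__(self) -> None:
        if len(self.shapes) != len(self.angles_per_shape):
            raise ValueError("shapes and angles_per_shape must align")
        if not self.shapes:
            raise ValueError("need at least one ellipse shape")
        for s, k in zip(self.shapes, self.angles_per_shape):
            if s < 1:
                raise ValueError("ellipse shape ratios must be >= 1")
            if k < 1:
                raise ValueError("angles_per_shape entries must be >= 1")
            if s == 1 and k != 1:
                raise ValueError("a circle (shape 1) takes exactly 1 angle")
        for name in ("max_spatial_fraction", "max_temporal_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.rates not in ("high", "low", "both"):
            raise ValueError("rates must be one of high/low/both")
        if self.time_agg_years < 1:
            raise ValueError("time_agg_years must be >= 1")
        if self.max_reported < 1:
            raise ValueError("max_reported must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full 18-model study run."""

    cohort: CohortConfig
    scan: ScanConfig = field(default_factory=ScanConfig)
    bonferroni_m: int = 18

    def __post_init__(self) -> None:
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")

    # -- dict / YAML round trip ------------------------------------------

    def to_dict(self) -> dict:
        return _as_plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cohort = dict(d["cohort"])
        cohort["bbox"] = tuple(cohort["bbox"])
        cohort["urban_centers"] = tuple(
            UrbanCenter(**uc) for uc in cohort["urban_centers"]
        )
        scan = dict(d.get("scan", {}))
        for key in ("shapes", "angles_per_shape"):
            if key in scan:
                scan[key] = tuple(scan[key])
        return cls(
            cohort=CohortConfig(**cohort),
            scan=ScanConfig(**scan),
            bonferroni_m=d.get("bonferroni_m", 18),
        )

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _as_plain(obj):
    """Tuples -> lists recursively so YAML emits plain sequences."""
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def planted_to_dict(planted: Sequence[PlantedCluster]) -> list[dict]:
    return [_as_plain(dataclasses.asdict(p)) for p in planted]


def planted_from_dict(rows: Sequence[dict]) -> tuple[PlantedCluster, ...]:
    out = []
    for row in rows:
        row = dict(row)
        row["center"] = tuple(row["center"])
        out.append(PlantedCluster(**row))
    return tuple(out)
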