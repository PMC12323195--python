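"""Area normalisation, objective 3-scale scoring, and feature vectors.

The size statistic is the normalised area ``A_norm = A_detected / A_label``:
the detected flushing pixel count divided by the pixel count of the arm
label in the same calibrated image.  Because both areas live in the same
frame, the ratio is invariant to resolution and camera distance — the
device-independence property the pipeline is built around.

``A_norm`` is quantised on an objective 3-point scale whose default
cut-points (0.1091 and 0.1598) were calibrated on the open dataset against
the manual 4-point scores: they are the midpoints between the mean
``A_norm`` of adjacent manual-score strata, with manual scores 2 and 3
merged (their mean areas are nearly identical, 0.1661 vs 0.1665).

A participant's descriptor is a 20-dimensional vector over the 4
concentrations x 5 time points, either of 3-scale scores or of raw
``A_norm`` values.  Ordering is concentration-major (0.1 M first) with time
ascending within each concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_consensus import CONCENTRATIONS_M, TIME_POINTS_MIN, BinaryMask


@dataclass(frozen=True)
class SiteGeometry:
    """Where the four niacin application sites sit in the model-input frame.

    ``site_bands`` are half-open column ranges ``(x0, x1)`` along the 512-px
    axis, one per concentration in ``concentrations`` order, pairwise
    disjoint.  The default partitions the configured application zone into
    four equal-width bands ordered by descending concentration.
    """

    concentrations: tuple[float, ...] = CONCENTRATIONS_M
    site_bands: tuple[tuple[int, int], ...] = ()
    image_width: int = 512

    def __post_init__(self) -> None:
        if not self.site_bands:
            object.__setattr__(self, "site_bands",
                               self.equal_bands(0, self.image_width))
        if len(self.site_bands) != len(self.concentrations):
            raise ValueError("need one site band per concentration")
        spans = sorted(self.site_bands)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"site bands overlap: {(a0, a1)} and {(b0, b1)}")

    @staticmethod
    def equal_bands(x0: int, x1: int, n: int = 4) -> tuple[tuple[int, int], ...]:
        edges = np.linspace(x0, x1, n + 1).round().astype(int)
        return tuple((int(edges[i]), int(edges[i + 1])) for i in range(n))

    @classmethod
    def for_zone(cls, x0: int, x1: int, image_width: int = 512) -> "SiteGeometry":
        return cls(site_bands=cls.equal_bands(x0, x1), image_width=image_width)


@dataclass(frozen=True)
class SiteMeasurement:
    """Detected area at one (concentration, time point) cell."""

    concentration: float
    time_min: int
    a_detected: int  # flushing pixels assigned to the site, calibrated frame
    a_label: int     # label pixels in the same frame

    @property
    def a_norm(self) -> float:
        return compute_a_norm(self.a_detected, self.a_label)


@dataclass(frozen=True)
class ScoreScale:
    """Cut-points of the objective 3-scale; defaults are the published ones."""

    t0: float = 0.1091
    t1: float = 0.1598

    def __post_init__(self) -> None:
        if not 0 < self.t0 < self.t1:
            raise ValueError(f"need 0 < t0 < t1, got ({self.t0}, {self.t1})")


@dataclass(frozen=True)
class ScoreDistributionStats:
    """Mean/variance/SD of ``A_norm`` per manual 4-point score stratum."""

    means: tuple[float, float, float, float]
    variances: tuple[float, float, float, float]
    sds: tuple[float, float, float, float]


@dataclass
class FeatureVector:
    """20-dimensional participant descriptor with its extraction scheme."""

    values: np.ndarray
    scheme: str  # three_scale | direct_area
    participant_id: str = ""

    SCHEMES = ("three_scale", "direct_area")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20,):
            raise ValueError(f"feature vector must have 20 entries, got {self.values.shape}")
        if self.scheme not in self.SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "three_scale" and not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("three_scale features must be scores in {0, 1, 2}")
        if (self.values < 0).any():
            raise ValueError("features must be non-negative")


#: (concentration, time) pairs in feature-vector order: concentration-major
#: (0.1 M -> 0.0001 M), time ascending (1, 5, 10, 15, 20 min).
FEATURE_ORDER: tuple[tuple[float, int], ...] = tuple(
    (c, t) for c in CONCENTRATIONS_M for t in TIME_POINTS_MIN
)


def assign_sites(flush_mask: BinaryMask, geometry: SiteGeometry
                 ) -> tuple[dict[float, int], int]:
    """Partition flushing pixels among the four concentration sites.

    Returns ``(areas, dropped)``: pixel counts per concentration plus the
    count of flushing pixels outside every site band.  The partition is by
    column band, so areas + dropped always sum to the total flushing area.
    """
    col_counts = flush_mask.pixels.sum(axis=0)
    areas: dict[float, int] = {}
    assigned = 0
    for conc, (x0, x1) in zip(geometry.concentrations, geometry.site_bands):
        a = int(col_counts[x0:x1].sum())
        areas[conc] = a
        assigned += a
    dropped = int(col_counts.sum()) - assigned
    return areas, dropped


def compute_a_norm(a_detected: float, a_label: float) -> float:
    """Normalised area ``A_detected / A_label``; the label area must be positive."""
    if a_label <= 0:
        raise ValueError(f"label area must be positive, got {a_label}")
    return a_detected / a_label


def derive_thresholds(stats: ScoreDistributionStats) -> tuple[float, float]:
    """Cut-points as midpoints between adjacent per-score mean areas.

    Manual scores 2 and 3 merge into objective score 2, so only the first
    three means are used: ``t0 = (mean0 + mean1)/2`` and
    ``t1 = (mean1 + mean2)/2``.  On the published stratum means this yields
    (0.10915, 0.1598); the published lower cut-point 0.1091 is the same
    value truncated to four decimals.
    """
    m = stats.means
    if not (m[0] < m[1] < m[2]):
        raise ValueError(f"per-score means must increase: {m}")
    return (m[0] + m[1]) / 2.0, (m[1] + m[2]) / 2.0


def score_3scale(a_norm: float, scale: ScoreScale | None = None) -> int:
    """Quantise ``A_norm``: 0 below t0, 1 in [t0, t1), 2 at or above t1."""
    scale = scale or ScoreScale()
    if a_norm < 0:
        raise ValueError(f"a_norm must be non-negative, got {a_norm}")
    if a_norm < scale.t0:
        return 0
    if a_norm < scale.t1:
        return 1
    return 2


def build_feature_vector(
    measurements: Mapping[tuple[float, int], SiteMeasurement] | Sequence[SiteMeasurement],
    scheme: str = "three_scale",
    scale: ScoreScale | None = None,
    participant_id: str = "",
) -> FeatureVector:
    """Assemble the 20-dim descriptor from a complete 4 x 5 measurement grid.

    ``measurements`` maps ``(concentration, time_min)`` to a
    :class:`SiteMeasurement` (a sequence is keyed automatically).  A missing
    cell is an error naming the (concentration, time) pair.
    """
    if not isinstance(measurements, Mapping):
        measurements = {(m.concentration, m.time_min): m for m in measurements}
    values = []
    for conc, t in FEATURE_ORDER:
        m = measurements.get((conc, t))
        if m is None:
            raise KeyError(f"missing measurement for concentration {conc} M at {t} min")
        a = m.a_norm
        values.append(float(score_3scale(a, scale)) if scheme == "three_scale" else a)
    return FeatureVector(values=np.asarray(values), scheme=scheme,
                         participant_id=participant_id)


def feature_vector_from_grid(
    a_norm_grid: np.ndarray,
    scheme: str = "three_scale",
    scale: ScoreScale | None = None,
    participant_id: str = "",
) -> FeatureVector:
    """Descriptor straight from a 4 x 5 ``A_norm`` array (concentration x time)."""
    grid = np.asarray(a_norm_grid, dtype=float)
    if grid.shape != (4, 5):
        raise ValueError(f"expected a 4x5 grid, got {grid.shape}")
    flat = grid.reshape(-1)
    if scheme == "three_scale":
        flat = np.array([score_3scale(a, scale) for a in flat], dtype=float)
    return FeatureVector(values=flat, scheme=scheme, participant_id=participant_id)


def measure_image(
    flush_mask: BinaryMask,
    label_mask: BinaryMask,
    geometry: SiteGeometry,
    time_min: int,
) -> list[SiteMeasurement]:
    """Per-site measurements for one calibrated image's predicted mask."""
    if label_mask.area_px <= 0:
        raise ValueError("label mask is empty; cannot normalise areas")
    areas, _ = assign_sites(flush_mask, geometry)
    return [
        SiteMeasurement(concentration=c, time_min=time_min,
                        a_detected=areas[c], a_label=label_mask.area_px)
        for c in geometry.concentrations
    ]
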