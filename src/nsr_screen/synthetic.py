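"""Synthetic NSR cohorts and rendered arm photographs with ground truth.

The generator emulates the statistical structure the pipeline assumes so
every stage is testable without downloading the real dataset:

* **Cohort** — 60 healthy controls plus 20 participants in each of the
  depression, bipolar and schizophrenia groups (120 participants, 5
  photographs each = 600 images).
* **Kinetics** — the true normalised flushing area follows a saturating
  exponential ``a(t) = a_max * amp(conc) * (1 - exp(-r * (t - delay)+))``
  with per-participant lognormal heterogeneity and additive Gaussian noise
  clipped at zero.  Patient groups flush more slowly (smaller rate, longer
  onset delay) and less (smaller plateau) than controls, and amplitude
  decreases with dilution, essentially vanishing at 0.0001 M.
* **Rendering** — a skin-coloured arm strip carrying a label fiducial with
  a white reference patch and four circular application sites; flushing is
  drawn as a reddened ellipse whose pixel area equals the true ``A_norm``
  times the label pixel area.  A per-photograph camera-distance scale and a
  per-participant diagonal RGB colour cast exercise the calibration steps.
  Ground-truth masks are defined before blur/cast/noise, mirroring human
  annotation of the visible erythema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .io_consensus import (
    CONCENTRATIONS_M,
    TIME_POINTS_MIN,
    BinaryMask,
    InfoRecord,
    NsrImage,
    Participant,
    write_dataset,
)
from .quantify import SiteGeometry, score_3scale


@dataclass
class CohortConfig:
    n_hc: int = 60
    n_per_disorder: int = 20
    time_points: tuple[int, ...] = TIME_POINTS_MIN
    concentrations: tuple[float, ...] = CONCENTRATIONS_M
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc <= 0 or self.n_per_disorder <= 0:
            raise ValueError("cohort counts must be positive")

    @property
    def n_participants(self) -> int:
        return self.n_hc + 3 * self.n_per_disorder


@dataclass(frozen=True)
class GroupKinetics:
    rate: float      # 1/min growth rate of the flushing area
    a_max: float     # plateau A_norm at the strongest concentration
    delay: float     # onset delay in minutes


@dataclass
class FlushKinetics:
    """Group- and concentration-dependent flushing dynamics.

    Defaults encode the qualitative clinical picture: patients' flushing
    develops more slowly and plateaus lower than controls', and the most
    dilute application (0.0001 M) barely responds.  ``subject_sd`` is the
    sd of a per-participant lognormal amplitude/rate multiplier;
    ``noise_sd`` is additive per-measurement noise in A_norm units.
    """

    groups: Mapping[str, GroupKinetics] = field(default_factory=lambda: {
        "HC": GroupKinetics(rate=0.30, a_max=0.26, delay=1.0),
        "DP": GroupKinetics(rate=0.14, a_max=0.20, delay=3.0),
        "BP": GroupKinetics(rate=0.14, a_max=0.20, delay=3.0),
        "SZ": GroupKinetics(rate=0.13, a_max=0.19, delay=3.0),
    })
    conc_amplitude: Mapping[float, float] = field(default_factory=lambda: {
        0.1: 1.0, 0.01: 0.75, 0.001: 0.45, 0.0001: 0.04,
    })
    noise_sd: float = 0.03
    subject_sd: float = 0.25

    def __post_init__(self) -> None:
        amps = [self.conc_amplitude[c] for c in sorted(self.conc_amplitude, reverse=True)]
        if any(b > a for a, b in zip(amps, amps[1:])):
            raise ValueError("amplitude must be non-increasing with dilution")

    @classmethod
    def null(cls, **kwargs) -> "FlushKinetics":
        """Identical kinetics for every group (no group effect)."""
        hc = GroupKinetics(rate=0.22, a_max=0.23, delay=2.0)
        return cls(groups={g: hc for g in ("HC", "DP", "BP", "SZ")}, **kwargs)

    @classmethod
    def noiseless(cls) -> "FlushKinetics":
        return cls(noise_sd=0.0, subject_sd=0.0)

    def mean_curve(self, group: str, concentration: float, t: float) -> float:
        g = self.groups[group]
        dt = max(t - g.delay, 0.0)
        return g.a_max * self.conc_amplitude[concentration] * (1.0 - np.exp(-g.rate * dt))


def generate_cohort(
    config: CohortConfig | None = None,
    kinetics: FlushKinetics | None = None,
) -> tuple[list[Participant], dict[str, np.ndarray]]:
    """Participants plus their true 4 x 5 ``A_norm`` grids.

    Grid rows follow ``config.concentrations`` (strongest first), columns
    ``config.time_points``.  Deterministic for a given ``config.seed``.
    """
    config = config or CohortConfig()
    kinetics = kinetics or FlushKinetics()
    rng = np.random.default_rng(config.seed)
    participants: list[Participant] = []
    grids: dict[str, np.ndarray] = {}
    roster = [("HC", config.n_hc)] + [(g, config.n_per_disorder)
                                      for g in ("DP", "BP", "SZ")]
    for group, count in roster:
        for i in range(count):
            pid = f"{group}{i + 1:03d}"
            participants.append(Participant(id=pid, group=group))
            mult = float(np.exp(rng.normal(0.0, kinetics.subject_sd))) \
                if kinetics.subject_sd > 0 else 1.0
            grid = np.empty((len(config.concentrations), len(config.time_points)))
            for r, conc in enumerate(config.concentrations):
                for c, t in enumerate(config.time_points):
                    a = mult * kinetics.mean_curve(group, conc, t)
                    if kinetics.noise_sd > 0:
                        a += rng.normal(0.0, kinetics.noise_sd)
                    grid[r, c] = max(a, 0.0)
            grids[pid] = grid
    return participants, grids


def generate_feature_table(
    config: CohortConfig | None = None,
    kinetics: FlushKinetics | None = None,
    scheme: str = "three_scale",
) -> tuple[np.ndarray, np.ndarray, list[Participant]]:
    """Feature matrix (n, 20), group labels, and participants.

    A shortcut past rendering/segmentation for classifier tests: features
    come straight from the true ``A_norm`` grids, quantised for the
    ``three_scale`` scheme or used directly for ``direct_area``.
    """
    participants, grids = generate_cohort(config, kinetics)
    rows = []
    for p in participants:
        flat = grids[p.id].reshape(-1)
        if scheme == "three_scale":
            flat = np.array([score_3scale(a) for a in flat], dtype=float)
        elif scheme != "direct_area":
            raise ValueError(f"unknown scheme {scheme!r}")
        rows.append(flat)
    X = np.vstack(rows)
    y = np.array([p.group for p in participants])
    return X, y, participants


# --------------------------------------------------------------------------
# rendering


@dataclass
class RenderConfig:
    """Geometry and photometry of the rendered arm strip (base scale)."""

    base_hw: tuple[int, int] = (160, 640)
    label_rect: tuple[int, int, int, int] = (20, 60, 10, 106)   # r0, r1, c0, c1
    white_rect: tuple[int, int, int, int] = (24, 56, 58, 102)   # inside the label
    site_centers_x: tuple[int, ...] = (192, 320, 448, 576)
    site_center_y: int = 104
    site_radius: int = 24
    skin_rgb: tuple[int, int, int] = (205, 170, 150)
    flush_rgb: tuple[int, int, int] = (204, 88, 88)
    label_gray: int = 120
    cast_range: tuple[float, float] = (0.7, 1.3)
    distance_range: tuple[float, float] = (0.8, 1.25)
    blur_sd: float = 0.8
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.white_rect
        lr0, lr1, lc0, lc1 = self.label_rect
        if not (lr0 <= r0 < r1 <= lr1 and lc0 <= c0 < c1 <= lc1):
            raise ValueError("white patch must lie inside the label")
        xs = sorted(self.site_centers_x)
        for a, b in zip(xs, xs[1:]):
            if b - a < 2 * self.site_radius:
                raise ValueError("application sites overlap")

    @property
    def label_area_px(self) -> int:
        r0, r1, c0, c1 = self.label_rect
        return (r1 - r0) * (c1 - c0)

    def site_geometry(self, model_hw: tuple[int, int] = (128, 512)) -> SiteGeometry:
        """Site bands in the model-input frame matching this layout."""
        _, w = self.base_hw
        zone_start = self.label_rect[3]  # application zone right of the label
        sx = model_hw[1] / w
        return SiteGeometry.for_zone(int(round(zone_start * sx)), model_hw[1],
                                     image_width=model_hw[1])


def render_image(
    participant: Participant,
    time_min: int,
    a_norm_row: Mapping[float, float],
    render: RenderConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[NsrImage, BinaryMask, BinaryMask]:
    """One photograph plus its ground-truth flushing and label masks.

    ``a_norm_row`` maps each concentration to the true ``A_norm`` at this
    time point; each site's flushing ellipse is rasterised to that fraction
    of the label's pixel area.  A camera-distance scale, a device colour
    cast, blur and pixel noise are applied to the image only.
    """
    render = render or RenderConfig()
    rng = rng or np.random.default_rng(render.seed)
    d = rng.uniform(*render.distance_range)
    H = int(round(render.base_hw[0] * d))
    W = int(round(render.base_hw[1] * d))

    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = render.skin_rgb
    # gentle vertical shading so the skin is not perfectly uniform
    img *= (0.95 + 0.1 * np.linspace(0, 1, H))[:, None, None]

    def scaled_rect(rect):
        r0, r1, c0, c1 = (int(round(v * d)) for v in rect)
        return r0, max(r1, r0 + 1), c0, max(c1, c0 + 1)

    lr0, lr1, lc0, lc1 = scaled_rect(render.label_rect)
    wr0, wr1, wc0, wc1 = scaled_rect(render.white_rect)
    img[lr0:lr1, lc0:lc1] = render.label_gray
    img[wr0:wr1, wc0:wc1] = 255.0
    label_mask = np.zeros((H, W), dtype=bool)
    label_mask[lr0:lr1, lc0:lc1] = True
    label_area = int(label_mask.sum())

    flush_mask = np.zeros((H, W), dtype=bool)
    for conc, cx in zip(sorted(a_norm_row, reverse=True), render.site_centers_x):
        a_norm = float(a_norm_row[conc])
        if a_norm <= 0:
            continue
        target_px = a_norm * label_area
        ratio = rng.uniform(0.75, 1.0)  # minor/major ellipse axis ratio
        major = np.sqrt(target_px / (np.pi * ratio))
        minor = ratio * major
        band_half = (render.site_centers_x[1] - render.site_centers_x[0]) / 2 * d
        if major > band_half:  # would spill into the neighbouring site band
            warnings.warn(
                f"flushing area at {conc} M exceeds its site region; clipping",
                stacklevel=2,
            )
            major = band_half
            minor = min(minor, band_half)
        cy = render.site_center_y * d
        rr, cc = draw_ellipse(cy, cx * d, major, minor, shape=(H, W))
        flush_mask[rr, cc] = True

    # paint flushing with a soft edge; ground truth stays the sharp ellipse
    soft = gaussian_filter(flush_mask.astype(np.float64), 1.0)[..., None]
    img = img * (1 - soft) + np.asarray(render.flush_rgb, dtype=np.float64) * soft

    # relative channel gains; normalised below 1 so the white patch never
    # saturates (a real sensor keeps the brightest surface in range)
    cast = rng.uniform(*render.cast_range, size=3)
    cast = cast / cast.max() * rng.uniform(0.85, 1.0)
    img = img * cast
    if render.blur_sd > 0:
        img = gaussian_filter(img, (render.blur_sd, render.blur_sd, 0))
    if render.noise_sd > 0:
        img = img + rng.normal(0, render.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    image = NsrImage(pixels=img, participant_id=participant.id, time_min=time_min)
    return (image, BinaryMask(pixels=flush_mask, kind="flush"),
            BinaryMask(pixels=label_mask, kind="label"))


def _manual_score(a_norm: float) -> int:
    """Synthetic stand-in for the human 4-point score: the objective scale
    with 'erythema beyond the patch area' approximated by a high cut."""
    if a_norm >= 0.22:
        return 3
    return score_3scale(a_norm)


def generate_image_dataset(
    config: CohortConfig | None = None,
    kinetics: FlushKinetics | None = None,
    render: RenderConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[NsrImage], list[BinaryMask], list[BinaryMask], list[InfoRecord],
           list[Participant]]:
    """Render the full cohort; optionally write it in the standard layout.

    Returns (images, flush_masks, label_masks, info_records, participants);
    with the default configuration that is 600 images from 120 participants.
    Fully deterministic: every photograph's randomness derives from
    ``(render.seed, participant index, time index)``.
    """
    config = config or CohortConfig()
    kinetics = kinetics or FlushKinetics()
    render = render or RenderConfig()
    participants, grids = generate_cohort(config, kinetics)
    images: list[NsrImage] = []
    flush_masks: list[BinaryMask] = []
    label_masks: list[BinaryMask] = []
    records: list[InfoRecord] = []
    for pi, p in enumerate(participants):
        grid = grids[p.id]
        for ti, t in enumerate(config.time_points):
            row = {c: grid[ci, ti] for ci, c in enumerate(config.concentrations)}
            rng = np.random.default_rng((render.seed, pi, ti))
            img, flush, label = render_image(p, t, row, render, rng)
            images.append(img)
            flush_masks.append(flush)
            label_masks.append(label)
            records.append(InfoRecord(
                participant_id=p.id, group=p.group, time_min=t,
                manual_scores={c: _manual_score(row[c]) for c in config.concentrations},
            ))
    if out_dir is not None:
        write_dataset(images, flush_masks, records, out_dir, label_masks=label_masks)
    return images, flush_masks, label_masks, records, participants
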