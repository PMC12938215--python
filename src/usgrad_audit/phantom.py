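"""Synthetic sector-scan B-mode phantoms with exact ground-truth masks.

Real endobronchial ultrasound (EBUS) recordings of mediastinal and hilar
lymph-node stations are not publicly available, so this module emulates
their salient content: a fan-shaped sector footprint with the transducer
apex at the top-center, multiplicative speckle over a smooth background,
hypoechoic (darker-than-background) elliptical lymph nodes, anechoic
(near-black) circular vessels, bright near-field tissue bands, and the two
classic artifacts (distal acoustic shadowing and periodic reverberation).
Every synthesized structure is rasterized analytically, so each frame
carries pixel-exact binary masks for the four annotation categories.

Eight station classes (4L, 4R, 7L, 7R, 10L, 10R, 11L, 11R) are told apart
by where their structures sit in sector coordinates: paired left/right
stations mirror each other in azimuth, while the 4/7/10/11 levels differ in
node depth, node multiplicity and vessel placement — a cartoon of the
anatomical landmarks bronchoscopists use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

#: Fixed station/class order used everywhere in the package.
STATIONS = ("4L", "4R", "7L", "7R", "10L", "10R", "11L", "11R")

MASK_CATEGORIES = ("lymph_node", "vessel", "artifact", "other_structure")


@dataclass(frozen=True)
class StationTemplate:
    """Layout prior for one station in sector coordinates.

    Azimuth is expressed as a fraction of the sector half-width in [-1, 1]
    (negative = probe-left), radius as a fraction of the radial depth.
    """

    station: str
    node_count_range: tuple[int, int]
    node_radius_frac: tuple[float, float]
    node_angle_frac: tuple[float, float]
    node_scale: float = 1.0
    vessel_radius_frac: float = 0.45
    vessel_angle_frac: float = 0.35
    vessel_scale: float = 1.0


def _mirror(t: StationTemplate, station: str) -> StationTemplate:
    return replace(
        t,
        station=station,
        node_angle_frac=(-t.node_angle_frac[1], -t.node_angle_frac[0]),
        vessel_angle_frac=-t.vessel_angle_frac,
    )


_4L = StationTemplate(
    "4L", node_count_range=(1, 2), node_radius_frac=(0.22, 0.42),
    node_angle_frac=(-0.75, -0.35), node_scale=1.0,
    vessel_radius_frac=0.40, vessel_angle_frac=0.40, vessel_scale=1.3,
)
_7L = StationTemplate(
    "7L", node_count_range=(1, 1), node_radius_frac=(0.58, 0.80),
    node_angle_frac=(-0.45, -0.10), node_scale=1.6,
    vessel_radius_frac=0.25, vessel_angle_frac=0.55, vessel_scale=0.7,
)
_10L = StationTemplate(
    "10L", node_count_range=(1, 2), node_radius_frac=(0.40, 0.58),
    node_angle_frac=(-0.90, -0.55), node_scale=1.0,
    vessel_radius_frac=0.65, vessel_angle_frac=-0.15, vessel_scale=1.1,
)
_11L = StationTemplate(
    "11L", node_count_range=(2, 3), node_radius_frac=(0.50, 0.75),
    node_angle_frac=(-0.60, -0.15), node_scale=0.7,
    vessel_radius_frac=0.50, vessel_angle_frac=0.60, vessel_scale=0.8,
)

STATION_TEMPLATES: dict[str, StationTemplate] = {
    "4L": _4L, "4R": _mirror(_4L, "4R"),
    "7L": _7L, "7R": _mirror(_7L, "7R"),
    "10L": _10L, "10R": _mirror(_10L, "10R"),
    "11L": _11L, "11R": _mirror(_11L, "11R"),
}


@dataclass(frozen=True)
class SectorGeometry:
    """Fan geometry: apex at top-center, row 0 is proximal."""

    apex_row: float = 0.01
    apex_col: float = 0.5
    angular_width: float = 70.0   # degrees
    radial_depth: float = 0.92    # fraction of image size
    near_field: float = 0.05      # fraction of image size


@dataclass(frozen=True)
class SpeckleConfig:
    mean_intensity: float = 0.40
    noise_scale: float = 0.35     # relative std of the multiplicative field


@dataclass(frozen=True)
class PhantomConfig:
    """Everything needed to synthesize a dataset deterministically.

    `node_count_range`/`vessel_prob` of None defer to the station template;
    explicit values override it globally (e.g. ``(0, 0)`` and ``0.0`` yield
    structureless pure-speckle sectors).
    """

    image_size: int = 224
    sector: SectorGeometry = field(default_factory=SectorGeometry)
    speckle: SpeckleConfig = field(default_factory=SpeckleConfig)
    node_count_range: Optional[tuple[int, int]] = None
    node_axis_px: tuple[float, float] = (26.0, 16.0)  # full axis lengths at the configured size
    node_axis_jitter: float = 0.25
    node_contrast: float = 0.35
    vessel_prob: Optional[float] = None
    vessel_radius_px: float = 11.0
    artifact_prob: float = 0.30
    other_structure_prob: float = 0.40
    quality_score_range: tuple[float, float] = (0.20, 1.00)
    quality_floor: float = 0.30
    n_patients: int = 10
    frames_per_patient: int = 40
    seed: int = 0

    @classmethod
    def easy(cls, **overrides) -> "PhantomConfig":
        """Well-separated study conditions: every frame of interpretable
        quality, fewer artifacts, less node-size jitter. Used for runs whose
        point is the audit workflow rather than classifier robustness."""
        base = dict(quality_score_range=(0.5, 1.0), artifact_prob=0.15,
                    node_axis_jitter=0.15)
        base.update(overrides)
        return cls(**base)

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0.0 < self.sector.angular_width <= 180.0:
            raise ValueError("angular_width must lie in (0, 180] degrees")
        for name, p in [("artifact_prob", self.artifact_prob),
                        ("other_structure_prob", self.other_structure_prob)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.vessel_prob is not None and not 0.0 <= self.vessel_prob <= 1.0:
            raise ValueError("vessel_prob must lie in [0, 1]")
        lo, hi = self.quality_score_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("quality_score_range must be within [0, 1]")
        if self.n_patients < 3:
            raise ValueError("n_patients must be >= 3 for a patient-wise 70/20/10 split")


@dataclass
class PhantomFrame:
    """One synthetic frame: image in [0,1] plus per-category binary masks."""

    image: np.ndarray
    masks: dict[str, np.ndarray]
    station: str
    patient_id: str
    quality: float
    frame_id: str = ""

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            if m.shape != self.image.shape:
                raise ValueError(f"mask '{name}' shape {m.shape} != image shape {self.image.shape}")


# ---------------------------------------------------------------------------
# geometry helpers

def _sector_coords(size: int, geom: SectorGeometry):
    """Per-pixel (radius, azimuth) about the apex, plus the sector footprint."""
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dy = rows - geom.apex_row * size
    dx = cols - geom.apex_col * size
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dx, dy))  # 0 = straight down, +right
    depth = geom.radial_depth * size
    half = geom.angular_width / 2.0
    footprint = (r >= geom.near_field * size) & (r <= depth) & (np.abs(theta) <= half)
    return r, theta, footprint, depth, half


def _polar_to_xy(size: int, geom: SectorGeometry, radius_frac: float, angle_frac: float):
    depth = geom.radial_depth * size
    half = geom.angular_width / 2.0
    r = radius_frac * depth
    th = np.radians(angle_frac * half)
    row = geom.apex_row * size + r * np.cos(th)
    col = geom.apex_col * size + r * np.sin(th)
    return row, col


def _ellipse_mask(size: int, center_rc: tuple[float, float], axes: tuple[float, float],
                  rotation_deg: float) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dy = rows - center_rc[0]
    dx = cols - center_rc[1]
    phi = np.radians(rotation_deg)
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    a, b = axes[0] / 2.0, axes[1] / 2.0
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disc_mask(size: int, center_rc: tuple[float, float], radius: float) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    return (rows - center_rc[0]) ** 2 + (cols - center_rc[1]) ** 2 <= radius ** 2


# ---------------------------------------------------------------------------
# frame synthesis

def generate_frame(config: PhantomConfig, station: str, patient_id: str,
                   rng: np.random.Generator) -> PhantomFrame:
    """Synthesize one frame for `station` with pixel-exact structure masks.

    Structures modulate a smooth echogenicity map (nodes darken, vessels
    nearly null, near-field tissue bands brighten), speckle multiplies it,
    and artifacts (shadow wedge, reverberation arcs) act on the final
    intensities. Frames whose sampled quality falls below the
    interpretability floor are additionally blurred and contrast-compressed.
    """
    if station not in STATION_TEMPLATES:
        raise ValueError(
            f"unknown station {station!r}; valid stations are {', '.join(STATIONS)}"
        )
    tpl = STATION_TEMPLATES[station]
    size = config.image_size
    geom = config.sector
    r, theta, footprint, depth, half = _sector_coords(size, geom)

    quality = float(rng.uniform(*config.quality_score_range))

    # echogenicity map: mild depth-dependent attenuation of a uniform background
    echo = config.speckle.mean_intensity * (1.15 - 0.30 * np.clip(r / depth, 0, 1))

    masks = {k: np.zeros((size, size), dtype=bool) for k in MASK_CATEGORIES}

    # --- lymph nodes ------------------------------------------------------
    lo, hi = (config.node_count_range if config.node_count_range is not None
              else tpl.node_count_range)
    n_nodes = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    node_extents = []  # (theta_lo, theta_hi, r_far) for shadow placement
    for _ in range(n_nodes):
        rf = rng.uniform(*tpl.node_radius_frac)
        af = rng.uniform(*tpl.node_angle_frac)
        center = _polar_to_xy(size, geom, rf, af)
        jit = config.node_axis_jitter
        a = config.node_axis_px[0] * tpl.node_scale * (1 + rng.uniform(-jit, jit))
        b = config.node_axis_px[1] * tpl.node_scale * (1 + rng.uniform(-jit, jit))
        rot = rng.uniform(0, 180)
        ell = _ellipse_mask(size, center, (a, b), rot) & footprint
        echo[ell] *= config.node_contrast
        masks["lymph_node"] |= ell
        node_extents.append((af * half - 6, af * half + 6, rf * depth + a / 2))

    # --- vessel -----------------------------------------------------------
    vp = config.vessel_prob if config.vessel_prob is not None else 1.0
    if rng.uniform() < vp:
        center = _polar_to_xy(size, geom, tpl.vessel_radius_frac + rng.uniform(-0.05, 0.05),
                              tpl.vessel_angle_frac + rng.uniform(-0.08, 0.08))
        radius = config.vessel_radius_px * tpl.vessel_scale * (size / 224.0) * rng.uniform(0.85, 1.15)
        disc = _disc_mask(size, center, radius) & footprint
        echo[disc] *= 0.05
        masks["vessel"] |= disc

    # --- other structure: bright near-field tissue band -------------------
    if rng.uniform() < config.other_structure_prob:
        band_r = rng.uniform(0.10, 0.20) * depth
        band_w = rng.uniform(0.03, 0.06) * depth
        side = rng.choice([-1.0, 1.0])
        band = (np.abs(r - band_r) <= band_w) & (theta * side > 0) & footprint
        echo[band] *= 1.9
        masks["other_structure"] |= band

    # --- speckle ----------------------------------------------------------
    ns = max(config.speckle.noise_scale, 1e-6)
    shape_k = 1.0 / ns ** 2
    field_ = rng.gamma(shape_k, 1.0 / shape_k, size=(size, size))
    field_ = ndimage.gaussian_filter(field_, 0.6)
    img = echo * field_

    # --- artifacts --------------------------------------------------------
    if rng.uniform() < config.artifact_prob:
        if node_extents and rng.uniform() < 0.5:
            # acoustic shadow distal to a node
            th_lo, th_hi, r_far = node_extents[int(rng.integers(len(node_extents)))]
            wedge = (theta >= th_lo) & (theta <= th_hi) & (r > r_far) & footprint
            img[wedge] *= 0.18
            masks["artifact"] |= wedge
        else:
            # reverberation: periodic bright arcs below the near field
            r0 = rng.uniform(0.25, 0.45) * depth
            spacing = rng.uniform(0.10, 0.16) * depth
            th_c = rng.uniform(-0.5, 0.5) * half
            arc_mask = np.zeros_like(footprint)
            for n in range(3):
                rn = r0 + n * spacing
                arc = (np.abs(r - rn) <= 2.2) & (np.abs(theta - th_c) <= half * 0.45) & footprint
                img[arc] += 0.45 * (0.8 ** n)
                arc_mask |= arc
            masks["artifact"] |= arc_mask

    img = np.clip(img, 0.0, 1.0)
    img[~footprint] = 0.0
    for k in masks:
        masks[k] &= footprint

    if quality < config.quality_floor:
        img = ndimage.gaussian_filter(img, 2.5)
        img = np.clip(img.mean() + 0.45 * (img - img.mean()), 0.0, 1.0)
        img[~footprint] = 0.0

    return PhantomFrame(image=img.astype(np.float64), masks=masks, station=station,
                        patient_id=str(patient_id), quality=quality)


def generate_dataset(config: PhantomConfig) -> tuple[list[PhantomFrame], pd.DataFrame]:
    """Generate `n_patients x frames_per_patient` frames plus a manifest.

    Stations cycle within each patient (offset by patient index) so every
    patient contributes frames from every station once
    ``frames_per_patient >= 8``, and every station is represented overall.
    The manifest lists the relative paths `save_dataset` would write.
    """
    total = config.n_patients * config.frames_per_patient
    if total < len(STATIONS):
        raise ValueError(
            f"{config.n_patients} patients x {config.frames_per_patient} frames "
            f"= {total} frames cannot cover all {len(STATIONS)} stations"
        )
    rng = np.random.default_rng(config.seed)
    frames: list[PhantomFrame] = []
    rows = []
    for p in range(config.n_patients):
        patient_id = f"p{p:03d}"
        for i in range(config.frames_per_patient):
            station = STATIONS[(i + p) % len(STATIONS)]
            frame = generate_frame(config, station, patient_id, rng)
            frame.frame_id = f"{patient_id}_f{i:04d}"
            frames.append(frame)
            rows.append({
                "image": f"images/{frame.frame_id}.png",
                "mask_lymph_node": f"masks/{frame.frame_id}_lymph_node.png",
                "mask_vessel": f"masks/{frame.frame_id}_vessel.png",
                "mask_artifact": f"masks/{frame.frame_id}_artifact.png",
                "mask_other": f"masks/{frame.frame_id}_other.png",
                "station": station,
                "patient_id": patient_id,
                "quality": round(frame.quality, 6),
            })
    manifest = pd.DataFrame(rows)
    return frames, manifest
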