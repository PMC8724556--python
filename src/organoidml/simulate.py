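"""Synthetic brightfield plate simulator with per-organoid ground truth.

Generates plates that emulate the assay's phenotypes: dark textured
organoids (tens to hundreds of micrometres) on a brighter noisy
background; *live* organoids smooth, with a darker rim and a brighter
lumen, growing slowly; *dead* organoids with harmonically perturbed
(irregular) boundaries, granular interiors and a modest post-mortem
spread.  Death follows an exponential waiting time whose hazard rises
with dose through a Hill curve, so kill kinetics are both dose- and
time-dependent.  A fluorescence channel renders nucleus-sized
vital-dye-positive spots inside dead organoids, each of which can be lost
at later timepoints with a configurable probability — reproducing the
transient-dye failure mode that makes dye-based dead counts fall behind
over time.

Everything is reproducible from the config seed; per-well and
per-organoid substreams make results independent of iteration order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .errors import OrganoidMLError, ValidationError
from .imaging import (
    BRIGHTFIELD,
    FLUORESCENCE,
    Image2D,
    ImageStack,
    PlateLayout,
    RunConfig,
)
from .segmentation import BACKGROUND, ORGANOID, OrganoidROI, Stroke

LIVE = "live"
DEAD = "dead"

# upper bound on the boundary-perturbation factor of dead organoids; the
# placement step reserves this much extra radius so perturbed footprints
# never cross the minimum gap or the field border
BOUNDARY_PERT_MAX = 1.25


class PlacementError(OrganoidMLError):
    """Organoids could not be packed into the field at the requested density."""


@dataclass
class WellSpec:
    well: str
    pdo: str = "PDO-SIM"
    treatment: str = "media"
    dose: float = 0.0
    unit: str = "uM"
    group: str = "media"
    control: str = "negative"  # negative | positive | treated


def make_wells(
    conditions: list[tuple[str, float, str]],
    n_replicates: int = 3,
    pdo: str = "PDO-SIM",
) -> list[WellSpec]:
    """Build replicate wells from (treatment, dose, control-flag) conditions."""
    wells = []
    for i, (treatment, dose, control) in enumerate(conditions):
        for r in range(n_replicates):
            row = chr(ord("A") + i)
            wells.append(
                WellSpec(
                    well=f"{row}{r + 1}",
                    pdo=pdo,
                    treatment=treatment,
                    dose=dose,
                    unit="uM",
                    group=f"{treatment}_{dose:g}",
                    control=control,
                )
            )
    return wells


def _default_wells() -> list[WellSpec]:
    return make_wells(
        [
            ("media", 0.0, "negative"),
            ("staurosporine", 5.0, "positive"),
            ("irinotecan", 10.0, "treated"),
            ("irinotecan", 40.0, "treated"),
        ]
    )


@dataclass
class SimConfig:
    """Study conditions of the simulated assay.

    Geometry mirrors the imaging protocol (days 0/1/3/7; ~1 mm field);
    organoid sizes span the assay's 30–300 um diameter range (lognormal
    radii, median 28 um).  Kill kinetics: hazard/day = baseline +
    h_max * dose^gamma / (dose^gamma + ec50^gamma); positive-control wells
    are saturated at baseline + h_max regardless of dose.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 2.0
    days: tuple[float, ...] = (0, 1, 3, 7)
    wells: list[WellSpec] = field(default_factory=_default_wells)
    n_organoids: tuple[int, int] = (30, 38)  # uniform inclusive range per well
    # radii (um)
    radius_um_median: float = 26.0
    radius_um_sigma: float = 0.22
    radius_um_min: float = 22.0
    radius_um_max: float = 70.0
    growth_um_per_day: float = 1.5
    dead_spread_factor: float = 1.12
    # brightfield rendering
    background: float = 1000.0
    bg_noise_sd: float = 8.0
    contrast: float = 300.0
    live_base_attenuation: float = 0.35
    live_rim_gain: float = 0.20
    live_lumen_depth: float = 0.55
    live_texture_sd: float = 0.04  # x contrast, smooth residual texture
    dead_base_attenuation: float = 0.55
    dead_granule_sd: float = 0.35  # x contrast, granular speckle
    dead_boundary_amp: float = 0.05  # per-harmonic boundary perturbation
    phenotype_jitter: float = 0.35  # per-organoid spread of texture params
    # kinetics
    h_max: float = 0.4
    ec50: float = 10.0
    hill_gamma: float = 1.0
    baseline_hazard: float = 0.0
    # vital dye
    spots_per_dead: float = 4.0
    spot_area_um2_mean: float = 110.0  # ~12 um nucleus; clears the 65 um^2
    spot_area_sigma: float = 0.25  # call floor even after 2 um/px rasterization
    dye_loss_prob: float = 0.3
    fluor_background: float = 50.0
    fluor_noise_sd: float = 5.0
    fluor_spot_intensity: float = 1000.0
    # placement
    min_gap_um: float = 10.0
    border_fraction: float = 0.0  # fraction deliberately overlapping the border
    max_placement_tries: int = 2000
    n_z: int = 3
    seed: int = 0

    def hazard(self, dose: float, control: str = "treated") -> float:
        if control == "positive":
            return self.baseline_hazard + self.h_max
        if control == "negative" or dose == 0:
            return self.baseline_hazard
        d = dose**self.hill_gamma
        return self.baseline_hazard + self.h_max * d / (d + self.ec50**self.hill_gamma)


@dataclass
class SimOrganoid:
    organoid_id: int
    well: str
    cy_um: float
    cx_um: float
    r0_um: float
    death_time_days: float  # inf = never dies
    boundary_amps: np.ndarray
    boundary_phases: np.ndarray
    spot_offsets_um: np.ndarray  # (n_spots, 2) relative to center
    spot_radii_um: np.ndarray
    touches_border: bool = False
    # per-organoid phenotype jitter (multiplicative, ~1)
    tex_gain: float = 1.0
    gran_gain: float = 1.0
    rim_gain: float = 1.0
    atten_gain: float = 1.0
    lumen_gain: float = 1.0

    def status(self, day: float) -> str:
        return DEAD if self.death_time_days <= day else LIVE

    def radius(self, day: float, cfg: SimConfig) -> float:
        if self.status(day) == LIVE:
            return min(self.r0_um + cfg.growth_um_per_day * day, cfg.radius_um_max)
        r_at_death = min(
            self.r0_um + cfg.growth_um_per_day * self.death_time_days, cfg.radius_um_max
        )
        return r_at_death * cfg.dead_spread_factor


@dataclass
class SimulatedPlate:
    """In-memory plate: images, fluorescence, ground truth and layout."""

    config: SimConfig
    organoids: dict  # well -> list[SimOrganoid]
    images: dict  # (well, day) -> Image2D (brightfield projection)
    fluorescence: dict  # (well, day) -> Image2D
    truth: pd.DataFrame
    layout: PlateLayout

    def live_fraction(self, well: str, day: float) -> float:
        sub = self.truth[(self.truth["well"] == well) & (self.truth["day"] == day)]
        return float((sub["status"] == LIVE).mean())

    def stack(self, well: str, day: float) -> ImageStack:
        """Brightfield z-stack whose maximum projection is the rendered scene.

        Plane 0 carries the scene; deeper planes are the scene minus a
        nonnegative random dimming, so the per-pixel maximum reconstructs
        the scene exactly while still exercising the projection step.
        """
        cfg = self.config
        scene = self.images[(well, day)].pixels
        widx = [w.well for w in cfg.wells].index(well)
        didx = list(cfg.days).index(day)
        rng = np.random.default_rng([cfg.seed % (2**31), widx, didx, 97])
        planes = [scene]
        for _ in range(cfg.n_z - 1):
            planes.append(np.clip(scene - np.abs(rng.normal(20.0, 10.0, scene.shape)), 0, None))
        return ImageStack(
            planes=np.stack(planes),
            pixel_size_um=cfg.pixel_size_um,
            z_start_um=20.0,
            z_step_um=20.0,
            channel=BRIGHTFIELD,
            well=well,
            timepoint_day=day,
        )


def _draw_radius(rng: np.random.Generator, cfg: SimConfig) -> float:
    r = rng.lognormal(np.log(cfg.radius_um_median), cfg.radius_um_sigma)
    return float(np.clip(r, cfg.radius_um_min, cfg.radius_um_max))


def _draw_phenotype(rng: np.random.Generator, cfg: SimConfig) -> dict:
    """Per-organoid texture/morphology variability.

    Live organoids vary widely in how much residual texture and how
    pronounced a lumen they show; dead organoids vary in granule strength.
    This overlap is what forces the classifier to combine several features
    rather than lean on a single perfectly separating one.
    """
    j = cfg.phenotype_jitter
    return {
        "tex_gain": float(rng.uniform(1.0 - j, 1.0 + 3.5 * j)),
        "gran_gain": float(rng.uniform(1.0 - 1.6 * j, 1.0 + j)),
        "rim_gain": float(rng.uniform(0.1, 1.9)),
        "atten_gain": float(rng.uniform(0.85, 1.15)),
        "lumen_gain": float(rng.uniform(0.1, 1.45)),
    }


def _place_organoids(
    rng: np.random.Generator, cfg: SimConfig, well: str, hazard: float, id_offset: int
) -> list[SimOrganoid]:
    H_um = cfg.shape[0] * cfg.pixel_size_um
    W_um = cfg.shape[1] * cfg.pixel_size_um
    n = int(rng.integers(cfg.n_organoids[0], cfg.n_organoids[1] + 1))
    n_border = int(round(cfg.border_fraction * n))
    organoids: list[SimOrganoid] = []
    max_day = max(cfg.days)
    # largest first: greatly improves rejection-sampling packing success
    radii = sorted((_draw_radius(rng, cfg) for _ in range(n)), reverse=True)
    for i, r0 in enumerate(radii):
        r_max = (
            min(r0 + cfg.growth_um_per_day * max_day, cfg.radius_um_max)
            * cfg.dead_spread_factor
            * BOUNDARY_PERT_MAX
        )
        on_border = i < n_border
        placed = False
        for _ in range(cfg.max_placement_tries):
            if on_border:
                # center within one radius of an edge so the mask overlaps it
                edge = rng.integers(0, 4)
                along = rng.uniform(r_max, (W_um if edge < 2 else H_um) - r_max)
                off = rng.uniform(-0.5 * r_max, 0.5 * r_max)
                if edge == 0:
                    cy, cx = off, along
                elif edge == 1:
                    cy, cx = H_um - off, along
                elif edge == 2:
                    cy, cx = along, off
                else:
                    cy, cx = along, W_um - off
            else:
                cy = rng.uniform(r_max + cfg.min_gap_um, H_um - r_max - cfg.min_gap_um)
                cx = rng.uniform(r_max + cfg.min_gap_um, W_um - r_max - cfg.min_gap_um)
            ok = all(
                np.hypot(cy - o.cy_um, cx - o.cx_um)
                >= r_max
                + min(o.r0_um + cfg.growth_um_per_day * max_day, cfg.radius_um_max)
                * cfg.dead_spread_factor
                * BOUNDARY_PERT_MAX
                + cfg.min_gap_um
                for o in organoids
            )
            if ok:
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place organoid {i + 1}/{n} in well {well}; reduce density"
            )
        death = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
        amps = rng.normal(0.0, cfg.dead_boundary_amp, 5)  # harmonics 3..7
        phases = rng.uniform(0, 2 * np.pi, 5)
        jit = _draw_phenotype(rng, cfg)
        n_spots = max(1, int(rng.poisson(cfg.spots_per_dead)))
        areas = rng.lognormal(np.log(cfg.spot_area_um2_mean), cfg.spot_area_sigma, n_spots)
        spot_r = np.sqrt(areas / np.pi)
        ang = rng.uniform(0, 2 * np.pi, n_spots)
        rad = rng.uniform(0, 0.55, n_spots) * r0
        offsets = np.stack([rad * np.sin(ang), rad * np.cos(ang)], axis=1)
        organoids.append(
            SimOrganoid(
                organoid_id=id_offset + i + 1,
                well=well,
                cy_um=float(cy),
                cx_um=float(cx),
                r0_um=r0,
                death_time_days=float(death),
                boundary_amps=amps,
                boundary_phases=phases,
                spot_offsets_um=offsets,
                spot_radii_um=spot_r,
                touches_border=on_border,
                **jit,
            )
        )
    return organoids


def _organoid_window(o: SimOrganoid, r_um: float, cfg: SimConfig):
    px = cfg.pixel_size_um
    pad = r_um * 1.4 + 4 * px
    r0 = max(0, int((o.cy_um - pad) / px))
    r1 = min(cfg.shape[0], int((o.cy_um + pad) / px) + 1)
    c0 = max(0, int((o.cx_um - pad) / px))
    c1 = min(cfg.shape[1], int((o.cx_um + pad) / px) + 1)
    yy = (np.arange(r0, r1) + 0.5) * px - o.cy_um
    xx = (np.arange(c0, c1) + 0.5) * px - o.cx_um
    dy, dx = np.meshgrid(yy, xx, indexing="ij")
    return (slice(r0, r1), slice(c0, c1)), np.hypot(dy, dx), np.arctan2(dy, dx)


def _boundary_radius(o: SimOrganoid, r_um: float, theta: np.ndarray, dead: bool) -> np.ndarray:
    if not dead:
        return np.full_like(theta, r_um)
    pert = np.zeros_like(theta)
    for k, (a, ph) in enumerate(zip(o.boundary_amps, o.boundary_phases), start=3):
        pert += a * np.cos(k * theta + ph)
    # bounded so the footprint never exceeds the placement exclusion radius
    return r_um * np.clip(1.0 + pert, 0.75, BOUNDARY_PERT_MAX)


def _render_brightfield(
    organoids: list[SimOrganoid], day: float, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    px = cfg.pixel_size_um
    canvas = cfg.background + rng.normal(0.0, cfg.bg_noise_sd, cfg.shape)
    for o in organoids:
        dead = o.status(day) == DEAD
        r_um = o.radius(day, cfg)
        window, rho, theta = _organoid_window(o, r_um, cfg)
        r_eff = _boundary_radius(o, r_um, theta, dead)
        soft = np.clip((r_eff - rho) / px + 0.5, 0.0, 1.0)  # ~1 px soft edge
        if not dead:
            prof = cfg.live_base_attenuation + cfg.live_rim_gain * o.rim_gain * np.exp(
                -((rho - 0.82 * r_um) ** 2) / (2 * (0.15 * r_um) ** 2)
            )
            lumen = np.clip(cfg.live_lumen_depth * o.lumen_gain, 0.0, 0.8)
            prof *= 1.0 - lumen * np.exp(-(rho**2) / (2 * (0.35 * r_um) ** 2))
            tex = ndi.gaussian_filter(rng.normal(0.0, 1.0, rho.shape), 2.0)
            sd = tex.std()
            if sd > 0:
                tex /= sd
            atten = cfg.contrast * o.atten_gain * (
                prof + cfg.live_texture_sd * o.tex_gain * tex
            )
        else:
            gran = ndi.gaussian_filter(rng.normal(0.0, 1.0, rho.shape), 0.8)
            sd = gran.std()
            if sd > 0:
                gran /= sd
            atten = cfg.contrast * o.atten_gain * (
                cfg.dead_base_attenuation + cfg.dead_granule_sd * o.gran_gain * gran
            )
        atten = np.clip(atten, 0.0, 1.1 * cfg.contrast) * soft
        canvas[window] -= atten
    return np.clip(canvas, 0.0, None)


def _dye_retained(o: SimOrganoid, day: float, cfg: SimConfig, rng_factory) -> np.ndarray:
    """Boolean per spot: still dye-positive at this imaging day."""
    observed = [d for d in cfg.days if o.death_time_days <= d]
    if not observed or day < observed[0]:
        return np.zeros(len(o.spot_radii_um), dtype=bool)
    rng = rng_factory(o.organoid_id)
    retained = np.ones(len(o.spot_radii_um), dtype=bool)
    for d in observed:
        if d == observed[0]:
            pass  # first dead observation: all spots present
        else:
            retained &= rng.random(len(retained)) < (1.0 - cfg.dye_loss_prob)
        if d == day:
            break
    return retained


def _render_fluorescence(
    organoids: list[SimOrganoid], day: float, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    px = cfg.pixel_size_um
    canvas = cfg.fluor_background + rng.normal(0.0, cfg.fluor_noise_sd, cfg.shape)
    base_seed = cfg.seed % (2**31)

    def rng_factory(org_id: int) -> np.random.Generator:
        return np.random.default_rng([base_seed, 7919, org_id])

    for o in organoids:
        if o.status(day) != DEAD:
            continue
        retained = _dye_retained(o, day, cfg, rng_factory)
        for keep, (oy, ox), sr in zip(retained, o.spot_offsets_um, o.spot_radii_um):
            if not keep:
                continue
            cy, cx = o.cy_um + oy, o.cx_um + ox
            r0 = max(0, int((cy - sr - 2 * px) / px))
            r1 = min(cfg.shape[0], int((cy + sr + 2 * px) / px) + 1)
            c0 = max(0, int((cx - sr - 2 * px) / px))
            c1 = min(cfg.shape[1], int((cx + sr + 2 * px) / px) + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            yy = (np.arange(r0, r1) + 0.5) * px - cy
            xx = (np.arange(c0, c1) + 0.5) * px - cx
            dy, dx = np.meshgrid(yy, xx, indexing="ij")
            canvas[r0:r1, c0:c1] += cfg.fluor_spot_intensity * (np.hypot(dy, dx) <= sr)
    return np.clip(canvas, 0.0, None)


def simulate_plate(config: SimConfig | None = None, render: bool = True) -> SimulatedPlate:
    """Render the whole plate at every imaging day, with ground truth.

    ``render=False`` skips image synthesis (the image dicts stay empty) but
    draws the same organoids, death times and dye states — handy for
    checking the kinetics at large n without paying for rendering.
    """
    cfg = config or SimConfig()
    if cfg.ec50 <= 0:
        raise ValidationError("ec50 must be > 0")
    base_seed = cfg.seed % (2**31)
    organoids: dict[str, list[SimOrganoid]] = {}
    images: dict[tuple[str, float], Image2D] = {}
    fluor: dict[tuple[str, float], Image2D] = {}
    truth_rows = []
    id_offset = 0
    rng_factory = None
    for widx, spec in enumerate(cfg.wells):
        rng_place = np.random.default_rng([base_seed, widx, 11])
        hazard = cfg.hazard(spec.dose, spec.control)
        orgs = _place_organoids(rng_place, cfg, spec.well, hazard, id_offset)
        id_offset += len(orgs)
        organoids[spec.well] = orgs

        def dye_rng(org_id: int) -> np.random.Generator:
            return np.random.default_rng([base_seed, 7919, org_id])

        for didx, day in enumerate(cfg.days):
            if render:
                rng_bf = np.random.default_rng([base_seed, widx, didx, 2])
                rng_fl = np.random.default_rng([base_seed, widx, didx, 3])
                images[(spec.well, day)] = Image2D(
                    pixels=_render_brightfield(orgs, day, cfg, rng_bf),
                    pixel_size_um=cfg.pixel_size_um,
                    channel=BRIGHTFIELD,
                    well=spec.well,
                    timepoint_day=day,
                )
                fluor[(spec.well, day)] = Image2D(
                    pixels=_render_fluorescence(orgs, day, cfg, rng_fl),
                    pixel_size_um=cfg.pixel_size_um,
                    channel=FLUORESCENCE,
                    well=spec.well,
                    timepoint_day=day,
                )
            for o in orgs:
                retained = _dye_retained(o, day, cfg, dye_rng)
                truth_rows.append(
                    {
                        "organoid_id": o.organoid_id,
                        "well": spec.well,
                        "day": day,
                        "status": o.status(day),
                        "radius_um": o.radius(day, cfg),
                        "cx_um": o.cx_um,
                        "cy_um": o.cy_um,
                        "dye_positive": bool(retained.any()),
                        "touches_border": o.touches_border,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    layout = PlateLayout(
        table=pd.DataFrame(
            [
                {
                    "well": w.well,
                    "pdo": w.pdo,
                    "treatment": w.treatment,
                    "dose": w.dose,
                    "unit": w.unit,
                    "group": w.group,
                    "control": w.control,
                }
                for w in cfg.wells
            ]
        )
    )
    return SimulatedPlate(
        config=cfg, organoids=organoids, images=images, fluorescence=fluor,
        truth=truth, layout=layout,
    )


# ---------------------------------------------------------------------------
# annotations and training fixtures
# ---------------------------------------------------------------------------


def make_texture_annotations(
    plate: SimulatedPlate,
    image_keys: list[tuple[str, float]],
    brush_px: float = 15.0,
    strokes_per_class: int = 6,
    seed: int = 0,
) -> tuple[list[Image2D], list[Stroke]]:
    """Ground-truth-guided annotation strokes for texture training.

    Organoid strokes are brush-sized disks at organoid centers; background
    strokes are disks well clear of every organoid.  Mimics a user
    scribbling on a few images with a 15 px brush.
    """
    cfg = plate.config
    rng = np.random.default_rng([cfg.seed % (2**31), seed, 13])
    images, strokes = [], []
    radius = max(1, int(brush_px // 2))
    H, W = cfg.shape
    dr, dc = np.meshgrid(np.arange(-radius, radius + 1), np.arange(-radius, radius + 1),
                         indexing="ij")
    disk = dr[np.hypot(dr, dc) <= radius], dc[np.hypot(dr, dc) <= radius]
    for idx, (well, day) in enumerate(image_keys):
        image = plate.images[(well, day)]
        images.append(image)
        orgs = plate.organoids[well]
        px = cfg.pixel_size_um
        chosen = rng.choice(len(orgs), size=min(strokes_per_class, len(orgs)), replace=False)
        for oi in chosen:
            o = orgs[oi]
            r = int(o.cy_um / px)
            c = int(o.cx_um / px)
            rr = np.clip(r + disk[0], 0, H - 1)
            cc = np.clip(c + disk[1], 0, W - 1)
            strokes.append(Stroke(image_index=idx, rows=rr, cols=cc, label=ORGANOID))
        placed = 0
        tries = 0
        while placed < strokes_per_class and tries < 500:
            tries += 1
            r = rng.integers(radius, H - radius)
            c = rng.integers(radius, W - radius)
            y_um, x_um = (r + 0.5) * px, (c + 0.5) * px
            clear = all(
                np.hypot(y_um - o.cy_um, x_um - o.cx_um)
                > o.radius(day, cfg) * 1.5 + brush_px * px
                for o in orgs
            )
            if clear:
                rr = np.clip(r + disk[0], 0, H - 1)
                cc = np.clip(c + disk[1], 0, W - 1)
                strokes.append(Stroke(image_index=idx, rows=rr, cols=cc, label=BACKGROUND))
                placed += 1
    return images, strokes


@dataclass
class TrainingPatch:
    """A rendered single-organoid patch with its true mask and label."""

    image: Image2D
    roi: OrganoidROI
    label: str


def make_training_fixture(
    config: SimConfig | None = None,
    n_live: int = 80,
    n_dead: int = 99,
    seed: int | None = None,
) -> list[TrainingPatch]:
    """Labeled single-organoid patches for classifier training.

    Defaults mirror the assay's training design (80 live from media
    controls, 99 dead from the staurosporine positive control).  Each patch
    is rendered with the same texture model as the plate simulator; the ROI
    is the true footprint.
    """
    cfg = config or SimConfig()
    if n_live < 1 or n_dead < 1:
        raise ValidationError("need at least one patch per class")
    base_seed = (seed if seed is not None else cfg.seed) % (2**31)
    patches: list[TrainingPatch] = []
    labels = [LIVE] * n_live + [DEAD] * n_dead
    px = cfg.pixel_size_um
    for i, label in enumerate(labels):
        rng = np.random.default_rng([base_seed, 23, i])
        r0 = _draw_radius(rng, cfg)
        day = float(rng.choice(cfg.days[1:]))  # observed at a post-baseline day
        death = 0.0 if label == DEAD else np.inf
        side_um = 2 * (
            (r0 + cfg.growth_um_per_day * max(cfg.days))
            * cfg.dead_spread_factor
            * BOUNDARY_PERT_MAX
            + 40
        )
        n_px = int(side_um / px)
        amps = rng.normal(0.0, cfg.dead_boundary_amp, 5)
        phases = rng.uniform(0, 2 * np.pi, 5)
        o = SimOrganoid(
            organoid_id=i + 1,
            well="patch",
            cy_um=n_px * px / 2,
            cx_um=n_px * px / 2,
            r0_um=r0,
            death_time_days=death,
            boundary_amps=amps,
            boundary_phases=phases,
            spot_offsets_um=np.zeros((1, 2)),
            spot_radii_um=np.zeros(1),
            **_draw_phenotype(rng, cfg),
        )
        patch_cfg = dataclasses.replace(cfg, shape=(n_px, n_px))
        pixels = _render_brightfield([o], day, patch_cfg, rng)
        image = Image2D(pixels=pixels, pixel_size_um=px, well="patch", timepoint_day=day)
        r_um = o.radius(day, cfg)
        window, rho, theta = _organoid_window(o, r_um, patch_cfg)
        r_eff = _boundary_radius(o, r_um, theta, label == DEAD)
        mask_win = rho <= r_eff
        full = np.zeros((n_px, n_px), dtype=bool)
        full[window] = mask_win
        rr, cc = np.nonzero(full)
        bbox = (rr.min(), cc.min(), rr.max() + 1, cc.max() + 1)
        mask = full[bbox[0] : bbox[2], bbox[1] : bbox[3]]
        roi = OrganoidROI(
            roi_id=i + 1,
            well="patch",
            field=0,
            timepoint_day=day,
            bbox=bbox,
            mask=mask,
            centroid_um=(rr.mean() * px, cc.mean() * px),
            area_um2=float(mask.sum() * px * px),
            touches_border=False,
            pixel_size_um=px,
        )
        patches.append(TrainingPatch(image=image, roi=roi, label=label))
    return patches


def patch_features(
    patches: list[TrainingPatch],
    feature_config=None,
    texture_model=None,
    seg_params=None,
) -> pd.DataFrame:
    """Extract the 25-feature panel from training patches, with labels.

    With a texture model the patch is segmented exactly like experimental
    images and the ROI covering the patch center is measured — this keeps
    training-set masks statistically identical to pipeline masks, mirroring
    how annotators label already-segmented objects.  Without one, the true
    rendered footprint is used (falls back to it too when segmentation
    finds nothing).
    """
    from .features import FeatureConfig, background_median, feature_vector
    from .segmentation import segment_organoids

    feature_config = feature_config or FeatureConfig()
    rows = []
    for i, patch in enumerate(patches):
        roi = patch.roi
        label_map = None
        if texture_model is not None:
            result = segment_organoids(patch.image, texture_model, seg_params)
            if result.rois:
                cy = patch.image.shape[0] / 2 * patch.image.pixel_size_um
                cx = patch.image.shape[1] / 2 * patch.image.pixel_size_um
                roi = min(
                    result.rois,
                    key=lambda r: np.hypot(r.centroid_um[0] - cy, r.centroid_um[1] - cx),
                )
                label_map = result.label_map
        if label_map is not None:
            fg = label_map > 0
        else:
            fg = np.zeros(patch.image.shape, dtype=bool)
            b = roi.bbox
            fg[b[0] : b[2], b[1] : b[3]] |= roi.mask
        bg = background_median(patch.image, fg)
        vals = feature_vector(patch.image, roi, feature_config, bg)
        rows.append({"patch_id": i, "label": patch.label, **vals})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk export (same layout imaging_io reads)
# ---------------------------------------------------------------------------


def write_plate(plate: SimulatedPlate, outdir: str | Path, run_config: RunConfig | None = None) -> RunConfig:
    """Write TIFF stacks, plate map, ground truth and config echo to disk."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = plate.config
    rc = run_config or RunConfig(
        pixel_size_um=cfg.pixel_size_um, z_start_um=20.0, z_step_um=20.0,
        days=list(cfg.days),
    )
    for (well, day) in plate.images:
        stack = plate.stack(well, day)
        tifffile.imwrite(
            rc.stack_path(outdir, well, 0, f"{day:g}", BRIGHTFIELD),
            stack.planes.astype(np.float32),
            photometric="minisblack",
        )
        tifffile.imwrite(
            rc.stack_path(outdir, well, 0, f"{day:g}", FLUORESCENCE),
            plate.fluorescence[(well, day)].pixels.astype(np.float32),
            photometric="minisblack",
        )
    plate.layout.table.to_csv(outdir / "plate_map.csv", index=False)
    plate.truth.to_csv(outdir / "ground_truth.csv", index=False)
    echo = dataclasses.asdict(cfg)
    echo["wells"] = [dataclasses.asdict(w) for w in cfg.wells]
    for key, val in list(echo.items()):
        if isinstance(val, tuple):
            echo[key] = list(val)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh)
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "pixel_size_um": rc.pixel_size_um,
                "z_start_um": rc.z_start_um,
                "z_step_um": rc.z_step_um,
                "filename_template": rc.filename_template,
                "days": list(rc.days),
            },
            fh,
        )
    return rc
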