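"""Synthetic fluorescence-microscopy movies and traces with known ground truth.

The simulators emulate the experimental modalities the analysis pipeline is
built for: fields of bright centrosomes on a noisy background, FRAP movies
with a bleach event and either liquid-like (scaffold-wide exchange) or
solid-like (core-limited) recovery, two-channel single-molecule movies in
which transiently bound molecules either ride an outward flux or stay put
while bound, and FCS intensity traces from particles diffusing through a 3-D
Gaussian observation volume.

All randomness flows through ``numpy.random.default_rng`` seeded explicitly,
so identical configuration + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "SimConfig",
    "Emitter",
    "FluxRegime",
    "ScaffoldMode",
    "FluxMovie",
    "FrapMovie",
    "PlacementError",
    "render_frame",
    "simulate_centrosome_field",
    "simulate_flux_movie",
    "simulate_frap_movie",
    "simulate_fcs_trace",
]


class PlacementError(RuntimeError):
    """Requested object density is incompatible with the separation constraint."""


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry, optics and detector parameters for a simulation.

    Defaults mirror a spinning-disk single-molecule acquisition: 100 nm
    pixels, one frame every 10 s for 30 min, and a near-diffraction-limited
    PSF (sigma 110 nm) after maximum projection.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 10.0
    n_frames: int = 180
    psf_sigma_nm: float = 110.0
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    photon_scale: float = 500.0
    bleach_rate_per_s: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.image_shape
        if ny < 16 or nx < 16:
            raise ValueError("image_shape must be at least 16 px on each side")
        for name in ("pixel_size_nm", "frame_interval_s", "psf_sigma_nm", "photon_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background_level and read_noise_sd must be >= 0")
        if self.bleach_rate_per_s < 0:
            raise ValueError("bleach_rate_per_s must be >= 0")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm


@dataclass(frozen=True)
class Emitter:
    """A point source at a continuous (y, x) pixel position."""

    position: tuple[float, float]
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")


@dataclass(frozen=True)
class FluxRegime:
    """The two hypotheses for single-molecule behaviour while bound.

    ``flux``: a bound molecule's radial distance from its centriole grows at
    ``outward_speed_nm_s`` (physical outward transport of the molecule).
    ``static_turnover``: the molecule stays exactly where it bound; any
    apparent In/Out asymmetry must then come from where binding/unbinding
    *sites* are, not from motion.

    Binding radii are drawn from a folded normal (isotropic in angle); bound
    dwell times are exponential with mean ``dwell_mean_s``.
    ``target_occupancy`` sets the expected instantaneous fraction of
    centrosomes carrying at least one visible labeled molecule (the sparse
    single-molecule condition).
    """

    mode: str = "flux"
    bind_radius_mean_nm: float = 300.0
    bind_radius_sd_nm: float = 150.0
    outward_speed_nm_s: float = 10.0
    dwell_mean_s: float = 40.0
    labeled_fraction: float = 0.1
    target_occupancy: float = 0.07
    blink_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("flux", "static_turnover"):
            raise ValueError("mode must be 'flux' or 'static_turnover'")
        if self.mode == "static_turnover" and self.outward_speed_nm_s != 0:
            raise ValueError("static_turnover requires outward_speed_nm_s = 0")
        if not (0 < self.labeled_fraction <= 1):
            raise ValueError("labeled_fraction must be in (0, 1]")
        if self.dwell_mean_s <= 0 or self.bind_radius_mean_nm < 0 or self.bind_radius_sd_nm < 0:
            raise ValueError("invalid kinetic parameters")
        if not (0 < self.target_occupancy < 1):
            raise ValueError("target_occupancy must be in (0, 1)")
        if not (0 <= self.blink_prob < 0.5):
            raise ValueError("blink_prob must be in [0, 0.5)")


@dataclass(frozen=True)
class ScaffoldMode:
    """Scaffold material state controlling FRAP recovery geometry.

    ``liquid``: every scaffold element exchanges with the cytoplasmic pool at
    ``exchange_rate_per_s`` (internal mixing), so recovery is scaffold-wide
    and, for a single centrosome with an effectively infinite pool, exactly
    one-phase association. ``solid``: exchange is confined to a central core
    of radius ``central_recovery_radius_nm``; the periphery never recovers
    and there is no inter-centrosome transfer.
    """

    mode: str = "liquid"
    exchange_rate_per_s: float = 0.05
    immobile_fraction: float = 0.0
    central_recovery_radius_nm: float = 400.0
    internal_mixing: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("liquid", "solid"):
            raise ValueError("mode must be 'liquid' or 'solid'")
        if self.mode == "solid" and self.internal_mixing:
            raise ValueError("solid mode excludes internal mixing")
        if not (0 <= self.immobile_fraction <= 1):
            raise ValueError("immobile_fraction must be in [0, 1]")
        if self.exchange_rate_per_s <= 0 or self.central_recovery_radius_nm <= 0:
            raise ValueError("rates and radii must be > 0")


@dataclass
class FluxMovie:
    """Two-channel single-molecule movie plus ground truth.

    ``stack`` has axes (frame, channel, y, x); channel 0 is the persistent
    centriole marker, channel 1 the transient single molecules. ``stack`` is
    None for truth-only simulations (``render=False``).
    """

    stack: np.ndarray | None
    molecules: pd.DataFrame
    centrioles: pd.DataFrame
    config: SimConfig
    regime: FluxRegime


@dataclass
class FrapMovie:
    """FRAP movie plus ground truth (rates, geometry, noiseless ROI sums)."""

    stack: np.ndarray
    truth: dict
    config: SimConfig
    scaffold: ScaffoldMode


def _pixel_integrated_gaussian(center: float, sigma: float, lo: int, hi: int) -> np.ndarray:
    """Integral of a unit-mass 1-D Gaussian over pixels lo..hi-1 (centers at integers)."""
    edges = np.arange(lo, hi + 1) - 0.5
    c = erf((edges - center) / (sigma * math.sqrt(2.0)))
    return 0.5 * (c[1:] - c[:-1])


def render_frame(
    emitters,
    config: SimConfig,
    noise: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one noiseless or noisy frame from a list of point emitters.

    The noiseless image is ``background_level + photon_scale * sum_i
    brightness_i * PSF_i`` with a pixel-integrated isotropic Gaussian PSF, so
    the total above-background signal of a fully in-frame emitter equals
    ``photon_scale * brightness`` exactly. With ``noise=True``, Poisson shot
    noise is applied to the expected photon image, then additive Gaussian
    read noise, and the result is clipped at zero.
    """
    if config.psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be > 0")
    ny, nx = config.image_shape
    image = np.full((ny, nx), float(config.background_level))
    sigma = config.psf_sigma_px
    halfwin = int(math.ceil(6.0 * sigma)) + 1
    for em in emitters:
        if isinstance(em, Emitter):
            (ey, ex), b = em.position, em.brightness
        else:  # (y, x, brightness) tuple
            ey, ex, b = em
        if b == 0:
            continue
        y0 = max(0, int(math.floor(ey)) - halfwin)
        y1 = min(ny, int(math.ceil(ey)) + halfwin + 1)
        x0 = max(0, int(math.floor(ex)) - halfwin)
        x1 = min(nx, int(math.ceil(ex)) + halfwin + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        gy = _pixel_integrated_gaussian(ey, sigma, y0, y1)
        gx = _pixel_integrated_gaussian(ex, sigma, x0, x1)
        image[y0:y1, x0:x1] += config.photon_scale * b * np.outer(gy, gx)
    if noise:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        image = rng.poisson(image).astype(float)
        if config.read_noise_sd > 0:
            image += rng.normal(0.0, config.read_noise_sd, size=image.shape)
        image = np.clip(image, 0.0, None)
    return image


def _emitter_frame_mass(ey: float, ex: float, sigma: float, shape: tuple[int, int]) -> float:
    """Fraction of a unit-mass PSF centered at (ey, ex) that falls inside the frame."""
    ny, nx = shape
    my = _pixel_integrated_gaussian(ey, sigma, 0, ny).sum()
    mx = _pixel_integrated_gaussian(ex, sigma, 0, nx).sum()
    return float(my * mx)


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_separation: float,
    max_tries: int = 5000,
) -> np.ndarray:
    ny, nx = shape
    if ny - 2 * margin <= 0 or nx - 2 * margin <= 0:
        raise PlacementError("margin leaves no interior to place objects in")
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} objects with separation {min_separation:.1f} px "
                f"in {shape} after {max_tries} tries"
            )
        tries += 1
        cand = np.array(
            [rng.uniform(margin, ny - 1 - margin), rng.uniform(margin, nx - 1 - margin)]
        )
        if all(np.hypot(*(cand - p)) >= min_separation for p in pts):
            pts.append(cand)
    return np.array(pts).reshape(n, 2)


def simulate_centrosome_field(
    config: SimConfig,
    n_centrosomes: int = 10,
    brightness_range: tuple[float, float] = (0.8, 1.2),
    seed: int | None = None,
    min_separation_px: float | None = None,
    noise: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate a field of static centrosomes; return (stack, truth table).

    The truth table has one row per centrosome with its continuous position,
    brightness, integrated in-frame intensity (photons above background) and
    the nominal disc area it occupies (radius 2 sigma of the PSF).
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    sigma = config.psf_sigma_px
    sep = 4.0 * sigma if min_separation_px is None else float(min_separation_px)
    margin = 4.0 * sigma + 2.0
    if n_centrosomes > 0:
        pts = _place_points(rng, n_centrosomes, config.image_shape, margin, sep)
        bright = rng.uniform(*brightness_range, size=n_centrosomes)
    else:
        pts = np.empty((0, 2))
        bright = np.empty(0)
    rows = []
    for i in range(n_centrosomes):
        mass = _emitter_frame_mass(pts[i, 0], pts[i, 1], sigma, config.image_shape)
        rows.append(
            {
                "centrosome_id": i,
                "y_px": pts[i, 0],
                "x_px": pts[i, 1],
                "brightness": bright[i],
                "sum_intensity": config.photon_scale * bright[i] * mass,
                "area_px": int(round(math.pi * (2.0 * sigma) ** 2)),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["centrosome_id", "y_px", "x_px", "brightness", "sum_intensity", "area_px"],
    )
    frames = []
    for f in range(config.n_frames):
        decay = math.exp(-config.bleach_rate_per_s * f * config.frame_interval_s)
        emitters = [(pts[i, 0], pts[i, 1], bright[i] * decay) for i in range(n_centrosomes)]
        frames.append(render_frame(emitters, config, noise=noise, rng=rng))
    return np.stack(frames), truth


def simulate_flux_movie(
    config: SimConfig,
    regime: FluxRegime,
    n_centrosomes: int = 12,
    seed: int | None = None,
    centriole_brightness: float = 2.0,
    molecule_brightness: float = 1.0,
    min_separation_px: float = 32.0,
    noise: bool = True,
    render: bool = True,
) -> FluxMovie:
    """Simulate a two-channel single-molecule movie under a flux regime.

    Channel 0 holds persistent centriole emitters; channel 1 the transiently
    bound labeled molecules. Labeled binding events arrive per centrosome as
    a Poisson process whose rate is set so the expected instantaneous
    fraction of centrosomes with at least one visible molecule equals
    ``regime.target_occupancy``. Ground truth records exact (continuous)
    bind/unbind times and positions per molecule.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    T_total = config.n_frames * config.frame_interval_s
    margin = max(4.0 * config.psf_sigma_px + 2.0, min_separation_px / 2.0)
    centers = _place_points(rng, n_centrosomes, config.image_shape, margin, min_separation_px)

    # Occupancy of visible molecules per centrosome is Poisson with mean mu;
    # P(>=1) = 1 - exp(-mu) = target  =>  event rate = mu / mean dwell.
    mu = -math.log(1.0 - regime.target_occupancy)
    rate = mu / regime.dwell_mean_s

    mol_rows = []
    mol_id = 0
    for cid in range(n_centrosomes):
        n_events = rng.poisson(rate * T_total)
        bind_times = np.sort(rng.uniform(0.0, T_total, size=n_events))
        for tb in bind_times:
            dwell = rng.exponential(regime.dwell_mean_s)
            tu = tb + dwell
            r0_nm = abs(rng.normal(regime.bind_radius_mean_nm, regime.bind_radius_sd_nm))
            theta = rng.uniform(0.0, 2.0 * math.pi)
            uy, ux = math.sin(theta), math.cos(theta)
            r0 = r0_nm / config.pixel_size_nm
            by = centers[cid, 0] + r0 * uy
            bx = centers[cid, 1] + r0 * ux
            if regime.mode == "flux":
                r1 = (r0_nm + regime.outward_speed_nm_s * dwell) / config.pixel_size_nm
            else:
                r1 = r0
            ey = centers[cid, 0] + r1 * uy
            ex = centers[cid, 1] + r1 * ux
            mol_rows.append(
                {
                    "molecule_id": mol_id,
                    "centrosome_id": cid,
                    "bind_t_s": tb,
                    "unbind_t_s": tu,
                    "bind_y_px": by,
                    "bind_x_px": bx,
                    "unbind_y_px": ey,
                    "unbind_x_px": ex,
                    "radius0_nm": r0_nm,
                    "dir_y": uy,
                    "dir_x": ux,
                }
            )
            mol_id += 1
    molecules = pd.DataFrame(
        mol_rows,
        columns=[
            "molecule_id",
            "centrosome_id",
            "bind_t_s",
            "unbind_t_s",
            "bind_y_px",
            "bind_x_px",
            "unbind_y_px",
            "unbind_x_px",
            "radius0_nm",
            "dir_y",
            "dir_x",
        ],
    )

    cent_rows = [
        {"frame": f, "centrosome_id": i, "y_px": centers[i, 0], "x_px": centers[i, 1]}
        for f in range(config.n_frames)
        for i in range(n_centrosomes)
    ]
    centrioles = pd.DataFrame(cent_rows, columns=["frame", "centrosome_id", "y_px", "x_px"])
    if not render:
        return FluxMovie(
            stack=None, molecules=molecules, centrioles=centrioles, config=config, regime=regime
        )

    # Blinking: one-frame dark states while bound, never two in a row.
    dark: dict[int, set[int]] = {}
    for row in molecules.itertuples():
        f0 = int(math.ceil(row.bind_t_s / config.frame_interval_s))
        f1 = int(math.floor(row.unbind_t_s / config.frame_interval_s))
        frames_bound = range(max(f0, 0), min(f1, config.n_frames - 1) + 1)
        dk: set[int] = set()
        prev_dark = False
        for f in frames_bound:
            if not prev_dark and rng.uniform() < regime.blink_prob:
                dk.add(f)
                prev_dark = True
            else:
                prev_dark = False
        dark[row.molecule_id] = dk

    ny, nx = config.image_shape
    stack = np.empty((config.n_frames, 2, ny, nx))
    for f in range(config.n_frames):
        t = f * config.frame_interval_s
        decay = math.exp(-config.bleach_rate_per_s * t)
        ch0 = [(centers[i, 0], centers[i, 1], centriole_brightness * decay) for i in range(n_centrosomes)]
        ch1 = []
        bound = molecules[(molecules.bind_t_s <= t) & (molecules.unbind_t_s > t)]
        for row in bound.itertuples():
            if f in dark[row.molecule_id]:
                continue
            if regime.mode == "flux":
                r_nm = row.radius0_nm + regime.outward_speed_nm_s * (t - row.bind_t_s)
                r = r_nm / config.pixel_size_nm
                y = centers[row.centrosome_id, 0] + r * row.dir_y
                x = centers[row.centrosome_id, 1] + r * row.dir_x
            else:
                y, x = row.bind_y_px, row.bind_x_px
            ch1.append((y, x, molecule_brightness * decay))
        stack[f, 0] = render_frame(ch0, config, noise=noise, rng=rng)
        stack[f, 1] = render_frame(ch1, config, noise=noise, rng=rng)

    return FluxMovie(stack=stack, molecules=molecules, centrioles=centrioles, config=config, regime=regime)


def _scaffold_grid(center: tuple[float, float], radius_px: float) -> np.ndarray:
    """Unit-spaced sub-emitter positions filling a disc."""
    cy, cx = center
    r = int(math.ceil(radius_px))
    ys, xs = np.mgrid[-r : r + 1, -r : r + 1]
    keep = ys**2 + xs**2 <= radius_px**2
    return np.column_stack([cy + ys[keep], cx + xs[keep]]).astype(float)


def simulate_frap_movie(
    config: SimConfig,
    scaffold: ScaffoldMode,
    bleach_roi: tuple[float, float, float],
    bleach_frame: int,
    paired: bool = False,
    seed: int | None = None,
    residual_fraction: float = 0.1,
    centrosome_radius_nm: float = 1200.0,
    partner_offset_px: float | None = None,
    sub_brightness: float = 0.02,
    cyto_level: float = 0.0,
    pool_capacity_ratio: float = 5.0,
    noise: bool = True,
) -> FrapMovie:
    """Simulate a FRAP movie: a scaffold bleached at t=0 inside a circular ROI.

    The bleached centrosome is a disc of sub-emitters centered on the ROI.
    At ``bleach_frame`` the fluorescent fraction of every sub-emitter inside
    the ROI drops to ``residual_fraction``; recovery then follows the
    scaffold mode. Liquid + unpaired uses an effectively infinite cytoplasmic
    pool, making the ROI-summed recovery exactly one-phase association;
    liquid + paired couples both centrosomes to a finite shared pool
    (``pool_capacity_ratio`` times the total scaffold capacity), so the
    unbleached partner declines as bleached molecules mix in. Solid mode
    confines recovery to the central core and has no inter-centrosome
    exchange. Global photobleaching at ``config.bleach_rate_per_s`` applies
    multiplicatively throughout.
    """
    cy, cx, r_roi = bleach_roi
    ny, nx = config.image_shape
    if not (0 <= cy < ny and 0 <= cx < nx) or r_roi <= 0:
        raise ValueError("bleach ROI must lie inside the frame")
    if cy - r_roi < 0 or cy + r_roi >= ny or cx - r_roi < 0 or cx + r_roi >= nx:
        raise ValueError("bleach ROI extends outside the frame")
    if not (0 <= bleach_frame < config.n_frames):
        raise ValueError("bleach_frame outside movie")
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)

    R_px = centrosome_radius_nm / config.pixel_size_nm
    sub1 = _scaffold_grid((cy, cx), R_px)
    centers = [(cy, cx)]
    subs = [sub1]
    if paired:
        off = partner_offset_px if partner_offset_px is not None else 3.5 * R_px
        p_center = (cy, cx + off)
        if p_center[1] + R_px >= nx:
            raise ValueError("partner centrosome extends outside the frame")
        centers.append(p_center)
        subs.append(_scaffold_grid(p_center, R_px))

    k = scaffold.exchange_rate_per_s
    f_imm = scaffold.immobile_fraction
    core_px = scaffold.central_recovery_radius_nm / config.pixel_size_nm
    dt_frame = config.frame_interval_s
    t_b = bleach_frame * dt_frame

    # Per-sub-emitter fluorescent fraction trajectories, shape (n_frames, n_sub).
    n_sub = [s.shape[0] for s in subs]
    frac = [np.ones((config.n_frames, n)) for n in n_sub]
    in_roi = [np.hypot(s[:, 0] - cy, s[:, 1] - cx) <= r_roi for s in subs]
    exchanging = []
    for ci, s in enumerate(subs):
        if scaffold.mode == "liquid":
            exchanging.append(np.ones(s.shape[0], dtype=bool))
        else:
            d = np.hypot(s[:, 0] - centers[ci][0], s[:, 1] - centers[ci][1])
            exchanging.append(d <= core_px)
    if not in_roi[0].any():
        raise ValueError("bleach ROI does not overlap the simulated centrosome")

    b0 = [np.ones(n) for n in n_sub]
    b0[0] = np.where(in_roi[0], residual_fraction, 1.0)

    use_finite_pool = paired and scaffold.mode == "liquid"
    if use_finite_pool:
        cap_total = float(sum(n_sub))
        pool_cap = pool_capacity_ratio * cap_total
        pool_fluo = pool_cap  # pool starts fully fluorescent
        b = [x.copy() for x in b0]
        dt_sub = dt_frame / 20.0
        for f in range(config.n_frames):
            for ci in range(len(subs)):
                frac[ci][f] = b[ci] if f >= bleach_frame else 1.0
            if f < bleach_frame:
                continue
            n_steps = 20
            for _ in range(n_steps):
                phi = pool_fluo / pool_cap
                flow = 0.0
                for ci in range(len(subs)):
                    mob = (1.0 - f_imm) * np.ones(n_sub[ci])
                    db = k * (phi - b[ci]) * mob * dt_sub
                    db = np.where(exchanging[ci], db, 0.0)
                    b[ci] = b[ci] + db
                    flow += db.sum()
                pool_fluo -= flow
    else:
        for ci in range(len(subs)):
            for f in range(config.n_frames):
                if f < bleach_frame:
                    continue
                t = f * dt_frame - t_b
                rec = 1.0 + (b0[ci] - 1.0) * np.exp(-k * t)
                val = f_imm * b0[ci] + (1.0 - f_imm) * rec
                frac[ci][f] = np.where(exchanging[ci], val, b0[ci])

    roi_masks = []
    yy, xx = np.mgrid[0:ny, 0:nx]
    for c in centers:
        roi_masks.append((yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r_roi**2)

    stack = np.empty((config.n_frames, ny, nx))
    roi_sums = np.zeros((config.n_frames, len(centers)))
    for f in range(config.n_frames):
        t = f * dt_frame
        decay = math.exp(-config.bleach_rate_per_s * t)
        emitters = []
        for ci, s in enumerate(subs):
            br = sub_brightness * frac[ci][f] * decay
            emitters.extend((s[j, 0], s[j, 1], br[j]) for j in range(n_sub[ci]))
        clean = render_frame(emitters, config, noise=False)
        if cyto_level:
            clean = clean + cyto_level * decay
        for ci in range(len(centers)):
            roi_sums[f, ci] = (clean[roi_masks[ci]] - config.background_level).sum()
        if noise:
            img = rng.poisson(clean).astype(float)
            if config.read_noise_sd > 0:
                img += rng.normal(0.0, config.read_noise_sd, size=img.shape)
            stack[f] = np.clip(img, 0.0, None)
        else:
            stack[f] = clean

    truth = {
        "k": k,
        "bleach_rate_per_s": config.bleach_rate_per_s,
        "immobile_fraction": f_imm,
        "residual_fraction": residual_fraction,
        "bleach_frame": bleach_frame,
        "bleach_roi": bleach_roi,
        "centers": centers,
        "scaffold_radius_px": R_px,
        "roi_sums_noiseless": roi_sums,
    }
    return FrapMovie(stack=stack, truth=truth, config=config, scaffold=scaffold)


def simulate_fcs_trace(
    true_params,
    duration_s: float,
    sample_interval_s: float,
    seed: int = 0,
    cpm: float = 10.0,
    waist_um: float = 0.2,
    box_volume_ratio: float = 150.0,
    shot_noise: bool = False,
) -> np.ndarray:
    """Simulate an FCS intensity trace from Brownian particles in a 3-D Gaussian volume.

    ``true_params`` is an :class:`~pcmflux.fcs.FCSParams`; particle numbers
    and diffusion coefficients are derived from N, the diffusion times and the
    lateral beam waist (axial waist = S * lateral). The detection profile is
    ``exp(-2 r_xy^2/w^2 - 2 z^2/wz^2)`` in a periodic box, and intensities are
    scaled so the mean equals ``N * cpm`` (without dark states). Optional
    two-state dark switching (triplet and/or blinking) multiplies emission by
    a telegraph process.
    """
    from .fcs import FCSParams  # local import to avoid a cycle

    p: FCSParams = true_params
    n_samples = int(round(duration_s / sample_interval_s))
    if p.N == 0:
        return np.zeros(n_samples)
    tau_min = min(p.tauD)
    if sample_interval_s >= tau_min:
        raise ValueError("sample_interval_s must be < the shortest diffusion time (aliasing)")
    corr_times = list(p.tauD)
    if p.T > 0:
        corr_times.append(p.tau_T)
    if p.B > 0:
        corr_times.append(p.tau_B)
    if duration_s < 100.0 * max(corr_times):
        raise ValueError("duration_s must be >= 100x the longest correlation time")

    rng = np.random.default_rng(seed)
    w = waist_um
    wz = p.S * w
    v_eff = math.pi**1.5 * w * w * wz
    # box dilution: a recurrent particle in a periodic box has a positive
    # time-averaged weight, which depresses the within-trace ACF by about
    # V_eff/V_box; keep the box many effective volumes large
    Lz = 4.0 * wz
    Lxy = math.sqrt(box_volume_ratio * v_eff / Lz)
    box_vol = Lxy * Lxy * Lz
    conc = p.N / v_eff

    # species split
    fracs = np.asarray(p.f, dtype=float)
    taus = np.asarray(p.tauD, dtype=float)
    # grand-canonical particle count: a fixed count in a closed box would
    # suppress number fluctuations by v_eff/box_vol and depress G(tau)
    m_total = conc * box_vol
    counts = rng.poisson(np.maximum(fracs * m_total, 0.0))
    q = cpm * 2.0**1.5  # peak brightness such that <I> = N * cpm

    has_dark = p.T > 0 or p.B > 0
    trace = np.zeros(n_samples)
    block = 4096
    for sp, (m, tau) in enumerate(zip(counts, taus)):
        if m == 0:
            continue
        D = w * w / (4.0 * tau)
        step_sd = math.sqrt(2.0 * D * sample_interval_s)
        if not has_dark:
            # numpy generates the Gaussian steps (fast, single RNG stream);
            # a compiled kernel walks, wraps and accumulates the weights
            kernel = _get_brownian_kernel()
            xs = rng.uniform(-Lxy / 2, Lxy / 2, m)
            ys = rng.uniform(-Lxy / 2, Lxy / 2, m)
            zs = rng.uniform(-Lz / 2, Lz / 2, m)
            out = np.zeros(n_samples)
            start = 0
            while start < n_samples:
                nb = min(8192, n_samples - start)
                steps = rng.standard_normal(size=(nb, m, 3), dtype=np.float32)
                steps *= np.float32(step_sd)
                kernel(steps, xs, ys, zs, Lxy, Lz, w, wz, out, start)
                start += nb
            trace += q * out
            continue
        # float32 throughout the Brownian inner loop: step noise dwarfs the
        # rounding error and the random-number + exp cost halves
        pos = np.column_stack(
            [
                rng.uniform(-Lxy / 2, Lxy / 2, m),
                rng.uniform(-Lxy / 2, Lxy / 2, m),
                rng.uniform(-Lz / 2, Lz / 2, m),
            ]
        ).astype(np.float32)
        emit = _dark_state_trace(rng, p, m, n_samples, sample_interval_s)
        start = 0
        while start < n_samples:
            nb = min(block, n_samples - start)
            steps = rng.standard_normal(size=(nb, m, 3), dtype=np.float32)
            steps *= np.float32(step_sd)
            path = pos[None, :, :] + np.cumsum(steps, axis=0)
            path[:, :, :2] = (path[:, :, :2] + np.float32(Lxy / 2)) % np.float32(Lxy) - np.float32(Lxy / 2)
            path[:, :, 2] = (path[:, :, 2] + np.float32(Lz / 2)) % np.float32(Lz) - np.float32(Lz / 2)
            wgt = np.exp(
                -2.0 * (path[:, :, 0] ** 2 + path[:, :, 1] ** 2) / np.float32(w * w)
                - 2.0 * path[:, :, 2] ** 2 / np.float32(wz * wz)
            )
            if emit is not None:
                wgt = wgt * emit[start : start + nb]
            trace[start : start + nb] += q * wgt.sum(axis=1, dtype=np.float64)
            pos = path[-1]
            start += nb
    if shot_noise:
        trace = rng.poisson(np.clip(trace, 0.0, None) * sample_interval_s) / sample_interval_s
    return trace


def _brownian_intensity_impl(steps, xs, ys, zs, Lxy, Lz, w, wz, out, offset):
    half_xy = Lxy / 2.0
    half_z = Lz / 2.0
    inv_w2 = 2.0 / (w * w)
    inv_wz2 = 2.0 / (wz * wz)
    nb = steps.shape[0]
    m = xs.shape[0]
    for t in range(nb):
        s = 0.0
        for j in range(m):
            x = xs[j] + steps[t, j, 0]
            y = ys[j] + steps[t, j, 1]
            z = zs[j] + steps[t, j, 2]
            if x > half_xy:
                x -= Lxy
            elif x < -half_xy:
                x += Lxy
            if y > half_xy:
                y -= Lxy
            elif y < -half_xy:
                y += Lxy
            if z > half_z:
                z -= Lz
            elif z < -half_z:
                z += Lz
            xs[j] = x
            ys[j] = y
            zs[j] = z
            arg = -(x * x + y * y) * inv_w2 - z * z * inv_wz2
            if arg > -20.0:
                s += math.exp(arg)
        out[offset + t] = s


_brownian_intensity_jit = None


def _get_brownian_kernel():
    global _brownian_intensity_jit
    if _brownian_intensity_jit is None:
        from numba import njit

        _brownian_intensity_jit = njit(cache=True)(_brownian_intensity_impl)
    return _brownian_intensity_jit


def _dark_state_trace(
    rng: np.random.Generator,
    p,
    m: int,
    n_samples: int,
    dt: float,
) -> np.ndarray | None:
    """Telegraph emission factors (n_samples, m) for triplet/blinking, or None."""
    states = None
    for frac, tau in ((p.T, p.tau_T), (p.B, p.tau_B)):
        if frac <= 0:
            continue
        s = np.empty((n_samples, m))
        # equilibrium: P(dark) = frac; rates from correlation time tau
        k_dark = frac / tau
        k_bright = (1.0 - frac) / tau
        for j in range(m):
            t, on = 0.0, rng.uniform() >= frac
            edges, vals = [0.0], [1.0 if on else 0.0]
            while t < n_samples * dt:
                rate = k_dark if on else k_bright
                t += rng.exponential(1.0 / rate)
                on = not on
                edges.append(t)
                vals.append(1.0 if on else 0.0)
            idx = np.searchsorted(np.asarray(edges), np.arange(n_samples) * dt, side="right") - 1
            s[:, j] = np.asarray(vals)[idx]
        states = s if states is None else states * s
    return states
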