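"""Ground-truthed synthetic inputs for every downstream stage.

Three generators live here:

* :func:`generate_timelapse` — confocal-like 4D movies of bright spherical
  lipid droplets (LDs) on a dark background, in which donor/acceptor pairs
  execute exponential neutral-lipid transfer with volume conservation,
  blurred by a Gaussian PSF and corrupted by shot + read noise. Every movie
  comes with a per-frame truth table of volumes and centroids.
* :func:`generate_surface_pair` — analytic monolayer surface pairs (parallel
  planes, concentric spheres, perturbed planes) sampled as per-z-slice
  control points, emulating manual monolayer traces in tomograms, with the
  true separation known everywhere.
* :func:`generate_sphere_sections` — circle radii of two parallel
  cross-sections of a sphere, the input of sphere-radius recovery.

The transfer dynamics follow the donor model ``Vd(t) = Vd0(1 - exp(Rd(t -
tmax)))`` and the acceptor model ``Va(t) = Va0 + (Vamax - Va0) exp(Ra(t -
tmax))`` with ``Vamax = Va0 + Vd0`` (conservation) and, for single-event
physics, ``Ra = Rd``. During transfer the donor stays tangent to its
acceptor so that the masks remain in contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .kinetics import acceptor_volume, donor_volume
from .stack import TimelapseStack

__all__ = [
    "GroundTruthEvent",
    "StaticLD",
    "SimulationConfig",
    "SurfacePairSpec",
    "SurfacePairTruth",
    "generate_timelapse",
    "generate_surface_pair",
    "generate_sphere_sections",
    "simulate_event_traces",
]


def _radius_from_volume(v: np.ndarray | float) -> np.ndarray | float:
    return (3.0 * np.asarray(v) / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class GroundTruthEvent:
    """One donor/acceptor transfer event with known kinetics.

    Centers are (x, y, z) in µm at frame 0; volumes in µm³; rates in 1/s;
    times in s. ``Vamax = Va0 + Vd0`` is enforced (volume conservation
    across the pair). ``Ra`` defaults to ``Rd``; setting it differently is
    only meaningful for fixtures that exercise the multi-transfer filter
    and breaks per-frame conservation by construction.
    """

    donor_center: tuple[float, float, float]
    acceptor_center: tuple[float, float, float]
    Vd0: float
    Va0: float
    Rd: float
    t_contact: float
    tmax: float
    Ra: float | None = None

    def __post_init__(self) -> None:
        if self.Vd0 <= 0 or self.Va0 <= 0:
            raise ValueError("Vd0 and Va0 must be positive")
        if self.Rd <= 0:
            raise ValueError("Rd must be positive")
        if not self.t_contact < self.tmax:
            raise ValueError("t_contact must precede tmax")
        if self.Ra is None:
            self.Ra = self.Rd
        elif self.Ra <= 0:
            raise ValueError("Ra must be positive")

    @property
    def Vamax(self) -> float:
        return self.Va0 + self.Vd0

    def donor_volume_at(self, t: float) -> float:
        """True donor volume (µm³); constant before contact, 0 after tmax."""
        t_eff = max(t, self.t_contact)
        if t_eff >= self.tmax:
            return 0.0
        return float(donor_volume(t_eff, self.Vd0, self.Rd, self.tmax))

    def acceptor_volume_at(self, t: float) -> float:
        t_eff = max(t, self.t_contact)
        if t_eff >= self.tmax:
            return self.Vamax
        return float(acceptor_volume(t_eff, self.Va0, self.Vamax, self.Ra, self.tmax))


@dataclass
class StaticLD:
    """A droplet with constant volume, not involved in any event."""

    center: tuple[float, float, float]
    volume: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")


@dataclass
class SimulationConfig:
    """Acquisition and optics parameters of a synthetic movie.

    Defaults mirror confocal live imaging of LipidTOX-stained LDs: 0.12 µm
    pixels, 0.4 µm z sections, frames every 20 s. ``photon_scale`` is the
    expected photon count per unit fluorophore density (a solid LD has
    density 1); shot noise is Poisson on ``photon_scale * signal +
    background_level`` with additive Gaussian read noise.
    """

    image_shape: tuple[int, int, int]  # (z, y, x) voxels
    voxel_size_xy: float = 0.12  # µm
    voxel_size_z: float = 0.4  # µm
    frame_interval: float = 20.0  # s
    n_frames: int = 40
    psf_sigma: float = 0.15  # µm, isotropic-equivalent blur
    photon_scale: float = 200.0
    read_noise_sd: float = 2.0
    background_level: float = 10.0
    shot_noise: bool = True
    rng_seed: int = 0
    events: list[GroundTruthEvent] = field(default_factory=list)
    static_lds: list[StaticLD] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.image_shape) != 3 or any(s <= 0 for s in self.image_shape):
            raise ValueError("image_shape must be three positive sizes (z, y, x)")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if min(self.voxel_size_xy, self.voxel_size_z, self.frame_interval) <= 0:
            raise ValueError("voxel sizes and frame interval must be positive")
        if self.voxel_size_z < self.voxel_size_xy:
            raise ValueError(
                "voxel_size_z < voxel_size_xy: z sections are coarser than "
                "pixels in this acquisition geometry"
            )
        if self.psf_sigma < 0 or self.read_noise_sd < 0 or self.background_level < 0:
            raise ValueError("psf_sigma, read_noise_sd, background_level must be >= 0")

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical field of view (z, y, x) in µm."""
        nz, ny, nx = self.image_shape
        return (nz * self.voxel_size_z, ny * self.voxel_size_xy, nx * self.voxel_size_xy)

    @property
    def voxel_size_zyx(self) -> tuple[float, float, float]:
        return (self.voxel_size_z, self.voxel_size_xy, self.voxel_size_xy)


# ---------------------------------------------------------------------------
# time-lapse generation
# ---------------------------------------------------------------------------


def _ld_states(config: SimulationConfig, t: float) -> list[dict]:
    """True (center, volume) of every LD alive at time t.

    Donor centers track tangency: before contact the donor drifts linearly
    from its initial position onto the tangent point, and during transfer it
    stays tangent to the acceptor while both radii change.
    """
    states: list[dict] = []
    for j, ld in enumerate(config.static_lds):
        states.append(
            {"ld_id": f"static{j}", "role": "static", "event": -1,
             "center": np.asarray(ld.center, float), "volume": ld.volume}
        )
    for i, ev in enumerate(config.events):
        a_center = np.asarray(ev.acceptor_center, float)
        va = ev.acceptor_volume_at(t)
        states.append(
            {"ld_id": f"e{i}_acceptor", "role": "acceptor", "event": i,
             "center": a_center, "volume": va}
        )
        vd = ev.donor_volume_at(t)
        if vd <= 0:
            continue
        ra = _radius_from_volume(va)
        rd = _radius_from_volume(vd)
        d0 = np.asarray(ev.donor_center, float)
        sep0 = d0 - a_center
        dist0 = float(np.linalg.norm(sep0))
        if dist0 == 0:
            raise ValueError("donor and acceptor centers coincide")
        u = sep0 / dist0
        rd0 = _radius_from_volume(ev.donor_volume_at(ev.t_contact - 1e-9))
        ra0 = _radius_from_volume(ev.acceptor_volume_at(ev.t_contact - 1e-9))
        gap0 = dist0 - (rd0 + ra0)
        if gap0 < -1e-9:
            raise ValueError(
                f"event {i}: donor and acceptor overlap before contact "
                f"(gap {gap0:.3f} µm)"
            )
        if t < ev.t_contact and ev.t_contact > 0:
            gap = gap0 * max(0.0, (ev.t_contact - t) / ev.t_contact)
        else:
            gap = 0.0
        center = a_center + u * (ra + rd + gap)
        states.append(
            {"ld_id": f"e{i}_donor", "role": "donor", "event": i,
             "center": center, "volume": vd}
        )
    return states


def _rasterize_sphere(
    density: np.ndarray,
    center_um: np.ndarray,
    radius_um: float,
    voxel_zyx: tuple[float, float, float],
    supersample: int = 3,
) -> None:
    """Add a solid sphere of unit density into `density` (z, y, x array).

    A voxel's value is the sphere-voxel overlap fraction estimated by
    `supersample`³ subsamples per voxel (accurate to ~1%). `center_um` is
    (x, y, z) in µm.
    """
    cz, cy, cx = center_um[2], center_um[1], center_um[0]
    centers = (cz, cy, cx)
    s = supersample
    lo, hi, axes_sub = [], [], []
    for ax, (c, v, n) in enumerate(zip(centers, voxel_zyx, density.shape)):
        i0 = max(int(np.floor((c - radius_um) / v)) - 1, 0)
        i1 = min(int(np.ceil((c + radius_um) / v)) + 1, n - 1)
        if i1 < i0:
            return
        lo.append(i0)
        hi.append(i1)
        idx = np.arange(i0, i1 + 1)
        # subsample coordinates within each voxel, in µm, offset from center
        sub = (idx[:, None] + (np.arange(s)[None, :] + 0.5) / s) * v - c
        axes_sub.append(sub**2)
    dz2 = axes_sub[0][:, :, None, None, None, None]
    dy2 = axes_sub[1][None, None, :, :, None, None]
    dx2 = axes_sub[2][None, None, None, None, :, :]
    inside = (dz2 + dy2 + dx2) <= radius_um**2
    frac = inside.mean(axis=(1, 3, 5))
    density[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += frac


def _validate_geometry(config: SimulationConfig, states: list[dict], t: float) -> None:
    ez, ey, ex = config.extent_um
    margin = 2.0 * config.psf_sigma
    partners = {
        (f"e{i}_donor", f"e{i}_acceptor") for i in range(len(config.events))
    }
    for st in states:
        r = float(_radius_from_volume(st["volume"]))
        x, y, z = st["center"]
        if not (
            r + margin <= x <= ex - r - margin
            and r + margin <= y <= ey - r - margin
            and r + margin <= z <= ez - r - margin
        ):
            raise ValueError(
                f"LD {st['ld_id']} leaves the field of view at t={t:.0f} s "
                f"(needs margin {margin:.2f} µm)"
            )
    for i, a in enumerate(states):
        for b in states[i + 1 :]:
            pair = (a["ld_id"], b["ld_id"])
            if pair in partners or pair[::-1] in partners:
                continue
            d = float(np.linalg.norm(a["center"] - b["center"]))
            if d < _radius_from_volume(a["volume"]) + _radius_from_volume(b["volume"]):
                raise ValueError(
                    f"non-partner LDs {pair[0]} and {pair[1]} overlap at t={t:.0f} s"
                )


def generate_timelapse(
    config: SimulationConfig,
) -> tuple[TimelapseStack, pd.DataFrame]:
    """Render a movie of transferring LD pairs plus its truth table.

    Returns
    -------
    stack
        Float32 ``(t, z, y, x)`` stack with calibration metadata.
    truth
        One row per (frame, live LD): ``frame, time_s, ld_id, role,
        event_index, x_um, y_um, z_um, volume_um3, radius_um``. For every
        donor/acceptor pair with ``Ra == Rd`` the two volumes sum to
        ``Vd0 + Va0`` in every frame.
    """
    rng = np.random.default_rng(config.rng_seed)
    nz, ny, nx = config.image_shape
    sigma_vox = (
        config.psf_sigma / config.voxel_size_z,
        config.psf_sigma / config.voxel_size_xy,
        config.psf_sigma / config.voxel_size_xy,
    )
    frames = np.empty((config.n_frames, nz, ny, nx), dtype=np.float32)
    rows: list[dict] = []
    for fi, t in enumerate(config.timestamps):
        states = _ld_states(config, t)
        _validate_geometry(config, states, t)
        density = np.zeros((nz, ny, nx), dtype=np.float64)
        for st in states:
            r = float(_radius_from_volume(st["volume"]))
            _rasterize_sphere(density, st["center"], r, config.voxel_size_zyx)
            rows.append(
                {
                    "frame": fi,
                    "time_s": t,
                    "ld_id": st["ld_id"],
                    "role": st["role"],
                    "event_index": st["event"],
                    "x_um": st["center"][0],
                    "y_um": st["center"][1],
                    "z_um": st["center"][2],
                    "volume_um3": st["volume"],
                    "radius_um": r,
                }
            )
        if config.psf_sigma > 0:
            density = gaussian_filter(density, sigma_vox, mode="constant")
        expected = config.photon_scale * density + config.background_level
        if config.shot_noise:
            img = rng.poisson(expected).astype(np.float64)
        else:
            img = expected
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
        frames[fi] = img.astype(np.float32)
    stack = TimelapseStack(
        data=frames,
        voxel_size_xy=config.voxel_size_xy,
        voxel_size_z=config.voxel_size_z,
        timestamps=config.timestamps,
        metadata={"rng_seed": config.rng_seed, "synthetic": True},
    )
    truth = pd.DataFrame(rows)
    return stack, truth


# ---------------------------------------------------------------------------
# analytic surface pairs (monolayer-trace fixtures)
# ---------------------------------------------------------------------------

_GEOMETRIES = ("parallel-planes", "concentric-spheres", "sinusoidally-perturbed-planes")


@dataclass
class SurfacePairSpec:
    """Two apposed analytic surfaces sampled like manual monolayer traces.

    All lengths in nm. ``control_point_z_spacing`` emulates tracing every
    few virtual slices (tomographic voxels are 0.71-0.75 nm in z).
    """

    geometry_kind: str = "parallel-planes"
    nominal_separation: float = 10.0
    extent: float = 200.0
    control_point_z_spacing: float = 5.0
    n_points_per_slice: int = 25
    perturbation_amplitude: float = 0.0
    sphere_radius: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry_kind not in _GEOMETRIES:
            raise ValueError(
                f"unknown geometry_kind {self.geometry_kind!r}; one of {_GEOMETRIES}"
            )
        if self.nominal_separation <= 0 or self.control_point_z_spacing <= 0:
            raise ValueError("separation and z spacing must be positive")
        if self.extent <= 0 or self.n_points_per_slice < 2:
            raise ValueError("extent must be positive, >=2 points per slice")


@dataclass
class SurfacePairTruth:
    """True inter-surface separation, defined at every position."""

    geometry_kind: str
    nominal_separation: float

    def distance_at(self, points: np.ndarray) -> np.ndarray:
        """True separation (nm) at an (N, 3) array of positions."""
        return np.full(np.asarray(points).shape[0], self.nominal_separation)


def _trace_frame(surface_id: str, pts: list[tuple[float, float, float]]) -> pd.DataFrame:
    df = pd.DataFrame(pts, columns=["x_nm", "y_nm", "z_nm"])
    df.insert(0, "surface_id", surface_id)
    df["point_index"] = df.groupby("z_nm").cumcount()
    return df


def generate_surface_pair(
    spec: SurfacePairSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, SurfacePairTruth]:
    """Sample control points from each surface of an analytic pair.

    Returns two control-point tables (``surface_id, x_nm, y_nm, z_nm,
    point_index``; points ordered within each z slice) and the analytic
    truth. For the perturbed-planes geometry both surfaces carry the same
    smooth random corrugation, so the true separation stays at the nominal
    value while the traces are wavy.
    """
    rng = np.random.default_rng(spec.rng_seed)
    sep = spec.nominal_separation
    pts_a: list[tuple[float, float, float]] = []
    pts_b: list[tuple[float, float, float]] = []

    if spec.geometry_kind in ("parallel-planes", "sinusoidally-perturbed-planes"):
        zs = np.arange(0.0, spec.extent + 1e-9, spec.control_point_z_spacing)
        xs = np.linspace(0.0, spec.extent, spec.n_points_per_slice)
        if spec.geometry_kind == "sinusoidally-perturbed-planes":
            # smooth corrugation: a few random low-frequency sinusoids
            k = 2.0 * math.pi / spec.extent
            coef = rng.normal(size=(3, 4))

            def bump(x, z):
                out = np.zeros_like(np.asarray(x, float))
                for m in range(3):
                    out += coef[m, 0] * np.sin((m + 1) * k * x + coef[m, 1]) * np.sin(
                        (m + 1) * k * z + coef[m, 2]
                    )
                norm = np.abs(coef[:, 0]).sum() or 1.0
                return spec.perturbation_amplitude * out / norm

        else:

            def bump(x, z):
                return np.zeros_like(np.asarray(x, float))

        for z in zs:
            b = bump(xs, z)
            pts_a.extend(zip(xs, b, np.full_like(xs, z)))
            pts_b.extend(zip(xs, b + sep, np.full_like(xs, z)))
    else:  # concentric-spheres
        r_in, r_out = spec.sphere_radius, spec.sphere_radius + sep
        z_half = min(spec.extent / 2.0, 0.7 * r_in)
        zs = np.arange(-z_half, z_half + 1e-9, spec.control_point_z_spacing)
        theta = np.linspace(-math.pi / 3, math.pi / 3, spec.n_points_per_slice)
        for z in zs:
            for pts, R in ((pts_a, r_in), (pts_b, r_out)):
                rho = math.sqrt(R**2 - z**2)
                pts.extend(zip(rho * np.cos(theta), rho * np.sin(theta), np.full_like(theta, z)))

    trace_a = _trace_frame("A", pts_a)
    trace_b = _trace_frame("B", pts_b)
    return trace_a, trace_b, SurfacePairTruth(spec.geometry_kind, sep)


# ---------------------------------------------------------------------------
# sphere cross-sections
# ---------------------------------------------------------------------------


def generate_sphere_sections(
    R: float, h1: float, z_spacing: float
) -> tuple[float, float, float]:
    """Circle radii of two sphere cross-sections spaced by ``z_spacing``.

    Slicing a sphere of radius ``R`` (nm) at heights ``h1`` and
    ``h1 + z_spacing`` above the equator yields circles of radii
    ``a = sqrt(R² - h1²)`` and ``b = sqrt(R² - (h1 + z_spacing)²)`` —
    the measurements from which the sphere radius is recovered.
    """
    if R <= 0 or z_spacing <= 0:
        raise ValueError("R and z_spacing must be positive")
    if abs(h1) + z_spacing >= R:
        raise ValueError("section planes must lie strictly inside the sphere")
    a = math.sqrt(R**2 - h1**2)
    b = math.sqrt(R**2 - (h1 + z_spacing) ** 2)
    return a, b, z_spacing


def standard_transfer_movie(seed: int = 0, n_events: int = 5) -> SimulationConfig:
    """A benchmark movie: several independent transfer events in one field.

    Five (by default) donor/acceptor pairs are laid out on a grid in a
    16 x 160 x 160-voxel field (0.12 µm pixels, 0.4 µm sections, 20-s
    frames, 40 frames). Rate constants are log-uniform in 0.006-0.02 /s,
    donor volumes 1.5-4 µm³, acceptors 4-8 µm³; completion times spread
    over the second half of the movie. Event order and parameters are
    drawn from ``seed``.
    """
    if not 1 <= n_events <= 6:
        raise ValueError("layout supports 1-6 events")
    rng = np.random.default_rng(seed)
    slots = [(y, x) for y in (4.8, 14.4) for x in (3.6, 9.6, 15.6)]
    rng.shuffle(slots)
    frame_interval = 20.0
    tmax_frames = rng.choice(np.arange(24, 38), size=n_events, replace=False)
    events = []
    for k in range(n_events):
        y, x = slots[k]
        rd = float(np.exp(rng.uniform(np.log(0.006), np.log(0.02))))
        vd0 = float(rng.uniform(1.5, 4.0))
        va0 = float(rng.uniform(4.0, 8.0))
        tmax = float(tmax_frames[k]) * frame_interval
        t_contact = max(100.0, tmax - min(3.5 / rd, 480.0))
        t_contact = round(t_contact / frame_interval) * frame_interval
        rd0 = float(_radius_from_volume(vd0))
        ra0 = float(_radius_from_volume(va0))
        side = 1.0 if y < 9.0 else -1.0  # donors point into the central corridor
        donor_y = y + side * (rd0 + ra0 + 1.0)
        events.append(
            GroundTruthEvent(
                donor_center=(x, donor_y, 3.2),
                acceptor_center=(x, y, 3.2),
                Vd0=vd0, Va0=va0, Rd=rd,
                t_contact=t_contact, tmax=tmax,
            )
        )
    return SimulationConfig(
        image_shape=(16, 160, 160),
        n_frames=40,
        events=events,
        rng_seed=int(rng.integers(2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# volume-trace cohorts (no imaging; fitting-stage inputs)
# ---------------------------------------------------------------------------


def simulate_event_traces(
    n_events: int,
    *,
    rd_range: tuple[float, float] = (0.002, 0.022),
    frame_interval: float = 20.0,
    volume_noise_frac: float = 0.05,
    vd0_range: tuple[float, float] = (1.0, 10.0),
    ra_equals_rd: bool = True,
    rng: np.random.Generator | int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy measured volume traces for a cohort of transfer events.

    Rd is log-uniform over ``rd_range`` (the observed physiological range of
    donor rate constants); Vd0 log-uniform over ``vd0_range`` µm³; the
    acceptor starts 1-4x the donor volume. Each event is observed every
    ``frame_interval`` s over a window ending at tmax whose length covers
    the informative part of the exponential (about 4/Rd, clipped to 8-80
    samples). Measured volumes carry multiplicative Gaussian noise of
    fractional SD ``volume_noise_frac``, emulating segmentation-level
    volumetric error at typical imaging SNR.

    Returns ``(traces, truth)``: traces has columns ``event_id, time_s,
    donor_volume_um3, acceptor_volume_um3, tmax_s``; truth one row per event
    with the generating parameters.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    lo, hi = rd_range
    trace_rows = []
    truth_rows = []
    for i in range(n_events):
        rd = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        vd0 = float(np.exp(rng.uniform(*np.log(vd0_range))))
        va0 = vd0 * float(rng.uniform(1.0, 4.0))
        ra = rd if ra_equals_rd else rd * float(np.exp(rng.normal(0.0, 0.5)))
        n_obs = int(np.clip(round(4.0 / rd / frame_interval), 8, 80))
        tmax = n_obs * frame_interval
        t = np.arange(n_obs) * frame_interval  # last sample one frame before tmax
        vd = donor_volume(t, vd0, rd, tmax)
        va = acceptor_volume(t, va0, va0 + vd0, ra, tmax)
        vd_obs = np.clip(vd * (1.0 + volume_noise_frac * rng.standard_normal(n_obs)), 0.0, None)
        va_obs = np.clip(va * (1.0 + volume_noise_frac * rng.standard_normal(n_obs)), 0.0, None)
        truth_rows.append(
            {"event_id": i, "Vd0": vd0, "Va0": va0, "Vamax": va0 + vd0,
             "Rd": rd, "Ra": ra, "tmax_s": tmax}
        )
        for ts, d, a in zip(t, vd_obs, va_obs):
            trace_rows.append(
                {"event_id": i, "time_s": ts, "donor_volume_um3": d,
                 "acceptor_volume_um3": a, "tmax_s": tmax}
            )
    return pd.DataFrame(trace_rows), pd.DataFrame(truth_rows)
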