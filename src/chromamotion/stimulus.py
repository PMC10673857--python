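"""Visual stimulus generation and display calibration.

Two stimulus families are rendered onto a regular azimuth × elevation
angular grid as two-channel (UV, green) frame stacks:

* **Expanding discs** — an object of radius *r* approaching at constant
  speed *v* subtends a half-angle θ(t) = arctan((r/v) / t_c), where t_c is
  the time remaining to collision.  With r/v = 120 ms the disc grows from
  θ ≈ 6.8° one second before collision to 90° (full display) at collision.
  Either a UV disc expands over a calibrated green background, or a green
  disc expands over a UV background (the screen switching from green to UV
  at stimulus onset).

* **Competing ON/OFF edges** — the display is split into windows of equal
  angular width; within every window a green edge and a UV edge sweep in
  opposite directions, filling the window once per cycle (30° in 250 ms =
  120 °/s, 4 Hz).  The OFF variant is the ON frame sequence played in
  reverse temporal order within each cycle; counterclockwise stimuli are
  the clockwise frames mirrored about the vertical axis.

UV intensities are 4-bit integers (0–15).  The green channel is never an
independent variable: its value at every display location comes from a
calibration mask built so that green irradiance equals a fixed scalar
(default 2.3) times the UV irradiance at that location, compensating the
wavelength-dependent scatter of the projection screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "DiscSpec",
    "EdgeSpec",
    "FrameSet",
    "CalibrationMap",
    "disc_half_angle",
    "render_disc",
    "render_competing_edges",
    "build_green_mask",
    "default_display_grid",
]

UV_MAX = 15


def _check_uv_level(level, name="uv_level"):
    if not (0 <= level <= UV_MAX):
        raise ValueError(f"{name} must be in 0..{UV_MAX}, got {level}")


@dataclass(frozen=True)
class DiscSpec:
    """Geometry and chromatic configuration of one expanding disc.

    ``uv_level`` is the disc intensity for UV-on-green discs and the
    *background* intensity for green-on-UV discs (the green disc itself is
    fixed by the calibration mask).
    """

    r_over_v: float = 0.120          # s; radius-to-speed ratio of the approach
    center_azimuth: float = 60.0     # deg
    center_elevation: float = 0.0    # deg
    start_half_angle: float = 6.8    # deg
    disc_channel: str = "UV_on_green"
    uv_level: int = 15
    expansion_duration: float = 1.0  # s
    hold_duration: float = 1.0       # s

    def __post_init__(self):
        if self.r_over_v <= 0:
            raise ValueError("r_over_v must be positive")
        if self.expansion_duration <= 0:
            raise ValueError("expansion_duration must be positive")
        if self.hold_duration < 0:
            raise ValueError("hold_duration must be non-negative")
        if self.disc_channel not in ("UV_on_green", "green_on_UV"):
            raise ValueError(f"unknown disc_channel {self.disc_channel!r}")
        _check_uv_level(self.uv_level)


@dataclass(frozen=True)
class EdgeSpec:
    """Competing ON/OFF edge stimulus parameters."""

    window_width: float = 30.0   # deg of azimuth per window
    n_windows: int = 8
    cycle_period: float = 0.25   # s per edge sweep
    duration: float = 2.0        # s total; integer number of cycles
    polarity: str = "ON"
    rotation: str = "CW"
    uv_level: int = 7

    def __post_init__(self):
        if self.window_width <= 0 or self.n_windows < 1:
            raise ValueError("window_width and n_windows must be positive")
        if self.window_width * self.n_windows > 360.0:
            raise ValueError("windows exceed the full 360 deg azimuth span")
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")
        n_cycles = self.duration / self.cycle_period
        if abs(n_cycles - round(n_cycles)) > 1e-9 or round(n_cycles) < 1:
            raise ValueError("duration must be a positive integer multiple of cycle_period")
        if self.polarity not in ("ON", "OFF"):
            raise ValueError("polarity must be 'ON' or 'OFF'")
        if self.rotation not in ("CW", "CCW"):
            raise ValueError("rotation must be 'CW' or 'CCW'")
        _check_uv_level(self.uv_level)

    @property
    def edge_speed(self) -> float:
        """Angular speed of each edge, deg/s."""
        return self.window_width / self.cycle_period

    @property
    def cycle_frequency(self) -> float:
        """Temporal frequency of the edge sweep, Hz."""
        return 1.0 / self.cycle_period

    @property
    def n_cycles(self) -> int:
        return int(round(self.duration / self.cycle_period))


@dataclass
class FrameSet:
    """Time-ordered two-channel stimulus frames on an angular grid.

    ``uv`` holds integer intensity levels 0–15; ``green`` holds the
    real-valued calibrated mask intensity wherever green is on (0 where it
    is off).  Axis order is (time, azimuth-bin, elevation-bin).
    """

    uv: np.ndarray
    green: np.ndarray
    frame_rate: float
    azimuth: np.ndarray
    elevation: np.ndarray
    channel_labels: tuple[str, str] = ("UV", "green")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.uv = np.asarray(self.uv)
        self.green = np.asarray(self.green, dtype=float)
        if self.uv.shape != self.green.shape or self.uv.ndim != 3:
            raise ValueError("uv and green must be matching (T, A, E) arrays")
        if self.uv.min() < 0 or self.uv.max() > UV_MAX:
            raise ValueError(f"UV values must be integers in 0..{UV_MAX}")

    @property
    def n_frames(self) -> int:
        return self.uv.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class CalibrationMap:
    """Display calibration: UV irradiance grid and matched green mask.

    Sites sample the display in coarse angular steps (10° in the reference
    instrument).  ``green_mask`` is chosen so that modelled green irradiance
    equals ``scale`` × UV irradiance at every site.
    """

    site_azimuth: np.ndarray     # (A,)
    site_elevation: np.ndarray   # (E,)
    uv_irradiance: np.ndarray    # (A, E)
    green_mask: np.ndarray       # (A, E)
    scale: float = 2.3

    def __post_init__(self):
        self.site_azimuth = np.asarray(self.site_azimuth, dtype=float)
        self.site_elevation = np.asarray(self.site_elevation, dtype=float)
        self.uv_irradiance = np.asarray(self.uv_irradiance, dtype=float)
        self.green_mask = np.asarray(self.green_mask, dtype=float)
        shape = (self.site_azimuth.size, self.site_elevation.size)
        if self.uv_irradiance.shape != shape or self.green_mask.shape != shape:
            raise ValueError("irradiance/mask grids must be (n_az_sites, n_el_sites)")

    @classmethod
    def uniform(cls, uv_irradiance=1.0, scale=2.3,
                azimuth_range=(-120.0, 120.0), elevation_range=(-45.0, 45.0),
                step=10.0) -> "CalibrationMap":
        """Spatially uniform calibration (handy default for synthetic work)."""
        az = np.arange(azimuth_range[0], azimuth_range[1] + step / 2, step)
        el = np.arange(elevation_range[0], elevation_range[1] + step / 2, step)
        uv = np.full((az.size, el.size), float(uv_irradiance))
        return cls(az, el, uv, scale * uv, scale)

    def green_at(self, azimuth, elevation) -> np.ndarray:
        """Green mask intensity at arbitrary angles via nearest-site lookup."""
        az = np.asarray(azimuth, dtype=float)
        el = np.asarray(elevation, dtype=float)
        ia = np.abs(az[..., None] - self.site_azimuth).argmin(axis=-1)
        ie = np.abs(el[..., None] - self.site_elevation).argmin(axis=-1)
        return self.green_mask[ia, ie]


def build_green_mask(uv_irradiance, scale=2.3, site_azimuth=None, site_elevation=None,
                     green_response=None) -> tuple[CalibrationMap, np.ndarray]:
    """Construct the green luminance mask matching a UV irradiance grid.

    Under a linear display model (``green irradiance = green_response ×
    mask value``, response defaulting to 1 per site), the mask value is
    chosen so the achieved green irradiance is ``scale`` × UV irradiance at
    every site.  Returns the calibration map and the residual ratio grid
    (achieved green / UV irradiance) for QC; under the linear model the
    ratio equals ``scale`` to rounding error.
    """
    uv = np.asarray(uv_irradiance, dtype=float)
    if uv.ndim != 2:
        raise ValueError("uv_irradiance must be a 2-D site grid")
    if np.any(uv <= 0):
        raise ValueError("UV irradiance must be positive at every site")
    if scale <= 0:
        raise ValueError("scale must be positive")
    response = np.ones_like(uv) if green_response is None else np.asarray(green_response, dtype=float)
    if np.any(response <= 0):
        raise ValueError("green response must be positive at every site")
    mask = scale * uv / response
    achieved = mask * response
    ratio = achieved / uv
    if site_azimuth is None:
        site_azimuth = np.arange(uv.shape[0], dtype=float) * 10.0
    if site_elevation is None:
        site_elevation = np.arange(uv.shape[1], dtype=float) * 10.0
    return CalibrationMap(site_azimuth, site_elevation, uv, mask, scale), ratio


def disc_half_angle(r_over_v, time_to_collision):
    """Half-angle (deg) subtended by a constant-velocity approaching disc.

    θ = arctan(r/v ÷ t_c); the collision limit t_c = 0 returns 90°.
    Accepts scalar or array ``time_to_collision``.
    """
    if r_over_v <= 0:
        raise ValueError("r_over_v must be positive")
    ttc = np.asarray(time_to_collision, dtype=float)
    if np.any(ttc < 0):
        raise ValueError("time_to_collision must be non-negative")
    with np.errstate(divide="ignore"):
        theta = np.degrees(np.arctan(r_over_v / ttc))
    theta = np.where(ttc == 0, 90.0, theta)
    return float(theta) if np.isscalar(time_to_collision) else theta


def default_display_grid(bin_size=1.0, azimuth_range=(-20.0, 100.0),
                         elevation_range=(-50.0, 50.0)):
    """Bin-center angular grid of the imaging display span (1°/bin default)."""
    az = np.arange(azimuth_range[0], azimuth_range[1], bin_size) + bin_size / 2
    el = np.arange(elevation_range[0], elevation_range[1], bin_size) + bin_size / 2
    return az, el


def _angular_distance(az_grid, el_grid, az0, el0):
    """Great-circle distance (deg) from (az0, el0) to every grid bin."""
    az = np.radians(az_grid)[:, None]
    el = np.radians(el_grid)[None, :]
    a0, e0 = np.radians(az0), np.radians(el0)
    cosd = np.sin(el) * np.sin(e0) + np.cos(el) * np.cos(e0) * np.cos(az - a0)
    return np.degrees(np.arccos(np.clip(cosd, -1.0, 1.0)))


def render_disc(spec: DiscSpec, calib: CalibrationMap, frame_rate=60.0,
                azimuth=None, elevation=None, green_multiplier=1.0) -> FrameSet:
    """Render an expanding-disc stimulus as a two-channel frame stack.

    A grid bin belongs to the disc iff its great-circle angular distance to
    the disc center is at most the current half-angle; the half-angle time
    course places collision at the end of the expansion, so frame k (of n)
    shows θ evaluated at t_c = duration − (k+1)/rate and the last expansion
    frame (t_c = 0, θ = 90°) covers the whole display.  The final frame is
    then held for ``hold_duration``.  For green-on-UV discs the background
    is UV (at ``spec.uv_level``) and the disc is calibrated green.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if azimuth is None or elevation is None:
        azimuth, elevation = default_display_grid()
    azimuth = np.asarray(azimuth, dtype=float)
    elevation = np.asarray(elevation, dtype=float)
    step = max(
        np.diff(azimuth).max() if azimuth.size > 1 else 0.0,
        np.diff(elevation).max() if elevation.size > 1 else 0.0,
    )
    if 2 * spec.start_half_angle < step:
        raise ValueError(
            f"grid spacing {step}° too coarse to represent a "
            f"{spec.start_half_angle}° starting half-angle"
        )

    n_exp = int(round(spec.expansion_duration * frame_rate))
    if n_exp < 1:
        raise ValueError("expansion shorter than one frame")
    n_hold = int(round(spec.hold_duration * frame_rate))
    ttc = np.maximum(spec.expansion_duration - (np.arange(n_exp) + 1) / frame_rate, 0.0)
    half_angles = disc_half_angle(spec.r_over_v, ttc)

    dist = _angular_distance(azimuth, elevation, spec.center_azimuth, spec.center_elevation)
    green_bg = calib.green_at(*np.meshgrid(azimuth, elevation, indexing="ij")) * green_multiplier

    shape = (n_exp + n_hold, azimuth.size, elevation.size)
    uv = np.zeros(shape, dtype=np.int16)
    green = np.zeros(shape, dtype=float)
    for k in range(n_exp):
        # θ ≥ 90° means the disc has passed the display plane: full coverage.
        in_disc = np.ones_like(dist, bool) if half_angles[k] >= 90.0 else dist <= half_angles[k]
        if spec.disc_channel == "UV_on_green":
            uv[k][in_disc] = spec.uv_level
            green[k] = np.where(in_disc, 0.0, green_bg)
        else:  # green disc on UV background, screen switched to UV at onset
            uv[k] = np.where(in_disc, 0, spec.uv_level)
            green[k] = np.where(in_disc, green_bg, 0.0)
    uv[n_exp:] = uv[n_exp - 1]
    green[n_exp:] = green[n_exp - 1]

    meta = {"spec": asdict(spec), "kind": "disc",
            "half_angles": np.concatenate([half_angles, np.full(n_hold, 90.0)])}
    return FrameSet(uv, green, frame_rate, azimuth, elevation, meta=meta)


def render_competing_edges(spec: EdgeSpec, calib: CalibrationMap, frame_rate=60.0,
                           elevation=None, green_multiplier=1.0) -> FrameSet:
    """Render the competing green/UV edge stimulus.

    The azimuth grid spans the windowed region (``n_windows × window_width``
    degrees, centered on 0) at 1°/bin; windows are defined in angular
    coordinates, i.e. already perspective-corrected.  In each clockwise ON
    cycle a green edge grows rightward from the left window border while a
    UV edge grows leftward from the right border, both filling the window
    at the end of the cycle.  OFF frames are the ON frames of each cycle in
    reverse temporal order; CCW frames are the CW frames mirrored in
    azimuth.  Both identities are exact by construction.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    n_per_cycle = spec.cycle_period * frame_rate
    if abs(n_per_cycle - round(n_per_cycle)) > 1e-9 or round(n_per_cycle) < 1:
        raise ValueError("cycle_period must span an integer number of frames")
    n_per_cycle = int(round(n_per_cycle))

    total_az = spec.window_width * spec.n_windows
    azimuth = np.arange(-total_az / 2, total_az / 2, 1.0) + 0.5
    if elevation is None:
        elevation = default_display_grid()[1]
    elevation = np.asarray(elevation, dtype=float)

    rel = (azimuth + total_az / 2) % spec.window_width  # position within own window
    green_bg = calib.green_at(*np.meshgrid(azimuth, elevation, indexing="ij")) * green_multiplier

    filled = (np.arange(n_per_cycle) + 1) / n_per_cycle  # fraction swept per frame
    cycle_uv = np.zeros((n_per_cycle, azimuth.size, elevation.size), dtype=np.int16)
    cycle_green = np.zeros_like(cycle_uv, dtype=float)
    for k, f in enumerate(filled):
        green_on = rel < f * spec.window_width             # green edge from the left
        uv_on = rel >= (1.0 - f) * spec.window_width       # UV edge from the right
        cycle_uv[k][uv_on, :] = spec.uv_level
        cycle_green[k][green_on, :] = green_bg[green_on, :]

    if spec.polarity == "OFF":
        cycle_uv = cycle_uv[::-1]
        cycle_green = cycle_green[::-1]

    uv = np.tile(cycle_uv, (spec.n_cycles, 1, 1))
    green = np.tile(cycle_green, (spec.n_cycles, 1, 1))

    if spec.rotation == "CCW":
        uv = uv[:, ::-1, :]
        green = green[:, ::-1, :]

    meta = {"spec": asdict(spec), "kind": "edges", "n_frames_per_cycle": n_per_cycle}
    return FrameSet(np.ascontiguousarray(uv), np.ascontiguousarray(green),
                    frame_rate, azimuth, elevation, meta=meta)
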