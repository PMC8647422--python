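"""Digital 4D flow jet phantom with known regurgitant ground truth.

The generator emulates the situation the quantification pipeline is built
for: an atrial chamber region containing an eccentric regurgitant jet that
is active over a mid-to-late-systolic window, embedded in velocity noise,
with acquisition parameters (voxel size, temporal resolution, VENC) in the
range typical of clinical 4D flow CMR. A matched digital ventricle/aorta
pair is generated for the indirect volumetric comparator.

The jet is modeled as a straight cylinder of finite length emanating from
the regurgitant orifice, carrying a half-sine orifice flow-rate curve

    Q(t) = Q_max * sin(pi * (t - onset) / (offset - onset)),

whose closed-form time integral 2 * Q_max * T / pi is scaled to a target
regurgitant volume. The cross-sectional velocity profile is a top-hat or a
(truncated) Gaussian; no attempt is made at Navier-Stokes realism — the
phantom exists so that parameter recovery can be measured against an exact
truth, not to model hemodynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .io import FlowCurve, VelocityField4D, VolumeCurve

__all__ = [
    "JetSpec",
    "PhantomConfig",
    "JetTruth",
    "PhantomTruth",
    "generate_jet_phantom",
    "wrap_velocities",
    "generate_indirect_inputs",
]

#: Gaussian profiles are truncated at 3 sigma; fraction of an infinite
#: Gaussian's flux inside that radius, used to normalize the amplitude.
_GAUSS_TRUNC = 1.0 - math.exp(-4.5)


@dataclass
class JetSpec:
    """Geometry and flow program of a single regurgitant jet.

    ``target_volume`` (mL) is the authoritative flow scale; if
    ``peak_flow_rate`` (mL/s) is given instead, the volume is derived from
    the half-sine closed form 2*Qmax*T/pi.
    """

    orifice_center: tuple[float, float, float] = (30.0, 30.0, 22.0)  # mm
    axis: np.ndarray = dc_field(default_factory=lambda: np.array([1.0, 1.0, 2.0]))
    onset_ms: float = 210.0
    offset_ms: float = 550.0
    target_volume: float | None = 16.0
    peak_flow_rate: float | None = None
    core_radius: float = 4.4  # mm (Gaussian profile: 2 sigma)
    length_mm: float = 30.0
    #: the core extends this far beyond both ends of the tracked segment so
    #: that a plane through any in-segment peak samples fully developed flow
    overshoot_mm: float = 6.0
    profile: str = "tophat"  # or "gaussian"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if self.axis.ndim == 1:
            n = np.linalg.norm(self.axis)
            if n == 0:
                raise ValueError("jet axis must be nonzero")
            self.axis = self.axis / n
        else:  # per-frame axis, normalized row-wise
            norms = np.linalg.norm(self.axis, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError("jet axis must be nonzero in every frame")
            self.axis = self.axis / norms
        if self.offset_ms <= self.onset_ms:
            raise ValueError("jet offset must be strictly after onset")
        if self.profile not in ("tophat", "gaussian"):
            raise ValueError(f"unknown velocity profile {self.profile!r}")
        if self.target_volume is None:
            if self.peak_flow_rate is None:
                raise ValueError("one of target_volume / peak_flow_rate is required")
            self.target_volume = 2.0 * self.peak_flow_rate * self.duration_s / math.pi
        if self.target_volume < 0:
            raise ValueError("target_volume must be nonnegative")

    @property
    def duration_s(self) -> float:
        return (self.offset_ms - self.onset_ms) / 1000.0

    @property
    def qmax(self) -> float:
        """Peak orifice flow rate in mL/s implied by the target volume."""
        return math.pi * self.target_volume / (2.0 * self.duration_s)

    @property
    def peak_core_speed(self) -> float:
        """Peak on-axis velocity in cm/s implied by flow scale and profile."""
        if self.profile == "tophat":
            area = math.pi * self.core_radius**2
            return self.qmax / (0.01 * area)
        sigma = self.core_radius / 2.0
        return self.qmax / (0.01 * 2.0 * math.pi * sigma**2 * _GAUSS_TRUNC)

    def flow_rate(self, t_ms: np.ndarray | float) -> np.ndarray:
        """Orifice flow rate Q(t) in mL/s at time(s) t in ms."""
        t = np.asarray(t_ms, dtype=float)
        phase = (t - self.onset_ms) / (self.offset_ms - self.onset_ms)
        q = self.qmax * np.sin(np.pi * np.clip(phase, 0.0, 1.0))
        return np.where((phase > 0) & (phase < 1), q, 0.0)

    def axis_at(self, frame: int) -> np.ndarray:
        return self.axis if self.axis.ndim == 1 else self.axis[frame]


@dataclass
class PhantomConfig:
    """Study conditions of a synthetic 4D flow dataset.

    Defaults follow a clinical mid-range acquisition: 2.5 mm isotropic
    voxels, 20 frames at 38 ms temporal resolution, VENC 150 cm/s, a
    16 mL eccentric jet active mid-to-late systole, and 5 cm/s additive
    Gaussian velocity noise per component.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    spacing: float | tuple[float, float, float] = 2.5  # mm
    n_frames: int = 20
    frame_spacing: float = 38.0  # ms
    venc: float = 150.0  # cm/s
    jet: JetSpec = dc_field(default_factory=JetSpec)
    second_jet: JetSpec | None = None
    noise_sd: float = 5.0  # cm/s per velocity component
    seed: int = 0
    # digital ventricle/aorta for the indirect comparator
    lv_edv: float = 134.0  # mL
    aortic_forward: float = 79.0  # mL

    def __post_init__(self) -> None:
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * 3
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def frame_times(self) -> np.ndarray:
        """Mid-frame times in ms."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_spacing

    @property
    def cycle_ms(self) -> float:
        return self.n_frames * self.frame_spacing

    def jets(self) -> list[JetSpec]:
        out = [self.jet] if self.jet is not None and self.jet.target_volume > 0 else []
        if self.second_jet is not None and self.second_jet.target_volume > 0:
            out.append(self.second_jet)
        return out


@dataclass
class JetTruth:
    """Per-jet ground truth."""

    orifice_center: np.ndarray
    axis_per_frame: np.ndarray  # (n_frames, 3)
    onset_ms: float
    offset_ms: float
    volume: float  # mL
    flow_curve: FlowCurve
    active_frames: list[int]
    core_radius: float
    profile: str


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom dataset."""

    true_flow_curve: FlowCurve  # total orifice flow rate, densely sampled
    true_volume: float  # mL, analytic
    per_jet: list[JetTruth]
    orifice_center: np.ndarray
    jet_axis_per_frame: np.ndarray
    active_frames: list[int]
    atrial_roi_mask: np.ndarray  # (x, y, z) bool
    static_tissue_mask: np.ndarray  # (x, y, z) bool, disjoint from ROI
    core_mask: np.ndarray  # (t, x, y, z) bool: jet-core voxels per frame
    seed: int
    noise_sd: float


def _voxel_centers_mm(config: PhantomConfig) -> np.ndarray:
    """(nx, ny, nz, 3) physical coordinates of voxel centers."""
    axes = [np.arange(n) * s for n, s in zip(config.grid_shape, config.spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def _segment_distance(points: np.ndarray, center: np.ndarray, axis: np.ndarray,
                      length: float) -> np.ndarray:
    """Distance from each point to the segment center + s*axis, s in [0, length]."""
    d = points - center
    s = np.clip(d @ axis, 0.0, length)
    closest = center + s[..., None] * axis
    return np.linalg.norm(points - closest, axis=-1)


def _check_jet_fits(config: PhantomConfig, jet: JetSpec) -> None:
    if 2.0 * jet.core_radius < 3.0 * min(config.spacing):
        raise ValueError(
            f"core radius {jet.core_radius} mm too small: core diameter must span "
            f">= 3 voxels at spacing {min(config.spacing)} mm"
        )
    extent = np.array(config.grid_shape) * np.array(config.spacing)
    axes = jet.axis[None, :] if jet.axis.ndim == 1 else jet.axis
    for ax in axes:
        for s in (-jet.overshoot_mm, jet.length_mm + jet.overshoot_mm):
            p = np.asarray(jet.orifice_center) + s * ax
            if np.any(p - jet.core_radius < 0) or np.any(p + jet.core_radius > extent):
                raise ValueError("jet exits grid bounds; enlarge grid or move orifice")


def generate_jet_phantom(config: PhantomConfig) -> tuple[VelocityField4D, PhantomTruth]:
    """Generate a seeded 4D flow phantom and its ground truth.

    The returned field is the *unwrapped* truth: core velocities may exceed
    VENC (apply :func:`wrap_velocities` to simulate acquisition aliasing).
    At each active frame the jet core carries a cross-sectional flux equal
    to the analytic orifice flow rate Q(t); everywhere else the mean
    velocity is zero. Gaussian noise of sd ``noise_sd`` is added to every
    component. Deterministic given ``config.seed``.
    """
    jets = config.jets()
    for jet in jets:
        _check_jet_fits(config, jet)

    times = config.frame_times
    shape = (config.n_frames, *config.grid_shape, 3)
    vel = np.zeros(shape, dtype=float)
    core_mask = np.zeros((config.n_frames, *config.grid_shape), dtype=bool)
    points = _voxel_centers_mm(config)

    per_jet: list[JetTruth] = []
    for jet in jets:
        q_frames = jet.flow_rate(times)
        active = [int(i) for i in np.nonzero(q_frames > 0)[0]]
        axis_per_frame = (
            np.tile(jet.axis, (config.n_frames, 1)) if jet.axis.ndim == 1 else jet.axis
        )
        center = np.asarray(jet.orifice_center, dtype=float)
        for i in active:
            ax = axis_per_frame[i]
            d = points - center
            s = d @ ax
            r = np.linalg.norm(d - s[..., None] * ax, axis=-1)
            in_seg = (s >= -jet.overshoot_mm) & (s <= jet.length_mm + jet.overshoot_mm)
            in_track = (s >= 0) & (s <= jet.length_mm)
            if jet.profile == "tophat":
                mask = in_seg & (r <= jet.core_radius)
                amp = q_frames[i] / (0.01 * math.pi * jet.core_radius**2)
                vel[i][mask] += amp * ax
            else:
                sigma = jet.core_radius / 2.0
                mask = in_seg & (r <= 3.0 * sigma)
                v0 = q_frames[i] / (0.01 * 2.0 * math.pi * sigma**2 * _GAUSS_TRUNC)
                prof = v0 * np.exp(-(r[mask] ** 2) / (2.0 * sigma**2))
                vel[i][mask] += prof[:, None] * ax
            core_mask[i] |= in_track & (r <= jet.core_radius)
        dense_t = np.arange(jet.onset_ms, jet.offset_ms + 0.5, 1.0)
        per_jet.append(
            JetTruth(
                orifice_center=center,
                axis_per_frame=axis_per_frame,
                onset_ms=jet.onset_ms,
                offset_ms=jet.offset_ms,
                volume=jet.target_volume,
                flow_curve=FlowCurve(dense_t, jet.flow_rate(dense_t)),
                active_frames=active,
                core_radius=jet.core_radius,
                profile=jet.profile,
            )
        )

    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        vel += rng.normal(0.0, config.noise_sd, size=shape)

    # atrial ROI: a finite sleeve around each jet's tracked segment (no end
    # caps, so the overshoot flow beyond the segment is not detectable);
    # static tissue: far from all jets.
    roi = np.zeros(config.grid_shape, dtype=bool)
    static = np.ones(config.grid_shape, dtype=bool)
    for jet in jets:
        axes = jet.axis[None, :] if jet.axis.ndim == 1 else np.unique(jet.axis, axis=0)
        center = np.asarray(jet.orifice_center, dtype=float)
        for ax in axes:
            d = points - center
            s = d @ ax
            r = np.linalg.norm(d - s[..., None] * ax, axis=-1)
            roi |= (s >= 0) & (s <= jet.length_mm) & (r <= jet.core_radius + 10.0)
            dist = _segment_distance(points, center, ax, jet.length_mm)
            static &= dist >= jet.core_radius + 20.0
    if not jets:
        # no-jet phantom: a central ellipsoidal "atrium" and an outer shell
        extent = np.array(config.grid_shape) * np.array(config.spacing)
        rel = (points - extent / 2.0) / (extent / 4.0)
        roi = np.linalg.norm(rel, axis=-1) <= 1.0
        static = np.linalg.norm(rel, axis=-1) >= 1.6

    dense_t = np.arange(0.0, config.cycle_ms + 0.5, 1.0)
    total_q = np.zeros_like(dense_t)
    for jet in jets:
        total_q += jet.flow_rate(dense_t)
    true_volume = float(sum(j.target_volume for j in jets))
    active_frames = sorted({i for jt in per_jet for i in jt.active_frames})

    field = VelocityField4D(
        velocities=vel,
        spacing=np.asarray(config.spacing),
        frame_times=times,
        venc=config.venc,
    )
    ref = per_jet[0] if per_jet else None
    truth = PhantomTruth(
        true_flow_curve=FlowCurve(dense_t, total_q),
        true_volume=true_volume,
        per_jet=per_jet,
        orifice_center=ref.orifice_center if ref else np.zeros(3),
        jet_axis_per_frame=ref.axis_per_frame if ref else np.zeros((config.n_frames, 3)),
        active_frames=active_frames,
        atrial_roi_mask=roi,
        static_tissue_mask=static,
        core_mask=core_mask,
        seed=config.seed,
        noise_sd=config.noise_sd,
    )
    return field, truth


def wrap_velocities(field: VelocityField4D) -> VelocityField4D:
    """Simulate VENC aliasing: fold every component into [-venc, +venc).

    v -> ((v + venc) mod 2*venc) - venc, applied per voxel/frame/component.
    """
    out = field.copy()
    out.velocities = np.mod(out.velocities + field.venc, 2.0 * field.venc) - field.venc
    return out


def generate_indirect_inputs(
    truth: PhantomTruth, config: PhantomConfig
) -> tuple[VolumeCurve, FlowCurve]:
    """Digital ventricle/aorta pair consistent with the jet truth.

    Constructs an LV volume curve whose stroke volume (EDV - ESV) equals
    the configured aortic forward volume plus the phantom's regurgitant
    volume, and an aortic flow curve whose positive-part trapezoidal
    integral equals the forward volume exactly, so that the indirect
    method (SV minus forward flow) recovers the truth in closed loop.
    """
    if config.aortic_forward <= 0:
        raise ValueError("aortic forward volume must be positive")
    times = config.frame_times
    sv = config.aortic_forward + truth.true_volume
    edv = config.lv_edv
    esv = edv - sv
    if esv <= 0:
        raise ValueError(
            f"EDV {edv} mL too small for stroke volume {sv} mL; raise lv_edv"
        )

    # ejection over systole, partial refill afterwards (extrema are what matter)
    t0, t1 = 80.0, 560.0
    volumes = np.empty_like(times)
    for i, t in enumerate(times):
        if t <= t0:
            volumes[i] = edv
        elif t <= t1:
            volumes[i] = edv - sv * 0.5 * (1.0 - math.cos(math.pi * (t - t0) / (t1 - t0)))
        else:
            frac = (t - t1) / max(config.cycle_ms - t1, 1.0)
            volumes[i] = esv + 0.9 * sv * 0.5 * (1.0 - math.cos(math.pi * frac))
    # pin the sampled extrema exactly to EDV/ESV (frame times need not hit
    # the analytic end-systole), preserving the curve shape in between
    volumes = esv + (volumes - volumes.min()) * sv / (volumes.max() - volumes.min())

    rates = np.where(
        (times > t0) & (times < t1),
        np.sin(np.pi * (times - t0) / (t1 - t0)),
        -0.02,  # mild diastolic backflow; excluded by the positive-part integral
    )
    pos = np.clip(rates, 0.0, None)
    pos_integral = np.trapezoid(pos, times) / 1000.0  # ms * (unit) -> scale below
    rates = rates * (config.aortic_forward / pos_integral)

    return VolumeCurve(times, volumes), FlowCurve(times, rates)
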