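"""Direct regurgitant-jet quantification from 4D flow velocity fields.

The pipeline mirrors how an experienced reader quantifies mitral
regurgitation (MR) directly on 4D flow CMR:

1. find the timeframes in which a regurgitant jet is present in the
   atrial region (:func:`detect_regurgitant_frames`);
2. at each such frame, locate the peak velocity within the jet and orient
   an oblique multiplanar-reformatted (MPR) plane through it,
   perpendicular to the local jet direction (:func:`locate_jet_peak`,
   :class:`MPRPlane`);
3. resample the through-plane velocity on that plane, segment the jet
   cross-section, and integrate velocity over the cross-section to get a
   regurgitant flow rate (:func:`sample_throughplane`,
   :func:`segment_jet_cross_section`, :func:`compute_flow_rate`);
4. spline-interpolate the per-frame flow-rate curve and integrate it over
   the jet period to obtain the regurgitant volume
   (:func:`integrate_regurgitant_curve`).

Multiple simultaneous jets are tracked independently and their volumes
summed; if no jet is found the regurgitant volume is zero.

The manual steps of the clinical workflow (visual frame inspection,
manual plane placement, manual contouring) are replaced by automated
surrogates with configurable parameters (:class:`TrackingParams`); the
landmarks and the orientation rule are the same, the operator heuristics
are this package's own.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .io import VelocityField4D

__all__ = [
    "TrackingParams",
    "MPRPlane",
    "PlaneSample",
    "JetDetection",
    "FrameTrack",
    "JetResult",
    "JetTrackResult",
    "JetTrackingError",
    "detect_regurgitant_frames",
    "locate_jet_peak",
    "sample_throughplane",
    "segment_jet_cross_section",
    "compute_flow_rate",
    "integrate_regurgitant_curve",
    "track_mitral_regurgitation",
]


class JetTrackingError(RuntimeError):
    """Raised when a tracking stage cannot produce a valid result."""


@dataclass
class TrackingParams:
    """Tunable parameters of the automated tracking surrogates.

    speed_threshold
        Jet-detection speed threshold in cm/s. Default 15 cm/s, i.e. three
        times the per-component velocity noise of a typical acquisition,
        so that weak early/late jet frames are still detected while
        isolated noise voxels are not.
    min_component_voxels
        Minimum 26-connected suprathreshold component size accepted as a
        jet (default 20 voxels; smaller clusters at the default threshold
        are overwhelmingly noise).
    link_distance_mm
        Maximum centroid displacement between consecutive frames for two
        components to be linked into the same jet.
    plane_extent_mm / plane_pixel_mm
        Size and pixel spacing of the reformatted plane raster. 40 mm at
        1 mm pixels oversamples typical 4D flow voxels (2.1-4.0 mm) and
        covers clinical jet cross-sections.
    segment_rel_threshold
        Jet cross-section = pixels above this fraction of the in-plane
        maximum through-plane velocity (default 0.25), restricted to the
        8-connected component containing the plane origin.
    flux_dilation_px
        The flow integral includes this many pixels of dilation around the
        segmented contour, so the partial-volume rim of the jet (velocity
        smeared below the threshold by voxel averaging) is counted; beyond
        the rim the through-plane velocity is centered on zero and adds no
        systematic flux.
    slab_offsets_mm
        Flow is averaged over parallel planes at these offsets (mm) along
        the jet axis around the peak plane. The regurgitant flux is the
        same through every cross-section of the jet, so this averages out
        the voxel-scale jitter of any single oblique reformat.
    """

    speed_threshold: float = 15.0
    min_component_voxels: int = 20
    link_distance_mm: float = 15.0
    plane_extent_mm: float = 40.0
    plane_pixel_mm: float = 1.0
    segment_rel_threshold: float = 0.25
    flux_dilation_px: int = 2
    slab_offsets_mm: tuple[float, ...] = (-3.0, -1.5, 0.0, 1.5, 3.0)


@dataclass
class MPRPlane:
    """Oblique reformatted plane through the jet's peak-velocity landmark.

    ``normal`` is the through-plane direction, oriented along the jet flow
    so that regurgitant flow is positive. {u, v, normal} is orthonormal
    and right-handed (u x v = normal).
    """

    origin: np.ndarray  # mm
    normal: np.ndarray
    in_plane_u: np.ndarray
    in_plane_v: np.ndarray
    extent: float  # mm
    pixel_spacing: float  # mm

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        for name in ("normal", "in_plane_u", "in_plane_v"):
            vec = np.asarray(getattr(self, name), dtype=float)
            n = np.linalg.norm(vec)
            if not np.isclose(n, 1.0, atol=1e-8):
                raise ValueError(f"{name} must be a unit vector")
            setattr(self, name, vec)
        basis = np.array([self.in_plane_u, self.in_plane_v, self.normal])
        if not np.allclose(basis @ basis.T, np.eye(3), atol=1e-8):
            raise ValueError("{u, v, normal} must be orthonormal")
        if not np.allclose(np.cross(self.in_plane_u, self.in_plane_v), self.normal,
                           atol=1e-8):
            raise ValueError("{u, v, normal} must be right-handed (u x v = normal)")
        n_pix = self.extent / self.pixel_spacing
        if abs(n_pix - round(n_pix)) > 1e-9 or round(n_pix) < 1:
            raise ValueError("extent must be an integer multiple of pixel_spacing")

    @classmethod
    def from_normal(
        cls, origin: np.ndarray, normal: np.ndarray,
        extent: float = 40.0, pixel_spacing: float = 1.0,
    ) -> "MPRPlane":
        """Build an orthonormal in-plane basis for a given through-plane axis."""
        normal = np.asarray(normal, dtype=float)
        nn = np.linalg.norm(normal)
        if nn == 0:
            raise ValueError("normal must be nonzero")
        normal = normal / nn
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(normal)))] = 1.0
        u = helper - np.dot(helper, normal) * normal
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        return cls(origin, normal, u, v, float(extent), float(pixel_spacing))

    @property
    def n_pixels(self) -> int:
        return int(round(self.extent / self.pixel_spacing))

    def pixel_centers_mm(self) -> np.ndarray:
        """(n, n, 3) physical coordinates of pixel centers, centered on origin."""
        n = self.n_pixels
        offs = (np.arange(n) + 0.5 - n / 2.0) * self.pixel_spacing
        a, b = np.meshgrid(offs, offs, indexing="ij")
        return (
            self.origin
            + a[..., None] * self.in_plane_u
            + b[..., None] * self.in_plane_v
        )


@dataclass
class PlaneSample:
    """Through-plane velocity raster sampled on an MPR plane."""

    through_plane_velocity: np.ndarray  # cm/s, (n, n)
    jet_mask: np.ndarray  # bool, (n, n)
    pixel_area: float  # mm^2
    frame_index: int
    out_of_bounds_mask: np.ndarray  # bool, (n, n)

    def __post_init__(self) -> None:
        if not (
            self.jet_mask.shape
            == self.through_plane_velocity.shape
            == self.out_of_bounds_mask.shape
        ):
            raise ValueError("masks must match the raster shape")
        if np.any(self.jet_mask & self.out_of_bounds_mask):
            raise ValueError("jet mask must exclude out-of-bounds pixels")


@dataclass
class JetDetection:
    """A jet as a linked sequence of suprathreshold components over frames."""

    frames: list[int] = dc_field(default_factory=list)
    masks: dict[int, np.ndarray] = dc_field(default_factory=dict)
    centroids: dict[int, np.ndarray] = dc_field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(sum(m.sum() for m in self.masks.values()))


@dataclass
class FrameTrack:
    frame_index: int
    time_ms: float
    peak_location: np.ndarray  # mm
    peak_speed: float  # cm/s
    plane: MPRPlane
    flow_rate: float  # mL/s


@dataclass
class JetResult:
    frames: list[FrameTrack]
    volume: float  # mL
    start_frame: int
    end_frame: int

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def flow_curve(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([f.time_ms for f in self.frames]),
            np.array([f.flow_rate for f in self.frames]),
        )


@dataclass
class JetTrackResult:
    """Outcome of direct jet tracking on one dataset."""

    jets: list[JetResult]
    total_mr_volume: float  # mL
    mr_start_frame: int | None
    mr_end_frame: int | None

    @property
    def n_jets(self) -> int:
        return len(self.jets)

    @property
    def mr_duration_frames(self) -> int:
        if self.mr_start_frame is None:
            return 0
        return self.mr_end_frame - self.mr_start_frame + 1

    def to_dict(self) -> dict:
        return {
            "total_mr_volume_ml": self.total_mr_volume,
            "n_jets": self.n_jets,
            "mr_start_frame": self.mr_start_frame,
            "mr_end_frame": self.mr_end_frame,
            "mr_duration_frames": self.mr_duration_frames,
            "jets": [
                {
                    "volume_ml": j.volume,
                    "start_frame": j.start_frame,
                    "end_frame": j.end_frame,
                    "frames": [
                        {
                            "frame": f.frame_index,
                            "time_ms": f.time_ms,
                            "peak_location_mm": list(map(float, f.peak_location)),
                            "peak_speed_cms": f.peak_speed,
                            "flow_rate_mls": f.flow_rate,
                        }
                        for f in j.frames
                    ],
                }
                for j in self.jets
            ],
        }


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def detect_regurgitant_frames(
    field: VelocityField4D,
    atrial_roi: np.ndarray,
    speed_threshold: float = 15.0,
    min_component_voxels: int = 20,
    link_distance_mm: float = 15.0,
) -> list[JetDetection]:
    """Find regurgitant jets as linked suprathreshold components.

    Per frame, 26-connected components of speed >= ``speed_threshold``
    inside the atrial ROI with at least ``min_component_voxels`` voxels
    are taken as jet candidates; candidates in consecutive frames are
    linked into jets by centroid proximity (< ``link_distance_mm``,
    ties broken by larger voxel overlap). An empty result means no MR.
    """
    atrial_roi = np.asarray(atrial_roi, dtype=bool)
    if not np.any(atrial_roi):
        raise ValueError("atrial ROI is empty")

    tracks: list[dict] = []
    for t in range(field.n_frames):
        sup = (field.speed(t) >= speed_threshold) & atrial_roi
        labels, n_comp = ndimage.label(sup, structure=_STRUCT_26)
        comps = []
        for lab in range(1, n_comp + 1):
            mask = labels == lab
            if mask.sum() < min_component_voxels:
                continue
            centroid = field.voxel_to_mm(np.argwhere(mask).mean(axis=0))
            comps.append({"mask": mask, "centroid": centroid})

        open_tracks = [tr for tr in tracks if tr["last_frame"] == t - 1]
        # candidate links sorted by distance; ties by larger mask overlap
        links = []
        for ci, comp in enumerate(comps):
            for tr in open_tracks:
                dist = float(np.linalg.norm(comp["centroid"] - tr["last_centroid"]))
                if dist < link_distance_mm:
                    overlap = int(np.sum(comp["mask"] & tr["last_mask"]))
                    links.append((dist, -overlap, ci, id(tr), tr))
        links.sort(key=lambda x: (x[0], x[1]))
        used_comps: set[int] = set()
        used_tracks: set[int] = set()
        for dist, _neg, ci, tid, tr in links:
            if ci in used_comps or tid in used_tracks:
                continue
            used_comps.add(ci)
            used_tracks.add(tid)
            tr["det"].frames.append(t)
            tr["det"].masks[t] = comps[ci]["mask"]
            tr["det"].centroids[t] = comps[ci]["centroid"]
            tr["last_frame"] = t
            tr["last_centroid"] = comps[ci]["centroid"]
            tr["last_mask"] = comps[ci]["mask"]
        for ci, comp in enumerate(comps):
            if ci in used_comps:
                continue
            det = JetDetection(frames=[t], masks={t: comp["mask"]},
                               centroids={t: comp["centroid"]})
            tracks.append(
                {
                    "det": det,
                    "last_frame": t,
                    "last_centroid": comp["centroid"],
                    "last_mask": comp["mask"],
                }
            )

    jets = [tr["det"] for tr in tracks]
    jets.sort(key=lambda d: (-d.n_voxels, d.frames[0]))
    return jets


def locate_jet_peak(
    field: VelocityField4D, frame: int, jet_component_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Peak-velocity landmark and local jet direction within a component.

    Returns (peak_location mm, unit jet direction, peak speed cm/s). The
    landmark is the highest-speed voxel of the component, skipping voxels
    flagged as alias-corrected so the plane is placed where the velocity
    measurement is trustworthy (the automated analogue of moving the plane
    further into the jet, away from aliased regions). The direction is the
    normalized mean velocity over the 3x3x3 neighborhood of the landmark,
    restricted to the component.
    """
    mask = np.asarray(jet_component_mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("jet component mask is empty at this frame")
    speed = field.speed(frame)
    usable = mask.copy()
    if field.alias_flags is not None:
        usable &= ~field.alias_flags[frame]
    if not np.any(usable):
        raise JetTrackingError(
            f"frame {frame}: every jet voxel is alias-flagged; peak unresolvable"
        )
    masked_speed = np.where(usable, speed, -np.inf)
    peak_idx = np.unravel_index(int(np.argmax(masked_speed)), speed.shape)
    peak_speed = float(speed[peak_idx])

    lo = [max(0, i - 1) for i in peak_idx]
    hi = [min(n, i + 2) for i, n in zip(peak_idx, field.grid_shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    nb_mask = mask[sl]
    nb_vel = field.velocities[frame][sl][nb_mask]
    direction = nb_vel.mean(axis=0)
    norm = np.linalg.norm(direction)
    if norm == 0:
        direction = field.velocities[frame][peak_idx]
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise JetTrackingError(f"frame {frame}: zero velocity at jet peak")
    return field.voxel_to_mm(np.array(peak_idx, dtype=float)), direction / norm, peak_speed


def sample_throughplane(
    field: VelocityField4D, frame: int, plane: MPRPlane
) -> PlaneSample:
    """Resample the through-plane velocity (v . normal) on an MPR plane.

    Each velocity component is trilinearly interpolated at every pixel
    center; pixels outside the volume are marked out-of-bounds and
    excluded from any downstream mask.
    """
    pts = plane.pixel_centers_mm()
    vox = field.mm_to_voxel(pts)
    dims = np.array(field.grid_shape, dtype=float)
    oob = np.any((vox < 0) | (vox > dims - 1), axis=-1)
    if np.all(oob):
        raise JetTrackingError("MPR plane lies entirely outside the volume")
    coords = np.moveaxis(vox, -1, 0)
    v_tp = np.zeros(pts.shape[:2])
    for c in range(3):
        interp = ndimage.map_coordinates(
            field.velocities[frame, ..., c], coords, order=1, mode="constant", cval=0.0
        )
        v_tp += interp * plane.normal[c]
    return PlaneSample(
        through_plane_velocity=v_tp,
        jet_mask=np.zeros_like(oob),
        pixel_area=plane.pixel_spacing**2,
        frame_index=frame,
        out_of_bounds_mask=oob,
    )


def segment_jet_cross_section(
    sample: PlaneSample, relative_threshold: float = 0.25
) -> np.ndarray:
    """Segment the jet cross-section on a through-plane raster.

    Pixels with through-plane velocity >= ``relative_threshold`` times the
    in-plane maximum, restricted to the 8-connected component containing
    the plane origin pixel (falling back to the component containing the
    raster maximum if the origin pixel itself is subthreshold). With no
    positive pixels the mask is empty and the flow rate is zero.
    """
    v = sample.through_plane_velocity
    valid = ~sample.out_of_bounds_mask
    if not np.any(valid & (v > 0)):
        sample.jet_mask = np.zeros_like(valid)
        return sample.jet_mask
    vmax = float(v[valid].max())
    above = valid & (v >= relative_threshold * vmax)
    labels, _ = ndimage.label(above, structure=_STRUCT_8)
    n = v.shape[0]
    origin_pix = (n // 2, v.shape[1] // 2)
    lab = labels[origin_pix]
    if lab == 0:
        peak_pix = np.unravel_index(int(np.argmax(np.where(valid, v, -np.inf))), v.shape)
        lab = labels[peak_pix]
    mask = labels == lab if lab != 0 else np.zeros_like(above)
    sample.jet_mask = mask
    return mask


def compute_flow_rate(sample: PlaneSample) -> float:
    """Flow rate in mL/s through the segmented cross-section.

    Q = sum over masked pixels of v_tp [cm/s] * pixel_area [mm^2] * 0.01,
    with negative pixels inside the mask contributing their signed value.
    """
    v = sample.through_plane_velocity[sample.jet_mask]
    return float(v.sum() * sample.pixel_area * 0.01)


def integrate_regurgitant_curve(
    times: np.ndarray, rates: np.ndarray, frame_interval: float | None = None
) -> float:
    """Regurgitant volume (mL) from a sampled flow-rate curve.

    A natural cubic spline is fitted through the sampled (t, Q) points
    augmented with zero-flow anchors half a frame interval before the
    first and after the last sample (the jet is taken to start and end
    between the adjacent frames), and integrated between the anchors. A
    boundary sample that is already exactly zero is its own anchor and is
    not padded further. The result is clamped at >= 0. A single-frame jet
    integrates the triangular pulse anchor-peak-anchor, i.e.
    Q * interval / 2.
    """
    times = np.asarray(times, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if times.ndim != 1 or times.shape != rates.shape or len(times) == 0:
        raise ValueError("times and rates must be equal-length 1-D arrays")
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    if len(times) == 1:
        dt = frame_interval if frame_interval is not None else 0.0
        return max(float(rates[0]) * dt / 2.0 / 1000.0, 0.0)

    dt = frame_interval if frame_interval is not None else float(np.median(np.diff(times)))
    t_aug, q_aug = list(times), list(rates)
    if rates[0] != 0.0:
        t_aug.insert(0, times[0] - dt / 2.0)
        q_aug.insert(0, 0.0)
    if rates[-1] != 0.0:
        t_aug.append(times[-1] + dt / 2.0)
        q_aug.append(0.0)
    t_aug, q_aug = np.asarray(t_aug), np.asarray(q_aug)
    spline = CubicSpline(t_aug, q_aug, bc_type="natural")
    volume = float(spline.integrate(t_aug[0], t_aug[-1])) / 1000.0  # ms*mL/s -> mL
    return max(volume, 0.0)


def track_mitral_regurgitation(
    field: VelocityField4D,
    atrial_roi: np.ndarray,
    params: TrackingParams | None = None,
) -> JetTrackResult:
    """End-to-end direct MR quantification on a preprocessed field.

    Orchestrates detection, per-frame peak location / plane placement /
    through-plane sampling / cross-section segmentation / flow rate, then
    per-jet spline integration and summation over jets. Planes are
    re-derived independently at every frame so they dynamically adapt to
    the jet direction. With no detected jet the MR volume is zero.
    """
    params = params or TrackingParams()
    detections = detect_regurgitant_frames(
        field,
        atrial_roi,
        speed_threshold=params.speed_threshold,
        min_component_voxels=params.min_component_voxels,
        link_distance_mm=params.link_distance_mm,
    )
    frame_dt = (
        float(np.median(np.diff(field.frame_times))) if field.n_frames > 1 else None
    )
    jets: list[JetResult] = []
    for det in detections:
        records: list[FrameTrack] = []
        for t in det.frames:
            loc, direction, speed = locate_jet_peak(field, t, det.masks[t])
            plane = MPRPlane.from_normal(
                loc, direction, params.plane_extent_mm, params.plane_pixel_mm
            )
            rates = []
            for offset in params.slab_offsets_mm or (0.0,):
                shifted = replace(plane, origin=loc + offset * direction)
                try:
                    sample = sample_throughplane(field, t, shifted)
                except JetTrackingError:
                    continue  # offset plane outside the volume; skip it
                segment_jet_cross_section(sample, params.segment_rel_threshold)
                if params.flux_dilation_px > 0 and np.any(sample.jet_mask):
                    sample.jet_mask = (
                        ndimage.binary_dilation(
                            sample.jet_mask,
                            structure=_STRUCT_8,
                            iterations=params.flux_dilation_px,
                        )
                        & ~sample.out_of_bounds_mask
                    )
                rates.append(compute_flow_rate(sample))
            if not rates:
                raise JetTrackingError(f"frame {t}: no slab plane intersects the volume")
            q = float(np.mean(rates))
            records.append(FrameTrack(t, float(field.frame_times[t]), loc, speed, plane, q))
        t_s, q_s = (
            np.array([r.time_ms for r in records]),
            np.array([r.flow_rate for r in records]),
        )
        volume = integrate_regurgitant_curve(t_s, q_s, frame_interval=frame_dt)
        jets.append(
            JetResult(records, volume, det.frames[0], det.frames[-1])
        )

    total = float(sum(j.volume for j in jets))
    start = min((j.start_frame for j in jets), default=None)
    end = max((j.end_frame for j in jets), default=None)
    return JetTrackResult(jets=jets, total_mr_volume=total,
                          mr_start_frame=start, mr_end_frame=end)
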