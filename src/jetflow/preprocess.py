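"""Pre-processing corrections applied before quantification.

Two corrections are provided, mirroring the corrected-data starting point
of clinical 4D flow analysis:

* :func:`unwrap_aliasing` — undo single velocity wraps (|k| <= 1) caused
  by velocities beyond the VENC limit, using a spatial neighborhood-median
  criterion iterated to convergence. Corrected voxels are recorded in
  ``alias_flags`` so downstream peak finding can avoid them.
* :func:`correct_background_offset` — remove eddy-current-like offsets by
  fitting a low-order spatial polynomial over static-tissue voxels per
  frame and component (or, for a 2D PC flow curve, by subtracting the mean
  rate over a declared diastasis window).

Maxwell-term correction is intentionally absent: it requires sequence
gradient information that is not part of the data contract.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io import FlowCurve, VelocityField4D

__all__ = ["unwrap_aliasing", "correct_background_offset"]

_FOOTPRINT_6 = np.zeros((3, 3, 3), dtype=bool)
_FOOTPRINT_6[1, 1, 0] = _FOOTPRINT_6[1, 1, 2] = True
_FOOTPRINT_6[1, 0, 1] = _FOOTPRINT_6[1, 2, 1] = True
_FOOTPRINT_6[0, 1, 1] = _FOOTPRINT_6[2, 1, 1] = True


def unwrap_aliasing(field: VelocityField4D, max_iter: int = 10) -> VelocityField4D:
    """Undo single VENC wraps by local spatial consistency.

    Per voxel/frame/component the method chooses k in {-1, 0, +1} so that
    ``v + 2*k*venc`` is closest to the median of the 6-neighborhood of the
    current estimate, and iterates until the assignment is stable. Voxels
    whose final k is nonzero are flagged in ``alias_flags``. A voxel is
    therefore never altered by anything other than a multiple of 2*venc,
    and an alias-free smooth field is returned unchanged.

    A whole region that is aliased coherently (e.g. a wide jet core that
    everywhere exceeds VENC) has no unwrapped neighbors to disagree with
    and cannot be recovered by this criterion; single-wrap cores narrower
    than their suprathreshold sheath (the usual case at VENC 150-250) are
    recovered from the rim inwards.
    """
    wrapped = field.velocities
    venc = field.venc
    current = wrapped.copy()
    k_prev = np.zeros(wrapped.shape, dtype=np.int8)
    for _ in range(max_iter):
        k_new = np.zeros_like(k_prev)
        for t in range(field.n_frames):
            for c in range(3):
                med = ndimage.median_filter(
                    current[t, ..., c], footprint=_FOOTPRINT_6, mode="nearest"
                )
                w = wrapped[t, ..., c]
                best = np.abs(w - med)
                kk = np.zeros(w.shape, dtype=np.int8)
                for k in (-1, 1):
                    cost = np.abs(w + 2.0 * k * venc - med)
                    take = cost < best
                    best = np.where(take, cost, best)
                    kk = np.where(take, np.int8(k), kk)
                k_new[t, ..., c] = kk
        if np.array_equal(k_new, k_prev):
            break
        k_prev = k_new
        current = wrapped + 2.0 * venc * k_new

    out = field.copy()
    out.velocities = current
    out.alias_flags = np.any(k_prev != 0, axis=-1)
    return out


def _fit_spatial_polynomial(
    values: np.ndarray, coords: np.ndarray, mask: np.ndarray, order: int
) -> np.ndarray:
    """Fit values over masked voxels; return the fitted surface everywhere."""
    cols = [np.ones(mask.sum())]
    full_cols = [np.ones(values.size)]
    if order >= 1:
        for d in range(3):
            cols.append(coords[..., d][mask])
            full_cols.append(coords[..., d].ravel())
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, values[mask], rcond=None)
    return (np.column_stack(full_cols) @ beta).reshape(values.shape)


def correct_background_offset(
    data: VelocityField4D | FlowCurve,
    static_mask: np.ndarray | None = None,
    *,
    window: tuple[float, float] | None = None,
    order: int = 1,
):
    """Remove background velocity/flow offsets.

    For a :class:`VelocityField4D`: fits, per frame and component, a
    spatial polynomial of the given order (default first-order, i.e. a
    plane) over ``static_mask`` voxels and subtracts it from the whole
    volume. After correction the static-region mean velocity is zero to
    within the fit residual.

    For a :class:`FlowCurve`: subtracts the mean rate over the declared
    diastasis ``window`` (ms), the standard stationary-flow reference.
    """
    if isinstance(data, FlowCurve):
        if window is None:
            raise ValueError("a diastasis window (t_lo, t_hi) in ms is required")
        sel = (data.times >= window[0]) & (data.times <= window[1])
        if not np.any(sel):
            raise ValueError("diastasis window contains no samples")
        return FlowCurve(data.times.copy(), data.rates - data.rates[sel].mean())

    field = data
    if static_mask is None or not np.any(static_mask):
        raise ValueError("a nonempty static-tissue mask is required")
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.shape != field.grid_shape:
        raise ValueError("static mask shape must match the voxel grid")

    idx = np.indices(field.grid_shape, dtype=float)
    coords = np.stack(
        [idx[d] * field.spacing[d] for d in range(3)], axis=-1
    )  # affine translation is irrelevant to the fit
    out = field.copy()
    for t in range(field.n_frames):
        for c in range(3):
            surface = _fit_spatial_polynomial(
                field.velocities[t, ..., c], coords, static_mask, order
            )
            out.velocities[t, ..., c] -= surface
    return out
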