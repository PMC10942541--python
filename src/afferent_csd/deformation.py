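"""Meningeal deformation series from image-registration parameters.

The per-frame affine corrections produced by registration encode how much
the tissue scaled (expansion/compression) and sheared in-plane, and the
per-frame Z-corrections encode motion toward or away from the skull.

The 2x2 linear part A of each affine is decomposed through its singular
values s1 >= s2, which are rotation invariant:

* isotropic stretch  = sqrt(s1 * s2) - 1   (signed; + = expansion)
* scale (um)         = stretch * r_ref, with r_ref half the FOV diagonal,
  i.e. the displacement of a corner point under the pure isotropic part
* shear              = (s1 - s2) / 2       (dimensionless anisotropy)

Z-shift is the plane correction times the plane spacing; positive values
mean movement toward the skull.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DeformationSeries", "decompose_affine", "zshift_um", "reference_radius_um"]


@dataclass
class DeformationSeries:
    scale: np.ndarray   # um, signed, + = expansion
    shear: np.ndarray   # dimensionless anisotropy
    zshift: np.ndarray  # um, + toward skull

    def shear_um(self, r_ref_um: float) -> np.ndarray:
        """Shear expressed as displacement (um) at the reference radius."""
        return self.shear * r_ref_um


def reference_radius_um(fov_size_um: tuple[float, float]) -> float:
    """Half the FOV diagonal, the lever arm converting stretch to um."""
    w, h = fov_size_um
    return 0.5 * float(np.hypot(w, h))


def decompose_affine(
    linear_parts: np.ndarray,
    fov_size_um: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Split per-frame 2x2 affine linear parts into scale and shear series.

    Singular frames are flagged and linearly interpolated from their
    neighbours.  The rotation component is discarded: singular values are
    unchanged by composition with any rotation.

    Returns (scale_um, shear) series.
    """
    A = np.asarray(linear_parts, dtype=float)
    if A.ndim != 3 or A.shape[1:] != (2, 2):
        raise ValueError("linear_parts must be [n_frames, 2, 2]")
    n = A.shape[0]
    svals = np.linalg.svd(A, compute_uv=False)  # sorted descending
    s1, s2 = svals[:, 0], svals[:, 1]
    det = np.abs(np.linalg.det(A))
    bad = ~np.isfinite(s1) | ~np.isfinite(s2) | (det < 1e-12)
    stretch = np.where(bad, np.nan, np.sqrt(np.clip(s1 * s2, 0, None)) - 1.0)
    shear = np.where(bad, np.nan, (s1 - s2) / 2.0)
    if bad.any():
        if bad.all():
            raise ValueError("every affine frame is singular")
        idx = np.arange(n)
        good = ~bad
        stretch = np.interp(idx, idx[good], stretch[good])
        shear = np.interp(idx, idx[good], shear[good])
    r_ref = reference_radius_um(fov_size_um)
    return stretch * r_ref, shear


def zshift_um(z_corrections: np.ndarray, plane_spacing_um: float) -> np.ndarray:
    """Z-shift in um from per-frame plane corrections (+ toward skull)."""
    if plane_spacing_um <= 0:
        raise ValueError("plane_spacing_um must be positive")
    return np.asarray(z_corrections, dtype=float) * plane_spacing_um


def deformation_from_session(session) -> DeformationSeries:
    """Derive the full deformation series from a recording session."""
    scale, shear = decompose_affine(session.affine_linear, session.fov_size_um)
    z = zshift_um(session.zshift_series, session.plane_spacing_um)
    return DeformationSeries(scale=scale, shear=shear, zshift=z)
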