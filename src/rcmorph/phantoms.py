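"""Analytic debug phantoms with closed-form length, diameter and volume.

These are the independent oracles for the measurement pipeline: straight
tubes, circular helices and tori whose arc length and volume are known in
closed form.  The direct rasterizers here use exact signed distances and do
not share code with :func:`rcmorph.synthetic.voxelize`, so they can also
cross-check the generator's rasterization.
"""

from __future__ import annotations

import numpy as np

from .synthetic import AnatomyModel, conical_helix
from .volume import LabelledVolume


def straight_tube_model(length: float, radius: float,
                        axis: np.ndarray | None = None) -> AnatomyModel:
    """Tube of constant radius along ``axis`` (default +x), basal end at origin."""
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)

    def centerline(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return t[:, None] * (length * axis)

    return AnatomyModel(centerline_fn=centerline,
                        radius_fn=lambda t: np.full(np.atleast_1d(t).shape, radius),
                        csf_cylinder=None, scala_axis=None,
                        shell_thickness_mm=0.04, cap_style="flat")


def circular_helix_model(helix_radius: float, pitch: float, n_turns: float,
                         tube_radius: float) -> AnatomyModel:
    """Circular helix tube; arc length is ``2*pi*n_turns*sqrt(r^2+(pitch/2pi)^2)``."""
    return AnatomyModel(
        centerline_fn=conical_helix(helix_radius, helix_radius, pitch, n_turns),
        radius_fn=lambda t: np.full(np.atleast_1d(t).shape, tube_radius),
        csf_cylinder=None, scala_axis=None, shell_thickness_mm=0.04,
        cap_style="flat")


def helix_arc_length(helix_radius: float, pitch: float, n_turns: float) -> float:
    """Closed-form arc length of a circular helix."""
    return 2.0 * np.pi * n_turns * np.hypot(helix_radius, pitch / (2.0 * np.pi))


def cylinder_mask_volume(length: float, radius: float, spacing: float,
                         label: int = 3) -> LabelledVolume:
    """Directly rasterized solid cylinder along +x (exact signed distance)."""
    pad = 3 * spacing
    nx = int(np.ceil((length + 2 * pad) / spacing)) + 1
    nr = int(np.ceil((radius + pad) / spacing))
    x = -pad + np.arange(nx) * spacing
    yz = np.arange(-nr, nr + 1) * spacing
    inside_x = (x >= 0) & (x <= length)
    rho2 = yz[:, None] ** 2 + yz[None, :] ** 2
    grid = (inside_x[:, None, None] & (rho2 <= radius ** 2)[None, :, :])
    origin = np.array([-pad, yz[0], yz[0]])
    return LabelledVolume(grid=(grid * label).astype(np.uint8),
                         spacing=spacing, origin=origin)


def torus_mask_volume(ring_radius: float, tube_radius: float, spacing: float,
                      label: int = 3) -> LabelledVolume:
    """Directly rasterized solid torus about +z; volume is ``2*pi^2*R*r^2``."""
    pad = 3 * spacing
    half_xy = ring_radius + tube_radius + pad
    nxy = 2 * int(np.ceil(half_xy / spacing)) + 1
    nz = 2 * int(np.ceil((tube_radius + pad) / spacing)) + 1
    xy = -half_xy + np.arange(nxy) * spacing
    z = -(nz // 2) * spacing + np.arange(nz) * spacing
    rho = np.sqrt(xy[:, None] ** 2 + xy[None, :] ** 2)
    d2 = (rho[:, :, None] - ring_radius) ** 2 + (z[None, None, :]) ** 2
    grid = d2 <= tube_radius ** 2
    origin = np.array([xy[0], xy[0], z[0]])
    return LabelledVolume(grid=(grid * label).astype(np.uint8),
                         spacing=spacing, origin=origin)
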