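"""Parametric synthetic temporal-bone anatomy.

This module generates ground-truth models and voxelized label maps of the
basal cochlear region: Rosenthal's canal (RC) as a tapering conical-helix
tube about the modiolar axis, its thin bony cover, the scala tympani, the
round-window (RW) membrane lying a few mm superficial to the basal canal,
the vestibulocochlear artery crossing the anterior grid cells, a stapedius
occlusion of one grid cell, and the central CSF nerve-exit space.

Every specimen is drawn from a configurable distribution
(:class:`rcmorph.config.GeneratorConfig`) whose defaults emulate the
published ten-bone cohort statistics, so downstream measurement stages can
be validated against known truth.  Generation is deterministic given
``(seed, config)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .config import ConfigError, GeneratorConfig
from .grids import cell_centers, inplane_basis, normalize
from .volume import LABEL_SCHEME_VERSION, LabelledVolume

__all__ = [
    "SpecimenParams", "AnatomyModel", "sample_specimen_params", "build_model",
    "voxelize", "write_ground_truth", "read_ground_truth", "generate_cohort",
    "InvalidParamsError", "GroundTruthParseError",
]


class InvalidParamsError(ValueError):
    """Raised when specimen parameters describe an unattainable geometry."""


class GroundTruthParseError(ValueError):
    """Raised when a ground-truth file is malformed."""


@dataclass
class SpecimenParams:
    """Ground-truth parametric description of one synthetic specimen.

    Lengths in mm except ``shell_thickness`` (µm).  ``rw_normal`` is the
    *outward* membrane normal (pointing out of the cochlea);
    ``rw_depth_to_canal`` is the distance from the membrane center to the
    canal *surface* along the inward normal.
    """

    seed: int
    helix_base_radius: float
    helix_apical_radius: float
    helix_pitch: float            # initial pitch (mm/turn); recalibrated by build_model
    n_turns: float
    target_length: float
    canal_diam_base: float
    canal_diam_45: float
    canal_diam_90: float
    canal_diam_apex: float
    shell_thickness: float        # µm
    dehiscence_fraction: float
    rw_center: tuple[float, float, float]
    rw_normal: tuple[float, float, float]
    rw_semiaxes: tuple[float, float]      # (anterior, superior) semi-axes
    rw_depth_to_canal: float
    artery_offset: float          # depth of artery below the membrane, mm
    artery_present: bool = True
    stapedius_cells: tuple[str, ...] = ("D1",)

    def validate(self) -> None:
        if not self.target_length > 0:
            raise InvalidParamsError(f"target_length must be positive, got {self.target_length}")
        diams = (self.canal_diam_base, self.canal_diam_45,
                 self.canal_diam_90, self.canal_diam_apex)
        if not all(d > 0 for d in diams):
            raise InvalidParamsError(f"all canal diameters must be positive, got {diams}")
        if not (self.canal_diam_base <= self.canal_diam_45 <= self.canal_diam_90):
            raise InvalidParamsError(
                "station diameters must grow monotonically base <= 45 <= 90, "
                f"got {diams[:3]}")
        if not (self.helix_base_radius > 0 and self.helix_apical_radius > 0):
            raise InvalidParamsError("helix radii must be positive")
        if not (0 <= self.dehiscence_fraction <= 1):
            raise InvalidParamsError(
                f"dehiscence_fraction must lie in [0, 1], got {self.dehiscence_fraction}")
        if self.n_turns <= 0.25:
            raise InvalidParamsError(f"n_turns must exceed 0.25, got {self.n_turns}")


@dataclass
class AnatomyModel:
    """Continuous ground-truth model of one specimen.

    ``centerline_fn`` maps t in [0, 1] to 3-D canal-axis points (mm), t=0 at
    the basal end; ``radius_fn`` gives the canal radius at t.  Structure
    fields are ``None`` for bare debug phantoms (tube-only models).
    """

    centerline_fn: Callable[[np.ndarray], np.ndarray]
    radius_fn: Callable[[np.ndarray], np.ndarray]
    modiolar_axis: tuple[np.ndarray, np.ndarray] | None = None   # (point, unit dir)
    rw_disc: tuple[np.ndarray, np.ndarray, tuple[float, float]] | None = None
    rw_thickness: float = 0.07
    artery_curve: np.ndarray | None = None        # (N, 3) polyline
    artery_radius: float = 0.1
    stapedius_region: tuple[str, ...] = ()
    stapedius_center: np.ndarray | None = None
    stapedius_radius: float = 0.3
    scala_axis: tuple[np.ndarray, np.ndarray] | None = None      # segment (a, b)
    scala_radius: float = 1.3
    csf_cylinder: tuple[float, float, float] | None = None       # (radius, z_lo, z_hi)
    shell_thickness_mm: float = 0.04
    dehiscence_fraction: float = 0.0
    cap_style: str = "round"     # "round": ball-capped tube ends; "flat": cut at end planes
    seed: int = 0
    labels_meta: str = LABEL_SCHEME_VERSION

    def sample_centerline(self, n: int = 4097) -> tuple[np.ndarray, np.ndarray]:
        """Dense centerline samples and their cumulative arc length (mm)."""
        t = np.linspace(0.0, 1.0, n)
        pts = self.centerline_fn(t)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        return pts, cum

    def arc_length(self, n: int = 4097) -> float:
        return float(self.sample_centerline(n)[1][-1])


# -- sampling ------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float], max_rejects: int) -> float:
    if sd == 0:
        lo, hi = bounds
        if not (lo <= mean <= hi):
            raise ConfigError(f"degenerate distribution mean {mean} outside bounds {bounds}")
        return mean
    for _ in range(max_rejects):
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    raise ConfigError(
        f"rejection sampling exceeded {max_rejects} draws for bounds {bounds}; "
        "distribution and bounds are inconsistent")


def sample_specimen_params(seed: int, config: GeneratorConfig | None = None) -> SpecimenParams:
    """Draw one specimen's ground-truth parameters; deterministic given seed."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    mr = config.max_rejects

    target_length = _truncated_normal(rng, config.length_mean, config.length_sd,
                                      config.length_bounds, mr)

    # Station diameters with monotone growth enforced by rejection.
    for _ in range(mr):
        d0 = rng.normal(config.diam_base_mean, config.diam_base_sd)
        d45 = rng.normal(config.diam_45_mean, config.diam_45_sd)
        d90 = rng.normal(config.diam_90_mean, config.diam_90_sd)
        dap = rng.normal(config.diam_apex_mean, config.diam_apex_sd)
        if config.diam_min <= d0 <= d45 <= d90 <= dap:
            break
    else:
        raise ConfigError(
            f"rejection sampling exceeded {mr} draws for monotone station diameters; "
            "diameter distributions are inconsistent")

    # Helix geometry must be jointly feasible with the target length: the
    # planar spiral arc is a hard lower bound on the attainable arc length
    # (pitch calibration can only add length), so reject draws that leave no
    # headroom for the pitch.
    for _ in range(mr):
        r_base = _truncated_normal(rng, config.helix_base_radius_mean,
                                   config.helix_base_radius_sd, (0.5, 5.0), mr)
        r_apex = _truncated_normal(rng, config.helix_apical_radius_mean,
                                   config.helix_apical_radius_sd, (0.3, 5.0), mr)
        n_turns = _truncated_normal(rng, config.n_turns_mean, config.n_turns_sd,
                                    (0.5, 4.0), mr)
        if _helix_arc_length(0.0, r_base, r_apex, n_turns) <= 0.97 * target_length:
            break
    else:
        raise ConfigError(
            f"rejection sampling exceeded {mr} draws for a helix geometry "
            "compatible with the target length; helix radius/turn distributions "
            "are inconsistent with the length distribution")
    shell = rng.uniform(*config.shell_thickness_range)
    dehiscence = rng.uniform(*config.dehiscence_fraction_range)

    depth = rng.uniform(*config.rw_depth_range)
    tilt = np.deg2rad(_truncated_normal(rng, config.rw_tilt_deg_mean,
                                        config.rw_tilt_deg_sd, (-80.0, 80.0), mr))
    sup_offset = rng.normal(config.rw_sup_offset_mean, config.rw_sup_offset_sd)
    artery_present = bool(rng.random() < config.artery_fraction)
    artery_offset = rng.uniform(*config.artery_offset_range)

    # Membrane pose: outward normal in the xy-plane, tilted away from the
    # basal canal tangent; center offset along the inward normal by
    # (depth + basal canal radius), then shifted along superior (+z).
    basal = np.array([r_base, 0.0, 0.0])
    u = np.array([np.cos(tilt), -np.sin(tilt), 0.0])
    rw_center = basal + (depth + d0 / 2.0) * u + np.array([0.0, 0.0, sup_offset])

    params = SpecimenParams(
        seed=int(seed),
        helix_base_radius=float(r_base),
        helix_apical_radius=float(r_apex),
        helix_pitch=float(config.pitch_initial),
        n_turns=float(n_turns),
        target_length=float(target_length),
        canal_diam_base=float(d0),
        canal_diam_45=float(d45),
        canal_diam_90=float(d90),
        canal_diam_apex=float(dap),
        shell_thickness=float(shell),
        dehiscence_fraction=float(dehiscence),
        rw_center=tuple(float(v) for v in rw_center),
        rw_normal=tuple(float(v) for v in u),
        rw_semiaxes=tuple(float(v) for v in config.rw_semiaxes),
        rw_depth_to_canal=float(depth),
        artery_offset=float(artery_offset),
        artery_present=artery_present,
        stapedius_cells=tuple(config.stapedius_cells),
    )
    params.validate()
    return params


# -- model construction --------------------------------------------------------

def _helix_speed(t: np.ndarray, r0: float, r1: float, theta_tot: float,
                 height: float) -> np.ndarray:
    dr = r1 - r0
    radius = r0 + dr * t
    return np.sqrt(dr ** 2 + (radius * theta_tot) ** 2 + height ** 2)


def _helix_arc_length(pitch: float, r0: float, r1: float, n_turns: float,
                      n: int = 2049) -> float:
    theta_tot = 2.0 * np.pi * n_turns
    t = np.linspace(0.0, 1.0, n)
    return float(np.trapezoid(_helix_speed(t, r0, r1, theta_tot, pitch * n_turns), t))


def conical_helix(r0: float, r1: float, pitch: float,
                  n_turns: float) -> Callable[[np.ndarray], np.ndarray]:
    """Parametric conical helix about +z, basal end at (r0, 0, 0), t in [0,1]."""
    theta_tot = 2.0 * np.pi * n_turns

    def fn(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        radius = r0 + (r1 - r0) * t
        theta = theta_tot * t
        return np.stack([radius * np.cos(theta), radius * np.sin(theta),
                         pitch * n_turns * t], axis=-1)

    return fn


def build_model(params: SpecimenParams, config: GeneratorConfig | None = None) -> AnatomyModel:
    """Build the continuous anatomy model for one specimen.

    The helix pitch is recalibrated so the numerically integrated centerline
    arc length matches ``params.target_length`` to within 0.1 %.
    """
    config = config or GeneratorConfig()
    params.validate()
    r0, r1 = params.helix_base_radius, params.helix_apical_radius
    n_turns = params.n_turns

    planar = _helix_arc_length(0.0, r0, r1, n_turns)
    if planar >= params.target_length:
        raise InvalidParamsError(
            f"target_length {params.target_length:.3f} mm is shorter than the planar "
            f"spiral arc {planar:.3f} mm; no pitch can attain it")
    hi = max(params.helix_pitch, 1.0)
    while _helix_arc_length(hi, r0, r1, n_turns) < params.target_length:
        hi *= 2.0
        if hi > 64.0:
            raise InvalidParamsError("pitch calibration diverged; inconsistent geometry")
    pitch = brentq(lambda p: _helix_arc_length(p, r0, r1, n_turns) - params.target_length,
                   0.0, hi, xtol=1e-10)

    apex_deg = 360.0 * n_turns
    knots_deg = np.array([0.0, 45.0, 90.0, apex_deg])
    knots_r = np.array([params.canal_diam_base, params.canal_diam_45,
                        params.canal_diam_90, params.canal_diam_apex]) / 2.0
    interp = PchipInterpolator(knots_deg, knots_r)

    def radius_fn(t: np.ndarray) -> np.ndarray:
        return np.asarray(interp(np.asarray(t, dtype=float) * apex_deg), dtype=float)

    shell_mm = params.shell_thickness / 1000.0
    winding_gap = np.hypot(pitch, (r0 - r1) / n_turns)
    max_tube = float(np.max(knots_r)) + shell_mm
    if 2.0 * max_tube >= 0.95 * winding_gap:
        raise InvalidParamsError(
            f"canal tube (radius+shell {max_tube:.3f} mm) would merge across helix "
            f"windings (gap {winding_gap:.3f} mm)")
    if float(np.max(knots_r)) >= 0.8 * min(r0, r1):
        raise InvalidParamsError("canal radius exceeds helix radius; tube engulfs the axis")

    rw_center = np.asarray(params.rw_center)
    rw_normal = normalize(params.rw_normal)
    basal = np.array([r0, 0.0, 0.0])

    cells = cell_centers(rw_center, rw_normal,
                         ant_half=params.rw_semiaxes[0], sup_half=params.rw_semiaxes[1])
    artery_curve = None
    if params.artery_present:
        qb = cells["B1"] - params.artery_offset * rw_normal
        qc = cells["C1"] - params.artery_offset * rw_normal
        axis = normalize(qc - qb)
        artery_curve = np.stack([qb - 0.8 * axis, qc + 0.8 * axis])

    stap_center = None
    if params.stapedius_cells:
        anchor = cells[params.stapedius_cells[0]]
        stap_center = anchor + (0.2 + 0.5 * config.stapedius_radius) * rw_normal

    return AnatomyModel(
        centerline_fn=conical_helix(r0, r1, pitch, n_turns),
        radius_fn=radius_fn,
        modiolar_axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])),
        rw_disc=(rw_center, rw_normal, tuple(params.rw_semiaxes)),
        rw_thickness=config.rw_thickness,
        artery_curve=artery_curve,
        artery_radius=config.artery_radius,
        stapedius_region=tuple(params.stapedius_cells),
        stapedius_center=stap_center,
        stapedius_radius=config.stapedius_radius,
        scala_axis=(rw_center, basal),
        scala_radius=config.scala_radius,
        csf_cylinder=(config.csf_radius, *config.csf_z_range),
        shell_thickness_mm=shell_mm,
        dehiscence_fraction=params.dehiscence_fraction,
        seed=params.seed,
    )


# -- voxelization --------------------------------------------------------------

def _segment_distance(px, py, pz, a, b):
    """Distance from broadcastable point grids to segment a-b (float32)."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    L2 = float(np.dot(d, d))
    wx, wy, wz = px - a[0], py - a[1], pz - a[2]
    if L2 == 0:
        return np.sqrt(wx ** 2 + wy ** 2 + wz ** 2, dtype=np.float32)
    s = np.clip((wx * d[0] + wy * d[1] + wz * d[2]) / L2, 0.0, 1.0).astype(np.float32)
    return np.sqrt((wx - s * d[0]) ** 2 + (wy - s * d[1]) ** 2
                   + (wz - s * d[2]) ** 2, dtype=np.float32)


def _subbox(shape, origin, spacing, lo_pt, hi_pt):
    """Slices of the grid covering a world-space box, clipped to the volume."""
    lo_i = np.maximum(np.floor((np.asarray(lo_pt) - origin) / spacing).astype(int), 0)
    hi_i = np.minimum(np.ceil((np.asarray(hi_pt) - origin) / spacing).astype(int) + 1,
                      np.asarray(shape))
    lo_i = np.minimum(lo_i, np.asarray(shape))
    return tuple(slice(a, b) for a, b in zip(lo_i, hi_i)), lo_i


def _axes_world(shape_slc, lo_i, origin, spacing):
    """Broadcastable world-coordinate axes (float32) for a sub-box."""
    ax = []
    for d, slc in enumerate(shape_slc):
        n = slc.stop - slc.start
        coords = (origin[d] + (lo_i[d] + np.arange(n)) * spacing).astype(np.float32)
        shp = [1, 1, 1]
        shp[d] = n
        ax.append(coords.reshape(shp))
    return ax


def _canal_surface_distance(shape, origin, spacing, pts, radii, reach,
                            interest):
    """Signed distance from voxel centers to the canal tube surface.

    Computed only within ``reach`` mm of the centerline bounding box, coarse
    (stride-3 nearest-sample query, nearest-neighbor upsample) everywhere and
    exact within a band around the distances in ``interest`` (the tube
    surface and the outer shell boundary), where label decisions are made.
    Outside the sub-box the returned field is +inf.
    """
    slc, lo_i = _subbox(shape, origin, spacing, pts.min(0) - reach, pts.max(0) + reach)
    sub_shape = tuple(s.stop - s.start for s in slc)
    tree = cKDTree(pts)
    stride = 3

    axes = [(origin[d] + (lo_i[d] + np.arange(0, sub_shape[d], stride)) * spacing)
            for d in range(3)]
    cx, cy, cz = np.meshgrid(*axes, indexing="ij")
    coarse_pts = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
    d_c, j_c = tree.query(coarse_pts, workers=-1)
    ds_c = (d_c - radii[j_c]).astype(np.float32).reshape(cx.shape)
    del cx, cy, cz, coarse_pts, d_c, j_c

    fine = ds_c
    for ax in range(3):
        fine = np.repeat(fine, stride, axis=ax)
    fine = fine[:sub_shape[0], :sub_shape[1], :sub_shape[2]]

    err = (stride - 1) * spacing * np.sqrt(3.0) + 0.75 * spacing
    band = np.zeros(sub_shape, dtype=bool)
    for target in interest:
        band |= np.abs(fine - target) <= err
    bidx = np.argwhere(band)
    if len(bidx):
        centers = origin + (bidx + lo_i) * spacing
        d_e, j_e = tree.query(centers, workers=-1)
        fine[band] = (d_e - radii[j_e]).astype(np.float32)

    full = np.full(shape, np.inf, dtype=np.float32)
    full[slc] = fine
    return full


def _dehiscence_carve(shell_zone: np.ndarray, fraction: float, seed: int,
                      shape, spacing: float) -> np.ndarray:
    """Boolean mask of shell voxels carved open by a smooth random field."""
    if fraction <= 0 or not shell_zone.any():
        return np.zeros(shape, dtype=bool)
    rng = np.random.default_rng([int(seed), 0x0DE5])
    cell_mm = 0.25
    coarse_shape = tuple(int(np.ceil(s * spacing / cell_mm)) + 2 for s in shape)
    noise = rng.standard_normal(coarse_shape)
    noise = ndimage.gaussian_filter(noise, sigma=1.0)
    vidx = np.argwhere(shell_zone)
    coords = (vidx * (spacing / cell_mm)).T
    vals = ndimage.map_coordinates(noise, coords, order=1, mode="nearest")
    thresh = np.quantile(vals, 1.0 - fraction)
    carved = np.zeros(shape, dtype=bool)
    carved[tuple(vidx[vals > thresh].T)] = True
    return carved


def voxelize(model: AnatomyModel, spacing: float, *,
             voxel_budget: int = 200_000_000, pad: float = 0.7) -> LabelledVolume:
    """Rasterize an anatomy model into a labelled voxel volume.

    Voxels are labelled by signed-distance tests in a fixed priority order
    (canal > artery > membrane > perilymph > bony shell > bone > background),
    so overlapping structures resolve deterministically.  The bony shell of
    the configured thickness (at least one voxel) surrounds the canal, with
    dehiscences carved where a smooth random field on the shell exceeds the
    quantile matching ``dehiscence_fraction``.
    """
    if not (0.005 <= spacing <= 0.05):
        raise ValueError(f"spacing must lie in [0.005, 0.05] mm, got {spacing}")

    pts, cum = model.sample_centerline(max(int(np.ceil(
        model.arc_length() / (spacing / 2.0))), 64) + 1)
    t_dense = cum / cum[-1]
    radii = model.radius_fn(t_dense).astype(np.float32)
    shell_eff = max(model.shell_thickness_mm, 1.05 * spacing)

    # Field of view: every structure plus a bone margin.
    boxes = [pts.min(0) - (radii.max() + shell_eff + pad),
             pts.max(0) + (radii.max() + shell_eff + pad)]
    corners = [boxes[0], boxes[1]]
    if model.rw_disc is not None:
        c, n, (a, b) = model.rw_disc
        from .grids import inplane_basis
        e_sup, e_ant = inplane_basis(n)
        for sa in (-1, 1):
            for sb in (-1, 1):
                for sn in (-1, 1):
                    corners.append(c + sa * a * e_ant + sb * b * e_sup
                                   + sn * (model.rw_thickness / 2 + pad) * n)
    if model.artery_curve is not None:
        corners += [model.artery_curve.min(0) - (model.artery_radius + pad),
                    model.artery_curve.max(0) + (model.artery_radius + pad)]
    if model.stapedius_center is not None:
        corners += [model.stapedius_center - (model.stapedius_radius + 0.2),
                    model.stapedius_center + (model.stapedius_radius + 0.2)]
    if model.csf_cylinder is not None:
        r7, zlo, zhi = model.csf_cylinder
        corners += [np.array([-r7 - pad, -r7 - pad, zlo - pad]),
                    np.array([r7 + pad, r7 + pad, zhi + pad])]
    corners = np.asarray(corners)
    lo = np.floor(corners.min(0) / spacing) * spacing
    hi = corners.max(0)
    shape = tuple((np.ceil((hi - lo) / spacing)).astype(int) + 1)
    if int(np.prod(shape)) > voxel_budget:
        raise ValueError(
            f"voxel budget exceeded: grid {shape} has {int(np.prod(shape)):,} voxels; "
            "spacing too fine for this field of view")
    origin = lo

    px = (origin[0] + np.arange(shape[0]) * spacing)[:, None, None].astype(np.float32)
    py = (origin[1] + np.arange(shape[1]) * spacing)[None, :, None].astype(np.float32)
    pz = (origin[2] + np.arange(shape[2]) * spacing)[None, None, :].astype(np.float32)

    reach = float(radii.max()) + shell_eff + pad + 0.2
    d_surf = _canal_surface_distance(shape, origin, spacing, pts, radii, reach,
                                     interest=(0.0, shell_eff))

    if model.cap_style == "flat":
        # cut the tube at its end planes so both ends are flat faces; the cut
        # is applied only inside a ball around each end so it cannot clip
        # other windings of a coiled tube
        for end_pt, inner_pt, r_end in ((pts[0], pts[1], radii[0]),
                                        (pts[-1], pts[-2], radii[-1])):
            outward = end_pt - inner_pt
            outward = (outward / np.linalg.norm(outward)).astype(np.float32)
            ball_r = float(r_end) + shell_eff + 4 * spacing
            d2 = ((px - end_pt[0]) ** 2 + (py - end_pt[1]) ** 2
                  + (pz - end_pt[2]) ** 2)
            excess = ((px - end_pt[0]) * outward[0] + (py - end_pt[1]) * outward[1]
                      + (pz - end_pt[2]) * outward[2])
            local = d2 <= ball_r ** 2
            d_surf[local] = np.maximum(d_surf[local], excess[local])
    elif model.cap_style != "round":
        raise ValueError(f"unknown cap_style {model.cap_style!r}")

    grid = np.zeros(shape, dtype=np.uint8)
    capsule = d_surf <= shell_eff + pad  # bone margin around the canal

    # Central CSF nerve-exit space (label 7) inside the modiolus.
    if model.csf_cylinder is not None:
        r7, zlo, zhi = model.csf_cylinder
        rho = np.sqrt(px ** 2 + py ** 2)
        csf = (rho <= r7) & (pz >= zlo) & (pz <= zhi)
        capsule |= (rho <= r7 + pad) & (pz >= zlo - pad) & (pz <= zhi + pad)
        del rho
    else:
        csf = None

    d_st = dn_rw = None
    if model.rw_disc is not None:
        c, n, (_, _) = model.rw_disc
        # signed distance to the membrane plane (positive = superficial side)
        dn_rw = ((px - c[0]) * n[0] + (py - c[1]) * n[1] + (pz - c[2]) * n[2])
    if model.scala_axis is not None:
        d_st = _segment_distance(px, py, pz, *model.scala_axis)
        capsule |= d_st <= model.scala_radius + pad

    rw = None
    if model.rw_disc is not None:
        c, n, (a, b) = model.rw_disc
        e_sup, e_ant = inplane_basis(n)
        half = np.array([a * abs(e_ant[d]) + b * abs(e_sup[d])
                         + (model.rw_thickness / 2 + pad) * abs(n[d]) + 0.3
                         for d in range(3)])
        slc, lo_i = _subbox(shape, origin, spacing, c - half, c + half)
        lx, ly, lz = _axes_world(slc, lo_i, origin, spacing)
        wx, wy, wz = lx - c[0], ly - c[1], lz - c[2]
        dn = wx * n[0] + wy * n[1] + wz * n[2]
        da = wx * e_ant[0] + wy * e_ant[1] + wz * e_ant[2]
        ds = wx * e_sup[0] + wy * e_sup[1] + wz * e_sup[2]
        ellipse = (da / a) ** 2 + (ds / b) ** 2
        rw = (slc, (np.abs(dn) <= model.rw_thickness / 2) & (ellipse <= 1.0))
        capsule[slc] |= (np.abs(dn) <= model.rw_thickness / 2 + pad) & (ellipse <= 1.44)
        del wx, wy, wz, dn, da, ds, ellipse

    art = None
    if model.artery_curve is not None:
        a0, a1 = model.artery_curve[0], model.artery_curve[-1]
        m = model.artery_radius + pad
        slc, lo_i = _subbox(shape, origin, spacing,
                            np.minimum(a0, a1) - m, np.maximum(a0, a1) + m)
        lx, ly, lz = _axes_world(slc, lo_i, origin, spacing)
        d_art = _segment_distance(lx, ly, lz, a0, a1)
        art = (slc, d_art <= model.artery_radius)
        capsule[slc] |= d_art <= model.artery_radius + pad
        del d_art

    stap = None
    if model.stapedius_center is not None:
        sc, rs = model.stapedius_center, model.stapedius_radius
        slc, lo_i = _subbox(shape, origin, spacing, sc - rs - 0.2, sc + rs + 0.2)
        lx, ly, lz = _axes_world(slc, lo_i, origin, spacing)
        blob = (np.sqrt((lx - sc[0]) ** 2 + (ly - sc[1]) ** 2 + (lz - sc[2]) ** 2) <= rs)
        stap = (slc, blob)
        capsule[slc] |= blob

    # Compose labels from lowest to highest priority.
    grid[capsule] = 1
    del capsule
    if csf is not None:
        grid[csf & (d_surf > shell_eff)] = 7
        del csf
    if d_st is not None:
        # perilymph fills the scala tube deep to the membrane plane, never
        # replacing the (at least one voxel thick) bony cover of the canal
        peri = (d_st <= model.scala_radius) & (d_surf > shell_eff)
        if dn_rw is not None:
            peri &= dn_rw <= spacing
        grid[peri] = 2
        del peri, d_st, dn_rw
    if stap is not None:
        grid[stap[0]][stap[1]] = 6

    shell_zone = (d_surf > 0) & (d_surf <= shell_eff)
    carved = _dehiscence_carve(shell_zone, model.dehiscence_fraction,
                               model.seed, shape, spacing)
    grid[carved] = 2
    del shell_zone, carved

    if rw is not None:
        grid[rw[0]][rw[1]] = 4
    if art is not None:
        grid[art[0]][art[1]] = 5
    grid[d_surf <= 0] = 3
    del d_surf

    return LabelledVolume(grid=grid, spacing=float(spacing), origin=np.asarray(origin))


# -- ground-truth IO -----------------------------------------------------------

def write_ground_truth(params: SpecimenParams, model: AnatomyModel,
                       path: str | Path) -> Path:
    """Write params plus a model summary as human-readable JSON."""
    path = Path(path)
    data = {
        "format": "rcmorph-ground-truth-1",
        "params": dataclasses.asdict(params),
        "model_summary": {
            "arc_length_mm": model.arc_length(),
            "label_scheme": model.labels_meta,
            "shell_thickness_mm": model.shell_thickness_mm,
            "stapedius_region": list(model.stapedius_region),
            "artery_present": model.artery_curve is not None,
        },
    }
    path.write_text(json.dumps(data, indent=2))
    return path


def read_ground_truth(path: str | Path) -> tuple[SpecimenParams, dict]:
    """Read a ground-truth file; returns (params, model summary)."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise GroundTruthParseError(f"not valid JSON: {exc}") from exc
    if "params" not in data:
        raise GroundTruthParseError("missing field: params")
    raw = data["params"]
    kwargs = {}
    for f in dataclasses.fields(SpecimenParams):
        if f.name not in raw:
            raise GroundTruthParseError(f"missing field: {f.name}")
        v = raw[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[f.name] = v
    if not isinstance(kwargs["seed"], int):
        raise GroundTruthParseError(f"seed must be an integer, got {kwargs['seed']!r}")
    params = SpecimenParams(**kwargs)
    params.validate()
    return params, data.get("model_summary", {})


# -- cohorts -------------------------------------------------------------------

def cohort_seeds(n: int, seed: int) -> list[int]:
    """Derive n per-specimen seeds from a master seed (deterministic)."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def generate_cohort(n: int, seed: int, config: GeneratorConfig | None = None,
                    spacing: float = 0.018, out_dir: str | Path | None = None,
                    fmt: str = "nrrd"):
    """Generate a cohort of specimens; yields (params, model, volume).

    If ``out_dir`` is given, each specimen's volume and ground truth are
    written there as ``specimen_XX.<fmt>`` / ``specimen_XX.json``.
    """
    from .volume import write_volume

    config = config or GeneratorConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(cohort_seeds(n, seed)):
        params = sample_specimen_params(s, config)
        model = build_model(params, config)
        volume = voxelize(model, spacing)
        if out_dir is not None:
            ext = {"nrrd": ".nrrd", "nifti": ".nii.gz"}[fmt]
            write_volume(volume, out_dir / f"specimen_{i:02d}{ext}")
            write_ground_truth(params, model, out_dir / f"specimen_{i:02d}.json")
        yield params, model, volume
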