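"""Shared fixtures: a small fast specimen and its voxelized volume."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from rcmorph.config import GeneratorConfig
from rcmorph.synthetic import SpecimenParams, build_model, voxelize

MINI_SPACING = 0.024


def mini_config(**overrides) -> GeneratorConfig:
    """Generator config scaled to a small, fast specimen geometry."""
    base = dict(csf_radius=0.5, csf_z_range=(0.15, 1.5), scala_radius=0.8,
                stapedius_radius=0.25)
    base.update(overrides)
    return GeneratorConfig(**base)


def mini_params(seed: int = 0, **overrides) -> SpecimenParams:
    """A hand-sized specimen (6 mm canal) for fast unit tests."""
    depth, d0 = 2.5, 0.12
    basal = np.array([0.9, 0.0, 0.0])
    u = np.array([1.0, 0.0, 0.0])
    center = basal + (depth + d0 / 2) * u + np.array([0.0, 0.0, -0.15])
    base = dict(
        seed=seed,
        helix_base_radius=0.9, helix_apical_radius=0.5,
        helix_pitch=1.5, n_turns=1.2, target_length=6.0,
        canal_diam_base=d0, canal_diam_45=0.30, canal_diam_90=0.36,
        canal_diam_apex=0.40,
        shell_thickness=40.0, dehiscence_fraction=0.0,
        rw_center=tuple(center), rw_normal=tuple(u), rw_semiaxes=(0.7, 0.5),
        rw_depth_to_canal=depth, artery_offset=1.2, artery_present=True,
        stapedius_cells=("D1",),
    )
    base.update(overrides)
    return SpecimenParams(**base)


@pytest.fixture(scope="session")
def mini_specimen():
    """(params, model, volume) of the small specimen at 24 µm spacing."""
    params = mini_params()
    config = mini_config()
    model = build_model(params, config)
    volume = voxelize(model, MINI_SPACING)
    return params, model, volume


@pytest.fixture()
def mini_cfg():
    return mini_config()
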