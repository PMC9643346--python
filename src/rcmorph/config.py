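"""Generator configuration: every distribution parameter of the synthetic cohort.

Defaults reproduce the cohort statistics of the ten-bone study the generator
emulates: canal length 14.568 ± 0.36058 mm, station diameters 0.109 / 0.427 /
0.502 mm at the base / 45° / 90° cochlear-angle stations, a 28–56 µm bony
cover, and a round-window membrane lying 3–4 mm superficial to the basal
canal.  Values not reported there (helix radii, turns, membrane semi-axes)
are literature-typical choices and are documented as such in the methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for invalid or inconsistent generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    # Canal arc length (mm): truncated normal.
    length_mean: float = 14.568
    length_sd: float = 0.36058
    length_bounds: tuple[float, float] = (13.5, 16.0)

    # Station diameters (mm): normals with monotone base <= 45 <= 90 <= apex
    # enforced by rejection.
    diam_base_mean: float = 0.109
    diam_base_sd: float = 0.023
    diam_45_mean: float = 0.427
    diam_45_sd: float = 0.069
    diam_90_mean: float = 0.502
    diam_90_sd: float = 0.072
    diam_apex_mean: float = 0.52
    diam_apex_sd: float = 0.05
    diam_min: float = 0.04

    # Helical geometry of the canal about the modiolar axis (mm / turns).
    helix_base_radius_mean: float = 1.6
    helix_base_radius_sd: float = 0.05
    helix_apical_radius_mean: float = 0.7
    helix_apical_radius_sd: float = 0.04
    n_turns_mean: float = 1.8
    n_turns_sd: float = 0.05
    pitch_initial: float = 2.0

    # Bony cover over the canal (µm): uniform.
    shell_thickness_range: tuple[float, float] = (28.0, 56.0)
    # Fraction of the shell surface that is dehiscent: uniform.
    dehiscence_fraction_range: tuple[float, float] = (0.0, 0.1)

    # Round-window membrane pose and size.
    rw_depth_range: tuple[float, float] = (3.0, 4.0)      # membrane -> canal surface, mm
    rw_semiaxes: tuple[float, float] = (0.9, 0.65)        # (anterior, superior) semi-axes, mm
    rw_thickness: float = 0.07                            # membrane slab thickness, mm
    rw_tilt_deg_mean: float = 20.0                        # azimuth of outward normal vs +x
    rw_tilt_deg_sd: float = 3.0
    rw_sup_offset_mean: float = -0.2                      # membrane center z - basal canal z, mm
    rw_sup_offset_sd: float = 0.05

    # Vestibulocochlear artery near the anterior (column-1) cells.
    artery_fraction: float = 1.0                          # fraction of specimens with artery present
    artery_offset_range: tuple[float, float] = (1.0, 1.8) # depth below membrane, mm
    artery_radius: float = 0.1

    # Stapedius muscle occludes these grid cells.
    stapedius_cells: tuple[str, ...] = ("D1",)
    stapedius_radius: float = 0.3

    # Scala tympani tube and central CSF space.
    scala_radius: float = 1.3
    csf_radius: float = 1.12
    csf_z_range: tuple[float, float] = (0.2, 4.2)

    max_rejects: int = 1000

    def validate(self) -> None:
        import math

        for name in ("length_mean", "diam_base_mean", "diam_45_mean", "diam_90_mean",
                     "diam_apex_mean", "helix_base_radius_mean", "helix_apical_radius_mean",
                     "n_turns_mean", "pitch_initial", "artery_radius", "scala_radius"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ConfigError(f"{name} must be finite and positive, got {v}")
        for name in ("length_sd", "diam_base_sd", "diam_45_sd", "diam_90_sd",
                     "diam_apex_sd", "helix_base_radius_sd", "helix_apical_radius_sd",
                     "n_turns_sd", "rw_tilt_deg_sd", "rw_sup_offset_sd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ConfigError(f"{name} must be finite and non-negative, got {v}")
        for name in ("length_bounds", "shell_thickness_range", "dehiscence_fraction_range",
                     "rw_depth_range", "artery_offset_range", "csf_z_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ConfigError(f"{name} must be an ordered finite interval, got ({lo}, {hi})")
        if not (0.0 <= self.artery_fraction <= 1.0):
            raise ConfigError(f"artery_fraction must lie in [0, 1], got {self.artery_fraction}")
        if self.max_rejects < 1:
            raise ConfigError("max_rejects must be >= 1")


_TUPLE_FIELDS = {f.name for f in dataclasses.fields(GeneratorConfig)
                 if "tuple" in str(f.type)}


def load_config(path: str | Path) -> GeneratorConfig:
    """Load a generator config from a YAML file; missing keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, value in raw.items():
        if key in _TUPLE_FIELDS:
            value = tuple(value)
        coerced[key] = value
    cfg = GeneratorConfig(**coerced)
    cfg.validate()
    return cfg


def save_config(config: GeneratorConfig, path: str | Path) -> Path:
    path = Path(path)
    data = dataclasses.asdict(config)
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
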