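"""YAML configuration for the simulator (geometry, spectrum, yield).

Schema (all keys optional; defaults are the package defaults)::

    geometry:
      half_width_x: 1.5        # mm
      half_width_y: 1.5        # mm
      length_z: 10.0           # mm
      n_crystal: 2.15
      n_coupling: 1.56
      reflector_reflectivity: 0.95
      attenuation_length: 300.0  # mm; use .inf for none
      max_bounces: 1000
    spectrum:
      mean_energy: 2.58        # eV
      sd_energy: 0.15          # eV
    yield:
      mean_photons_per_event: 2400.0
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .optics import CrystalGeometry, EmissionSpectrum, YieldModel

__all__ = ["SimulationConfig", "load_config"]


class SimulationConfig:
    """Bundle of geometry, emission spectrum and yield model."""

    def __init__(self, geometry=None, spectrum=None, yield_model=None):
        self.geometry = geometry or CrystalGeometry()
        self.spectrum = spectrum or EmissionSpectrum()
        self.yield_model = yield_model or YieldModel()


def load_config(path=None) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file (or defaults)."""
    if path is None:
        return SimulationConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {"geometry", "spectrum", "yield"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return SimulationConfig(
        geometry=CrystalGeometry(**raw.get("geometry", {})),
        spectrum=EmissionSpectrum(**raw.get("spectrum", {})),
        yield_model=YieldModel(**raw.get("yield", {})),
    )
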