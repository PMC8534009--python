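"""Shared domain containers for the barrier-integrity pipeline.

Unit conventions used throughout the package: volumes in mL (= cm^3),
areas in cm^2, concentrations in uM, lengths in um for images, time in
minutes at the interface and seconds internally, permeability in cm/s.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AssayGeometry:
    """Transwell geometry and sampling protocol for a permeability assay.

    Defaults follow the standard small-solute protocol: 0.9 cm^2 insert,
    1.5 mL lower / 0.5 mL upper chamber, 30 uM tracer in the upper
    chamber, 50 uL samples drawn from the lower chamber every 10 min for
    90 min and replaced with fresh medium.
    """

    membrane_area_cm2: float = 0.9
    lower_volume_ml: float = 1.5
    upper_volume_ml: float = 0.5
    upper_conc_um: float = 30.0
    sample_volume_ml: float = 0.05
    sample_interval_min: float = 10.0
    duration_min: float = 90.0

    def __post_init__(self) -> None:
        for name in ("membrane_area_cm2", "lower_volume_ml", "upper_volume_ml",
                     "upper_conc_um", "sample_interval_min", "duration_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sample_volume_ml < 0:
            raise ValueError("sample_volume_ml must be non-negative")
        if self.sample_volume_ml >= self.lower_volume_ml:
            raise ValueError("sample_volume_ml must be smaller than lower_volume_ml")
        if self.duration_min < self.sample_interval_min:
            raise ValueError("duration_min must be at least one sample interval")


@dataclass
class TranswellSeries:
    """Sampled lower-chamber tracer concentrations from one Transwell run.

    ``times_min`` starts at 0 and is strictly increasing; ``lower_conc_um``
    holds the concentration measured in each drawn sample (pre-replacement).
    """

    times_min: np.ndarray
    lower_conc_um: np.ndarray
    geometry: AssayGeometry
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.lower_conc_um = np.asarray(self.lower_conc_um, dtype=float)
        if self.times_min.shape != self.lower_conc_um.shape:
            raise ValueError("times and concentrations must have equal length")
        if self.times_min.size and self.times_min[0] != 0:
            raise ValueError("time axis must start at 0")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.lower_conc_um < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass
class PermeabilityResult:
    """Apparent and monolayer permeabilities for one Transwell series.

    ``p_total`` is the permeability of monolayer plus insert, ``p_insert``
    the blank-filter permeability, and ``p_barrier`` the monolayer-only
    value obtained from the series-resistance relation
    1/p_total = 1/p_barrier + 1/p_insert.
    """

    p_total: float
    slope_um_per_s: float
    slope_r2: float
    p_insert: float | None = None
    p_barrier: float | None = None


@dataclass(frozen=True)
class TeerRecord:
    """One background-corrected, area-normalised TEER measurement."""

    total_resistance_ohm: float
    blank_resistance_ohm: float
    membrane_area_cm2: float
    teer_ohm_cm2: float


@dataclass
class ImageStack:
    """A 3-D fluorescence stack (z, y, x) with physical pixel size."""

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float = 0.2
    channel: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D (z, y, x) array")
        if self.voxels.size == 0:
            raise ValueError("stack has no voxels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with WT/DEL group labels.

    ``counts`` is a DataFrame (index = gene ids, columns = sample ids);
    ``sample_groups`` maps each column to "WT" or "DEL". ``truth`` is an
    optional per-gene ground-truth table attached by the synthetic
    generator (columns: true_log2fc, is_de, in_deletion).
    """

    counts: "object"
    sample_groups: dict[str, str]
    truth: "object | None" = None

    def __post_init__(self) -> None:
        missing = [c for c in self.counts.columns if c not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        groups = set(self.sample_groups.values())
        if not groups <= {"WT", "DEL"}:
            raise ValueError("sample groups must be 'WT' or 'DEL'")

    def samples_in(self, group: str) -> list[str]:
        return [c for c in self.counts.columns if self.sample_groups[c] == group]
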