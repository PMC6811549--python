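"""Core in-memory containers for sweep-based intracellular recordings.

Units are fixed package-wide: time in seconds for sweep-level bookkeeping
(marker times, ``dt``), milliseconds inside analysis windows where noted,
voltage in mV, current in pA, conductance in nS, capacitance in pF.
A :class:`Sweep` stores the recorded channel (mV in current clamp, pA in
voltage clamp) together with the command/stimulus channel (pA or mV) and
event markers (uncaging times, stimulus times, simulator spike times).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"

ClampMode = Literal["current_clamp", "voltage_clamp"]


@dataclass
class Sweep:
    """One recorded sweep: signal + stimulus + markers.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds (20 kHz acquisition -> 5e-5).
    samples : ndarray
        Recorded channel; mV in current clamp, pA in voltage clamp.
    stimulus : ndarray
        Command channel, same length; pA in current clamp, mV in voltage clamp.
    mode : str
        ``"current_clamp"`` or ``"voltage_clamp"``.
    markers : list of (label, time_s)
        Event markers with times in seconds from sweep start.
    holding : float
        Holding level: mV (voltage clamp) or pA (current clamp bias).
    """

    dt: float
    samples: np.ndarray
    stimulus: np.ndarray
    mode: ClampMode = CURRENT_CLAMP
    markers: list[tuple[str, float]] = field(default_factory=list)
    holding: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.stimulus = np.asarray(self.stimulus, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if len(self.samples) != len(self.stimulus):
            raise ValueError(
                f"samples ({len(self.samples)}) and stimulus "
                f"({len(self.stimulus)}) lengths differ"
            )
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValueError(f"unknown clamp mode {self.mode!r}")
        dur = self.duration
        for label, t in self.markers:
            if not (0.0 <= t < dur):
                raise ValueError(
                    f"marker {label!r} at {t} s outside sweep [0, {dur}) s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Sweep duration in seconds."""
        return self.n_samples * self.dt

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) * self.dt

    def marker_times(self, label: str) -> list[float]:
        return [t for lab, t in self.markers if lab == label]


@dataclass
class CellRecord:
    """All sweeps from one cell, grouped by protocol, with nesting metadata.

    ``litter_id``/``animal_id``/``slice_id`` carry the hierarchical structure
    used as random effects in the group-level models.  ``qc`` holds measured
    quality-control quantities (holding current, V_m, series resistance);
    ``ground_truth`` holds simulator parameters when the cell is synthetic.
    """

    cell_id: str
    genotype: str
    animal_id: str
    litter_id: str = ""
    slice_id: str = ""
    sweeps: dict[str, list[Sweep]] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cell_id", "genotype", "animal_id"):
            if not getattr(self, name):
                raise ValueError(f"CellRecord requires non-empty {name}")

    def protocol(self, name: str) -> list[Sweep]:
        return self.sweeps.get(name, [])


@dataclass
class Cohort:
    """A set of cells plus provenance (seed, preset names) when synthetic."""

    cells: list[CellRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell_ids within a cohort must be unique")

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def by_genotype(self, genotype: str) -> list[CellRecord]:
        return [c for c in self.cells if c.genotype == genotype]

    def genotypes(self) -> list[str]:
        seen: list[str] = []
        for c in self.cells:
            if c.genotype not in seen:
                seen.append(c.genotype)
        return seen
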