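"""Shared acquisition and paradigm types.

These small value objects describe *when* and *on what grid* data were
acquired; every other module consumes them.  Times are seconds unless a
field name says otherwise (echo/repetition times are milliseconds, the
unit they are quoted in on the scanner console).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcqGeometry",
    "BlockParadigm",
    "BreathHoldParadigm",
    "PCASL_GEOMETRY",
    "SBO_GEOMETRY",
    "child_seed",
]


@dataclass(frozen=True)
class AcqGeometry:
    """Acquisition geometry and timing of an imaging series.

    Parameters
    ----------
    matrix_dims : tuple of int
        In-plane and through-plane matrix size (voxels).
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    tr : float
        Repetition time, ms.
    te1, te2 : float
        First and second echo times, ms. ``te1 < te2``.
    field_strength : float
        Main field, tesla.
    n_dynamics : int
        Number of repeated measurements (for ASL: label/control pairs).
    """

    matrix_dims: tuple[int, ...]
    voxel_size: tuple[float, ...]
    tr: float
    te1: float
    te2: float
    field_strength: float = 3.0
    n_dynamics: int = 1

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.matrix_dims):
            raise ValueError("matrix dimensions must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.tr <= 0 or self.te1 <= 0 or self.te2 <= 0:
            raise ValueError("timing parameters must be positive")
        if not self.te1 < self.te2:
            raise ValueError("te1 must be shorter than te2")
        if self.field_strength <= 0:
            raise ValueError("field strength must be positive")
        if self.n_dynamics < 1:
            raise ValueError("need at least one dynamic")

    @property
    def delta_te(self) -> float:
        """Inter-echo time TE2 - TE1, ms."""
        return self.te2 - self.te1


@dataclass(frozen=True)
class BlockParadigm:
    """Alternating rest/stimulation block design, starting and ending with rest.

    The default is the visual-stimulation design: four 54-s flickering
    checkerboard blocks separated (and flanked) by 54-s rest segments,
    i.e. 9 segments / 486 s in total.
    """

    segment_duration: float = 54.0
    n_stim_blocks: int = 4

    def __post_init__(self) -> None:
        if self.segment_duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.n_stim_blocks < 0:
            raise ValueError("number of stimulation blocks cannot be negative")

    @property
    def total_duration(self) -> float:
        return self.segment_duration * (2 * self.n_stim_blocks + 1)

    def boxcar(self, t: np.ndarray) -> np.ndarray:
        """Unit-height stimulus indicator evaluated at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        seg = np.floor_divide(t, self.segment_duration).astype(int)
        on = (seg % 2 == 1) & (seg < 2 * self.n_stim_blocks + 1) & (t >= 0)
        return on.astype(float)


@dataclass(frozen=True)
class BreathHoldParadigm:
    """Breath-hold challenge timing: 50-s free-breathing baseline, then
    two 36-s holds separated by a 50-s break."""

    baseline: float = 50.0
    hold_duration: float = 36.0
    n_holds: int = 2
    break_duration: float = 50.0

    def __post_init__(self) -> None:
        if min(self.baseline, self.hold_duration, self.break_duration) <= 0:
            raise ValueError("paradigm durations must be positive")
        if self.n_holds < 1:
            raise ValueError("need at least one breath hold")

    @property
    def total_duration(self) -> float:
        return (
            self.baseline
            + self.n_holds * self.hold_duration
            + (self.n_holds - 1) * self.break_duration
        )

    def hold_windows(self) -> list[tuple[float, float]]:
        """(start, end) of each hold in seconds from series start."""
        out = []
        t = self.baseline
        for _ in range(self.n_holds):
            out.append((t, t + self.hold_duration))
            t += self.hold_duration + self.break_duration
        return out


# Desk-scale default geometries.  In-plane matrix reduced relative to the
# acquisition; timing parameters are the acquisition values.
PCASL_GEOMETRY = AcqGeometry(
    matrix_dims=(32, 32, 8),
    voxel_size=(2.75, 2.75, 5.0),
    tr=4550.0,
    te1=13.0,
    te2=31.7,
    field_strength=3.0,
    n_dynamics=54,
)

SBO_GEOMETRY = AcqGeometry(
    matrix_dims=(64, 64, 1),
    voxel_size=(0.5, 0.5, 8.0),
    tr=30.0,
    te1=10.89,
    te2=24.16,
    field_strength=3.0,
    n_dynamics=5,
)


def child_seed(seed: int, *labels: object) -> int:
    """Derive a reproducible child seed (< 2**31) from a parent seed and labels.

    Used to fan a single run seed out to per-subject, per-modality
    generators without correlation between streams.
    """
    key = ("|".join(str(x) for x in (seed, *labels))).encode()
    return zlib.crc32(key) % (2**31)
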