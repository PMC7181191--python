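"""Acquisition-scheme parameters and spoiled gradient-echo signal physics.

A multiband (MB) EPI scheme is described by its repetition time TR, multiband
factor, in-plane SENSE acceleration, voxel geometry and flip angle.  At a
given TR the flip angle that maximizes steady-state signal for tissue with
longitudinal relaxation time T1 is the Ernst angle
``theta_E = arccos(exp(-TR/T1))``; the corresponding steady-state signal
(relative to full magnetization) is ``sqrt((1 - E) / (1 + E))`` with
``E = exp(-TR/T1)``.  Shorter TRs therefore trade reduced longitudinal
recovery (lower signal per frame, lower grey-white contrast) against more
samples per unit time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "SequenceSpec",
    "TissueRelaxation",
    "ernst_angle",
    "steady_state_signal",
    "volumes_for_duration",
    "load_sequence_table",
    "save_sequence_table",
    "default_sequence_table",
]

#: Conventional grey-matter T1 at 3 T used when none is supplied.  This value
#: reproduces the Ernst-optimized flip angles of the five bundled schemes.
DEFAULT_T1_GREY_S = 1.5


@dataclass(frozen=True)
class TissueRelaxation:
    """Longitudinal relaxation and proton density of grey and white matter."""

    t1_grey: float = DEFAULT_T1_GREY_S
    t1_white: float = 0.9
    proton_density_grey: float = 1.0
    proton_density_white: float = 0.75

    def __post_init__(self) -> None:
        for name in ("t1_grey", "t1_white", "proton_density_grey", "proton_density_white"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t1_grey <= self.t1_white:
            raise ValueError("t1_grey must exceed t1_white at 3 T")


@dataclass(frozen=True)
class SequenceSpec:
    """Parameters of one acquisition scheme.

    Parameters
    ----------
    name:
        Scheme label, e.g. ``"MB4S22.7iso0.63"``.
    tr:
        Volume repetition time in seconds.
    mb_factor:
        Multiband (simultaneous multislice) factor, >= 1.
    sense_factor:
        In-plane SENSE acceleration, > 0.
    voxel_dims:
        Acquired voxel size in mm, (x, y, z).
    slice_gap:
        Gap between slices in mm.
    flip_angle:
        Excitation flip angle in degrees.
    n_volumes:
        Number of volumes acquired in one session.
    n_slices:
        Slices per volume.
    """

    name: str
    tr: float
    mb_factor: int = 1
    sense_factor: float = 1.0
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 3.0)
    slice_gap: float = 0.0
    flip_angle: float = 90.0
    n_volumes: int = 1
    n_slices: int = 1

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.mb_factor < 1:
            raise ValueError("mb_factor must be >= 1")
        if self.sense_factor <= 0:
            raise ValueError("sense_factor must be positive")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel dimensions must be positive")
        if self.mb_factor * self.sense_factor < 1:
            raise ValueError("total acceleration mb*sense must be >= 1")
        if self.n_volumes < 1 or self.n_slices < 1:
            raise ValueError("n_volumes and n_slices must be >= 1")

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        vx, vy, vz = self.voxel_dims
        return vx * vy * vz

    @property
    def total_acceleration(self) -> float:
        return self.mb_factor * self.sense_factor

    @property
    def session_duration(self) -> float:
        """Nominal session length in seconds (``n_volumes * tr``)."""
        return self.n_volumes * self.tr

    def check_session_duration(self, duration: float, tolerance: float = 0.10) -> None:
        """Raise if ``n_volumes * tr`` is not within ``tolerance`` of ``duration``."""
        if abs(self.session_duration - duration) > tolerance * duration:
            raise ValueError(
                f"{self.name}: n_volumes*tr = {self.session_duration:.1f} s is not "
                f"within {tolerance:.0%} of session duration {duration:.1f} s"
            )


def ernst_angle(tr: float, t1: float = DEFAULT_T1_GREY_S) -> float:
    """Ernst angle in degrees for repetition time ``tr`` and relaxation ``t1``.

    The signal-maximizing flip angle of a spoiled gradient-echo sequence,
    ``arccos(exp(-tr/t1))``, always in the open interval (0, 90) degrees.
    """
    if tr <= 0 or t1 <= 0:
        raise ValueError("tr and t1 must be positive")
    return math.degrees(math.acos(math.exp(-tr / t1)))


def steady_state_signal(tr: float, t1: float = DEFAULT_T1_GREY_S) -> float:
    """Relative steady-state signal at the Ernst angle.

    ``sqrt((1 - E)/(1 + E))`` with ``E = exp(-tr/t1)``; strictly increasing
    in ``tr`` with limit 1 as TR grows (full longitudinal recovery).
    """
    if tr <= 0 or t1 <= 0:
        raise ValueError("tr and t1 must be positive")
    e1 = math.exp(-tr / t1)
    return math.sqrt((1.0 - e1) / (1.0 + e1))


def volumes_for_duration(duration: float, tr: float) -> int:
    """Whole volumes acquirable in ``duration`` seconds at repetition time ``tr``."""
    if duration <= 0 or tr <= 0:
        raise ValueError("duration and tr must be positive")
    # guard against floating-point shortfall on exact multiples (490/2.45)
    return int(math.floor(duration / tr + 1e-9))


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


_TABLE_COLUMNS = [
    "name", "tr_s", "mb", "sense", "vx_mm", "vy_mm", "vz_mm",
    "gap_mm", "flip_deg", "n_volumes", "n_slices",
]


def load_sequence_table(path: str | Path) -> list[SequenceSpec]:
    """Read acquisition schemes from a CSV table.

    Columns: ``name, tr_s, mb, sense, vx_mm, vy_mm, vz_mm, gap_mm, flip_deg,
    n_volumes, n_slices``.  Volume counts are taken as given, not recomputed.
    """
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sequence table missing columns: {sorted(missing)}")
    specs = []
    for row in df.itertuples(index=False):
        specs.append(
            SequenceSpec(
                name=str(row.name),
                tr=float(row.tr_s),
                mb_factor=int(row.mb),
                sense_factor=float(row.sense),
                voxel_dims=(float(row.vx_mm), float(row.vy_mm), float(row.vz_mm)),
                slice_gap=float(row.gap_mm),
                flip_angle=float(row.flip_deg),
                n_volumes=int(row.n_volumes),
                n_slices=int(row.n_slices),
            )
        )
    return specs


def save_sequence_table(specs: list[SequenceSpec], path: str | Path) -> None:
    """Write acquisition schemes to CSV in the canonical column order."""
    rows = []
    for s in specs:
        vx, vy, vz = s.voxel_dims
        rows.append(
            dict(
                name=s.name, tr_s=s.tr, mb=s.mb_factor, sense=s.sense_factor,
                vx_mm=vx, vy_mm=vy, vz_mm=vz, gap_mm=s.slice_gap,
                flip_deg=s.flip_angle, n_volumes=s.n_volumes, n_slices=s.n_slices,
            )
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)


def default_sequence_table() -> list[SequenceSpec]:
    """The five bundled acquisition schemes (TRs 2.45/2.00/1.22/0.70/0.63 s)."""
    with resources.as_file(
        resources.files("mbfmri").joinpath("data/sequence_table.csv")
    ) as p:
        return load_sequence_table(p)
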