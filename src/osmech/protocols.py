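"""Step-stress measurement protocols for the optical stretcher.

A protocol describes one creep experiment: the cell is held at trapping
power, a step stress is switched on for the stretch duration and the
relaxation at trapping power is recorded afterwards.  The step stress and
peak stretching force scale linearly with laser power (see
:mod:`osmech.rheology` for the calibration coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class StretchProtocol:
    """Timing and loading of a single step-stress creep measurement.

    Parameters
    ----------
    laser_power : float
        Stretching laser power in mW.
    step_stress : float
        Peak surface stress applied during the stretch phase, in Pa.
    peak_force : float
        Peak stretching force in pN.
    pre_stretch_duration : float
        Trap-only baseline recorded before the step, in s.
    stretch_duration : float
        Duration of the step stress, in s.
    relax_duration : float
        Observation time at trapping power after the step, in s.
    frame_rate : float
        Camera frame rate in Hz.
    """

    laser_power: float
    step_stress: float
    peak_force: float = 0.0
    pre_stretch_duration: float = 1.0
    stretch_duration: float = 10.0
    relax_duration: float = 2.0
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.laser_power < 0:
            raise ValueError("laser_power must be >= 0")
        if self.step_stress < 0:
            raise ValueError("step_stress must be >= 0")
        if self.stretch_duration <= 0:
            raise ValueError("stretch_duration must be > 0")
        if self.relax_duration < 0:
            raise ValueError("relax_duration must be >= 0")
        if self.pre_stretch_duration < 0:
            raise ValueError("pre_stretch_duration must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def total_duration(self) -> float:
        return self.pre_stretch_duration + self.stretch_duration + self.relax_duration

    @property
    def n_frames(self) -> int:
        """Number of frames recorded: floor(total duration x rate) + 1."""
        return int(self.total_duration * self.frame_rate) + 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StretchProtocol":
        return cls(**d)


def clinical_protocols(frame_rate: float = 30.0) -> list[StretchProtocol]:
    """The three-power clinical protocol set: 400/800/1200 mW, 10 s + 2 s.

    Each cell is measured at one power, chosen at random per cell, so that
    the cohort covers a broad force regime (roughly 0.4-1.1 Pa).
    """
    from .rheology import stress_from_power, force_from_power

    return [
        StretchProtocol(
            laser_power=p,
            step_stress=stress_from_power(p),
            peak_force=force_from_power(p),
            pre_stretch_duration=1.0,
            stretch_duration=10.0,
            relax_duration=2.0,
            frame_rate=frame_rate,
        )
        for p in (400.0, 800.0, 1200.0)
    ]


def cell_line_protocol(frame_rate: float = 30.0) -> StretchProtocol:
    """Single-power cell-line protocol: 875 mW, 5 s stretch + 2 s relaxation."""
    from .rheology import stress_from_power, force_from_power

    return StretchProtocol(
        laser_power=875.0,
        step_stress=stress_from_power(875.0),
        peak_force=force_from_power(875.0),
        pre_stretch_duration=1.0,
        stretch_duration=5.0,
        relax_duration=2.0,
        frame_rate=frame_rate,
    )
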