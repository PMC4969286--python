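"""Stimulation protocol dosimetry: injection time, total charge, current density.

Waveform kinds
--------------
``tdcs``
    Continuous direct current for the whole session.
``tpcs``
    Rectangular pulses of fixed duration repeated at a fixed rate; the
    period is ``pulse + inter-pulse interval`` (or ``1/frequency`` when the
    interval is not given), so current flows for the duty-cycle fraction of
    the session.
``so_tdcs``
    Slow-oscillatory direct current: a 0-to-peak sinusoid, flowing for the
    whole session with time-average amplitude of half the peak.  The
    half-amplitude mean is the package's charge convention for this
    waveform (it reproduces published charge figures for the 0.75 and
    1.5 mA protocols), not a statement from any single source.
``sham``
    A handful of initial pulses only (placebo); injection time is the pulse
    count times the pulse duration.
``conditioning``
    Brief continuous DC phases (e.g. 30 s in each direction for lidocaine
    iontophoresis); injection time is the summed phase durations.

Charge is ``current x injection time`` throughout (mean current for
``so_tdcs``), reported in millicoulombs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

__all__ = [
    "StimulationProtocol",
    "DoseReport",
    "injection_time",
    "total_charge",
    "dose_report",
    "preset_protocols",
    "mean_current_density",
]

KINDS = ("tdcs", "tpcs", "so_tdcs", "sham", "conditioning")


@dataclass(frozen=True)
class StimulationProtocol:
    """Waveform descriptor from which injection time and charge are derived.

    ``total_current_ma`` is the one-sided (anodal-side) total in mA — the
    peak value for ``so_tdcs``.  For ``tpcs``/``sham`` exactly one of
    ``ipi_s`` (inter-pulse interval) or ``frequency_hz`` may be given; if
    both are given they must agree (period = pulse + IPI = 1/frequency).
    """

    kind: str
    total_current_ma: float
    session_s: float
    pulse_s: float | None = None
    ipi_s: float | None = None
    frequency_hz: float | None = None
    n_pulses: int | None = None
    n_phases: int | None = None
    electrode_area_cm2: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.session_s <= 0:
            raise ValueError("session duration must be positive")
        if self.total_current_ma < 0:
            raise ValueError("total current must be non-negative")
        if self.kind in ("tpcs", "sham"):
            if self.pulse_s is None or self.pulse_s <= 0:
                raise ValueError(f"{self.kind} requires a positive pulse duration")
            if self.pulse_s > self.period_s + 1e-12:
                raise ValueError("pulse duration cannot exceed the period")
            if self.ipi_s is not None and self.frequency_hz is not None:
                implied = self.pulse_s + self.ipi_s
                if abs(implied - 1.0 / self.frequency_hz) > 1e-6 * implied:
                    raise ValueError(
                        f"inconsistent timing: pulse+IPI={implied} s but 1/frequency="
                        f"{1.0 / self.frequency_hz} s"
                    )
        if self.kind == "sham" and (self.n_pulses is None or self.n_pulses < 1):
            raise ValueError("sham requires n_pulses >= 1")

    @property
    def period_s(self) -> float:
        if self.ipi_s is not None:
            return self.pulse_s + self.ipi_s
        if self.frequency_hz is not None:
            return 1.0 / self.frequency_hz
        raise ValueError("pulsed protocol needs an inter-pulse interval or a frequency")

    @property
    def duty_cycle(self) -> float:
        if self.kind in ("tdcs", "so_tdcs", "conditioning"):
            return 1.0
        return self.pulse_s / self.period_s

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulationProtocol":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class DoseReport:
    """Derived dose quantities for one protocol."""

    injection_time_s: float
    total_charge_mc: float
    mean_current_density_ma_per_cm2: float | None


def injection_time(p: StimulationProtocol) -> float:
    """Total time (s) during which current actually flows."""
    if p.kind in ("tdcs", "so_tdcs"):
        # so-tDCS current flows continuously (time-varying amplitude)
        return p.session_s
    if p.kind == "conditioning":
        return p.session_s
    if p.kind == "sham":
        return p.n_pulses * p.pulse_s
    return p.session_s * p.duty_cycle  # tpcs


def total_charge(p: StimulationProtocol) -> float:
    """Total delivered charge in millicoulombs.

    ``charge = current x injection time`` for constant-amplitude waveforms;
    for slow-oscillatory DC the time-averaged amplitude of the 0-to-peak
    sinusoid (half the peak) replaces the constant current.
    """
    if p.kind == "so_tdcs":
        return (p.total_current_ma / 2.0) * p.session_s
    return p.total_current_ma * injection_time(p)


def mean_current_density(
    total_current_ma: float,
    n_electrodes: int,
    area_per_electrode_cm2: float = 1.0,
    round_2dp: bool = True,
) -> float:
    """Average current density over the electrode montage, mA/cm^2.

    ``total / (n x area)``; with ``round_2dp`` the result is rounded
    half-up to two decimals (the convention used when quoting montage dose
    levels).  Decimal arithmetic avoids binary half-way artifacts.
    """
    if n_electrodes <= 0 or area_per_electrode_cm2 <= 0:
        raise ValueError("electrode count and area must be positive")
    value = Decimal(str(total_current_ma)) / (
        Decimal(n_electrodes) * Decimal(str(area_per_electrode_cm2))
    )
    if round_2dp:
        value = value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(value)


def dose_report(p: StimulationProtocol, n_electrodes: int | None = None) -> DoseReport:
    density = None
    if p.electrode_area_cm2 and n_electrodes:
        density = mean_current_density(
            p.total_current_ma, n_electrodes, p.electrode_area_cm2 / n_electrodes
        )
    elif p.electrode_area_cm2:
        # treat the stored area as the total montage area
        density = mean_current_density(p.total_current_ma, 1, p.electrode_area_cm2)
    return DoseReport(
        injection_time_s=injection_time(p),
        total_charge_mc=total_charge(p),
        mean_current_density_ma_per_cm2=density,
    )


def preset_protocols() -> dict[str, StimulationProtocol]:
    """Named protocols for the dense-array pulsed study and published comparators.

    Pulsed presets carry pulse + inter-pulse interval as ground truth
    (published frequencies like "1.8 Hz" are rounded values of
    ``1/(pulse+IPI)``).  ``present_tpcs`` uses the cohort-mean total
    current of 1.16 mA; per-plan currents override it in practice.
    """
    return {
        # 100 ms pulses at 0.5 Hz for 17 min, dense-array reciprocity montage
        "present_tpcs": StimulationProtocol(
            kind="tpcs",
            total_current_ma=1.16,
            session_s=1020.0,
            pulse_s=0.1,
            frequency_hz=0.5,
            electrode_area_cm2=8.0,
            label="pulsed 0.5 Hz, dense-array reciprocity montage",
        ),
        # 30 s DC in each direction at 400 uA total (lidocaine iontophoresis)
        "conditioning": StimulationProtocol(
            kind="conditioning",
            total_current_ma=0.4,
            session_s=60.0,
            n_phases=2,
            electrode_area_cm2=8.0,
            label="DC conditioning, 30 s per direction",
        ),
        # placebo: five pulses over 10 s through two shallow local pairs
        "sham": StimulationProtocol(
            kind="sham",
            total_current_ma=0.2,
            session_s=10.0,
            pulse_s=0.1,
            frequency_hz=0.5,
            n_pulses=5,
            electrode_area_cm2=4.0,
            label="placebo, five pulses",
        ),
        # classical anodal tDCS threshold protocol: 1 mA for 3 min, 35 cm^2 pad
        "nitsche_anodal": StimulationProtocol(
            kind="tdcs",
            total_current_ma=1.0,
            session_s=60.0,
            electrode_area_cm2=35.0,
            label="anodal tDCS comparator, 1 mA x 60 s",
        ),
        # cathodal tDCS comparator: 1 mA for 5 min, 35 cm^2 pad
        "nitsche_cathodal": StimulationProtocol(
            kind="tdcs",
            total_current_ma=1.0,
            session_s=300.0,
            electrode_area_cm2=35.0,
            label="cathodal tDCS comparator, 1 mA x 300 s",
        ),
        # anodal tDCS comparator: 0.7 mA for 10 min, 24 cm^2
        "groppa_tdcs": StimulationProtocol(
            kind="tdcs",
            total_current_ma=0.7,
            session_s=600.0,
            electrode_area_cm2=24.0,
            label="tDCS comparator, 0.7 mA x 600 s",
        ),
        # pulsed comparator, short inter-pulse interval (~1.8 Hz)
        "groppa_tpcs_short": StimulationProtocol(
            kind="tpcs",
            total_current_ma=1.5,
            session_s=300.0,
            pulse_s=0.5,
            ipi_s=0.05,
            electrode_area_cm2=24.0,
            label="tPCS comparator, 500 ms pulses, 50 ms IPI",
        ),
        # pulsed comparator, long inter-pulse interval (~0.9 Hz)
        "groppa_tpcs_long": StimulationProtocol(
            kind="tpcs",
            total_current_ma=1.5,
            session_s=600.0,
            pulse_s=0.5,
            ipi_s=0.65,
            electrode_area_cm2=24.0,
            label="tPCS comparator, 500 ms pulses, 650 ms IPI",
        ),
        # slow-oscillatory tDCS comparators, 0.8 Hz sinusoid from 0 to peak
        "sotdcs_low": StimulationProtocol(
            kind="so_tdcs",
            total_current_ma=0.75,
            session_s=600.0,
            frequency_hz=0.8,
            electrode_area_cm2=12.0,
            label="slow-oscillatory tDCS, 0.75 mA peak",
        ),
        "sotdcs_high": StimulationProtocol(
            kind="so_tdcs",
            total_current_ma=1.5,
            session_s=600.0,
            frequency_hz=0.8,
            electrode_area_cm2=12.0,
            label="slow-oscillatory tDCS, 1.5 mA peak",
        ),
    }
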