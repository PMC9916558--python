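"""Charge accounting for biphasic stimulation patterns.

The stimulator delivers charge-balanced biphasic rectangular pulses
(anodic + cathodic phase of equal duration and amplitude, separated by a
short interphase gap), either continuously or with a minutes-scale on/off
raster. "Total charge" is reported as the single-phase charge magnitude
summed over all delivered pulses — the biphasic pair nets zero by
construction, so the net charge is not a useful comparator.

Units follow bench conventions: amplitude in µA, phase duration and gap in
µs, rate in Hz, raster in minutes, run length in hours; per-phase charge in
nC and total charge in mC.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BiphasicPulseTrain",
    "ChargeSummary",
    "charge_summary",
    "pattern_catalog",
    "evaporation_excess",
]


@dataclass(frozen=True)
class BiphasicPulseTrain:
    """One stimulation pattern.

    ``on_minutes``/``off_minutes`` encode the raster; continuous stimulation
    is ``off_minutes = 0`` (the on length is then irrelevant).
    """

    name: str
    amplitude_ua: float
    phase_duration_us: float = 30.0
    interphase_gap_us: float = 2.1
    rate_hz: float = 1000.0
    on_minutes: float = 1.0
    off_minutes: float = 0.0
    total_duration_h: float = 72.0

    def __post_init__(self) -> None:
        if self.amplitude_ua < 0:
            raise ValueError("amplitude must be >= 0")
        if self.phase_duration_us <= 0 or self.rate_hz <= 0:
            raise ValueError("phase duration and rate must be > 0")
        if self.on_minutes <= 0:
            raise ValueError("on_minutes must be > 0 (continuous = off_minutes 0)")
        if self.off_minutes < 0 or self.total_duration_h < 0:
            raise ValueError("off_minutes and total_duration_h must be >= 0")
        # the full pulse (both phases + gap) must fit into one period
        period_us = 1e6 / self.rate_hz
        if 2 * self.phase_duration_us + self.interphase_gap_us > period_us:
            raise ValueError(
                f"pulse of {2 * self.phase_duration_us + self.interphase_gap_us} µs "
                f"does not fit into a {period_us:.1f} µs period at {self.rate_hz} Hz"
            )

    @property
    def duty_fraction(self) -> float:
        if self.off_minutes == 0:
            return 1.0
        return self.on_minutes / (self.on_minutes + self.off_minutes)


@dataclass(frozen=True)
class ChargeSummary:
    name: str
    charge_per_phase_nc: float
    duty_fraction: float
    pulses_delivered: float
    total_charge_mc: float


def charge_summary(train: BiphasicPulseTrain) -> ChargeSummary:
    """Derived charge quantities of one pulse train.

    charge/phase [nC] = amplitude [µA] × phase duration [µs] / 1000;
    pulses = rate × run length × duty fraction; total charge [mC] sums the
    single-phase magnitude over all pulses.
    """
    q_phase_nc = train.amplitude_ua * train.phase_duration_us / 1e3
    duty = train.duty_fraction
    pulses = train.rate_hz * train.total_duration_h * 3600.0 * duty
    total_mc = q_phase_nc * pulses / 1e6
    return ChargeSummary(train.name, q_phase_nc, duty, pulses, total_mc)


def pattern_catalog() -> list[BiphasicPulseTrain]:
    """The study's five patterns: 10/100/500/1000 µA continuous plus
    1000 µA with a 1-min-on / 2-min-off raster; all 30 µs phases, 2.1 µs
    gap, 1000 Hz, 72 h."""
    trains = [
        BiphasicPulseTrain(name=f"{a:g}", amplitude_ua=a)
        for a in (10.0, 100.0, 500.0, 1000.0)
    ]
    trains.append(
        BiphasicPulseTrain(
            name="1000_1on2off", amplitude_ua=1000.0, on_minutes=1.0, off_minutes=2.0
        )
    )
    return trains


def evaporation_excess(
    loss_lid_g: float,
    loss_inset_g: float,
    wells: int,
    volume_per_well_ul: float,
) -> tuple[float, float]:
    """Bench QC: extra evaporation caused by the electrode inset.

    Returns ``(excess_total_g, excess_per_well_pct)``. The per-well percent
    assumes 1 g/mL, i.e. grams convert 1:1 to mL of medium.
    """
    if loss_lid_g < 0 or loss_inset_g < 0:
        raise ValueError("weight losses must be >= 0")
    if wells <= 0 or volume_per_well_ul <= 0:
        raise ValueError("wells and volume_per_well_ul must be > 0")
    excess_g = loss_inset_g - loss_lid_g
    excess_ul_per_well = excess_g / wells * 1e6 / 1e3  # g -> mg -> µL at 1 g/mL
    pct = excess_ul_per_well / volume_per_well_ul * 100.0
    return excess_g, pct
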