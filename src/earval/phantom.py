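"""Conductive-phantom bench math and QC metrics.

A conductive ear phantom is a molded medium (salt-doped agar, salt-
doped ballistic gelatin, or carbon-fiber-doped silicone) through which
a known signal is played while an ear-EEG device records.  This module
covers:

* mixture recipes — given a base quantity (water mass or silicone
  volume) and target weight percentages, solve for the component
  masses.  For solutes at fractions p_i of the *total* mixture mass
  in water w, the masses are ``m_i = p_i * w / (1 - sum(p))``;
  defaults: agar 4% + salt 0.5% (agar = 8w/191, salt = w/191), and
  gelatin 15% + salt 8% (gelatin = 15w/77, salt = 8w/77).  For the
  silicone composite at CF weight percent X of fiber+silicone,
  ``CF = S * X / (100 - X)`` with S the silicone mass from volume and
  density (1.11 g/mL), giving CF = S/199 at 0.5% and S/99 at 1.0%.
* conductivity from a two-wire resistance measurement on a strip
  sample: sigma = L / (R * A), rho = 1/sigma.
* electrode-contact impedance QC against meter readings in kOhm.
* noise-floor RMS (0.3-100 Hz band) of a no-input recording.
* SNR of a simulated 10 Hz square-wave "alpha" signal.
* integrity trends of phantom mass / transmitted amplitude over days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from earval.core import Recording
from earval.spectral import SnrResult, narrowband_snr, welch_psd

__all__ = [
    "MixtureRecipe",
    "ConductivityMeasure",
    "mixture_agar",
    "mixture_bg",
    "mixture_cf",
    "conductivity",
    "impedance_qc",
    "noise_floor",
    "simulated_signal_snr",
    "integrity_trend",
    "STRIP_LENGTH_M",
    "STRIP_CROSS_SECTION_M2",
    "QC_THRESHOLDS_KOHM",
]

#: Conductivity test-strip geometry: 30 x 10 x 2 mm.
STRIP_LENGTH_M = 0.03
STRIP_CROSS_SECTION_M2 = 10e-3 * 2e-3

#: Impedance class boundaries in kOhm; a value equal to a boundary
#: takes the worse class.  The 10 kOhm "good" anchor is standard EEG
#: practice; >= 50 kOhm (the analog meter's limit) means no contact.
QC_THRESHOLDS_KOHM = {"good": 10.0, "acceptable": 20.0, "poor": 50.0}


@dataclass
class MixtureRecipe:
    """Solved component masses for one phantom filling material."""

    material: str
    base_quantity: float          # water mass (g) or silicone volume (mL)
    base_unit: str                # "g" or "mL"
    component_masses: dict[str, float]
    weight_fractions: dict[str, float]
    rounding: str = "none"

    def total_mass(self) -> float:
        base_mass = (self.base_quantity if self.base_unit == "g"
                     else self.weight_fractions.get("_base_mass_g", 0.0))
        return base_mass + sum(self.component_masses.values())


@dataclass
class ConductivityMeasure:
    """Two-wire resistance converted to resistivity/conductivity."""

    resistance: float       # Ohm
    length: float           # m
    cross_section: float    # m^2
    resistivity: float      # Ohm m
    conductivity: float     # S/m


def _apply_rounding(value: float, rounding: str) -> float:
    if rounding == "none":
        return value
    if rounding == "up":
        return float(math.ceil(value))
    if rounding == "nearest":
        return float(math.floor(value + 0.5))
    raise ValueError(f"unknown rounding mode {rounding!r}")


def _solute_masses(water_g: float, percents: dict[str, float],
                   rounding: str) -> tuple[dict, dict]:
    if water_g < 0:
        raise ValueError("water mass must be non-negative")
    total_pct = sum(percents.values())
    if any(not 0 < p < 100 for p in percents.values()) or total_pct >= 100:
        raise ValueError(
            f"infeasible weight percentages {percents} (sum must be < 100)")
    masses = {name: _apply_rounding(p / (100.0 - total_pct) * water_g, rounding)
              for name, p in percents.items()}
    fractions = {name: p / 100.0 for name, p in percents.items()}
    return masses, fractions


def mixture_agar(water_g: float, agar_pct: float = 4.0,
                 salt_pct: float = 0.5, rounding: str = "up"
                 ) -> MixtureRecipe:
    """Salt-doped agar recipe (defaults 4% agar, 0.5% salt by weight).

    With the defaults the closed form is agar = 8w/191 and
    salt = w/191; masses are rounded up to the nearest gram by
    default, matching kitchen-scale practice (700 g of water gives
    30 g agar, 4 g salt).
    """
    masses, fractions = _solute_masses(
        water_g, {"agar": agar_pct, "salt": salt_pct}, rounding)
    return MixtureRecipe("agar", water_g, "g", masses, fractions, rounding)


def mixture_bg(water_g: float, gel_pct: float = 15.0,
               salt_pct: float = 8.0, rounding: str = "none"
               ) -> MixtureRecipe:
    """Salt-doped ballistic-gelatin recipe (defaults 15% gelatin, 8%
    salt by weight): gelatin = 15w/77, salt = 8w/77."""
    masses, fractions = _solute_masses(
        water_g, {"gelatin": gel_pct, "salt": salt_pct}, rounding)
    return MixtureRecipe("bg", water_g, "g", masses, fractions, rounding)


def mixture_cf(silicone_ml: float, density_g_per_ml: float = 1.11,
               cf_pct: float = 1.0, rounding: str = "nearest"
               ) -> MixtureRecipe:
    """Carbon-fiber-doped silicone recipe.

    The fiber mass satisfies CF/(CF + S) = X%, i.e.
    ``CF = S * X / (100 - X)`` with silicone mass S = volume x
    density.  Above 1.0% the composite becomes too dense to mold with
    hand mixing, so percentages beyond that carry a feasibility
    warning.
    """
    if silicone_ml < 0 or density_g_per_ml <= 0:
        raise ValueError("silicone volume and density must be positive")
    if not 0 <= cf_pct < 100:
        raise ValueError(f"infeasible CF weight percentage {cf_pct}")
    if cf_pct > 1.0:
        import warnings
        warnings.warn(
            f"CF fraction {cf_pct}% exceeds 1.0%; the composite is "
            "likely too dense to mold", stacklevel=2)
    s_mass = silicone_ml * density_g_per_ml
    cf_mass = _apply_rounding(s_mass * cf_pct / (100.0 - cf_pct), rounding) \
        if cf_pct > 0 else 0.0
    return MixtureRecipe(
        "cf_silicone", silicone_ml, "mL",
        {"carbon_fiber": cf_mass, "silicone": s_mass},
        {"carbon_fiber": cf_pct / 100.0},
        rounding,
    )


def conductivity(resistance_ohm: float, length_m: float = STRIP_LENGTH_M,
                 cross_section_m2: float = STRIP_CROSS_SECTION_M2
                 ) -> ConductivityMeasure:
    """sigma = L / (R * A) from a two-wire strip measurement."""
    if resistance_ohm <= 0 or length_m <= 0 or cross_section_m2 <= 0:
        raise ValueError("resistance, length and cross-section must be > 0")
    sigma = length_m / (resistance_ohm * cross_section_m2)
    return ConductivityMeasure(
        resistance=resistance_ohm,
        length=length_m,
        cross_section=cross_section_m2,
        resistivity=1.0 / sigma,
        conductivity=sigma,
    )


def impedance_qc(values: dict[str, float | str],
                 meter_limit_kohm: float = 50.0,
                 thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Classify per-electrode contact impedances.

    ``values`` maps electrode label to impedance in kOhm, or the
    string ``"saturated"`` when the meter pegged at its limit.
    Classes partition [0, inf): good < 10, acceptable [10, 20),
    poor [20, 50), no_contact >= 50 kOhm or saturated (boundaries
    assigned upward).  Returns a DataFrame with columns ``electrode``,
    ``impedance_kohm``, ``saturated``, ``qc_class``.
    """
    thr = dict(QC_THRESHOLDS_KOHM if thresholds is None else thresholds)
    thr["poor"] = min(thr.get("poor", meter_limit_kohm), meter_limit_kohm)
    rows = []
    for label, value in values.items():
        saturated = isinstance(value, str)
        if saturated and value != "saturated":
            raise ValueError(f"impedance for {label!r} must be a number in "
                             f"kOhm or 'saturated', got {value!r}")
        kohm = math.nan if saturated else float(value)
        if not saturated and kohm < 0:
            raise ValueError(f"negative impedance for {label!r}")
        if saturated or kohm >= thr["poor"]:
            qc = "no_contact"
        elif kohm >= thr["acceptable"]:
            qc = "poor"
        elif kohm >= thr["good"]:
            qc = "acceptable"
        else:
            qc = "good"
        rows.append({"electrode": label, "impedance_kohm": kohm,
                     "saturated": saturated, "qc_class": qc})
    return pd.DataFrame(rows)


def noise_floor(rec: Recording, band: tuple[float, float] = (0.3, 100.0),
                order: int = 4) -> pd.Series:
    """Per-channel RMS (µV) after zero-phase band-pass filtering.

    The default 0.3-100 Hz band matches offline treatment of no-input
    bench recordings; wet-electrode floors should come out close to or
    under 1 µVrms, bad contacts on the order of hundreds of µVrms.
    """
    if rec.duration < 2.0:
        raise ValueError(
            f"recording of {rec.duration:.2f} s too short (need >= 2 s)")
    lo, hi = band
    hi = min(hi, rec.fs / 2 * 0.99)
    sos = _signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs,
                         output="sos")
    filtered = _signal.sosfiltfilt(sos, rec.data, axis=1)
    rms = np.sqrt((filtered ** 2).mean(axis=1))
    return pd.Series(rms, index=rec.channel_labels, name="noise_uvrms")


def simulated_signal_snr(rec: Recording, f0: float = 10.0,
                         band: tuple[float, float] = (5.0, 15.0),
                         alpha: float = 0.01,
                         window_s: float = 8.0) -> dict[str, SnrResult]:
    """Narrowband SNR of a played-back phantom signal, per channel.

    Welch PSD (default 8 s window) followed by the narrowband SNR at
    ``f0`` against ``band``; significance is the ANOVA peak test at
    the stated ``alpha`` (default 1%).  A channel is deemed to carry
    the simulated signal when ``p_value < alpha``.
    """
    window_s = min(window_s, rec.duration)
    psd = welch_psd(rec, window_s=window_s)
    return {label: narrowband_snr(psd, label, f0, band)
            for label in rec.channel_labels}


def integrity_trend(series: list[tuple[int, float]],
                    value_name: str = "value") -> pd.DataFrame:
    """Per-day deltas and percent change from day 1 of a phantom
    integrity series (mass in g, or transmitted amplitude in mV).

    No interpolation between days; duplicate day indices are an input
    error.  Returns columns ``day``, ``value_name``, ``delta``,
    ``pct_change_from_day1``.
    """
    if not series:
        raise ValueError("need at least one (day, value) entry")
    days = [d for d, _ in series]
    if len(set(days)) != len(days):
        raise ValueError(f"duplicate day indices in {days}")
    frame = pd.DataFrame(sorted(series), columns=["day", value_name])
    frame["delta"] = frame[value_name].diff()
    first = frame[value_name].iloc[0]
    frame["pct_change_from_day1"] = (frame[value_name] - first) / first * 100.0
    return frame
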