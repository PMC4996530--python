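"""Growth, feed-efficiency and biometric indices plus marker-based
apparent digestibility for tank-level feeding-trial records.

All formulas operate on tank means: Wi/Wf are mean initial/final wet
weights (g fish^-1), FI is feed intake (g fish^-1, as-fed), FL fork
length (cm).  Digestibility uses an indigestible marker (yttrium oxide)
measured in diet and faeces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "TankRecord",
    "sgr",
    "fer",
    "fulton_k",
    "somatic_index",
    "apparent_digestibility",
    "DataQualityWarning",
]


class DataQualityWarning(UserWarning):
    """Non-fatal anomaly in trial data (e.g. digestibility outside [0, 100])."""


@dataclass
class TankRecord:
    """One tank's observations over the trial period.

    ``system_id`` identifies the recirculation system the tank sits in
    (the blocking factor of the design).  Marker data, fork length and
    tissue weights are optional; metrics needing them raise if absent.
    """

    tank_id: str
    diet: str
    system_id: str | None = None
    n_fish: int | None = None
    wi_g: float = 0.0
    wf_g: float = 0.0
    fi_g: float = 0.0
    days: int = 0
    fl_cm: float | None = None
    tissue_weights_g: dict[str, float] = field(default_factory=dict)
    marker: dict[str, tuple[float, float]] = field(default_factory=dict)
    # marker maps analyte -> (diet concentration, faeces concentration);
    # the special analyte "yttrium" is the inert marker itself.

    def __post_init__(self) -> None:
        if self.wi_g <= 0 or self.wf_g <= 0:
            raise ValueError(f"tank {self.tank_id}: weights must be positive")
        if self.fi_g < 0:
            raise ValueError(f"tank {self.tank_id}: feed intake must be >= 0")
        if self.days <= 0:
            raise ValueError(f"tank {self.tank_id}: days must be positive")


def sgr(record: TankRecord) -> float:
    """Specific growth rate (% d^-1) = 100 ln(Wf/Wi) / d.

    Note: some write-ups print this as ``100 (ln Wf / ln Wi) / d``; only
    the log-ratio form is dimensionally sound and reproduces tabulated
    trial values, so that is what is computed.
    """
    return 100.0 * math.log(record.wf_g / record.wi_g) / record.days


def fer(record: TankRecord) -> float:
    """Feed efficiency ratio (g g^-1) = weight gain / feed intake."""
    if record.fi_g == 0:
        raise ValueError(f"tank {record.tank_id}: feed intake is zero")
    return (record.wf_g - record.wi_g) / record.fi_g


def fulton_k(record: TankRecord, weight_g: float | None = None) -> float:
    """Fulton's condition factor k = 100 W / FL^3 (W g, FL cm).

    The conventional x100 factor keeps salmonid values near 1.  Uses the
    final weight unless ``weight_g`` is given.
    """
    if record.fl_cm is None or record.fl_cm <= 0:
        raise ValueError(f"tank {record.tank_id}: fork length unavailable")
    w = record.wf_g if weight_g is None else weight_g
    return 100.0 * w / record.fl_cm**3


def somatic_index(tissue_g: float, body_g: float) -> float:
    """Somatic index (%) = 100 x tissue weight / body weight (HSI, GSI, PCSI)."""
    if body_g <= 0:
        raise ValueError("body weight must be positive")
    if tissue_g > body_g:
        warnings.warn(
            f"tissue weight {tissue_g} g exceeds body weight {body_g} g",
            DataQualityWarning,
            stacklevel=2,
        )
    return 100.0 * tissue_g / body_g


def apparent_digestibility(
    y_diet: float, y_faeces: float, x_diet: float, x_faeces: float
) -> float:
    """Marker-based apparent digestibility coefficient (%).

    AD = 100 - 100 (Y_diet / Y_faeces) (X_faeces / X_diet), where Y is
    the inert-marker concentration and X the nutrient concentration.
    Values outside [0, 100] are reported as-is with a data-quality
    warning (they flag analytical error, never get clamped).
    """
    if y_faeces <= 0 or x_diet <= 0 or y_diet <= 0:
        raise ValueError("marker and diet-nutrient concentrations must be positive")
    if x_faeces < 0:
        raise ValueError("faecal nutrient concentration must be >= 0")
    ad = 100.0 - 100.0 * (y_diet / y_faeces) * (x_faeces / x_diet)
    if not 0.0 <= ad <= 100.0:
        warnings.warn(
            f"apparent digestibility {ad:.2f}% outside [0, 100]",
            DataQualityWarning,
            stacklevel=2,
        )
    return ad


def tank_digestibility(record: TankRecord, analyte: str, marker_analyte: str = "yttrium") -> float:
    """Apparent digestibility of ``analyte`` for one tank from its stored
    marker concentrations."""
    if marker_analyte not in record.marker or analyte not in record.marker:
        raise ValueError(
            f"tank {record.tank_id}: need concentrations for {marker_analyte!r} and {analyte!r}"
        )
    y_diet, y_faeces = record.marker[marker_analyte]
    x_diet, x_faeces = record.marker[analyte]
    return apparent_digestibility(y_diet, y_faeces, x_diet, x_faeces)
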