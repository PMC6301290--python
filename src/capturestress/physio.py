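"""Blood-panel preparation: pH temperature correction, validation, flags.

Point-of-care analysers measure blood pH at 37 °C; for ectotherms the value
is corrected back to ambient (sea-surface) temperature, a proxy for body
temperature. The correction coefficients come from the literature and are
user-supplied: the default mode is the identity, with a logged notice, since
no universal slope is appropriate and current best practice is instrument-
side correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Optional

from .io import PhysioPanel

logger = logging.getLogger(__name__)

#: plasma potassium threshold for hyperkalemia, mmol l⁻¹ (strict)
HYPERKALEMIA_MMOL_L = 7.0

_identity_notice_emitted = False


@dataclass(frozen=True)
class PhCorrection:
    """Temperature correction applied to pH measured at 37 °C.

    mode="identity" leaves values unchanged; mode="linear" applies
    pH(T) = pH37 + slope · (37 − T), with a user-supplied slope in
    pH units per °C taken from the literature.
    """

    mode: str = "identity"
    slope: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("identity", "linear"):
            raise ValueError(f"unknown pH correction mode {self.mode!r}")


def correct_ph(ph37: float, sst_c: Optional[float],
               corr: PhCorrection = PhCorrection()) -> float:
    """Correct a 37 °C pH reading to sea-surface temperature."""
    if not 6.0 <= ph37 <= 8.5:
        raise ValueError(f"ph37={ph37} outside plausible range [6.0, 8.5]")
    if corr.mode == "identity":
        global _identity_notice_emitted
        if not _identity_notice_emitted:
            logger.info("pH correction mode is 'identity'; supply a linear "
                        "slope from the literature to correct to SST")
            _identity_notice_emitted = True
        return ph37
    if sst_c is None:
        raise ValueError("SST is required for linear pH temperature "
                         "correction but is missing")
    return ph37 + corr.slope * (37.0 - sst_c)


def flag_hyperkalemia(panel: PhysioPanel,
                      threshold: float = HYPERKALEMIA_MMOL_L,
                      ) -> Optional[bool]:
    """True iff plasma K⁺ strictly exceeds the threshold; None if missing."""
    k = panel.potassium_mmol_l
    if k is None:
        return None
    return k > threshold


#: validation limits: Table-style observed min/max widened by 50%
_PANEL_RANGES = {
    "ph37": (6.0, 8.5),
    "lactate_mmol_l": (0.0, 30.0),
    "glucose_mmol_l": (0.0, 51.0),
    "haematocrit_pct": (0.0, 100.0),
    "sodium_mmol_l": (80.0, 525.0),
    "potassium_mmol_l": (0.0, 14.5),
    "chloride_mmol_l": (95.0, 405.0),
    "calcium_mmol_l": (0.0, 11.5),
}


def validate_panel(panel: PhysioPanel,
                   ranges: Optional[dict] = None) -> list[str]:
    """Validate a blood panel; returns warnings, raises on impossible values.

    Concentrations must be non-negative and haematocrit within [0, 100];
    violations raise ``ValueError``. Values inside the hard limits but
    outside the configured plausibility ranges produce warning strings.
    An all-missing panel is retained with a warning.
    """
    ranges = ranges or _PANEL_RANGES
    warnings = []
    any_present = False
    for f in fields(panel):
        v = getattr(panel, f.name)
        if v is None:
            continue
        any_present = True
        if v < 0:
            raise ValueError(f"{f.name} cannot be negative: {v}")
        if f.name == "haematocrit_pct" and v > 100:
            raise ValueError(f"haematocrit_pct cannot exceed 100: {v}")
        lo, hi = ranges.get(f.name, (-float("inf"), float("inf")))
        if not lo <= v <= hi:
            msg = f"{f.name}={v} outside plausible range [{lo}, {hi}]"
            warnings.append(msg)
            logger.warning("%s", msg)
    if not any_present:
        warnings.append("panel has no measured endpoints")
        logger.warning("panel has no measured endpoints; retained")
    return warnings
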