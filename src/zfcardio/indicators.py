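"""The six cardiac-function indicators.

All fractions (FAC, FS, EF) are carried as dimensionless values in [0, 1];
multiplying by 100 for display is a formatting concern, handled in reports.
Volumes use the prolate-spheroid model of the larval ventricle: for full
long-axis length ``a`` and full short-axis length ``b``,

    V = (4/3) * pi * (a/2) * (b/2)^2 = pi * a * b^2 / 6

which is the sphere volume pi d^3 / 6 when a = b = d.

Definitions
-----------
HR   heart rate, beats/min
FAC  fractional area change, (EDA - ESA) / EDA
FS   fractional shortening of the short axis, (Dd - Ds) / Dd
EDV  end-diastolic volume, ESV end-systolic volume (prolate spheroid)
SV   stroke volume, EDV - ESV
EF   ejection fraction, SV / EDV
CO   cardiac output, SV * HR (volume per minute)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import DomainError

if TYPE_CHECKING:  # pragma: no cover
    from .cycles import PhaseSummary

logger = logging.getLogger(__name__)


@dataclass
class CardiacIndicators:
    """One fish's (or one parameter set's) cardiac-function panel."""

    hr_bpm: float
    fac: float
    fs: float
    edv_um3: float
    esv_um3: float
    sv_um3: float
    ef: float
    co_um3_min: float

    def as_dict(self) -> dict[str, float]:
        return {
            "hr_bpm": self.hr_bpm,
            "fac": self.fac,
            "fs": self.fs,
            "edv_um3": self.edv_um3,
            "esv_um3": self.esv_um3,
            "sv_um3": self.sv_um3,
            "ef": self.ef,
            "co_um3_min": self.co_um3_min,
        }


#: Column order used in per-fish indicator tables.
INDICATOR_FIELDS = ("hr_bpm", "fac", "fs", "edv_um3", "esv_um3", "sv_um3",
                    "ef", "co_um3_min")


def compute_fac(eda_um2: float, esa_um2: float) -> float:
    """Fractional area change (EDA - ESA) / EDA."""
    if eda_um2 <= 0:
        raise DomainError(f"FAC requires EDA > 0, got {eda_um2}")
    return (eda_um2 - esa_um2) / eda_um2


def compute_fs(dd_um: float, ds_um: float) -> float:
    """Fractional shortening (Dd - Ds) / Dd of the short axis.

    A systolic axis exceeding the diastolic one yields a negative FS; this is
    physically suspicious but formula-admissible, so it is logged, not
    rejected.
    """
    if dd_um <= 0:
        raise DomainError(f"FS requires Dd > 0, got {dd_um}")
    fs = (dd_um - ds_um) / dd_um
    if fs < 0:
        logger.warning("negative FS (%.4f): systolic short axis %.3g exceeds "
                       "diastolic %.3g", fs, ds_um, dd_um)
    return fs


def ventricular_volume(a_um: float, b_um: float) -> float:
    """Prolate-spheroid volume pi*a*b^2/6 from FULL axis lengths (um^3)."""
    if a_um < 0 or b_um < 0:
        raise DomainError("axis lengths must be non-negative")
    if b_um > a_um:
        logger.warning("short axis %.3g exceeds long axis %.3g", b_um, a_um)
    return math.pi * a_um * b_um * b_um / 6.0


def compute_sv(edv_um3: float, esv_um3: float) -> float:
    """Stroke volume EDV - ESV (um^3 per beat)."""
    sv = edv_um3 - esv_um3
    if sv < 0:
        logger.warning("negative SV (%.3g): ESV exceeds EDV", sv)
    return sv


def compute_ef(sv_um3: float, edv_um3: float) -> float:
    """Ejection fraction SV / EDV, dimensionless."""
    if edv_um3 <= 0:
        raise DomainError(f"EF requires EDV > 0, got {edv_um3}")
    return sv_um3 / edv_um3


def compute_co(sv_um3: float, hr_bpm: float) -> float:
    """Cardiac output SV * HR (um^3 per minute)."""
    if hr_bpm < 0:
        raise DomainError(f"CO requires HR >= 0, got {hr_bpm}")
    return sv_um3 * hr_bpm


def compute_all(phase: "PhaseSummary", hr_bpm: float,
                fish_id: str = "fish") -> CardiacIndicators:
    """Evaluate the full indicator panel from phase-averaged geometry.

    EDV/ESV come from the phase-mean long/short axes, FAC from the phase-mean
    areas, FS from the phase-mean short axes.  Domain errors are re-raised
    with the fish id attached.
    """
    try:
        edv = ventricular_volume(phase.a_ed_um, phase.b_ed_um)
        esv = ventricular_volume(phase.a_es_um, phase.b_es_um)
        sv = compute_sv(edv, esv)
        return CardiacIndicators(
            hr_bpm=hr_bpm,
            fac=compute_fac(phase.eda_um2, phase.esa_um2),
            fs=compute_fs(phase.dd_um, phase.ds_um),
            edv_um3=edv,
            esv_um3=esv,
            sv_um3=sv,
            ef=compute_ef(sv, edv),
            co_um3_min=compute_co(sv, hr_bpm),
        )
    except DomainError as err:
        raise DomainError(f"{fish_id}: {err}") from err
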