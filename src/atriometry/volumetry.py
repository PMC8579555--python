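"""Left atrial volume determination and derived indices.

Two volume routes are implemented:

* slice-stack summation — the per-slice cross-sectional areas drawn on a
  short-axis (SAX) cine stack are multiplied by the slab height and summed
  (Simpson-type 3D measurement, treated as the reference volume);
* biplane area-length — the 2D estimate 8/(3 pi) * A1 * A2 / L from two
  long-axis planimetry areas and the shorter of the two measured long-axis
  lengths.

On top of these sit cyclic volume change and expansion index, body-surface-
area indexing, enlargement classification against published cut-offs, and
the signed calculated-volume error (calculated minus reference).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContourStack",
    "Slice",
    "BiplaneMeasurement",
    "VolumeSeries",
    "SubjectInfo",
    "BsaFormula",
    "MinRule",
    "VolumeMethod",
    "Enlargement",
    "stack_volume",
    "biplane_volume",
    "volume_error",
    "series_extremes",
    "cyclic_change_and_expansion",
    "body_surface_area",
    "index_volume",
    "classify_enlargement",
]


class BsaFormula(str, enum.Enum):
    MOSTELLER = "mosteller"
    DUBOIS = "dubois"


class MinRule(str, enum.Enum):
    #: minimum volume taken at the first time frame of the cycle (default)
    FIRST_FRAME = "first-frame"
    #: global minimum over the cycle
    GLOBAL = "global"


class VolumeMethod(str, enum.Enum):
    SAX = "SAX"          # 3D slice-summation volume
    AL_LV = "AL-LV"      # biplane area-length, LV-oriented long-axis views
    AL_LA = "AL-LA"      # biplane area-length, LA-oriented long-axis views


class Enlargement(str, enum.Enum):
    NORMAL = "normal"
    ABNORMAL = "abnormal"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class Slice:
    """One short-axis slice: planimetry area (mm^2), thickness and gap (mm)."""

    area: float
    thickness: float
    gap: float = 0.0

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError(f"slice thickness must be positive, got {self.thickness}")
        if self.area < 0:
            raise ValueError(f"slice area must be non-negative, got {self.area}")
        if self.gap < 0:
            raise ValueError(f"slice gap must be non-negative, got {self.gap}")


@dataclass(frozen=True)
class ContourStack:
    """Ordered parallel slices for slice-summation volumetry."""

    slices: tuple
    phase_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "slices", tuple(self.slices))

    def __len__(self):
        return len(self.slices)


@dataclass(frozen=True)
class BiplaneMeasurement:
    """Two long-axis planimetry areas and axis lengths.

    a1, a2 in mm^2; l1, l2 in mm.  The area-length equation uses the
    shorter of the two lengths.  ``orientation`` records whether the views
    were LV- or LA-oriented; it does not affect the arithmetic.
    """

    a1: float
    a2: float
    l1: float
    l2: float
    orientation: VolumeMethod = VolumeMethod.AL_LV

    def __post_init__(self):
        for name in ("a1", "a2", "l1", "l2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class VolumeSeries:
    """Time-resolved chamber volumes over one cardiac cycle."""

    volumes: tuple          # mL, ordered by time frame
    phase_label: str = ""

    def __post_init__(self):
        vols = tuple(float(v) for v in self.volumes)
        if len(vols) == 0:
            raise ValueError("volume series must contain at least one frame")
        if any(v < 0 for v in vols):
            raise ValueError("volumes must be non-negative")
        object.__setattr__(self, "volumes", vols)


@dataclass(frozen=True)
class SubjectInfo:
    """Sex and body habitus for volume indexing."""

    sex: str                 # "female" | "male"
    weight: float            # kg
    height: float            # cm
    bsa: float = field(default=0.0)  # m^2; derived if not given

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")
        if self.bsa == 0.0:
            object.__setattr__(
                self, "bsa", body_surface_area(self.weight, self.height)
            )
        elif self.bsa <= 0:
            raise ValueError(f"bsa must be positive, got {self.bsa}")


# ---------------------------------------------------------------------------
# operations


def stack_volume(stack: ContourStack) -> float:
    """Slice-summation volume in mL: sum of area * (thickness + gap)."""
    if len(stack) == 0:
        raise ValueError("cannot compute volume of an empty contour stack")
    total_mm3 = sum(s.area * (s.thickness + s.gap) for s in stack.slices)
    return total_mm3 / 1000.0


def biplane_volume(m: BiplaneMeasurement) -> float:
    """Biplane area-length volume in mL: 8/(3 pi) * A1 * A2 / min(l1, l2)."""
    length = min(m.l1, m.l2)
    return (8.0 / (3.0 * np.pi)) * m.a1 * m.a2 / length / 1000.0


def volume_error(calculated: float, reference: float) -> float:
    """Signed calculated-volume error: calculated minus reference (mL)."""
    return calculated - reference


def series_extremes(series: VolumeSeries,
                    min_rule: MinRule = MinRule.FIRST_FRAME) -> dict:
    """Maximum and minimum volume of a cycle.

    The maximum is the largest frame (automated stand-in for visual frame
    selection).  The minimum is the first frame of the cycle by default, or
    the global minimum with ``MinRule.GLOBAL``.
    """
    vols = np.asarray(series.volumes)
    imax = int(np.argmax(vols))
    min_rule = MinRule(min_rule)
    if min_rule is MinRule.FIRST_FRAME:
        vmin = float(vols[0])
    else:
        vmin = float(vols.min())
    return {"max": float(vols[imax]), "max_frame": imax, "min": vmin}


def cyclic_change_and_expansion(vol_max: float, vol_min: float) -> dict:
    """Cyclic volume change (max - min, mL) and expansion index (change/min)."""
    if vol_min <= 0:
        raise ValueError(f"minimum volume must be positive, got {vol_min}")
    cyclic = vol_max - vol_min
    return {"cyclic_change": cyclic, "expansion_index": cyclic / vol_min}


def body_surface_area(weight: float, height: float,
                      formula: BsaFormula = BsaFormula.MOSTELLER) -> float:
    """Body surface area in m^2 from weight (kg) and height (cm)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    formula = BsaFormula(formula)
    if formula is BsaFormula.MOSTELLER:
        return float(np.sqrt(weight * height / 3600.0))
    return float(0.007184 * weight ** 0.425 * height ** 0.725)


def index_volume(volume: float, bsa: float) -> float:
    """Volume indexed to body surface area (mL/m^2)."""
    if bsa <= 0:
        raise ValueError(f"bsa must be positive, got {bsa}")
    return volume / bsa


#: Indexed maximum-volume enlargement cut-offs (mL/m^2), inclusive.
_SAX_THRESHOLD = {"female": 54.0, "male": 53.0}
_AL_LV_THRESHOLD = 55.0


def classify_enlargement(indexed: float, sex: str,
                         method: VolumeMethod) -> Enlargement:
    """Classify an indexed maximum LA volume against published cut-offs.

    Slice-summation (SAX) volumes: >= 54 mL/m^2 in women, >= 53 mL/m^2 in
    men.  LV-oriented biplane volumes: >= 55 mL/m^2 for both sexes.  No
    upper normal limit exists for LA-oriented biplane volumes, so that
    method returns ``NOT_APPLICABLE``.
    """
    if indexed < 0:
        raise ValueError(f"indexed volume must be non-negative, got {indexed}")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    method = VolumeMethod(method)
    if method is VolumeMethod.AL_LA:
        return Enlargement.NOT_APPLICABLE
    if method is VolumeMethod.SAX:
        threshold = _SAX_THRESHOLD[sex]
    else:
        threshold = _AL_LV_THRESHOLD
    return Enlargement.ABNORMAL if indexed >= threshold else Enlargement.NORMAL
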