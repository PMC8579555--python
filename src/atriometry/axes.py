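"""3D chamber-axis construction and angle measurement from landmarks.

Five anatomical points — the center of the most dorsal part of the left
atrium, the mitral-ring center at end-diastole (ED) and end-systole (ES),
the LV apex, and the most lateral point of the right-ventricular free wall
— define two long axes and two planes:

* LA long axis: mitral-ring center -> dorsal LA;
* LV long axis: mitral-ring center -> LV apex;
* 4-chamber (4CH) plane: LV apex, ED mitral center, lateral RV wall;
* axes plane: LV apex, ED mitral center, dorsal LA (contains both axes).

``la_lv_deviation_angle`` is the 3D angle between the two long axes with
0 deg meaning anatomically parallel axes.  Because atrium and ventricle lie
on opposite sides of the mitral ring, the mitral->apex and mitral->dorsal
vectors of parallel axes are ANTI-parallel; the reported angle is therefore
180 deg minus the raw vector angle.

``la_rotation_angle`` is the dihedral angle between the axes plane and the
4CH plane, folded to [0, 90] deg by default; an optional signed variant
keeps the side information (positive when the dorsal LA lies on the
aortic / 3-chamber side of the 4CH plane, i.e. opposite the lateral RV
point).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkSet",
    "AngleResult",
    "Phase",
    "la_lv_deviation_angle",
    "cyclic_angle_change",
    "la_rotation_angle",
    "analyze_landmarks",
]

_COINCIDENT_TOL = 1e-9


class Phase(str, enum.Enum):
    ED = "ED"
    ES = "ES"


@dataclass(frozen=True)
class LandmarkSet:
    """Five 3D anatomical points (mm) defining the LA and LV long axes."""

    dorsal_la: np.ndarray
    mitral_center_ed: np.ndarray
    mitral_center_es: np.ndarray
    lv_apex: np.ndarray
    rv_lateral: np.ndarray

    def __post_init__(self):
        for name in ("dorsal_la", "mitral_center_ed", "mitral_center_es",
                     "lv_apex", "rv_lateral"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,):
                raise ValueError(f"{name} must be a 3D point, got shape {p.shape}")
            if not np.isfinite(p).all():
                raise ValueError(f"{name} contains non-finite coordinates")
            object.__setattr__(self, name, p)
        for mc_name in ("mitral_center_ed", "mitral_center_es"):
            mc = getattr(self, mc_name)
            if np.linalg.norm(self.lv_apex - mc) < _COINCIDENT_TOL:
                raise ValueError(f"lv_apex coincides with {mc_name}")
            if np.linalg.norm(self.dorsal_la - mc) < _COINCIDENT_TOL:
                raise ValueError(f"dorsal_la coincides with {mc_name}")

    def mitral_center(self, phase: Phase) -> np.ndarray:
        phase = Phase(phase)
        return self.mitral_center_ed if phase is Phase.ED else self.mitral_center_es

    def transformed(self, rotation=None, translation=None, scale=1.0):
        """Rigid motion plus optional uniform scaling of all five points."""
        def _t(p):
            q = p * scale
            if rotation is not None:
                q = np.asarray(rotation, float) @ q
            if translation is not None:
                q = q + np.asarray(translation, float)
            return q
        return LandmarkSet(*(_t(getattr(self, n)) for n in (
            "dorsal_la", "mitral_center_ed", "mitral_center_es",
            "lv_apex", "rv_lateral")))


@dataclass(frozen=True)
class AngleResult:
    """Axis-angle summary: deviation at ED/ES, cyclic change, rotation (deg)."""

    la_lv_angle_ed: float
    la_lv_angle_es: float
    cyclic_angle_change: float
    la_rotation_angle: float


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, numerically safe."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def la_lv_deviation_angle(landmarks: LandmarkSet, phase: Phase = Phase.ED) -> float:
    """3D angle between the LA and LV long axes (deg, 0 = parallel anatomy).

    Both axes are anchored at the mitral center of the requested phase:
    LA axis = mitral -> dorsal LA, LV axis = mitral -> apex.  180 deg minus
    the raw vector angle is returned so that anatomically parallel (tip-to-
    tip anti-parallel) axes score 0.
    """
    mc = landmarks.mitral_center(phase)
    u = landmarks.dorsal_la - mc
    v = landmarks.lv_apex - mc
    if np.linalg.norm(u) < _COINCIDENT_TOL or np.linalg.norm(v) < _COINCIDENT_TOL:
        raise ValueError("axis-defining points coincide with the mitral center")
    return 180.0 - _angle_between(u, v)


def cyclic_angle_change(ed_deg: float, es_deg: float) -> float:
    """ED minus ES deviation angle (deg, signed; positive = more aligned at ES)."""
    return ed_deg - es_deg


def _plane_normal(p0, p1, p2, label: str) -> np.ndarray:
    n = np.cross(p1 - p0, p2 - p0)
    span = max(np.linalg.norm(p1 - p0), np.linalg.norm(p2 - p0), 1.0)
    if np.linalg.norm(n) < 1e-9 * span * span:
        raise ValueError(f"the three points defining the {label} plane are collinear")
    return n / np.linalg.norm(n)


def la_rotation_angle(landmarks: LandmarkSet, signed: bool = False) -> float:
    """LA-axis rotation angle to the 4-chamber plane (deg).

    Dihedral angle between the 4CH plane (apex, ED mitral center, lateral
    RV) and the plane containing both long axes (apex, ED mitral center,
    dorsal LA).  Unsigned in [0, 90] by default.  With ``signed=True`` the
    sign follows the side of the 4CH plane on which the dorsal LA lies,
    positive along the normal of the ordered triple (apex, mitral, RV) —
    the rotation sense toward the aortic / 3-chamber side for a standard
    left-handed patient coordinate layout; range (-90, 90].
    """
    apex = landmarks.lv_apex
    mc = landmarks.mitral_center_ed
    n_4ch = _plane_normal(apex, mc, landmarks.rv_lateral, "4-chamber")
    n_axes = _plane_normal(apex, mc, landmarks.dorsal_la, "LA/LV axes")
    cosang = np.clip(abs(n_4ch @ n_axes), 0.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))
    if not signed:
        return angle
    side = np.sign(n_4ch @ (landmarks.dorsal_la - mc))
    return angle if side >= 0 else -angle


def analyze_landmarks(landmarks: LandmarkSet) -> AngleResult:
    """All axis angles from one landmark set.

    The rotation angle is defined at end-diastole only.
    """
    ed = la_lv_deviation_angle(landmarks, Phase.ED)
    es = la_lv_deviation_angle(landmarks, Phase.ES)
    return AngleResult(
        la_lv_angle_ed=ed,
        la_lv_angle_es=es,
        cyclic_angle_change=cyclic_angle_change(ed, es),
        la_rotation_angle=la_rotation_angle(landmarks),
    )
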