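"""Patient-specific compressive load on each lumbar vertebra.

The load applied to a vertebral body during upright stance scales with the
body mass carried above that level and with a posture/lever multiplier.  We
use the generic form

    F(level) = a_level * weight_kg * g * m_level * (height_cm / href_cm)

where ``a_level`` is the trunk-mass fraction supported at the level
(increasing caudally, L1 < L2 < L3 < L4), ``m_level`` a dimensionless
lever-arm multiplier, and the last factor a linear height adjustment around a
reference stature.  The default coefficient table is a documented stand-in
calibrated to give loads of a few hundred newtons for an average adult; every
coefficient is overridable via :class:`LoadModel` or a JSON table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

GRAVITY_M_S2 = 9.81

LUMBAR_LEVELS = ("L1", "L2", "L3", "L4")

#: Default trunk-mass fraction per level (dimensionless, increasing caudally).
DEFAULT_MASS_FRACTIONS = {"L1": 0.45, "L2": 0.47, "L3": 0.50, "L4": 0.53}

#: Default posture/lever multiplier (same for every lumbar level).
DEFAULT_LEVER_MULTIPLIER = 1.3

#: Stature at which the height adjustment factor equals one.
DEFAULT_REFERENCE_HEIGHT_CM = 170.0


@dataclass(frozen=True)
class Patient:
    """Anthropometric record driving the load computation."""

    id: str
    sex: str
    age_years: float
    weight_kg: float
    height_cm: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.age_years < 0:
            raise ValueError("age_years must be nonnegative")
        if not 20.0 < self.weight_kg < 300.0:
            raise ValueError(f"weight_kg {self.weight_kg} outside plausible range (20, 300)")
        if not 100.0 < self.height_cm < 230.0:
            raise ValueError(f"height_cm {self.height_cm} outside plausible range (100, 230)")


@dataclass(frozen=True)
class LoadModel:
    """Per-level coefficient table for the vertebral load formula."""

    mass_fractions: dict = field(default_factory=lambda: dict(DEFAULT_MASS_FRACTIONS))
    lever_multipliers: dict = field(
        default_factory=lambda: {lv: DEFAULT_LEVER_MULTIPLIER for lv in LUMBAR_LEVELS}
    )
    reference_height_cm: float = DEFAULT_REFERENCE_HEIGHT_CM
    height_adjust: bool = True
    gravity: float = GRAVITY_M_S2

    def __post_init__(self) -> None:
        fracs = [self.mass_fractions[lv] for lv in LUMBAR_LEVELS if lv in self.mass_fractions]
        if any(not 0.0 < a < 1.0 for a in fracs):
            raise ValueError("mass fractions must lie in (0, 1)")
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("mass fractions must increase from L1 to L4")
        if any(m < 1.0 for m in self.lever_multipliers.values()):
            raise ValueError("lever multipliers must be >= 1")
        if self.reference_height_cm <= 0:
            raise ValueError("reference_height_cm must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "LoadModel":
        """Load a coefficient table from a JSON file.

        Recognised keys: ``mass_fractions`` (level -> fraction),
        ``lever_multipliers`` (level -> multiplier or a single number),
        ``reference_height_cm``, ``height_adjust``.
        """
        with open(path) as fh:
            raw = json.load(fh)
        kwargs = {}
        if "mass_fractions" in raw:
            kwargs["mass_fractions"] = {str(k): float(v) for k, v in raw["mass_fractions"].items()}
        if "lever_multipliers" in raw:
            lm = raw["lever_multipliers"]
            if isinstance(lm, (int, float)):
                lm = {lv: float(lm) for lv in LUMBAR_LEVELS}
            else:
                lm = {str(k): float(v) for k, v in lm.items()}
            kwargs["lever_multipliers"] = lm
        if "reference_height_cm" in raw:
            kwargs["reference_height_cm"] = float(raw["reference_height_cm"])
        if "height_adjust" in raw:
            kwargs["height_adjust"] = bool(raw["height_adjust"])
        return cls(**kwargs)


def vertebral_load(patient: Patient, level: str, model: LoadModel | None = None) -> float:
    """Compressive load (N) on one lumbar vertebra for a given patient.

    Strictly positive, linear in body weight, and strictly increasing from
    L1 to L4 for a fixed patient (enforced by the coefficient invariants).
    """
    if model is None:
        model = LoadModel()
    if level not in model.mass_fractions:
        raise ValueError(
            f"unknown vertebral level {level!r}; expected one of {sorted(model.mass_fractions)}"
        )
    a = model.mass_fractions[level]
    m = model.lever_multipliers.get(level, DEFAULT_LEVER_MULTIPLIER)
    force = a * patient.weight_kg * model.gravity * m
    if model.height_adjust:
        force *= patient.height_cm / model.reference_height_cm
    return force
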