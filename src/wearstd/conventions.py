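"""Sensor-location naming, anatomical axis convention, and measurement units.

Standardized tri-axial signals are stored with columns ordered vertical (V),
medio-lateral (ML), antero-posterior (AP).  A device whose axes do not already
follow that convention is brought into it by a *signed permutation* of its
columns — never by a rotation: small mounting misalignments are deliberately
left in the data, and any re-alignment belongs to downstream analysis, not to
storage.

Sign convention adopted here (the axis map makes it a one-line config change):
V positive up, AP positive forward, ML positive toward the subject's right,
which keeps (V, ML, AP) a right-handed frame.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "AxisMap",
    "LocationRegistry",
    "DEFAULT_LOCATIONS",
    "HandednessError",
    "NamingError",
    "UnitError",
    "convert_units",
    "unit_conversion",
    "TARGET_UNITS",
    "SENSOR_KINDS",
]


class HandednessError(ValueError):
    """Axis map would flip handedness (determinant -1)."""


class NamingError(ValueError):
    """Location name violates the UpperCamelCase convention."""


class UnitError(ValueError):
    """Unrecognized source unit for a sensor kind."""


# ---------------------------------------------------------------------------
# Location registry
# ---------------------------------------------------------------------------

#: Seed names: the consortium locations plus those used by the pre-existing
#: datasets the convention was designed around.
DEFAULT_LOCATIONS: frozenset[str] = frozenset(
    {
        "LowerBack",
        "LowerBack2",
        "LeftFoot",
        "RightFoot",
        "Wrist",
        "LeftLowerShank",
        "RightLowerShank",
        "Head",
        "Neck",
        "Chest",
        "LeftShank",
        "RightShank",
    }
)

# One or more words, each starting with a capital letter; trailing digits allow
# disambiguators such as "LowerBack2".  No spaces, underscores or dashes.
_NAME_RE = re.compile(r"^(?:[A-Z][a-z]*[0-9]*)+$")


class LocationRegistry:
    """Registry of recognized sensor-location names.

    New locations may be registered as long as they follow the single-string
    UpperCamelCase naming rule (e.g. ``LeftLowerShank``).
    """

    def __init__(self, names: Iterable[str] | None = None) -> None:
        self._names: set[str] = set(DEFAULT_LOCATIONS if names is None else names)

    @staticmethod
    def is_valid_name(name: str) -> bool:
        return bool(_NAME_RE.match(name))

    def register(self, name: str) -> "LocationRegistry":
        """Add *name* to the registry; idempotent for known names.

        Raises :class:`NamingError` if the name breaks the naming rule.
        """
        if not self.is_valid_name(name):
            raise NamingError(
                f"location name {name!r} must be a single UpperCamelCase string "
                "(each word capitalized, no spaces or underscores), "
                "e.g. 'LeftLowerShank'"
            )
        self._names.add(name)
        return self

    def __contains__(self, name: str) -> bool:
        return name in self._names

    @property
    def names(self) -> frozenset[str]:
        return frozenset(self._names)


# ---------------------------------------------------------------------------
# Axis remapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AxisMap:
    """Signed permutation taking device columns (x, y, z) to (V, ML, AP).

    ``perm[j]`` is the device-column index feeding standardized column *j*
    (0 = V, 1 = ML, 2 = AP) and ``signs[j]`` its sign.  Both the device frame
    and the anatomical frame are right-handed, so the induced matrix must have
    determinant +1; a -1 map would silently negate every gyroscope rotation.
    """

    perm: tuple[int, int, int] = (0, 1, 2)
    signs: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if sorted(self.perm) != [0, 1, 2]:
            raise ValueError(f"perm must be a permutation of (0, 1, 2), got {self.perm}")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError(f"signs must be +/-1, got {self.signs}")

    @property
    def matrix(self) -> np.ndarray:
        m = np.zeros((3, 3))
        for j in range(3):
            m[j, self.perm[j]] = self.signs[j]
        return m

    @property
    def determinant(self) -> int:
        return round(float(np.linalg.det(self.matrix)))

    def check(self) -> None:
        if self.determinant != 1:
            raise HandednessError(
                f"axis map {self} has determinant {self.determinant}; both frames "
                "are right-handed, so only det +1 signed permutations are allowed"
            )

    def inverse(self) -> "AxisMap":
        perm = [0, 0, 0]
        signs = [1, 1, 1]
        for j in range(3):
            perm[self.perm[j]] = j
            signs[self.perm[j]] = self.signs[j]
        return AxisMap(tuple(perm), tuple(signs))

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "AxisMap":
        """Build from a config-style mapping like ``{"V": "-y", "ML": "z", "AP": "x"}``.

        Keys are the anatomical axes; values name a device axis (x/y/z) with an
        optional sign prefix.
        """
        axis_index = {"x": 0, "y": 1, "z": 2}
        perm = [0, 0, 0]
        signs = [1, 1, 1]
        for j, target in enumerate(("V", "ML", "AP")):
            try:
                src = mapping[target].strip()
            except KeyError:
                raise ValueError(f"axis map is missing the {target!r} axis") from None
            sign = 1
            if src[0] in "+-":
                sign = -1 if src[0] == "-" else 1
                src = src[1:]
            if src not in axis_index:
                raise ValueError(f"unknown device axis {src!r} (expected x, y or z)")
            perm[j] = axis_index[src]
            signs[j] = sign
        return cls(tuple(perm), tuple(signs))

    def to_mapping(self) -> dict[str, str]:
        names = "xyz"
        return {
            target: ("-" if self.signs[j] < 0 else "") + names[self.perm[j]]
            for j, target in enumerate(("V", "ML", "AP"))
        }

    def apply(self, signal: np.ndarray) -> np.ndarray:
        """Remap an N x 3 signal into V/ML/AP column order."""
        self.check()
        signal = np.asarray(signal)
        if signal.ndim != 2 or signal.shape[1] != 3:
            raise ValueError(f"expected an N x 3 matrix, got shape {signal.shape}")
        out = np.empty_like(signal, dtype=float)
        for j in range(3):
            out[:, j] = self.signs[j] * signal[:, self.perm[j]]
        return out


def remap_axes(signal: np.ndarray, axis_map: AxisMap) -> np.ndarray:
    """Reorder/flip the columns of *signal* into the V, ML, AP convention."""
    return axis_map.apply(signal)


# ---------------------------------------------------------------------------
# Measurement units
# ---------------------------------------------------------------------------

STANDARD_GRAVITY = 9.80665  # m/s^2, exact by definition

SENSOR_KINDS = ("acc", "gyr", "mag", "bar", "temp")

#: Storage units: g, deg/s, microtesla, hectopascal, degrees Celsius.
TARGET_UNITS = {"acc": "g", "gyr": "deg/s", "mag": "uT", "bar": "hPa", "temp": "degC"}

# target = a * source + b; temperature is the only affine family.
_CONVERSIONS: dict[str, dict[str, tuple[float, float]]] = {
    "acc": {
        "g": (1.0, 0.0),
        "m/s^2": (1.0 / STANDARD_GRAVITY, 0.0),
        "m/s2": (1.0 / STANDARD_GRAVITY, 0.0),
        "mg": (1e-3, 0.0),
    },
    "gyr": {
        "deg/s": (1.0, 0.0),
        "dps": (1.0, 0.0),
        "rad/s": (180.0 / math.pi, 0.0),
        "mdps": (1e-3, 0.0),
    },
    "mag": {
        "uT": (1.0, 0.0),
        "µT": (1.0, 0.0),
        "mT": (1e3, 0.0),
        "nT": (1e-3, 0.0),
        "T": (1e6, 0.0),
        "gauss": (100.0, 0.0),
        "mgauss": (0.1, 0.0),
    },
    "bar": {
        "hPa": (1.0, 0.0),
        "mbar": (1.0, 0.0),
        "Pa": (1e-2, 0.0),
        "kPa": (10.0, 0.0),
        "bar": (1e3, 0.0),
        "atm": (1013.25, 0.0),
    },
    "temp": {
        "degC": (1.0, 0.0),
        "C": (1.0, 0.0),
        "K": (1.0, -273.15),
        "degF": (5.0 / 9.0, -160.0 / 9.0),
        "F": (5.0 / 9.0, -160.0 / 9.0),
    },
}


def unit_conversion(source_unit: str, sensor_kind: str) -> tuple[float, float]:
    """Affine coefficients ``(a, b)`` with ``target = a * source + b``."""
    if sensor_kind not in _CONVERSIONS:
        raise UnitError(
            f"unknown sensor kind {sensor_kind!r}; expected one of {SENSOR_KINDS}"
        )
    table = _CONVERSIONS[sensor_kind]
    try:
        return table[source_unit]
    except KeyError:
        raise UnitError(
            f"unknown unit {source_unit!r} for sensor kind {sensor_kind!r}; "
            f"recognized units: {sorted(table)}"
        ) from None


def convert_units(values: np.ndarray, source_unit: str, sensor_kind: str) -> np.ndarray:
    """Convert *values* from *source_unit* to the storage unit of *sensor_kind*.

    Storage units are g (accelerometer, via standard gravity 9.80665 m/s^2),
    deg/s (gyroscope), µT (magnetometer), hPa (barometer) and °C (temperature).
    """
    a, b = unit_conversion(source_unit, sensor_kind)
    return np.asarray(values, dtype=float) * a + b


def convert_units_inverse(
    values: np.ndarray, source_unit: str, sensor_kind: str
) -> np.ndarray:
    """Map storage-unit values back into *source_unit* (exact affine inverse)."""
    a, b = unit_conversion(source_unit, sensor_kind)
    return (np.asarray(values, dtype=float) - b) / a
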