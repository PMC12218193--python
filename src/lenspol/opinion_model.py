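"""Core data types for opinion waves and Likert-to-continuum coding.

An *opinion wave* is one cross-sectional survey round: ``n`` respondents with
positions in the bounded opinion space ``[0, 1]^m`` (one axis per survey item),
a group identity label each (the reserved label ``"None"`` marks nonpartisans,
who treat the whole sample as their in-group), and a positive analysis weight.

Ordinal Likert codes are mapped onto the unit interval by a
:class:`LikertScheme`; the default 5-point scheme is equally spaced,
``{1..5} -> {0, 0.25, 0.5, 0.75, 1}``. The subjective distance metric built
downstream is invariant to the affine choice of this mapping, so equal spacing
is the minimal assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NONPARTISAN_LABEL = "None"

__all__ = [
    "NONPARTISAN_LABEL",
    "LikertScheme",
    "OpinionWave",
    "Violation",
    "map_likert_to_unit",
    "validate_wave",
]


@dataclass(frozen=True)
class LikertScheme:
    """Mapping between ordinal response codes and unit-interval values.

    Parameters
    ----------
    levels : tuple of int
        Admissible ordinal codes in increasing order (e.g. ``(1, 2, 3, 4, 5)``).
    unit_values : tuple of float
        Strictly increasing values in ``[0, 1]`` the codes map to; the first
        must be 0 and the last 1.
    missing_codes : frozenset of int
        Codes treated as invalid answers (refusal / don't know / no answer).
    """

    levels: tuple[int, ...] = (1, 2, 3, 4, 5)
    unit_values: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    missing_codes: frozenset[int] = frozenset((6, 7, 8, 9))

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.unit_values):
            raise ValueError("levels and unit_values must have equal length")
        if len(self.levels) < 2:
            raise ValueError("a Likert scheme needs at least two levels")
        vals = np.asarray(self.unit_values, dtype=float)
        if not np.all(np.diff(vals) > 0):
            raise ValueError("unit_values must be strictly increasing")
        if vals[0] != 0.0 or vals[-1] != 1.0:
            raise ValueError("unit_values must start at 0 and end at 1")
        if set(self.levels) & set(self.missing_codes):
            raise ValueError("missing_codes overlap admissible levels")

    @classmethod
    def equally_spaced(cls, k: int = 5, missing_codes=None) -> "LikertScheme":
        """Equally spaced ``k``-point scheme with codes ``1..k``.

        Missing codes default to the next four codes above the scale
        (``6..9`` on a 5-point scheme, the common survey convention).
        """
        if missing_codes is None:
            missing_codes = range(k + 1, k + 5)
        vals = tuple(np.linspace(0.0, 1.0, k))
        return cls(tuple(range(1, k + 1)), vals, frozenset(missing_codes))

    def to_unit(self, code: int) -> float:
        return self.unit_values[self.levels.index(code)]

    def to_code(self, value: float) -> int:
        """Ordinal code of the nearest unit value (nearest-level snapping)."""
        idx = int(np.argmin(np.abs(np.asarray(self.unit_values) - value)))
        return self.levels[idx]


@dataclass
class OpinionWave:
    """One survey wave: opinions in ``[0,1]^m`` with identities and weights."""

    wave_label: str
    opinions: np.ndarray  # (n, m) float
    identities: list[str]
    weights: np.ndarray  # (n,) positive float
    item_names: list[str]

    def __post_init__(self) -> None:
        self.opinions = np.atleast_2d(np.asarray(self.opinions, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.identities = [str(g) for g in self.identities]
        self.item_names = list(self.item_names)
        problems = validate_wave(self, _structural_only=True)
        if problems:
            raise ValueError("malformed wave: " + "; ".join(str(p) for p in problems))

    @property
    def n(self) -> int:
        return self.opinions.shape[0]

    @property
    def m(self) -> int:
        return self.opinions.shape[1]

    def groups(self) -> list[str]:
        """Distinct identity labels in first-appearance order."""
        return list(dict.fromkeys(self.identities))

    def group_mask(self, group_label: str) -> np.ndarray:
        return np.asarray([g == group_label for g in self.identities])


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_wave`."""

    invariant: str
    row: int | None
    column: int | None
    value: object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = "" if self.row is None else f" at row {self.row}"
        if self.column is not None:
            loc += f", column {self.column}"
        return f"{self.invariant}{loc}: {self.value!r}"


def map_likert_to_unit(raw_responses, scheme: LikertScheme):
    """Map an ``(n, m)`` matrix of ordinal codes onto ``[0, 1]``.

    Returns ``(values, valid_rows)`` where ``values`` is the float matrix of
    unit-interval coordinates (NaN where a missing code sat) and
    ``valid_rows`` is a boolean mask of rows containing no missing code.
    Rows flagged ``False`` are meant for listwise exclusion downstream.

    Raises
    ------
    ValueError
        If any entry is neither an admissible nor a declared missing code;
        the message names the offending row, column and code.
    """
    raw = np.atleast_2d(np.asarray(raw_responses))
    lookup = {code: val for code, val in zip(scheme.levels, scheme.unit_values)}
    values = np.full(raw.shape, np.nan, dtype=float)
    valid_rows = np.ones(raw.shape[0], dtype=bool)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            code = raw[i, j]
            code_i = None
            try:
                code_i = int(code)
                is_int = float(code) == code_i
            except (TypeError, ValueError):
                is_int = False
            if is_int and code_i in lookup:
                values[i, j] = lookup[code_i]
            elif is_int and code_i in scheme.missing_codes:
                valid_rows[i] = False
            elif not is_int and np.isnan(float(code)):
                valid_rows[i] = False
            else:
                raise ValueError(
                    f"unknown response code {code_i if is_int else code!r} "
                    f"at row {i}, column {j}: "
                    f"not in levels {scheme.levels} or missing codes "
                    f"{sorted(scheme.missing_codes)}"
                )
    return values, valid_rows


def validate_wave(wave: OpinionWave, _structural_only: bool = False) -> list[Violation]:
    """Check :class:`OpinionWave` invariants; empty list means all hold.

    Diagnostic: never raises. Each violation names the invariant, the row
    and the offending value.
    """
    out: list[Violation] = []
    n, m = wave.opinions.shape
    if len(wave.identities) != n:
        out.append(Violation("identities length != n", None, None, len(wave.identities)))
    if wave.weights.shape[0] != n:
        out.append(Violation("weights length != n", None, None, wave.weights.shape[0]))
    if len(wave.item_names) != m:
        out.append(Violation("item_names length != m", None, None, len(wave.item_names)))
    if m < 1:
        out.append(Violation("m < 1", None, None, m))
    if n < 2:
        out.append(Violation("n < 2", None, None, n))
    if _structural_only or out:
        return out
    bad = ~np.isfinite(wave.opinions) | (wave.opinions < 0) | (wave.opinions > 1)
    for i, j in zip(*np.nonzero(bad)):
        out.append(Violation("opinion outside [0,1]", int(i), int(j), float(wave.opinions[i, j])))
    bad_w = ~np.isfinite(wave.weights) | (wave.weights <= 0)
    for i in np.nonzero(bad_w)[0]:
        out.append(Violation("weight not strictly positive and finite", int(i), None, float(wave.weights[i])))
    return out
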