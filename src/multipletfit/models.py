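"""Signal models: pseudo-Voigt peaks, first-order multiplet patterns, model registry.

A signal is a multiplet: a set of component peaks whose positions are signed
half-integer combinations of named coupling constants around a common centre
``x_s``, whose relative amplitudes follow first-order (binomial) weights, and
which share one linewidth ``lw`` and one Gaussian fraction ``a``.  The total
intensity parameter ``I`` is distributed over components by the pattern
weights, which sum to exactly 1 (rational arithmetic).

Lineshape convention: ``lw`` enters the Gaussian as a sigma-like parameter
(``2*lw**2`` in the exponent) and the Lorentzian as its half width at half
maximum.  The half-height full width of the mixed profile therefore depends on
``a``; :func:`peak_fwhm` computes it and it is reported alongside fitted
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, DomainError, FormatError, ValidationError

__all__ = [
    "PeakShapeParams",
    "MultipletPattern",
    "ParameterSpec",
    "SignalModel",
    "ModelRegistry",
    "pseudo_voigt",
    "expand_multiplet",
    "simulate_signal",
    "simulate_spectrum",
    "suggest_models",
    "register_model",
    "load_model_file",
    "signal_area",
    "peak_fwhm",
    "default_registry",
    "SHAPE_PARAMS",
]

#: parameter names shared by every model (everything else is a coupling name)
SHAPE_PARAMS = ("x_s", "I", "lw", "a")


@dataclass(frozen=True)
class PeakShapeParams:
    """Parameters of one pseudo-Voigt component peak.

    Attributes
    ----------
    x0 : float
        Peak position (ppm).
    h : float
        Apex height (intensity units).
    lw : float
        Linewidth parameter (ppm, > 0): Gaussian sigma / Lorentzian HWHM.
    a : float
        Gaussian fraction, in [0, 1].
    """

    x0: float
    h: float
    lw: float
    a: float

    def __post_init__(self) -> None:
        if not self.lw > 0:
            raise DomainError(f"lw must be > 0, got {self.lw}")
        if not 0.0 <= self.a <= 1.0:
            raise DomainError(f"a must be in [0, 1], got {self.a}")


def pseudo_voigt(x: np.ndarray, p: PeakShapeParams) -> np.ndarray:
    """Evaluate a pseudo-Voigt peak on a ppm grid.

    ``h * (a * exp(-(x-x0)^2 / (2*lw^2)) + (1-a) / (1 + ((x-x0)/lw)^2))``

    The value at ``x0`` equals ``h`` for any ``a`` and the profile is an even
    function of ``x - x0``.
    """
    x = np.asarray(x, dtype=float)
    u = (x - p.x0) / p.lw
    gauss = np.exp(-0.5 * u * u)
    lorentz = 1.0 / (1.0 + u * u)
    return p.h * (p.a * gauss + (1.0 - p.a) * lorentz)


@dataclass(frozen=True)
class MultipletPattern:
    """First-order multiplet geometry.

    ``peak_offsets[i]`` maps coupling-constant names to rational coefficients;
    component ``i`` sits at ``x_s + sum(coeff * J[name])``.  ``peak_weights``
    are the relative amplitudes (fractions summing to 1).
    """

    name: str
    j_names: tuple[str, ...]
    peak_offsets: tuple[Mapping[str, Fraction], ...]
    peak_weights: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        if len(self.peak_offsets) != len(self.peak_weights):
            raise ValidationError(
                f"pattern {self.name!r}: peak_offsets has {len(self.peak_offsets)} "
                f"entries but peak_weights has {len(self.peak_weights)}"
            )
        if sum(self.peak_weights) != 1:
            raise ValidationError(
                f"pattern {self.name!r}: peak_weights sum to "
                f"{sum(self.peak_weights)}, expected 1"
            )
        if any(w <= 0 for w in self.peak_weights):
            raise ValidationError(f"pattern {self.name!r}: peak_weights must be positive")
        for offs in self.peak_offsets:
            unknown = set(offs) - set(self.j_names)
            if unknown:
                raise ValidationError(
                    f"pattern {self.name!r}: peak_offsets reference unknown "
                    f"coupling name(s) {sorted(unknown)}"
                )
        # mirror symmetry: every (offset, weight) has a negated twin of equal weight
        pool = [(self._canon(o), w) for o, w in zip(self.peak_offsets, self.peak_weights)]
        for offs, w in pool:
            mirrored = tuple((name, -c) for name, c in offs)
            if (mirrored, w) not in pool:
                raise ValidationError(
                    f"pattern {self.name!r}: peak_offsets are not symmetric about 0 "
                    f"with mirror-symmetric peak_weights (offending offset {dict(offs)})"
                )

    def _canon(self, offs: Mapping[str, Fraction]) -> tuple[tuple[str, Fraction], ...]:
        return tuple((n, Fraction(offs.get(n, 0))) for n in self.j_names)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_offsets)

    def canonical_order(self) -> list[int]:
        """Component indices sorted by offset evaluated at J1 > J2 > ... > 0.

        Uses a geometric probe (1, 1/2, 1/4, ...) so the ordering is the
        sorted-position ordering whenever the first-listed coupling is the
        largest — the documented convention for multi-J patterns.
        """
        probe = {n: Fraction(1, 2**i) for i, n in enumerate(self.j_names)}
        vals = [
            sum(c * probe[n] for n, c in self._canon(o))
            for o in self.peak_offsets
        ]
        return sorted(range(self.n_peaks), key=lambda i: vals[i])


@dataclass(frozen=True)
class ParameterSpec:
    """Default initial value and bound rule for one model parameter.

    ``bound_mode`` semantics:

    * ``absolute`` — ``lower``/``upper`` are the bounds.
    * ``relative`` — for position-like parameters (unit ``ppm``) the bounds are
      additive offsets around the initial value (``init - lower``,
      ``init + upper``); for scale-like parameters (``intensity`` or
      ``dimensionless``) they are multiplicative factors.
    """

    name: str
    default_init: float | None
    lower: float
    upper: float
    bound_mode: str = "absolute"
    unit: str = "dimensionless"

    def __post_init__(self) -> None:
        if self.bound_mode not in ("absolute", "relative"):
            raise ValidationError(
                f"parameter {self.name!r}: bound_mode must be 'absolute' or "
                f"'relative', got {self.bound_mode!r}"
            )
        if self.unit not in ("ppm", "intensity", "dimensionless"):
            raise ValidationError(f"parameter {self.name!r}: unknown unit {self.unit!r}")
        if self.bound_mode == "absolute" and not self.lower <= self.upper:
            raise ValidationError(
                f"parameter {self.name!r}: lower ({self.lower}) > upper ({self.upper})"
            )
        if (
            self.bound_mode == "absolute"
            and self.default_init is not None
            and not self.lower <= self.default_init <= self.upper
        ):
            raise ValidationError(
                f"parameter {self.name!r}: default_init {self.default_init} outside "
                f"[{self.lower}, {self.upper}]"
            )

    def resolve_bounds(self, init: float) -> tuple[float, float]:
        """Concrete (lower, upper) bracketing ``init``."""
        if self.bound_mode == "absolute":
            lo, hi = self.lower, self.upper
        elif self.unit == "ppm":
            lo, hi = init - self.lower, init + self.upper
        else:  # multiplicative factors on a scale-like parameter
            lo, hi = init * self.lower, init * self.upper
            if lo > hi:  # negative init flips the factor interval
                lo, hi = hi, lo
        lo = min(lo, init)
        hi = max(hi, init)
        return lo, hi


def _default_specs(j_names: Sequence[str]) -> dict[str, ParameterSpec]:
    specs = {
        "x_s": ParameterSpec("x_s", None, 0.25, 0.25, "relative", "ppm"),
        "I": ParameterSpec("I", None, 0.1, 10.0, "relative", "intensity"),
        "lw": ParameterSpec("lw", None, 0.1, 10.0, "relative", "dimensionless"),
        "a": ParameterSpec("a", 0.5, 0.0, 1.0, "absolute", "dimensionless"),
    }
    for j in j_names:
        specs[j] = ParameterSpec(j, None, 0.1, 0.1, "relative", "ppm")
    return specs


@dataclass(frozen=True)
class SignalModel:
    """A multiplet pattern plus parameter specifications.

    Parameters always cover ``x_s``, ``I``, ``lw``, ``a`` and every coupling
    name of the pattern.
    """

    name: str
    pattern: MultipletPattern
    parameter_specs: Mapping[str, ParameterSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        specs = dict(self.parameter_specs)
        defaults = _default_specs(self.pattern.j_names)
        for pname, spec in defaults.items():
            specs.setdefault(pname, spec)
        extra = set(specs) - set(defaults)
        if extra:
            raise ValidationError(
                f"model {self.name!r}: parameter_specs contain unknown names {sorted(extra)}"
            )
        for pname, spec in specs.items():
            if spec.name != pname:
                raise ValidationError(
                    f"model {self.name!r}: spec stored under {pname!r} is named {spec.name!r}"
                )
        object.__setattr__(self, "parameter_specs", specs)

    @property
    def n_peaks(self) -> int:
        return self.pattern.n_peaks

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(SHAPE_PARAMS) + self.pattern.j_names


def expand_multiplet(
    pattern: MultipletPattern, xs: float, J: Mapping[str, float]
) -> list[tuple[float, float]]:
    """Component (position, weight) pairs, sorted by position, weights sum to 1.

    Raises
    ------
    ConfigurationError
        If a coupling name required by the pattern is missing from ``J``.
    DomainError
        If any supplied coupling value is negative.
    """
    missing = [n for n in pattern.j_names if n not in J]
    if missing:
        raise ConfigurationError(
            f"pattern {pattern.name!r}: missing coupling constant(s) {missing}"
        )
    for n in pattern.j_names:
        if J[n] < 0:
            raise DomainError(f"coupling constant {n!r} must be >= 0, got {J[n]}")
    peaks = [
        (xs + sum(float(c) * J[n] for n, c in offs.items()), float(w))
        for offs, w in zip(pattern.peak_offsets, pattern.peak_weights)
    ]
    peaks.sort(key=lambda t: t[0])
    return peaks


def simulate_signal(
    model: SignalModel, values: Mapping[str, float], x: np.ndarray
) -> np.ndarray:
    """Intensity of one multiplet on grid ``x``.

    Component amplitudes are ``I * weight`` (so ``I`` is the sum of component
    amplitudes); all components share ``lw`` and ``a``.
    """
    missing = [n for n in model.parameter_names if n not in values]
    if missing:
        raise ConfigurationError(
            f"model {model.name!r}: missing parameter value(s) {missing}"
        )
    xs = values["x_s"]
    intensity = values["I"]
    lw = values["lw"]
    a = values["a"]
    J = {n: values[n] for n in model.pattern.j_names}
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x)
    for pos, w in expand_multiplet(model.pattern, xs, J):
        y += pseudo_voigt(x, PeakShapeParams(pos, intensity * w, lw, a))
    return y


def simulate_spectrum(
    signals: Iterable[tuple[SignalModel, Mapping[str, float]]], x: np.ndarray
) -> np.ndarray:
    """Sum of :func:`simulate_signal` over all signals (zero vector if empty)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DomainError("simulation grid is empty")
    y = np.zeros_like(x)
    for model, values in signals:
        y += simulate_signal(model, values, x)
    return y


def signal_area(intensity: float, lw: float, a: float) -> float:
    """Analytic integral of one signal over the full axis.

    Per unit amplitude the Gaussian term integrates to ``lw*sqrt(2*pi)`` and
    the Lorentzian term to ``pi*lw``; weights sum to 1, so the signal area is
    independent of the coupling constants.
    """
    return intensity * lw * (a * math.sqrt(2.0 * math.pi) + (1.0 - a) * math.pi)


def peak_fwhm(lw: float, a: float) -> float:
    """Full width at half maximum of the mixed profile (numeric in between).

    Equals ``2*lw`` for a pure Lorentzian and ``2*sqrt(2*ln 2)*lw`` for a pure
    Gaussian.
    """
    if not lw > 0:
        raise DomainError(f"lw must be > 0, got {lw}")
    if not 0.0 <= a <= 1.0:
        raise DomainError(f"a must be in [0, 1], got {a}")
    if a == 0.0:
        return 2.0 * lw
    if a == 1.0:
        return 2.0 * math.sqrt(2.0 * math.log(2.0)) * lw

    def half_height(u: float) -> float:
        return a * math.exp(-0.5 * u * u) + (1.0 - a) / (1.0 + u * u) - 0.5

    root = brentq(half_height, 1e-12, 10.0)
    return 2.0 * root * lw


class ModelRegistry:
    """Name-keyed store of :class:`SignalModel` definitions."""

    def __init__(self) -> None:
        self._models: dict[str, SignalModel] = {}

    def register(self, model: SignalModel) -> SignalModel:
        if not isinstance(model, SignalModel):
            raise ValidationError("register expects a SignalModel")
        if model.name in self._models:
            raise ValidationError(f"model name {model.name!r} is already registered")
        self._models[model.name] = model
        return model

    def get(self, name: str) -> SignalModel:
        try:
            return self._models[name]
        except KeyError:
            raise ConfigurationError(f"unknown model {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._models

    def names(self) -> list[str]:
        return sorted(self._models)

    def suggest(self, n_peaks: int) -> list[str]:
        if n_peaks < 1:
            raise DomainError(f"n_peaks must be >= 1, got {n_peaks}")
        return sorted(n for n, m in self._models.items() if m.n_peaks == n_peaks)


def _sym_pattern(
    name: str,
    j_names: Sequence[str],
    components: Sequence[tuple[dict[str, Fraction], Fraction]],
) -> MultipletPattern:
    return MultipletPattern(
        name=name,
        j_names=tuple(j_names),
        peak_offsets=tuple(dict(o) for o, _ in components),
        peak_weights=tuple(w for _, w in components),
    )


def _builtin_models() -> list[SignalModel]:
    F = Fraction
    singlet = _sym_pattern("singlet", (), [({}, F(1))])
    doublet = _sym_pattern(
        "doublet",
        ("J",),
        [({"J": F(-1, 2)}, F(1, 2)), ({"J": F(1, 2)}, F(1, 2))],
    )
    triplet = _sym_pattern(
        "triplet",
        ("J",),
        [
            ({"J": F(-1)}, F(1, 4)),
            ({"J": F(0)}, F(1, 2)),
            ({"J": F(1)}, F(1, 4)),
        ],
    )
    quadruplet = _sym_pattern(
        "quadruplet",
        ("J",),
        [
            ({"J": F(-3, 2)}, F(1, 8)),
            ({"J": F(-1, 2)}, F(3, 8)),
            ({"J": F(1, 2)}, F(3, 8)),
            ({"J": F(3, 2)}, F(1, 8)),
        ],
    )
    dd = _sym_pattern(
        "doublet_of_doublets",
        ("J1", "J2"),
        [
            ({"J1": F(-1, 2), "J2": F(-1, 2)}, F(1, 4)),
            ({"J1": F(-1, 2), "J2": F(1, 2)}, F(1, 4)),
            ({"J1": F(1, 2), "J2": F(-1, 2)}, F(1, 4)),
            ({"J1": F(1, 2), "J2": F(1, 2)}, F(1, 4)),
        ],
    )
    return [SignalModel(p.name, p) for p in (singlet, doublet, triplet, quadruplet, dd)]


def default_registry() -> ModelRegistry:
    """A fresh registry holding the five built-in multiplet models."""
    reg = ModelRegistry()
    for m in _builtin_models():
        reg.register(m)
    return reg


#: process-wide registry used by the module-level convenience functions
_GLOBAL_REGISTRY = default_registry()


def register_model(model: SignalModel, registry: ModelRegistry | None = None) -> SignalModel:
    return (registry or _GLOBAL_REGISTRY).register(model)


def suggest_models(n_peaks: int, registry: ModelRegistry | None = None) -> list[str]:
    return (registry or _GLOBAL_REGISTRY).suggest(n_peaks)


def _parse_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(value).limit_denominator(10**6)
    raise ValidationError(f"cannot interpret {value!r} as a rational number")


def load_model_file(path: str | Path) -> SignalModel:
    """Build a :class:`SignalModel` from a declarative YAML/JSON model file.

    Expected layout::

        name: doublet_of_triplets
        j_names: [J1, J2]
        peaks:
          - {offset: {J1: -1/2, J2: -1}, weight: 1/8}
          - ...
        parameters:            # optional overrides
          lw: {init: 0.002, lower: 0.2, upper: 5, bound_mode: relative,
               unit: dimensionless}
    """
    import yaml

    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"model file {path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"model file {path}: top level must be a mapping")
    for key in ("name", "peaks"):
        if key not in raw:
            raise ValidationError(f"model file {path}: missing required key {key!r}")
    j_names = tuple(raw.get("j_names", ()))
    components = []
    for i, pk in enumerate(raw["peaks"]):
        offset = {n: _parse_fraction(c) for n, c in (pk.get("offset") or {}).items()}
        if "weight" not in pk:
            raise ValidationError(f"model file {path}: peaks[{i}] has no weight")
        components.append((offset, _parse_fraction(pk["weight"])))
    pattern = _sym_pattern(raw["name"], j_names, components)
    specs: dict[str, ParameterSpec] = {}
    for pname, ov in (raw.get("parameters") or {}).items():
        base = _default_specs(j_names).get(pname)
        if base is None:
            raise ValidationError(f"model file {path}: unknown parameter {pname!r}")
        specs[pname] = ParameterSpec(
            name=pname,
            default_init=ov.get("init", base.default_init),
            lower=ov.get("lower", base.lower),
            upper=ov.get("upper", base.upper),
            bound_mode=ov.get("bound_mode", base.bound_mode),
            unit=ov.get("unit", base.unit),
        )
    return SignalModel(raw["name"], pattern, specs)
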