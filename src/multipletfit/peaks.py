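"""Peak detection, signal assembly, and parameter initialization.

Peaks are local maxima inside a user-chosen ppm region; a plateau of equal
samples yields one peak at the plateau centre. The automatic threshold is
``k * sigma_noise`` with ``sigma_noise`` the scaled median absolute deviation
of the outer 10% of the region's samples on each side.

Initial values follow simple rules: the signal centre and total intensity come
from the peak list, coupling constants from the inter-peak spacings (exact
linear inversion of the multiplet offset geometry), and the linewidth from the
measured half-height width of resolvable peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DomainError, InitializationError, ValidationError
from .io import Spectrum1D
from .models import ModelRegistry, SignalModel, default_registry

__all__ = [
    "Peak",
    "Region",
    "ParamState",
    "SignalInstance",
    "pick_peaks",
    "group_signal",
    "initialize_parameters",
    "estimate_noise",
]

MIN_REGION_POINTS = 8


@dataclass(frozen=True)
class Peak:
    """A candidate peak: position, apex intensity, detection source."""

    position: float
    intensity: float
    source: str = "auto"  # auto | manual


@dataclass(frozen=True)
class Region:
    """Closed ppm interval [ppm_min, ppm_max] on a given spectrum's axis."""

    ppm_min: float
    ppm_max: float

    def __post_init__(self) -> None:
        if not self.ppm_min < self.ppm_max:
            raise ValidationError(
                f"region requires ppm_min < ppm_max, got [{self.ppm_min}, {self.ppm_max}]"
            )

    def slice(self, spectrum: Spectrum1D) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) restricted to the region; validates coverage and size."""
        if self.ppm_min < spectrum.ppm[0] or self.ppm_max > spectrum.ppm[-1]:
            raise DomainError(
                f"region [{self.ppm_min}, {self.ppm_max}] exceeds axis range "
                f"[{spectrum.ppm[0]}, {spectrum.ppm[-1]}]"
            )
        mask = (spectrum.ppm >= self.ppm_min) & (spectrum.ppm <= self.ppm_max)
        if int(mask.sum()) < MIN_REGION_POINTS:
            raise ValidationError(
                f"region [{self.ppm_min}, {self.ppm_max}] contains "
                f"{int(mask.sum())} grid points, need >= {MIN_REGION_POINTS}"
            )
        return spectrum.ppm[mask], spectrum.intensity[mask]


@dataclass
class ParamState:
    """Runtime state of one fit parameter of one signal."""

    name: str
    init: float
    lower: float
    upper: float
    value: float | None = None
    sd: float | None = None
    fixed: bool = False
    at_bound: bool = False
    sd_reliable: bool = True

    def __post_init__(self) -> None:
        if not self.lower <= self.init <= self.upper:
            raise ValidationError(
                f"parameter {self.name!r}: init {self.init} outside bounds "
                f"[{self.lower}, {self.upper}]"
            )


@dataclass
class SignalInstance:
    """A model bound to a region with concrete parameter states.

    A peak may belong to several instances (overlapping signals share peaks).
    ``params`` is empty until :func:`initialize_parameters` resolves it, unless
    explicit states were supplied.
    """

    id: str
    model: SignalModel
    peaks: list[Peak] = field(default_factory=list)
    params: dict[str, ParamState] = field(default_factory=dict)
    allow_negative: bool = False

    def __post_init__(self) -> None:
        if self.peaks and len(self.peaks) != self.model.n_peaks:
            raise ValidationError(
                f"signal {self.id!r}: model {self.model.name!r} expects "
                f"{self.model.n_peaks} peaks, got {len(self.peaks)}"
            )

    @property
    def resolved(self) -> bool:
        return set(self.params) == set(self.model.parameter_names)

    def values(self) -> dict[str, float]:
        """Current best values (fitted if available, else inits)."""
        return {
            n: (s.value if s.value is not None else s.init)
            for n, s in self.params.items()
        }


def estimate_noise(y: np.ndarray, edge_fraction: float = 0.1) -> float:
    """Robust noise sigma from the region's edge samples (scaled MAD)."""
    n = y.size
    m = max(1, int(round(edge_fraction * n)))
    edges = np.concatenate([y[:m], y[n - m:]])
    med = np.median(edges)
    return 1.4826 * float(np.median(np.abs(edges - med)))


def _local_maxima(y: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus give their centre index."""
    out: list[int] = []
    n = y.size
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        # run [i, j] of equal values; it is a maximum if both flanks are lower
        if y[i - 1] < y[i] and j + 1 < n and y[j + 1] < y[i]:
            out.append((i + j) // 2)
        i = j + 1
    return out


def pick_peaks(
    spectrum: Spectrum1D,
    region: Region,
    threshold: float | str = "auto",
    k: float = 5.0,
) -> list[Peak]:
    """Detect peaks in a region, sorted by ppm.

    ``threshold="auto"`` uses ``k * sigma_noise`` (edge MAD estimate); an
    explicit number is used verbatim.
    """
    x, y = region.slice(spectrum)
    if threshold == "auto":
        thr = k * estimate_noise(y)
    else:
        thr = float(threshold)
    return [
        Peak(position=float(x[i]), intensity=float(y[i]), source="auto")
        for i in _local_maxima(y)
        if y[i] > thr
    ]


def group_signal(
    peaks: Sequence[Peak],
    model_name: str,
    signal_id: str | None = None,
    registry: ModelRegistry | None = None,
) -> SignalInstance:
    """Group picked or manual peaks into a signal with the chosen model."""
    registry = registry or default_registry()
    model = registry.get(model_name)
    if len(peaks) != model.n_peaks:
        raise ValidationError(
            f"model {model_name!r} expects {model.n_peaks} peaks, "
            f"got {len(peaks)}"
        )
    return SignalInstance(
        id=signal_id or model_name,
        model=model,
        peaks=sorted(peaks, key=lambda p: p.position),
    )


def _measure_half_widths(
    spectrum: Spectrum1D, peaks: Sequence[Peak]
) -> list[float]:
    """Half-height full widths of peaks where both crossings are observable."""
    widths: list[float] = []
    x, y = spectrum.ppm, spectrum.intensity
    for pk in peaks:
        i = int(np.argmin(np.abs(x - pk.position)))
        half = pk.intensity / 2.0
        left = right = None
        j = i
        while j > 0:
            if y[j] < half:
                left = x[j]
                break
            if y[j] > pk.intensity:  # climbing a neighbouring peak
                break
            j -= 1
        j = i
        while j < y.size - 1:
            if y[j] < half:
                right = x[j]
                break
            if y[j] > pk.intensity:
                break
            j += 1
        if left is not None and right is not None:
            widths.append(float(right - left))
    return widths


def _solve_couplings(
    model: SignalModel, positions: np.ndarray
) -> tuple[float, dict[str, float]]:
    """Least-squares inversion of positions = x_s + coeffs . J.

    Components are matched to sorted positions via the pattern's canonical
    order (first-listed coupling largest). Exact for pattern-consistent
    positions; averages out small asymmetries otherwise.
    """
    pattern = model.pattern
    order = pattern.canonical_order()
    j_names = pattern.j_names
    design = np.ones((pattern.n_peaks, 1 + len(j_names)))
    for row, comp in enumerate(order):
        offs = pattern.peak_offsets[comp]
        for col, jn in enumerate(j_names, start=1):
            design[row, col] = float(offs.get(jn, 0))
    sol, *_ = np.linalg.lstsq(design, positions, rcond=None)
    xs = float(sol[0])
    J = {jn: float(sol[c]) for c, jn in enumerate(j_names, start=1)}
    return xs, J


def initialize_parameters(
    signal: SignalInstance, spectrum: Spectrum1D, region: Region | None = None
) -> SignalInstance:
    """Resolve init values and bounds for every parameter of ``signal``.

    Deterministic and idempotent: depends only on the member peaks, the model
    specs, and the spectrum. Returns a new instance; the input is unchanged.
    """
    model = signal.model
    if len(signal.peaks) != model.n_peaks:
        raise InitializationError(
            f"signal {signal.id!r}: cannot initialize without exactly "
            f"{model.n_peaks} member peaks"
        )
    positions = np.array(sorted(p.position for p in signal.peaks))
    needs_distinct = model.n_peaks > 1 and len(
        {tuple(sorted(o.items())) for o in model.pattern.peak_offsets}
    ) == model.n_peaks
    if needs_distinct and np.unique(positions).size < positions.size:
        raise InitializationError(
            f"signal {signal.id!r}: coincident peak positions are incompatible "
            f"with model {model.name!r}; consider a lower-multiplicity model"
        )
    xs_init, j_init = _solve_couplings(model, positions)
    j_init = {n: max(v, 0.0) for n, v in j_init.items()}
    i_init = float(sum(p.intensity for p in signal.peaks))

    widths = _measure_half_widths(spectrum, signal.peaks)
    lw_spec = model.parameter_specs["lw"]
    if widths:
        # half-height width of the mixed profile is 2..2.355*lw; use 2.2
        lw_init = float(np.median(widths)) / 2.2
    elif lw_spec.default_init is not None:
        lw_init = lw_spec.default_init
    else:
        if region is not None:
            span = region.ppm_max - region.ppm_min
        else:
            span = float(spectrum.ppm[-1] - spectrum.ppm[0])
        lw_init = span / (20.0 * model.n_peaks)
    lw_init = max(lw_init, float(np.diff(spectrum.ppm).min()))

    inits: dict[str, float] = {"x_s": xs_init, "I": i_init, "lw": lw_init}
    a_spec = model.parameter_specs["a"]
    inits["a"] = a_spec.default_init if a_spec.default_init is not None else 0.5
    inits.update(j_init)

    params: dict[str, ParamState] = {}
    for pname in model.parameter_names:
        spec = model.parameter_specs[pname]
        init = inits[pname]
        lo, hi = spec.resolve_bounds(init)
        if pname == "a":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
            init = min(max(init, lo), hi)
        if pname in model.pattern.j_names:
            lo = max(lo, 0.0)
        if pname == "I" and not signal.allow_negative:
            lo = max(lo, 0.0)
        if pname == "lw":
            lo = max(lo, 1e-12)
        params[pname] = ParamState(pname, init, lo, hi)
    return replace(signal, params=params)
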