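"""Least-squares fitting of one region: cost, bounded minimization,
covariance-based uncertainties.

The cost is the plain sum of squared residuals between the experimental
intensities and the summed signal simulations. Minimization runs L-BFGS-B on
the cost normalized by the experimental sum of squares (scale invariance);
an optional seeded differential-evolution pass can precede the descent.
Standard deviations come from the finite-difference residual Jacobian at the
optimum: ``sd = sqrt(diag(s^2 (J'J)^-1))`` with ``s^2 = cost / (n - k)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import DomainError, FitError
from .models import peak_fwhm, signal_area, simulate_signal
from .peaks import SignalInstance

__all__ = ["FitOptions", "FitProblem", "FitResult", "cost", "fit", "uncertainty"]

_BOUND_TOL = 1e-8  # relative slack for "parameter sits on a bound"
_EXACT_NORMCOST = 1e-9  # normalized cost below which a fit is exact


@dataclass(frozen=True)
class FitOptions:
    """Optimizer knobs; all recorded in the run log by callers."""

    global_refine: bool = False
    seed: int | None = None
    max_iter: int = 2000
    gtol: float = 1e-10  # gradient-projection tolerance on the normalized cost
    ftol: float = 1e-15
    de_popsize: int = 15
    de_maxiter: int = 200


class FitProblem:
    """A region's experimental trace plus the signal instances to fit.

    Flattens the free (non-fixed) parameters of all signals into one vector
    with per-entry bounds; every vector entry maps to exactly one
    (signal, parameter) pair.
    """

    def __init__(
        self,
        x: np.ndarray,
        a: np.ndarray,
        signals: Sequence[SignalInstance],
        options: FitOptions | None = None,
        sf_mhz: float | None = None,
    ) -> None:
        self.x = np.asarray(x, dtype=float)
        self.a = np.asarray(a, dtype=float)
        if self.x.shape != self.a.shape or self.x.ndim != 1:
            raise DomainError("x and a must be equal-length 1D arrays")
        if len(signals) == 0:
            raise DomainError("a fit problem needs at least one signal")
        for sig in signals:
            if not sig.resolved:
                raise DomainError(
                    f"signal {sig.id!r} has unresolved parameters; run "
                    "initialize_parameters first"
                )
        self.signals = list(signals)
        self.options = options or FitOptions()
        self.sf_mhz = sf_mhz
        self.free_index: list[tuple[int, str]] = [
            (i, pname)
            for i, sig in enumerate(self.signals)
            for pname in sig.model.parameter_names
            if not sig.params[pname].fixed
        ]
        if not self.free_index:
            raise DomainError("all parameters are fixed; nothing to fit")
        self.bounds = np.array(
            [
                (self.signals[i].params[p].lower, self.signals[i].params[p].upper)
                for i, p in self.free_index
            ]
        )
        if not np.all(np.isfinite(self.bounds)):
            raise DomainError("all parameter bounds must be finite")

    # -- vector packing -----------------------------------------------------
    @property
    def n_free(self) -> int:
        return len(self.free_index)

    def initial_vector(self) -> np.ndarray:
        return np.array(
            [self.signals[i].params[p].init for i, p in self.free_index]
        )

    def _values_at(self, p: np.ndarray) -> list[dict[str, float]]:
        values = [
            {
                n: (s.value if s.fixed and s.value is not None else s.init)
                for n, s in sig.params.items()
            }
            for sig in self.signals
        ]
        for entry, (i, pname) in zip(p, self.free_index):
            values[i][pname] = float(entry)
        return values

    def model_y(self, p: np.ndarray) -> np.ndarray:
        y = np.zeros_like(self.x)
        for sig, vals in zip(self.signals, self._values_at(p)):
            y += simulate_signal(sig.model, vals, self.x)
        return y

    def residual(self, p: np.ndarray) -> np.ndarray:
        return self.a - self.model_y(p)

    def _raw_cost(self, p: np.ndarray) -> float:
        r = self.residual(p)
        return float(r @ r)


def cost(problem: FitProblem, p: np.ndarray) -> float:
    """Sum of squared residuals at ``p``; enforces bounds for external callers."""
    p = np.asarray(p, dtype=float)
    if p.shape != (problem.n_free,):
        raise DomainError(
            f"parameter vector has length {p.size}, expected {problem.n_free}"
        )
    lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]
    if np.any(p < lo - 1e-12) or np.any(p > hi + 1e-12):
        bad = int(np.argmax((p < lo - 1e-12) | (p > hi + 1e-12)))
        i, name = problem.free_index[bad]
        raise DomainError(
            f"parameter {name!r} of signal {problem.signals[i].id!r} "
            f"({p[bad]}) violates bounds [{lo[bad]}, {hi[bad]}]"
        )
    return problem._raw_cost(p)


@dataclass
class FitResult:
    """Optimized parameters, uncertainties, and diagnostics for one region."""

    values: np.ndarray
    sds: np.ndarray  # NaN where undefined/unreliable
    cost: float
    converged: bool
    message: str
    n_eval: int
    residual: np.ndarray
    signals: list[dict] = field(default_factory=list)
    singular_covariance: bool = False

    def value_of(self, signal_id: str, pname: str) -> float:
        for sig in self.signals:
            if sig["id"] == signal_id:
                return sig["parameters"][pname]["value"]
        raise KeyError(signal_id)

    def sd_of(self, signal_id: str, pname: str) -> float:
        for sig in self.signals:
            if sig["id"] == signal_id:
                return sig["parameters"][pname]["sd"]
        raise KeyError(signal_id)


def _checked_cost(problem: FitProblem, norm: float):
    def f(p: np.ndarray) -> float:
        c = problem._raw_cost(p)
        if not math.isfinite(c):
            raise FitError(f"non-finite cost at parameter vector {p.tolist()}")
        return c / norm

    return f


def fit(problem: FitProblem) -> FitResult:
    """Bounded minimization of the region cost.

    Runs an optional seeded differential-evolution refinement, then L-BFGS-B
    from the best known point. Guarantees monotone improvement: the reported
    cost never exceeds the cost at the initial vector.
    """
    opts = problem.options
    p0 = problem.initial_vector()
    norm = float(problem.a @ problem.a)
    if norm == 0.0:
        norm = 1.0
    f = _checked_cost(problem, norm)
    n_eval = 0
    c0 = f(p0)
    n_eval += 1

    start = p0
    if opts.global_refine:
        de = optimize.differential_evolution(
            f,
            bounds=problem.bounds,
            seed=opts.seed,
            popsize=opts.de_popsize,
            maxiter=opts.de_maxiter,
            init="latinhypercube",
            polish=False,
            tol=1e-10,
        )
        n_eval += de.nfev
        if de.fun < c0:
            start = de.x

    res = optimize.minimize(
        f,
        start,
        method="L-BFGS-B",
        bounds=problem.bounds,
        options={
            "maxiter": opts.max_iter,
            "maxfun": 10 * opts.max_iter * max(problem.n_free, 1),
            "ftol": opts.ftol,
            "gtol": opts.gtol,
        },
    )
    n_eval += res.nfev
    best, c_best = res.x, float(res.fun)
    if f(start) < c_best:
        best, c_best = start, f(start)
    if c0 < c_best:  # never report worse than the initialization
        best, c_best = p0, c0
    raw_cost = c_best * norm

    sds, singular, at_bound = uncertainty(problem, best, raw_cost)
    residual = problem.residual(best)
    # a normalized cost at the roundoff floor is an exact solution even when
    # the line search reports abnormal termination (nothing left to improve);
    # even an SNR-10000 spectrum sits ~3 orders of magnitude above 1e-9
    converged = math.isfinite(raw_cost) and (
        bool(res.success) or c_best <= _EXACT_NORMCOST
    )

    # write back into the parameter states
    for (i, pname), v, sd, ab in zip(problem.free_index, best, sds, at_bound):
        st = problem.signals[i].params[pname]
        st.value = float(v)
        st.sd = None if math.isnan(sd) else float(sd)
        st.at_bound = bool(ab)
        st.sd_reliable = not (ab or math.isnan(sd) or singular)

    signal_records = [_signal_record(sig, problem.sf_mhz) for sig in problem.signals]
    return FitResult(
        values=best.copy(),
        sds=sds,
        cost=raw_cost,
        converged=converged,
        message=str(res.message),
        n_eval=n_eval,
        residual=residual,
        signals=signal_records,
        singular_covariance=singular,
    )


def uncertainty(
    problem: FitProblem, p_opt: np.ndarray, cost_opt: float
) -> tuple[np.ndarray, bool, np.ndarray]:
    """Per-parameter sd from the covariance of the residual least squares.

    Returns ``(sds, singular_flag, at_bound_flags)``; entries of ``sds`` are
    NaN when undefined (``n <= k``). Parameters resting on a bound are
    flagged; their sd is still reported but marked unreliable by the caller.
    """
    n = problem.x.size
    k = problem.n_free
    lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]
    span = np.maximum(hi - lo, 1e-300)
    at_bound = (np.abs(p_opt - lo) <= _BOUND_TOL * span) | (
        np.abs(p_opt - hi) <= _BOUND_TOL * span
    )
    if n <= k:
        return np.full(k, np.nan), True, at_bound

    r0 = problem.residual(p_opt)
    jac = np.empty((n, k))
    for j in range(k):
        h = 1e-6 * max(abs(p_opt[j]), 1e-6 * span[j])
        step = h if p_opt[j] + h <= hi[j] else -h  # stay inside bounds
        pj = p_opt.copy()
        pj[j] += step
        jac[:, j] = (problem.residual(pj) - r0) / step

    jtj = jac.T @ jac
    s2 = cost_opt / (n - k)
    singular = False
    try:
        cov = s2 * np.linalg.inv(jtj)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
        singular = True
    diag = np.clip(np.diag(cov), 0.0, None)
    return np.sqrt(diag), singular, at_bound


def _signal_record(sig: SignalInstance, sf_mhz: float | None) -> dict:
    """JSON-ready record of one fitted signal incl. derived quantities."""
    params = {}
    for pname in sig.model.parameter_names:
        st = sig.params[pname]
        params[pname] = {
            "init": st.init,
            "lower": st.lower,
            "upper": st.upper,
            "value": st.value if st.value is not None else st.init,
            "sd": st.sd,
            "at_bound": st.at_bound,
            "fixed": st.fixed,
            "sd_reliable": st.sd_reliable,
        }
    vals = sig.values()
    derived = {
        "area": signal_area(vals["I"], vals["lw"], vals["a"]),
        "fwhm": peak_fwhm(vals["lw"], vals["a"]),
    }
    if sf_mhz:
        for jn in sig.model.pattern.j_names:
            derived[f"{jn}_hz"] = vals[jn] * sf_mhz
    return {
        "id": sig.id,
        "model": sig.model.name,
        "parameters": params,
        "derived": derived,
    }
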