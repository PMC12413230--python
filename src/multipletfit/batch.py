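"""Row-by-row fitting of a pseudo-2D series with reference propagation.

The user picks a reference row; it is fitted first from the supplied
initializations. Remaining rows are visited outward from the reference
(forward to the end, then backward to the start) and initialized either from
their already-fitted neighbour toward the reference (``previous-row`` mode,
default) or from the reference fit itself (``reference-always``). Relative
bounds are re-resolved around each new initialization so they travel with
drifting peaks; absolute bounds stay fixed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import BatchError, DomainError
from .fitting import FitOptions, FitProblem, FitResult, fit
from .io import SpectrumSeries
from .peaks import ParamState, Region, SignalInstance

__all__ = ["BatchPlan", "BatchResult", "plan_batch", "run_batch"]

MODES = ("previous-row", "reference-always")


@dataclass(frozen=True)
class BatchPlan:
    """Visit order and propagation mode for one series."""

    n_rows: int
    reference: int
    mode: str
    order: tuple[int, ...]

    def source_row(self, row: int) -> int:
        """Row whose fit seeds ``row``'s initialization."""
        if self.mode == "reference-always" or row == self.reference:
            return self.reference
        return row - 1 if row > self.reference else row + 1


def plan_batch(
    series: SpectrumSeries, reference: int, mode: str = "previous-row"
) -> BatchPlan:
    """Build the visit order: reference, then outward passes on both sides."""
    n = series.n_rows
    if not 0 <= reference < n:
        raise DomainError(f"reference row {reference} out of range [0, {n - 1}]")
    if mode not in MODES:
        raise DomainError(f"unknown propagation mode {mode!r}; expected one of {MODES}")
    order = (
        [reference]
        + list(range(reference + 1, n))
        + list(range(reference - 1, -1, -1))
    )
    return BatchPlan(n_rows=n, reference=reference, mode=mode, order=tuple(order))


@dataclass
class BatchResult:
    """Per-row fits plus a long-format parameter table and failure diagnostics."""

    results: dict[int, FitResult]
    table: pd.DataFrame
    failures: list[dict] = field(default_factory=list)


def _reinitialized(signals: list[SignalInstance], source: FitResult) -> list[SignalInstance]:
    """Fresh instances whose inits are the source row's fitted values.

    Relative bounds are recentred around the new inits via the model's
    parameter specs; absolute specs keep their fixed bounds.
    """
    out = []
    for sig, rec in zip(signals, source.signals):
        params: dict[str, ParamState] = {}
        for pname in sig.model.parameter_names:
            old = sig.params[pname]
            init = rec["parameters"][pname]["value"]
            spec = sig.model.parameter_specs[pname]
            if old.fixed:
                lo, hi = old.lower, old.upper
                init = old.init
            elif spec.bound_mode == "relative":
                lo, hi = spec.resolve_bounds(init)
            else:
                lo, hi = old.lower, old.upper
                init = min(max(init, lo), hi)
            if pname in sig.model.pattern.j_names or (
                pname == "I" and not sig.allow_negative
            ):
                lo = max(lo, 0.0)
            if pname == "a":
                lo, hi = max(lo, 0.0), min(hi, 1.0)
            if pname == "lw":
                lo = max(lo, 1e-12)
            init = min(max(init, lo), hi)
            params[pname] = ParamState(pname, init, lo, hi, fixed=old.fixed)
        out.append(replace(sig, params=params, peaks=list(sig.peaks)))
    return out


def run_batch(
    series: SpectrumSeries,
    region: Region,
    signals: list[SignalInstance],
    plan: BatchPlan,
    options: FitOptions | None = None,
    sf_mhz: float | None = None,
) -> BatchResult:
    """Fit every row of ``series`` following ``plan``.

    The reference row must converge (otherwise :class:`BatchError`). A failed
    non-reference row is retried once from the reference fit with global
    refinement enabled; if that also fails it is recorded and later rows fall
    back to reference initialization.
    """
    options = options or FitOptions()
    results: dict[int, FitResult] = {}
    failures: list[dict] = []

    def fit_row(row: int, row_signals: list[SignalInstance], opts: FitOptions) -> FitResult:
        spec = series.row(row)
        x, a = region.slice(spec)
        problem = FitProblem(x, a, row_signals, opts, sf_mhz=sf_mhz)
        return fit(problem)

    ref = plan.reference
    ref_signals = [copy.deepcopy(s) for s in signals]
    ref_result = fit_row(ref, ref_signals, options)
    if not ref_result.converged:
        raise BatchError(
            f"reference row {ref} did not converge: {ref_result.message}"
        )
    results[ref] = ref_result

    for row in plan.order[1:]:
        source = plan.source_row(row)
        source_result = results.get(source)
        if source_result is None or not source_result.converged:
            source_result = ref_result  # fall back past a failed neighbour
        row_signals = _reinitialized(signals, source_result)
        try:
            result = fit_row(row, row_signals, options)
        except Exception as exc:  # keep the batch alive
            result = None
            err = str(exc)
        else:
            err = result.message
        if result is None or not result.converged:
            retry_opts = replace_options(options, global_refine=True)
            row_signals = _reinitialized(signals, ref_result)
            try:
                retry = fit_row(row, row_signals, retry_opts)
            except Exception as exc:
                retry = None
                err = str(exc)
            if retry is not None and retry.converged:
                result = retry
            else:
                failures.append({"row": row, "message": err})
                if retry is not None:
                    result = retry
        if result is not None:
            results[row] = result

    rows = []
    for row in sorted(results):
        res = results[row]
        label = series.labels[row]
        for sig in res.signals:
            for pname, st in sig["parameters"].items():
                rows.append(
                    {
                        "row": row,
                        "label": label,
                        "signal_id": sig["id"],
                        "parameter": pname,
                        "value": st["value"],
                        "sd": st["sd"],
                        "converged": res.converged,
                    }
                )
            for dname, dval in sig["derived"].items():
                rows.append(
                    {
                        "row": row,
                        "label": label,
                        "signal_id": sig["id"],
                        "parameter": dname,
                        "value": dval,
                        "sd": None,
                        "converged": res.converged,
                    }
                )
    table = pd.DataFrame(rows)
    return BatchResult(results=results, table=table, failures=failures)


def replace_options(options: FitOptions, **kw) -> FitOptions:
    return replace(options, **kw)
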