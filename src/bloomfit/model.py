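"""Nonlinear least-squares fitting of the growth-and-decline curve.

The public surface follows the Model -> fit() -> Results pattern:

>>> model = ChurchillModel(series)          # one replicate's counts
>>> res = model.fit()                       # multi-start least squares
>>> res.params.lambda1, res.bse, res.rss

The objective is ordinary least squares on the natural-log count scale,
because the curve predicts ln N directly.  Positivity of all four
parameters is enforced by optimizing their logarithms, which keeps the
solver unconstrained and smooth; wide box bounds on the log scale only
guard against runaway iterates, and a solution pinned to those guards is
flagged as non-converged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from . import curve
from .curve import ChurchillParams
from .errors import (
    ConsistencyError,
    InsufficientDataError,
    InvalidCountError,
)

__all__ = ["SampleMetadata", "TimeSeries", "FitOptions", "ChurchillModel",
           "ChurchillResults", "initial_guess", "fit_churchill"]

logger = logging.getLogger(__name__)

# log-parameter guard bounds: K in [1e-3, 1e3] ln-units, rates in [1e-7, 10] /h
_LOG_BOUNDS_LO = np.log([1e-3, 1e-3, 1e-7, 1e-7])
_LOG_BOUNDS_HI = np.log([1e3, 1e3, 10.0, 10.0])
_RATE_FLOOR = 1e-4  # h^-1, floor for initial-guess rates


@dataclass(frozen=True)
class SampleMetadata:
    """Identifies one experimental replicate within the factorial design."""

    host: str = ""
    inoculum: str = ""
    vitamin: str = ""
    replicate: str = ""


@dataclass(frozen=True)
class TimeSeries:
    """One replicate's timed counts: the unit of curve fitting.

    ``times`` are hours since inoculation (strictly increasing, >= 0);
    ``counts`` are cells/µL and must be strictly positive so the ln
    transform is defined.
    """

    times: np.ndarray
    counts: np.ndarray
    metadata: SampleMetadata = field(default_factory=SampleMetadata)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or len(t) != len(c) or len(t) < 1:
            raise InsufficientDataError(
                "times and counts must be 1-D of equal length >= 1"
            )
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be >= 0 and strictly increasing")
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise InvalidCountError("counts must be finite and > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def ln_counts(self) -> np.ndarray:
        return np.log(self.counts)

    @property
    def label(self) -> str:
        m = self.metadata
        return f"{m.host}/{m.inoculum}/{m.vitamin}/rep{m.replicate}"


@dataclass(frozen=True)
class FitOptions:
    """Solver configuration.

    ftol/gtol are the relative residual-SS and gradient-norm convergence
    tolerances; ``restarts`` counts starting points (1 deterministic start
    from :func:`initial_guess` plus ``restarts - 1`` multiplicatively
    jittered starts with factors uniform in [0.5, 2], seeded by
    ``restart_seed``); ``min_obs`` is the minimum number of observations
    accepted for a 4-parameter fit.
    """

    ftol: float = 1e-10
    gtol: float = 1e-8
    max_iter: int = 500
    restarts: int = 4
    restart_seed: int = 0
    min_obs: int = 5

    def __post_init__(self) -> None:
        if self.ftol <= 0 or self.gtol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.min_obs < 4:
            raise ValueError("min_obs must be >= 4 (one per parameter)")


def initial_guess(series: TimeSeries, min_obs: int = 5) -> ChurchillParams:
    """Heuristic starting parameters from the data.

    K2 starts at the maximum 3-point sliding-window mean of ln counts (the
    peak plateau); K1 solves the t=0 identity 1/y0 = 1/K1 + 1/K2 from the
    first ln count, falling back to K2/10 when that has no positive
    solution.  The rates start from the slopes of ln(ln count) against
    time before and after the peak window (the curve is ~ K1 e^(lambda1 t)
    early and ~ K2 e^(-lambda2 t) late, so ln of the ln-count is ~linear in
    t in each regime).  All four are clipped strictly positive, with a
    1e-4 h^-1 floor on the rates.
    """
    if len(series) < min_obs:
        raise InsufficientDataError(
            f"need >= {min_obs} observations, got {len(series)}"
        )
    t = series.times
    y = series.ln_counts

    win = np.convolve(y, np.ones(3) / 3.0, mode="valid")
    i_peak = int(np.argmax(win)) + 1  # center of the best window
    k2 = float(win[i_peak - 1])
    k2 = max(k2, 1e-3)

    y0 = y[0]
    inv_k1 = 1.0 / y0 - 1.0 / k2 if y0 > 0 else None
    k1 = 1.0 / inv_k1 if inv_k1 is not None and inv_k1 > 0 else k2 / 10.0

    def _log_slope(idx: np.ndarray) -> float | None:
        mask = y[idx] > 0
        if mask.sum() < 2:
            return None
        ti, yi = t[idx][mask], np.log(y[idx][mask])
        if np.ptp(ti) == 0:
            return None
        return float(np.polyfit(ti, yi, 1)[0])

    s_up = _log_slope(np.arange(0, i_peak + 1))
    s_dn = _log_slope(np.arange(i_peak, len(t)))
    lam1 = max(s_up if s_up is not None else _RATE_FLOOR, _RATE_FLOOR)
    lam2 = max(-s_dn if s_dn is not None else _RATE_FLOOR, _RATE_FLOOR)
    return ChurchillParams(k1=max(k1, 1e-3), k2=k2, lambda1=lam1, lambda2=lam2)


class ChurchillResults:
    """Fit results: estimates, uncertainties, diagnostics.

    Attributes
    ----------
    params : ChurchillParams
        Point estimates on the natural parameter scale.
    bse : ndarray
        Per-parameter standard errors from the Jacobian at the solution,
        sigma^2 (J'J)^-1 with sigma^2 = RSS / (n - 4).
    rss : float
        Residual sum of squares on the ln-count scale.
    converged : bool
        True when the solver met its tolerance and no parameter is pinned
        to a guard bound.
    fittedvalues : ndarray
        Predicted ln counts at the observed times.
    """

    _PARAM_NAMES = ("K1", "K2", "lambda1", "lambda2")

    def __init__(self, model: "ChurchillModel", params: ChurchillParams,
                 rss: float, converged: bool, message: str = ""):
        self.model = model
        self.params = params
        self.rss = float(rss)
        self.converged = bool(converged)
        self.message = message
        self.n_obs = len(model.series)
        self.df_resid = self.n_obs - 4
        self.fittedvalues = curve.ln_abundance(params, model.series.times)
        self.resid = model.series.ln_counts - self.fittedvalues
        self.bse = self._standard_errors()

    def _standard_errors(self) -> np.ndarray:
        jac = curve.gradient(self.params, self.model.series.times).T  # (n, 4)
        sigma2 = self.rss / self.df_resid if self.df_resid > 0 else np.nan
        try:
            cov = sigma2 * np.linalg.pinv(jac.T @ jac)
            return np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
            return np.full(4, np.nan)

    def predict(self, t) -> np.ndarray:
        """Predicted ln count at arbitrary times."""
        return curve.ln_abundance(self.params, t)

    @property
    def peak_time(self) -> float:
        return curve.peak_time(self.params)

    def summary(self) -> str:
        p = self.params.as_array()
        lines = [
            "Churchill/Usagi growth-decline fit",
            f"  series: {self.model.series.label}",
            f"  n_obs: {self.n_obs}   RSS(ln scale): {self.rss:.6g}   "
            f"converged: {self.converged}",
            f"  peak time: {self.peak_time:.2f} h",
            f"  {'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        for name, est, se in zip(self._PARAM_NAMES, p, self.bse):
            lines.append(f"  {name:>8} {est:>12.6g} {se:>12.3g}")
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Plot observed ln counts and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        ax.plot(s.times, s.ln_counts, "ko", label="observed ln count")
        tg = np.linspace(s.times[0], s.times[-1], n_grid)
        ax.plot(tg, self.predict(tg), "b-", label="fitted curve")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("ln count (cells/µL)")
        ax.set_title(s.label)
        ax.legend()
        return ax


class ChurchillModel:
    """Growth-and-decline curve model for one replicate's count series.

    Parameters
    ----------
    series : TimeSeries
        The replicate to fit.  Use :meth:`from_dataframe` to build models
        from a tidy count table, or :meth:`pooled` to fit one curve to the
        union of several replicates' points (illustrative only; inference
        uses per-replicate fits).
    """

    def __init__(self, series: TimeSeries):
        self.series = series

    @classmethod
    def from_dataframe(cls, df, host=None, inoculum=None, vitamin=None,
                       replicate=None) -> "ChurchillModel":
        """Build a model for one replicate selected from a tidy count table.

        The frame needs columns host, inoculum, vitamin, replicate, time_h,
        count_per_uL; the four filters must isolate a single replicate.
        """
        sub = df
        sel = {"host": host, "inoculum": inoculum, "vitamin": vitamin,
               "replicate": replicate}
        for col, val in sel.items():
            if val is not None:
                sub = sub[sub[col].astype(str) == str(val)]
        keys = sub[["host", "inoculum", "vitamin", "replicate"]].drop_duplicates()
        if len(keys) != 1:
            raise ConsistencyError(
                f"selection must isolate exactly one replicate, got {len(keys)}"
            )
        sub = sub.sort_values("time_h")
        meta = SampleMetadata(*(str(v) for v in keys.iloc[0]))
        return cls(TimeSeries(sub["time_h"].to_numpy(float),
                              sub["count_per_uL"].to_numpy(float), meta))

    @classmethod
    def pooled(cls, series_list) -> "ChurchillModel":
        """One model over the pooled points of several replicates."""
        t = np.concatenate([s.times for s in series_list])
        c = np.concatenate([s.counts for s in series_list])
        order = np.argsort(t, kind="stable")
        t, c = t[order], c[order]
        # collapse duplicate times by geometric-mean count (ln-scale mean)
        ut, inv = np.unique(t, return_inverse=True)
        lc = np.zeros(len(ut))
        np.add.at(lc, inv, np.log(c))
        lc /= np.bincount(inv)
        meta = replace(series_list[0].metadata, replicate="pooled")
        return cls(TimeSeries(ut, np.exp(lc), meta))

    def fit(self, options: FitOptions | None = None) -> ChurchillResults:
        """Multi-start nonlinear least squares on the ln-count scale.

        Deterministic given the options: the first start is the data-driven
        heuristic, the rest are jittered copies from a seeded generator.
        Returns converged=False (never raises) when no start meets the
        tolerances or the best solution sits on a guard bound.
        """
        opts = options or FitOptions()
        series = self.series
        if len(series) < opts.min_obs:
            raise InsufficientDataError(
                f"need >= {opts.min_obs} observations, got {len(series)}"
            )
        t, y = series.times, series.ln_counts

        def resid(log_theta: np.ndarray) -> np.ndarray:
            p = ChurchillParams.from_array(np.exp(log_theta))
            return curve.ln_abundance(p, t) - y

        def jac(log_theta: np.ndarray) -> np.ndarray:
            theta = np.exp(log_theta)
            p = ChurchillParams.from_array(theta)
            return curve.gradient(p, t).T * theta  # chain rule d/d log

        guess = initial_guess(series, opts.min_obs).as_array()
        rng = np.random.default_rng(opts.restart_seed)
        starts = [guess]
        for _ in range(opts.restarts - 1):
            starts.append(guess * rng.uniform(0.5, 2.0, size=4))

        best = None
        for x0 in starts:
            x0 = np.clip(np.log(x0), _LOG_BOUNDS_LO, _LOG_BOUNDS_HI)
            try:
                sol = least_squares(
                    resid, x0, jac=jac,
                    bounds=(_LOG_BOUNDS_LO, _LOG_BOUNDS_HI),
                    ftol=opts.ftol, xtol=opts.ftol, gtol=opts.gtol,
                    max_nfev=opts.max_iter * 4,
                )
            except Exception as exc:  # solver blow-up on a bad start
                logger.debug("start failed for %s: %s", series.label, exc)
                continue
            if best is None or sol.cost < best.cost:
                best = sol

        if best is None:  # pragma: no cover - least_squares is robust
            raise RuntimeError(f"all starts failed for {series.label}")

        at_bound = bool(
            np.any(best.x <= _LOG_BOUNDS_LO + 1e-6)
            or np.any(best.x >= _LOG_BOUNDS_HI - 1e-6)
        )
        params = ChurchillParams.from_array(np.exp(best.x))
        # a rate whose total effect over the observed span is negligible is
        # not identified by the data (flat / monotone series)
        span = t[-1] - t[0]
        unresolved = min(params.lambda1, params.lambda2) * span < 1e-3
        converged = bool(best.success) and not at_bound and not unresolved
        if not converged:
            reason = ("parameter at guard bound" if at_bound
                      else "growth or decline phase not resolved by the data"
                      if unresolved else best.message)
            logger.warning("non-converged fit for %s (%s)", series.label, reason)
        return ChurchillResults(self, params, rss=2.0 * best.cost,
                                converged=converged, message=best.message)


def fit_churchill(series: TimeSeries,
                  options: FitOptions | None = None) -> ChurchillResults:
    """Functional wrapper: ``ChurchillModel(series).fit(options)``."""
    return ChurchillModel(series).fit(options)
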