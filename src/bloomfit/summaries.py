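"""Per-replicate response statistics for downstream inference.

Each replicate contributes three responses: the fitted growth exponent
(lambda1), the fitted decline exponent (lambda2), and the maximum
abundance — a data statistic, not a fit output, defined as the best mean
of three consecutive ln counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InsufficientDataError
from .model import ChurchillResults, FitOptions, SampleMetadata, TimeSeries

__all__ = ["ReplicateParameters", "max_abundance", "summarize_replicate",
           "fit_experiment", "RESPONSES"]

#: canonical response names used throughout inference and reports
RESPONSES = ("growth", "max_abundance", "decline")


def max_abundance(series: TimeSeries, method: str = "mean_of_ln") -> float:
    """Peak statistic: the best 3-consecutive-timepoint window.

    ``mean_of_ln`` (default) returns the maximum over all length-3 windows
    of the mean ln count, consistent with performing every analysis on
    ln-transformed counts.  ``ln_of_mean`` averages raw counts first and
    logs the result; the two differ only by within-window spread (AM-GM)
    and are exposed for sensitivity checks.  Ties go to the earliest
    window.
    """
    if len(series) < 3:
        raise InsufficientDataError("max_abundance needs >= 3 timepoints")
    if method == "mean_of_ln":
        vals = np.convolve(series.ln_counts, np.ones(3) / 3.0, mode="valid")
    elif method == "ln_of_mean":
        vals = np.log(np.convolve(series.counts, np.ones(3) / 3.0, mode="valid"))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(vals[np.argmax(vals)])  # argmax takes the earliest tie


@dataclass(frozen=True)
class ReplicateParameters:
    """The derived response triple for one replicate."""

    metadata: SampleMetadata
    growth: float          # lambda1, h^-1
    decline: float         # lambda2, h^-1
    max_abundance: float   # ln(cells/µL)
    fit_converged: bool

    def as_dict(self) -> dict:
        m = self.metadata
        return {
            "host": m.host, "inoculum": m.inoculum, "vitamin": m.vitamin,
            "replicate": m.replicate, "growth": self.growth,
            "decline": self.decline, "max_abundance": self.max_abundance,
            "fit_converged": self.fit_converged,
        }


def summarize_replicate(series: TimeSeries, fit: ChurchillResults,
                        peak_method: str = "mean_of_ln") -> ReplicateParameters:
    """Assemble the three responses for one replicate.

    The fit must have been produced from the same replicate; a metadata
    mismatch raises :class:`ConsistencyError`.  A non-converged fit is
    carried through with its flag so inference can exclude it.
    """
    if fit.model.series.metadata != series.metadata:
        raise ConsistencyError(
            f"series {series.label} does not match fit "
            f"{fit.model.series.label}"
        )
    return ReplicateParameters(
        metadata=series.metadata,
        growth=fit.params.lambda1,
        decline=fit.params.lambda2,
        max_abundance=max_abundance(series, method=peak_method),
        fit_converged=fit.converged,
    )


def fit_experiment(series_list, options: FitOptions | None = None,
                   peak_method: str = "mean_of_ln") -> pd.DataFrame:
    """Fit every replicate and tabulate the responses.

    Returns a tidy frame with one row per replicate (columns host,
    inoculum, vitamin, replicate, growth, decline, max_abundance,
    fit_converged), ready for :mod:`bloomfit.inference`.
    """
    from .model import ChurchillModel  # local import to avoid cycle at init

    rows = []
    for series in series_list:
        try:
            res = ChurchillModel(series).fit(options)
            rows.append(summarize_replicate(series, res, peak_method).as_dict())
        except InsufficientDataError as exc:
            raise InsufficientDataError(
                f"replicate {series.label}: {exc}") from exc
    return pd.DataFrame(rows)
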