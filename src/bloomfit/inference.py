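"""Factorial inference on per-replicate growth responses.

For each host and each response (growth exponent, maximum abundance,
decline exponent) the replicate values are modelled with a saturated
cell-means linear model over the inoculum x vitamin design: every design
cell gets its own mean, and a single pooled residual variance is estimated
from within-cell spread.  Estimated marginal means, pairwise contrasts
with studentized-range (Tukey) multiplicity adjustment, and the percent
impact statistic

    impact% = 100 * (effector - default) / (0.5 * (effector + default))

reproduce the treatment-comparison tables of a factorial co-culture
experiment: inoculation-vs-control and inoculation-vs-inoculation
contrasts within each vitamin level, and replete-vs-deficient vitamin
contrasts within each inoculation state.  Impacts are classified as
beneficial (more growth, higher peak, slower decline) or detrimental
(the reverse directions).

The model surface follows the Model -> fit() -> Results pattern; the
cell-means arithmetic is authored here (it is exact for this design) and
the studentized-range distribution comes from scipy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    InsufficientReplicationError,
    SpecificationError,
    UndefinedImpactError,
)
from .summaries import RESPONSES

__all__ = [
    "CellMeansModel", "CellMeansResults", "ContrastResult", "ImpactRecord",
    "ImpactTables", "impact_percent", "classify_direction",
    "build_impact_tables", "REPORT_COLUMNS",
]

_ADJUST_METHODS = ("tukey", "none")


def impact_percent(effector_mean: float, default_mean: float) -> float:
    """Percent difference relative to the mean of the two conditions.

    Antisymmetric in its arguments and scale-invariant; bounded by ±200
    when both means share a sign.  Undefined when the means average to
    zero.
    """
    avg = 0.5 * (effector_mean + default_mean)
    if avg == 0:
        raise UndefinedImpactError("condition means average to zero")
    return 100.0 * (effector_mean - default_mean) / avg


def classify_direction(response: str, estimate_sign: float) -> str:
    """Map a contrast's sign to beneficial / detrimental / none.

    More growth or a higher peak is beneficial; a faster decline is
    detrimental — so the decline response flips the sign convention.
    """
    if response not in RESPONSES:
        raise SpecificationError(f"unknown response {response!r}")
    if estimate_sign == 0:
        return "none"
    positive_is_good = response in ("growth", "max_abundance")
    good = (estimate_sign > 0) == positive_is_good
    return "beneficial" if good else "detrimental"


@dataclass(frozen=True)
class ContrastResult:
    """One marginal-means contrast (cell A minus cell B)."""

    response: str
    a: tuple
    b: tuple
    mean_a: float
    mean_b: float
    estimate: float
    se: float
    t: float
    df: int
    p_unadjusted: float
    p_adjusted: float
    adjust: str
    family_size: int


@dataclass(frozen=True)
class ImpactRecord:
    """A contrast augmented with the percent-impact effect metric."""

    contrast: ContrastResult
    impact_percent: float
    significant: bool
    direction: str
    host: str = ""
    within: str = ""


class CellMeansModel:
    """Saturated cell-means model for one host and one response.

    Parameters
    ----------
    data : DataFrame
        Per-replicate responses restricted to a single host.  Needs the
        factor columns and the response column; rows with
        ``fit_converged == False`` are dropped before modelling.
    response : str
        One of ``growth``, ``max_abundance``, ``decline``.
    factors : sequence of str
        Design factors (default inoculum and vitamin).  A single factor
        gives the one-way path used e.g. for comparing bacterial strains
        grown in broth.
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 factors: Sequence[str] = ("inoculum", "vitamin")):
        if response not in data.columns:
            raise SpecificationError(f"response column {response!r} missing")
        self.response = response
        self.factors = tuple(factors)
        df = data
        if "fit_converged" in df.columns:
            df = df[df["fit_converged"].astype(bool)]
        df = df.dropna(subset=[response])
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_replicates(cls, table: pd.DataFrame, host: str, response: str,
                        factors: Sequence[str] = ("inoculum", "vitamin"),
                        ) -> "CellMeansModel":
        """Restrict a multi-host replicate table to one host and build."""
        sub = table[table["host"] == host]
        if sub.empty:
            raise SpecificationError(f"host {host!r} not in table")
        return cls(sub, response, factors)

    def fit(self) -> "CellMeansResults":
        """Estimate cell means and the pooled residual variance.

        Every non-empty cell must hold >= 2 replicates so it contributes
        to the pooled variance; pooled variance is the within-cell sum of
        squares over the residual degrees of freedom
        (N - number of cells).
        """
        grouped = self.data.groupby(list(self.factors))[self.response]
        means, counts, ss_within = {}, {}, 0.0
        for key, vals in grouped:
            key = key if isinstance(key, tuple) else (key,)
            v = vals.to_numpy(float)
            if len(v) < 2:
                raise InsufficientReplicationError(
                    f"cell {key} has {len(v)} replicate(s); >= 2 required"
                )
            means[key] = float(v.mean())
            counts[key] = len(v)
            ss_within += float(((v - v.mean()) ** 2).sum())
        n_total = int(sum(counts.values()))
        df_resid = n_total - len(means)
        sigma2 = ss_within / df_resid if df_resid > 0 else 0.0
        return CellMeansResults(self, means, counts, sigma2, df_resid)


class CellMeansResults:
    """Fitted cell means with pooled-variance inference."""

    def __init__(self, model: CellMeansModel, cell_means: Mapping[tuple, float],
                 cell_n: Mapping[tuple, int], sigma2: float, df_resid: int):
        self.model = model
        self.cell_means = dict(cell_means)
        self.cell_n = dict(cell_n)
        self.sigma2 = float(sigma2)
        self.df_resid = int(df_resid)

    # -- estimated marginal means ------------------------------------

    def _match(self, at: Mapping[str, str]) -> list[tuple]:
        unknown = set(at) - set(self.model.factors)
        if unknown:
            raise SpecificationError(f"unknown factor(s) {sorted(unknown)}")
        idx = {f: i for i, f in enumerate(self.model.factors)}
        cells = [c for c in self.cell_means
                 if all(c[idx[f]] == lvl for f, lvl in at.items())]
        if not cells:
            raise SpecificationError(f"no cells match {dict(at)}")
        return sorted(cells)

    def marginal_mean(self, at: Mapping[str, str]) -> tuple[float, float]:
        """Marginal mean and SE for a cell or margin.

        A fully specified ``at`` returns the cell mean with
        SE = sqrt(sigma2 / n).  A partial specification averages the
        matching cell means with equal weight and propagates the SE,
        Var = sigma2 / k^2 * sum(1/n_i) — the estimated-marginal-means
        convention of averaging over the unspecified factor's levels.
        """
        cells = self._match(at)
        k = len(cells)
        mean = float(np.mean([self.cell_means[c] for c in cells]))
        var = self.sigma2 / k**2 * sum(1.0 / self.cell_n[c] for c in cells)
        return mean, float(np.sqrt(var))

    # -- contrasts ----------------------------------------------------

    def _p_values(self, t_stat: float, family_size: int,
                  adjust: str) -> tuple[float, float]:
        if np.isnan(t_stat):
            return 1.0, 1.0
        p_un = float(2.0 * stats.t.sf(abs(t_stat), self.df_resid))
        if adjust == "tukey" and family_size > 1:
            # number of levels generating family_size = k*(k-1)/2 pairs
            k = int(round((1 + np.sqrt(1 + 8 * family_size)) / 2))
            p_adj = float(stats.studentized_range.sf(
                np.sqrt(2.0) * abs(t_stat), k, self.df_resid))
        else:
            p_adj = p_un
        p_adj = min(max(p_adj, p_un), 1.0)
        return p_un, p_adj

    def contrast(self, cell_a: Mapping[str, str], cell_b: Mapping[str, str],
                 adjust: str = "none", family_size: int = 1) -> ContrastResult:
        """Difference of two cell means with pooled-variance t inference."""
        if adjust not in _ADJUST_METHODS:
            raise ConfigurationError(f"unknown adjustment {adjust!r}")
        (ca,), (cb,) = self._match(cell_a), self._match(cell_b)
        ma, mb = self.cell_means[ca], self.cell_means[cb]
        est = ma - mb
        se = float(np.sqrt(self.sigma2 *
                           (1.0 / self.cell_n[ca] + 1.0 / self.cell_n[cb])))
        if se == 0:
            t_stat = 0.0 if est == 0 else np.inf * np.sign(est)
        else:
            t_stat = est / se
        p_un, p_adj = self._p_values(t_stat, family_size, adjust)
        return ContrastResult(
            response=self.model.response, a=ca, b=cb, mean_a=ma, mean_b=mb,
            estimate=est, se=se, t=float(t_stat), df=self.df_resid,
            p_unadjusted=p_un, p_adjusted=p_adj, adjust=adjust,
            family_size=family_size,
        )

    def pairwise_contrasts(self, factor: str,
                           within: Mapping[str, str] | None = None,
                           adjust: str = "tukey") -> list[ContrastResult]:
        """All pairwise contrasts among a factor's levels.

        The family is every pair among the factor's levels present within
        the conditioning levels; the Tukey studentized-range adjustment is
        applied across that whole family (families of one pair are left
        unadjusted).
        """
        if adjust not in _ADJUST_METHODS:
            raise ConfigurationError(f"unknown adjustment {adjust!r}")
        within = dict(within or {})
        if factor not in self.model.factors or factor in within:
            raise SpecificationError(f"bad contrast factor {factor!r}")
        idx = self.model.factors.index(factor)
        levels = sorted({c[idx] for c in self._match(within)})
        if len(levels) < 2:
            raise SpecificationError(
                f"factor {factor!r} has < 2 levels within {within}"
            )
        pairs = list(itertools.combinations(levels, 2))
        fam = len(pairs)
        return [
            self.contrast({**within, factor: la}, {**within, factor: lb},
                          adjust=adjust, family_size=fam)
            for la, lb in pairs
        ]

    def vitamin_contrast(self, inoculum: str, replete: str = "replete",
                         deficient: str = "deficient") -> ContrastResult:
        """Replete-minus-deficient contrast for one inoculation state.

        A two-level family, so no multiplicity adjustment is applied.
        """
        if "vitamin" not in self.model.factors:
            raise SpecificationError("model has no vitamin factor")
        return self.contrast({"inoculum": inoculum, "vitamin": replete},
                             {"inoculum": inoculum, "vitamin": deficient},
                             adjust="none", family_size=1)

    # -- one-factor path ----------------------------------------------

    def anova_oneway(self) -> tuple[float, float]:
        """One-way ANOVA F test that all cell means are equal.

        Only meaningful for a single-factor model (e.g. comparing broth
        growth across bacterial strains).  Returns (F, p).
        """
        cells = list(self.cell_means)
        grand = np.average([self.cell_means[c] for c in cells],
                           weights=[self.cell_n[c] for c in cells])
        ss_b = sum(self.cell_n[c] * (self.cell_means[c] - grand) ** 2
                   for c in cells)
        df_b = len(cells) - 1
        if df_b == 0 or self.sigma2 == 0:
            return np.inf if ss_b > 0 else 0.0, 0.0 if ss_b > 0 else 1.0
        f_stat = (ss_b / df_b) / self.sigma2
        return float(f_stat), float(stats.f.sf(f_stat, df_b, self.df_resid))

    def summary(self) -> str:
        lines = [
            f"Cell-means model: response={self.model.response}, "
            f"factors={self.model.factors}",
            f"  cells: {len(self.cell_means)}   pooled sigma2: "
            f"{self.sigma2:.6g}   df_resid: {self.df_resid}",
            f"  {'cell':<40} {'n':>3} {'mean':>12} {'SE':>10}",
        ]
        for c in sorted(self.cell_means):
            se = np.sqrt(self.sigma2 / self.cell_n[c])
            lines.append(f"  {str(c):<40} {self.cell_n[c]:>3} "
                         f"{self.cell_means[c]:>12.6g} {se:>10.3g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------
# report tables

REPORT_COLUMNS = ["host", "response", "within", "comparison_a", "comparison_b",
                  "mean_a", "mean_b", "estimate", "se", "t", "df",
                  "impact_percent", "p_adjusted", "direction", "significant"]


def _record(res: CellMeansResults, c: ContrastResult, host: str, within: str,
            alpha: float) -> ImpactRecord:
    imp = impact_percent(c.mean_a, c.mean_b)
    return ImpactRecord(
        contrast=c, impact_percent=imp, significant=bool(c.p_adjusted < alpha),
        direction=classify_direction(c.response, np.sign(c.estimate)),
        host=host, within=within,
    )


def _rows(records: list[ImpactRecord], label_idx: int) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.contrast
        rows.append({
            "host": r.host, "response": c.response, "within": r.within,
            "comparison_a": c.a[label_idx], "comparison_b": c.b[label_idx],
            "mean_a": c.mean_a, "mean_b": c.mean_b, "estimate": c.estimate,
            "se": c.se, "t": c.t, "df": c.df,
            "impact_percent": r.impact_percent, "p_adjusted": c.p_adjusted,
            "direction": r.direction, "significant": r.significant,
        })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df.sort_values(
        ["host", "response", "within", "comparison_a", "comparison_b"]
    ).reset_index(drop=True)


@dataclass
class ImpactTables:
    """The three report tables (unfiltered) plus the significance level.

    ``inoculation_vs_control`` and ``inoculation_pairs`` hold the
    inoculum-vs-control and inoculum-vs-inoculum contrasts within each
    vitamin level (one Tukey family per host x response x vitamin level);
    ``vitamin`` holds the replete-minus-deficient contrast within each
    inoculation state.
    """

    inoculation_vs_control: pd.DataFrame
    inoculation_pairs: pd.DataFrame
    vitamin: pd.DataFrame
    alpha: float = 0.05

    def filtered(self, alpha: float | None = None) -> "ImpactTables":
        """Copy keeping only rows significant at ``alpha``."""
        a = self.alpha if alpha is None else alpha
        def _f(df):
            return df[df["p_adjusted"] < a].reset_index(drop=True)
        return ImpactTables(_f(self.inoculation_vs_control),
                            _f(self.inoculation_pairs), _f(self.vitamin), a)

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {"inoculation_vs_control": self.inoculation_vs_control,
                "inoculation_pairs": self.inoculation_pairs,
                "vitamin": self.vitamin}


def build_impact_tables(table: pd.DataFrame, alpha: float = 0.05,
                        control_label: str = "control",
                        adjust: str = "tukey",
                        responses: Sequence[str] = RESPONSES) -> ImpactTables:
    """Run the full factorial inference over every host and response.

    Returns the unfiltered tables; apply ``.filtered()`` for the
    significant-rows view.  Percent impacts are computed from the two raw
    condition means (identical to model-adjusted means on this balanced
    design); the effector is the inoculation (against control), the first
    inoculum (against the second), or the replete vitamin condition
    (against deficient).
    """
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must be in (0, 1]")
    t2, t3, t4 = [], [], []
    vit_idx, inoc_idx = 1, 0  # column order in (inoculum, vitamin) cells
    for host in sorted(table["host"].unique()):
        for response in responses:
            res = CellMeansModel.from_replicates(table, host, response).fit()
            vit_levels = sorted({c[vit_idx] for c in res.cell_means})
            inoc_levels = sorted({c[inoc_idx] for c in res.cell_means})
            for vit in vit_levels:
                cons = res.pairwise_contrasts(
                    "inoculum", within={"vitamin": vit}, adjust=adjust)
                for c in cons:
                    pair = (c.a[inoc_idx], c.b[inoc_idx])
                    if control_label in pair:
                        # orient: inoculation minus control
                        if pair[0] == control_label:
                            c = res.contrast(
                                {"inoculum": pair[1], "vitamin": vit},
                                {"inoculum": pair[0], "vitamin": vit},
                                adjust=c.adjust, family_size=c.family_size)
                        t2.append(_record(res, c, host, vit, alpha))
                    else:
                        t3.append(_record(res, c, host, vit, alpha))
            for inoc in inoc_levels:
                try:
                    c = res.vitamin_contrast(inoc)
                except SpecificationError:
                    continue
                t4.append(_record(res, c, host, inoc, alpha))
    return ImpactTables(_rows(t2, inoc_idx), _rows(t3, inoc_idx),
                        _rows(t4, vit_idx), alpha)
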