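"""Synthetic factorial co-culture experiments.

Generates tidy count tables with the statistical structure the analysis
pipeline assumes: per design cell a true growth-and-decline curve, a
replicate-level lognormal jitter on the true parameters, and multiplicative
lognormal observation noise on the counts.  The default design mirrors a
3-host x 6-inoculation-state x 2-vitamin-level batch-culture experiment
with 3 replicates per cell, diatoms starting at a few cells per µL,
counted at inoculation, again about a day later, and then on a ~60-hour
cadence for ~26 days.

Seeding: a single master seed; every (cell, replicate) gets its own
independent substream derived by stably hashing the cell labels, so adding
or removing a design cell never perturbs the draws of another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import curve
from .curve import ChurchillParams
from .errors import ConfigurationError
from .model import SampleMetadata, TimeSeries

__all__ = ["NoiseModel", "ScenarioSpec", "default_design",
           "simulate_timeseries", "simulate_experiment",
           "DEFAULT_HOSTS", "DEFAULT_INOCULA", "DEFAULT_VITAMINS",
           "DEFAULT_PARAMS", "CONTROL_LABEL"]

DEFAULT_HOSTS = (
    "Chaetoceros sp. KBDT20",
    "Chaetoceros sp. KBDT32",
    "Amphiprora sp. KBDT35",
)
CONTROL_LABEL = "control"
DEFAULT_INOCULA = (
    "Alteromonas 2016",
    "Alteromonas 2024",
    "Alteromonas scs5",
    "Marinobacter scs77",
    "Marinobacter scs85",
    CONTROL_LABEL,
)
DEFAULT_VITAMINS = ("replete", "deficient")

#: Base curve: initial density exp(K1*K2/(K1+K2)) ≈ 3.6 cells/µL (within the
#: 1–10 cells/µL inoculation window), peak near 230 h at ~10^3 cells/µL.
DEFAULT_PARAMS = ChurchillParams(k1=1.5, k2=9.0, lambda1=0.02, lambda2=0.001)

#: 0 h, ~1 day, then every 60 h out to 624 h (26 days): 12 timepoints.
DEFAULT_SCHEDULE = (0.0, 24.0) + tuple(float(t) for t in range(84, 625, 60))

_PARAM_FIELDS = ("k1", "k2", "lambda1", "lambda2")


@dataclass(frozen=True)
class NoiseModel:
    """Observation and replicate-level noise.

    ``count_cv`` is the coefficient of variation of the mean-one lognormal
    factor multiplying each count (flow-cytometry counts are positive with
    roughly constant CV).  ``param_jitter_cv`` is the CV of the mean-one
    lognormal factors applied to each replicate's true parameters,
    representing biological replicate-to-replicate variation.
    """

    count_cv: float = 0.05
    param_jitter_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.count_cv < 0 or self.param_jitter_cv < 0:
            raise ConfigurationError("noise CVs must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       size) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class ScenarioSpec:
    """A full synthetic-experiment description.

    ``effects`` plants treatment effects as strictly positive multipliers
    on the true parameters of matching cells: keys are
    ``(host, inoculum, vitamin)`` with ``None`` as a wildcard, values map a
    parameter name (k1, k2, lambda1, lambda2) to its multiplier.  The
    master ``seed`` is mandatory; all randomness flows from it.
    """

    seed: int
    hosts: Sequence[str] = DEFAULT_HOSTS
    inocula: Sequence[str] = DEFAULT_INOCULA
    vitamins: Sequence[str] = DEFAULT_VITAMINS
    replicates: int = 3
    schedule: Sequence[float] = DEFAULT_SCHEDULE
    base_params: ChurchillParams = DEFAULT_PARAMS
    effects: Mapping[tuple, Mapping[str, float]] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        sched = np.asarray(self.schedule, dtype=float)
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if sched[0] != 0 or np.any(np.diff(sched) <= 0):
            raise ConfigurationError(
                "schedule must start at 0 and strictly increase")
        for key, mult in self.effects.items():
            if len(key) != 3:
                raise ConfigurationError(f"effect key {key} must have 3 parts")
            bad = set(mult) - set(_PARAM_FIELDS)
            if bad:
                raise ConfigurationError(f"unknown parameter(s) {sorted(bad)}")
            if any(m <= 0 for m in mult.values()):
                raise ConfigurationError("effect multipliers must be > 0")

    @property
    def cells(self) -> list[tuple[str, str, str]]:
        return [(h, i, v) for h in self.hosts for i in self.inocula
                for v in self.vitamins]

    def cell_params(self, host: str, inoculum: str,
                    vitamin: str) -> ChurchillParams:
        """True parameters of a cell: base times matching effect multipliers."""
        vals = {f: getattr(self.base_params, f) for f in _PARAM_FIELDS}
        for (h, i, v), mult in self.effects.items():
            if ((h is None or h == host) and (i is None or i == inoculum)
                    and (v is None or v == vitamin)):
                for name, m in mult.items():
                    vals[name] *= m
        return ChurchillParams(**vals)


def default_design(seed: int) -> ScenarioSpec:
    """The default factorial scenario: 36 cells x 3 replicates, no effects."""
    return ScenarioSpec(seed=seed)


def _substream(master_seed: int, *labels) -> np.random.Generator:
    """Independent generator for a labelled unit, stable under design edits."""
    digest = hashlib.sha256("\x1f".join(str(x) for x in labels).encode())
    words = [int.from_bytes(digest.digest()[i:i + 4], "little")
             for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([master_seed] + words))


def simulate_timeseries(params: ChurchillParams, schedule,
                        noise: NoiseModel | None = None,
                        seed: int | np.random.Generator = 0,
                        metadata: SampleMetadata | None = None) -> TimeSeries:
    """One replicate's counts: exp(curve) times mean-one lognormal noise."""
    noise = noise or NoiseModel()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sched = np.asarray(schedule, dtype=float)
    mean_counts = np.exp(curve.ln_abundance(params, sched))
    eps = _lognormal_factors(rng, noise.count_cv, len(sched))
    return TimeSeries(sched, mean_counts * eps,
                      metadata or SampleMetadata())


def simulate_experiment(spec: ScenarioSpec,
                        as_series: bool = False):
    """Simulate the whole design.

    Returns a tidy frame with columns host, inoculum, vitamin, replicate,
    time_h, count_per_uL (one row per cell x replicate x timepoint), or a
    list of :class:`TimeSeries` when ``as_series`` is true.  Each
    replicate's true parameters are its cell's parameters jittered by
    mean-one lognormal factors drawn from that replicate's own seeded
    substream.
    """
    series_list: list[TimeSeries] = []
    for host, inoc, vit in spec.cells:
        cell_p = spec.cell_params(host, inoc, vit)
        for rep in range(1, spec.replicates + 1):
            rng = _substream(spec.seed, host, inoc, vit, rep)
            jit = _lognormal_factors(rng, spec.noise.param_jitter_cv, 4)
            rep_p = ChurchillParams.from_array(cell_p.as_array() * jit)
            meta = SampleMetadata(host=host, inoculum=inoc, vitamin=vit,
                                  replicate=str(rep))
            series_list.append(simulate_timeseries(
                rep_p, spec.schedule, spec.noise, rng, meta))
    if as_series:
        return series_list
    rows = []
    for s in series_list:
        m = s.metadata
        for t, c in zip(s.times, s.counts):
            rows.append({"host": m.host, "inoculum": m.inoculum,
                         "vitamin": m.vitamin, "replicate": m.replicate,
                         "time_h": t, "count_per_uL": c})
    return pd.DataFrame(rows)


def series_from_table(df: pd.DataFrame) -> list[TimeSeries]:
    """Split a tidy count table into per-replicate series (sorted times)."""
    out = []
    keys = ["host", "inoculum", "vitamin", "replicate"]
    for key, sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("time_h")
        meta = SampleMetadata(*(str(k) for k in key))
        out.append(TimeSeries(sub["time_h"].to_numpy(float),
                              sub["count_per_uL"].to_numpy(float), meta))
    return out
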