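"""Staged, constrained fitting of mixing-model coefficients from relaxometry data.

The nine coefficients of each rate surface are estimated in four stages, each
conditioning on the previous ones:

1. deionized-water records fix the intercept ``c1`` (mean measured rate);
2. agarose-only records fix ``c2, c3`` (nonnegative least squares on
   ``rate - c1`` against ``[G, G**2]``);
3. salt-only records fix ``c4, c5`` likewise against ``[N, N**2]``;
4. mixed records fix the interaction terms ``c6..c9`` against
   ``[G*N, G**2*N, G*N**2, G**2*N**2]`` with ``c1..c5`` held fixed.

Nonnegativity is enforced by the solver (not by clipping), and after each
stage coefficients smaller than the zeroing threshold are set to zero without
refitting.  Before fitting, replicate measurements are reduced to one record
per composition at the temperature closest to the 20 degC target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .mixing_model import (
    ZERO_THRESHOLD,
    CoefficientSet,
    ConcentrationPair,
    MixingModel,
    evaluate_rate,
)

__all__ = [
    "MeasurementRecord",
    "FitConfig",
    "FitError",
    "FitStageError",
    "select_fit_measurements",
    "fit_water",
    "fit_agarose_only",
    "fit_salt_only",
    "fit_full",
    "fit_mixing_model",
    "read_measurements",
    "write_measurements",
    "records_to_frame",
]


class FitError(ValueError):
    """A fitting stage could not be completed."""


class FitStageError(FitError):
    """A stage failure, annotated with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclass(frozen=True)
class MeasurementRecord:
    """One sample's composition, field, temperature and measured times.

    ``t1_s`` / ``t2_s`` may be None when that relaxation time was not
    measured; at least one must be present and positive.
    """

    sample_id: str
    salt: str
    salt_conc: float
    agarose_conc: float
    field_T: float
    temperature_C: float
    t1_s: float | None = None
    t2_s: float | None = None
    protocol: str = "not_applicable"
    site: str = ""
    measured_on: str = ""

    def __post_init__(self) -> None:
        if self.t1_s is None and self.t2_s is None:
            raise ValueError(f"record {self.sample_id!r}: neither T1 nor T2 present")
        for name, value in (("t1_s", self.t1_s), ("t2_s", self.t2_s)):
            if value is not None and not (math.isfinite(value) and value > 0):
                raise ValueError(f"record {self.sample_id!r}: {name}={value} must be positive and finite")
        if self.salt_conc < 0 or self.agarose_conc < 0:
            raise ValueError(f"record {self.sample_id!r}: concentrations must be >= 0")
        if self.salt == "none" and self.salt_conc != 0:
            raise ValueError(f"record {self.sample_id!r}: salt='none' requires salt_conc=0")

    @property
    def composition(self) -> tuple[float, float]:
        return (self.agarose_conc, self.salt_conc)

    def time(self, kind: str) -> float | None:
        return self.t1_s if kind == "T1" else self.t2_s


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the staged fit."""

    zero_threshold: float = ZERO_THRESHOLD
    target_temperature_C: float = 20.0
    nonnegative: bool = True
    loss_domain: str = "rate"  # "rate" or "time"
    average_domain: str = "time"  # replicate averaging: "time" or "rate"

    def __post_init__(self) -> None:
        if self.zero_threshold <= 0:
            raise ValueError("zero_threshold must be > 0")
        if self.loss_domain not in ("rate", "time"):
            raise ValueError(f"loss_domain must be 'rate' or 'time', got {self.loss_domain!r}")
        if self.average_domain not in ("time", "rate"):
            raise ValueError(f"average_domain must be 'time' or 'rate', got {self.average_domain!r}")


# ---------------------------------------------------------------------------
# Replicate selection and averaging
# ---------------------------------------------------------------------------

def _average(values: Sequence[float], domain: str) -> float:
    arr = np.asarray(values, dtype=float)
    if domain == "time":
        return float(arr.mean())
    return float(1.0 / np.mean(1.0 / arr))


def select_fit_measurements(
    records: Iterable[MeasurementRecord], config: FitConfig = FitConfig()
) -> list[MeasurementRecord]:
    """Reduce replicates to one record per composition near the target temperature.

    Per unique (salt, agarose, salt concentration) composition, only records
    at the temperature(s) nearest ``config.target_temperature_C`` are kept;
    equidistant temperatures are all retained.  Retained records are averaged
    (time domain by default) into a single record.
    """
    records = list(records)
    if not records:
        return []
    fields = {r.field_T for r in records}
    if len(fields) > 1:
        raise ValueError(f"records span multiple field strengths: {sorted(fields)}")

    by_comp: dict[tuple, list[MeasurementRecord]] = {}
    for r in records:
        by_comp.setdefault((r.salt, r.agarose_conc, r.salt_conc), []).append(r)

    out = []
    for key, group in by_comp.items():
        dist = [abs(r.temperature_C - config.target_temperature_C) for r in group]
        dmin = min(dist)
        kept = [r for r, d in zip(group, dist) if d == dmin]
        t1s = [r.t1_s for r in kept if r.t1_s is not None]
        t2s = [r.t2_s for r in kept if r.t2_s is not None]
        first = kept[0]
        out.append(replace(
            first,
            t1_s=_average(t1s, config.average_domain) if t1s else None,
            t2_s=_average(t2s, config.average_domain) if t2s else None,
            temperature_C=float(np.mean([r.temperature_C for r in kept])),
            sample_id=first.sample_id if len(kept) == 1 else first.sample_id + "+avg",
        ))
    return out


# ---------------------------------------------------------------------------
# Fit stages
# ---------------------------------------------------------------------------

def _threshold(values: np.ndarray, threshold: float) -> np.ndarray:
    out = values.copy()
    out[np.abs(out) < threshold] = 0.0
    return out


def _stage_solve(X: np.ndarray, times: np.ndarray, fixed_rate: np.ndarray,
                 config: FitConfig) -> np.ndarray:
    """Solve ``1/times - fixed_rate ~ X @ c`` for nonnegative c.

    Rate-domain loss is a (nonnegative) linear least-squares problem; the
    time-domain option refines that solution by minimizing residuals on the
    measured times directly.
    """
    y = 1.0 / times - fixed_rate
    if config.nonnegative:
        coef, _ = nnls(X, y)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    if config.loss_domain == "time":
        def resid(c):
            return 1.0 / (fixed_rate + X @ c) - times
        lower = 0.0 if config.nonnegative else -np.inf
        coef = least_squares(resid, x0=np.maximum(coef, 0.0) + 1e-12,
                             bounds=(lower, np.inf), xtol=1e-14, ftol=1e-14).x
    return coef


def fit_water(records: Iterable[MeasurementRecord], kind: str = "T1") -> float:
    """Intercept coefficient from deionized-water records: the mean measured rate."""
    times = [r.time(kind) for r in records
             if r.agarose_conc == 0 and r.salt_conc == 0 and r.time(kind) is not None]
    if not times:
        raise FitStageError(
            "water", f"no water record with a {kind} measurement; supply an intercept explicitly")
    return float(np.mean([1.0 / t for t in times]))


def _single_component_fit(records, kind, c1, conc_of, stage, config):
    data = [(conc_of(r), r.time(kind)) for r in records if r.time(kind) is not None]
    if len({c for c, _ in data}) < 2:
        raise FitStageError(stage, f"need >= 2 distinct concentrations to fit {kind}, got {len({c for c, _ in data})}")
    conc = np.array([c for c, _ in data])
    times = np.array([t for _, t in data])
    X = np.column_stack([conc, conc**2])
    coef = _stage_solve(X, times, np.full_like(times, c1), config)
    return tuple(_threshold(coef, config.zero_threshold))


def fit_agarose_only(records: Iterable[MeasurementRecord], c1: float,
                     kind: str = "T1", config: FitConfig = FitConfig()) -> tuple[float, float]:
    """Fit (c2, c3) from salt-free records, the intercept held fixed."""
    recs = [r for r in records if r.salt_conc == 0]
    return _single_component_fit(recs, kind, c1, lambda r: r.agarose_conc, "agarose-only", config)


def fit_salt_only(records: Iterable[MeasurementRecord], c1: float,
                  kind: str = "T1", config: FitConfig = FitConfig()) -> tuple[float, float]:
    """Fit (c4, c5) from agarose-free records, the intercept held fixed."""
    recs = [r for r in records if r.agarose_conc == 0]
    return _single_component_fit(recs, kind, c1, lambda r: r.salt_conc, "salt-only", config)


def fit_full(records: Iterable[MeasurementRecord], fixed: Sequence[float],
             kind: str = "T1", config: FitConfig = FitConfig()) -> CoefficientSet:
    """Fit the interaction terms ``c6..c9`` with ``c1..c5`` fixed.

    With no mixed (agarose + salt) records the additive model stands and the
    interaction terms are returned as zero.
    """
    if len(fixed) != 5:
        raise ValueError("fixed must hold exactly c1..c5")
    mixed = [r for r in records
             if r.agarose_conc > 0 and r.salt_conc > 0 and r.time(kind) is not None]
    if not mixed:
        coef = np.zeros(4)
    else:
        G = np.array([r.agarose_conc for r in mixed])
        N = np.array([r.salt_conc for r in mixed])
        times = np.array([r.time(kind) for r in mixed])
        c1, c2, c3, c4, c5 = fixed
        fixed_rate = c1 + c2 * G + c3 * G**2 + c4 * N + c5 * N**2
        X = np.column_stack([G * N, G**2 * N, G * N**2, G**2 * N**2])
        coef = _stage_solve(X, times, fixed_rate, config)
        coef = _threshold(coef, config.zero_threshold)
    return CoefficientSet(tuple(fixed) + tuple(coef), kind)


def fit_mixing_model(records: Iterable[MeasurementRecord], salt: str, field_T: float,
                     config: FitConfig = FitConfig()) -> MixingModel:
    """Run the full staged pipeline for one salt at one field strength.

    Records are filtered to the requested salt (water records, salt "none",
    always participate), reduced by :func:`select_fit_measurements`, then the
    four stages run once per relaxation kind.
    """
    pool = [r for r in records
            if r.field_T == field_T and (r.salt == salt or r.salt_conc == 0)]
    if not pool:
        raise FitError(f"no measurements for salt={salt!r} at {field_T} T")
    selected = select_fit_measurements(pool, config)

    sets = {}
    for kind in ("T1", "T2"):
        avail = [r for r in selected if r.time(kind) is not None]
        c1 = fit_water(avail, kind)
        agarose = [r for r in avail if r.salt_conc == 0 and r.agarose_conc > 0]
        c23 = (fit_agarose_only(avail, c1, kind, config) if agarose else (0.0, 0.0))
        salty = [r for r in avail if r.agarose_conc == 0 and r.salt_conc > 0]
        c45 = (fit_salt_only(avail, c1, kind, config) if salty else (0.0, 0.0))
        sets[kind] = fit_full(avail, (c1,) + c23 + c45, kind, config)

    n = len(selected)
    provenance = (f"fit: salt={salt}, field={field_T} T, {n} compositions, "
                  f"loss={config.loss_domain}, zero_threshold={config.zero_threshold}")
    return MixingModel(salt=salt, field_T=field_T,
                       t1_coeffs=sets["T1"], t2_coeffs=sets["T2"], provenance=provenance)


# ---------------------------------------------------------------------------
# Measurement-table I/O (canonical dialect: comma-separated, period decimal)
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ["sample_id", "salt", "salt_conc", "agarose_conc",
                     "field_T", "temperature_C", "t1_s", "t2_s"]
_OPTIONAL_COLUMNS = ["protocol", "site", "measured_on"]


def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read a delimited measurement table into validated records."""
    df = pd.read_csv(path)
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(MeasurementRecord(
            sample_id=str(row.sample_id),
            salt=str(row.salt),
            salt_conc=float(row.salt_conc),
            agarose_conc=float(row.agarose_conc),
            field_T=float(row.field_T),
            temperature_C=float(row.temperature_C),
            t1_s=None if pd.isna(row.t1_s) else float(row.t1_s),
            t2_s=None if pd.isna(row.t2_s) else float(row.t2_s),
            protocol=str(getattr(row, "protocol", "not_applicable")),
            site=str(getattr(row, "site", "")),
            measured_on=str(getattr(row, "measured_on", "")),
        ))
    return records


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id, "salt": r.salt, "salt_conc": r.salt_conc,
        "agarose_conc": r.agarose_conc, "field_T": r.field_T,
        "temperature_C": r.temperature_C, "t1_s": r.t1_s, "t2_s": r.t2_s,
        "protocol": r.protocol, "site": r.site, "measured_on": r.measured_on,
    } for r in records])


def write_measurements(records: Iterable[MeasurementRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
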