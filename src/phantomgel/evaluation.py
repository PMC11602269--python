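"""Quantitative assessment of mimic accuracy and measurement variability.

Two families of metrics:

* **Mimic accuracy** — signed percent error of a measured mimic relaxation
  time against its tissue target, ``100 * (measured - target) / target``,
  summarized per salt and field, with the fraction of error values inside a
  |error| < threshold band (10% by default).
* **Measurement variability** — repeated measurements of one sample are
  normalized to their mean, ``100 * (value - mean) / mean``, and summarized
  per condition (repeatability, protocol dependence, temperature dependence)
  as the mean absolute deviation, the extreme deviations, and the count of
  samples whose worst deviation exceeds the acceptability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MimicResult",
    "VariabilitySummary",
    "normalized_deviations",
    "summarize_condition",
    "mimic_errors",
    "fraction_within",
]


@dataclass(frozen=True)
class MimicResult:
    """Measured-vs-target relaxation errors for one mimic sample."""

    tissue: str
    salt: str
    field_T: float
    target_t1_s: float | None = None
    target_t2_s: float | None = None
    measured_t1_s: float | None = None
    measured_t2_s: float | None = None
    err_t1_pct: float | None = None
    err_t2_pct: float | None = None
    note: str = ""  # e.g. "no matching target"


@dataclass(frozen=True)
class VariabilitySummary:
    """Summary of normalized deviations for one condition / field / kind."""

    condition: str  # repeatability | protocol | temperature
    field_T: float
    kind: str
    mean_abs_pct: float
    min_pct: float
    max_pct: float
    n_samples: int
    n_above_threshold: int
    threshold_pct: float = 10.0

    def __post_init__(self) -> None:
        if self.min_pct > self.max_pct:
            raise ValueError("min_pct must be <= max_pct")
        if self.mean_abs_pct < 0:
            raise ValueError("mean_abs_pct must be >= 0")
        if self.n_above_threshold > self.n_samples:
            raise ValueError("n_above_threshold cannot exceed n_samples")


def normalized_deviations(values: Sequence[float]) -> np.ndarray:
    """Signed percent deviations of repeated measurements from their mean.

    ``d_i = 100 * (v_i - mean) / mean``; the deviations sum to zero and are
    invariant under rescaling all values by a constant.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 repeated measurements, got {arr.size}")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("measurements must be positive and finite")
    mean = arr.mean()
    return 100.0 * (arr - mean) / mean


def summarize_condition(groups: Mapping[str, Sequence[float]], condition: str,
                        field_T: float, kind: str,
                        threshold_pct: float = 10.0) -> VariabilitySummary:
    """Pool per-sample deviation sets into one condition summary.

    ``groups`` maps sample id to that sample's signed percent deviations.
    The mean is of absolute deviations pooled over all samples; min/max are
    the extreme signed deviations anywhere; a sample counts as above
    threshold when its largest absolute deviation exceeds ``threshold_pct``.
    """
    if not groups:
        raise ValueError("no deviation groups supplied")
    pooled = np.concatenate([np.asarray(d, dtype=float) for d in groups.values()])
    n_above = sum(np.max(np.abs(np.asarray(d, dtype=float))) > threshold_pct
                  for d in groups.values())
    return VariabilitySummary(
        condition=condition, field_T=field_T, kind=kind,
        mean_abs_pct=float(np.mean(np.abs(pooled))),
        min_pct=float(pooled.min()), max_pct=float(pooled.max()),
        n_samples=len(groups), n_above_threshold=int(n_above),
        threshold_pct=threshold_pct,
    )


def _pct_err(measured, target):
    if measured is None or target is None or pd.isna(measured) or pd.isna(target):
        return None
    return 100.0 * (measured - target) / target


def mimic_errors(targets: pd.DataFrame, measurements: pd.DataFrame) -> list[MimicResult]:
    """Join measured mimics against tissue targets and compute percent errors.

    ``targets`` columns: tissue, field_T, t1_s, t2_s (optionally salt, when
    targets are salt-specific).  ``measurements`` columns: tissue, salt,
    field_T, t1_s, t2_s.  Every measured row yields a result; rows with no
    matching target carry a note instead of errors.
    """
    keys = ["tissue", "field_T"] + (["salt"] if "salt" in targets.columns else [])
    tgt = targets.set_index(keys)
    results = []
    for row in measurements.itertuples(index=False):
        key = tuple(getattr(row, k) for k in keys)
        key = key[0] if len(key) == 1 else key
        try:
            t = tgt.loc[key]
        except KeyError:
            results.append(MimicResult(
                tissue=row.tissue, salt=row.salt, field_T=row.field_T,
                measured_t1_s=getattr(row, "t1_s", None),
                measured_t2_s=getattr(row, "t2_s", None),
                note="no matching target"))
            continue
        if isinstance(t, pd.DataFrame):
            t = t.iloc[0]
        tt1 = None if pd.isna(t.get("t1_s")) else float(t["t1_s"])
        tt2 = None if pd.isna(t.get("t2_s")) else float(t["t2_s"])
        mt1 = None if pd.isna(getattr(row, "t1_s", None)) else float(row.t1_s)
        mt2 = None if pd.isna(getattr(row, "t2_s", None)) else float(row.t2_s)
        results.append(MimicResult(
            tissue=row.tissue, salt=row.salt, field_T=row.field_T,
            target_t1_s=tt1, target_t2_s=tt2,
            measured_t1_s=mt1, measured_t2_s=mt2,
            err_t1_pct=_pct_err(mt1, tt1), err_t2_pct=_pct_err(mt2, tt2)))
    return results


def fraction_within(results: Iterable[MimicResult], threshold_pct: float = 10.0,
                    exclude: Iterable[str] = (), unit: str = "datapoint") -> float:
    """Percentage of mimic errors with magnitude strictly below the threshold.

    ``unit="datapoint"`` counts each present T1 and T2 error individually;
    ``unit="sample"`` counts a mimic once, inside only when all its present
    errors are inside.  Tissues in ``exclude`` (e.g. CSF, which no salt can
    mimic at lab temperature) are dropped before counting.
    """
    if unit not in ("datapoint", "sample"):
        raise ValueError(f"unit must be 'datapoint' or 'sample', got {unit!r}")
    excl = set(exclude)
    kept = [r for r in results if r.tissue not in excl]
    if unit == "datapoint":
        errs = [e for r in kept for e in (r.err_t1_pct, r.err_t2_pct) if e is not None]
        if not errs:
            raise ValueError("no error values remain after exclusion")
        within = sum(abs(e) < threshold_pct for e in errs)
        return 100.0 * within / len(errs)
    samples = [r for r in kept if r.err_t1_pct is not None or r.err_t2_pct is not None]
    if not samples:
        raise ValueError("no samples remain after exclusion")
    within = sum(all(abs(e) < threshold_pct
                     for e in (r.err_t1_pct, r.err_t2_pct) if e is not None)
                 for r in samples)
    return 100.0 * within / len(samples)
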