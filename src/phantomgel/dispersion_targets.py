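"""Relaxation-dispersion curves: fit T(B0) per tissue and interpolate targets.

Tissue relaxation times vary with magnetic field strength (the NMRD
profile).  To pick a phantom target at an arbitrary field, a parametric
dispersion curve is fitted to literature / fast-field-cycling observations of
one tissue and evaluated at the field of interest.

Two built-in families are provided, and neither is privileged:

* ``power_law`` — ``T = A * B0**beta`` (fitted on times); a two-parameter
  form that captures the roughly log-linear rise of tissue T1 with field.
* ``lorentzian_sum`` — a rate-domain spectral-density form
  ``R = B + sum_i C_i * tau_i / (1 + (omega * tau_i)**2)`` with
  ``omega = gamma * B0`` (proton angular Larmor frequency), fitted on rates.

Targets can also be supplied directly as a literal table, bypassing fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import lmfit

__all__ = [
    "GAMMA_PROTON",
    "DispersionObservation",
    "DispersionModel",
    "fit_dispersion",
    "target_at_field",
    "band_coverage",
    "evaluate_dispersion",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.6752218744e8


@dataclass(frozen=True)
class DispersionObservation:
    """One relaxation-time observation of a tissue at one field."""

    tissue: str
    field_T: float
    value_s: float
    kind: str = "T1"
    source: str = "literature"  # or "ffc_ex_vivo"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.field_T) and self.field_T > 0):
            raise ValueError(f"field_T must be positive and finite, got {self.field_T}")
        if not (np.isfinite(self.value_s) and self.value_s > 0):
            raise ValueError(f"value_s must be positive and finite, got {self.value_s}")
        if self.kind not in ("T1", "T2"):
            raise ValueError(f"kind must be 'T1' or 'T2', got {self.kind!r}")


@dataclass(frozen=True)
class DispersionModel:
    """A fitted parametric dispersion curve for one tissue and relaxation kind."""

    form: str  # "power_law" or "lorentzian_sum"
    params: Mapping[str, float]
    kind: str
    tissue: str
    field_range_T: tuple[float, float] = (0.0, np.inf)
    residual_rms: float = float("nan")

    def __call__(self, field_T) -> np.ndarray | float:
        return evaluate_dispersion(self.form, self.params, field_T)


def _power_law_time(params, B0):
    return params["A"] * np.asarray(B0, dtype=float) ** params["beta"]


def _lorentzian_rate(params, B0):
    omega = GAMMA_PROTON * np.asarray(B0, dtype=float)
    rate = np.full_like(omega, float(params["B"]), dtype=float)
    i = 1
    while f"C{i}" in params:
        C, tau = params[f"C{i}"], params[f"tau{i}"]
        rate = rate + C * tau / (1.0 + (omega * tau) ** 2)
        i += 1
    return rate


def evaluate_dispersion(form: str, params: Mapping[str, float], field_T) -> np.ndarray | float:
    """Relaxation time (seconds) predicted at ``field_T`` by a parameter set."""
    if form == "power_law":
        out = _power_law_time(params, field_T)
    elif form == "lorentzian_sum":
        out = 1.0 / _lorentzian_rate(params, field_T)
    else:
        raise ValueError(f"unknown dispersion form {form!r}")
    return float(out) if np.isscalar(field_T) or np.ndim(field_T) == 0 else out


_DEFAULT_SETUPS = {
    "power_law": {"A": (1.0, 1e-6, 100.0), "beta": (0.2, -2.0, 2.0)},
    "lorentzian_sum": {
        "B": (1.0, 1e-6, 1e3),
        "C1": (1e9, 1e6, 1e14), "tau1": (1e-9, 1e-12, 1e-5),
        "C2": (1e8, 1e6, 1e14), "tau2": (1e-7, 1e-12, 1e-5),
    },
}


def fit_dispersion(observations: Iterable[DispersionObservation], form: str = "power_law",
                   init_and_bounds: Mapping[str, tuple[float, float, float]] | None = None
                   ) -> DispersionModel:
    """Bounded nonlinear least squares of a dispersion form to one tissue's data.

    ``init_and_bounds`` maps each parameter name to ``(init, lower, upper)``;
    built-in defaults are used otherwise.  The power law is fitted on times,
    the Lorentzian-sum form on rates, matching each family's natural
    linearity; the optimizer works against log-spaced field values as given.
    """
    obs = list(observations)
    tissues = {o.tissue for o in obs}
    kinds = {o.kind for o in obs}
    if len(tissues) != 1 or len(kinds) != 1:
        raise ValueError("observations must cover exactly one tissue and one relaxation kind")
    setup = dict(_DEFAULT_SETUPS[form] if form in _DEFAULT_SETUPS
                 else {})
    if form not in _DEFAULT_SETUPS:
        raise ValueError(f"unknown dispersion form {form!r}")
    if init_and_bounds:
        setup.update(init_and_bounds)
    if len(obs) < len(setup):
        raise ValueError(f"need >= {len(setup)} observations to fit {form}, got {len(obs)}")
    fields = np.array([o.field_T for o in obs])
    values = np.array([o.value_s for o in obs])
    if np.ptp(fields) == 0:
        raise ValueError("all observations share one field strength; dispersion is unidentifiable")

    # Lorentzian parameter magnitudes span many decades (C_i ~ 1e9 s^-2,
    # tau_i ~ 1e-9 s), so that family is optimized over log10-parameters.
    log_space = form == "lorentzian_sum"
    params = lmfit.Parameters()
    for name, (init, lo, hi) in setup.items():
        if log_space:
            params.add(name, value=np.log10(init), min=np.log10(max(lo, 1e-300)),
                       max=np.log10(hi))
        else:
            params.add(name, value=init, min=lo, max=hi)

    def natural(p):
        vals = p.valuesdict()
        return {k: 10.0**v for k, v in vals.items()} if log_space else vals

    if form == "power_law":
        def residual(p):
            return _power_law_time(natural(p), fields) - values
    else:
        rates = 1.0 / values

        def residual(p):
            return (_lorentzian_rate(natural(p), fields) - rates) / rates

    result = lmfit.minimize(residual, params, method="least_squares",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
    fitted = natural(result.params)
    fitted = {k: float(v) for k, v in fitted.items()}
    rms = float(np.sqrt(np.mean(np.asarray(result.residual) ** 2)))
    return DispersionModel(form=form, params=fitted,
                           kind=obs[0].kind, tissue=obs[0].tissue,
                           field_range_T=(float(fields.min()), float(fields.max())),
                           residual_rms=rms)


def target_at_field(model: DispersionModel, field_T: float) -> float:
    """Interpolated target relaxation time at ``field_T``.

    Evaluating outside the fitted field range emits an extrapolation warning
    but still returns the value.
    """
    if not (np.isfinite(field_T) and field_T > 0):
        raise ValueError(f"field_T must be positive and finite, got {field_T}")
    lo, hi = model.field_range_T
    if not (lo <= field_T <= hi):
        warnings.warn(
            f"field {field_T} T outside the fitted range [{lo}, {hi}] T; extrapolating",
            stacklevel=2)
    return float(model(field_T))


def band_coverage(fields_T: Sequence[float], values_s: Sequence[float],
                  model: DispersionModel, tolerance: float = 0.10
                  ) -> list[tuple[float, float]]:
    """Field intervals where a measured curve stays within a fractional band of the model.

    ``fields_T``/``values_s`` sample the measured dispersion of a mimic on an
    increasing field grid.  Returns the maximal contiguous intervals where
    ``|curve - model| / model <= tolerance``; band crossings between samples
    are located by linear interpolation of the relative deviation in
    log-field.
    """
    fields = np.asarray(fields_T, dtype=float)
    values = np.asarray(values_s, dtype=float)
    if fields.size == 0:
        return []
    if fields.size != values.size:
        raise ValueError("fields and values must have equal length")
    if np.any(np.diff(fields) <= 0):
        raise ValueError("fields must be strictly increasing")

    ref = np.asarray(model(fields), dtype=float)
    dev = np.abs(values - ref) / ref  # relative deviation, >= 0
    inside = dev <= tolerance
    x = np.log(fields)

    intervals: list[tuple[float, float]] = []
    start: float | None = None

    def crossing(i: int) -> float:
        # field where dev == tolerance between samples i and i+1
        d0, d1 = dev[i] - tolerance, dev[i + 1] - tolerance
        frac = d0 / (d0 - d1)
        return float(np.exp(x[i] + frac * (x[i + 1] - x[i])))

    if inside[0]:
        start = float(fields[0])
    for i in range(len(fields) - 1):
        if inside[i] and not inside[i + 1]:
            intervals.append((start, crossing(i)))
            start = None
        elif not inside[i] and inside[i + 1]:
            start = crossing(i)
    if start is not None:
        intervals.append((start, float(fields[-1])))
    return intervals
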