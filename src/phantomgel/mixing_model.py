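"""Second-order polynomial mixing models for doped-agarose relaxation phantoms.

A mixing model maps the composition of an agarose gel doped with a
paramagnetic salt to its longitudinal and transverse relaxation rates at one
magnetic field strength:

    R(G, N) = c1 + c2*G + c3*G**2 + c4*N + c5*N**2
              + c6*G*N + c7*G**2*N + c8*G*N**2 + c9*G**2*N**2

where ``G`` is the agarose concentration (percent weight/volume), ``N`` the
salt concentration (millimolar), and ``R`` a relaxation rate in 1/s (either
R1 = 1/T1 or R2 = 1/T2).  All coefficients are nonnegative, so the rate
surfaces are nondecreasing in both concentrations and the pure-water rate
``c1`` is the global minimum.

The module also ships the published coefficient tables for four salts
(CuSO4, GdCl3-EDTA, MnCl2, NiCl2) at 0.0065, 0.064 and 0.55 T as packaged
data, loadable with :func:`load_published_models`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SALTS",
    "FIELDS_T",
    "ZERO_THRESHOLD",
    "ConcentrationPair",
    "CoefficientSet",
    "MixingModel",
    "ModelLoadError",
    "evaluate_rate",
    "predict_times",
    "load_published_models",
    "load_models",
    "save_models",
    "default_limits",
]

#: Salt species with published coefficient tables.
SALTS = ("CuSO4", "GdCl3-EDTA", "MnCl2", "NiCl2")

#: Field strengths (tesla) with published coefficient tables.
FIELDS_T = (0.0065, 0.064, 0.55)

#: Coefficients below this magnitude are set to zero during fitting.
ZERO_THRESHOLD = 1e-4


class ModelLoadError(ValueError):
    """Raised when a model file violates the schema or its invariants."""


@dataclass(frozen=True)
class ConcentrationPair:
    """A gel composition: agarose in percent w/v, salt in mM."""

    agarose: float
    salt: float

    def __post_init__(self) -> None:
        for name, value in (("agarose", self.agarose), ("salt", self.salt)):
            if not np.isfinite(value):
                raise ValueError(f"{name} concentration must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} concentration must be >= 0, got {value}")


@dataclass(frozen=True)
class CoefficientSet:
    """Nine polynomial coefficients of one rate surface (R1 or R2).

    Invariants: all coefficients are nonnegative, and none lies strictly
    between 0 and ``ZERO_THRESHOLD`` (small fitted values are zeroed).
    """

    coefficients: tuple[float, ...]
    relaxation_kind: str  # "T1" or "T2"

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        if len(coeffs) != 9:
            raise ValueError(f"expected 9 coefficients, got {len(coeffs)}")
        if self.relaxation_kind not in ("T1", "T2"):
            raise ValueError(f"relaxation_kind must be 'T1' or 'T2', got {self.relaxation_kind!r}")
        for i, c in enumerate(coeffs, start=1):
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"coefficient c{i} must be finite and >= 0, got {c}")
            if 0 < c < ZERO_THRESHOLD:
                raise ValueError(
                    f"coefficient c{i}={c} is nonzero but below the zeroing threshold {ZERO_THRESHOLD}"
                )

    def __iter__(self):
        return iter(self.coefficients)

    def __getitem__(self, i):
        return self.coefficients[i]


@dataclass(frozen=True)
class MixingModel:
    """One salt/field pair's T1 and T2 rate surfaces plus provenance."""

    salt: str
    field_T: float
    t1_coeffs: CoefficientSet
    t2_coeffs: CoefficientSet
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.field_T <= 0 or not np.isfinite(self.field_T):
            raise ValueError(f"field_T must be positive and finite, got {self.field_T}")
        if self.t1_coeffs.relaxation_kind != "T1":
            raise ValueError("t1_coeffs must have relaxation_kind 'T1'")
        if self.t2_coeffs.relaxation_kind != "T2":
            raise ValueError("t2_coeffs must have relaxation_kind 'T2'")

    @property
    def key(self) -> tuple[str, float]:
        return (self.salt, self.field_T)

    def coeffs(self, kind: str) -> CoefficientSet:
        if kind == "T1":
            return self.t1_coeffs
        if kind == "T2":
            return self.t2_coeffs
        raise ValueError(f"kind must be 'T1' or 'T2', got {kind!r}")


def _design_terms(G, N):
    """The nine polynomial basis terms, broadcastable over arrays."""
    G = np.asarray(G, dtype=float)
    N = np.asarray(N, dtype=float)
    one = np.ones(np.broadcast(G, N).shape)
    return np.stack(
        [one, G * one, G**2 * one, N * one, N**2 * one,
         G * N, G**2 * N, G * N**2, G**2 * N**2],
        axis=-1,
    )


def evaluate_rate(coeffs: CoefficientSet | Iterable[float], conc: ConcentrationPair) -> float:
    """Evaluate the rate surface at one composition; returns a rate in 1/s.

    With all coefficients nonnegative the result is at least the water
    intercept ``c1``.
    """
    if not isinstance(conc, ConcentrationPair):
        conc = ConcentrationPair(*conc)
    c = np.asarray(list(coeffs), dtype=float)
    terms = _design_terms(conc.agarose, conc.salt)
    return float(terms @ c)


def evaluate_rate_grid(coeffs: CoefficientSet | Iterable[float], G, N) -> np.ndarray:
    """Vectorized rate evaluation over broadcastable concentration arrays."""
    c = np.asarray(list(coeffs), dtype=float)
    return _design_terms(G, N) @ c


def predict_times(model: MixingModel, conc: ConcentrationPair) -> tuple[float, float]:
    """Predicted (T1, T2) in seconds at a composition: reciprocals of the rates."""
    r1 = evaluate_rate(model.t1_coeffs, conc)
    r2 = evaluate_rate(model.t2_coeffs, conc)
    if r1 <= 0 or r2 <= 0:
        raise ValueError(
            "degenerate mixing model: zero relaxation rate at "
            f"(G={conc.agarose}, N={conc.salt})"
        )
    return 1.0 / r1, 1.0 / r2


# ---------------------------------------------------------------------------
# Model-file I/O
# ---------------------------------------------------------------------------

_REQUIRED_ENTRY_KEYS = {"salt", "field_T", "t1_coefficients", "t2_coefficients"}


def _model_from_entry(entry: Mapping) -> MixingModel:
    missing = _REQUIRED_ENTRY_KEYS - entry.keys()
    if missing:
        raise ModelLoadError(f"model entry missing keys {sorted(missing)}: {entry!r}")
    salt = entry["salt"]
    if salt not in SALTS:
        raise ModelLoadError(f"unknown salt {salt!r}; expected one of {SALTS}")
    try:
        t1 = CoefficientSet(tuple(entry["t1_coefficients"]), "T1")
        t2 = CoefficientSet(tuple(entry["t2_coefficients"]), "T2")
        return MixingModel(
            salt=salt,
            field_T=float(entry["field_T"]),
            t1_coeffs=t1,
            t2_coeffs=t2,
            provenance=str(entry.get("provenance", "")),
        )
    except ValueError as exc:
        raise ModelLoadError(f"invalid model entry for {salt} at {entry.get('field_T')} T: {exc}") from exc


def load_models(source: str | Path) -> dict[tuple[str, float], MixingModel]:
    """Load mixing models from a JSON model file, keyed by (salt, field_T).

    The file holds ``{"units": {...}, "models": [...]}``; every entry is
    validated before any model is returned, so a bad file yields no partial
    collection.
    """
    text = Path(source).read_text()
    return _load_models_text(text, name=str(source))


def _load_models_text(text: str, name: str = "<model file>") -> dict[tuple[str, float], MixingModel]:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelLoadError(f"{name}: not valid JSON: {exc}") from exc
    entries = doc.get("models") if isinstance(doc, dict) else None
    if not entries:
        raise ModelLoadError(f"{name}: no model entries found")
    models = {}
    for entry in entries:
        model = _model_from_entry(entry)
        if model.key in models:
            raise ModelLoadError(f"{name}: duplicate model for {model.key}")
        models[model.key] = model
    return models


def save_models(models: Iterable[MixingModel], path: str | Path,
                units: Mapping[str, str] | None = None) -> None:
    """Serialize models to the JSON model-file format; round-trips exactly."""
    doc = {
        "schema": "phantomgel-mixing-models-v1",
        "units": dict(units) if units else {"agarose": "percent w/v", "salt": "mM",
                                            "rate": "1/s", "field": "T"},
        "models": [
            {
                "salt": m.salt,
                "field_T": m.field_T,
                "t1_coefficients": list(m.t1_coeffs),
                "t2_coefficients": list(m.t2_coeffs),
                "provenance": m.provenance,
            }
            for m in models
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_published_models() -> dict[tuple[str, float], MixingModel]:
    """The 12 published mixing models (4 salts x 3 fields) shipped with the package."""
    text = resources.files("phantomgel.data").joinpath("published_models.json").read_text()
    models = _load_models_text(text, name="published_models.json")
    if len(models) != 12:
        raise ModelLoadError(f"expected 12 packaged models, found {len(models)}")
    return models


def default_limits() -> dict:
    """Default concentration bounds per salt for recipe inversion.

    Returns ``{"agarose_max": float, "salt_max": {salt: float}}``.
    """
    text = resources.files("phantomgel.data").joinpath("limits.json").read_text()
    doc = json.loads(text)
    return {"agarose_max": float(doc["agarose_max"]),
            "salt_max": {k: float(v) for k, v in doc["salt_max"].items()}}
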