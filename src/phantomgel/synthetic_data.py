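"""Synthetic relaxometry and dispersion data with known ground truth.

Every other module is testable without downloads: measurements are generated
by forward-evaluating a mixing model over a concentration design (water,
agarose-only, salt-only and mixed subsets, as in a real test-sample study)
and perturbing the times with multiplicative log-normal noise, whose few-
percent default scale matches the variability typical of multi-site
relaxometry.  Dispersion observations are generated from a chosen parametric
form the same way.  All randomness is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dispersion_targets import DispersionObservation, evaluate_dispersion
from .mixing_model import ConcentrationPair, MixingModel, predict_times
from .model_fitting import MeasurementRecord

__all__ = ["DesignSpec", "generate_measurements", "generate_dispersion"]


@dataclass(frozen=True)
class DesignSpec:
    """A concentration design plus noise/replication settings.

    ``noise_sigma`` is the log-scale standard deviation of multiplicative
    log-normal noise on the generated times (0 disables noise); the 0.02
    default reflects the few-percent repeatability of relaxation
    measurements.  ``temperature_jitter_C`` only labels records — it
    exercises replicate selection, with no physical temperature model.
    """

    agarose_levels: Sequence[float] = (0.5, 1.0, 2.0, 4.0)
    salt_levels: Sequence[float] = (0.5, 1.0, 2.0, 5.0)
    include_water: bool = True
    include_single_component: bool = True
    replicates: int = 1
    temperature_C: float = 20.0
    temperature_jitter_C: float = 0.0
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.agarose_levels) or any(n < 0 for n in self.salt_levels):
            raise ValueError("concentration levels must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def compositions(self) -> list[tuple[float, float]]:
        pts: list[tuple[float, float]] = []
        if self.include_water:
            pts.append((0.0, 0.0))
        if self.include_single_component:
            pts.extend((g, 0.0) for g in self.agarose_levels if g > 0)
            pts.extend((0.0, n) for n in self.salt_levels if n > 0)
        pts.extend((g, n) for g in self.agarose_levels for n in self.salt_levels
                   if g > 0 and n > 0)
        return pts


def generate_measurements(model: MixingModel, design: DesignSpec = DesignSpec()
                          ) -> list[MeasurementRecord]:
    """Forward-simulate a measurement table from a mixing model.

    Each design point's noiseless times come from the model's rate surfaces;
    noise multiplies each time by ``exp(sigma * z)`` with standard-normal
    ``z``.  Output is deterministic for a given design (seed included).
    """
    rng = np.random.default_rng(design.seed)
    records = []
    for i, (g, n) in enumerate(design.compositions()):
        t1, t2 = predict_times(model, ConcentrationPair(g, n))
        for rep in range(design.replicates):
            if design.noise_sigma > 0:
                f1, f2 = np.exp(design.noise_sigma * rng.standard_normal(2))
            else:
                f1 = f2 = 1.0
            temp = design.temperature_C
            if design.temperature_jitter_C > 0:
                temp += design.temperature_jitter_C * rng.standard_normal()
            records.append(MeasurementRecord(
                sample_id=f"syn-{i:03d}r{rep}",
                salt=model.salt if n > 0 else "none",
                salt_conc=n, agarose_conc=g,
                field_T=model.field_T, temperature_C=float(temp),
                t1_s=t1 * f1, t2_s=t2 * f2,
                protocol="not_applicable", site="synthetic",
                measured_on="synthetic"))
    return records


def generate_dispersion(form: str, params: Mapping[str, float],
                        fields_T: Sequence[float], tissue: str = "synthetic",
                        kind: str = "T1", noise_sigma: float = 0.0,
                        seed: int = 0) -> list[DispersionObservation]:
    """Simulate dispersion observations from a parametric form at given fields."""
    rng = np.random.default_rng(seed)
    obs = []
    for b0 in fields_T:
        value = evaluate_dispersion(form, params, float(b0))
        if noise_sigma > 0:
            value *= float(np.exp(noise_sigma * rng.standard_normal()))
        obs.append(DispersionObservation(tissue=tissue, field_T=float(b0),
                                         value_s=value, kind=kind, source="literature"))
    return obs
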