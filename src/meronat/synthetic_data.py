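"""Synthetic cohorts, TDM observations and MIC distributions.

The generators emulate a routine-care ICU meropenem dataset: a cohort
whose characteristic distributions match stated median and 5th/95th
percentile targets (creatinine clearance, age, weight, serum albumin,
male fraction), therapeutic drug monitoring samples taken once per dosing
interval at variable times after the dose, and EUCAST-like MIC frequency
distributions over doubling dilutions.

Defaults reproduce the reference cohort: median CLCR 86.4 mL/min
(5th-95th: 35.4-161), median weight 73 kg, median albumin 2.5 g/dL,
65.2% male, a mean of 5.7 samples per patient, and sampling a median of
6.2 h after the last dose (5th-95th: 3.72-8.13 h). Serum creatinine is
back-solved from the drawn CLCR through the inverted Cockcroft-Gault
equation so records are internally consistent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError
from .patients import FEMALE, MALE, Patient
from .poppk import (DosingRegimen, IndividualParameters, PopPKModel,
                    concentration, individual_parameters)
from .risk_cfr import MICDistribution

log = logging.getLogger(__name__)

_Z95 = stats.norm.ppf(0.95)   # 1.6449


@dataclass
class QuantileSpec:
    """Distribution of one positive characteristic by median and percentiles.

    Lognormal (default) solves (median, p95) for (mu, sigma) and validates
    the implied 5th percentile against the target, warning when off by more
    than 15% — right-skewed clinical variables rarely match a two-parameter
    family at all three quantiles. A truncated-normal family is available
    for symmetric characteristics. ``p95 == median`` degenerates to a point
    mass at the median.
    """

    median: float
    p5: float
    p95: float
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if not self.p5 <= self.median <= self.p95:
            raise ValidationError(
                f"percentile targets must be ordered p5 <= median <= p95, got "
                f"({self.p5}, {self.median}, {self.p95})"
            )
        if self.p5 <= 0:
            raise ValidationError("characteristics must be strictly positive")
        if self.family not in ("lognormal", "truncnorm"):
            raise ValidationError(f"unknown family {self.family!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.p95 == self.median:
            return np.full(n, self.median)
        if self.family == "lognormal":
            mu = math.log(self.median)
            sigma = math.log(self.p95 / self.median) / _Z95
            implied_p5 = self.median * math.exp(-_Z95 * sigma)
            if abs(implied_p5 - self.p5) > 0.15 * self.p5 and not getattr(
                    self, "_p5_warned", False):
                object.__setattr__(self, "_p5_warned", True)
                log.warning(
                    "lognormal(median=%.3g, p95=%.3g) implies p5=%.3g vs target "
                    "%.3g (off by >15%%)", self.median, self.p95, implied_p5, self.p5,
                )
            return rng.lognormal(mu, sigma, size=n)
        # truncated normal on (0, inf), sd from the upper half-width
        sd = (self.p95 - self.median) / _Z95
        a = (0.0 - self.median) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=self.median, scale=sd,
                                   size=n, random_state=rng)


@dataclass
class SamplingTimeSpec:
    """Time after last dose at which the TDM sample is drawn, in hours.

    Modelled as ``interval * Beta(a, b)`` with (a, b) calibrated so the
    median and 5th percentile hit their targets; the 95th percentile target
    can exceed the dosing interval in routine data (delayed re-dosing) and
    is then capped at the interval.
    """

    median: float = 6.2
    p5: float = 3.72
    p95: float = 8.13

    def __post_init__(self) -> None:
        if not 0 < self.p5 <= self.median <= self.p95:
            raise ValidationError("sampling-time percentiles must be ordered and > 0")

    def sample(self, n: int, interval: float, rng: np.random.Generator) -> np.ndarray:
        if self.p5 == self.median == min(self.p95, interval):
            return np.full(n, min(self.median, interval))
        a, b = _beta_shape(
            round(self.median / interval, 6), round(self.p5 / interval, 6)
        )
        return interval * rng.beta(a, b, size=n)


@lru_cache(maxsize=32)
def _beta_shape(median_frac: float, p5_frac: float) -> tuple:
    """Solve Beta(a, b) shape so ppf(0.5) and ppf(0.05) hit the targets."""
    if not 0 < p5_frac < median_frac < 1:
        raise ValidationError(
            f"infeasible beta targets: median fraction {median_frac}, p5 {p5_frac}"
        )

    def resid(logab):
        a, b = np.exp(logab)
        return [
            stats.beta.ppf(0.5, a, b) - median_frac,
            stats.beta.ppf(0.05, a, b) - p5_frac,
        ]

    sol = optimize.fsolve(resid, x0=np.log([3.0, 1.5]), full_output=True)
    x, _, ier, msg = sol
    if ier != 1:
        raise ValidationError(f"beta calibration failed: {msg}")
    a, b = np.exp(x)
    return float(a), float(b)


@dataclass
class CohortSpec:
    """Study-condition targets for the synthetic cohort."""

    n_patients: int = 155
    clcr: QuantileSpec = field(default_factory=lambda: QuantileSpec(86.4, 35.4, 161.0))
    age: QuantileSpec = field(default_factory=lambda: QuantileSpec(57.0, 33.7, 79.0))
    weight: QuantileSpec = field(default_factory=lambda: QuantileSpec(73.0, 50.0, 97.3))
    albumin: QuantileSpec = field(default_factory=lambda: QuantileSpec(2.5, 2.3, 3.2))
    male_fraction: float = 0.652
    samples_per_patient_mean: float = 5.7
    sampling_time: SamplingTimeSpec = field(default_factory=SamplingTimeSpec)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0 <= self.male_fraction <= 1:
            raise ValidationError("male_fraction must be in [0, 1]")
        if self.samples_per_patient_mean < 1:
            raise ValidationError("samples_per_patient_mean must be >= 1")


def generate_patients(
    spec: CohortSpec,
    rng: np.random.Generator,
    enforce_inclusion: bool = False,
    clcr_bounds: tuple = (25.0, 255.0),
) -> list[Patient]:
    """Draw a cohort; characteristics independent, creatinine back-solved.

    With ``enforce_inclusion`` the CLCR draw is resampled into
    ``clcr_bounds`` (the applicability screen) and the number of resampled
    draws is logged.
    """
    n = spec.n_patients
    clcr = spec.clcr.sample(n, rng)
    if enforce_inclusion:
        lo, hi = clcr_bounds
        n_resampled = 0
        bad = (clcr < lo) | (clcr > hi)
        while np.any(bad):
            n_resampled += int(bad.sum())
            clcr[bad] = spec.clcr.sample(int(bad.sum()), rng)
            bad = (clcr < lo) | (clcr > hi)
        if n_resampled:
            log.info("resampled %d clcr draws into [%g, %g] mL/min", n_resampled, lo, hi)
    age = np.clip(spec.age.sample(n, rng), 18.0, 110.0)
    weight = spec.weight.sample(n, rng)
    albumin = spec.albumin.sample(n, rng)
    male = rng.random(n) < spec.male_fraction

    patients = []
    for i in range(n):
        sex = MALE if male[i] else FEMALE
        scr = (140.0 - age[i]) * weight[i] / (72.0 * clcr[i])
        if sex == FEMALE:
            scr *= 0.85
        patients.append(Patient(
            id=f"SYN-{i + 1:04d}",
            sex=sex,
            age=float(age[i]),
            weight=float(weight[i]),
            serum_creatinine=float(scr),
            serum_albumin=float(albumin[i]),
            rrt=False,
        ))
    return patients


def generate_tdm(
    patients: Sequence[Patient],
    regimen: DosingRegimen,
    pk_model: PopPKModel,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[list, dict]:
    """Simulate routine TDM observations for a cohort.

    Per patient: individual PK parameters are drawn once (ground truth,
    returned for recovery tests); the number of observed q8h dosing
    intervals is 1 + Poisson(mean - 1); one sample per interval at an
    offset drawn from the calibrated sampling-time distribution;
    concentrations include residual error (proportional + additive,
    truncated at 0).

    Returns (observations, {patient_id: IndividualParameters}).
    """
    from .evaluation import TDMObservation  # local import avoids a cycle

    observations = []
    truth: dict[str, IndividualParameters] = {}
    for p in patients:
        params = individual_parameters(pk_model, p, rng)
        truth[p.id] = params
        n_intervals = 1 + rng.poisson(max(spec.samples_per_patient_mean - 1.0, 0.0))
        history = [
            (regimen.dose, regimen.infusion_duration, k * regimen.interval)
            for k in range(n_intervals)
        ]
        offsets = spec.sampling_time.sample(n_intervals, regimen.interval, rng)
        # keep samples strictly after infusion start
        offsets = np.maximum(offsets, regimen.infusion_duration + 1e-3)
        for k in range(n_intervals):
            t = k * regimen.interval + float(offsets[k])
            c = float(concentration(params, history, t))
            eps_p = rng.normal(0.0, pk_model.residual_prop_sd)
            eps_a = rng.normal(0.0, pk_model.residual_add_sd)
            c_obs = max(c * (1.0 + eps_p) + eps_a, 0.0)
            observations.append(TDMObservation(
                patient_id=p.id,
                dose_history=history,
                sample_time=t,
                concentration=c_obs,
            ))
    return observations, truth


def generate_mic_distribution(
    pathogen_name: str,
    modal_mic: float,
    spread: float,
    n_isolates: int,
    rng: np.random.Generator,
    source_label: str = "synthetic",
) -> MICDistribution:
    """A synthetic EUCAST-like MIC frequency distribution.

    Isolate counts follow a multinomial over doubling-dilution bins with
    probabilities from a discretised lognormal centred at ``modal_mic``
    (``spread`` in dilution steps on the log2 scale; 0 puts every isolate
    in the modal bin). The modal MIC must itself lie on the doubling grid
    anchored at 1 mg/L.
    """
    if n_isolates < 1:
        raise ValidationError(f"n_isolates must be >= 1, got {n_isolates}")
    if modal_mic <= 0:
        raise ValidationError(f"modal_mic must be > 0, got {modal_mic}")
    if spread < 0:
        raise ValidationError(f"spread must be >= 0, got {spread}")
    k0 = math.log2(modal_mic)
    if abs(k0 - round(k0)) > 1e-6:
        raise ValidationError(
            f"modal_mic {modal_mic} is not on the doubling-dilution grid"
        )
    k0 = int(round(k0))
    if spread == 0:
        bins = [(modal_mic, n_isolates)]
        return MICDistribution(pathogen_name, bins, source_label)
    ks = np.arange(k0 - 6, k0 + 7)
    probs = np.exp(-0.5 * ((ks - k0) / spread) ** 2)
    probs /= probs.sum()
    counts = rng.multinomial(n_isolates, probs)
    bins = [(float(2.0**k), int(c)) for k, c in zip(ks, counts) if c > 0]
    return MICDistribution(pathogen_name, bins, source_label)
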