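"""Pathogen-sensitivity risk modes and color-coded classification.

Three ways to resolve the microbiological side of the risk question:

* **mic** — the isolate's MIC is known: evaluate the single-MIC risk.
* **pathogen_cfr** — only the species is known: weight the per-MIC risks
  by the pathogen's MIC frequency distribution (EUCAST-style). The
  cumulative fraction of response CFR = sum_i f_i * PTA(mic_i); the risk
  of non-attainment is 1 - CFR = sum_i f_i * risk(mic_i).
* **breakpoint** — nothing is known: evaluate at a user-chosen clinical
  breakpoint MIC.

Risks are classified into the tool's traffic-light bands
(green <= 10%, orange > 10% to <= 50%, red > 50%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ApplicabilityError, ValidationError
from .patients import Patient

log = logging.getLogger(__name__)

#: The 8 doubling-dilution MIC levels used throughout the risk comparison.
DEFAULT_MIC_GRID: tuple = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)

GREEN, ORANGE, RED = "green", "orange", "red"

#: Per-patient traffic-light thresholds (boundary-inclusive on the low side).
GREEN_MAX = 0.10
ORANGE_MAX = 0.50

#: MIC at or above which low-renal-function patients trigger the disclaimer.
DISCLAIMER_MIC = 8.0
DISCLAIMER_CLCR = 50.0

RiskFn = Callable[[float], float]


@dataclass
class MICDistribution:
    """Pathogen-labelled isolate counts over doubling-dilution MIC bins.

    Bin MICs must be strictly increasing and lie on a common doubling grid
    (each successive MIC an exact power-of-two multiple of its predecessor;
    gaps allowed). ``source_label`` records provenance and is echoed to the
    user with every risk result.
    """

    pathogen: str
    bins: Sequence[tuple]         # (mic mg/L, count)
    source_label: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValidationError(f"{self.pathogen}: distribution has no bins")
        mics = [m for m, _ in self.bins]
        counts = [c for _, c in self.bins]
        if any(m <= 0 for m in mics):
            raise ValidationError(f"{self.pathogen}: MIC values must be > 0")
        if any(c < 0 or c != int(c) for c in counts):
            raise ValidationError(f"{self.pathogen}: counts must be non-negative integers")
        for lo, hi in zip(mics, mics[1:]):
            ratio = math.log2(hi / lo)
            if hi <= lo or abs(ratio - round(ratio)) > 1e-6 or round(ratio) < 1:
                raise ValidationError(
                    f"{self.pathogen}: MIC bins must be strictly increasing on a "
                    f"doubling grid; got {lo} -> {hi}"
                )
        if sum(counts) <= 0:
            raise ValidationError(f"{self.pathogen}: total isolate count must be > 0")
        self.bins = [(float(m), int(c)) for m, c in self.bins]

    @property
    def mics(self) -> np.ndarray:
        return np.array([m for m, _ in self.bins])

    @property
    def frequencies(self) -> np.ndarray:
        counts = np.array([c for _, c in self.bins], dtype=float)
        return counts / counts.sum()

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.bins)


@dataclass
class RiskResult:
    """Outcome of one risk assessment, with provenance echo."""

    risk: float
    mode: str                        # mic | pathogen_cfr | breakpoint
    category: str                    # green | orange | red
    inputs_echo: dict = field(default_factory=dict)
    disclaimer_flags: list = field(default_factory=list)


def classify_risk(risk: float) -> str:
    """Traffic-light category: green <= 0.10 < orange <= 0.50 < red."""
    if not 0.0 <= risk <= 1.0:
        raise ValidationError(f"risk must be in [0, 1], got {risk}")
    if risk <= GREEN_MAX:
        return GREEN
    if risk <= ORANGE_MAX:
        return ORANGE
    return RED


def pta_curve(risk_fn: RiskFn, mic_grid: Sequence[float] = DEFAULT_MIC_GRID) -> dict:
    """Evaluate a bound risk function over a MIC grid; returns {mic: risk}.

    ``risk_fn`` is a single-argument callable mic -> risk, typically the
    regression or PK engine bound to one patient.
    """
    mic_grid = list(mic_grid)
    if not mic_grid:
        raise ValidationError("mic_grid must be non-empty")
    if any(m <= 0 for m in mic_grid):
        raise ValidationError("mic_grid values must be > 0")
    curve = {float(m): float(risk_fn(m)) for m in mic_grid}
    risks = list(curve.values())
    if any(b < a - 1e-9 for a, b in zip(risks, risks[1:])):
        log.warning("risk curve is not non-decreasing in MIC (Monte-Carlo noise?)")
    return curve


def cfr_risk(
    pta_risks: Mapping[float, float],
    dist: MICDistribution,
    risk_fn: Optional[RiskFn] = None,
) -> float:
    """Risk of non-attainment against a whole MIC distribution (1 - CFR).

    Weighted average of per-MIC risks with the distribution's normalized
    frequencies. Bins absent from ``pta_risks`` are evaluated exactly at
    the bin MIC via ``risk_fn`` (no grid interpolation); without a
    ``risk_fn`` an uncovered bin is an error.
    """
    freqs = dist.frequencies
    total = 0.0
    for (mic, _), f in zip(dist.bins, freqs):
        if mic in pta_risks:
            r = pta_risks[mic]
        elif risk_fn is not None:
            r = float(risk_fn(mic))
        else:
            raise ValidationError(
                f"{dist.pathogen}: no risk value for MIC bin {mic} mg/L and no "
                "risk_fn to evaluate it"
            )
        total += f * r
    return float(total)


def breakpoint_risk(risk_fn: RiskFn, breakpoint_mic: float) -> float:
    """Single-MIC risk at a user-chosen (e.g. EUCAST S) breakpoint."""
    if breakpoint_mic <= 0:
        raise ValidationError(f"breakpoint_mic must be > 0, got {breakpoint_mic}")
    return float(risk_fn(breakpoint_mic))


def _disclaimer_flags(clcr: float, contributing_mics: Sequence[float]) -> list:
    """Low renal function combined with high MIC voids the regression engine."""
    flags = []
    if clcr < DISCLAIMER_CLCR and any(m >= DISCLAIMER_MIC for m in contributing_mics):
        flags.append("clcr_below_50_with_high_mic")
    return flags


def assess(
    patient: Patient,
    risk_fn: RiskFn,
    mic: Optional[float] = None,
    pathogen: Optional[str] = None,
    breakpoint_mic: Optional[float] = None,
    distributions: Optional[Mapping[str, MICDistribution]] = None,
    clcr_range: tuple = (25.0, 255.0),
) -> RiskResult:
    """Resolve the risk-input mode and produce a classified RiskResult.

    Mode precedence when several inputs are given: mic > pathogen >
    breakpoint. Refuses patients with CLCR outside the applicability range
    and flags the combination (CLCR < 50 mL/min, any contributing
    MIC >= 8 mg/L) for which the regression engine is known to
    underestimate risk.
    """
    clcr = patient.resolve_clcr()
    lo, hi = clcr_range
    if not lo <= clcr <= hi:
        raise ApplicabilityError(
            f"clcr {clcr:g} mL/min outside the applicability range {lo:g}-{hi:g} mL/min"
        )
    echo: dict = {"patient_id": patient.id, "clcr_ml_min": clcr}

    if mic is not None:
        if mic <= 0:
            raise ValidationError(f"mic must be > 0, got {mic}")
        risk = float(risk_fn(mic))
        mode = "mic"
        echo["mic_mg_l"] = mic
        mics = [mic]
    elif pathogen is not None:
        if not distributions or pathogen not in distributions:
            raise ValidationError(f"no MIC distribution available for {pathogen!r}")
        dist = distributions[pathogen]
        risk = cfr_risk({}, dist, risk_fn=risk_fn)
        mode = "pathogen_cfr"
        echo["pathogen"] = pathogen
        echo["mic_source"] = dist.source_label
        mics = [m for (m, _), f in zip(dist.bins, dist.frequencies) if f > 0]
    elif breakpoint_mic is not None:
        risk = breakpoint_risk(risk_fn, breakpoint_mic)
        mode = "breakpoint"
        echo["breakpoint_mg_l"] = breakpoint_mic
        mics = [breakpoint_mic]
    else:
        raise ValidationError(
            "no resolvable risk mode: provide mic, pathogen, or breakpoint_mic"
        )

    return RiskResult(
        risk=risk,
        mode=mode,
        category=classify_risk(min(max(risk, 0.0), 1.0)),
        inputs_echo=echo,
        disclaimer_flags=_disclaimer_flags(clcr, mics),
    )


def cohort_band(median_risk: float) -> str:
    """Cohort-summary banding with strict boundaries: <10%, 10-50%, >50%.

    This is the rule used for summarising pathogens over a cohort; it
    differs at the boundaries from the per-patient traffic light
    (:func:`classify_risk`), which is boundary-inclusive (green <= 10%).
    """
    if median_risk < 0.10:
        return "below_10"
    if median_risk <= 0.50:
        return "10_to_50"
    return "above_50"


def cohort_pathogen_summary(
    patients: Sequence[Patient],
    distributions: Mapping[str, MICDistribution],
    risk_fn_factory: Callable[[Patient], RiskFn],
) -> tuple[pd.DataFrame, dict]:
    """Median per-pathogen cohort risk and the fraction of pathogens per band.

    For each pathogen, the CFR-based risk of non-attainment is computed for
    every patient and summarised by the cohort median; pathogens are then
    banded (<10%, 10-50%, >50%). Returns (per-pathogen table, band
    fractions summing to 1).
    """
    if not patients:
        raise ValidationError("need at least one patient")
    if not distributions:
        raise ValidationError("need at least one MIC distribution")
    rows = []
    risk_fns = [risk_fn_factory(p) for p in patients]
    for name, dist in distributions.items():
        risks = [cfr_risk({}, dist, risk_fn=fn) for fn in risk_fns]
        med = float(np.median(risks))
        rows.append({
            "pathogen": name,
            "median_risk": med,
            "band": cohort_band(med),
            "n_patients": len(patients),
            "source_label": dist.source_label,
        })
    table = pd.DataFrame(rows)
    fractions = {
        band: float((table["band"] == band).mean())
        for band in ("below_10", "10_to_50", "above_50")
    }
    return table, fractions
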