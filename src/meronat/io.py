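"""Configuration and tabular file I/O.

Config is JSON (validated into typed model objects); all tabular exchange
is CSV with a provenance header block (lines starting ``#``: config hash,
seed, tool version, source labels) so every output file records how it was
produced. Timestamps are deliberately excluded to keep reruns
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .evaluation import TDMObservation
from .patients import Patient
from .poppk import DosingRegimen, PopPKModel
from .regression_risk import RegressionRiskModel
from .risk_cfr import DEFAULT_MIC_GRID, MICDistribution

log = logging.getLogger(__name__)

_PATIENT_COLUMNS = ["id", "sex", "age_years", "weight_kg", "scr_mg_dl",
                    "albumin_g_dl", "rrt", "clcr_ml_min"]
_PATIENT_MANDATORY = ["id", "sex", "age_years", "weight_kg", "scr_mg_dl", "albumin_g_dl"]
_TDM_COLUMNS = ["patient_id", "dose_mg", "tinf_h", "dose_time_h",
                "sample_time_h", "conc_mg_l"]
_MIC_COLUMNS = ["pathogen", "mic_mg_l", "count"]


@dataclass
class ToolConfig:
    """Everything the tool needs to run: models, regimen, thresholds, flags."""

    regression: RegressionRiskModel = None
    pk: PopPKModel = field(default_factory=PopPKModel)
    regimen: DosingRegimen = field(default_factory=DosingRegimen)
    mic_grid: tuple = DEFAULT_MIC_GRID
    green_max: float = 0.10
    orange_max: float = 0.50
    unbound_fraction: float = 1.0
    pe_sign_convention: str = "predicted_minus_observed"
    gaussian_approx: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.green_max <= self.orange_max < 1:
            raise ValidationError(
                f"risk thresholds must satisfy 0 < green <= orange < 1, got "
                f"({self.green_max}, {self.orange_max})"
            )
        grid = list(self.mic_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError("mic_grid must be strictly increasing")
        self.mic_grid = tuple(float(m) for m in grid)

    def config_hash(self) -> str:
        payload = {
            "regression": self.regression.__dict__ if self.regression else None,
            "pk": self.pk.__dict__,
            "regimen": self.regimen.__dict__,
            "mic_grid": list(self.mic_grid),
            "green_max": self.green_max,
            "orange_max": self.orange_max,
            "unbound_fraction": self.unbound_fraction,
            "pe_sign_convention": self.pe_sign_convention,
            "gaussian_approx": self.gaussian_approx,
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return digest[:12]


def _default_config_dict() -> dict:
    with resources.files("meronat.data").joinpath("default_config.json").open() as fh:
        return json.load(fh)


def load_config(path: Optional[str | Path] = None, seed: Optional[int] = None) -> ToolConfig:
    """Load the packaged default config, optionally overlaid by a user JSON.

    User files only need the keys they change; nested sections
    (``regression``, ``pk``, ``regimen``) are merged key-by-key.
    """
    raw = _default_config_dict()
    if path is not None:
        with open(path) as fh:
            user = json.load(fh)
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(raw.get(key), dict):
                raw[key].update(value)
            else:
                raw[key] = value
    reg = raw["regression"]
    cfg = ToolConfig(
        regression=RegressionRiskModel(
            intercept=reg["intercept"],
            slope=reg["slope"],
            residual_sd=reg["residual_sd"],
            n_train=reg["n_train"],
            mean_ln_x=reg["mean_ln_x"],
            sxx=reg["sxx"],
            clcr_range=(reg.get("clcr_min", 25.0), reg.get("clcr_max", 255.0)),
            gaussian_approx=raw.get("gaussian_approx", False),
        ),
        pk=PopPKModel(**raw["pk"]),
        regimen=DosingRegimen(**raw["regimen"]),
        mic_grid=tuple(raw.get("mic_grid", DEFAULT_MIC_GRID)),
        green_max=raw.get("green_max", 0.10),
        orange_max=raw.get("orange_max", 0.50),
        unbound_fraction=raw.get("unbound_fraction", 1.0),
        pe_sign_convention=raw.get("pe_sign_convention", "predicted_minus_observed"),
        gaussian_approx=raw.get("gaussian_approx", False),
        seed=raw.get("seed", 0),
    )
    if seed is not None:
        cfg.seed = seed
    return cfg


# ---------------------------------------------------------------------------
# provenance-stamped CSV
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, meta: Optional[Mapping] = None) -> None:
    """Write a CSV with a ``#``-prefixed provenance header block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# tool_version: {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def _read_table(path: str | Path, mandatory: Sequence[str],
                known: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {missing}")
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.warning("%s: ignoring unknown columns %s", path, unknown)
    return df


def read_header_meta(path: str | Path) -> dict:
    """Parse the ``# key: value`` provenance block of one of our CSV files."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def _opt(row, col):
    v = row.get(col, np.nan)
    return None if pd.isna(v) else float(v)


def read_patients_csv(path: str | Path) -> list[Patient]:
    df = _read_table(path, _PATIENT_MANDATORY, _PATIENT_COLUMNS)
    patients = []
    for _, row in df.iterrows():
        sex = None if pd.isna(row["sex"]) else str(row["sex"]).strip().lower()
        if sex in ("m", "f"):
            sex = {"m": "male", "f": "female"}[sex]
        rrt = False
        if "rrt" in df.columns and not pd.isna(row["rrt"]):
            rrt = str(row["rrt"]).strip().lower() in ("1", "true", "yes", "y")
        patients.append(Patient(
            id=str(row["id"]),
            sex=sex,
            age=_opt(row, "age_years"),
            weight=_opt(row, "weight_kg"),
            serum_creatinine=_opt(row, "scr_mg_dl"),
            serum_albumin=_opt(row, "albumin_g_dl"),
            rrt=rrt,
            clcr=_opt(row, "clcr_ml_min"),
        ))
    return patients


def write_patients_csv(patients: Sequence[Patient], path: str | Path,
                       meta: Optional[Mapping] = None) -> None:
    df = pd.DataFrame([{
        "id": p.id,
        "sex": p.sex,
        "age_years": p.age,
        "weight_kg": p.weight,
        "scr_mg_dl": p.serum_creatinine,
        "albumin_g_dl": p.serum_albumin,
        "rrt": int(p.rrt),
        "clcr_ml_min": p.clcr,
    } for p in patients])
    write_table(df, path, meta)


def read_tdm_csv(path: str | Path) -> list[TDMObservation]:
    """Read dose-event and sample rows into observations.

    Rows with dose columns define the patient's dose history; rows with
    sample columns define observations (a row may carry both). Every
    observation receives the patient's full dose history.
    """
    df = _read_table(path, ["patient_id"], _TDM_COLUMNS)
    observations = []
    errors = []
    for pid, group in df.groupby("patient_id", sort=False):
        doses = group.dropna(subset=["dose_mg", "tinf_h", "dose_time_h"])
        history = sorted(
            {(float(r.dose_mg), float(r.tinf_h), float(r.dose_time_h))
             for r in doses.itertuples()},
            key=lambda d: d[2],
        )
        samples = group.dropna(subset=["sample_time_h", "conc_mg_l"])
        for i, r in enumerate(samples.itertuples()):
            try:
                observations.append(TDMObservation(
                    patient_id=str(pid),
                    dose_history=history,
                    sample_time=float(r.sample_time_h),
                    concentration=float(r.conc_mg_l),
                ))
            except ValidationError as exc:
                errors.append(f"patient {pid} sample {i}: {exc}")
    if errors:
        raise ValidationError(f"{path}: invalid rows:\n" + "\n".join(errors))
    return observations


def write_tdm_csv(observations: Sequence[TDMObservation], path: str | Path,
                  meta: Optional[Mapping] = None) -> None:
    rows = []
    seen: set = set()
    for obs in observations:
        for dose, tinf, start in obs.dose_history:
            key = (obs.patient_id, dose, tinf, start)
            if key not in seen:
                seen.add(key)
                rows.append({"patient_id": obs.patient_id, "dose_mg": dose,
                             "tinf_h": tinf, "dose_time_h": start,
                             "sample_time_h": np.nan, "conc_mg_l": np.nan})
        rows.append({"patient_id": obs.patient_id, "dose_mg": np.nan,
                     "tinf_h": np.nan, "dose_time_h": np.nan,
                     "sample_time_h": obs.sample_time,
                     "conc_mg_l": obs.concentration})
    write_table(pd.DataFrame(rows), path, meta)


def read_mic_distributions_csv(
    path: str | Path, source_label: Optional[str] = None
) -> dict[str, MICDistribution]:
    """Read one file holding MIC frequency tables for many pathogens.

    The source label is taken from the file's provenance header
    (``# source_label: ...``) unless given explicitly.
    """
    if source_label is None:
        source_label = read_header_meta(path).get("source_label", str(path))
    df = _read_table(path, _MIC_COLUMNS, _MIC_COLUMNS)
    out = {}
    for pathogen, group in df.groupby("pathogen", sort=False):
        bins = sorted(
            (float(r.mic_mg_l), int(r.count)) for r in group.itertuples()
        )
        out[str(pathogen)] = MICDistribution(str(pathogen), bins, source_label)
    return out


def write_mic_distributions_csv(
    distributions: Mapping[str, MICDistribution], path: str | Path,
    meta: Optional[Mapping] = None,
) -> None:
    rows = [
        {"pathogen": d.pathogen, "mic_mg_l": mic, "count": count}
        for d in distributions.values() for mic, count in d.bins
    ]
    labels = {d.source_label for d in distributions.values()}
    meta = dict(meta or {})
    meta.setdefault("source_label", "; ".join(sorted(labels)))
    write_table(pd.DataFrame(rows), path, meta)


def read_breakpoints_csv(path: str | Path) -> dict[str, float]:
    df = _read_table(path, ["pathogen", "s_breakpoint_mg_l"],
                     ["pathogen", "s_breakpoint_mg_l"])
    return {str(r.pathogen): float(r.s_breakpoint_mg_l) for r in df.itertuples()}
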