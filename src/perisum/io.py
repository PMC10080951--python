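"""Tables, configuration, fixtures and the end-to-end pipeline.

Threshold tables are comma-delimited UTF-8 with header; sensitivities
may be given in perimetric dB or as DLS (dB/10) and are normalised to
dB on read.  The seeded fixture generator emulates the experimental
design of the summation study: 12 diagonal locations, Goldmann sizes
I-V everywhere at 200 ms, five durations (15-200 ms) at the outer ring,
model-generated thresholds plus Gaussian test-retest noise, and
MOCS-style trial tables produced by synthetic observers for the four
extreme size/duration combinations.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .mosaic import ConvergenceProfile, convergence_ratio, read_density_table
from .optics import OpticsParams
from .pooling import RetinalContext, UniformContext
from .psychophysics import MOCS_REPEATS, mocs_design, p_seen, synthetic_observer
from .summation import (
    SpatiotemporalParams,
    SpatiotemporalSummationModel,
    predicted_dls,
)

__all__ = [
    "GOLDMANN_DIAMETERS_DEG",
    "goldmann_area_deg2",
    "default_density_profile",
    "context_for_eccentricity",
    "read_thresholds",
    "write_thresholds",
    "FixtureSpec",
    "generate_fixture",
    "default_config",
    "load_config",
    "validate_config",
    "run_pipeline",
]

#: Goldmann stimulus diameters, deg (each size has 4x the previous area)
GOLDMANN_DIAMETERS_DEG = {"I": 0.10, "II": 0.21, "III": 0.43, "IV": 0.86, "V": 1.72}

STANDARD_DURATIONS_MS = (15.0, 30.0, 55.0, 105.0, 200.0)
STANDARD_LOCATIONS = tuple(
    (sx * d, sy * d) for d in (7.0, 4.0, 1.0) for sx in (1, -1) for sy in (1, -1)
)
FOS_COMBINATIONS = (("I", 15.0), ("I", 200.0), ("V", 15.0), ("V", 200.0))


def goldmann_area_deg2(label: str) -> float:
    return float(np.pi * (GOLDMANN_DIAMETERS_DEG[label] / 2.0) ** 2)


def default_density_profile() -> ConvergenceProfile:
    """Synthetic parafoveal P-OFF-RGC-RF / cone density profile.

    Representative macular values: RGC-RF density falls steeply with
    eccentricity while cone/RGC convergence rises from ~7 to ~9 over the
    central 10 deg.  Interpolated log-linearly between anchors; users
    with imaging-derived estimates should supply their own table.
    """
    return ConvergenceProfile(
        eccentricity=np.array([1.414, 5.657, 9.899]),
        rgc_density=np.array([449.7, 121.4, 63.7]),
        cone_density=np.array([3206.0, 923.0, 583.0]),
    )


def context_for_eccentricity(
    ecc: float,
    profile: ConvergenceProfile | None = None,
    optics: OpticsParams | None = None,
    mode: str = "signed",
    uniform: bool = True,
):
    """Retinal context at an eccentricity (uniform-map or full-mosaic)."""
    profile = profile or default_density_profile()
    dens = profile.rgc_density_at(ecc)
    c = convergence_ratio(profile, ecc)
    if uniform:
        return UniformContext(rgc_density=dens, convergence=c)
    return RetinalContext(
        rgc_density=dens,
        convergence=c,
        optics=optics or OpticsParams(enabled=False),
        mode=mode,
        eccentricity=ecc,
    )


# ---------------------------------------------------------------------------
# threshold tables
# ---------------------------------------------------------------------------

_THRESHOLD_KEY = ["x_deg", "y_deg", "diameter_deg", "duration_ms"]


def read_thresholds(path) -> pd.DataFrame:
    """Read a threshold table; returns columns x_deg, y_deg, diameter_deg,
    duration_ms, db (perimetric dB).

    Accepts either a ``db`` or a ``dls`` sensitivity column (DLS is
    converted as dB = 10 x DLS) and either ``diameter_deg`` or a Goldmann
    ``size_label`` column.  Malformed rows raise with their line number.
    """
    df = pd.read_csv(path)
    if "diameter_deg" not in df.columns:
        if "size_label" in df.columns:
            bad = ~df["size_label"].astype(str).isin(GOLDMANN_DIAMETERS_DEG)
            if bad.any():
                row = int(df.index[bad][0]) + 2  # header + 1-based
                raise ValueError(f"unknown Goldmann size label at line {row}")
            df["diameter_deg"] = df["size_label"].map(GOLDMANN_DIAMETERS_DEG)
        else:
            raise ValueError("threshold table needs a 'diameter_deg' or 'size_label' column")
    if "db" not in df.columns:
        if "dls" in df.columns:
            df["db"] = 10.0 * df["dls"]
        else:
            raise ValueError("threshold table needs a 'db' or 'dls' column")
    missing = [c for c in _THRESHOLD_KEY if c not in df.columns]
    if missing:
        raise ValueError(f"threshold table missing columns: {missing}")
    for col in _THRESHOLD_KEY + ["db"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2
            raise ValueError(f"non-numeric value in column {col!r} at line {row}")
        df[col] = vals
    key_cols = _THRESHOLD_KEY + (["repeat"] if "repeat" in df.columns else [])
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(f"duplicate (location, size, duration) key at line {row}")
    return df


def write_thresholds(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Study-design fixture: the experimental grid plus generating truth.

    Defaults reproduce the summation study's design (12 diagonal
    locations; durations beyond 200 ms only at the {+-7, +-7} ring; four
    retested FOS combinations) with per-eccentricity integration
    constants and offsets at representative median values and ~1 dB
    test-retest noise.
    """

    # convergence-weighted integration constants and offsets (the default
    # contexts weight each RGC by its cone/RGC convergence ratio)
    tau_by_ecc: dict = field(default_factory=lambda: {1.414: 8625.0, 5.657: 7128.0, 9.899: 5789.0})
    offset_by_ecc: dict = field(default_factory=lambda: {1.414: 2.31, 5.657: 2.42, 9.899: 2.40})
    k: float = 4.0
    sizes: tuple = tuple(GOLDMANN_DIAMETERS_DEG)
    durations_ms: tuple = STANDARD_DURATIONS_MS
    locations: tuple = STANDARD_LOCATIONS
    noise_sd_db: float = 1.0
    seed: int = 0
    profile: ConvergenceProfile | None = None
    uniform_context: bool = True

    def contexts(self) -> dict:
        eccs = sorted({round(float(np.hypot(x, y)), 3) for x, y in self.locations})
        return {
            e: context_for_eccentricity(e, self.profile, uniform=self.uniform_context)
            for e in eccs
        }


def _thread_grid(spec: FixtureSpec):
    """The 140 independent strategy threads of the default design."""
    outer = max(round(float(np.hypot(x, y)), 3) for x, y in spec.locations)
    for (x, y) in spec.locations:
        ecc = round(float(np.hypot(x, y)), 3)
        for label in spec.sizes:
            durations = spec.durations_ms if ecc == outer else (200.0,)
            for T in durations:
                yield (x, y, ecc, label, T)


def generate_fixture(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model-generated threshold and MOCS trial tables, fully seeded.

    Thresholds are the model's predicted sensitivities plus Gaussian
    test-retest noise.  Trials implement the two-stage FOS protocol for
    the four extreme size/duration combinations at the outer ring:
    levels from :func:`mocs_design` on the true observer parameters,
    25 repeats per level, responses drawn from the observer's FOS curve.
    """
    rng = np.random.default_rng(spec.seed)
    contexts = spec.contexts()
    rows = []
    for (x, y, ecc, label, T) in _thread_grid(spec):
        params = SpatiotemporalParams(
            tau=spec.tau_by_ecc[ecc], k=spec.k, offset=spec.offset_by_ecc[ecc]
        )
        area = goldmann_area_deg2(label)
        s = contexts[ecc].area_to_input(area)
        db_true = 10.0 * predicted_dls(s, T, params)
        db_obs = db_true + (rng.normal(0.0, spec.noise_sd_db) if spec.noise_sd_db > 0 else 0.0)
        rows.append(
            dict(x_deg=x, y_deg=y, size_label=label,
                 diameter_deg=GOLDMANN_DIAMETERS_DEG[label], duration_ms=T,
                 db=db_obs, db_true=db_true)
        )
    thresholds = pd.DataFrame(rows)

    outer = max(round(float(np.hypot(x, y)), 3) for x, y in spec.locations)
    trial_rows = []
    for (x, y) in spec.locations:
        ecc = round(float(np.hypot(x, y)), 3)
        if ecc != outer:
            continue
        params = SpatiotemporalParams(
            tau=spec.tau_by_ecc[ecc], k=spec.k, offset=spec.offset_by_ecc[ecc]
        )
        for label, T in FOS_COMBINATIONS:
            obs = synthetic_observer(
                params, contexts[ecc], GOLDMANN_DIAMETERS_DEG[label], T,
                lapse_rate=0.01, guess_rate=0.01,
            )
            levels = mocs_design(obs.mu, float(np.clip(obs.sigma, 1.0, 10.0)))
            for level in levels:
                seen = rng.random(MOCS_REPEATS) < p_seen(level, obs)
                for s_flag in seen:
                    trial_rows.append(
                        dict(x_deg=x, y_deg=y, size_label=label, duration_ms=T,
                             stimulus_db=float(level), seen=int(s_flag))
                    )
    trials = pd.DataFrame(trial_rows)
    return thresholds, trials


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    return {
        "seed": 1,
        "mosaic": {"density_table": None},
        "optics": {
            "enabled": False,
            "pupil_mm": 3.0,
            "age": 30.0,
            "pigmentation": "medium",
            "wavelength_nm": 555.0,
        },
        "model": {"k": 4.0, "tau_init": 1000.0},
        "fixture": {"noise_sd_db": 1.0, "uniform_context": True},
        "strategy": {
            "zest": {"stop_sd": 1.5, "likelihood_sd": 1.0, "rate": 0.03},
            "questplus": {"stop_entropy": 4.5, "sigma_min": 1.0, "sigma_max": 10.0},
        },
        "output": {"report": "report.json"},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = default_config()
    for section, value in cfg.items():
        if isinstance(value, dict) and isinstance(merged.get(section), dict):
            merged[section].update(value)
        else:
            merged[section] = value
    return merged


def validate_config(cfg: dict) -> list[str]:
    """Range and consistency checks; returns a list of error strings."""
    errors = []
    model = cfg.get("model", {})
    if model.get("k", 4.0) < 1:
        errors.append(f"model.k must be >= 1, got {model.get('k')}")
    if model.get("tau_init", 1.0) <= 0:
        errors.append("model.tau_init must be positive")
    optics = cfg.get("optics", {})
    pupil = optics.get("pupil_mm", 3.0)
    if not 1.0 < pupil < 9.0:
        errors.append(f"optics.pupil_mm must be in (1, 9), got {pupil}")
    if optics.get("pigmentation", "medium") not in ("light", "medium", "dark"):
        errors.append(f"optics.pigmentation invalid: {optics.get('pigmentation')!r}")
    strat = cfg.get("strategy", {})
    rate = strat.get("zest", {}).get("rate", 0.03)
    if not 0 <= rate < 0.5:
        errors.append(f"strategy.zest.rate must be in [0, 0.5), got {rate}")
    fix = cfg.get("fixture", {})
    if fix.get("noise_sd_db", 1.0) < 0:
        errors.append("fixture.noise_sd_db must be non-negative")
    table = cfg.get("mosaic", {}).get("density_table")
    if table is not None:
        try:
            prof = read_density_table(table)
            if np.any(np.asarray(prof.rgc_density) <= 0) or np.any(np.asarray(prof.cone_density) <= 0):
                errors.append("mosaic.density_table: densities must be positive")
        except Exception as exc:  # noqa: BLE001 - report as config error
            errors.append(f"mosaic.density_table: {exc}")
    return errors


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict, out_path=None) -> dict:
    """Fixture -> per-eccentricity fit -> Ricco-area report.

    Deterministic given the config seed; each stage is logged with its
    parameters and wall-clock duration.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    logs = []

    def stage(name, **kw):
        logs.append({"stage": name, "elapsed_s": round(time.time() - t0, 3), **kw})

    t0 = time.time()
    seed = int(cfg.get("seed", 1))
    profile = (
        read_density_table(cfg["mosaic"]["density_table"])
        if cfg.get("mosaic", {}).get("density_table")
        else None
    )
    spec = FixtureSpec(
        noise_sd_db=float(cfg["fixture"]["noise_sd_db"]),
        seed=seed,
        profile=profile,
        uniform_context=bool(cfg["fixture"].get("uniform_context", True)),
        k=float(cfg["model"]["k"]),
    )
    thresholds, trials = generate_fixture(spec)
    stage("fixture", n_thresholds=len(thresholds), n_trials=len(trials), seed=seed)

    contexts = spec.contexts()
    report = {"seed": seed, "eccentricities": {}}
    for ecc, ctx in contexts.items():
        t0 = time.time()
        grp = thresholds[np.hypot(thresholds.x_deg, thresholds.y_deg).round(3) == ecc]
        model = SpatiotemporalSummationModel.from_dataframe(grp, ctx, k=spec.k)
        res = model.fit()
        ricco = {
            f"{int(T)}ms": res.ricco_area(T, ctx)
            for T in sorted(grp.duration_ms.unique())
        }
        report["eccentricities"][str(ecc)] = {
            "tau_input_ms": res.tau,
            "offset_dls": res.offset,
            "rmse_db": res.rmse_db,
            "n_obs": res.nobs,
            "ricco_area_deg2_by_duration": ricco,
            "critical_input_rgc_200ms": res.critical_input(200.0).S_c,
        }
        stage("fit", eccentricity=ecc, tau=res.tau, rmse_db=res.rmse_db)

    report["logs"] = logs
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
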