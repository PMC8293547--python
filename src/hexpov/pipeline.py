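"""End-to-end study orchestration.

Runs the full analysis at desk scale: simulate (or ingest) household
microdata, regional indicators and spatial weights; compute regional
HFGT profiles under a primary and an alternative poverty line; test
global spatial autocorrelation of breadth, depth and strength; run the
local (LISA) analysis on breadth when the global test is significant;
screen collinearity; fit lasso, ridge and elastic-net models of breadth
on the indicators with cross-validated penalty selection; and compare
the selected supports across poverty lines as a robustness check.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .poverty import (PovertyLine, adjust_poverty_line, clean_records,
                      regional_profiles, HOUSEHOLD_COLUMNS)
from .regnet import (compare_supports, cross_validate, standardize, vif)
from .spatial import (SpatialWeights, classify_lisa, global_morans_i,
                      local_morans_i, read_edgelist_csv, read_gal,
                      row_standardize, write_gal)
from .synth import (N_INDICATORS, SyntheticScenario, generate_households,
                    generate_lattice_weights, generate_regional_indicators)

__all__ = ["RunConfig", "StudyReport", "run_study", "read_inputs", "write_report"]

logger = logging.getLogger(__name__)

INDICATOR_COLUMNS = tuple(f"X{j + 1}" for j in range(N_INDICATORS))


@dataclass
class RunConfig:
    """Everything needed to reproduce one study run."""

    mode: str = "simulate"                       # "simulate" | "ingest"
    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)
    households_path: str | None = None
    indicators_path: str | None = None
    weights_path: str | None = None
    poverty_line: float = 2300.0
    poverty_line_label: str = "baseline"
    # the alternative line: explicit value, or a CPI chain applied to the
    # primary line (alt_cpi_chain wins when both are given)
    alt_poverty_line: float | None = None
    alt_cpi_chain: tuple = ()
    weights_scheme: str = "queen"
    n_perm: int = 999
    significance_level: float = 0.05
    spatial_seed: int = 0
    lisa_gating: bool = True
    reg_alpha: float = 0.5
    k_folds: int = 10
    n_lambda: int = 100
    lambda_ratio: float = 1e-4
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"mode must be 'simulate' or 'ingest', got {self.mode!r}")
        if self.mode == "ingest":
            for nm in ("households_path", "indicators_path", "weights_path"):
                p = getattr(self, nm)
                if p is None or not Path(p).exists():
                    raise ValueError(f"ingest mode requires existing {nm}, got {p}")

    def alternative_line(self) -> PovertyLine:
        base = PovertyLine(self.poverty_line, self.poverty_line_label)
        if self.alt_cpi_chain:
            return adjust_poverty_line(base, list(self.alt_cpi_chain))
        if self.alt_poverty_line is not None:
            return PovertyLine(self.alt_poverty_line, "alternative")
        # default robustness perturbation: the CPI-chained line ratio used
        # for the 2011->2018 update of the RMB 2300 standard
        return PovertyLine(self.poverty_line * 2648.56 / 2300.0, "cpi-chained")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["beta_true"] = self.scenario.beta_true.tolist()
        d["alt_cpi_chain"] = list(self.alt_cpi_chain)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scen = raw.pop("scenario", None)
        if scen is not None:
            if "lattice_dims" in scen:
                scen["lattice_dims"] = tuple(scen["lattice_dims"])
            if "income_lognormal_params" in scen:
                scen["income_lognormal_params"] = tuple(scen["income_lognormal_params"])
            if "beta_true" in scen:
                scen["beta_true"] = np.asarray(scen["beta_true"], dtype=float)
            if "indicator_corr_blocks" in scen:
                scen["indicator_corr_blocks"] = tuple(
                    tuple(b) for b in scen["indicator_corr_blocks"])
            raw["scenario"] = SyntheticScenario(**scen)
        if "alt_cpi_chain" in raw:
            raw["alt_cpi_chain"] = tuple(raw["alt_cpi_chain"])
        return cls(**raw)


@dataclass
class StudyReport:
    """Structured result of one full run; serializable to JSON + CSVs."""

    config: dict
    config_hash: str
    version: str
    cleaning: dict
    poverty_lines: dict                      # label -> z
    profiles: dict                           # label -> DataFrame
    pooled: dict                             # label -> {breadth, depth, strength}
    moran: dict                              # index name -> result dict
    lisa_ran: bool
    lisa: pd.DataFrame | None
    collinearity: pd.DataFrame
    fits: dict                               # model name -> summary dict
    cv_curves: dict                          # model name -> DataFrame
    robustness: dict

    def to_jsonable(self) -> dict:
        return {
            "config": _jsonable(self.config),
            "config_hash": self.config_hash,
            "version": self.version,
            "cleaning": _jsonable(self.cleaning),
            "poverty_lines": self.poverty_lines,
            "profiles": {k: v.to_dict("records") for k, v in self.profiles.items()},
            "pooled": _jsonable(self.pooled),
            "moran": _jsonable(self.moran),
            "lisa_ran": self.lisa_ran,
            "lisa": None if self.lisa is None else self.lisa.to_dict("records"),
            "collinearity": self.collinearity.to_dict("records"),
            "fits": _jsonable(self.fits),
            "robustness": _jsonable(self.robustness),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_inputs(households_path, indicators_path, weights_path):
    """Load and schema-validate the three study inputs.

    Weights are read from GAL-dialect text (``.gal``) or an edge-list CSV,
    with the indicator table fixing the region order.
    """
    households = pd.read_csv(households_path)
    missing = [c for c in HOUSEHOLD_COLUMNS if c not in households.columns]
    if missing:
        raise ValueError(f"household table missing columns: {missing}")
    indicators = pd.read_csv(indicators_path)
    missing = [c for c in ("region_id",) + INDICATOR_COLUMNS
               if c not in indicators.columns]
    if missing:
        raise ValueError(f"indicator table missing columns: {missing}")
    wp = Path(weights_path)
    if wp.suffix.lower() == ".gal":
        weights = read_gal(wp)
    else:
        weights = read_edgelist_csv(wp, region_ids=indicators["region_id"].astype(str))
    if weights.n != len(indicators):
        raise ValueError(f"weights cover {weights.n} regions but indicator "
                         f"table has {len(indicators)}")
    logger.info("loaded %d households, %d regions", len(households), len(indicators))
    return households, indicators, weights


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_study(config: RunConfig) -> StudyReport:
    """Execute every stage and assemble the report.

    Stage order: simulate/ingest -> clean -> regional profiles under both
    poverty lines -> global Moran's I on breadth/depth/strength -> LISA on
    breadth (gated on the global breadth test when ``lisa_gating``) ->
    collinearity diagnostics -> lasso / ridge / elastic-net CV fits ->
    support comparison across poverty lines. Any stage error aborts with
    the stage name attached (:class:`StageError`).
    """
    stage = "init"

    def _stage(name: str) -> float:
        nonlocal stage
        stage = name
        logger.info("stage: %s", name)
        return time.perf_counter()

    try:
        return _run_study_stages(config, _stage)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def _run_study_stages(config: RunConfig, _stage) -> StudyReport:
    truth = None
    if config.mode == "simulate":
        t0 = _stage("simulate")
        scen = config.scenario
        rows, cols = scen.lattice_dims
        weights = generate_lattice_weights(rows, cols, config.weights_scheme)
        indicators = generate_regional_indicators(scen)
        households, truth = generate_households(scen, indicators, weights)
    else:
        t0 = _stage("ingest")
        households, indicators, weights = read_inputs(
            config.households_path, config.indicators_path, config.weights_path)

    _stage("clean")
    clean, report_clean = clean_records(households)

    _stage("profiles")
    primary = PovertyLine(config.poverty_line, config.poverty_line_label)
    alt = config.alternative_line()
    lines = {"primary": primary, "alternative": alt}
    profiles = {}
    pooled = {}
    for label, line in lines.items():
        prof = regional_profiles(clean, line)
        profiles[label] = prof
        w = prof["n"] / prof["n"].sum()
        pooled[label] = {
            "breadth": float((w * prof["breadth"]).sum()),
            "depth": float((w * prof["depth"]).sum()),
            "strength": float((w * prof["strength"]).sum()),
            "q_total": int(prof["q"].sum()),
            "n_total": int(prof["n"].sum()),
        }

    _stage("moran")
    Wrs = row_standardize(weights)
    prof = profiles["primary"].set_index("region_id")
    region_order = [str(r) for r in Wrs.region_ids]
    missing_regions = [r for r in region_order if r not in prof.index.astype(str)]
    if missing_regions:
        raise ValueError(f"regions with no surviving households: {missing_regions}")
    prof = prof.loc[[r for r in region_order]]
    moran = {}
    for index_name in ("breadth", "depth", "strength"):
        res = global_morans_i(prof[index_name].to_numpy(), Wrs,
                              n_perm=config.n_perm, seed=config.spatial_seed)
        moran[index_name] = dataclasses.asdict(res)

    lisa_df = None
    breadth_sig = moran["breadth"]["p_perm"] < config.significance_level
    lisa_ran = breadth_sig or not config.lisa_gating
    if lisa_ran:
        _stage("lisa")
        lisa = local_morans_i(prof["breadth"].to_numpy(), Wrs,
                              n_perm=config.n_perm, seed=config.spatial_seed,
                              level=config.significance_level)
        lisa_df = classify_lisa(lisa, level=config.significance_level)
    else:
        logger.info("stage: lisa skipped (global breadth test not significant)")

    _stage("vif")
    Xraw = indicators.set_index("region_id").loc[region_order, list(INDICATOR_COLUMNS)]
    collin = vif(Xraw.to_numpy(), list(INDICATOR_COLUMNS))

    _stage("fit")
    fits, cv_curves = {}, {}
    for label, y in (("primary", profiles["primary"].set_index("region_id")
                      .loc[region_order, "breadth"]),
                     ("alternative", profiles["alternative"].set_index("region_id")
                      .loc[region_order, "breadth"])):
        D = standardize(Xraw.to_numpy(), y.to_numpy(), list(INDICATOR_COLUMNS))
        models = ({"lasso": 1.0, "ridge": 0.0, "enet": config.reg_alpha}
                  if label == "primary" else {"enet": config.reg_alpha})
        for model, a in models.items():
            fit = cross_validate(D, alpha=a, k=config.k_folds, seed=config.cv_seed,
                                 n_lambda=config.n_lambda, ratio=config.lambda_ratio)
            key = model if label == "primary" else f"{model}_{label}"
            fits[key] = fit.summary()
            cv_curves[key] = pd.DataFrame({
                "lambda": fit.lambda_path, "cv_mse": fit.cv_mse_mean,
                "cv_mse_se": fit.cv_mse_se,
            })
            if label == "primary":
                fits_obj = fit if model == "enet" else None
                if fits_obj is not None:
                    enet_primary = fit
            else:
                enet_alt = fit

    _stage("robustness")
    overlap = compare_supports(enet_primary, enet_alt)
    robustness = dataclasses.asdict(overlap)
    if truth is not None:
        robustness["true_support"] = truth.support

    return StudyReport(
        config=config.to_dict(), config_hash=config.config_hash(),
        version=__version__,
        cleaning={"n_input": report_clean.n_input, "n_kept": report_clean.n_kept,
                  "dropped": report_clean.dropped},
        poverty_lines={k: v.z for k, v in lines.items()},
        profiles=profiles, pooled=pooled, moran=moran,
        lisa_ran=lisa_ran, lisa=lisa_df, collinearity=collin,
        fits=fits, cv_curves=cv_curves, robustness=robustness,
    )


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Write report.json plus per-stage CSV artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report.to_jsonable(), indent=2, sort_keys=True) + "\n")
    for label, prof in report.profiles.items():
        prof.to_csv(outdir / f"profiles_{label}.csv", index=False)
    if report.lisa is not None:
        report.lisa.to_csv(outdir / "lisa.csv", index=False)
    report.collinearity.to_csv(outdir / "collinearity.csv", index=False)
    for model, curve in report.cv_curves.items():
        curve.to_csv(outdir / f"cv_curve_{model}.csv", index=False)


def read_report(outdir: str | Path) -> dict:
    return json.loads((Path(outdir) / "report.json").read_text())
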