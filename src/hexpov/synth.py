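"""Synthetic household microdata, regional indicators, and lattice weights.

Real studies of health-expenditure poverty pair a household survey (income,
health spending, reimbursement) with regional health-system aggregates; both
are restricted-access. This module generates all three inputs with known
ground truth so the full pipeline is testable offline:

* regions live on a rows-by-cols lattice with rook or queen contiguity;
* each region carries 20 standardized health-service-equity indicators
  X1..X20, optionally with designated collinear columns;
* per region r the probability that an initially non-poor household is
  pushed below the poverty line by out-of-pocket spending is

      p_r = logistic(beta0 + Xstd_r . beta + u_r),
      u = (I - rho * W)^-1 eps,   eps ~ N(0, noise_sd^2),

  a sparse linear signal on the indicators plus a spatially autoregressive
  disturbance — exactly the two phenomena (indicator dependence, spatial
  clustering) the downstream inference is designed to detect.

Reproducibility: one integer seed drives three named substreams
(indicators, disturbance, households), so regenerating one stage never
perturbs the draws of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .spatial import SpatialWeights, row_standardize, write_gal, write_edgelist_csv
from .poverty import HOUSEHOLD_COLUMNS

__all__ = [
    "SyntheticScenario",
    "TruthRecord",
    "generate_lattice_weights",
    "generate_regional_indicators",
    "generate_households",
    "write_households_csv",
    "write_indicators_csv",
    "write_truth_json",
]

N_INDICATORS = 20

_STREAM_NAMES = ("indicators", "disturbance", "households")


def _default_beta_true() -> np.ndarray:
    """7-sparse truth on the logit scale.

    Support and signs mirror the indicator families a regional health-equity
    study would flag: grassroots capacity and insurance participation raising
    impoverishment risk (X2, X5, X7, X13, X17 positive), preventive checkups
    and overall health spending lowering it (X10, X16 negative).
    """
    beta = np.zeros(N_INDICATORS)
    beta[[1, 4, 6]] = [1.0, 0.8, 0.6]     # X2, X5, X7
    beta[9] = -0.8                        # X10
    beta[12] = 0.6                        # X13
    beta[15] = -0.6                       # X16
    beta[16] = 0.5                        # X17
    return beta


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic replicate.

    Defaults describe the reference configuration: a 20x10 lattice of 200
    regions, 500 surveyed households per region, the RMB 2300/year poverty
    line, a 7-sparse effect vector on standardized indicators, and a
    spatially autoregressive logit disturbance at rho = 0.8 whose scale
    (noise_sd = 0.66) puts the logit-scale signal share near 0.8.
    """

    n_regions: int = 200
    lattice_dims: tuple[int, int] = (20, 10)
    households_per_region: int = 500
    poverty_line_z: float = 2300.0
    beta_true: np.ndarray = field(default_factory=_default_beta_true)
    beta0_true: float = float(logit(0.12))
    spatial_rho: float = 0.8
    noise_sd: float = 0.66
    indicator_corr_blocks: tuple = ()
    income_lognormal_params: tuple[float, float] = (10.3, 0.8)
    already_poor_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        rows, cols = self.lattice_dims
        if rows * cols != self.n_regions:
            raise ValueError(f"lattice {rows}x{cols} does not cover "
                             f"{self.n_regions} regions")
        if self.beta_true.shape != (N_INDICATORS,):
            raise ValueError(f"beta_true must have length {N_INDICATORS}")
        if not abs(self.spatial_rho) < 1:
            raise ValueError("|spatial_rho| must be < 1")
        if self.n_regions < 2 or self.households_per_region < 1:
            raise ValueError("counts must be positive (>= 2 regions)")
        if not 0 <= self.already_poor_fraction <= 1:
            raise ValueError("already_poor_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def region_ids(self) -> list[str]:
        return [f"R{i:04d}" for i in range(self.n_regions)]

    @property
    def true_support(self) -> list[str]:
        return [f"X{j + 1}" for j in np.flatnonzero(self.beta_true)]

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAM_NAMES))
        return {name: np.random.default_rng(ss)
                for name, ss in zip(_STREAM_NAMES, children)}


@dataclass
class TruthRecord:
    """Ground truth behind one synthetic replicate."""

    region_ids: list[str]
    p: np.ndarray          # per-region impoverishment probability
    u: np.ndarray          # spatial disturbance on the logit scale
    eta: np.ndarray        # full linear predictor
    beta_true: np.ndarray
    beta0_true: float
    spatial_rho: float
    support: list[str]


def generate_lattice_weights(rows: int, cols: int, scheme: str = "queen") -> SpatialWeights:
    """Binary contiguity weights on a rows-by-cols lattice.

    ``rook`` joins horizontal/vertical neighbors, ``queen`` adds diagonals.
    The adjacency is symmetric with no self-neighbors and is *not* yet
    row-standardized.
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError(f"degenerate lattice {rows}x{cols}: need >= 2 cells")
    if scheme not in ("rook", "queen"):
        raise ValueError(f"scheme must be 'rook' or 'queen', got {scheme!r}")
    if scheme == "rook":
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    n = rows * cols
    ids = [f"R{i:04d}" for i in range(n)]
    neighbors, weights = [], []
    for r in range(rows):
        for c in range(cols):
            nb = [(r + dr) * cols + (c + dc)
                  for dr, dc in steps
                  if 0 <= r + dr < rows and 0 <= c + dc < cols]
            nb.sort()
            neighbors.append(np.array(nb, dtype=int))
            weights.append(np.ones(len(nb)))
    return SpatialWeights(ids, neighbors, weights, standardized=False)


def generate_regional_indicators(scenario: SyntheticScenario) -> pd.DataFrame:
    """n_regions x 20 indicator table (columns region_id, X1..X20).

    Base columns are iid standard normal across regions; each entry of
    ``indicator_corr_blocks`` — a (target, source, coefficient, noise_sd)
    tuple — then overwrites the target column with a linear function of the
    source plus independent noise, to exercise collinearity diagnostics.
    """
    rng = scenario.streams()["indicators"]
    X = rng.standard_normal((scenario.n_regions, N_INDICATORS))
    names = [f"X{j + 1}" for j in range(N_INDICATORS)]
    col = {nm: j for j, nm in enumerate(names)}
    for target, source, coef, nsd in scenario.indicator_corr_blocks:
        noise = rng.standard_normal(scenario.n_regions) * nsd if nsd > 0 else 0.0
        X[:, col[target]] = coef * X[:, col[source]] + noise
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "region_id", scenario.region_ids)
    return df


def _sar_disturbance(scenario: SyntheticScenario, weights: SpatialWeights,
                     rng: np.random.Generator) -> np.ndarray:
    Wrs = weights if weights.standardized else row_standardize(weights)
    A = np.eye(scenario.n_regions) - scenario.spatial_rho * Wrs.to_dense()
    eps = rng.normal(0.0, scenario.noise_sd, scenario.n_regions)
    try:
        return np.linalg.solve(A, eps)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - |rho|<1 prevents this
        raise ValueError(f"(I - rho W) is singular at rho={scenario.spatial_rho}") from exc


def generate_households(
    scenario: SyntheticScenario,
    indicators: pd.DataFrame,
    weights: SpatialWeights,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Household microdata realizing the scenario's impoverishment model.

    Within each region, an ``already_poor_fraction`` of households receive
    pre-expenditure income below the poverty line z; the rest draw
    z + LogNormal(mu, sigma) income and independently cross below z after
    out-of-pocket spending with the region's probability p_r. Reimbursement
    fields are constructed so that
    out-of-pocket = total - reimbursed - expected_reimbursed reproduces the
    intended crossing exactly.
    """
    if len(indicators) != scenario.n_regions or weights.n != scenario.n_regions:
        raise ValueError("indicators and weights must cover every region")
    streams = scenario.streams()
    xcols = [f"X{j + 1}" for j in range(N_INDICATORS)]
    X = indicators[xcols].to_numpy(dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xstd = (X - X.mean(axis=0)) / sd
    u = _sar_disturbance(scenario, weights, streams["disturbance"])
    eta = scenario.beta0_true + Xstd @ scenario.beta_true + u
    p = expit(eta)

    rng = streams["households"]
    m = scenario.households_per_region
    z = scenario.poverty_line_z
    mu, sigma = scenario.income_lognormal_params
    n_poor = int(round(scenario.already_poor_fraction * m))
    n_free = m - n_poor

    frames = []
    for r in range(scenario.n_regions):
        income = np.empty(m)
        oop = np.empty(m)
        # households already below the line before any health spending
        income[:n_poor] = z * rng.uniform(0.2, 0.999, n_poor)
        oop[:n_poor] = rng.uniform(0.0, 1.0, n_poor) * 0.2 * income[:n_poor]
        # initially non-poor households
        inc_free = z + rng.lognormal(mu, sigma, n_free)
        cross = rng.uniform(size=n_free) < p[r]
        post = z * rng.uniform(0.0, 1.0, n_free)          # used only if crossing
        slack = np.minimum(inc_free - z, 0.3 * inc_free)  # keeps non-crossers above z
        oop_free = np.where(cross, inc_free - post,
                            rng.uniform(0.0, 1.0, n_free) * slack)
        income[n_poor:] = inc_free
        oop[n_poor:] = oop_free
        # split total spending into out-of-pocket + reimbursement (50/50
        # between realized and expected; only their sum matters downstream)
        reimb_frac = rng.uniform(0.2, 0.6, m)
        total = oop / (1.0 - reimb_frac)
        reimbursed = (total - oop) / 2.0
        frames.append(pd.DataFrame({
            "region_id": scenario.region_ids[r],
            "income": income,
            "health_exp_total": total,
            "reimbursed": reimbursed,
            "expected_reimbursed": reimbursed,
        }))
    households = pd.concat(frames, ignore_index=True)[list(HOUSEHOLD_COLUMNS)]
    truth = TruthRecord(region_ids=scenario.region_ids, p=p, u=u, eta=eta,
                        beta_true=scenario.beta_true.copy(),
                        beta0_true=scenario.beta0_true,
                        spatial_rho=scenario.spatial_rho,
                        support=scenario.true_support)
    return households, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_households_csv(households: pd.DataFrame, path: str | Path) -> None:
    households.to_csv(path, index=False)


def write_indicators_csv(indicators: pd.DataFrame, path: str | Path) -> None:
    indicators.to_csv(path, index=False)


def write_truth_json(truth: TruthRecord, path: str | Path) -> None:
    payload = {
        "region_ids": truth.region_ids,
        "p": truth.p.tolist(),
        "u": truth.u.tolist(),
        "eta": truth.eta.tolist(),
        "beta_true": truth.beta_true.tolist(),
        "beta0_true": truth.beta0_true,
        "spatial_rho": truth.spatial_rho,
        "support": truth.support,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
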