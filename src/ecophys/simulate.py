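"""Seeded generators emulating the inputs of every analysis stage.

These forward models are exact inverses of the analysis stages in the
zero-noise limit, which makes them the recovery oracles for the test suite:

* growth curves: lag -> logistic (or Gompertz) growth toward a carrying
  capacity, observed through multiplicative lognormal counting noise at
  sparse, irregular sampling times — the regime of flow-cytometry counts of
  slow-growing marine isolates;
* condition grids: a cardinal (CTMI-form) response maps temperature or a
  salinity analogue to the true doubling rate, zero outside (T_min, T_max),
  producing asymmetric growth envelopes;
* cell populations: lognormal true (length, radius) pairs with l >= 2r
  enforced, projected to a stadium area, observed through noisy multi-point
  radius measurements in pixels;
* recruitment tables: per-sample genome abundances from a log-linear
  environment model, converted to read counts under a fixed read length.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .growth import GrowthCurve
from .morphology import CellMeasurement, stadium_area
from .ecology import RecruitmentTable

import pandas as pd

__all__ = [
    "GrowthSimParams",
    "CardinalResponse",
    "CellSimParams",
    "RecruitmentSimParams",
    "simulate_growth_curve",
    "simulate_envelope_experiment",
    "simulate_cell_population",
    "simulate_recruitment",
]


def _lognormal_sigma(cv: float) -> float:
    """Lognormal sigma with coefficient of variation cv (E[X]=exp(s^2/2))."""
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass(frozen=True)
class GrowthSimParams:
    """Truth model for one growth curve.

    N(t) = N0 for t < lag, then logistic growth at true rate ``mu``
    (doublings/day) toward carrying capacity K; observations are
    N(t) * exp(eps) with eps ~ Normal(0, sqrt(ln(1 + cv^2))).
    """

    N0: float = 1e4
    lag: float = 0.0
    mu: float = 1.5
    K: float = 1e7
    noise_cv: float = 0.01
    sample_times: tuple[float, ...] = tuple(np.linspace(0.0, 6.0, 10))
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sample_times", tuple(float(t) for t in self.sample_times)
        )
        if not (self.K > self.N0 > 0):
            raise ValueError("need K > N0 > 0")
        if self.lag < 0 or self.noise_cv < 0:
            raise ValueError("lag and noise_cv must be >= 0")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample times must be strictly increasing")


@dataclass(frozen=True)
class CardinalResponse:
    """Cardinal (CTMI-form) response of doubling rate to a condition.

    mu(T) is mu_opt at T_opt, falls to zero at T_min and T_max, and is zero
    outside (T_min, T_max); the shape is asymmetric about the optimum.
    """

    T_min: float
    T_opt: float
    T_max: float
    mu_opt: float

    def __post_init__(self) -> None:
        if not (self.T_min < self.T_opt < self.T_max):
            raise ValueError("need T_min < T_opt < T_max")
        if self.mu_opt <= 0:
            raise ValueError("mu_opt must be > 0")

    def rate(self, T: float) -> float:
        if not (self.T_min < T < self.T_max):
            return 0.0
        Tn, To, Tx = self.T_min, self.T_opt, self.T_max
        num = (T - Tx) * (T - Tn) ** 2
        den = (To - Tn) * ((To - Tn) * (T - To) - (To - Tx) * (To + Tn - 2 * T))
        return float(self.mu_opt * num / den)


@dataclass(frozen=True)
class CellSimParams:
    """Truth model for a pleomorphic capsule-shaped cell population."""

    n_cells: int = 24
    length_median_um: float = 1.65
    length_gsd: float = 1.25
    radius_median_um: float = 0.23
    radius_gsd: float = 1.15
    radii_per_cell: int = 3
    radius_noise_cv: float = 0.03
    scale_um_per_px: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.radii_per_cell < 1:
            raise ValueError("need n_cells >= 1 and radii_per_cell >= 1")
        if min(self.length_median_um, self.radius_median_um, self.scale_um_per_px) <= 0:
            raise ValueError("distribution medians and scale must be > 0")
        if self.length_gsd < 1 or self.radius_gsd < 1:
            raise ValueError("geometric SDs must be >= 1")
        if self.radius_noise_cv < 0:
            raise ValueError("radius noise cv must be >= 0")


@dataclass(frozen=True)
class RecruitmentSimParams:
    """Truth model for sample x genome recruitment counts.

    log abundance of genome g in sample s is
    ``baseline_g + slope_g * env_s + Normal(0, noise_sd)``; abundances are
    normalized per sample and converted to counts at a fixed read length.
    Because of the per-sample normalization the model is compositional:
    only differences between genome slopes are identifiable downstream, so
    the defaults give the first two genomes a steeper negative environment
    response than the last two.
    """

    genome_lengths_bp: tuple[float, ...] = (3.6e6, 3.6e6, 3.7e6, 3.5e6)
    env: tuple[float, ...] = field(default_factory=tuple)
    baseline: tuple[float, ...] | None = None
    slope: tuple[float, ...] | float = (-0.08, -0.08, -0.02, -0.02)
    noise_sd: float = 0.3
    total_bp_per_sample: float = 1e8
    read_length_bp: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.genome_lengths_bp):
            raise ValueError("genome lengths must be > 0")
        if len(self.env) == 0:
            raise ValueError("need at least one sample environment value")
        if self.total_bp_per_sample <= 0 or self.read_length_bp <= 0:
            raise ValueError("totals and read length must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_growth_curve(
    p: GrowthSimParams,
    strain_id: str = "sim",
    replicate_id: str = "r1",
    condition: dict | None = None,
    model: Literal["logistic", "gompertz"] = "logistic",
) -> GrowthCurve:
    """Generate one noisy growth curve from the truth model."""
    rng = np.random.default_rng(p.seed)
    t = np.asarray(p.sample_times, dtype=float)
    dt = np.clip(t - p.lag, 0.0, None)
    k = p.mu * np.log(2.0)  # per-day exponential rate
    if model == "logistic":
        truth = p.K / (1.0 + (p.K / p.N0 - 1.0) * np.exp(-k * dt))
    elif model == "gompertz":
        truth = p.K * np.exp(np.log(p.N0 / p.K) * np.exp(-k * dt))
    else:
        raise ValueError("model must be 'logistic' or 'gompertz'")
    sigma = _lognormal_sigma(p.noise_cv)
    noise = rng.normal(0.0, sigma, size=t.size) if sigma > 0 else np.zeros(t.size)
    observed = truth * np.exp(noise)
    return GrowthCurve(
        strain_id=strain_id,
        replicate_id=replicate_id,
        condition=dict(condition or {}),
        times=t,
        densities=observed,
    )


def simulate_envelope_experiment(
    r: CardinalResponse,
    conditions: Sequence[float],
    reps: int,
    base: GrowthSimParams,
    variable: str = "temperature_C",
    strain_id: str = "sim",
) -> dict[float, list[GrowthCurve]]:
    """Curves per condition x replicate with rates from the cardinal model.

    Conditions outside (T_min, T_max) yield flat (no-growth) curves apart
    from observation noise. Seeds are derived deterministically from
    ``base.seed`` per condition and replicate.
    """
    if reps < 1:
        raise ValueError("need reps >= 1")
    out: dict[float, list[GrowthCurve]] = {}
    for ci, cond in enumerate(conditions):
        mu = r.rate(float(cond))
        curves = []
        for rep in range(reps):
            params = GrowthSimParams(
                N0=base.N0,
                lag=base.lag,
                mu=mu,
                K=base.K if mu > 0 else base.N0 * 1.0001,
                noise_cv=base.noise_cv,
                sample_times=base.sample_times,
                seed=base.seed + 1000 * ci + rep,
            )
            curves.append(
                simulate_growth_curve(
                    params,
                    strain_id=strain_id,
                    replicate_id=f"r{rep + 1}",
                    condition={variable: float(cond)},
                )
            )
        out[float(cond)] = curves
    return out


def simulate_cell_population(p: CellSimParams) -> list[CellMeasurement]:
    """Draw a population of capsule cells and emit pixel-space measurements.

    True (l, r) pairs are lognormal with l >= 2r enforced by resampling; the
    emitted area is the exact stadium projection of the true pair, and each
    of the ``radii_per_cell`` radius measurements carries multiplicative
    lognormal noise.
    """
    rng = np.random.default_rng(p.seed)
    sigma_l = np.log(p.length_gsd)
    sigma_r = np.log(p.radius_gsd)
    noise_sigma = _lognormal_sigma(p.radius_noise_cv)
    cells: list[CellMeasurement] = []
    for i in range(p.n_cells):
        while True:
            l = float(np.exp(rng.normal(np.log(p.length_median_um), sigma_l)))
            r = float(np.exp(rng.normal(np.log(p.radius_median_um), sigma_r)))
            if l >= 2 * r:
                break
        S = stadium_area(l, r)
        if noise_sigma > 0:
            radii = r * np.exp(rng.normal(0.0, noise_sigma, size=p.radii_per_cell))
        else:
            radii = np.full(p.radii_per_cell, r)
        cells.append(
            CellMeasurement(
                cell_id=f"cell{i + 1:03d}",
                area_px2=S / p.scale_um_per_px**2,
                radii_px=tuple(radii / p.scale_um_per_px),
                scale_um_per_px=p.scale_um_per_px,
            )
        )
    return cells


def simulate_recruitment(p: RecruitmentSimParams) -> RecruitmentTable:
    """Generate a recruitment count table from the abundance model."""
    rng = np.random.default_rng(p.seed)
    n_g = len(p.genome_lengths_bp)
    env = np.asarray(p.env, dtype=float)
    n_s = env.size
    baseline = (
        np.zeros(n_g) if p.baseline is None else np.asarray(p.baseline, dtype=float)
    )
    slope = np.broadcast_to(np.asarray(p.slope, dtype=float), (n_g,))
    log_ab = baseline[:, None] + slope[:, None] * env[None, :]
    if p.noise_sd > 0:
        log_ab = log_ab + rng.normal(0.0, p.noise_sd, size=(n_g, n_s))
    ab = np.exp(log_ab)
    shares = ab / ab.sum(axis=0, keepdims=True)
    reads_total = p.total_bp_per_sample / p.read_length_bp
    counts = np.floor(shares * reads_total)  # never exceeds the bp budget
    genomes = [f"g{i + 1}" for i in range(n_g)]
    samples = [f"s{j + 1}" for j in range(n_s)]
    counts_df = pd.DataFrame(counts, index=genomes, columns=samples)
    recruited = pd.Series(
        counts.sum(axis=0) * p.read_length_bp, index=samples, name="recruited_bp"
    )
    meta = pd.DataFrame({"environment": env}, index=samples)
    return RecruitmentTable(
        counts=counts_df,
        genome_lengths=pd.Series(p.genome_lengths_bp, index=genomes, dtype=float),
        recruited_bp=recruited,
        total_bp=pd.Series(p.total_bp_per_sample, index=samples, dtype=float),
        sample_metadata=meta,
    )
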