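"""Seeded synthetic data: controlled-feeding experiment tables and food webs.

Two generators with known ground truth make every estimator in the package
testable without external data:

* :func:`simulate_experiments` emulates a compilation of controlled feeding
  experiments on fish (one row per study: observed diet and consumer δ15N with
  known study-level errors) generated from the linear narrowing-discrimination
  model Δ15N = β0 + β1·δ15N_diet plus between-study residual.
* :func:`simulate_foodweb` emulates a single-site specimen table (individual
  fish δ15N by species and functional group) generated on the scaled
  enrichment curve from species-level true trophic positions.

Ground truth is always returned in a separate table and never consumed by the
estimators under test.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meta import ExperimentObservation
from .scaled import (
    BaselineSpec,
    DiscriminationLine,
    ScaledParams,
    delta15N_at_tp,
    derive_scaled_params,
)


@dataclass(frozen=True)
class ExperimentSimConfig:
    """Configuration for a synthetic controlled-feeding experiment table.

    Defaults match the conditions of the fish discrimination meta-analysis:
    59 studies, β0 = 5.92‰, β1 = −0.27, with dietary δ15N spanning the
    experimental literature's range [0, 20]‰.
    """

    n_studies: int = 59
    true_beta0: float = 5.92
    true_beta1: float = -0.27
    diet_range: tuple[float, float] = (0.0, 20.0)
    resid_scale: float = 0.4
    sigma_d: float = 0.3
    sigma_c: float = 0.3
    seed: int = 0
    heavy_tails: bool = False  # Student-t(3) noise, for robustness checks only

    def __post_init__(self):
        if self.diet_range[0] >= self.diet_range[1]:
            raise ValueError("diet_range must satisfy lo < hi")
        if min(self.resid_scale, self.sigma_d, self.sigma_c) < 0:
            raise ValueError("scales must be non-negative")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")


@dataclass(frozen=True)
class FoodwebSimConfig:
    """Configuration for a synthetic single-site food-web specimen table.

    species_tp maps species name -> (functional_group, true TP).  Baseline
    individuals (at ``baseline_tl``) are generated in addition, under the
    species name ``baseline_species``.
    """

    species_tp: dict[str, tuple[str, float]]
    n_per_species: int = 10
    baseline_delta15N: float = 5.2
    baseline_tl: int = 2
    baseline_species: str = "zooplankton_pool"
    n_baseline: int = 16
    baseline_sd: float = 0.8
    line: DiscriminationLine = field(
        default_factory=lambda: DiscriminationLine(beta0=5.92, beta1=-0.27)
    )
    individual_sd: float = 0.4
    site: str = "synthetic_site"
    seed: int = 0

    def __post_init__(self):
        if self.individual_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for sp, (_, tp) in self.species_tp.items():
            if tp < self.baseline_tl:
                raise ValueError(f"true TP of {sp} below baseline TL {self.baseline_tl}")


def _noise(rng: np.random.Generator, scale: float, size: int, heavy: bool) -> np.ndarray:
    if scale == 0:
        return np.zeros(size)
    if heavy:
        return scale * rng.standard_t(df=3, size=size)
    return rng.normal(0.0, scale, size=size)


def simulate_experiments(
    config: ExperimentSimConfig,
) -> tuple[list[ExperimentObservation], pd.DataFrame]:
    """Generate a synthetic controlled-feeding experiment table.

    True diets are Uniform over ``diet_range``; true discrimination is
    β0 + β1·diet + Normal(0, resid_scale); observed diet/consumer values add
    Normal(0, σ_d)/Normal(0, σ_c) measurement noise.  Deterministic per seed.

    Returns
    -------
    observations : list of ExperimentObservation
        What an estimator sees (observed values and known sigmas only).
    truth : DataFrame
        Ground-truth columns (true_diet, true_discrimination, true_consumer and
        the generating coefficients), never consumed by estimators.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_studies
    true_diet = rng.uniform(*config.diet_range, size=n)
    resid = _noise(rng, config.resid_scale, n, config.heavy_tails)
    true_disc = config.true_beta0 + config.true_beta1 * true_diet + resid
    true_consumer = true_diet + true_disc
    obs_diet = true_diet + _noise(rng, config.sigma_d, n, config.heavy_tails)
    obs_consumer = true_consumer + _noise(rng, config.sigma_c, n, config.heavy_tails)

    diet_source = rng.choice(["artificial", "natural"], size=n)
    environment = rng.choice(["marine", "freshwater"], size=n)
    tissue = rng.choice(["muscle", "whole"], size=n)

    observations = [
        ExperimentObservation(
            study_id=f"sim{i:03d}",
            diet_delta15N_obs=float(obs_diet[i]),
            diet_sigma=config.sigma_d,
            consumer_delta15N_obs=float(obs_consumer[i]),
            consumer_sigma=config.sigma_c,
            diet_source=str(diet_source[i]),
            environment=str(environment[i]),
            equilibrium_reported=True,
            tissue=str(tissue[i]),
        )
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "study_id": [o.study_id for o in observations],
            "true_diet": true_diet,
            "true_discrimination": true_disc,
            "true_consumer": true_consumer,
        }
    )
    truth.attrs["true_beta0"] = config.true_beta0
    truth.attrs["true_beta1"] = config.true_beta1
    truth.attrs["resid_scale"] = config.resid_scale
    return observations, truth


def simulate_foodweb(config: FoodwebSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic single-site specimen table on the scaled curve.

    Each individual's δ15N is delta15N_at_tp(true TP) + Normal(0,
    individual_sd); baseline individuals are Normal(baseline_delta15N,
    baseline_sd).  Deterministic per seed.

    Returns (specimens, truth): the specimen table in the standard schema
    (specimen_id, species, functional_group, d15n, d13c, length_cm, site) and
    a ground-truth table (specimen_id, species, true_tp; baseline rows carry
    the baseline TL as truth).
    """
    rng = np.random.default_rng(config.seed)
    params = derive_scaled_params(config.line)
    base = BaselineSpec(
        baseline_delta15N=config.baseline_delta15N, baseline_tl=config.baseline_tl
    )

    rows, truth_rows = [], []
    idx = 0
    for _ in range(config.n_baseline):
        d15n = config.baseline_delta15N + float(_noise(rng, config.baseline_sd, 1, False)[0])
        rows.append(
            dict(
                specimen_id=f"sp{idx:04d}",
                species=config.baseline_species,
                functional_group="zooplankton",
                d15n=d15n,
                d13c=np.nan,
                length_cm=np.nan,
                site=config.site,
            )
        )
        truth_rows.append(
            dict(specimen_id=f"sp{idx:04d}", species=config.baseline_species,
                 true_tp=float(config.baseline_tl))
        )
        idx += 1

    for species, (group, true_tp) in config.species_tp.items():
        mu = float(delta15N_at_tp(params, base, true_tp))
        if mu >= params.delta15N_lim:  # unreachable by construction; guard anyway
            raise ValueError(f"true TP of {species} maps above the saturating limit")
        noise = _noise(rng, config.individual_sd, config.n_per_species, False)
        for j in range(config.n_per_species):
            rows.append(
                dict(
                    specimen_id=f"sp{idx:04d}",
                    species=species,
                    functional_group=group,
                    d15n=mu + float(noise[j]),
                    d13c=np.nan,
                    length_cm=np.nan,
                    site=config.site,
                )
            )
            truth_rows.append(
                dict(specimen_id=f"sp{idx:04d}", species=species, true_tp=true_tp)
            )
            idx += 1

    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
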