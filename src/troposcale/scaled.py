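"""Saturating (scaled) nitrogen-enrichment model and trophic-position estimators.

The diet-tissue discrimination factor Δ15N of fish is not constant: controlled
feeding experiments show it declines linearly with the δ15N of the diet,

    Δ15N = β0 + β1 · δ15N_diet,        with β0 > 0 and −1 < β1 < 0.

Iterating one trophic step, δ15N_{t+1} = δ15N_t + β0 + β1·δ15N_t, is an affine
recursion whose fixed point is the saturating limit δ15N_lim = −β0/β1 and whose
geometric contraction factor is (1 + β1) = e^{−k}, giving the per-trophic-step
rate k = −ln(1 + β1).  The resulting δ15N–TP curve has the von Bertalanffy form

    δ15N(TP) = δ15N_lim − (δ15N_lim − δ15N_base) · exp(−k · (TP − TL_base)),

which inverts to the scaled trophic-position estimator

    TP = TL_base + [ln(δ15N_lim − δ15N_base) − ln(δ15N_lim − δ15N)] / k.

The conventional additive estimator (Post-style, constant Δ15N = 3.4‰) is
provided for comparison: TP = TL_base + (δ15N − δ15N_base) / 3.4.

All δ15N quantities are in per mil (‰); trophic position is dimensionless and
continuous.  Trophic-level convention: primary producers TL1, herbivorous
zooplankton TL2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_DELTA_CONST = 3.4
"""Conventional constant diet-tissue discrimination factor (‰ per TL step)."""


class ScaledFrameworkError(ValueError):
    """Invalid parameter regime for the scaled framework."""


class UndefinedTPError(ScaledFrameworkError):
    """Consumer δ15N at or above the saturating limit: scaled TP is undefined.

    Carries the offending consumer value and the limit so callers can decide
    whether to drop, report, or treat the specimen as effectively unbounded.
    """

    def __init__(self, consumer_delta15N: float, delta15N_lim: float):
        self.consumer_delta15N = consumer_delta15N
        self.delta15N_lim = delta15N_lim
        super().__init__(
            f"consumer d15N {consumer_delta15N:.4g} ‰ >= saturating limit "
            f"{delta15N_lim:.4g} ‰; scaled TP undefined"
        )


@dataclass(frozen=True)
class DiscriminationLine:
    """Linear Δ15N–dietary-δ15N relationship: Δ15N = beta0 + beta1·δ15N_diet.

    beta0 is in ‰, beta1 dimensionless.  A valid scaled framework requires
    beta0 > 0 and −1 < beta1 < 0 (narrowing but non-overshooting enrichment).
    """

    beta0: float
    beta1: float


@dataclass(frozen=True)
class ScaledParams:
    """Derived saturating-curve parameters.

    delta15N_lim : ‰, asymptotic δ15N of an infinitely long food chain
    k            : per-TL-step rate of approach to the limit (dimensionless)
    """

    delta15N_lim: float
    k: float


@dataclass(frozen=True)
class BaselineSpec:
    """A food-web baseline: pooled δ15N of organisms with known trophic level.

    baseline_tl must be 2 (e.g. herbivorous zooplankton) or 3 (zooplanktivores).
    sd and n are reporting metadata from pooling, not used in point estimation.
    """

    baseline_delta15N: float
    baseline_tl: int
    species: tuple[str, ...] = ()
    sd: float | None = None
    n: int | None = None

    def __post_init__(self):
        if self.baseline_tl not in (2, 3):
            raise ValueError(f"baseline_tl must be 2 or 3, got {self.baseline_tl}")


@dataclass(frozen=True)
class TPEstimate:
    """A per-consumer trophic-position estimate under a named framework."""

    tp: float
    framework: str  # "scaled" | "additive"
    baseline_tl: int
    interval: tuple[float, float] | None = None
    level: float | None = None
    undefined_fraction: float = 0.0


def derive_scaled_params(line: DiscriminationLine) -> ScaledParams:
    """Derive (δ15N_lim, k) from the discrimination line.

    δ15N_lim = −β0/β1 is the fixed point of the per-step recursion
    x ← x + β0 + β1·x; k = −ln(1 + β1) is its geometric approach rate.

    Raises
    ------
    ScaledFrameworkError
        If beta1 ≥ 0 (no saturation — use the additive framework) or
        beta1 ≤ −1 (overshooting/oscillatory regime) or beta0 ≤ 0.
    """
    b0, b1 = line.beta0, line.beta1
    if b1 >= 0:
        raise ScaledFrameworkError(
            f"beta1 = {b1:.4g} >= 0: discrimination does not narrow, no "
            "saturating limit exists; use the additive framework instead"
        )
    if b1 <= -1:
        raise ScaledFrameworkError(
            f"beta1 = {b1:.4g} <= -1: per-step map overshoots the limit "
            "(oscillatory regime); scaled framework invalid"
        )
    if b0 <= 0:
        raise ScaledFrameworkError(f"beta0 = {b0:.4g} <= 0: limit would be non-positive")
    return ScaledParams(delta15N_lim=-b0 / b1, k=-math.log1p(b1))


def predict_discrimination(line: DiscriminationLine, diet_delta15N):
    """Predicted Δ15N (‰) for a given dietary δ15N: β0 + β1·δ15N_diet."""
    return line.beta0 + line.beta1 * np.asarray(diet_delta15N, dtype=float)[()]


def _check_baseline(params: ScaledParams, base: BaselineSpec) -> None:
    if base.baseline_delta15N >= params.delta15N_lim:
        raise ScaledFrameworkError(
            f"baseline d15N {base.baseline_delta15N:.4g} ‰ is at/above the "
            f"saturating limit {params.delta15N_lim:.4g} ‰"
        )


def delta15N_at_tp(params: ScaledParams, base: BaselineSpec, tp):
    """Forward curve: δ15N (‰) of a consumer at trophic position ``tp``.

    δ15N(tp) = δ15N_lim − (δ15N_lim − δ15N_base)·exp(−k·(tp − TL_base)).
    Strictly increasing in tp with asymptote δ15N_lim; at integer offsets it
    equals iterated application of the per-step discrimination map.
    Extrapolation below the baseline TL is permitted with a warning.
    """
    _check_baseline(params, base)
    tp = np.asarray(tp, dtype=float)
    if np.any(tp < base.baseline_tl):
        warnings.warn(
            "trophic position below the baseline TL: extrapolating the scaled "
            "curve below its anchor",
            stacklevel=2,
        )
    lim = params.delta15N_lim
    out = lim - (lim - base.baseline_delta15N) * np.exp(-params.k * (tp - base.baseline_tl))
    return out[()]


def tp_scaled(
    params: ScaledParams, base: BaselineSpec, consumer_delta15N: float
) -> TPEstimate:
    """Scaled trophic position of a consumer from its δ15N value.

    Exact inverse of :func:`delta15N_at_tp`.  Raises :class:`UndefinedTPError`
    when the consumer δ15N is at or above δ15N_lim.
    """
    _check_baseline(params, base)
    lim = params.delta15N_lim
    if consumer_delta15N >= lim:
        raise UndefinedTPError(consumer_delta15N, lim)
    tp = base.baseline_tl + (
        math.log(lim - base.baseline_delta15N) - math.log(lim - consumer_delta15N)
    ) / params.k
    return TPEstimate(tp=tp, framework="scaled", baseline_tl=base.baseline_tl)


def tp_additive(
    consumer_delta15N: float,
    base: BaselineSpec,
    delta_const: float = DEFAULT_DELTA_CONST,
) -> TPEstimate:
    """Conventional additive trophic position with constant discrimination.

    TP = TL_base + (δ15N_consumer − δ15N_base) / Δ_const, default Δ_const 3.4‰.
    """
    if delta_const <= 0:
        raise ValueError(f"delta_const must be positive, got {delta_const}")
    tp = base.baseline_tl + (consumer_delta15N - base.baseline_delta15N) / delta_const
    return TPEstimate(tp=tp, framework="additive", baseline_tl=base.baseline_tl)


def tp_with_posterior(
    beta0_draws: Sequence[float],
    beta1_draws: Sequence[float],
    base: BaselineSpec,
    consumer_delta15N: float,
    level: float = 0.95,
    undefined_as_inf: bool = False,
) -> TPEstimate:
    """Propagate regression-posterior uncertainty into a scaled TP estimate.

    Each (β0, β1) draw defines its own saturating curve; the consumer's TP is
    computed per draw.  Draws whose δ15N_lim lies at/below the consumer value
    leave TP undefined: by default they are excluded from the quantiles and
    reported via ``undefined_fraction`` (set ``undefined_as_inf`` to treat them
    as +∞ instead, which shifts upper quantiles to ``inf`` once the undefined
    tail mass crosses the quantile).  Draws in the non-narrowing regime
    (β1 ≥ 0 or ≤ −1) are likewise counted as undefined.

    Raises ``UndefinedTPError`` if every draw is undefined for this consumer.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    b0 = np.asarray(beta0_draws, dtype=float)
    b1 = np.asarray(beta1_draws, dtype=float)
    if b0.shape != b1.shape or b0.size == 0:
        raise ValueError("beta0/beta1 draw vectors must be equal-length and non-empty")

    valid = (b1 < 0) & (b1 > -1) & (b0 > 0)
    lim = np.where(valid, -b0 / np.where(b1 == 0, np.nan, b1), np.nan)
    k = np.where(valid, -np.log1p(np.where(valid, b1, -0.5)), np.nan)
    defined = valid & (consumer_delta15N < lim) & (base.baseline_delta15N < lim)

    undefined_fraction = 1.0 - defined.mean()
    if not defined.any():
        raise UndefinedTPError(consumer_delta15N, float(np.nanmax(lim)))

    tp = np.full(b0.shape, np.inf)
    tp[defined] = base.baseline_tl + (
        np.log(lim[defined] - base.baseline_delta15N)
        - np.log(lim[defined] - consumer_delta15N)
    ) / k[defined]

    pool = tp if undefined_as_inf else tp[defined]
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(pool, [alpha, 0.5, 1.0 - alpha])
    return TPEstimate(
        tp=float(med),
        framework="scaled",
        baseline_tl=base.baseline_tl,
        interval=(float(lo), float(hi)),
        level=level,
        undefined_fraction=float(undefined_fraction),
    )
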