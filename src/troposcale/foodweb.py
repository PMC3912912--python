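"""Food-web trophic-position tables, discrete-TL grids and method comparison.

Turns single-site specimen tables (individual fish δ15N values with species
and functional-group labels) into per-individual and per-group trophic
position estimates under the scaled and additive frameworks, builds discrete
trophic-level grids showing the per-step discrimination each framework
implies, and quantifies the between-method differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scaled import (
    DEFAULT_DELTA_CONST,
    BaselineSpec,
    ScaledParams,
    UndefinedTPError,
    delta15N_at_tp,
    tp_additive,
    tp_scaled,
    tp_with_posterior,
)

SPECIMEN_COLUMNS = ["specimen_id", "species", "functional_group", "d15n",
                    "d13c", "length_cm", "site"]

FUNCTIONAL_GROUPS = ("zooplankton", "zooplanktivore", "primary_piscivore",
                     "secondary_piscivore", "tertiary_piscivore", "other")


def pool_baseline(
    specimens: pd.DataFrame, species: list[str], tl: int
) -> BaselineSpec:
    """Pool baseline individuals into a BaselineSpec.

    The baseline δ15N is the unweighted arithmetic mean over all individuals
    of the listed species; SD and n are carried for reporting.
    """
    sub = specimens[specimens["species"].isin(species)]
    if sub.empty:
        raise ValueError(f"no specimens match baseline species {species}")
    vals = sub["d15n"].to_numpy(dtype=float)
    return BaselineSpec(
        baseline_delta15N=float(vals.mean()),
        baseline_tl=tl,
        species=tuple(species),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n=int(vals.size),
    )


def build_grid(
    framework: str,
    base: BaselineSpec,
    max_tl: int = 7,
    params: ScaledParams | None = None,
    delta_const: float = DEFAULT_DELTA_CONST,
) -> pd.DataFrame:
    """Discrete-TL grid: δ15N at each integer TL and the per-step Δ15N.

    additive: δ15N(TL) = base + Δ_const·(TL − TL_base), constant steps.
    scaled:   δ15N(TL) from the saturating curve; steps narrow with TL.

    Returns a tidy frame with columns (framework, baseline_tl, tl, d15n,
    step_discrimination); step_discrimination[t] = d15n[t+1] − d15n[t]
    (NaN on the last row).
    """
    if max_tl < base.baseline_tl:
        raise ValueError("max_tl must be >= baseline_tl")
    tls = np.arange(base.baseline_tl, max_tl + 1)
    if framework == "additive":
        d15n = base.baseline_delta15N + delta_const * (tls - base.baseline_tl)
    elif framework == "scaled":
        if params is None:
            raise ValueError("scaled grid requires ScaledParams")
        d15n = np.asarray(delta15N_at_tp(params, base, tls), dtype=float)
    else:
        raise ValueError(f"unknown framework {framework!r}")
    steps = np.append(np.diff(d15n), np.nan)
    return pd.DataFrame(
        dict(framework=framework, baseline_tl=base.baseline_tl, tl=tls,
             d15n=d15n, step_discrimination=steps)
    )


def estimate_foodweb_tp(
    specimens: pd.DataFrame,
    base: BaselineSpec,
    framework: str,
    params: ScaledParams | None = None,
    delta_const: float = DEFAULT_DELTA_CONST,
    posterior: tuple[np.ndarray, np.ndarray] | None = None,
    level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual trophic positions for a specimen table.

    framework "additive" uses the constant-Δ15N estimator; "scaled" uses the
    saturating-curve inverse, either at fixed ``params`` or propagating a
    regression ``posterior`` (beta0 draws, beta1 draws) per individual.

    Returns
    -------
    table : DataFrame
        One row per estimable specimen: specimen_id, species,
        functional_group, d15n, framework, baseline_tl, tp, tp_lo, tp_hi,
        undefined_fraction.
    undefined : DataFrame
        Side report of specimens whose δ15N lies at/above the saturating
        limit for every draw (never silently dropped).
    """
    if framework not in ("scaled", "additive"):
        raise ValueError(f"unknown framework {framework!r}")
    if framework == "scaled" and params is None and posterior is None:
        raise ValueError("scaled estimates need params or posterior draws")
    rows, undef_rows = [], []
    for rec in specimens.itertuples(index=False):
        d15n = float(rec.d15n)
        common = dict(
            specimen_id=rec.specimen_id, species=rec.species,
            functional_group=rec.functional_group, d15n=d15n,
            framework=framework, baseline_tl=base.baseline_tl,
        )
        try:
            if framework == "additive":
                est = tp_additive(d15n, base, delta_const)
            elif posterior is not None:
                est = tp_with_posterior(posterior[0], posterior[1], base, d15n, level)
            else:
                est = tp_scaled(params, base, d15n)
        except UndefinedTPError as err:
            undef_rows.append(dict(**common, delta15N_lim=err.delta15N_lim))
            continue
        lo, hi = est.interval if est.interval else (np.nan, np.nan)
        rows.append(dict(**common, tp=est.tp, tp_lo=lo, tp_hi=hi,
                         undefined_fraction=est.undefined_fraction))
    table = pd.DataFrame(
        rows, columns=list(rows[0].keys()) if rows else
        ["specimen_id", "species", "functional_group", "d15n", "framework",
         "baseline_tl", "tp", "tp_lo", "tp_hi", "undefined_fraction"],
    )
    undefined = pd.DataFrame(
        undef_rows, columns=["specimen_id", "species", "functional_group",
                             "d15n", "framework", "baseline_tl", "delta15N_lim"],
    )
    return table, undefined


def group_summary(tp_table: pd.DataFrame, by: str = "functional_group") -> pd.DataFrame:
    """Mean ± SD of TP per group (over individuals, not species means)."""
    g = tp_table.groupby(by)["tp"]
    return pd.DataFrame(dict(mean_tp=g.mean(), sd_tp=g.std(ddof=1), n=g.size()))


def species_summary(tp_table: pd.DataFrame) -> pd.DataFrame:
    """Species-level aggregation (mean ± SD over that species' individuals)."""
    return group_summary(tp_table, by="species")


def compare_frameworks(
    tp_scaled_table: pd.DataFrame, tp_additive_table: pd.DataFrame
) -> dict:
    """Between-framework comparison on identical specimen sets.

    Differences are scaled − additive per specimen.  Returns a dict with
    ``per_specimen`` (DataFrame: specimen_id, species, functional_group, d15n,
    tp_scaled, tp_additive, diff), ``per_group`` (mean and max |diff| per
    functional group), ``max_abs_diff`` and baseline pairing metadata.
    """
    a = tp_scaled_table.set_index("specimen_id")
    b = tp_additive_table.set_index("specimen_id")
    if set(a.index) != set(b.index):
        raise ValueError("framework tables cover different specimen sets")
    b = b.loc[a.index]
    per = pd.DataFrame(
        dict(
            species=a["species"],
            functional_group=a["functional_group"],
            d15n=a["d15n"],
            tp_scaled=a["tp"],
            tp_additive=b["tp"],
        )
    )
    per["diff"] = per["tp_scaled"] - per["tp_additive"]
    grp = per.groupby("functional_group")["diff"]
    per_group = pd.DataFrame(
        dict(mean_diff=grp.mean(), max_abs_diff=grp.apply(lambda s: s.abs().max()),
             n=grp.size())
    )
    return dict(
        per_specimen=per.reset_index(),
        per_group=per_group,
        max_abs_diff=float(per["diff"].abs().max()),
        baselines=dict(
            scaled_baseline_tl=int(a["baseline_tl"].iloc[0]),
            additive_baseline_tl=int(b["baseline_tl"].iloc[0]),
        ),
    )


def crossing_point(
    params: ScaledParams, base: BaselineSpec, delta_const: float = DEFAULT_DELTA_CONST
) -> float:
    """Consumer δ15N at which scaled and additive TP estimates agree.

    Both estimators equal TL_base at the baseline δ15N; above the crossing the
    scaled estimate exceeds the additive one (the additive framework
    under-recovers high trophic positions), below it the sign flips.  The
    baseline itself is always a crossing; a second, non-trivial crossing
    exists because the scaled curve is convex in δ15N.  Returned is the
    non-trivial crossing (δ15N > baseline) found by bisection, or the baseline
    value if none exists below the saturating limit.
    """
    from scipy.optimize import brentq

    lim = params.delta15N_lim
    b = base.baseline_delta15N

    def gap(x):
        return (
            tp_scaled(params, base, x).tp - tp_additive(x, base, delta_const).tp
        )

    lo = b + 1e-6
    hi = lim - 1e-9 * max(1.0, abs(lim))
    # scan for a sign change beyond the trivial root at the baseline
    xs = np.linspace(lo, hi, 512)
    vals = np.array([gap(x) for x in xs])
    sign = np.sign(vals)
    flips = np.nonzero(np.diff(sign))[0]
    if flips.size == 0:
        return b
    i = flips[0]
    return float(brentq(gap, xs[i], xs[i + 1], xtol=1e-12))
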