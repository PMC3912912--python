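"""CSV/JSON/YAML readers and writers shared by all commands.

Fixed dialect throughout: UTF-8, comma separator, dot decimal, lower-case
headers; no locale dependence.  Floats are written with 17 significant digits
so write → read roundtrips are value-preserving.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .meta import ExperimentObservation, PosteriorDraws
from .foodweb import SPECIMEN_COLUMNS

logger = logging.getLogger("troposcale")

EXPERIMENT_COLUMNS = [
    "study_id", "diet_d15n", "diet_sigma", "consumer_d15n", "consumer_sigma",
    "discrimination", "discrimination_sigma", "diet_source", "environment",
    "equilibrium", "tissue",
]

TP_COLUMNS = ["specimen_id", "species", "functional_group", "d15n", "framework",
              "baseline_tl", "tp", "tp_lo", "tp_hi", "undefined_fraction"]

_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_experiments(
    path, sd_to_se_n_column: str | None = None
) -> list[ExperimentObservation]:
    """Read a controlled-feeding experiment CSV into typed records.

    Rows may report the consumer δ15N directly or only the discrimination
    Δ15N; the missing one is derived from consumer = diet + Δ.  The reported
    error is stored as the known study sigma as-is; if ``sd_to_se_n_column``
    names a sample-size column, errors are converted SD → SE by dividing by
    √n first.  Missing sigmas are imputed with the column median (logged).

    Raises :class:`SchemaError` on missing columns; malformed numeric fields
    are reported with their row number.
    """
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    _require_columns(df, ["study_id", "diet_d15n"], path)
    for col in EXPERIMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    numeric = ["diet_d15n", "diet_sigma", "consumer_d15n", "consumer_sigma",
               "discrimination", "discrimination_sigma"]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()].tolist()
            rows = [i + 2 for i in bad]  # +2: header line and 1-based rows
            raise SchemaError(f"{path}: non-numeric value in column {col!r} "
                              f"at file line(s) {rows}")

    if sd_to_se_n_column is not None:
        _require_columns(df, [sd_to_se_n_column], path)
        root_n = np.sqrt(pd.to_numeric(df[sd_to_se_n_column]))
        for col in ("diet_sigma", "consumer_sigma", "discrimination_sigma"):
            df[col] = df[col] / root_n

    # a row missing consumer_d15n must carry discrimination, and vice versa
    n_imputed = 0
    for col in ("diet_sigma", "consumer_sigma"):
        src = df[col]
        if col == "consumer_sigma":
            # Δ-only rows: take the reported discrimination error as the
            # consumer-side sigma when no consumer sigma is given
            src = src.fillna(df["discrimination_sigma"])
        if src.isna().any():
            med = float(src.median())
            if np.isnan(med):
                raise SchemaError(f"{path}: column {col!r} entirely missing; "
                                  "cannot impute")
            n_imputed += int(src.isna().sum())
            src = src.fillna(med)
        df[col] = src
    if n_imputed:
        logger.warning("imputed %d missing sigma value(s) with column medians",
                       n_imputed)

    observations = []
    for i, row in df.iterrows():
        have_c = not pd.isna(row["consumer_d15n"])
        have_disc = not pd.isna(row["discrimination"])
        if not have_c and not have_disc:
            raise SchemaError(
                f"{path}: line {i + 2}: neither consumer_d15n nor "
                "discrimination present"
            )
        try:
            observations.append(
                ExperimentObservation(
                    study_id=str(row["study_id"]),
                    diet_delta15N_obs=float(row["diet_d15n"]),
                    diet_sigma=float(row["diet_sigma"]),
                    consumer_sigma=float(row["consumer_sigma"]),
                    consumer_delta15N_obs=float(row["consumer_d15n"]) if have_c else None,
                    discrimination_obs=None if have_c else float(row["discrimination"]),
                    diet_source=str(row["diet_source"]) if not pd.isna(row["diet_source"]) else "artificial",
                    environment=str(row["environment"]) if not pd.isna(row["environment"]) else "marine",
                    equilibrium_reported=bool(row["equilibrium"]) if not pd.isna(row["equilibrium"]) else True,
                    tissue=str(row["tissue"]) if not pd.isna(row["tissue"]) else "muscle",
                )
            )
        except ValueError as err:
            raise SchemaError(f"{path}: line {i + 2}: {err}") from err
    logger.info("read %d experiment record(s) from %s", len(observations), path)
    return observations


def write_experiments(observations: list[ExperimentObservation], path) -> None:
    rows = [
        dict(
            study_id=o.study_id, diet_d15n=o.diet_delta15N_obs,
            diet_sigma=o.diet_sigma, consumer_d15n=o.consumer_delta15N_obs,
            consumer_sigma=o.consumer_sigma, discrimination=o.discrimination_obs,
            discrimination_sigma=np.nan, diet_source=o.diet_source,
            environment=o.environment, equilibrium=o.equilibrium_reported,
            tissue=o.tissue,
        )
        for o in observations
    ]
    pd.DataFrame(rows, columns=EXPERIMENT_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT, encoding="utf-8"
    )


def read_specimens(path) -> pd.DataFrame:
    """Read a specimen CSV (specimen_id, species, functional_group, d15n,
    d13c, length_cm, site); d13c and length_cm are optional pass-through."""
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    _require_columns(df, ["specimen_id", "species", "functional_group", "d15n"], path)
    bad = df.index[pd.to_numeric(df["d15n"], errors="coerce").isna()].tolist()
    if bad:
        raise SchemaError(f"{path}: non-numeric d15n at file line(s) "
                          f"{[i + 2 for i in bad]}")
    for col in SPECIMEN_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    logger.info("read %d specimen record(s) from %s", len(df), path)
    return df[SPECIMEN_COLUMNS]


def write_specimens(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def write_tp_table(table: pd.DataFrame, path) -> None:
    """Write a tidy TP table; roundtrips through read_tp_table bit-exactly."""
    cols = [c for c in TP_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in TP_COLUMNS
    ]
    table[cols].to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def read_tp_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    _require_columns(df, ["specimen_id", "framework", "baseline_tl", "tp"], path)
    return df


def write_posterior(draws: PosteriorDraws, out_dir) -> None:
    """Export posterior draws as plain CSV plus a JSON diagnostics sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    draws.params_frame().to_csv(out / "posterior.csv", index=False,
                                float_format=_FLOAT_FMT, encoding="utf-8")
    latent = pd.DataFrame(
        np.hstack([draws.latent_theta_d, draws.latent_theta_c]),
        columns=[f"theta_d_{s}" for s in draws.study_ids]
        + [f"theta_c_{s}" for s in draws.study_ids],
    )
    latent.to_csv(out / "latent_states.csv", index=False,
                  float_format=_FLOAT_FMT, encoding="utf-8")
    with open(out / "diagnostics.json", "w", encoding="utf-8") as fh:
        json.dump(draws.diagnostics, fh, indent=2, sort_keys=True)


def read_posterior_params(path) -> tuple[np.ndarray, np.ndarray]:
    """Read (beta0, beta1) draw vectors from an exported posterior CSV."""
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    _require_columns(df, ["beta0", "beta1"], path)
    return df["beta0"].to_numpy(), df["beta1"].to_numpy()


def read_config(path) -> dict:
    """Read a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_run_info(out_dir, config: dict) -> None:
    """Emit the reproducibility block (config + seed + version) for a run."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"package": "troposcale", "version": __version__, **config}
    with open(out / "run_info.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
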