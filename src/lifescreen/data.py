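"""Survival-record data model, file I/O, vial-mean aggregation, and
deviation-from-control computation.

The atomic observation of the screen is one fly's death age, recorded on a
census grid (deaths scored every ``census_interval`` days, so the recorded
age is the census day on or after true death). All downstream analyses
operate on the mean life span of replicate vials, expressed per line and sex
as deviations from the contemporaneous co-isogenic control within the same
experimental block.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SEXES = ("male", "female")
POOLED = "pooled"
SURVIVAL_COLUMNS = ("block", "line", "sex", "vial", "death_age")

_GRID_TOL = 1e-9


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class ValidationError(ValueError):
    """A row violates the survival-record invariants."""


@dataclasses.dataclass(frozen=True)
class SurvivalRecord:
    """One fly's death age with its block/line/sex/vial labels."""

    block: str
    line: str
    sex: str
    vial: str
    death_age: float


def _separator_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def validate_survival(
    frame: pd.DataFrame,
    census_interval: float = 2.0,
    first_census: float | None = None,
) -> pd.DataFrame:
    """Validate a survival table against the record invariants.

    Death ages must be positive and lie on the census grid
    ``first_census + k * census_interval`` (``first_census`` defaults to one
    census interval); sex must be exactly ``male`` or ``female``. Returns the
    frame with canonical column order and dtypes, row order preserved.
    """
    missing = [c for c in SURVIVAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"survival table is missing column(s): {missing}")
    if first_census is None:
        first_census = census_interval
    out = frame.loc[:, list(SURVIVAL_COLUMNS)].copy()
    for col in ("block", "line", "sex", "vial"):
        out[col] = out[col].astype(str)
    out["death_age"] = pd.to_numeric(out["death_age"], errors="raise").astype(float)

    bad_sex = ~out["sex"].isin(SEXES)
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise ValidationError(
            f"row {row}: sex {out['sex'].iloc[row]!r} is not one of {SEXES}"
        )
    ages = out["death_age"].to_numpy()
    if (ages <= 0).any():
        row = int(np.flatnonzero(ages <= 0)[0])
        raise ValidationError(f"row {row}: death_age {ages[row]} is not positive")
    steps = (ages - first_census) / census_interval
    off = (np.abs(steps - np.round(steps)) > _GRID_TOL) | (ages < first_census - _GRID_TOL)
    if off.any():
        row = int(np.flatnonzero(off)[0])
        raise ValidationError(
            f"row {row}: death_age {ages[row]} is not on the census grid "
            f"(first census day {first_census}, interval {census_interval})"
        )
    return out


def read_survival_table(
    path: str | os.PathLike,
    census_interval: float = 2.0,
    first_census: float | None = None,
) -> pd.DataFrame:
    """Read and validate a survival CSV/TSV (separator chosen by extension)."""
    frame = pd.read_csv(path, sep=_separator_for(path))
    return validate_survival(frame, census_interval=census_interval, first_census=first_census)


def write_survival_table(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a survival table; round-trips losslessly through the reader."""
    frame.loc[:, list(SURVIVAL_COLUMNS)].to_csv(
        path, sep=_separator_for(path), index=False
    )


def to_records(frame: pd.DataFrame) -> list[SurvivalRecord]:
    return [SurvivalRecord(*row) for row in frame.loc[:, list(SURVIVAL_COLUMNS)].itertuples(index=False)]


def from_records(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=list(SURVIVAL_COLUMNS))


def vial_means(records: pd.DataFrame) -> pd.DataFrame:
    """Mean life span of each replicate vial.

    Groups by (block, line, sex, vial) and returns ``mean_lifespan`` (the
    arithmetic mean of death ages) and ``n_flies`` per vial. Invariant to the
    input row order.
    """
    if len(records) == 0:
        raise ValueError("cannot compute vial means of an empty record table")
    grouped = (
        records.groupby(["block", "line", "sex", "vial"], sort=True)["death_age"]
        .agg(mean_lifespan="mean", n_flies="count")
        .reset_index()
    )
    return grouped


def deviations_from_control(
    vials: pd.DataFrame, control_line: str, value_col: str = "mean_lifespan"
) -> pd.DataFrame:
    """Per line and sex, the deviation of the line mean from the control mean.

    Deviations are computed within experimental block ("contemporaneous"): a
    line's sex mean (mean of its vial means) minus the control line's sex mean
    in the same block. A ``pooled`` row per line holds the mean of the two sex
    deviations. Unequal replicate counts are allowed.
    """
    required = {"block", "line", "sex", value_col}
    missing = required - set(vials.columns)
    if missing:
        raise SchemaError(f"vial-mean table is missing column(s): {sorted(missing)}")

    line_sex = (
        vials.groupby(["block", "line", "sex"], sort=True)[value_col]
        .agg(line_mean="mean", n_replicates="count")
        .reset_index()
    )
    rows = []
    for block, sub in line_sex.groupby("block", sort=True):
        ctrl = sub[sub["line"] == control_line].set_index("sex")["line_mean"]
        sexes_present = sub["sex"].unique()
        for sex in sexes_present:
            if sex not in ctrl.index:
                raise ValueError(
                    f"control line {control_line!r} has no vials for sex "
                    f"{sex!r} in block {block!r}"
                )
        for line, lsub in sub.groupby("line", sort=True):
            sex_dev = {}
            for _, r in lsub.iterrows():
                dev = r["line_mean"] - ctrl[r["sex"]]
                sex_dev[r["sex"]] = dev
                rows.append(
                    {
                        "block": block,
                        "line": line,
                        "sex": r["sex"],
                        "deviation": dev,
                        "n_replicates": int(r["n_replicates"]),
                    }
                )
            if sex_dev:
                rows.append(
                    {
                        "block": block,
                        "line": line,
                        "sex": POOLED,
                        "deviation": float(np.mean(list(sex_dev.values()))),
                        "n_replicates": int(lsub["n_replicates"].sum()),
                    }
                )
    return pd.DataFrame(rows, columns=["block", "line", "sex", "deviation", "n_replicates"])
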