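"""Participant-level trial data: containers, CSV I/O, covariate encoding.

A trial table holds one row per randomized participant: arm assignment,
baseline covariates (sex, age, university site, weekly frequency of heavy
episodic drinking), a follow-up completion flag, and — for completers only —
the outcome, grams of alcohol consumed per week (a non-negative integer
count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical column order for trial CSV files
TRIAL_COLUMNS = ["id", "group", "sex", "age", "university", "hed", "followed_up", "g_week"]

#: default arm labels, reference (control) first so that IRR < 1 favors intervention
DEFAULT_ARM_LABELS = ("control", "intervention")


class TrialSchemaError(ValueError):
    """A trial CSV is missing required columns or misdeclares them."""


class TrialValidationError(ValueError):
    """A trial row violates the data contract (named by row where possible)."""


@dataclass
class TrialDataset:
    """Ordered participant records for a two-arm randomized trial.

    Parameters
    ----------
    records : pandas.DataFrame
        One row per participant with columns ``id, group, sex, age,
        university, hed, followed_up, g_week``.  ``g_week`` is a nullable
        integer column, present exactly for rows with ``followed_up`` true.
    arm_labels : tuple of str
        The two arm labels, reference (control) arm first.
    provenance : str
        Free text recording where the data came from (file path or a
        simulation-config digest).
    """

    records: pd.DataFrame
    arm_labels: tuple[str, str] = DEFAULT_ARM_LABELS
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise TrialSchemaError(f"missing required column(s): {', '.join(missing)}")
        if len(self.arm_labels) != 2:
            raise TrialValidationError("arm_labels must have exactly 2 entries")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise TrialValidationError(f"duplicate participant id(s): {dupes[:5]}")
        bad_arm = ~df["group"].isin(self.arm_labels)
        if bad_arm.any():
            row = int(np.flatnonzero(bad_arm.to_numpy())[0])
            raise TrialValidationError(
                f"row {row}: group {df['group'].iloc[row]!r} is not one of {self.arm_labels}"
            )
        followed = df["followed_up"].astype(bool)
        g = df["g_week"]
        present = g.notna()
        mismatch = followed != present
        if mismatch.any():
            row = int(np.flatnonzero(mismatch.to_numpy())[0])
            state = "missing" if followed.iloc[row] else "present"
            raise TrialValidationError(
                f"row {row}: g_week is {state} but followed_up is {bool(followed.iloc[row])}"
            )
        vals = g[present]
        if len(vals):
            arr = vals.to_numpy(dtype=float)
            if (arr < 0).any() or (arr != np.round(arr)).any():
                row = int(np.flatnonzero(present.to_numpy())[np.flatnonzero((arr < 0) | (arr != np.round(arr)))[0]])
                raise TrialValidationError(
                    f"row {row}: g_week must be a non-negative integer, got {g.iloc[row]!r}"
                )
        if (df["age"].to_numpy(dtype=float) < 0).any() or (df["hed"].to_numpy(dtype=float) < 0).any():
            raise TrialValidationError("age and hed must be non-negative")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def control_label(self) -> str:
        return self.arm_labels[0]

    @property
    def intervention_label(self) -> str:
        return self.arm_labels[1]


@dataclass
class DesignMatrix:
    """Numeric design for NB regression, with an explicit column map.

    The first column is the intercept; there is exactly one GROUP indicator
    column (1 = intervention, 0 = control reference); one-hot-encoded
    categoricals drop their reference level.
    """

    values: np.ndarray
    column_map: list[tuple[str, str]]  # (source variable, level or "numeric")
    outcome: np.ndarray
    row_ids: list
    arm_labels: tuple[str, str] = DEFAULT_ARM_LABELS

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [src if lvl in ("numeric", "-") else f"{src}[{lvl}]" for src, lvl in self.column_map]

    def group_column(self) -> int:
        """Index of the GROUP indicator column."""
        for j, (src, _) in enumerate(self.column_map):
            if src == "group":
                return j
        raise KeyError("design has no GROUP column")

    def arm_mask(self, arm: str) -> np.ndarray:
        """Boolean row mask for one arm, decoded from the GROUP indicator."""
        g = self.values[:, self.group_column()]
        if arm == self.arm_labels[1]:
            return g == 1.0
        if arm == self.arm_labels[0]:
            return g == 0.0
        raise KeyError(f"unknown arm {arm!r}")


@dataclass
class ArmAttrition:
    n_randomized: int
    n_followed_up: int
    percent: float | None  # rounded to 1 decimal; None for an empty arm


@dataclass
class AttritionReport:
    """Follow-up rates per arm (1-decimal percent) and overall (integer percent)."""

    per_arm: dict[str, ArmAttrition]
    overall_randomized: int
    overall_followed_up: int
    overall_percent: int | None


_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no"}


def _parse_followed(value, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise TrialValidationError(f"row {row}: cannot parse followed_up value {value!r}")


def load_trial_csv(path, schema: Mapping[str, str] | None = None,
                   arm_labels: tuple[str, str] = DEFAULT_ARM_LABELS) -> TrialDataset:
    """Load a participant-level trial table from CSV.

    Parameters
    ----------
    path : str or Path
        Comma-separated UTF-8 file with a header row.
    schema : mapping, optional
        Maps canonical column names (``id``, ``group``, ...) to the column
        names actually present in the file.
    arm_labels : tuple of str
        Arm labels, control (reference) first.

    Raises
    ------
    TrialSchemaError
        If a required column is absent.
    TrialValidationError
        If a row's value violates the contract; the message names the row.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in TRIAL_COLUMNS}
    raw = raw.rename(columns=rename)
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise TrialSchemaError(f"missing required column(s): {', '.join(missing)}")

    n = len(raw)
    followed = [_parse_followed(v, i) for i, v in enumerate(raw["followed_up"])]
    g_week = np.full(n, pd.NA, dtype=object)
    for i, (f, v) in enumerate(zip(followed, raw["g_week"])):
        s = str(v).strip()
        if not f:
            if s not in ("", "NA", "nan", "None"):
                raise TrialValidationError(
                    f"row {i}: g_week given ({s!r}) but followed_up is false"
                )
            continue
        try:
            x = float(s)
        except ValueError:
            raise TrialValidationError(f"row {i}: g_week {s!r} is not a number") from None
        if x < 0 or x != round(x):
            raise TrialValidationError(f"row {i}: g_week must be a non-negative integer, got {s}")
        g_week[i] = int(round(x))

    def _num(col: str) -> np.ndarray:
        try:
            return raw[col].astype(float).to_numpy()
        except ValueError:
            for i, v in enumerate(raw[col]):
                try:
                    float(v)
                except ValueError:
                    raise TrialValidationError(f"row {i}: {col} value {v!r} is not numeric") from None
            raise

    df = pd.DataFrame(
        {
            "id": raw["id"].to_numpy(),
            "group": raw["group"].to_numpy(),
            "sex": raw["sex"].to_numpy(),
            "age": _num("age"),
            "university": raw["university"].to_numpy(),
            "hed": _num("hed"),
            "followed_up": np.asarray(followed, dtype=bool),
            "g_week": pd.array(g_week, dtype="Int64"),
        }
    )
    return TrialDataset(df, arm_labels=arm_labels, provenance=str(path))


def write_trial_csv(dataset: TrialDataset, path) -> None:
    """Write a trial table as the canonical comma-separated UTF-8 CSV."""
    out = dataset.records.copy()
    out["followed_up"] = out["followed_up"].astype(bool).map({True: "true", False: "false"})
    out["g_week"] = out["g_week"].astype(object).where(out["g_week"].notna(), "")
    out.to_csv(path, index=False, columns=TRIAL_COLUMNS, encoding="utf-8")


def complete_cases(dataset: TrialDataset) -> TrialDataset:
    """Restrict to participants with an observed follow-up outcome.

    Implements the intention-to-treat-with-complete-cases restriction (which
    assumes outcomes are missing at random); row order is preserved.
    """
    mask = dataset.records["followed_up"].astype(bool).to_numpy()
    return TrialDataset(
        dataset.records.loc[mask].reset_index(drop=True),
        arm_labels=dataset.arm_labels,
        provenance=dataset.provenance,
    )


def encode_design(
    dataset: TrialDataset,
    numeric_vars: Sequence[str] = ("age", "hed"),
    categorical_vars: Sequence[str] = ("sex", "university"),
) -> DesignMatrix:
    """One-hot encode a complete-case dataset into a regression design.

    Layout: intercept, GROUP indicator (1 = intervention), numeric columns
    untransformed, then (levels - 1) indicator columns per categorical with
    the lexicographically first level as the dropped reference.

    Raises
    ------
    ValueError
        If the dataset is empty or contains unfollowed rows.
    """
    df = dataset.records
    if len(df) == 0:
        raise ValueError("no rows to encode")
    if not df["followed_up"].astype(bool).all():
        raise ValueError("encode_design requires a complete-case dataset; run complete_cases first")

    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    cmap: list[tuple[str, str]] = [("intercept", "-")]

    cols.append((df["group"].to_numpy() == dataset.intervention_label).astype(float))
    cmap.append(("group", dataset.intervention_label))

    for v in numeric_vars:
        cols.append(df[v].to_numpy(dtype=float))
        cmap.append((v, "numeric"))

    for v in categorical_vars:
        levels = sorted(pd.unique(df[v].astype(str)))
        if len(levels) == 1:
            warnings.warn(
                f"categorical {v!r} has a single level ({levels[0]!r}); it contributes no columns",
                UserWarning,
                stacklevel=2,
            )
            continue
        for lvl in levels[1:]:  # drop reference level
            cols.append((df[v].astype(str).to_numpy() == lvl).astype(float))
            cmap.append((v, lvl))

    X = np.column_stack(cols)
    y = df["g_week"].to_numpy(dtype=np.int64)
    return DesignMatrix(
        values=X,
        column_map=cmap,
        outcome=y,
        row_ids=list(df["id"]),
        arm_labels=dataset.arm_labels,
    )


def attrition_summary(dataset: TrialDataset) -> AttritionReport:
    """Per-arm and overall follow-up rates from a randomized (not complete-case) dataset.

    Per-arm percentages are rounded to 1 decimal, the overall percentage to
    the nearest integer.  An empty arm yields a missing percentage and a
    warning.
    """
    df = dataset.records
    per_arm: dict[str, ArmAttrition] = {}
    for arm in dataset.arm_labels:
        sub = df[df["group"] == arm]
        n_rand = len(sub)
        n_fu = int(sub["followed_up"].astype(bool).sum())
        if n_rand == 0:
            warnings.warn(f"arm {arm!r} is empty; its follow-up percentage is undefined",
                          UserWarning, stacklevel=2)
            pct = None
        else:
            pct = round(100.0 * n_fu / n_rand, 1)
        per_arm[arm] = ArmAttrition(n_rand, n_fu, pct)
    n_rand = len(df)
    n_fu = int(df["followed_up"].astype(bool).sum())
    overall = round(100.0 * n_fu / n_rand) if n_rand else None
    return AttritionReport(per_arm, n_rand, n_fu, overall)
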