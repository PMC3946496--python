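"""Observation tables, mean standardization, fixed-effect designs, and the
selection-analysis table.

Trait order is fixed everywhere as (wing, tarsus, mass, bill). Traits are
standardized by their overall mean (not the SD), which keeps variances
dimensionless and comparable across traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAITS = ("wing", "tarsus", "mass", "bill")

DEFAULT_COLUMN_MAP = {
    "id": "id", "year": "year", "sex": "sex", "age": "age", "date": "date",
    "wing": "wing", "tarsus": "tarsus", "mass": "mass", "bill": "bill",
    "fledged": "fledged",
}


@dataclass
class ObservationTable:
    """Repeated annual trait records with covariates and fledgling counts.

    ``data`` holds one row per (individual, year) record with columns
    id, year, sex, age (NaN = unknown), date (NaN = unknown), the four
    traits (NaN = missing) and fledged (NaN = missing).
    """

    data: pd.DataFrame
    traits: tuple = TRAITS

    def __post_init__(self) -> None:
        missing = [c for c in ("id", "year", "sex") + tuple(self.traits) if c not in self.data.columns]
        if missing:
            raise ValueError(f"observation table lacks columns {missing}")
        all_missing = self.data[list(self.traits)].isna().all(axis=1)
        if all_missing.any():
            raise ValueError("rows with every trait missing are not allowed")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.data["id"]))

    def counts(self) -> pd.DataFrame:
        """Per-trait observation and individual counts."""
        rows = []
        for t in self.traits:
            ok = self.data[t].notna()
            rows.append({"trait": t, "n_observations": int(ok.sum()),
                         "n_individuals": int(self.data.loc[ok, "id"].nunique())})
        return pd.DataFrame(rows)

    def copy_with(self, data: pd.DataFrame) -> "ObservationTable":
        return ObservationTable(data=data, traits=self.traits)


@dataclass
class StandardizationRecord:
    """Per-trait overall means used for mean standardization."""

    means: dict  # trait -> mean in original units
    standardized: bool = True

    def unstandardize(self, obs: ObservationTable) -> ObservationTable:
        df = obs.data.copy()
        for t, m in self.means.items():
            df[t] = df[t] * m
        return obs.copy_with(df)


def read_observations(path, column_map=None, traits=TRAITS, adult_only_flag: str | None = None) -> ObservationTable:
    """Read and validate an observation CSV.

    ``column_map`` maps the canonical names (id, year, sex, age, date,
    wing, tarsus, mass, bill, fledged) to the file's column names.
    Missing values are empty cells or 'NA'. Rows with all traits missing
    are dropped with a warning. Negative trait values or fledgling counts
    are hard errors. If ``adult_only_flag`` names a 0/1 column, rows with
    0 (offspring of the year) are excluded.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    rename = {v: k for k, v in cmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    if adult_only_flag and adult_only_flag in df.columns:
        df = df[df[adult_only_flag].astype(float) > 0].drop(columns=[adult_only_flag])
    for col in ("id", "sex"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    for col in ("year",):
        df[col] = df[col].astype(int)
    for col in ("age", "date", "fledged") + tuple(traits):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="raise")
    for t in traits:
        if (df[t].dropna() < 0).any():
            raise ValueError(f"negative values in trait column {t!r}")
    fl = df["fledged"].dropna()
    if (fl < 0).any():
        raise ValueError("negative fledgling counts")
    all_missing = df[list(traits)].isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropped {int(all_missing.sum())} row(s) with all traits missing", stacklevel=2)
        df = df[~all_missing]
    return ObservationTable(data=df.reset_index(drop=True), traits=traits)


def mean_standardize(obs: ObservationTable) -> tuple[ObservationTable, StandardizationRecord]:
    """Divide each trait by its overall (all years, all individuals) mean."""
    df = obs.data.copy()
    means = {}
    for t in obs.traits:
        vals = df[t].dropna()
        if len(vals) < 2:
            raise ValueError(f"trait {t!r} has fewer than 2 observations")
        m = float(vals.mean())
        if m <= 0:
            raise ValueError(f"non-positive mean for trait {t!r}")
        means[t] = m
        df[t] = df[t] / m
    return obs.copy_with(df), StandardizationRecord(means=means)


@dataclass
class FixedDesign:
    """Fixed-effect design matrix shared across traits.

    Columns: intercept, sex contrasts, centered age, centered age^2 and
    centered date polynomial terms as configured. Unknown-age (or
    unknown-date) rows get 0 in the corresponding columns, i.e. the mean
    is substituted. Aliased (constant) columns are dropped.
    """

    matrix: np.ndarray  # (n_rows, p)
    columns: list[str]
    dropped: list[str] = field(default_factory=list)
    trait_effects: dict = field(default_factory=dict)  # effect name -> traits it applies to

    @property
    def n_effects(self) -> int:
        return self.matrix.shape[1]


DEFAULT_EFFECT_SPEC = {
    "sex": list(TRAITS),
    "age": list(TRAITS),  # linear + quadratic
    "date": ["mass", "bill"],  # polynomial, degree below
    "date_degree": 2,
}


def build_fixed_design(obs: ObservationTable, effect_spec=None) -> FixedDesign:
    """Build the shared fixed-effect design.

    Age is mean-centred over known-age rows and unknown ages are set to 0
    after centring (mean substitution); the same convention applies to
    date. Sex enters as a single +/-0.5 contrast for two-level data or as
    treatment contrasts otherwise.
    """
    spec = dict(DEFAULT_EFFECT_SPEC)
    if effect_spec:
        spec.update(effect_spec)
    df = obs.data
    n = len(df)
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(n))]
    trait_effects = {"intercept": list(obs.traits)}

    if spec.get("sex"):
        levels = sorted(df["sex"].astype(str).unique())
        if len(levels) == 2:
            c = np.where(df["sex"].astype(str) == levels[1], 0.5, -0.5)
            cols.append((f"sex[{levels[1]}]", c))
            trait_effects[f"sex[{levels[1]}]"] = list(spec["sex"])
        else:
            for lev in levels[1:]:
                cols.append((f"sex[{lev}]", (df["sex"].astype(str) == lev).astype(float).to_numpy()))
                trait_effects[f"sex[{lev}]"] = list(spec["sex"])

    predropped: list[str] = []
    if spec.get("age"):
        age = df["age"].to_numpy(dtype=float)
        known = ~np.isnan(age)
        if not known.any():
            predropped += ["age", "age2"]  # all-unknown ages alias the intercept
        else:
            centred = np.zeros(n)
            centred[known] = age[known] - age[known].mean()
            cols.append(("age", centred))
            cols.append(("age2", centred**2))  # unknown-age rows stay exactly 0 in both terms
            trait_effects["age"] = list(spec["age"])
            trait_effects["age2"] = list(spec["age"])

    if spec.get("date"):
        if "date" not in df.columns or df["date"].isna().all():
            raise ValueError("date effect requested but no date column present")
        date = df["date"].to_numpy(dtype=float)
        known = ~np.isnan(date)
        centred = np.zeros(n)
        centred[known] = date[known] - date[known].mean()
        for deg in range(1, int(spec.get("date_degree", 2)) + 1):
            term = centred**deg
            term[known] -= term[known].mean()
            term[~known] = 0.0
            name = "date" if deg == 1 else f"date{deg}"
            cols.append((name, term))
            trait_effects[name] = list(spec["date"])

    names = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])
    # drop aliased columns: zero variance (except intercept) or rank deficiency
    keep, dropped = [0], list(predropped)
    for j in range(1, X.shape[1]):
        col = X[:, j]
        trial = X[:, keep + [j]]
        if np.allclose(col, 0) or np.linalg.matrix_rank(trial) <= len(keep):
            dropped.append(names[j])
        else:
            keep.append(j)
    return FixedDesign(
        matrix=X[:, keep],
        columns=[names[j] for j in keep],
        dropped=dropped,
        trait_effects={k: v for k, v in trait_effects.items() if k in {names[j] for j in keep}},
    )


@dataclass
class SelectionTable:
    """Rows ready for Lande-Arnold regression.

    ``data`` has columns id, year, w (relative fitness, mean 1 within
    year) and the four traits (fixed effects removed, mean 0 within year).
    """

    data: pd.DataFrame
    traits: tuple = TRAITS

    def __post_init__(self) -> None:
        for year, grp in self.data.groupby("year"):
            if abs(grp["w"].mean() - 1.0) > 1e-9:
                raise ValueError(f"relative fitness in year {year} does not average 1")
            for t in self.traits:
                if abs(grp[t].mean()) > 1e-9:
                    raise ValueError(f"trait {t} in year {year} is not centred")

    def __len__(self) -> int:
        return len(self.data)

    def design(self, quadratic: bool = False) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Regression design (with intercept) and response for gradient fits."""
        Z = self.data[list(self.traits)].to_numpy(dtype=float)
        names = ["intercept"] + list(self.traits)
        blocks = [np.ones((len(Z), 1)), Z]
        if quadratic:
            t = len(self.traits)
            for i in range(t):
                blocks.append((Z[:, i] ** 2)[:, None])
                names.append(f"{self.traits[i]}^2")
            for i in range(t):
                for j in range(i + 1, t):
                    blocks.append((Z[:, i] * Z[:, j])[:, None])
                    names.append(f"{self.traits[i]}:{self.traits[j]}")
        return np.hstack(blocks), self.data["w"].to_numpy(dtype=float), names

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def prepare_selection_table(obs_std: ObservationTable, design: FixedDesign,
                            fixed_coef: np.ndarray, traits=TRAITS) -> SelectionTable:
    """Build the selection-analysis table from standardized observations.

    Processing order: traits are already mean-standardized; fixed-effect
    contributions (coefficients from the fitted animal model, one column
    per trait) are subtracted; each trait is then centred within year.
    Relative fitness is the fledgling count divided by its annual mean;
    years with zero mean fitness are dropped with a warning. Only rows
    with all traits and fitness present are kept.
    """
    df = obs_std.data.copy()
    fixed_coef = np.asarray(fixed_coef, dtype=float)
    if fixed_coef.shape != (design.n_effects, len(traits)):
        raise ValueError("fixed_coef must be (n_effects, n_traits)")
    contrib = design.matrix @ fixed_coef  # (n, t), includes intercept
    for k, t in enumerate(traits):
        df[t] = df[t] - contrib[:, k]
    complete = df[list(traits)].notna().all(axis=1) & df["fledged"].notna()
    df = df[complete].copy()
    if df.empty:
        raise ValueError("no complete rows for selection analysis")
    year_mean = df.groupby("year")["fledged"].transform("mean")
    dead_years = sorted(df.loc[year_mean == 0, "year"].unique())
    if dead_years:
        warnings.warn(f"dropped year(s) with zero total fledglings: {dead_years}", stacklevel=2)
        df = df[year_mean > 0].copy()
        year_mean = df.groupby("year")["fledged"].transform("mean")
    if df.empty:
        raise ValueError("no year with positive mean fitness")
    df["w"] = df["fledged"] / year_mean
    for t in traits:
        df[t] = df[t] - df.groupby("year")[t].transform("mean")
    out = df[["id", "year", "w", *traits]].reset_index(drop=True)
    return SelectionTable(data=out, traits=tuple(traits))
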