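"""Synthetic pedigrees, phenotypes and fitness with known ground truth.

The generator mirrors the fitted model: breeding values follow the
pedigree (parental average plus Mendelian segregation, with the
segregation variance shrunk for inbred parents), phenotypes add
permanent-environment, year, fixed and residual effects on the
mean-standardized scale and are then rescaled to configured trait means,
and fledgling counts are Poisson around a quadratic fitness surface.
All randomness derives from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from qgconstraints.pedigree import Pedigree, inbreeding_coefficients
from qgconstraints.phenotypes import ObservationTable, TRAITS


def _default_G() -> np.ndarray:
    sd = np.sqrt(np.array([0.00030, 0.00045, 0.00110, 0.00040]))
    C = np.full((4, 4), 0.4)
    np.fill_diagonal(C, 1.0)
    return C * np.outer(sd, sd)


def _default_cov(scale: float, var=(0.00030, 0.00045, 0.00110, 0.00040)) -> np.ndarray:
    return np.diag(np.asarray(var) * scale)


@dataclass
class SimConfig:
    """Ground-truth configuration for one synthetic population."""

    n_founders: int = 100
    generations: int = 5
    mean_offspring: float = 2.2        # Poisson mean per monogamous pair
    immigrants_per_generation: int = 10
    repeat_rate: float = 0.5           # chance of each additional annual record
    max_repeats: int = 4
    missing_rate: tuple = (0.05, 0.05, 0.05, 0.05)
    unknown_age_fraction: float = 0.1
    trait_names: tuple = TRAITS
    trait_means: tuple = (65.92, 16.7, 11.07, 9.86)
    G_true: np.ndarray = field(default_factory=_default_G)
    PE_true: np.ndarray = field(default_factory=lambda: _default_cov(0.6))
    YEAR_true: np.ndarray = field(default_factory=lambda: _default_cov(0.2))
    R_true: np.ndarray = field(default_factory=lambda: _default_cov(1.2))
    sex_effect: tuple = (0.01, 0.005, 0.02, 0.0)       # male minus female, standardized scale
    age_linear: tuple = (0.004, 0.0, 0.006, 0.002)
    age_quadratic: tuple = (-0.001, 0.0, -0.001, 0.0)
    date_effect: tuple = (0.0, 0.0, -0.0005, -0.0002)  # per-day linear, mass/bill style
    beta_true: tuple = (0.0, 0.7, -0.2, 0.0)
    gamma_true: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    mean_fitness: float = 2.5          # annual mean fledgling count
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("G_true", "PE_true", "YEAR_true", "R_true", "gamma_true"):
            M = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            setattr(self, name, M)
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
        t = len(self.trait_names)
        for name in ("G_true", "PE_true", "YEAR_true", "R_true"):
            M = getattr(self, name)
            if M.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t}")
            if name == "G_true" and np.any(np.linalg.eigvalsh(M) <= 0):
                raise ValueError("G_true must be positive definite")
        if not 0 <= self.repeat_rate <= 1:
            raise ValueError("repeat_rate must be in [0, 1]")
        if any(not 0 <= m <= 1 for m in self.missing_rate):
            raise ValueError("missing rates must be in [0, 1]")
        if self.mean_fitness < 0:
            raise ValueError("mean_fitness must be non-negative")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def expected_pedigree_size(self) -> float:
        """Expectation under the Poisson branching process."""
        size = float(self.n_founders)
        total = size
        for _ in range(1, self.generations):
            size = (size / 2) * self.mean_offspring + self.immigrants_per_generation
            total += size
        return total

    def rng_streams(self, names):
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


@dataclass
class SimTruth:
    """Realized effects and parameters of one simulated dataset."""

    config: SimConfig
    breeding_values: pd.DataFrame     # per individual, standardized scale
    year_effects: pd.DataFrame
    generation: dict                  # individual id -> generation index

    def to_json(self, path) -> None:
        import json

        cfg = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in asdict(self.config).items()}
        payload = {
            "config": cfg,
            "breeding_values": self.breeding_values.to_dict(orient="list"),
            "year_effects": self.year_effects.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete-generation pedigree with random monogamous pairing.

    Generation 0 holds ``n_founders`` founders; each later generation is
    produced by randomly pairing the previous generation (leftover
    individual unpaired) with Poisson(mean_offspring) offspring per pair,
    plus unrelated immigrants.
    """
    if cfg.n_founders < 1:
        raise ValueError("need at least one founder")
    if cfg.generations < 1:
        raise ValueError("need at least one generation")
    rng = cfg.rng_streams(["pedigree"])["pedigree"]
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    generation: list[int] = []

    def add(s: int, d: int, gen: int) -> int:
        idx = len(ids)
        ids.append(f"I{idx:06d}")
        sire.append(s)
        dam.append(d)
        generation.append(gen)
        return idx

    current = [add(-1, -1, 0) for _ in range(cfg.n_founders)]
    for g in range(1, cfg.generations):
        perm = rng.permutation(current)
        nxt: list[int] = []
        for k in range(len(perm) // 2):
            s, d = int(perm[2 * k]), int(perm[2 * k + 1])
            for _ in range(rng.poisson(cfg.mean_offspring)):
                nxt.append(add(s, d, g))
        for _ in range(cfg.immigrants_per_generation):
            nxt.append(add(-1, -1, g))
        if not nxt:
            nxt = [add(-1, -1, g)]  # keep the population alive
        current = nxt
    ped = Pedigree(ids, np.array(sire), np.array(dam))
    ped.generation = dict(zip(ids, generation))  # type: ignore[attr-defined]
    return ped


def _breeding_values(ped: Pedigree, G: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """BVs by the parental-average + Mendelian-segregation recursion.

    Segregation variance is (0.5 - 0.25 (F_s + F_d)) G with only the known
    parents' inbreeding entering; founders (and missing parent halves)
    contribute full unshared variance.
    """
    n, t = len(ped), G.shape[0]
    F = inbreeding_coefficients(ped)
    L = np.linalg.cholesky(G)
    z = rng.standard_normal((n, t))
    a = np.empty((n, t))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            mean = 0.5 * (a[s] + a[d])
            seg = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mean = 0.5 * a[p]
            seg = 0.75 - 0.25 * F[p]
        else:
            mean = 0.0
            seg = 1.0
        a[i] = mean + np.sqrt(seg) * (z[i] @ L.T)
    return a


def simulate_phenotypes(ped: Pedigree, cfg: SimConfig) -> tuple[ObservationTable, SimTruth]:
    """Generate repeated annual trait records for a pedigree.

    Phenotypes are built on the standardized (mean 1) scale and rescaled
    to ``trait_means``; missingness and unknown ages are applied last.
    Rows that would lose every trait keep one value so the table stays
    valid.
    """
    rng = cfg.rng_streams(["pedigree", "phenotypes"])["phenotypes"]
    t = cfg.n_traits
    n = len(ped)
    generation = getattr(ped, "generation", None)
    if generation is None:
        generation = {iid: 0 for iid in ped.ids}

    a = _breeding_values(ped, cfg.G_true, rng)
    pe = rng.multivariate_normal(np.zeros(t), cfg.PE_true, size=n)

    n_years = max(g for g in generation.values()) + cfg.max_repeats + 2
    yr_eff = rng.multivariate_normal(np.zeros(t), cfg.YEAR_true, size=n_years)
    sexes = rng.choice(["F", "M"], size=n)

    L_R = np.linalg.cholesky(cfg.R_true)
    rows = []
    for i, iid in enumerate(ped.ids):
        g = generation[iid]
        n_rep = 1 + int(rng.binomial(cfg.max_repeats - 1, cfg.repeat_rate)) if cfg.max_repeats > 1 else 1
        for r in range(n_rep):
            year = g + 1 + r
            age = 1 + r
            date = float(rng.uniform(0, 30))
            e = L_R @ rng.standard_normal(t)
            yv = (1.0 + a[i] + pe[i] + yr_eff[year]
                  + (0.5 if sexes[i] == "M" else -0.5) * np.asarray(cfg.sex_effect)
                  + age * np.asarray(cfg.age_linear)
                  + age**2 * np.asarray(cfg.age_quadratic)
                  + date * np.asarray(cfg.date_effect)
                  + e)
            rows.append((iid, year, sexes[i], float(age), date, *yv))
    df = pd.DataFrame(rows, columns=["id", "year", "sex", "age", "date", *cfg.trait_names])
    for k, name in enumerate(cfg.trait_names):
        df[name] = df[name] * cfg.trait_means[k]

    # missingness, but never empty a whole row
    for k, name in enumerate(cfg.trait_names):
        drop = rng.random(len(df)) < cfg.missing_rate[k]
        df.loc[drop, name] = np.nan
    empty = df[list(cfg.trait_names)].isna().all(axis=1)
    if empty.any():
        first = cfg.trait_names[0]
        # regenerate the first trait for emptied rows at its mean (kept, not missing)
        df.loc[empty, first] = cfg.trait_means[0]
    if cfg.unknown_age_fraction > 0:
        unk = rng.random(n) < cfg.unknown_age_fraction
        unk_ids = {ped.ids[i] for i in np.flatnonzero(unk)}
        df.loc[df["id"].isin(unk_ids), "age"] = np.nan
    df["fledged"] = np.nan

    truth = SimTruth(
        config=cfg,
        breeding_values=pd.DataFrame(a, columns=list(cfg.trait_names)).assign(id=list(ped.ids)),
        year_effects=pd.DataFrame(yr_eff, columns=list(cfg.trait_names)).assign(year=range(n_years)),
        generation=generation,
    )
    return ObservationTable(data=df, traits=cfg.trait_names), truth


def simulate_fitness(obs: ObservationTable, cfg: SimConfig) -> ObservationTable:
    """Draw fledgling counts from the configured selection surface.

    Expected relative fitness is max(0, 1 + beta'z + 0.5 z' gamma z) on
    within-year-centred mean-standardized traits (gamma in the doubled
    convention); counts are Poisson(w * mean_fitness). Rows with missing
    traits get no fitness record.
    """
    if cfg.mean_fitness < 0:
        raise ValueError("mean_fitness must be non-negative")
    rng = cfg.rng_streams(["pedigree", "phenotypes", "fitness"])["fitness"]
    df = obs.data.copy()
    traits = list(obs.traits)
    Z = df[traits].to_numpy(dtype=float)
    means = np.nanmean(Z, axis=0)
    Z = Z / means
    complete = ~np.isnan(Z).any(axis=1)
    zc = np.full_like(Z, np.nan)
    years = df["year"].to_numpy()
    for y in np.unique(years):
        sel = complete & (years == y)
        if sel.any():
            zc[sel] = Z[sel] - Z[sel].mean(axis=0)
    beta = np.asarray(cfg.beta_true, dtype=float)
    gamma = np.asarray(cfg.gamma_true, dtype=float)
    w = np.full(len(df), np.nan)
    zs = zc[complete]
    w[complete] = np.maximum(0.0, 1.0 + zs @ beta + 0.5 * np.einsum("ij,jk,ik->i", zs, gamma, zs))
    fled = np.full(len(df), np.nan)
    fled[complete] = rng.poisson(w[complete] * cfg.mean_fitness)
    df["fledged"] = fled
    return obs.copy_with(df)
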