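import numpy as np
import pytest

import qgconstraints as qg
from qgconstraints.pedigree import Pedigree
from qgconstraints.simulate import SimConfig


def random_pedigree(n: int, seed: int, p_known: float = 0.8) -> Pedigree:
    """Random valid pedigree: each individual's parents drawn from earlier ids."""
    rng = np.random.default_rng(seed)
    n_founders = max(2, n // 10)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(n_founders, n):
        if rng.random() < p_known:
            sire[i] = rng.integers(0, i)
        if rng.random() < p_known:
            d = rng.integers(0, i)
            dam[i] = d if d != sire[i] else -1
    return Pedigree([f"X{i}" for i in range(n)], sire, dam)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated population with phenotypes and fitness."""
    cfg = SimConfig(n_founders=80, generations=4, seed=11)
    ped = qg.simulate_pedigree(cfg)
    obs, truth = qg.simulate_phenotypes(ped, cfg)
    obs = qg.simulate_fitness(obs, cfg)
    return cfg, ped, obs, truth


@pytest.fixture(scope="session")
def small_chain(small_sim):
    """A short but valid animal-model chain on the small population."""
    cfg, ped, obs, truth = small_sim
    obs_std, std = qg.mean_standardize(obs)
    design = qg.build_fixed_design(obs_std)
    Vp = np.nanvar(obs_std.data[list(obs.traits)].to_numpy(dtype=float), axis=0)
    prior = qg.default_informative_prior(4, Vp, 3)
    settings = qg.MCMCSettings(iterations=2500, burn_in=700, thinning=15, seed=5)
    chain = qg.fit_animal_model(obs_std, design, ped, prior, settings)
    return obs_std, std, design, chain
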