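import numpy as np
import pandas as pd
import pytest

from btsel import landscape as L
from btsel import simulate as S


@pytest.fixture(scope="session")
def small_landscape():
    land = L.generate_landscape(
        L.LandscapeSpec(shape=(40, 40), open_fraction=0.15, n_primary_roads=2,
                        n_secondary_roads=2, n_access_points=4, seed=11)
    )
    return land


@pytest.fixture(scope="session")
def small_surfaces(small_landscape):
    return L.compute_surfaces(small_landscape)


def recovery_params(seed, n_ind=60, repeats=90, v_ind=0.45, v_e=0.55,
                    population=S.GEORGIA):
    """Single-population generator with no fixed effects: the parameter-
    recovery workhorse.  std_* columns carry the standardized-scale truth;
    raw columns are shifted far from zero so no truncation occurs."""
    tp = S.TraitParams(mu=0.0, beta_hunt=0.0, beta_post=0.0, beta_pop=0.0,
                       beta_hunt_pop=0.0, beta_post_pop=0.0,
                       v_ind=v_ind, v_e=v_e, raw_mean=1000.0, raw_sd=1.0)
    return S.SimulationParams(
        traits={t: tp for t in S.TRAITS},
        n_per_population={population: n_ind},
        repeats_mean=repeats, repeats_sd=0, repeats_min=min(repeats, 7),
        repeats_max=153,
        p_harvest={population: 0.0}, p_pred={population: 0.0},
        gamma_harvest={population: {t: 0.0 for t in S.TRAITS}},
        gamma_pred={population: {t: 0.0 for t in S.TRAITS}},
        seed=seed,
    )


def simulate_recovery_dataset(seed, **kwargs):
    params = recovery_params(seed, **kwargs)
    profiles = S.simulate_individuals(params)
    profiles["fate"] = "survived"
    profiles["fate_date"] = pd.NaT
    records = S.simulate_trait_observations(profiles, params, keep_standardized=True)
    return profiles, records


def selection_experiment_params(seed, gamma_edge, n_ind=59, repeats=60):
    """One-population cohort with harvest selection only on distance-to-edge."""
    return S.SimulationParams(
        n_per_population={S.GEORGIA: n_ind},
        repeats_mean=repeats, repeats_sd=0, repeats_min=7, repeats_max=153,
        p_harvest={S.GEORGIA: 13 / 59}, p_pred={S.GEORGIA: 0.0},
        gamma_harvest={S.GEORGIA: {"dist_access": 0.0, "speed": 0.0,
                                   "dist_open": 0.0, "dist_edge": gamma_edge}},
        gamma_pred={S.GEORGIA: {t: 0.0 for t in S.TRAITS}},
        seed=seed,
    )
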