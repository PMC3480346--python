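"""Shared fixtures: the heavier synthetic scenarios are built once per
session and reused by module tests and the acceptance suite."""

import numpy as np
import pandas as pd
import pytest

import climniche as cn


@pytest.fixture(scope="session")
def gradient_bundle():
    """900-county lattice, 3 iid predictors, linear-gradient coefficient
    surfaces, growth-rate noise SD 0.05."""
    return cn.make_gradient_scenario(n_side=30, noise_sd=0.05, seed=11)


@pytest.fixture(scope="session")
def gradient_fit(gradient_bundle):
    """GWR fit (bisquare, fraction 0.15) on the first interval of the
    gradient scenario, with lambda recomputed from the generated censuses."""
    b = gradient_bundle
    years = list(b.config.census_years)
    t0, t1 = years[0], years[1]
    lam = cn.growth_rate(b.county_table[f"pop_{t0}"].to_numpy(),
                         b.county_table[f"pop_{t1}"].to_numpy(), t0, t1)
    names = list(b.truth.true_beta.columns)
    X = b.county_table[names].to_numpy()
    coords = b.county_table[["x", "y"]].to_numpy(float)
    fit = cn.fit_gwr(X, lam, coords, cn.KernelSpec(fraction=0.15),
                     predictor_names=names)
    return b, lam, fit


@pytest.fixture(scope="session")
def amplification_bundle():
    """Constant climate, growth proportional to county temperature, with the
    analytic exposure trajectory attached."""
    return cn.make_amplification_scenario()


@pytest.fixture(scope="session")
def model_selection_case():
    """Spatially varying climate effects, constant non-climate effects:
    the four-model AICc comparison on the first interval."""
    b = cn.make_model_selection_scenario(n_side=20, seed=0)
    growth = cn.build_growth_table(b.county_table, b.normals,
                                   list(b.config.census_years))
    sub = growth[growth["t0"] == 1900].reset_index(drop=True)
    comp = cn.compare_models(sub, sub[["x", "y"]].to_numpy(float))
    return b, sub, comp


@pytest.fixture(scope="session")
def bimodal_fixture():
    """Counties clustered at two known centers in climate space, binned on a
    20x20 unit grid; the truth is the pair of generating centers."""
    axis1 = cn.AxisSpec("annual_temp", 0.0, 20.0, 20)
    axis2 = cn.AxisSpec("temp_seasonality", 0.0, 20.0, 20)
    rng = np.random.default_rng(42)
    n = 2000
    centers = ((5.0, 6.0), (14.0, 13.0))
    c1 = np.concatenate([rng.normal(centers[0][0], 1.2, n // 2),
                         rng.normal(centers[1][0], 1.2, n // 2)])
    c2 = np.concatenate([rng.normal(centers[0][1], 1.2, n // 2),
                         rng.normal(centers[1][1], 1.2, n // 2)])
    pop = np.concatenate([np.full(n // 2, 500.0), np.full(n // 2, 900.0)])
    keep = (c1 > 0) & (c1 < 20) & (c2 > 0) & (c2 < 20)
    return dict(axis1=axis1, axis2=axis2, c1=c1[keep], c2=c2[keep],
                pop=pop[keep], centers=centers)
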