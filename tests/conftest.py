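"""Shared fixtures: small synthetic landscapes and fitted model sets.

Everything is generated programmatically at collection time from fixed
seeds, so the suite needs no data files.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import connectgene as cg
import connectgene.sdm as sdm_mod


@pytest.fixture(scope="session")
def small_layers():
    """Three autocorrelated covariate layers on a 60x60, 50 m grid."""
    return cg.generate_env_layers((60, 60), 3, 4.0, seed=11, cell_size=50.0)


@pytest.fixture(scope="session")
def strong_suitability(small_layers):
    """Steep virtual-species suitability with ~10% of cells suitable."""
    return cg.make_true_suitability(small_layers, (6.0, 4.0, 2.4), -9.0)


@pytest.fixture(scope="session")
def sdm_case(small_layers, strong_suitability):
    """Presence/background split plus all five fitted models with thresholds."""
    pres = cg.sample_occurrences(strong_suitability, 150, seed=21)
    bg = cg.sample_background(small_layers, 600, pres, seed=22)
    pts = cg.PointSet.concat([pres, bg])
    train, test = cg.split_train_test(pts, 0.7, seed=23)
    X_train = sdm_mod.extract_covariates(small_layers, train).to_numpy()
    X_test = sdm_mod.extract_covariates(small_layers, test).to_numpy()
    settings = {"BRT": {"n_estimators": 80}, "RF": {"n_estimators": 80}}
    fits = {}
    for kind in cg.MODEL_KINDS:
        fit = cg.fit_sdm(
            kind,
            train.subset(np.nonzero(train.label == 1)[0]),
            train.subset(np.nonzero(train.label == 0)[0]),
            small_layers,
            settings.get(kind),
            seed=25,
        )
        fit.threshold = sdm_mod._max_sss_threshold(train.label, fit.predict(X_train))
        fits[kind] = fit
    return {
        "layers": small_layers,
        "suitability": strong_suitability,
        "presences": pres,
        "background": bg,
        "points": pts,
        "train": train,
        "test": test,
        "X_train": X_train,
        "X_test": X_test,
        "fits": fits,
        "settings": settings,
    }


@pytest.fixture()
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
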