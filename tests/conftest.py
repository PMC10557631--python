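import warnings

import numpy as np
import pytest

import lesionmap as lm


@pytest.fixture(scope="session")
def grid20():
    return lm.build_lattice(20, 20)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions: 40x40 lattice, one hex-radius-3 lesion."""
    return lm.generate_spatial_dataset(lm.SpatialSimConfig(seed=0))


@pytest.fixture(scope="session")
def subspot_bundle():
    """Small bundle with per-subspot expression and cell-type ground truth."""
    cfg = lm.SpatialSimConfig(
        n_rows=20, n_cols=20, n_genes=300, seed=0,
        subspot_expression=True, lesions=(lm.LesionSpec((10, 10), 2),),
    )
    return lm.generate_spatial_dataset(cfg)


@pytest.fixture(scope="session")
def mri_series():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lm.generate_mri_series(lm.MRISimConfig(seed=0))


def pre_and_next_scan(series):
    """Indices of the last pre-lesion scan and the appearance scan."""
    appear = series.config.lesions[0].appear_day
    pre = max(i for i, d in enumerate(series.scan_days) if d < appear)
    nxt = min(i for i, d in enumerate(series.scan_days) if d >= appear)
    return pre, nxt
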