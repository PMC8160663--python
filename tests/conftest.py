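import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from omskit import design, simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# coarse axis keeps matrix sizes small while leaving band shapes resolvable
AXIS = np.arange(400.0, 1101.0, 5.0)


@pytest.fixture(scope="session")
def two_components():
    return [
        simulate.ComponentSpectrum((simulate.GaussianBand(550.0, 60.0, 1.0),)),
        simulate.ComponentSpectrum((simulate.GaussianBand(900.0, 60.0, 0.8),)),
    ]


@pytest.fixture(scope="session")
def d20v125_scheme():
    return design.scheme_from_spec(design.parse_designation("d20v125"))


@pytest.fixture
def mixture_set(two_components, d20v125_scheme):
    conc = design.to_concentrations(
        d20v125_scheme, design.FactorMapping(((1.0, 13.0), (1.0, 13.0)))
    )
    return simulate.mixture_spectra(
        conc,
        two_components,
        noise=simulate.NoiseHierarchy(replicate=0.002),
        seed=1,
        axis=AXIS,
        roles=d20v125_scheme.roles,
    )


def make_set(X, axis=None, time=None, ids=None):
    """Wrap a bare matrix into a SpectraSet with minimal metadata."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if axis is None:
        axis = np.arange(X.shape[1], dtype=float)
    meta = pd.DataFrame(
        {
            "id": np.arange(n) if ids is None else ids,
            "batch": 0,
            "sample": np.arange(n),
            "position": 0,
            "replicate": 0,
            "time": np.arange(n, dtype=float) if time is None else time,
            "role": "train",
        }
    )
    return simulate.SpectraSet(axis=np.asarray(axis, float), X=X, meta=meta)
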