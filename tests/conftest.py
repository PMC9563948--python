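import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from lungdr.cohorts import STAGES, Cohort
from lungdr.reference import model2_reference_params
from lungdr.synthetic import SyntheticDesign, generate_dataset


def make_cohort(**kw):
    """A valid single-stage IIIA cohort, overridable field by field."""
    defaults = dict(
        id="c1",
        study="s1",
        publication_year=2010,
        treatment="sCRT",
        n_patients=100,
        os2_observed=40.0,
        dose_gy=60.0,
        dose_per_fraction_gy=2.0,
        n_fractions=30,
        duration_days=40.0,
        stage_fractions={"I": 0.0, "II": 0.0, "IIIA": 1.0, "IIIB": 0.0},
        het_corrected=True,
    )
    defaults.update(kw)
    return Cohort(**defaults)


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture(scope="session")
def default_dataset():
    """51 synthetic cohorts from the full-model reference truth."""
    return generate_dataset(SyntheticDesign(seed=3))


@pytest.fixture(scope="session")
def model2_dataset_x10():
    """51 cohorts from the chemo-era (model 2) truth at 10x patients."""
    design = SyntheticDesign(seed=11, truth=model2_reference_params(),
                             truth_spec="model2", patients_multiplier=10.0)
    return generate_dataset(design)


class FlatLayout:
    """Identity-packed layout over a plain box, for analytic test surfaces."""

    def __init__(self, names, lower, upper):
        self.names = tuple(names)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.slices = {}

    @property
    def n_params(self):
        return len(self.names)

    def index(self, name):
        return self.names.index(name)

    def unpack(self, z):
        return np.asarray(z, dtype=float).copy()


class AnalyticModel:
    """Stand-in model whose -2logL is a supplied analytic function."""

    def __init__(self, fun, names, lower, upper):
        self.layout = FlatLayout(names, lower, upper)
        self._fun = fun

    def neg2_loglik_values(self, v):
        return float(self._fun(np.asarray(v, dtype=float)))


class AnalyticFit:
    """Stand-in fit result at a known optimum of an analytic surface."""

    def __init__(self, model, values):
        self.model = model
        self.values = np.asarray(values, dtype=float)
        self.z_opt = self.values.copy()
        self.neg2_loglik = model.neg2_loglik_values(self.values)
        self.boundary_flags = set()


@pytest.fixture
def analytic_fit_factory():
    def factory(fun, optimum, names=None, lower=None, upper=None):
        k = len(optimum)
        names = names or [f"p{i}" for i in range(k)]
        lower = lower if lower is not None else [-50.0] * k
        upper = upper if upper is not None else [50.0] * k
        model = AnalyticModel(fun, names, lower, upper)
        return AnalyticFit(model, optimum)

    return factory
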