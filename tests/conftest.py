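import itertools

import numpy as np
import pytest

from rsmextract import datasets
from rsmextract.model import fit_quadratic


@pytest.fixture(scope="session")
def kwz():
    """The packaged 29-run extraction design and its response table."""
    design, responses = datasets.load_design()
    return design, responses


@pytest.fixture(scope="session")
def kwz_fits(kwz):
    """Full quadratic fits of all five modelled responses."""
    design, responses = kwz
    return {name: fit_quadratic(design, responses[name]) for name in datasets.RESPONSE_NAMES}


@pytest.fixture(scope="session")
def kwz_models(kwz_fits):
    return {name: fit.model for name, fit in kwz_fits.items()}


def brute_force_quadratic(model, points):
    """Independent term-by-term evaluation of a quadratic surface.

    Deliberately written as explicit loops over intercept, linear,
    interaction and quadratic terms so it shares no code with
    ``QuadraticModel.predict``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    k = points.shape[1]
    out = np.zeros(len(points))
    for r, x in enumerate(points):
        total = model.intercept
        for i in range(k):
            total += model.linear[i] * x[i]
            total += model.quadratic[i] * x[i] * x[i]
        for i, j in itertools.combinations(range(k), 2):
            total += model.interaction[i, j] * x[i] * x[j]
        out[r] = total
    return out


def grid_max_oracle(model, n=21):
    """Dense lattice search over the coded cube using the brute-force
    evaluator; returns (best value, best point)."""
    axes = [np.linspace(-1.0, 1.0, n)] * model.k
    pts = np.array(list(itertools.product(*axes)))
    vals = _vector_brute(model, pts)
    i = int(np.argmax(vals))
    return float(vals[i]), pts[i]


def _vector_brute(model, pts):
    # vectorized transcription of brute_force_quadratic (kept independent
    # of build_model_matrix); validated against the scalar loop in tests
    vals = np.full(len(pts), model.intercept, dtype=float)
    k = pts.shape[1]
    for i in range(k):
        vals += model.linear[i] * pts[:, i] + model.quadratic[i] * pts[:, i] ** 2
    for i, j in itertools.combinations(range(k), 2):
        vals += model.interaction[i, j] * pts[:, i] * pts[:, j]
    return vals
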