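"""Shared fixtures: random frames, ideal lattices, and the (expensive)
session-scoped RDF-matching experiment."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import rdfbias as rb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_random_frame(rng, n=30, box_len=6.0, species=None) -> rb.Frame:
    pos = rng.uniform(0.0, box_len, size=(n, 3))
    return rb.Frame(pos, np.full(3, box_len), species)


def make_fcc_frame(spacing: float = 1.1, reps: int = 4) -> rb.Frame:
    """Perfect FCC crystal under periodic boundaries."""
    a = spacing * np.sqrt(2.0)
    basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    cells = np.array(
        [[x, y, z] for x in range(reps) for y in range(reps) for z in range(reps)]
    )
    pos = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    return rb.Frame(pos, np.full(3, reps * a))


@pytest.fixture
def fcc_frame() -> rb.Frame:
    return make_fcc_frame()


@pytest.fixture(scope="session")
def lj_matching():
    """The LJ RDF-matching experiment (ε 1.0 → target ε 1.3), run once.

    Several convergence and recovery checks share this run; it takes a
    few minutes of MD.
    """
    from rdfbias.experiments import lj_rdf_matching_experiment

    return lj_rdf_matching_experiment(seed=1, n_updates=300)
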