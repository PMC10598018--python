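"""Shared fixtures: small connectomes and planted datasets reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import eigencoupling as ec


@pytest.fixture(scope="session")
def sc60():
    return ec.generate_structural_connectome(60, 0.3, decay_length=1.5, seed=7)


@pytest.fixture(scope="session")
def basis60(sc60):
    return ec.eigendecompose(ec.build_laplacian(sc60))


@pytest.fixture(scope="session")
def dense200():
    """Dense smooth connectome where low eigenmodes are well delocalized."""
    sc = ec.generate_structural_connectome(200, 0.7, decay_length=2.0, seed=11)
    return sc, ec.eigendecompose(ec.build_laplacian(sc))


@pytest.fixture(scope="session")
def hier100():
    """Hierarchical two-community connectome with mixed band planting."""
    sc, mask = ec.generate_hierarchical_connectome(100, 0.25, seed=13)
    basis = ec.eigendecompose(ec.build_laplacian(sc))
    gt = ec.banded_ground_truth(
        basis,
        low_indices=range(2, 11),
        high_indices=range(90, 101),
        transmodal_mask=mask,
        noise_sigma=0.02,
        seed=17,
        gradient=sc.coordinates[:, 2],
    )
    fc = ec.plant_functional_connectome(basis, gt)
    return sc, basis, gt, fc, mask


@pytest.fixture(scope="session")
def single_band_fc(basis60):
    """Noiseless FC planted entirely in the low band (modes 2..8)."""
    gt = ec.banded_ground_truth(basis60, range(2, 9), range(50, 61),
                                noise_sigma=0.0, seed=23)
    return gt, ec.plant_functional_connectome(basis60, gt)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
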