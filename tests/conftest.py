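"""Shared fixtures: a small NaCl slab and a coarse fitted grid.

The coarse grid (0.2 A spacing, short z window) is accurate enough for the
engine/scan behaviour tests while keeping the suite fast; the acceptance
tests build their own fine 0.1 A grid.
"""

import numpy as np
import pytest

from gridff import (FieldSet, GlobalParams, GridSpec, build_gridset,
                    build_rocksalt_slab)


@pytest.fixture(scope="session")
def params():
    return GlobalParams()


@pytest.fixture(scope="session")
def nacl(params):
    return build_rocksalt_slab(1, 1, 3)


@pytest.fixture(scope="session")
def coarse_gridset(nacl, params):
    spec = GridSpec(origin=(0.0, 0.0, 0.6), spacing=0.2, dims=(20, 20, 44))
    return build_gridset(nacl, spec, params)


@pytest.fixture(scope="session")
def coarse_fieldset(coarse_gridset):
    return FieldSet.from_gridset(coarse_gridset, tol=1e-9)


def single_atom_molecule(z, q=0.0, x=1.0, y=1.0, eps=0.004553, radius=1.9255):
    """One C-like atom as a minimal rigid adsorbate."""
    from gridff import Molecule

    return Molecule(["C"], np.array([[x, y, z]]), np.array([q]),
                    np.array([eps]), np.array([radius]),
                    np.array([12.011]))
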