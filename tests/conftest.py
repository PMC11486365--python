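import numpy as np
import pytest

from tango.chain_builder import TorsionPrescription, build_chain
from tango.torsion_core import AngleKind, ResidueTorsions


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def aform_model():
    """A-form-like 6-mer used as a generic parsed-structure stand-in."""
    return build_chain(TorsionPrescription.uniform("GCGCGC"))


def torsions_from_matrix(matrix, kinds):
    """Build synthetic ResidueTorsions records from an (n_res, n_kinds)
    array of degrees (NaN = undefined); geometry-free comparison inputs."""
    records = []
    for row in np.atleast_2d(np.asarray(matrix, dtype=float)):
        angles = {k: float("nan") for k in AngleKind}
        for kind, value in zip(kinds, row):
            angles[kind] = float(value)
        records.append(ResidueTorsions(angles=angles))
    return records
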