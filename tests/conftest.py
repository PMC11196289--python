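import dataclasses

import pytest

from vdsspred import (
    load_drug_table,
    load_method_constants,
    load_tissue_table,
)
from vdsspred.synthetic import synthetic_kn_constants


@pytest.fixture(scope="session")
def drugs():
    """Packaged four-drug table keyed by name."""
    return {d.name: d for d in load_drug_table()}


@pytest.fixture(scope="session")
def tissues():
    return load_tissue_table()


@pytest.fixture(scope="session")
def tissue_dicts(tissues):
    """Plain-dict view of the tissue table for the brute-force oracle."""
    return [
        {
            "tissue": t.tissue,
            "volume": t.volume,
            "f_nl": t.f_nl,
            "f_np": t.f_np,
            "f_ew": t.f_ew,
            "f_iw": t.f_iw,
            "albumin_ratio": t.albumin_ratio,
            "lipoprotein_ratio": t.lipoprotein_ratio,
        }
        for t in tissues
    ]


@pytest.fixture(scope="session")
def constants():
    return load_method_constants()


@pytest.fixture(scope="session")
def kn_constants(constants):
    """Method constants with the synthetic microsomal regression enabled."""
    return dataclasses.replace(
        constants,
        korzekwa_nagar=dataclasses.replace(
            constants.korzekwa_nagar, fum_regression=synthetic_kn_constants()
        ),
    )


@pytest.fixture(scope="session")
def observed(drugs):
    return {name: d.observed_vdss for name, d in drugs.items()}
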