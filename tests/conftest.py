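"""Shared fixtures: named reference molecules and a small trained bundle.

Everything is generated programmatically (no stored data files); the
session-scoped training fixtures keep the slow model fits to one pass.
"""

import pytest

from ffforge import mlmodels, synthdata

NAMED = ("methane", "ethane", "butane", "benzene", "cyclopentanone",
         "aniline", "1-octanol")


@pytest.fixture(scope="session")
def named_mols():
    return {name: synthdata.molecule_from_smiles(smi, name=name, seed=7)
            for name, smi in synthdata.NAMED_SMILES.items()}


@pytest.fixture(scope="session")
def fixture_set():
    """The default fixture set: 7 named anchors + 50 generated molecules."""
    return synthdata.fixture_molecules(seed=7, n_generated=50)


@pytest.fixture(scope="session")
def training_bundle_data(fixture_set):
    return synthdata.make_training_set(fixture_set)


@pytest.fixture(scope="session")
def trained_bundle(training_bundle_data):
    """All five heads trained on the 57-molecule set (CV skipped for speed;
    the acceptance suite exercises the full protocol at scale)."""
    return mlmodels.train_bundle(training_bundle_data, seed=7, cv_folds=0)
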