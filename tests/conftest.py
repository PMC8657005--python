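import numpy as np
import pytest

from msihet.peptide_id import build_peptide_table
from msihet.synthetic import SimConfig, generate_protein_fasta, simulate_msi_dataset


@pytest.fixture(scope="session")
def proteins():
    return generate_protein_fasta(25, 300, seed=7)


@pytest.fixture(scope="session")
def peptide_db(proteins):
    return build_peptide_table(proteins)


@pytest.fixture(scope="session")
def small_config():
    """Compact study design used by the mid-level integration tests."""
    return SimConfig(
        n_patients=3,
        rois_per_patient_per_class=2,
        pixels_per_roi=12,
        n_peptides=60,
        n_differential=8,
        fold_change=2.0,
        mz_range=(600.0, 1300.0),
        axis_spacing=0.02,
        peak_sigma_mz=0.012,
        drift_max_ppm=20.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, peptide_db):
    return simulate_msi_dataset(small_config, peptide_db)


@pytest.fixture(scope="session")
def noisefree_config(small_config):
    import dataclasses

    return dataclasses.replace(
        small_config,
        drift_max_ppm=0.0,
        noise_sd=0.0,
        baseline_scale=0.0,
        axis_spacing=0.01,
        peak_sigma_mz=0.008,
        pixels_per_roi=3,
        fold_change=1.0,
    )


@pytest.fixture(scope="session")
def noisefree_dataset(noisefree_config, peptide_db):
    return simulate_msi_dataset(noisefree_config, peptide_db)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
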