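"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from histomol import synthetic_data as sd


def noise_free_spec(tumor_class: str = "ccRCC", grid: int = 10,
                    seed: int = 7) -> sd.MsiPhantomSpec:
    """Phantom spec with every stochastic term switched off."""
    spec = sd.default_phantom_spec(tumor_class, seed=seed, grid=grid,
                                   noise_sd=0.0, baseline_amplitude=0.0,
                                   tic_variation_cv=0.0)
    spec.class_signature_peaks = {
        c: [(mz, m, 0.0) for mz, m, _cv in peaks]
        for c, peaks in spec.class_signature_peaks.items()
    }
    spec.shared_peaks = [(mz, m, 0.0) for mz, m, _cv in spec.shared_peaks]
    return spec


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free ccRCC phantom (tumor + stroma + background)."""
    return sd.generate_msi_phantom(noise_free_spec())


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise RO phantom."""
    return sd.generate_msi_phantom(sd.default_phantom_spec("RO", seed=11, grid=10))


@pytest.fixture(scope="session")
def protein_table():
    """Default-design protein table (28 patients, 30 informative proteins)."""
    return sd.generate_protein_table(sd.ProteomeDesign(seed=5))


@pytest.fixture(scope="session")
def small_protein_table():
    """Small, fast protein table: 60 proteins, 2 patients x 3 classes."""
    design = sd.ProteomeDesign(
        n_proteins_total=60, n_class_specific_per_class=5,
        patients_per_class={"ccRCC": 3, "RO": 3, "ChRCC": 3},
        spots_per_patient_range=(3, 3), n_contaminant_rows=2,
        n_reverse_rows=2, seed=9,
    )
    return sd.generate_protein_table(design)
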