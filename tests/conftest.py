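import numpy as np
import pytest

from phenogate.synth import SyntheticCellSpec, generate_cell_image


@pytest.fixture(scope="session")
def compact_cell():
    """One noiseless, blur-free compact cell with its ground truth."""
    spec = SyntheticCellSpec("compact", target_a=1.5, target_mi=2.0,
                             psf_sigma=0.0, noise_sd=0.0, seed=1)
    return generate_cell_image(spec)


@pytest.fixture(scope="session")
def dispersed_cell():
    """One noiseless, blur-free totally dispersed cell with ground truth."""
    spec = SyntheticCellSpec("totally_dispersed", target_a=15.0, target_mi=0.4,
                             psf_sigma=0.0, noise_sd=0.0, seed=7)
    return generate_cell_image(spec)


def brute_force_golgi_features(cell_mask, golgi_mask, golgi_channel, reference=100.0):
    """Independent pixel-counting oracle for (A, MI), written without the
    package's feature code: explicit loops over every pixel."""
    n_cell = n_golgi = 0
    golgi_sum = 0.0
    h, w = cell_mask.shape
    for i in range(h):
        for j in range(w):
            if cell_mask[i, j]:
                n_cell += 1
            if golgi_mask[i, j]:
                n_golgi += 1
                golgi_sum += float(golgi_channel[i, j])
    a = 100.0 * n_golgi / n_cell
    mi = (golgi_sum / n_golgi) / reference if n_golgi else float("nan")
    return a, mi
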