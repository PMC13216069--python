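import numpy as np
import pytest

from motifsyntax import Motif, PlantedModel, make_background_library


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def simple_motif():
    """A 5-position positive motif with distinct argmax bases (GATAA)."""
    cwm = np.zeros((4, 5))
    consensus = "GATAA"
    for j, b in enumerate(consensus):
        cwm["ACGT".index(b), j] = 0.5
        cwm[("ACGT".index(b) + 1) % 4, j] = 0.1
    ppm = np.full((4, 5), 0.1)
    for j, b in enumerate(consensus):
        ppm["ACGT".index(b), j] = 0.7
    return Motif(label="GATA", cwm=cwm, ppm=ppm, polarity="positive", n_seqlets=100)


@pytest.fixture(scope="session")
def small_planted():
    """Planted model on a 200-bp window: one +0.5 and one -0.3 motif, no jitter."""
    return PlantedModel(
        baseline=2.0,
        motif_effects={"GATAACCG": 0.5, "CACCTGGT": -0.3},
        fold_jitter_sd=0.0,
        window_length=200,
        profile_length=100,
        n_folds=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_library(small_planted):
    return make_background_library(
        n=8,
        length=200,
        gc_target=0.5,
        tolerance=0.1,
        forbidden_motifs=list(small_planted.motif_effects),
        seed=3,
    )
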