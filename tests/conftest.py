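import numpy as np
import pandas as pd
import pytest

from eelvision.msp import Spectrum
from eelvision.synthetic import SpectrumSimConfig, simulate_spectra

WL = np.arange(350.0, 750.5, 1.0)


def metadata_for(spectra) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": s.cell_id,
                "specimen_id": s.specimen_id,
                "stage": s.stage,
                "cell_type": s.cell_type,
            }
            for s in spectra
        ]
    )


@pytest.fixture(scope="session")
def noiseless_a1_493() -> Spectrum:
    cfg = SpectrumSimConfig(true_lambda_max=493.0, chromophore="A1",
                            n_cells=1, noise_sd=0.0, seed=11)
    return simulate_spectra(cfg)[0]


@pytest.fixture(scope="session")
def noiseless_a2_520() -> Spectrum:
    cfg = SpectrumSimConfig(true_lambda_max=520.0, chromophore="A2",
                            n_cells=1, noise_sd=0.0, seed=12)
    return simulate_spectra(cfg)[0]
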