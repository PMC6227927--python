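import numpy as np
import pytest

import synchrofluor as sf
from synchrofluor import quantitation as qt
from synchrofluor import synth_spectra as ss


@pytest.fixture(scope="session")
def models():
    """Default BAM/TEB band models, zero-crossing-validated once per session."""
    return ss.default_bam_teb_models(validate=True)


@pytest.fixture(scope="session")
def assays():
    bam_assay, teb_assay = qt.default_assays()
    return {"BAM": bam_assay, "TEB": teb_assay}


@pytest.fixture(scope="session")
def noiseless_curves(models, assays):
    """Calibration curves fitted from noiseless simulated series."""
    curves = {}
    for model in models:
        assay = assays[model.name]
        samples = ss.generate_calibration_set(model, noise=None, seed=0)
        amps = [qt.measure(s.eem, assay) for s in samples]
        concs = [s.concentrations[model.name] for s in samples]
        curves[model.name] = sf.fit_calibration(
            concs, amps, analyte=model.name, wavelength=assay.readout_wavelength
        )
    return curves


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
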