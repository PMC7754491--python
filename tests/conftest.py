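import numpy as np
import pytest

from plastevol.synthdata import GeneratorParams, LineMeta


@pytest.fixture
def clean_params():
    """Generator with no contaminants, no ontogeny and no growth noise."""
    return GeneratorParams(
        debris_fraction=0.0,
        dead_fraction=0.0,
        doublet_fraction=0.0,
        ontogeny_amp1=0.0,
        ontogeny_amp2=0.0,
        growth_noise_sd=0.0,
    )


def make_line(line_id="L0", rho2=0.5, strain="A", regime="fluctuating"):
    rho = np.sqrt(rho2)
    return LineMeta(
        line_id=line_id,
        strain=strain,
        regime=regime,
        treatment_rho_bar=None if regime == "constant" else rho,
        realized_rho=np.nan if regime == "constant" else rho,
        predictability=np.nan if regime == "constant" else rho2,
    )
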