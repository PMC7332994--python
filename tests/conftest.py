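import numpy as np
import pytest

from ecmturnover import (
    fit_anterograde,
    fit_logistic,
    fit_retrograde,
    generate_embryo_traces,
    smooth_moving_average,
    subtract_autofluorescence,
)
from ecmturnover.synthetic import perl_scenario

#: Ground-truth half-lives (h) spanning the modeled and pulse-chase regimes.
RECOVERY_TRUTHS = (7.0, 10.0, 14.0)


@pytest.fixture(scope="session")
def recovery_ensembles():
    """Closed-loop ensembles: generate -> preprocess -> logistic -> both fits.

    For each ground-truth half-life, 10 Perlecan-like embryos (2% noise,
    fixed seed) are pushed through the full inference chain; the fixture
    yields the scenario plus per-embryo anterograde and retrograde fits.
    Session-scoped because several tests interrogate the same ensembles.
    """
    out = {}
    for hl in RECOVERY_TRUTHS:
        sc = perl_scenario(hl, noise_sd=0.02, n_embryos=10, seed=42)
        ds = generate_embryo_traces(sc)
        controls = [smooth_moving_average(c) for c in ds.controls]
        antero, retro = [], []
        for tr in ds.embryos:
            f = subtract_autofluorescence(smooth_moving_average(tr), controls)
            lf = fit_logistic(f)
            antero.append(fit_anterograde(sc.mrna_program, lf))
            retro.append(fit_retrograde(lf, sc.mrna_program))
        out[hl] = (sc, antero, retro)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
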