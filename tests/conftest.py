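import numpy as np
import pytest

from invade import synth

INVADER = "Solidago canadensis"


@pytest.fixture(scope="session")
def landscape():
    """Default synthetic environmental stack (60x60, 0.5 km cells)."""
    return synth.gen_landscape(synth.LandscapeSpec(seed=5))


@pytest.fixture(scope="session")
def masked_landscape():
    """Stack with a contiguous nodata region (about 30% of the grid)."""
    return synth.gen_landscape(
        synth.LandscapeSpec(n_rows=40, n_cols=40, nodata_fraction=0.3, seed=9)
    )


@pytest.fixture(scope="session")
def survey_plots(landscape):
    """Moderate-size synthetic survey for unit tests."""
    return synth.gen_survey(landscape, synth.SurveySpec(n_plots=200, seed=0))


@pytest.fixture(scope="session")
def occurrences_and_background(landscape):
    """Occurrences from a known truth model plus a background sample."""
    from invade import maxent

    truth = synth.TruthModel(coef_linear={"bio16": 0.25, "bio6": 0.6})
    occ = synth.gen_occurrences(landscape, truth, n=300, seed=2)
    bg_env, bg_xy = maxent.sample_background(landscape, n=1500, seed=3)
    pres_env = landscape.sample(occ.points[:, 0], occ.points[:, 1])
    assert not np.isnan(pres_env).any()
    return {"truth": truth, "occ": occ, "pres_env": pres_env, "bg_env": bg_env}
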