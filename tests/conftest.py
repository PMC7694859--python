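import pytest

import echoref as er


@pytest.fixture(scope="session")
def default_cohort():
    """Full default synthetic screening cohort (seed 0)."""
    return er.generate_cohort(er.SimConfig(seed=0, truth=er.default_truth()))


@pytest.fixture(scope="session")
def screened_cohort(default_cohort):
    screened, _ = er.screen_cohort(default_cohort)
    return screened


@pytest.fixture(scope="session")
def lvdd_fit(screened_cohort):
    return er.fit_allometric(screened_cohort.nonsighthound(), "LVDd")


@pytest.fixture(scope="session")
def noise_free_truth():
    """Truth with every noise source switched off and no deviant breeds."""
    truth = er.default_truth()
    truth.sigma_log = {v: 0.0 for v in er.VARIABLES}
    truth.examiner_sd_log = 0.0
    truth.outlier_rate = 0.0
    for br in truth.breeds:
        br.multipliers = {}
    return truth


def law_abiding_cohort(seed: int, n_total: int):
    """Cohort of the breeds that follow the population law exactly
    (deviance multiplier 1.0), rescaled to about ``n_total`` dogs."""
    truth = er.default_truth()
    law = [
        br.name
        for br in truth.breeds
        if not br.sighthound and not br.multipliers
    ]
    base = sum(br.n for br in truth.breeds if br.name in law)
    n_over = {
        br.name: (int(round(br.n * n_total / base)) if br.name in law else 0)
        for br in truth.breeds
    }
    return er.generate_cohort(
        er.SimConfig(seed=seed, truth=truth, n_per_breed=n_over)
    )
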