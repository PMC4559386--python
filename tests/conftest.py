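import numpy as np
import pandas as pd
import pytest

from tempodisc import CohortConfig, build_choice_design, generate_cohort


def threshold_choices(design: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Deterministic monotone responder: sooner iff amount >= threshold.

    For 0 < threshold <= 20 this answers every catch trial logically
    (0 euros -> later, 20 euros -> sooner).
    """
    out = design.copy()
    out["choice"] = np.where(
        out["sooner_amount"] >= threshold, "sooner", "later"
    )
    return out


@pytest.fixture
def design():
    return build_choice_design("P001", seed=123)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_participants=20, seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=7))
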