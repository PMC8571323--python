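import numpy as np
import pandas as pd
import pytest

from endomark.simulate import CohortSimConfig, generate_trial_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    return generate_trial_cohort(CohortSimConfig(seed=11))


@pytest.fixture(scope="session")
def null_config_kwargs() -> dict:
    """Generating model with no biomarker effect in either arm."""
    return dict(
        n_per_arm={"TDM1P": 52, "TH": 31},
        beta0=-1.4,
        beta_arm=1.0,
        beta_marker=0.0,
        beta_interaction=0.0,
        beta_hr=0.8,
    )


@pytest.fixture(scope="session")
def strong_interaction_cohort() -> pd.DataFrame:
    """A cohort with a clear biomarker×treatment interaction."""
    cfg = CohortSimConfig(
        seed=7,
        n_per_arm={"TDM1P": 200, "TH": 200},
        biomarker_mean={"TDM1P": 10.35, "TH": 10.35},
        beta0=-1.1,
        beta_arm=-0.63,
        beta_marker=0.0,
        beta_interaction=2.58,
        beta_hr=0.0,
        breakpoint=10.35,
    )
    return generate_trial_cohort(cfg)


def make_two_arm_cohort(x_exp, y_exp, x_ctrl, y_ctrl) -> pd.DataFrame:
    """Assemble a minimal two-arm cohort from explicit marker/outcome vectors."""
    rows = []
    for arm, xs, ys in (("TDM1P", x_exp, y_exp), ("TH", x_ctrl, y_ctrl)):
        for i, (x, y) in enumerate(zip(xs, ys)):
            rows.append(
                {
                    "patient_id": f"{arm}-{i:03d}",
                    "arm": arm,
                    "hr_status": "HRpos",
                    "pcr": bool(y),
                    "platform": "P32627",
                    "RAB4A": 0.0,
                    "RAB5A": float(x),
                    "RAB11A": 0.0,
                    "ERBB2": 0.0,
                }
            )
    return pd.DataFrame(rows)
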