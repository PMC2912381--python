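from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

DATA_DIR = Path(__file__).parent / "data"

# significance codes of the secondary-screen fixture -> representative P
# values inside each printed bound (ns: P>0.1; m: 0.05<P<0.1; 1..4: the
# star codes P<0.05, <0.01, <0.001, <0.0001)
SIG_P = {"ns": 0.5, "m": 0.075, "1": 0.03, "2": 0.005, "3": 0.0005, "4": 0.00005}


@pytest.fixture(scope="session")
def longlived_lines() -> pd.DataFrame:
    """Secondary-screen fixture: the 58 long-lived insertion lines with
    their percent deviations, standardised effects a/sigma_P, ANOVA
    significance codes, and published sex-effect category."""
    return pd.read_csv(DATA_DIR / "longlived_lines.csv", dtype={c: str for c in
                       ("sig_L", "sig_LxS", "sig_L_male", "sig_L_female")})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture()
def small_survival() -> pd.DataFrame:
    """A tiny valid survival table: 2 lines x 2 sexes x 2 vials x 3 flies."""
    rows = []
    age = iter([40, 42, 44, 50, 52, 54, 46, 48, 50, 56, 58, 60,
                38, 40, 42, 48, 50, 52, 44, 46, 48, 54, 56, 58])
    for line in ("control", "L0001"):
        for sex in ("male", "female"):
            for vial in ("v1", "v2"):
                for _ in range(3):
                    rows.append(
                        {"block": "b1", "line": line, "sex": sex,
                         "vial": vial, "death_age": next(age)}
                    )
    return pd.DataFrame(rows)
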