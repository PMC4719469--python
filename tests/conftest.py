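import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from kalnirs.hrf import HRFParameters, discretize_hrf
from kalnirs.simulate import NoiseConfig, ProtocolConfig, simulate_experiment


@pytest.fixture(scope="session")
def params():
    """Canonical HRF parameters (delta 2 s, tau 1.5 s, 2 Hz)."""
    return HRFParameters(delta=2.0, tau=1.5, fs=2.0)


@pytest.fixture(scope="session")
def model(params):
    return discretize_hrf(params)


@pytest.fixture(scope="session")
def atc_subject():
    """One simulated ATC-protocol subject with default noise."""
    proto = ProtocolConfig.atc()
    noise = NoiseConfig.default(proto)
    return simulate_experiment(proto, noise, seed=7)


@pytest.fixture(scope="session")
def atc_features(atc_subject):
    """Kalman-filtered trial features for the ATC subject."""
    from kalnirs.features import extract_trial_features
    from kalnirs.pipeline import filter_recording

    rec, ev, _ = atc_subject
    filt = filter_recording(rec, ev, "kalman_augmented", qr_ratio=0.5,
                            chromophores=("HbO2",))
    return extract_trial_features(filt, ev)


def make_features(values_by_level: dict, optode: int = 1) -> pd.DataFrame:
    """Tidy feature table from {level: [per-subject values]}."""
    rows = []
    onset = 0.0
    for level, vals in values_by_level.items():
        for s, v in enumerate(vals):
            rows.append({
                "subject_id": f"S{s + 1:02d}", "optode": optode,
                "level": level, "delta_hbo2": float(v),
                "delta_hhb": -0.3 * float(v), "onset_s": onset,
            })
            onset += 40.0
    return pd.DataFrame(rows)
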