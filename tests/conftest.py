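import numpy as np
import pandas as pd
import pytest

from memoryprime import SimConfig

# proportions used by the planted-recovery simulation study: only the three
# Class-B-relevant classes plus unresponsive background, so the conditional
# Class-B composition is 0.16 : 0.025 : 0.014 ~ 80.4 / 12.6 / 7.0 percent
RECOVERY_PROPORTIONS = {
    "null": 0.801,
    "deprimed": 0.160,
    "persistent_primed": 0.025,
    "transgressive": 0.014,
}


@pytest.fixture
def zero_noise_config():
    """Noise-free, bias-free experiment: every ratio is an exact planted effect."""
    return SimConfig(
        n_transcripts=400,
        noise_sd_log2=0.0,
        dye_bias_coeffs=(0.0,),
        seed=7,
    )


def make_contrast_table(entries: dict[str, tuple[float, str]]) -> pd.DataFrame:
    """Minimal ContrastTable from {transcript_id: (p, direction)}."""
    ids = list(entries)
    p = np.array([entries[t][0] for t in ids])
    direction = [entries[t][1] for t in ids]
    mean = np.where(np.array(direction) == "up", 1.0, -1.0)
    return pd.DataFrame(
        {"mean_M": mean, "p": p, "direction": direction, "is_de": p < 0.05},
        index=pd.Index(ids, name="transcript_id"),
    )
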