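import numpy as np
import pandas as pd
import pytest

from actinomet.preprocess import FilterParams, filter_media, merge_modes, subtract_blanks
from actinomet.synthdata import SynthConfig, generate_experiment
from actinomet.tabio import FeatureTable


def make_feature_table(
    intensities: dict[str, list[float]],
    roles: dict[str, str],
    mz=None,
    mode: str = "positive",
    prefix: str = "F",
) -> FeatureTable:
    """Small helper: build a FeatureTable from a samples->values mapping."""
    frame = pd.DataFrame(intensities, dtype=float)
    n = len(frame)
    frame.index = pd.Index([f"{prefix}{i + 1}" for i in range(n)], name="feature_id")
    if mz is None:
        mz = np.linspace(150.0, 900.0, n)
    return FeatureTable(
        intensities=frame,
        mz=pd.Series(np.asarray(mz, dtype=float), index=frame.index),
        rt=pd.Series(np.linspace(1.0, 10.0, n), index=frame.index),
        sample_roles=roles,
        mode=mode,
    )


@pytest.fixture(scope="session")
def experiment():
    """One default synthetic experiment shared by read-only tests."""
    return generate_experiment(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def merged_clean(experiment):
    """The same experiment after blank/medium filters and mode merging."""
    pi, ni, _, _ = experiment
    params = FilterParams()
    return merge_modes(
        filter_media(subtract_blanks(pi, params), params),
        filter_media(subtract_blanks(ni, params), params),
    )
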