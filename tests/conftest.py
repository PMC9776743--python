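import pandas as pd
import pytest

from fgbkit import MeasurementModel, build_registry


@pytest.fixture(scope="session")
def registry():
    return build_registry(barcode_length=30, seed=1)


@pytest.fixture(scope="session")
def equal_mix(registry):
    """48 clones at equal fractions."""
    return pd.Series(1.0 / 48, index=registry.bc_ids)


@pytest.fixture(scope="session")
def default_model():
    return MeasurementModel()


@pytest.fixture(scope="session")
def fitted_thresholds(registry, equal_mix, default_model):
    """Thresholds fitted once on a clean 20k-event acquisition."""
    from fgbkit import fit_thresholds, generate_events

    events = generate_events(equal_mix, 20_000, default_model, registry, seed=11)
    return fit_thresholds(events, method="mixture2", seed=0)
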