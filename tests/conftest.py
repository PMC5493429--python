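import numpy as np
import pytest

from kcna5.ikur import wt_model, mutant_model


@pytest.fixture(scope="session")
def wt():
    return wt_model()


@pytest.fixture(scope="session")
def mutants():
    return {label: mutant_model(label)
            for label in ("D332H", "E48G", "A305T", "Y155C", "D469E", "P488S")}


@pytest.fixture(scope="session")
def voltage_grid():
    """1 mV grid over the physiological clamp range."""
    return np.arange(-100.0, 80.0 + 0.5, 1.0)


@pytest.fixture(scope="session")
def paced_metrics():
    """AP metrics of every lineage x mutation at 1 Hz (lone AF), shared.

    Computed once per session; several ordering and invariant tests consume
    this table.
    """
    from kcna5.ap_metrics import measure_ap
    from kcna5.cells.base import PacingProtocol, build_cell, pace

    out = {}
    proto = PacingProtocol(n_s1=12, s1_cl=1000.0)
    for model_id in ("courtemanche", "courtemanche_newIKur", "grandi"):
        for mut in (None, "D332H", "E48G", "A305T", "Y155C", "D469E", "P488S"):
            cell = build_cell(model_id, mutation=mut)
            t, v = pace(cell, proto, tail=1000.0)
            out[(model_id, mut or "WT")] = measure_ap(t, v, proto.onsets(),
                                                      beat=-1)
    return out


@pytest.fixture(scope="session")
def caf_metrics():
    """AP metrics under chronic-AF remodelling at 1 Hz, shared."""
    from kcna5.ap_metrics import measure_ap
    from kcna5.cells.base import PacingProtocol, build_cell, pace

    out = {}
    proto = PacingProtocol(n_s1=12, s1_cl=1000.0)
    for model_id in ("courtemanche", "courtemanche_newIKur", "grandi"):
        for mut in (None, "D332H", "E48G", "A305T", "Y155C", "D469E", "P488S"):
            cell = build_cell(model_id, mutation=mut, caf=True)
            t, v = pace(cell, proto, tail=1000.0)
            out[(model_id, mut or "WT")] = measure_ap(t, v, proto.onsets(),
                                                      beat=-1)
    return out
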