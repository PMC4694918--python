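import numpy as np
import pandas as pd
import pytest

from tsmir.containers import ExprMatrix, SurvivalTable


def make_expr(values, feature_ids=None, sample_ids=None, meta=None, **kw):
    """Small helper: ExprMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    if meta is None:
        meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    return ExprMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids), meta, **kw
    )


def make_survival(times, events):
    ids = [f"s{i}" for i in range(len(times))]
    return SurvivalTable(
        pd.DataFrame(
            {"time": np.asarray(times, float), "event": np.asarray(events, int)},
            index=pd.Index(ids, name="sample_id"),
        )
    )


@pytest.fixture
def paired_screen():
    """Treated/control pair with two planted 4-fold miRNAs, zero noise."""
    from tsmir.simulate import gen_unmasking_experiment

    return gen_unmasking_experiment(
        n_mirna=20, n_silenced=2, n_lines=4, effect_range=(4.0, 4.0),
        noise_sd=0.0, seed=11,
    )
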