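import numpy as np
import pandas as pd
import pytest

import thymotrace as tt


@pytest.fixture(scope="session")
def default_events():
    """10,000 untreated events from the default marker model."""
    return tt.gen_cytometry_events(tt.CytometrySimConfig(n_events=10_000, seed=11))


@pytest.fixture(scope="session")
def staged(default_events):
    """Transformed events, fitted valley thresholds and stage labels."""
    transformed = tt.arcsinh_transform(default_events)
    thresholds = tt.fit_positivity_thresholds(transformed, method="valley")
    labels = tt.assign_stages(transformed, thresholds)
    return transformed, thresholds, labels


@pytest.fixture(scope="session")
def default_expression():
    """Default synthetic expression matrix with its planted truth."""
    return tt.gen_expression_matrix(tt.ExpressionSimConfig(seed=7))


@pytest.fixture(scope="session")
def curve_events():
    """700 cells on a noiseless 1-D curve in 6-D, 100 per population.

    Returns (EventMatrix, curve parameter). Evenly spaced sampling keeps
    the k-NN graph of the curve connected.
    """
    t = np.linspace(0.0, 1.0, 700)
    X = np.column_stack(
        [np.sin(2 * t), np.cos(2 * t), t**2, t, 0.5 * np.sin(3 * t), 0.3 * t]
    )
    pops = np.repeat(list(tt.STAGES), 100)
    events = tt.EventMatrix(
        pd.DataFrame(X, columns=list(tt.REQUIRED_MARKERS)),
        pd.DataFrame({"true_stage": pops}),
        transformed=True,
    )
    return events, t


def make_clonotype_table(counts, cdr3aa=None, v=None):
    """Small literal clonotype table for arithmetic tests."""
    n = len(counts)
    counts = np.asarray(counts)
    df = pd.DataFrame(
        {
            "count": counts,
            "freq": counts / counts.sum(),
            "cdr3nt": [f"TGTGCT{'AAA' * i}TTT" for i in range(n)],
            "cdr3aa": cdr3aa if cdr3aa is not None else ["CAF"] * n,
            "v": v if v is not None else ["TRDV1"] * n,
            "d": ["TRDD1"] * n,
            "j": ["TRDJ1"] * n,
        }
    )
    return tt.ClonotypeTable(df)
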