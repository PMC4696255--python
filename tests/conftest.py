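"""Shared fixtures: a hand-built QC matrix with a fully hand-computed
ledger, small simulated datasets, and helpers to build normalized
matrices without the (slow) imputation step when nothing is missing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from arraycascade import (
    ArraySimConfig,
    EffectSpec,
    FlaggedMatrix,
    NormalizedMatrix,
    quantile_normalize,
    simulate_arrays,
    to_log2,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

NAN = float("nan")


@pytest.fixture(scope="session")
def hand_qc_matrix() -> FlaggedMatrix:
    """12 probes x 6 arrays exercising every QC rule.

    Expected ledger (hand enumeration, see test_qc / test_acceptance):
    controls 1; poor values 7 (P03, P06, P10 x2, P12 x3); negative values 1
    (P04; P06's negative cell counts as poor by precedence); rule A probes
    3 (P05 pre-existing missing, P10 and P12 via poor-masking); rule B
    probes 1 (P07, all values at threshold); outlier values 1 (P08's 41
    vs group median 10); 7 probes remain, 4 of them with 4 missing values.
    """
    arrays = ["A1", "A2", "A3", "B1", "B2", "B3"]
    group_of = {a: ("g1" if a.startswith("A") else "g2") for a in arrays}
    rows = {
        # pid: (is_control, values, flags)
        "P01": (True, [100, 100, 100, 100, 100, 100], "GGGGGG"),
        "P02": (False, [100, 100, 100, 100, 100, 100], "GGGGGG"),
        "P03": (False, [100, 100, 100, 100, 100, 100], "LGGGGG"),
        "P04": (False, [100, -50, 100, 100, 100, 100], "GGGGGG"),
        "P05": (False, [NAN, NAN, 100, 100, 100, 100], "GGGGGG"),
        "P06": (False, [-30, 100, 100, 100, 100, 100], "LGGGGG"),
        "P07": (False, [0, 0, 0, 0, 0, 0], "GGGGGG"),
        "P08": (False, [10, 10, 10, 10, 10, 41], "GGGGGG"),
        "P09": (False, [10, 10, 10, 10, 10, 40], "GGGGGG"),
        "P10": (False, [100, 100, 100, 100, 100, 100], "LLGGGG"),
        "P11": (False, [50, 60, 55, 70, 80, 75], "GGGGGG"),
        "P12": (False, [100, 100, 100, 100, 100, 100], "LLLGGG"),
    }
    return FlaggedMatrix(
        probe_ids=list(rows),
        array_ids=arrays,
        intensities=np.array([v for _, v, _ in rows.values()], dtype=float),
        flags=np.array([list(f) for _, _, f in rows.values()], dtype=object),
        is_control=np.array([c for c, _, _ in rows.values()]),
        gene_symbols=[f"SYM_{p}" for p in rows],
        group_of=group_of,
    )


def normalized_from_complete(m: FlaggedMatrix) -> NormalizedMatrix:
    """Quantile-normalize + log2 a complete (no-missing) flagged matrix,
    bypassing the imputation stage that would have nothing to do."""
    values = to_log2(quantile_normalize(m.intensities))
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=m.probe_ids, columns=m.array_ids),
        imputed=pd.DataFrame(False, index=m.probe_ids, columns=m.array_ids),
        group_of=dict(m.group_of),
    )


def clean_spiked_config(seed: int, n_probes: int = 10_000, frac_de: float = 0.05,
                        delta: float = 2.0) -> ArraySimConfig:
    """Corruption-free two-group design with fixed +/-delta spikes."""
    return ArraySimConfig(
        n_probes=n_probes,
        n_control=0 if n_probes < 2000 else 200,
        frac_de=frac_de,
        effect=EffectSpec(kind="fixed", value=delta, p_up=0.5),
        frac_poor_flag=0.0,
        frac_negative=0.0,
        frac_missing=0.0,
        frac_outlier=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Default-corruption simulation at reduced size, with ground truth."""
    cfg = ArraySimConfig(n_probes=3_000, n_control=200, seed=11)
    return simulate_arrays(cfg)
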