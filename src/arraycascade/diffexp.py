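"""Two-group differential expression on log2 expression values.

Classical pooled-variance Student's t-test per probe, Benjamini-Hochberg
FDR across probes, signed linear fold change from the log2 group-mean
difference, and the three-tier significance labelling used for reporting:

    L1 (high):  |FC| >= 2 and FDR q <= 0.01
    L2:         exactly one of the L1 conditions holds while the other
                falls in the low band (1.5 < |FC| < 2, or 0.01 < q <= 0.05)
    L3 (low):   both conditions fall in the low band

The signed fold-change convention is the one standard in microarray
reports: FC = 2^delta for delta >= 0 and -2^(-delta) for delta < 0, where
delta is the treated-minus-reference log2 mean difference, so a halving is
reported as -2 rather than 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .normalize import NormalizedMatrix


@dataclass(frozen=True)
class TierBands:
    fc_high: float = 2.0
    q_high: float = 0.01
    fc_low: float = 1.5
    q_low: float = 0.05


def t_test_two_group(
    x: np.ndarray, groups: np.ndarray, use_welch: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test.

    ``groups`` is a boolean/int vector marking the second (treated) group.
    Returns (t, p, degenerate); rows with zero pooled variance get t = 0,
    p = 1 and degenerate = True rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(groups).astype(bool)
    x1, x2 = x[:, ~g], x[:, g]
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError("each group needs at least two arrays")
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    if use_welch:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / (
            np.where(se2 > 0, (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1), 1)
        )
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full(x.shape[0], n1 + n2 - 2, dtype=float)
    degenerate = se2 <= 0
    se = np.sqrt(np.where(degenerate, 1.0, se2))
    t = np.where(degenerate, 0.0, (m2 - m1) / se)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, p, degenerate


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(delta: np.ndarray) -> np.ndarray:
    """Signed linear fold change from a log2 difference (FC = 1 at 0)."""
    delta = np.asarray(delta, dtype=float)
    return np.where(delta >= 0, np.exp2(delta), -np.exp2(-delta))


def call_levels(
    fc: np.ndarray, q: np.ndarray, bands: TierBands = TierBands()
) -> np.ndarray:
    """Assign the L1/L2/L3/none significance tier per probe."""
    afc = np.abs(np.asarray(fc, dtype=float))
    q = np.asarray(q, dtype=float)
    fc_high = afc >= bands.fc_high
    q_high = q <= bands.q_high
    fc_low = (afc > bands.fc_low) & (afc < bands.fc_high)
    q_low = (q > bands.q_high) & (q <= bands.q_low)
    level = np.full(afc.shape, "none", dtype=object)
    level[(fc_high & q_low) | (q_high & fc_low)] = "L2"
    level[fc_low & q_low] = "L3"
    level[fc_high & q_high] = "L1"
    return level


def differential_expression(
    nm: NormalizedMatrix,
    reference: str | None = None,
    treatment: str | None = None,
    bands: TierBands = TierBands(),
    use_welch: bool = False,
) -> pd.DataFrame:
    """Full per-probe DE table, indexed by probe id.

    Columns: mean_ref, mean_trt, delta (log2, treated minus reference),
    fc (signed linear), t, p, q, level, direction, degenerate.
    """
    groups = nm.groups
    if len(groups) != 2:
        raise DataError(f"exactly two groups required, got {groups}")
    if reference is None:
        reference = groups[0]
    if treatment is None:
        treatment = next(g for g in groups if g != reference)
    if reference not in groups or treatment not in groups:
        raise ConfigError(f"groups {reference!r}/{treatment!r} not in {groups}")

    cols = list(nm.values.columns)
    is_trt = np.array([nm.group_of[a] == treatment for a in cols])
    x = nm.values.to_numpy()
    t, p, degenerate = t_test_two_group(x, is_trt, use_welch=use_welch)
    q = bh_fdr(p)
    m_ref = x[:, ~is_trt].mean(axis=1)
    m_trt = x[:, is_trt].mean(axis=1)
    delta = m_trt - m_ref
    fc = fold_change(delta)
    level = call_levels(fc, q, bands)
    direction = np.where(delta > 0, "up", np.where(delta < 0, "down", "flat"))
    return pd.DataFrame(
        {
            "mean_ref": m_ref,
            "mean_trt": m_trt,
            "delta": delta,
            "fc": fc,
            "t": t,
            "p": p,
            "q": q,
            "level": level,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=pd.Index(nm.values.index, name="probe_id"),
    )


def significant_set(
    res: pd.DataFrame, fc_cut: float = 2.0, q_cut: float = 0.01
) -> tuple[list[str], list[str]]:
    """Probe ids with q <= q_cut and |FC| >= fc_cut, split up/down."""
    sig = res[(res["q"] <= q_cut) & (res["fc"].abs() >= fc_cut)]
    up = list(sig.index[sig["delta"] > 0])
    down = list(sig.index[sig["delta"] < 0])
    return up, down


def top_table(res: pd.DataFrame, symbols: dict[str, str] | None = None,
              n: int = 10) -> pd.DataFrame:
    """Report-style top table sorted by q then |FC|."""
    ordered = res.assign(_afc=res["fc"].abs()).sort_values(
        ["q", "_afc"], ascending=[True, False]
    )
    out = ordered.drop(columns="_afc").head(n)[["fc", "q", "level", "direction"]]
    if symbols:
        out = out.assign(symbol=[symbols.get(p, "") for p in out.index])
    return out
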