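"""Flag-aware quality-control cascade for single-channel arrays.

Stages, applied in this fixed order:

1. drop control probes (probe level)
2. mask values with a non-good quality flag (value level)
3. mask remaining negative values (value level)
4. drop probe sets where any group has >= 50 % missing values (probe level)
5. drop probe sets where no group has >= 50 % good-flagged values and
   >= 50 % values above threshold (probe level)
6. mask values deviating more than fourfold from their group median
   (value level)

Masked values become missing (NaN) and are imputed downstream; only probe-
level stages shrink the matrix. Every stage appends a record to the
:class:`FilterReport` ledger, including the denominator its percentage was
computed against, so runs can be audited line by line.

Denominator conventions: value-level stages 2-3 are reported against the
total raw cell count of the input matrix (probes x arrays before control
removal); probe-level stages 4-5 against the post-control probe count; the
outlier stage against the cell count of the matrix that survives probe
filtering; residual-missing statistics against the final matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, PipelineError
from .io import FlaggedMatrix


@dataclass(frozen=True)
class QcConfig:
    good_flag: str = "G"
    above_threshold: float = 0.0
    group_missing_frac: float = 0.5
    group_good_frac: float = 0.5
    outlier_fold: float = 4.0

    def __post_init__(self):
        for name in ("group_missing_frac", "group_good_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name}={v} outside (0, 1]")
        if self.outlier_fold <= 1.0:
            raise ConfigError(f"outlier_fold={self.outlier_fold} must be > 1")


@dataclass(frozen=True)
class StageRecord:
    stage: str
    unit: str  # "probe sets" | "values"
    n_removed: int
    denominator: int

    @property
    def percent_removed(self) -> float:
        if self.denominator == 0:
            return 0.0
        return round(100.0 * self.n_removed / self.denominator, 1)


@dataclass
class FilterReport:
    """Per-stage removal ledger plus end-state totals."""

    stages: list[StageRecord] = field(default_factory=list)
    probes_in: int = 0
    probes_remaining: int = 0
    probesets_with_missing: int = 0
    n_missing_values_remaining: int = 0

    def record(self, rec: StageRecord) -> None:
        self.stages.append(rec)

    def __getitem__(self, stage: str) -> StageRecord:
        for rec in self.stages:
            if rec.stage == stage:
                return rec
        raise KeyError(stage)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": r.stage,
                "unit": r.unit,
                "n_removed": r.n_removed,
                "denominator": r.denominator,
                "percent_removed": r.percent_removed,
            }
            for r in self.stages
        ]
        rows.append(
            {
                "stage": "remaining",
                "unit": "probe sets",
                "n_removed": self.probes_remaining,
                "denominator": self.probes_in,
                "percent_removed": float("nan"),
            }
        )
        rows.append(
            {
                "stage": "probesets_with_missing",
                "unit": "probe sets",
                "n_removed": self.probesets_with_missing,
                "denominator": self.probes_remaining,
                "percent_removed": round(
                    100.0 * self.probesets_with_missing / self.probes_remaining, 1
                )
                if self.probes_remaining
                else 0.0,
            }
        )
        return pd.DataFrame(rows)


def _group_indices(m: FlaggedMatrix) -> dict[str, np.ndarray]:
    groups = m.groups
    if len(groups) != 2:
        raise PipelineError("qc", f"exactly two groups required, got {groups}")
    return {g: m.array_indices_of_group(g) for g in groups}


def drop_controls(m: FlaggedMatrix) -> tuple[FlaggedMatrix, StageRecord]:
    """Remove control probes; counted at probe level against all probes."""
    n_removed = int(m.is_control.sum())
    out = m.subset_probes(~m.is_control)
    return out, StageRecord("control_probes", "probe sets", n_removed, m.n_probes)


def mask_poor_and_negative(
    m: FlaggedMatrix,
    cfg: QcConfig = QcConfig(),
    value_denominator: int | None = None,
) -> tuple[FlaggedMatrix, StageRecord, StageRecord]:
    """Mask poorly flagged values, then negative values, to missing.

    A cell that is both poorly flagged and negative is counted once, as
    poor (flag precedence). ``value_denominator`` defaults to the cell
    count of ``m``; the pipeline passes the raw pre-control cell count.
    """
    den = value_denominator if value_denominator is not None else m.n_probes * m.n_arrays
    out = m.copy()
    observed = ~np.isnan(out.intensities)
    poor = (out.flags != cfg.good_flag) & observed
    out.intensities[poor] = np.nan
    negative = (out.intensities < 0) & ~poor
    out.intensities[negative] = np.nan
    return (
        out,
        StageRecord("poor_flag_values", "values", int(poor.sum()), den),
        StageRecord("negative_values", "values", int(negative.sum()), den),
    )


def drop_unreliable_probesets(
    m: FlaggedMatrix, cfg: QcConfig = QcConfig()
) -> tuple[FlaggedMatrix, StageRecord, StageRecord]:
    """Probe-level rules A (group missingness) and B (group reliability).

    Rule A removes a probe set if *any* group has a missing-value fraction
    >= ``group_missing_frac``. Rule B removes a survivor of A if *no*
    group simultaneously has >= ``group_good_frac`` of its values good-
    flagged and >= ``group_good_frac`` of its values strictly above
    ``above_threshold`` (missing values count as neither).
    """
    gidx = _group_indices(m)
    n_probes = m.n_probes
    miss = np.isnan(m.intensities)

    rule_a = np.zeros(n_probes, dtype=bool)
    for idx in gidx.values():
        frac = miss[:, idx].mean(axis=1)
        rule_a |= frac >= cfg.group_missing_frac

    good = (m.flags == cfg.good_flag) & ~miss
    above = np.where(~miss, m.intensities > cfg.above_threshold, False)
    any_reliable = np.zeros(n_probes, dtype=bool)
    for idx in gidx.values():
        g_ok = good[:, idx].mean(axis=1) >= cfg.group_good_frac
        a_ok = above[:, idx].mean(axis=1) >= cfg.group_good_frac
        any_reliable |= g_ok & a_ok
    rule_b = ~rule_a & ~any_reliable

    out = m.subset_probes(~(rule_a | rule_b))
    return (
        out,
        StageRecord("group_missingness", "probe sets", int(rule_a.sum()), n_probes),
        StageRecord("group_reliability", "probe sets", int(rule_b.sum()), n_probes),
    )


def mask_outliers(
    m: FlaggedMatrix, cfg: QcConfig = QcConfig()
) -> tuple[FlaggedMatrix, StageRecord]:
    """Mask values deviating more than ``outlier_fold`` from the group median.

    The test is a strict ratio on the raw linear scale: x is an outlier iff
    x/med > fold or med/x > fold, where med is the median of the non-missing
    values of the probe within the group. Groups with fewer than two
    non-missing values are skipped (no meaningful median).
    """
    gidx = _group_indices(m)
    out = m.copy()
    x = out.intensities
    mask = np.zeros_like(x, dtype=bool)
    for idx in gidx.values():
        sub = x[:, idx]
        n_obs = (~np.isnan(sub)).sum(axis=1)
        med = np.full(sub.shape[0], np.nan)
        has_obs = n_obs > 0
        med[has_obs] = np.nanmedian(sub[has_obs], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = sub / med[:, None]
            is_out = (ratio > cfg.outlier_fold) | (
                (med[:, None] / sub) > cfg.outlier_fold
            )
        is_out &= ~np.isnan(sub)
        is_out &= (n_obs >= 2)[:, None]
        is_out &= (med > 0)[:, None]
        mask[:, idx] = is_out
    x[mask] = np.nan
    den = m.n_probes * m.n_arrays
    return out, StageRecord("outlier_values", "values", int(mask.sum()), den)


def run_qc(
    m: FlaggedMatrix, cfg: QcConfig = QcConfig()
) -> tuple[FlaggedMatrix, FilterReport]:
    """Run the full cascade and assemble the removal ledger."""
    report = FilterReport(probes_in=m.n_probes)
    raw_cells = m.n_probes * m.n_arrays

    cur, rec = drop_controls(m)
    report.record(rec)
    if cur.n_probes == 0:
        raise PipelineError("control_probes", "no probes left after control removal")

    cur, rec_poor, rec_neg = mask_poor_and_negative(cur, cfg, value_denominator=raw_cells)
    report.record(rec_poor)
    report.record(rec_neg)

    cur, rec_a, rec_b = drop_unreliable_probesets(cur, cfg)
    report.record(rec_a)
    report.record(rec_b)
    if cur.n_probes == 0:
        raise PipelineError("group_reliability", "no probes left after probe-set rules")

    cur, rec_out = mask_outliers(cur, cfg)
    report.record(rec_out)

    report.probes_remaining = cur.n_probes
    miss = np.isnan(cur.intensities)
    report.probesets_with_missing = int(miss.any(axis=1).sum())
    report.n_missing_values_remaining = int(miss.sum())
    return cur, report
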