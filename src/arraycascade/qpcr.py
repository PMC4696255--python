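"""RT-qPCR relative quantification by the 2^-ddCq method.

Workflow: technical replicates are averaged per biological replicate
first (the biological replicates carry the degrees of freedom); each
target's Cq is referenced against the arithmetic mean of the reference
genes' Cq means (equivalent to the geometric mean of their quantities);
the resulting dCq is referenced against the calibrator group's mean dCq;
relative quantity RQ = 2^-ddCq, so the calibrator group has RQ = 1 by
construction.

Amplification efficiency is estimated from a dilution-series standard
curve (ordinary least squares of Cq on log10 quantity); efficiency in
percent is 100 * (10^(-1/slope) - 1), i.e. a slope of -3.3219 means
perfect doubling. Efficiencies are reported alongside the results but not
folded into RQ by default; an efficiency-corrected mode using
(1+E)^-ddCq is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, InvalidCurveError


@dataclass
class QpcrPlate:
    """Long-format Cq records with reference and calibrator roles."""

    data: pd.DataFrame  # columns: gene, group, bio_rep, tech_rep, cq
    reference_genes: tuple[str, ...] = ("Rplp", "Ubc")
    calibrator: str = "noAR"

    def __post_init__(self):
        for col in ("gene", "group", "bio_rep", "tech_rep", "cq"):
            if col not in self.data.columns:
                raise DataError(f"qPCR table missing column {col!r}")
        if (self.data["cq"] <= 0).any():
            raise DataError("Cq values must be > 0")
        groups = set(self.data["group"])
        if self.calibrator not in groups:
            raise ConfigError(f"calibrator group {self.calibrator!r} not on plate")
        for ref in self.reference_genes:
            ref_groups = set(self.data.loc[self.data["gene"] == ref, "group"])
            if ref_groups != groups:
                raise DataError(
                    f"reference gene {ref!r} missing from groups "
                    f"{sorted(groups - ref_groups)}"
                )

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    @property
    def target_genes(self) -> list[str]:
        return [
            g for g in dict.fromkeys(self.data["gene"])
            if g not in self.reference_genes
        ]


@dataclass
class StandardCurve:
    gene: str
    log10_quantity: np.ndarray
    mean_cq: np.ndarray
    slope: float
    intercept: float
    r2: float

    @property
    def efficiency_pct(self) -> float:
        return 100.0 * (10.0 ** (-1.0 / self.slope) - 1.0)


def efficiency_from_dilution(
    cq_by_dilution: Sequence[tuple[float, float]], gene: str = ""
) -> StandardCurve:
    """Fit a standard curve to (log10 quantity, Cq) pairs.

    Requires at least three distinct dilutions; a non-negative slope (Cq
    not decreasing with template) is an invalid curve.
    """
    pairs = sorted(cq_by_dilution)
    lq = np.array([p[0] for p in pairs], dtype=float)
    cq = np.array([p[1] for p in pairs], dtype=float)
    if len(set(lq)) < 3:
        raise DataError("standard curve needs >= 3 distinct dilutions")
    fit = stats.linregress(lq, cq)
    if fit.slope >= 0:
        raise InvalidCurveError(
            f"standard curve slope {fit.slope:.4g} is non-negative for {gene!r}"
        )
    return StandardCurve(
        gene=gene,
        log10_quantity=lq,
        mean_cq=cq,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )


def _bio_means(plate: QpcrPlate) -> pd.DataFrame:
    """Average technical replicates: one Cq per (gene, group, bio_rep)."""
    return (
        plate.data.groupby(["gene", "group", "bio_rep"], sort=False)["cq"]
        .mean()
        .reset_index()
    )


def _delta_cq(plate: QpcrPlate) -> pd.DataFrame:
    """Per-replicate dCq = Cq(target) - mean over reference genes' Cq."""
    bio = _bio_means(plate)
    ref = bio[bio["gene"].isin(plate.reference_genes)]
    ref_mean = (
        ref.groupby(["group", "bio_rep"])["cq"].mean().rename("ref_cq").reset_index()
    )
    tgt = bio[~bio["gene"].isin(plate.reference_genes)]
    merged = tgt.merge(ref_mean, on=["group", "bio_rep"], how="left")
    if merged["ref_cq"].isna().any():
        bad = merged[merged["ref_cq"].isna()].iloc[0]
        raise DataError(
            f"no reference measurement for group {bad['group']!r} "
            f"replicate {bad['bio_rep']!r}"
        )
    merged["dcq"] = merged["cq"] - merged["ref_cq"]
    return merged[["gene", "group", "bio_rep", "dcq"]]


def ddcq(
    plate: QpcrPlate,
    efficiency: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Relative expression per (gene, group) with replicate dispersion.

    Returns one row per target gene and group with columns rq, sem,
    n_bio, ddcq. The calibrator group's RQ is exactly 1 (it is its own
    reference). When ``efficiency`` maps genes to E, the amplification
    factor (1+E) replaces 2 in the back-transform for those genes.
    """
    dcq = _delta_cq(plate)
    cal = (
        dcq[dcq["group"] == plate.calibrator]
        .groupby("gene")["dcq"]
        .mean()
        .rename("cal_dcq")
    )
    merged = dcq.merge(cal, on="gene", how="left")
    if merged["cal_dcq"].isna().any():
        gene = merged.loc[merged["cal_dcq"].isna(), "gene"].iloc[0]
        raise DataError(f"gene {gene!r} not measured in the calibrator group")
    merged["ddcq"] = merged["dcq"] - merged["cal_dcq"]

    def base_of(gene: str) -> float:
        if efficiency is None:
            return 2.0
        return 1.0 + float(efficiency.get(gene, 1.0))

    merged["rq_rep"] = [
        base_of(g) ** (-x) for g, x in zip(merged["gene"], merged["ddcq"])
    ]
    rows = []
    for (gene, group), sub in merged.groupby(["gene", "group"], sort=False):
        group_ddcq = float(sub["ddcq"].mean())
        rq = base_of(gene) ** (-group_ddcq)
        reps = sub["rq_rep"].to_numpy()
        sem = float(reps.std(ddof=1) / np.sqrt(len(reps))) if len(reps) > 1 else 0.0
        rows.append(
            {
                "gene": gene,
                "group": group,
                "rq": float(rq),
                "sem": sem,
                "n_bio": int(len(reps)),
                "ddcq": group_ddcq,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(plate: QpcrPlate, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA on per-replicate dCq, per target gene.

    With two groups this is equivalent to the two-sample t-test (F = t^2).
    Returns per gene: F, p, significant (p <= alpha).
    """
    dcq = _delta_cq(plate)
    rows = []
    for gene, sub in dcq.groupby("gene", sort=False):
        samples = [g["dcq"].to_numpy() for _, g in sub.groupby("group", sort=False)]
        if any(len(s) < 2 for s in samples):
            raise DataError(f"gene {gene!r}: need >= 2 replicates per group")
        if np.ptp(np.concatenate(samples)) == 0:
            f, p = 0.0, 1.0
        else:
            with np.errstate(invalid="ignore"):
                f, p = stats.f_oneway(*samples)
            if np.isnan(f):  # degenerate within-group variance
                f, p = 0.0, 1.0
        rows.append(
            {"gene": gene, "F": float(f), "p": float(p),
             "significant": bool(p <= alpha)}
        )
    return pd.DataFrame(rows).set_index("gene")


def concordance_with_array(
    rq: pd.DataFrame, de: pd.DataFrame, treated_group: str
) -> pd.DataFrame:
    """Direction agreement between qPCR RQ and array fold change.

    ``rq`` is the ddcq() output, ``de`` the DE table with a ``symbol``
    column (or symbol-valued index). Agreement means sign(log2 RQ) equals
    sign of the array's log2 difference. The summary fraction is stored in
    ``result.attrs['agreement_fraction']``.
    """
    if "symbol" in de.columns:
        delta_of = dict(zip(de["symbol"], de["delta"]))
    else:
        delta_of = dict(zip(de.index, de["delta"]))
    sub = rq[rq["group"] == treated_group]
    rows = []
    for _, rec in sub.iterrows():
        gene = rec["gene"]
        if gene not in delta_of:
            continue
        qpcr_sign = np.sign(np.log2(rec["rq"])) if rec["rq"] > 0 else 0.0
        array_sign = np.sign(delta_of[gene])
        rows.append(
            {
                "gene": gene,
                "rq": rec["rq"],
                "array_delta": delta_of[gene],
                "agree": bool(qpcr_sign == array_sign),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["agreement_fraction"] = (
        float(out["agree"].mean()) if len(out) else float("nan")
    )
    return out
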