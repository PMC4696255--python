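"""Synthetic data with known ground truth.

The array generator emulates the statistical structure of a six-array,
two-group single-channel microarray experiment: ~35k probe sets including
a block of control probes, log-normal intensities with probe-specific
baselines, a spiked fraction of truly differential probes with signed log2
effects, and four per-value corruption processes (poor quality flags,
negative intensities, missing values, multiplicative outliers).

The qPCR generator produces long-format Cq plates with configurable
per-gene relative quantities and amplification efficiencies, including
reference genes at constant quantity across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import FlaggedMatrix

# substream indices for the per-purpose RNGs derived from the global seed
_STREAMS = {
    "baseline": 0,
    "noise": 1,
    "effects": 2,
    "poor": 3,
    "negative": 4,
    "missing": 5,
    "outlier": 6,
    "qpcr": 7,
}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class EffectSpec:
    """Distribution of true signed log2 effects for differential probes.

    kinds:
      ``fixed``               |delta| = ``value``
      ``shifted_exponential`` |delta| = ``min_effect`` + Exp(``scale``)
      ``normal``              delta magnitude |N(``value``, ``scale``)|
    The sign is + (up in the treated group) with probability ``p_up``.
    """

    kind: str = "shifted_exponential"
    value: float = 2.0
    min_effect: float = 1.0
    scale: float = 0.7
    p_up: float = 0.3

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            mag = np.full(n, float(self.value))
        elif self.kind == "shifted_exponential":
            mag = self.min_effect + rng.exponential(self.scale, n)
        elif self.kind == "normal":
            mag = np.abs(rng.normal(self.value, self.scale, n))
        else:
            raise ConfigError(f"unknown effect distribution kind {self.kind!r}")
        sign = np.where(rng.random(n) < self.p_up, 1.0, -1.0)
        return sign * mag


@dataclass(frozen=True)
class ArraySimConfig:
    """Study conditions for the synthetic flagged matrix.

    Defaults mirror the layout of the experiment the pipeline targets:
    35,129 probe sets of which 1,280 are controls, three arrays per group,
    and per-value corruption rates of 0.6 % poor flags, 0.8 % negative
    values, 0.8 % missing values and 0.3 % outliers.
    """

    n_probes: int = 35_129
    n_control: int = 1_280
    arrays_per_group: int = 3
    groups: tuple[str, str] = ("noAR", "AR17")
    frac_de: float = 0.025
    effect: EffectSpec = field(default_factory=EffectSpec)
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.25
    frac_poor_flag: float = 0.006
    frac_negative: float = 0.008
    frac_missing: float = 0.008
    frac_outlier: float = 0.003
    outlier_factor: float = 6.0
    good_flag: str = "G"
    poor_flag: str = "L"
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_de", "frac_poor_flag", "frac_negative",
                     "frac_missing", "frac_outlier"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_control >= self.n_probes:
            raise ConfigError("n_control must be < n_probes")
        if self.arrays_per_group < 2:
            raise ConfigError("arrays_per_group must be >= 2")
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ConfigError("exactly two distinct group labels required")
        if self.outlier_factor <= 1.0:
            raise ConfigError("outlier_factor must be > 1")


@dataclass
class GroundTruth:
    """Bookkeeping of what the generator planted.

    ``de_probes`` maps probe id -> true signed log2 effect (treated minus
    reference). ``corrupted_cells`` maps corruption type -> list of
    (probe_index, array_index); the lists are disjoint per cell, resolved
    by the precedence missing > negative > poor > outlier.
    """

    de_probes: dict[str, float]
    corrupted_cells: dict[str, list[tuple[int, int]]]


def simulate_arrays(config: ArraySimConfig) -> tuple[FlaggedMatrix, GroundTruth]:
    """Draw a flagged matrix and its ground truth. Same config => same output."""
    n, k = config.n_probes, 2 * config.arrays_per_group
    npg = config.arrays_per_group
    ref, trt = config.groups

    probe_ids = [f"P{i:06d}" for i in range(n)]
    # controls occupy the tail block; they carry no true effect
    is_control = np.zeros(n, dtype=bool)
    is_control[n - config.n_control:] = True
    for i in np.flatnonzero(is_control):
        probe_ids[i] = f"CTRL{i:06d}"
    gene_symbols = [None if is_control[i] else f"Gene{i:06d}" for i in range(n)]

    array_ids = [f"{ref}_{j + 1}" for j in range(npg)] + [
        f"{trt}_{j + 1}" for j in range(npg)
    ]
    group_of = {a: (ref if j < npg else trt) for j, a in enumerate(array_ids)}

    baseline = _stream(config.seed, "baseline").normal(
        config.baseline_log2_mean, config.baseline_log2_sd, n
    )
    log2 = baseline[:, None] + _stream(config.seed, "noise").normal(
        0.0, config.noise_log2_sd, (n, k)
    )

    fx_rng = _stream(config.seed, "effects")
    candidates = np.flatnonzero(~is_control)
    n_de = int(round(config.frac_de * candidates.size))
    de_idx = fx_rng.choice(candidates, size=n_de, replace=False)
    effects = config.effect.draw(n_de, fx_rng)
    log2[de_idx, npg:] += effects[:, None]

    intensities = np.exp2(log2)
    flags = np.full((n, k), config.good_flag, dtype=object)

    # independent Bernoulli draws per corruption; precedence resolves overlap
    draw = {
        name: _stream(config.seed, name).random((n, k)) < frac
        for name, frac in (
            ("poor", config.frac_poor_flag),
            ("negative", config.frac_negative),
            ("missing", config.frac_missing),
            ("outlier", config.frac_outlier),
        )
    }
    missing = draw["missing"]
    negative = draw["negative"] & ~missing
    poor = draw["poor"] & ~missing & ~negative
    outlier = draw["outlier"] & ~missing & ~negative & ~poor

    intensities[missing] = np.nan
    intensities[negative] = -np.abs(intensities[negative])
    flags[poor] = config.poor_flag
    out_dir = _stream(config.seed, "outlier").random((n, k)) < 0.5
    intensities[outlier & out_dir] *= config.outlier_factor
    intensities[outlier & ~out_dir] /= config.outlier_factor

    truth = GroundTruth(
        de_probes={probe_ids[i]: float(d) for i, d in zip(de_idx, effects)},
        corrupted_cells={
            "missing": [tuple(c) for c in np.argwhere(missing)],
            "negative": [tuple(c) for c in np.argwhere(negative)],
            "poor": [tuple(c) for c in np.argwhere(poor)],
            "outlier": [tuple(c) for c in np.argwhere(outlier)],
        },
    )
    matrix = FlaggedMatrix(
        probe_ids=probe_ids,
        array_ids=array_ids,
        intensities=intensities,
        flags=flags,
        is_control=is_control,
        gene_symbols=gene_symbols,
        group_of=group_of,
    )
    return matrix, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    rows = [("de_probe", pid, f"{delta!r}") for pid, delta in truth.de_probes.items()]
    for kind, cells in truth.corrupted_cells.items():
        rows += [(kind, str(i), str(j)) for i, j in cells]
    pd.DataFrame(rows, columns=["record", "a", "b"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


def simulate_qpcr(
    true_rq: Mapping[str, float],
    groups: Sequence[str] = ("noAR", "AR17"),
    calibrator: str = "noAR",
    reference_genes: Sequence[str] = ("Rplp", "Ubc"),
    efficiency: Mapping[str, float] | float = 1.0,
    cq_sd: float = 0.0,
    n_bio: int = 3,
    n_tech: int = 2,
    base_cq: float = 24.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format Cq plate.

    ``true_rq`` maps target gene -> relative quantity in the treated group
    (calibrator quantity is 1); reference genes have quantity 1 in every
    group. Cq = base - log_{1+E}(quantity) + N(0, cq_sd). ``efficiency`` is
    E with amplification factor 1+E (E=1 is perfect doubling).
    """
    if len(groups) != 2:
        raise ConfigError("exactly two groups supported")
    if calibrator not in groups:
        raise ConfigError(f"calibrator {calibrator!r} not among groups {groups}")
    for g, rq in true_rq.items():
        if rq <= 0:
            raise ConfigError(f"true_rq for {g!r} must be > 0, got {rq}")

    def eff(gene: str) -> float:
        e = efficiency[gene] if isinstance(efficiency, Mapping) else float(efficiency)
        if not 0.7 <= 1.0 + e <= 3.0:
            raise ConfigError(f"amplification factor 1+E={1 + e} out of range for {gene}")
        return e

    rng = _stream(seed, "qpcr")
    records = []
    genes = list(true_rq) + [g for g in reference_genes if g not in true_rq]
    for gene in genes:
        is_ref = gene in reference_genes
        for group in groups:
            if is_ref or group == calibrator:
                quantity = 1.0
            else:
                quantity = float(true_rq[gene])
            mean_cq = base_cq - np.log(quantity) / np.log(1.0 + eff(gene))
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    cq = mean_cq + (rng.normal(0.0, cq_sd) if cq_sd > 0 else 0.0)
                    records.append((gene, group, b, t, cq))
    return pd.DataFrame(records, columns=["gene", "group", "bio_rep", "tech_rep", "cq"])
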