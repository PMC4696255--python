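"""Readers and writers for every on-disk artifact of the pipeline.

The central exchange format is the *flagged matrix* TSV: one row per probe
(probe set), one intensity column and one quality-flag column per array,
plus probe annotation. The layout is deliberately generic rather than a
clone of any vendor export; a documented column schema maps arbitrary
headers onto it.

Flagged matrix TSV layout (tab-separated)::

    # group   <array_id>   <group_label>        (one comment line per array)
    probe_id  gene_symbol  is_control  INT:<a1> ... INT:<ak>  FLAG:<a1> ... FLAG:<ak>

Missing intensities are encoded by an empty field (or any configured
missing token). Gene symbols may be empty: such probes are treated as
unannotated and still participate in differential expression, but are
excluded from gene-set enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import DataError, IntegrityError, SchemaError

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "null")


@dataclass(frozen=True)
class TableSchema:
    """Column-name configuration for flagged-matrix TSV files."""

    probe_col: str = "probe_id"
    symbol_col: str = "gene_symbol"
    control_col: str = "is_control"
    intensity_prefix: str = "INT:"
    flag_prefix: str = "FLAG:"
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS


@dataclass
class ParseLog:
    rows_in: int = 0
    rows_parsed: int = 0
    rows_rejected: int = 0
    n_missing_tokens: int = 0
    n_unparseable_cells: int = 0


@dataclass
class FlaggedMatrix:
    """Probe x array intensities with per-value quality flags.

    ``intensities`` is a float array on the raw linear scale with NaN for
    missing values; ``flags`` is an object array of single-token quality
    codes (the "good" code is configurable downstream, default ``"G"``).
    """

    probe_ids: list[str]
    array_ids: list[str]
    intensities: np.ndarray
    flags: np.ndarray
    is_control: np.ndarray
    gene_symbols: list[str | None] | None = None
    group_of: dict[str, str] = field(default_factory=dict)
    parse_log: ParseLog | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        self.is_control = np.asarray(self.is_control, dtype=bool)
        self.validate()

    # -- structural invariants -------------------------------------------------
    def validate(self) -> None:
        n, k = len(self.probe_ids), len(self.array_ids)
        if len(set(self.probe_ids)) != n:
            raise IntegrityError("duplicate probe ids")
        if len(set(self.array_ids)) != k:
            raise IntegrityError("duplicate array ids")
        if self.intensities.shape != (n, k):
            raise DataError(
                f"intensities shape {self.intensities.shape} != ({n}, {k})"
            )
        if self.flags.shape != (n, k):
            raise DataError(f"flags shape {self.flags.shape} != ({n}, {k})")
        if self.is_control.shape != (n,):
            raise DataError("is_control must have one entry per probe")
        if self.gene_symbols is not None and len(self.gene_symbols) != n:
            raise DataError("gene_symbols must have one entry per probe")
        if self.group_of:
            unknown = set(self.group_of) - set(self.array_ids)
            if unknown:
                raise DataError(f"group assignment for unknown arrays: {unknown}")
            missing = set(self.array_ids) - set(self.group_of)
            if missing:
                raise DataError(f"arrays without group assignment: {missing}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance across arrays."""
        seen: dict[str, None] = {}
        for a in self.array_ids:
            g = self.group_of.get(a)
            if g is not None:
                seen.setdefault(g, None)
        return list(seen)

    def array_indices_of_group(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.array_ids) if self.group_of.get(a) == group],
            dtype=int,
        )

    def subset_probes(self, keep: np.ndarray) -> "FlaggedMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return FlaggedMatrix(
            probe_ids=[self.probe_ids[i] for i in idx],
            array_ids=list(self.array_ids),
            intensities=self.intensities[idx].copy(),
            flags=self.flags[idx].copy(),
            is_control=self.is_control[idx].copy(),
            gene_symbols=None
            if self.gene_symbols is None
            else [self.gene_symbols[i] for i in idx],
            group_of=dict(self.group_of),
        )

    def copy(self) -> "FlaggedMatrix":
        return self.subset_probes(np.ones(self.n_probes, dtype=bool))


@dataclass(frozen=True)
class GeneSet:
    category: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets with a free-text category/description label."""

    sets: dict[str, GeneSet]

    def __post_init__(self):
        for name, gs in self.sets.items():
            if not gs.members:
                raise IntegrityError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        kept = {
            name: GeneSet(gs.category, tuple(m for m in gs.members if m in universe))
            for name, gs in self.sets.items()
        }
        return GeneSetCollection({n: g for n, g in kept.items() if g.members})


@dataclass
class RegulatorNetwork:
    """Signed regulator -> target edges (+1 activating, -1 repressing)."""

    edges: list[tuple[str, str, int]]

    def __post_init__(self):
        pairs = [(r, t) for r, t, _ in self.edges]
        if len(set(pairs)) != len(pairs):
            raise IntegrityError("duplicate (regulator, target) edges")
        bad = [e for e in self.edges if e[2] not in (1, -1)]
        if bad:
            raise DataError(f"edge signs must be +1/-1, got {bad[:3]}")

    def targets_of(self, regulator: str) -> list[tuple[str, int]]:
        return [(t, s) for r, t, s in self.edges if r == regulator]

    @property
    def regulators(self) -> list[str]:
        seen: dict[str, None] = {}
        for r, _, _ in self.edges:
            seen.setdefault(r, None)
        return list(seen)


# ---------------------------------------------------------------------------
# flagged matrix TSV
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    """Shortest round-trip decimal representation; missing -> empty field."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return repr(float(x))


def read_flagged_matrix(
    path: str | Path, schema: TableSchema = TableSchema()
) -> FlaggedMatrix:
    """Parse a flagged-matrix TSV.

    Unparseable numeric cells become missing values and are counted in the
    returned matrix's ``parse_log``; row order is preserved.
    """
    path = Path(path)
    group_of: dict[str, str] = {}
    data_lines: list[str] = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line.lstrip("# ").split("\t")
                if parts and parts[0] == "group" and len(parts) == 3:
                    group_of[parts[1]] = parts[2]
                continue
            if header is None:
                header = line.split("\t")
            else:
                data_lines.append(line)

    if header is None:
        raise SchemaError(f"{path}: no header row found")
    for col in (schema.probe_col, schema.control_col):
        if col not in header:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")

    int_cols = [c for c in header if c.startswith(schema.intensity_prefix)]
    flag_cols = [c for c in header if c.startswith(schema.flag_prefix)]
    int_arrays = [c[len(schema.intensity_prefix):] for c in int_cols]
    flag_arrays = [c[len(schema.flag_prefix):] for c in flag_cols]
    if not int_cols:
        raise SchemaError(f"{path}: no intensity columns ({schema.intensity_prefix}*)")
    if set(int_arrays) != set(flag_arrays):
        raise SchemaError(
            f"{path}: intensity/flag columns do not pair one-to-one "
            f"(intensities for {int_arrays}, flags for {flag_arrays})"
        )

    log = ParseLog(rows_in=len(data_lines))
    col_idx = {c: i for i, c in enumerate(header)}
    n_fields = len(header)

    probe_ids: list[str] = []
    symbols: list[str | None] = []
    is_control: list[bool] = []
    intens_rows: list[list[float]] = []
    flag_rows: list[list[str]] = []

    for line in data_lines:
        fields = line.split("\t")
        if len(fields) != n_fields:
            log.rows_rejected += 1
            continue
        probe_ids.append(fields[col_idx[schema.probe_col]])
        if schema.symbol_col in col_idx:
            sym = fields[col_idx[schema.symbol_col]]
            symbols.append(sym if sym else None)
        else:
            symbols.append(None)
        is_control.append(fields[col_idx[schema.control_col]] in ("1", "True", "true"))
        vals: list[float] = []
        for c in int_cols:
            tok = fields[col_idx[c]]
            if tok in schema.missing_tokens:
                vals.append(float("nan"))
                log.n_missing_tokens += 1
            else:
                try:
                    vals.append(float(tok))
                except ValueError:
                    vals.append(float("nan"))
                    log.n_unparseable_cells += 1
        intens_rows.append(vals)
        flag_rows.append(
            [fields[col_idx[schema.flag_prefix + a]] for a in int_arrays]
        )
        log.rows_parsed += 1

    if len(set(probe_ids)) != len(probe_ids):
        raise IntegrityError(f"{path}: duplicate probe ids")

    return FlaggedMatrix(
        probe_ids=probe_ids,
        array_ids=int_arrays,
        intensities=np.array(intens_rows, dtype=float).reshape(
            len(probe_ids), len(int_arrays)
        ),
        flags=np.array(flag_rows, dtype=object).reshape(
            len(probe_ids), len(int_arrays)
        ),
        is_control=np.array(is_control, dtype=bool),
        gene_symbols=symbols,
        group_of={a: group_of[a] for a in int_arrays if a in group_of},
        parse_log=log,
    )


def write_flagged_matrix(
    m: FlaggedMatrix, path: str | Path, schema: TableSchema = TableSchema()
) -> None:
    """Write a flagged matrix so that ``read_flagged_matrix`` round-trips it
    bit-identically (floats use shortest round-trip representation)."""
    path = Path(path)
    with open(path, "w") as fh:
        for a in m.array_ids:
            if a in m.group_of:
                fh.write(f"# group\t{a}\t{m.group_of[a]}\n")
        cols = (
            [schema.probe_col, schema.symbol_col, schema.control_col]
            + [schema.intensity_prefix + a for a in m.array_ids]
            + [schema.flag_prefix + a for a in m.array_ids]
        )
        fh.write("\t".join(cols) + "\n")
        syms = m.gene_symbols or [None] * m.n_probes
        for i, pid in enumerate(m.probe_ids):
            row = [pid, syms[i] or "", "1" if m.is_control[i] else "0"]
            row += [_fmt(v) for v in m.intensities[i]]
            row += [str(f) for f in m.flags[i]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# reports and generic tables
# ---------------------------------------------------------------------------


def write_report(report, path: str | Path) -> None:
    """Serialize a report (anything with ``to_frame()``) or a DataFrame as
    TSV with stable column order and 6 significant digits for floats."""
    if hasattr(report, "to_frame"):
        frame = report.to_frame()
    elif isinstance(report, pd.DataFrame):
        frame = report
    else:
        raise TypeError(f"cannot serialize report of type {type(report).__name__}")
    frame.to_csv(path, sep="\t", index=frame.index.name is not None,
                 float_format="%.6g")


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


# ---------------------------------------------------------------------------
# gene sets (GMT) and regulator networks
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then members, tab-separated.

    Duplicate members within a set are de-duplicated (order preserved);
    duplicate set names and empty member lists are integrity errors.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IntegrityError(
                    f"{path}:{lineno}: gene set with no members"
                )
            name, desc = parts[0], parts[1]
            if name in sets:
                raise IntegrityError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(p for p in parts[2:] if p))
            if not members:
                raise IntegrityError(f"{path}:{lineno}: gene set with no members")
            sets[name] = GeneSet(category=desc, members=members)
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, gs in coll.sets.items():
            fh.write("\t".join([name, gs.category, *gs.members]) + "\n")


def read_network(path: str | Path) -> RegulatorNetwork:
    """Read a signed edge list TSV with columns regulator, target, sign."""
    df = pd.read_csv(path, sep="\t")
    for col in ("regulator", "target", "sign"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    edges = [
        (str(r), str(t), int(s))
        for r, t, s in zip(df["regulator"], df["target"], df["sign"])
    ]
    return RegulatorNetwork(edges)


def write_network(net: RegulatorNetwork, path: str | Path) -> None:
    pd.DataFrame(net.edges, columns=["regulator", "target", "sign"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ("gene", "group", "bio_rep", "tech_rep", "cq")


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format Cq table (gene, group, bio_rep, tech_rep, cq)."""
    df = pd.read_csv(path, sep="\t")
    for col in QPCR_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    return df


def write_qpcr_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
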