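"""Optional adapter for GEO-deposited single-channel array series.

Maps the per-sample tables of a GEO family SOFT file onto the package's
:class:`~arraycascade.io.FlaggedMatrix`, so a deposited series can be run
through the same pipeline as synthetic data. Downloading is strictly
opt-in (:func:`fetch_geo` touches the network only when called
explicitly) and nothing in the package or its test suite requires it.

For the series this pipeline was designed around, GSE57653, the sample ->
group mapping is known and shipped as :data:`GSE57653_GROUPS`:
three non-transfected arrays (noAR) and three arrays transfected with the
androgen receptor carrying 17 CAG repeats (AR17).
"""

from __future__ import annotations

import gzip
import tempfile
import urllib.request
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError
from .io import FlaggedMatrix

GSE57653_GROUPS: dict[str, str] = {
    "GSM1385418": "noAR",
    "GSM1385419": "noAR",
    "GSM1386001": "noAR",
    "GSM1385420": "AR17",
    "GSM1385421": "AR17",
    "GSM1385422": "AR17",
}


def parse_family_soft(path: str | Path) -> dict[str, pd.DataFrame]:
    """Parse per-sample data tables out of a GEO family SOFT file.

    Returns sample accession -> DataFrame with the table's own columns
    (typically ID_REF, VALUE and a quality/flag column). Handles plain or
    gzip-compressed files.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    tables: dict[str, pd.DataFrame] = {}
    sample: str | None = None
    in_table = False
    header: list[str] | None = None
    rows: list[list[str]] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("^SAMPLE"):
                sample = line.split("=", 1)[1].strip()
            elif line.startswith("!sample_table_begin"):
                in_table, header, rows = True, None, []
            elif line.startswith("!sample_table_end"):
                if sample is None or header is None:
                    raise SchemaError(f"{path}: malformed sample table")
                tables[sample] = pd.DataFrame(rows, columns=header)
                in_table = False
            elif in_table:
                fields = line.split("\t")
                if header is None:
                    header = fields
                else:
                    rows.append(fields)
    if not tables:
        raise DataError(f"{path}: no sample tables found")
    return tables


def flagged_matrix_from_samples(
    tables: dict[str, pd.DataFrame],
    groups: dict[str, str],
    id_col: str = "ID_REF",
    value_col: str = "VALUE",
    flag_col: str | None = None,
    good_flag: str = "G",
    control_ids: set[str] | None = None,
) -> FlaggedMatrix:
    """Assemble sample tables into a FlaggedMatrix.

    ``flag_col=None`` auto-detects the first column whose name contains
    "flag" (case-insensitive); if no flag column exists every value is
    treated as good. Probes in ``control_ids`` are marked as controls.
    """
    missing = set(groups) - set(tables)
    if missing:
        raise DataError(f"samples missing from the series: {sorted(missing)}")
    sample_ids = [s for s in groups]  # preserve mapping order
    first = tables[sample_ids[0]]
    if id_col not in first.columns or value_col not in first.columns:
        raise SchemaError(f"sample tables need columns {id_col!r} and {value_col!r}")
    if flag_col is None:
        candidates = [c for c in first.columns if "flag" in c.lower()]
        flag_col = candidates[0] if candidates else None

    probe_ids = list(first[id_col])
    n = len(probe_ids)
    intens = np.full((n, len(sample_ids)), np.nan)
    flags = np.full((n, len(sample_ids)), good_flag, dtype=object)
    for j, s in enumerate(sample_ids):
        tab = tables[s]
        if list(tab[id_col]) != probe_ids:
            tab = tab.set_index(id_col).reindex(probe_ids).reset_index()
        intens[:, j] = pd.to_numeric(tab[value_col], errors="coerce").to_numpy()
        if flag_col is not None and flag_col in tab.columns:
            flags[:, j] = tab[flag_col].astype(str).to_numpy()

    ctrl = control_ids or set()
    return FlaggedMatrix(
        probe_ids=[str(p) for p in probe_ids],
        array_ids=sample_ids,
        intensities=intens,
        flags=flags,
        is_control=np.array([str(p) in ctrl for p in probe_ids]),
        gene_symbols=None,
        group_of=dict(groups),
    )


def fetch_geo(
    accession: str,
    cache_dir: str | Path = "~/.cache/arraycascade",
    timeout: float = 120.0,
) -> Path:
    """Download a series family SOFT file from GEO (explicitly opt-in).

    Returns the local path of the cached file; a cached copy is reused
    without touching the network. Failed downloads leave no partial cache.
    """
    if not accession.startswith("GSE") or not accession[3:].isdigit():
        raise DataError(f"not a GEO series accession: {accession!r}")
    cache_dir = Path(cache_dir).expanduser()
    cache_dir.mkdir(parents=True, exist_ok=True)
    dest = cache_dir / f"{accession}_family.soft.gz"
    if dest.exists():
        return dest
    stem = accession[:-3] + "nnn"
    url = (
        f"https://ftp.ncbi.nlm.nih.gov/geo/series/{stem}/{accession}/soft/"
        f"{accession}_family.soft.gz"
    )
    with tempfile.NamedTemporaryFile(dir=cache_dir, delete=False) as tmp:
        tmp_path = Path(tmp.name)
    try:
        urllib.request.urlretrieve(url, tmp_path)  # noqa: S310 - explicit opt-in
        tmp_path.replace(dest)
    except Exception as exc:
        tmp_path.unlink(missing_ok=True)
        raise DataError(f"could not fetch {accession} from GEO: {exc}") from exc
    return dest


def load_gse57653(cache_dir: str | Path = "~/.cache/arraycascade") -> FlaggedMatrix:
    """Convenience: fetch + parse + group the deposited series (network)."""
    path = fetch_geo("GSE57653", cache_dir)
    tables = parse_family_soft(path)
    return flagged_matrix_from_samples(tables, GSE57653_GROUPS)
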