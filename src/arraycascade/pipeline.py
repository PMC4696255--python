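"""End-to-end orchestration: qc -> impute/normalize -> DE -> clustering ->
enrichment/upstream, with one config, one seed and a machine-readable
summary.

Every run writes, into its output directory: the QC ledger, the
normalized matrix (with imputation provenance), the full DE table, Newick
trees for the significant-probe heatmap, enrichment and upstream tables
when gene sets / a network are supplied, a serialized copy of the config,
and ``summary.json`` with the headline counts. Identical config + seed
produce byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cluster import cluster_heatmap_order
from .diffexp import TierBands, differential_expression, significant_set
from .enrichment import annotation_clusters, fisher_enrich, upstream_z
from .errors import ConfigError, DataError, PipelineError
from .io import (
    FlaggedMatrix,
    GeneSetCollection,
    RegulatorNetwork,
    write_report,
)
from .normalize import NormalizedMatrix, impute_normalize
from .qc import QcConfig, run_qc


@dataclass
class PipelineConfig:
    seed: int  # mandatory: a run without a seed is a config error
    qc: QcConfig = field(default_factory=QcConfig)
    n_components: int = 2
    ppca_tol: float = 1e-6
    ppca_max_iter: int = 1000
    fc_cut: float = 2.0
    q_cut: float = 0.01
    bands: TierBands = field(default_factory=TierBands)
    reference: str | None = None
    treatment: str | None = None
    upstream_min_targets: int = 3
    enrichment_jaccard: float = 0.5

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory; refusing a time-based default")
        if not 0 < self.q_cut <= 1:
            raise ConfigError(f"q_cut={self.q_cut} outside (0, 1]")
        if self.fc_cut < 1:
            raise ConfigError(f"fc_cut={self.fc_cut} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError(f"{path}: config must define a seed")
        if "qc" in raw:
            raw["qc"] = QcConfig(**raw["qc"])
        if "bands" in raw:
            raw["bands"] = TierBands(**raw["bands"])
        return cls(**raw)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o).__name__)


def write_normalized_matrix(nm: NormalizedMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in nm.values.columns:
            if a in nm.group_of:
                fh.write(f"# group\t{a}\t{nm.group_of[a]}\n")
        fh.write("probe_id\t" + "\t".join(map(str, nm.values.columns)) + "\n")
        for pid, row in zip(nm.values.index, nm.values.to_numpy()):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_normalized_matrix(path: str | Path) -> NormalizedMatrix:
    group_of: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    data = []
    header = None
    for line in lines:
        if line.startswith("#"):
            parts = line.lstrip("# ").split("\t")
            if parts[0] == "group" and len(parts) == 3:
                group_of[parts[1]] = parts[2]
        elif header is None:
            header = line.split("\t")
        else:
            data.append(line.split("\t"))
    if header is None:
        raise DataError(f"{path}: empty file")
    df = pd.DataFrame(data, columns=header).set_index("probe_id").astype(float)
    return NormalizedMatrix(
        values=df,
        imputed=pd.DataFrame(False, index=df.index, columns=df.columns),
        group_of=group_of,
    )


def run_all(
    matrix: FlaggedMatrix,
    config: PipelineConfig,
    outdir: str | Path,
    gene_sets: GeneSetCollection | None = None,
    network: RegulatorNetwork | None = None,
) -> dict:
    """Run the full pipeline, writing all artifacts into ``outdir``.

    Returns the summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    (outdir / "config.yaml").write_text(cfg_yaml)
    cfg_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16]

    summary: dict = {"config_hash": cfg_hash, "seed": config.seed, "stages": {}}

    # ---- QC ---------------------------------------------------------------
    filtered, report = run_qc(matrix, config.qc)
    write_report(report, outdir / "filter_report.tsv")
    summary["stages"]["qc"] = {
        "probes_in": report.probes_in,
        "probes_remaining": report.probes_remaining,
        "probesets_with_missing": report.probesets_with_missing,
        "n_missing_values_remaining": report.n_missing_values_remaining,
    }

    # ---- imputation + normalization --------------------------------------
    nm, model = impute_normalize(
        filtered,
        n_components=config.n_components,
        tol=config.ppca_tol,
        max_iter=config.ppca_max_iter,
        seed=config.seed,
    )
    write_normalized_matrix(nm, outdir / "normalized_matrix.tsv")
    summary["stages"]["normalize"] = {
        "n_imputed": int(nm.imputed.to_numpy().sum()),
        "ppca_converged": bool(model.converged),
        "ppca_n_iter": int(model.n_iter),
    }

    # ---- differential expression ------------------------------------------
    de = differential_expression(
        nm, reference=config.reference, treatment=config.treatment,
        bands=config.bands,
    )
    if filtered.gene_symbols is not None:
        sym = dict(zip(filtered.probe_ids, filtered.gene_symbols))
        de["symbol"] = [sym.get(p) or "" for p in de.index]
    de_sorted = de.assign(_afc=de["fc"].abs()).sort_values(
        ["q", "_afc"], ascending=[True, False]
    ).drop(columns="_afc")
    write_report(de_sorted, outdir / "de_results.tsv")
    up, down = significant_set(de, fc_cut=config.fc_cut, q_cut=config.q_cut)
    summary["stages"]["de"] = {
        "n_significant": len(up) + len(down),
        "n_up": len(up),
        "n_down": len(down),
        "n_l1": int((de["level"] == "L1").sum()),
        "n_l2": int((de["level"] == "L2").sum()),
        "n_l3": int((de["level"] == "L3").sum()),
    }

    # ---- clustering --------------------------------------------------------
    try:
        row_tree, col_tree, ordered = cluster_heatmap_order(nm.values, de)
        (outdir / "rows.nwk").write_text(row_tree.to_newick() + "\n")
        (outdir / "cols.nwk").write_text(col_tree.to_newick() + "\n")
        ordered.to_csv(outdir / "ordered_matrix.tsv", sep="\t")
        summary["stages"]["cluster"] = {
            "n_leaves_rows": row_tree.n_leaves,
            "n_leaves_cols": col_tree.n_leaves,
            "column_order": col_tree.leaf_order(),
        }
    except DataError as exc:
        summary["stages"]["cluster"] = {"skipped": str(exc)}

    # ---- enrichment --------------------------------------------------------
    if gene_sets is not None:
        if "symbol" not in de.columns:
            raise PipelineError("enrichment", "matrix has no gene annotations")
        annotated = de[de["symbol"] != ""]
        universe = list(annotated["symbol"])
        query = list(annotated.loc[annotated["level"] == "L1", "symbol"])
        if query:
            enr = fisher_enrich(query, gene_sets, universe)
            write_report(enr, outdir / "enrichment.tsv")
            clusters = annotation_clusters(
                enr, gene_sets, query, jaccard_min=config.enrichment_jaccard
            )
            pd.DataFrame(
                [
                    {"cluster": c.name, "score": c.score,
                     "members": ";".join(c.members)}
                    for c in clusters
                ]
            ).to_csv(outdir / "annotation_clusters.tsv", sep="\t", index=False)
            summary["stages"]["enrichment"] = {
                "n_sets_tested": int(len(enr)),
                "n_clusters": len(clusters),
            }
        else:
            summary["stages"]["enrichment"] = {"skipped": "no significant genes"}

    # ---- upstream regulators ----------------------------------------------
    if network is not None:
        calls = upstream_z(de, network, min_targets=config.upstream_min_targets)
        write_report(calls, outdir / "upstream.tsv")
        summary["stages"]["upstream"] = {
            "n_regulators_scored": int(len(calls)),
            "n_activated": int((calls["call"] == "activated").sum()),
            "n_inhibited": int((calls["call"] == "inhibited").sum()),
        }

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return summary
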