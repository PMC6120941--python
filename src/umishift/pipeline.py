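"""End-to-end driver: SAM -> clusters -> counts -> complexity -> summary.

Every stage reads and writes plain files (TSV/JSON/BED/SAM) so any stage can
be run or inspected in isolation, and every filter logs its in/out record
counts — the method's conclusions rest on the proportions of reads surviving
each step.  Given identical inputs and configuration the output bundle is
byte-identical (stable sort orders everywhere).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import alignio, complexity, genecount, umicluster
from .errors import ConfigError, UmishiftError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults are the method's reference settings
    (mean UMI quality >= Q30, 3 bp cluster gap, stranded position keys)."""

    max_gap: int = umicluster.DEFAULT_MAX_GAP
    min_umi_qual: float = 30.0
    strand_mode: str = "stranded"  # or "ignore"
    unique_only: bool = False
    assume_unique_mapq: Optional[int] = None
    strict_ns: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if self.strand_mode not in ("stranded", "ignore"):
            raise ConfigError(f"unknown strand_mode {self.strand_mode!r}")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")


def clusters_to_frame(clusters: Sequence[umicluster.UmiReadCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "umi": [c.umi for c in clusters],
            "reference": [c.reference for c in clusters],
            "strand": [c.strand for c in clusters],
            "coordinates": [",".join(map(str, c.coordinates)) for c in clusters],
            "counts": [",".join(map(str, c.counts)) for c in clusters],
            "size": [c.size for c in clusters],
            "total_reads": [c.total_reads for c in clusters],
            "mode": [c.mode for c in clusters],
            "strict_class": [
                str(umicluster.classify_strict_shift(c)) for c in clusters
            ],
            "modal_sequence": [c.modal_sequence or "" for c in clusters],
        }
    )


def shift_frame(dist: umicluster.ShiftDistribution) -> pd.DataFrame:
    density = dist.density
    return pd.DataFrame(
        {
            "offset": list(density.keys()),
            "reads": [dist.pooled[o] for o in density],
            "density": list(density.values()),
        }
    )


def run_pipeline(
    sam_path,
    gff_path,
    outdir,
    config: Optional[RunConfig] = None,
) -> dict:
    """Run align-filter -> cluster -> count -> complexity; write the bundle.

    Returns the summary dictionary (also written as ``summary.json``).  Any
    stage failure removes the partial outputs and re-raises with the stage
    name attached.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(name: str) -> Path:
        path = outdir / name
        written.append(path)
        return path

    try:
        stage = "align-filter"
        stats = alignio.AlignFilterStats()
        alignments = alignio.load_umi_alignments(
            sam_path,
            ignore_strand=config.strand_mode == "ignore",
            assume_unique_mapq=config.assume_unique_mapq,
            stats=stats,
        )
        logger.info(
            "align-filter: %d in, %d unique kept (%d unmapped, %d non-unique)",
            stats.total,
            stats.kept,
            stats.unmapped,
            stats.non_unique,
        )

        stage = "cluster"
        clusters = umicluster.cluster_alignments(alignments, config.max_gap)
        clusters_to_frame(clusters).to_csv(
            emit("clusters.tsv"), sep="\t", index=False
        )
        summary = umicluster.summarize(clusters, config.strict_ns)
        shift_frame(umicluster.pooled_shift_distribution(clusters)).to_csv(
            emit("shifts_all.tsv"), sep="\t", index=False
        )
        for n, dist in summary.strict_shift_tables.items():
            shift_frame(dist).to_csv(
                emit(f"shifts_strict{n}.tsv"), sep="\t", index=False
            )
        logger.info(
            "cluster: %d reads -> %d clusters (max size %d)",
            summary.total_reads,
            summary.n_clusters,
            summary.max_size,
        )

        stage = "count"
        genes = genecount.GeneIndex.from_gff3(gff_path)
        collapsed_obs = genecount.observations_from_positions(
            (umicluster.collapse(c).position, 1) for c in clusters
        )
        genecount.write_bed(collapsed_obs, emit("collapsed.bed"))
        table = genecount.count_tables(clusters, genes, config.unique_only)
        table.to_csv(emit("gene_counts.tsv"), sep="\t", index=False)

        stage = "complexity"
        records, skipped = complexity.modal_read_complexity(clusters)
        pd.DataFrame(
            {
                "cluster_size": [r.cluster_size for r in records],
                "H_bits": [r.H for r in records],
                "I_bits": [r.I for r in records],
                "sequence": [r.sequence for r in records],
            }
        ).to_csv(emit("complexity.tsv"), sep="\t", index=False)
        anova = {}
        for metric in ("H", "I"):
            res = complexity.anova_by_cluster_size(records, metric)
            anova[metric] = (
                None
                if res is None
                else {
                    "F": res.F,
                    "p_value": res.p_value,
                    "df": [res.df_between, res.df_within],
                    "group_sizes": res.group_sizes,
                }
            )
        with open(emit("anova.json"), "w") as handle:
            json.dump(anova, handle, indent=2, sort_keys=True)

        stage = "summary"
        ratios = table["ratio"].dropna()
        quantiles = (
            {
                q: float(np.quantile(ratios, q))
                for q in (0.0, 0.25, 0.5, 0.75, 1.0)
            }
            if len(ratios)
            else {}
        )
        run_summary = {
            "config": dataclasses.asdict(config),
            "align_filter": stats.as_dict(),
            "clusters": summary.as_dict(),
            "genes": {
                "n_genes_observed": int(len(table)),
                "unassigned": table.attrs.get("unassigned", {}),
                "multi_gene": table.attrs.get("multi_gene", {}),
                "ratio_quantiles": quantiles,
            },
            "complexity": {"n_records": len(records), "skipped": skipped},
        }
        with open(emit("summary.json"), "w") as handle:
            json.dump(run_summary, handle, indent=2, sort_keys=True)
        return run_summary
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, UmishiftError):
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
        raise UmishiftError(f"stage {stage!r}: {exc}") from exc
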