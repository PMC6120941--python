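"""Synthetic UMI-tagged libraries with repeat-stabilised PCR stutter.

The generator emulates the minimal process that produces UMI-read clusters:
each gene has a fixed capture site; each captured molecule draws a random
UMI; PCR doubles the copy pool each cycle, and on repeat-bearing templates a
newly synthesised copy may slip by one repeat unit, shifting its effective
start coordinate.  Offsets therefore accumulate as a lazy random walk in
steps of the repeat unit, which yields a modal position with diminishing
flanks — the bell shape of real clusters — without hard-coding it, and
restricts offsets of a unit-*u* template to multiples of *u* (the
strictly-*u* signature).

Stutter is modelled at the mapped-start level (offset bookkeeping on the
reference), because the pipeline consumes alignments; the emitted SAM is
what an end-to-end aligner run over the emitted FASTQ would ideally
produce.  Every read is also recorded in a ground-truth provenance table,
so pipeline output can be scored molecule-by-molecule.

All randomness flows from one ``numpy`` generator seeded from the config:
identical configs give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignio import UmiAlignment, write_sam
from .errors import ConfigError
from .preprocess import UMI_HEADER_SEPARATOR
from .umicluster import levenshtein

_REFERENCE_NAME = "chrSim"
_BASES = np.array(list("ACGT"))
_MAX_UNIT = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic library.

    Defaults describe a small deep-sequenced library: 50 genes, 20 captured
    molecules each, 4 PCR doublings with every final copy sequenced (16
    reads per molecule), 10 bp UMIs, 36 bp reads.  ``stutter_prob`` is the
    per-cycle probability that a newly synthesised copy of a repeat-bearing
    template gains or loses one repeat unit; non-repeat templates never
    stutter.  ``per_base_error`` is the sequencing substitution rate,
    applied to read and UMI alike; the default is error-free so that
    recovery experiments isolate the stutter artefact.
    """

    seed: int = 1
    n_genes: int = 50
    gene_length: int = 400
    repeat_genes_fraction: float = 0.3
    molecules_per_gene: int = 20
    umi_length: int = 10
    pcr_cycles: int = 4
    stutter_prob: float = 0.1
    per_base_error: float = 0.0
    read_length: int = 36
    intergenic_gap: int = 200

    def __post_init__(self) -> None:
        for name in ("repeat_genes_fraction", "stutter_prob", "per_base_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.pcr_cycles < 0:
            raise ConfigError("pcr_cycles must be >= 0")
        if self.read_length + 2 * self.capture_margin > self.gene_length:
            raise ConfigError(
                "gene_length too small for read_length plus stutter margin"
            )

    @property
    def capture_margin(self) -> int:
        """Buffer around the capture site covering the largest possible shift."""
        return self.pcr_cycles * _MAX_UNIT + 4


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    capture_site: int  # 1-based coordinate where unshifted reads start
    repeat_unit: Optional[str]  # None for non-repeat templates


@dataclass
class SimulationTruth:
    """Ground truth: molecules per gene and one provenance row per read."""

    molecules_per_gene: dict[str, int]
    provenance: pd.DataFrame  # read_id, gene_id, molecule_id, true_umi,
    #                           observed_umi, capture_site, offset
    molecule_umis: dict[str, list[str]]  # gene_id -> true UMI per molecule


@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: dict[str, str]
    genes: list[GeneSpec]
    alignments: list[UmiAlignment]
    truth: SimulationTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != base]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _repeat_unit(rng: np.random.Generator, unit_size: int) -> str:
    # distinct bases within the unit, so the repeat is a true unit-n tandem
    bases = list(rng.choice(_BASES, size=unit_size, replace=False))
    return "".join(bases)


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate a library in memory: reference, genes, alignments, truth."""
    rng = np.random.default_rng(config.seed)
    margin = config.capture_margin

    genes: list[GeneSpec] = []
    chrom: list[str] = []
    cursor = 1  # 1-based
    n_repeat = int(round(config.repeat_genes_fraction * config.n_genes))
    for gi in range(config.n_genes):
        cursor += config.intergenic_gap
        start = cursor
        end = start + config.gene_length - 1
        capture = start + margin
        seq = list(_random_seq(rng, config.gene_length))
        unit: Optional[str] = None
        if gi < n_repeat:
            unit = _repeat_unit(rng, gi % _MAX_UNIT + 1)
            # repeat spans the capture window plus the largest possible shift
            span0 = capture - start - margin
            span1 = capture - start + config.read_length + margin
            block = (unit * ((span1 - span0) // len(unit) + 1))[: span1 - span0]
            seq[span0:span1] = list(block)
        chrom.append(_random_seq(rng, config.intergenic_gap))
        chrom.append("".join(seq))
        genes.append(GeneSpec(f"gene{gi + 1:04d}", start, end, capture, unit))
        cursor = end + 1
    chrom.append(_random_seq(rng, config.intergenic_gap))
    reference = {_REFERENCE_NAME: "".join(chrom)}
    ref_seq = reference[_REFERENCE_NAME]

    alignments: list[UmiAlignment] = []
    rows: list[tuple] = []
    molecules_per_gene: dict[str, int] = {}
    molecule_umis: dict[str, list[str]] = {}
    for gene in genes:
        molecules_per_gene[gene.gene_id] = config.molecules_per_gene
        umis: list[str] = []
        unit_len = len(gene.repeat_unit) if gene.repeat_unit else 0
        for mi in range(config.molecules_per_gene):
            true_umi = _random_seq(rng, config.umi_length)
            umis.append(true_umi)
            offsets = [0]
            for _ in range(config.pcr_cycles):
                children = []
                for off in offsets:
                    child = off
                    if unit_len and rng.random() < config.stutter_prob:
                        child += unit_len * (1 if rng.random() < 0.5 else -1)
                    children.append(child)
                offsets.extend(children)
            for ci, off in enumerate(offsets):
                start = gene.capture_site + off
                raw = ref_seq[start - 1 : start - 1 + config.read_length]
                read = _mutate(rng, raw, config.per_base_error)
                obs_umi = _mutate(rng, true_umi, config.per_base_error)
                read_id = f"sim.{gene.gene_id}.m{mi:03d}.c{ci:03d}"
                alignments.append(
                    UmiAlignment(
                        read_id=read_id,
                        umi=obs_umi,
                        reference=_REFERENCE_NAME,
                        strand="+",
                        coordinate=start,
                        sequence=read,
                    )
                )
                rows.append(
                    (
                        read_id,
                        gene.gene_id,
                        mi,
                        true_umi,
                        obs_umi,
                        gene.capture_site,
                        off,
                    )
                )
        molecule_umis[gene.gene_id] = umis

    provenance = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "gene_id",
            "molecule_id",
            "true_umi",
            "observed_umi",
            "capture_site",
            "offset",
        ],
    )
    truth = SimulationTruth(molecules_per_gene, provenance, molecule_umis)
    return SimulationResult(config, reference, genes, alignments, truth)


def write_gff3(genes: Sequence[GeneSpec], path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene in genes:
            handle.write(
                f"{_REFERENCE_NAME}\tumishift-sim\tgene\t{gene.start}\t{gene.end}"
                f"\t.\t+\t.\tID={gene.gene_id}\n"
            )


def write_fasta(reference: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in reference.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def simulate_library(
    config: SimulationConfig, outdir, emit_fastq: bool = False
) -> SimulationResult:
    """Run the generator and write the file bundle.

    Emits ``reference.fa``, ``genes.gff3``, ``reads.sam`` (NH:i:1, UMI in
    QNAME), ``truth_molecules.tsv``, ``truth_reads.tsv`` and ``config.json``
    under ``outdir``; optionally ``reads.fastq`` with the UMI inline at the
    5' end followed by a GGGG motif, for end-to-end runs through a real
    aligner.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = simulate(config)

    write_fasta(result.reference, outdir / "reference.fa")
    write_gff3(result.genes, outdir / "genes.gff3")
    refs = {name: len(seq) for name, seq in result.reference.items()}
    write_sam(result.alignments, outdir / "reads.sam", refs)

    pd.DataFrame(
        sorted(result.truth.molecules_per_gene.items()),
        columns=["gene_id", "true_molecules"],
    ).to_csv(outdir / "truth_molecules.tsv", sep="\t", index=False)
    result.truth.provenance.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as handle:
        json.dump(dataclasses.asdict(config), handle, indent=2, sort_keys=True)

    if emit_fastq:
        with open(outdir / "reads.fastq", "w") as handle:
            for aln in result.alignments:
                seq = aln.umi + "GGGG" + aln.sequence
                handle.write(f"@{aln.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    return result


@dataclass
class RecoveryReport:
    """Pipeline output scored against simulator ground truth."""

    per_gene: pd.DataFrame  # gene_id, true_molecules, umis_collapsed,
    #                         umis_uncollapsed, expected_uncollapsed,
    #                         abs_error, umi_collision
    exact_match_rate: float  # fraction of genes with collapsed == truth
    collision_free_exact_rate: float  # same, restricted to collision-free genes
    n_collision_genes: int
    error_histogram: dict[int, int]


def _has_umi_collision(umis: Sequence[str]) -> bool:
    # two molecules of one gene whose UMIs merge (identical or distance 1)
    # are indistinguishable from one molecule; an unavoidable error source
    for i in range(len(umis)):
        for j in range(i + 1, len(umis)):
            if levenshtein(umis[i], umis[j]) <= 1:
                return True
    return False


def truth_compare(gene_table: pd.DataFrame, truth: SimulationTruth) -> RecoveryReport:
    """Score a pipeline gene table against ground truth.

    ``expected_uncollapsed`` is what coordinate-exact UMI counting should
    report: per molecule, the number of distinct start offsets its reads
    occupy.  Genes with UMI collisions (two molecules whose UMIs are within
    Levenshtein distance 1) are flagged and scored separately, since no
    UMI-based method can resolve them.
    """
    observed = gene_table.set_index("gene_id")
    prov = truth.provenance
    expected_unc = (
        prov.groupby(["gene_id", "molecule_id"])["offset"]
        .nunique()
        .groupby("gene_id")
        .sum()
    )
    rows = []
    for gene_id, true_n in sorted(truth.molecules_per_gene.items()):
        collapsed = int(observed["umis_collapsed"].get(gene_id, 0))
        uncollapsed = int(observed["umis_uncollapsed"].get(gene_id, 0))
        rows.append(
            {
                "gene_id": gene_id,
                "true_molecules": true_n,
                "umis_collapsed": collapsed,
                "umis_uncollapsed": uncollapsed,
                "expected_uncollapsed": int(expected_unc.get(gene_id, 0)),
                "abs_error": abs(collapsed - true_n),
                "umi_collision": _has_umi_collision(truth.molecule_umis[gene_id]),
            }
        )
    per_gene = pd.DataFrame(rows)
    clean = per_gene[~per_gene["umi_collision"]]
    hist = Counter(per_gene["abs_error"].tolist())
    return RecoveryReport(
        per_gene=per_gene,
        exact_match_rate=float((per_gene["abs_error"] == 0).mean()),
        collision_free_exact_rate=(
            float((clean["abs_error"] == 0).mean()) if len(clean) else float("nan")
        ),
        n_collision_genes=int(per_gene["umi_collision"].sum()),
        error_histogram={int(k): int(v) for k, v in sorted(hist.items())},
    )
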