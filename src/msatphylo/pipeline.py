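"""End-to-end orchestration: decompose → consensus → distances → NJ tree.

Stages, in order: read per-locus FASTA, split every allele into flanks and
major region, classify and tabulate repeat architectures, center-star align
intraspecific flanks, build IUPAC consensus per locus and species,
concatenate across loci, align the concatenated consensus across species,
census variation, compute the K2P distance / difference matrix, and infer
the NJ tree with bootstrap supports.  All randomness lives in the bootstrap
and is governed by the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .consensus import (
    AlignScores,
    ConsensusSequence,
    SiteCensus,
    build_consensus,
    census_variation,
    center_star_align,
    concatenate_consensus,
    progressive_align,
)
from .distphylo import (
    DistanceMatrix,
    PhyloTree,
    bootstrap_support,
    build_distance_matrix,
    neighbor_joining,
)
from .repeats import AlleleRecord, decompose_major_region, tabulate_locus
from .seq_io import LocusConfig, SequenceRecord, read_fasta, write_text_atomic

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and record."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``fasta_by_locus`` (paths) or ``records_by_locus``
    (in-memory records) must be provided.  ``seed`` is mandatory whenever
    ``bootstrap_reps > 0``.
    """

    locus_configs: Mapping[str, LocusConfig]
    locus_order: Sequence[str]
    fasta_by_locus: Mapping[str, Path] | None = None
    records_by_locus: Mapping[str, Sequence[SequenceRecord]] | None = None
    scores: AlignScores = field(default_factory=AlignScores)
    ambiguity_threshold: float = 0.0
    bootstrap_reps: int = 1000
    seed: int | None = None
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if (self.fasta_by_locus is None) == (self.records_by_locus is None):
            raise ValueError("provide exactly one of fasta_by_locus / records_by_locus")
        for locus in self.locus_order:
            if locus not in self.locus_configs:
                raise ValueError(f"locus {locus!r} has no configuration (motif unknown)")
        if self.bootstrap_reps > 0 and self.seed is None:
            raise ValueError("a seed is required when bootstrapping")


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    alleles: dict[str, list[AlleleRecord]]
    failures: list[tuple[str, str, str]]  # (locus, record id, reason)
    locus_tables: dict[str, pd.DataFrame]
    consensus: dict[str, ConsensusSequence]  # species -> concatenated consensus
    cross_alignment: dict[str, str]  # species -> gapped row
    census: SiteCensus
    matrix: DistanceMatrix
    tree: PhyloTree
    newick: str
    log: list[str]


def _distance_table(matrix: DistanceMatrix) -> pd.DataFrame:
    """Square table: K2P distances above the diagonal, differences below."""
    taxa = matrix.taxa
    data = []
    for i, a in enumerate(taxa):
        row = []
        for j, _ in enumerate(taxa):
            if i == j:
                row.append("---")
            elif i < j:
                row.append(f"{matrix.d[i, j]:.3f}")
            else:
                row.append(str(int(matrix.differences[i, j])))
        data.append(row)
    return pd.DataFrame(data, index=list(taxa), columns=list(taxa))


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages in order; see the module docstring."""
    log: list[str] = []

    if cfg.records_by_locus is not None:
        records = {loc: list(recs) for loc, recs in cfg.records_by_locus.items()}
    else:
        records = {}
        for locus in cfg.locus_order:
            path = cfg.fasta_by_locus.get(locus)  # type: ignore[union-attr]
            if path is None:
                raise PipelineError(f"stage read: no FASTA for locus {locus!r}")
            records[locus] = read_fasta(path)
    for locus in cfg.locus_order:
        log.append(f"read: locus {locus}: {len(records.get(locus, []))} records")

    alleles: dict[str, list[AlleleRecord]] = {}
    failures: list[tuple[str, str, str]] = []
    for locus in cfg.locus_order:
        locus_cfg = cfg.locus_configs[locus]
        alleles[locus] = []
        for rec in records.get(locus, []):
            try:
                alleles[locus].append(decompose_major_region(rec, locus_cfg))
            except ValueError as exc:
                failures.append((locus, rec.id, str(exc)))
                logger.warning("stage decompose: %s/%s failed: %s", locus, rec.id, exc)
        log.append(
            f"decompose: locus {locus}: {len(alleles[locus])} ok, "
            f"{sum(1 for f in failures if f[0] == locus)} failed"
        )

    species = sorted({a.record.species for locus_alleles in alleles.values() for a in locus_alleles})
    if len(species) < 3:
        raise PipelineError(f"stage decompose: need >= 3 species, found {species}")

    locus_tables = {}
    for locus in cfg.locus_order:
        if alleles[locus]:
            locus_tables[locus] = tabulate_locus(alleles[locus])

    locus_consensus: dict[tuple[str, str], ConsensusSequence] = {}
    per_species_consensus: dict[str, ConsensusSequence] = {}
    for sp in species:
        per_locus = []
        for locus in cfg.locus_order:
            mine = [a for a in alleles[locus] if a.record.species == sp]
            if not mine:
                raise PipelineError(
                    f"stage consensus: species {sp!r} has no alleles at locus {locus!r}"
                )
            aln = progressive_align(
                [(a.flank5, a.flank3) for a in mine],
                locus=locus,
                species=sp,
                scores=cfg.scores,
            )
            cons = build_consensus(aln, cfg.ambiguity_threshold)
            locus_consensus[(sp, locus)] = cons
            per_locus.append(cons)
        per_species_consensus[sp] = concatenate_consensus(per_locus, cfg.locus_order)
        log.append(
            f"consensus: species {sp}: {per_species_consensus[sp].length} bp concatenated"
        )

    # Cross-species alignment is done locus by locus: the locus junctions are
    # known homology anchors, so indel placement cannot drift across them.
    cross_rows = {sp: [] for sp in species}
    for locus in cfg.locus_order:
        block = center_star_align(
            [locus_consensus[(sp, locus)].sequence for sp in species], cfg.scores
        )
        for sp, row in zip(species, block):
            cross_rows[sp].append(row)
    cross_alignment = {sp: "".join(parts) for sp, parts in cross_rows.items()}
    census = census_variation(list(cross_alignment.values()))
    log.append(
        f"census: {census.substitution_sites} substitution + {census.indel_sites} "
        f"indel sites over {census.columns} columns"
    )

    matrix = build_distance_matrix(cross_alignment)
    if cfg.bootstrap_reps > 0:
        tree = bootstrap_support(cross_alignment, n_reps=cfg.bootstrap_reps, seed=cfg.seed)
        log.append(f"tree: NJ with {cfg.bootstrap_reps} bootstrap replicates (seed {cfg.seed})")
    else:
        tree = neighbor_joining(matrix)
        log.append("tree: NJ without bootstrap")
    newick = tree.to_newick(decimals=3)

    report = RunReport(
        alleles=alleles,
        failures=failures,
        locus_tables=locus_tables,
        consensus=per_species_consensus,
        cross_alignment=cross_alignment,
        census=census,
        matrix=matrix,
        tree=tree,
        newick=newick,
        log=log,
    )
    if cfg.out_dir is not None:
        _write_report(report, Path(cfg.out_dir))
    return report


def _write_report(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for locus, table in report.locus_tables.items():
        write_text_atomic(table.to_csv(sep="\t", index=False), out_dir / f"{locus}_summary.tsv")
    write_text_atomic(
        _distance_table(report.matrix).to_csv(sep="\t"), out_dir / "distance_matrix.tsv"
    )
    census = report.census
    census_lines = ["metric\tvalue"]
    for name in (
        "columns",
        "substitution_sites",
        "indel_sites",
        "indel_monomorphic",
        "indel_polymorphic",
        "pct_substitution",
        "pct_indel",
        "at_content",
        "gc_content",
    ):
        value = getattr(census, name)
        census_lines.append(
            f"{name}\t{value:.2f}" if isinstance(value, float) else f"{name}\t{value}"
        )
    write_text_atomic("\n".join(census_lines) + "\n", out_dir / "census.tsv")
    write_text_atomic(report.newick + "\n", out_dir / "tree.nwk")
    aligned_fasta = "".join(
        f">{sp}\n{row}\n" for sp, row in report.cross_alignment.items()
    )
    write_text_atomic(aligned_fasta, out_dir / "consensus_aligned.fasta")
    write_text_atomic("\n".join(report.log) + "\n", out_dir / "pipeline.log")
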