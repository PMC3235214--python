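"""End-to-end orchestration: partition, assign, tabulate, tree, splice, qPCR.

Strata are processed independently per amplified region, mirroring separate
gag / 3'UTR analyses; within a region the genomic copies define the
subfamily partition, RNA records are assigned as queries, and antisense
transcripts additionally go through the splicing stage against the region's
global genomic consensus.  Each stage logs record counts; any stage error
aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import align, phylo, quant, splicing, subfamily
from .errors import AnalysisError, ConfigurationError, HetavarError
from .seq_io import (SequenceRecord, config_hash, write_bed, write_fasta,
                     write_manifest, write_newick, write_table)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis."""

    threshold: float = 0.10
    distance_mode: str = "pairwise"
    min_intron_length: int = splicing.DEFAULT_MIN_INTRON
    position_tolerance: int = splicing.DEFAULT_TOLERANCE
    bootstrap_replicates: int = 1000
    seed: int = 0
    baseline_strain: str = "Oregon-R"
    qpcr_efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ConfigurationError("threshold must be in (0, 1)")
        if self.bootstrap_replicates < 1:
            raise ConfigurationError("bootstrap_replicates must be >= 1")
        if self.distance_mode not in ("pairwise", "msa"):
            raise ConfigurationError("distance_mode must be 'pairwise' or 'msa'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RegionReport:
    """Results for one amplified region."""

    region: str
    partition: subfamily.SubfamilyPartition | None = None
    assignment: subfamily.Assignment | None = None
    abundance: pd.DataFrame | None = None
    tree: object | None = None
    msa: align.MultipleAlignment | None = None
    consensus: str | None = None
    intron_calls: dict[str, list] = dataclasses.field(default_factory=dict)
    variant_catalogue: list = dataclasses.field(default_factory=list)
    variant_labels: dict[str, str] = dataclasses.field(default_factory=dict)
    usage: dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)
    pwm: splicing.SpliceSitePWM | None = None


@dataclasses.dataclass
class Report:
    """Full-analysis result bundle."""

    regions: dict[str, RegionReport]
    qpcr_ratios: pd.Series | None
    config: AnalysisConfig
    manifest: dict


def _stage(name: str):
    logger.info("stage: %s", name)


def analyze_region(
    region: str,
    records: Sequence[SequenceRecord],
    config: AnalysisConfig,
) -> RegionReport:
    report = RegionReport(region=region)
    genomic = [r for r in records if r.material == "genomic"]
    rna = [r for r in records if r.material == "RNA"]
    _stage(f"{region}: {len(genomic)} genomic, {len(rna)} RNA records")
    if len(genomic) < 2:
        logger.warning("%s: fewer than 2 genomic records; region skipped", region)
        return report

    _stage(f"{region}: distance matrix + partition (threshold {config.threshold})")
    msa = None
    if config.distance_mode == "msa" or len(genomic) >= 2:
        msa = align.progressive_msa(genomic)
        report.msa = msa
    dm = align.distance_matrix(genomic, mode=config.distance_mode, msa=msa)
    report.partition = subfamily.complete_linkage_partition(dm, config.threshold)
    logger.info("%s: %d subfamilies over %d genomic records", region,
                report.partition.n_subfamilies, len(genomic))

    labels: dict[str, str] = dict(report.partition.labels)
    if rna:
        _stage(f"{region}: assigning {len(rna)} transcripts")
        report.assignment = subfamily.assign_queries(
            report.partition, genomic, rna, config.threshold
        )
        labels.update(report.assignment.labels)
    report.abundance = subfamily.abundance_table(
        labels, records, all_subfamilies=report.partition.subfamilies
    )

    if len(genomic) >= 4:
        _stage(f"{region}: NJ tree + {config.bootstrap_replicates} bootstraps")
        report.tree = phylo.bootstrap_support(
            msa, n_replicates=config.bootstrap_replicates, seed=config.seed
        )
    elif len(genomic) >= 3:
        report.tree = phylo.nj_tree(dm)

    antisense = [r for r in rna if r.strand == "antisense"]
    if antisense:
        _stage(f"{region}: splice calling on {len(antisense)} antisense transcripts")
        consensus = align.consensus_sequence(msa)
        report.consensus = consensus
        calls = {
            r.record_id: splicing.call_introns(
                r, consensus, min_intron_length=config.min_intron_length,
                reference_id=f"{region}_consensus",
            )
            for r in antisense
        }
        report.intron_calls = calls
        catalogue, vlabels = splicing.classify_variants(
            calls, position_tolerance=config.position_tolerance
        )
        report.variant_catalogue = catalogue
        report.variant_labels = vlabels
        report.usage = splicing.usage_tables(
            vlabels, {r.record_id: labels.get(r.record_id, "unassigned")
                      for r in antisense},
            records,
        )
        canonical = [c for cl in calls.values() for c in cl if c.canonical]
        if len(canonical) >= 2:
            report.pwm = splicing.build_splice_pwm(consensus, canonical)
        logger.info("%s: %d splice variants catalogued", region, len(catalogue))
    else:
        logger.info("%s: no antisense transcripts; splicing stage skipped", region)
    return report


def run_full_analysis(
    records: Sequence[SequenceRecord],
    config: AnalysisConfig | None = None,
    qpcr: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
    force: bool = False,
) -> Report:
    """Run the whole pipeline on annotated records (plus optional qPCR table).

    Returns the in-memory :class:`Report`; when ``outdir`` is given, also
    writes tables (TSV), trees (Newick), intron calls (BED6) and a manifest
    JSON there.
    """
    config = config or AnalysisConfig()
    missing = [r.record_id for r in records if r.region is None or r.material is None]
    if missing:
        raise AnalysisError(f"records lack metadata (attach a sample sheet): {missing[:5]}")

    regions = sorted({r.region for r in records})
    reports: dict[str, RegionReport] = {}
    for region in regions:
        sub = [r for r in records if r.region == region]
        try:
            reports[region] = analyze_region(region, sub, config)
        except HetavarError as exc:
            raise AnalysisError(f"stage failure in region {region}: {exc}") from exc

    ratios = None
    if qpcr is not None:
        _stage("qPCR relative copy number")
        ratios = quant.relative_copy_number(
            qpcr, config.baseline_strain, efficiency=config.qpcr_efficiency
        )

    manifest = {
        "config_hash": config_hash(config.to_dict()),
        "seed": config.seed,
        "n_records": len(records),
        "regions": {
            reg: {
                "n_records": sum(r.region == reg for r in records),
                "n_subfamilies": rep.partition.n_subfamilies if rep.partition else 0,
            }
            for reg, rep in reports.items()
        },
    }
    report = Report(regions=reports, qpcr_ratios=ratios, config=config,
                    manifest=manifest)
    if outdir is not None:
        write_report(report, outdir, force=force)
    return report


def write_report(report: Report, outdir: str | Path, force: bool = False) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def target(name: str) -> Path:
        p = outdir / name
        if p.exists() and not force:
            raise FileExistsError(f"{p} exists; use force to overwrite")
        return p

    for region, rep in report.regions.items():
        if rep.partition is not None:
            write_table(rep.partition.to_frame(), target(f"{region}_partition.tsv"))
        if rep.assignment is not None:
            write_table(rep.assignment.to_frame(), target(f"{region}_assignment.tsv"))
        if rep.abundance is not None:
            write_table(rep.abundance, target(f"{region}_abundance.tsv"))
        if rep.tree is not None:
            write_newick(rep.tree, target(f"{region}_tree.nwk"))
        if rep.intron_calls:
            flat = [c for cl in rep.intron_calls.values() for c in cl]
            write_bed(flat, target(f"{region}_introns.bed"))
            cat = pd.DataFrame(
                [
                    {"variant": v.variant_id, "n_members": v.n_members,
                     "introns": ";".join(f"{d}-{a}" for d, a in v.introns)}
                    for v in rep.variant_catalogue
                ]
            )
            write_table(cat, target(f"{region}_variants.tsv"))
            for name, df in rep.usage.items():
                write_table(df, target(f"{region}_{name}.tsv"))
        if rep.pwm is not None:
            write_table(rep.pwm.to_frame(), target(f"{region}_splice_pwm.tsv"))
        if rep.consensus is not None:
            write_fasta(
                [SequenceRecord(f"{region}_consensus", rep.consensus)],
                target(f"{region}_consensus.fasta"),
            )
    if report.qpcr_ratios is not None:
        df = report.qpcr_ratios.rename_axis("strain").reset_index()
        write_table(df, target("qpcr_ratios.tsv"))
    write_manifest(target("manifest.json"), report.config.to_dict(),
                   report.config.seed, extra={"manifest": report.manifest})
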