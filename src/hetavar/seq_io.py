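"""Reading and writing the on-disk formats the pipeline touches.

Sequence data moves as plain multi-FASTA plus a tab-separated sample sheet
carrying per-clone metadata (strain, amplified region, genomic vs RNA
material, and strand of the RNA amplification).  Downstream results are
written as tidy TSV tables, Newick trees, BED6 intron calls and a JSON run
manifest.  Everything is UTF-8 text with LF newlines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import FormatError

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACGTN")
VALID_ALIGNED = frozenset("ACGTN-")
REGIONS = ("gag", "3UTR")
MATERIALS = ("genomic", "RNA")
STRANDS = ("sense", "antisense", "na")

SHEET_COLUMNS = ["record_id", "strain", "region", "material", "strand"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclasses.dataclass
class SequenceRecord:
    """One cloned amplicon (or reference copy) plus its metadata.

    ``residues`` is the uppercase nucleotide string; metadata fields are
    ``None`` until a sample sheet is attached.  ``oriented`` marks records
    that were reverse-complemented on ingest so that every sequence is
    analyzed in a single common orientation.
    """

    record_id: str
    residues: str
    strain: str | None = None
    region: str | None = None
    material: str | None = None
    strand: str | None = None
    oriented: bool = False

    def __post_init__(self) -> None:
        if not self.record_id:
            raise FormatError("empty record id")
        if not self.residues:
            raise FormatError(f"record {self.record_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_residues(rec_id: str, seq: str, allow_gaps: bool) -> None:
    allowed = VALID_ALIGNED if allow_gaps else VALID_RESIDUES
    bad = set(seq) - allowed
    if bad:
        raise FormatError(
            f"record {rec_id!r} contains invalid characters: "
            f"{', '.join(sorted(bad))}"
        )


def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read a multi-FASTA into :class:`SequenceRecord` objects (metadata unset).

    Order is preserved; lowercase is folded to uppercase.  Characters outside
    ``{A,C,G,T,N}`` (plus ``-`` when ``allow_gaps``) and duplicate ids raise
    :class:`FormatError`.  An empty file returns an empty list with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        seq = str(bio.seq).upper()
        _check_residues(bio.id, seq, allow_gaps)
        if bio.id in seen:
            raise FormatError(f"duplicate record id {bio.id!r} in {path}")
        seen.add(bio.id)
        records.append(SequenceRecord(record_id=bio.id, residues=seq))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 70) -> None:
    """Write records as multi-FASTA wrapped at ``wrap`` columns."""
    path = Path(path)
    bios = [_BioRecord(Seq(r.residues), id=r.record_id, description="") for r in records]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bios)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the TSV sample sheet (record_id, strain, region, material, strand)."""
    try:
        sheet = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse sample sheet {path}: {exc}") from exc
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet {path} lacks columns: {', '.join(missing)}")
    for i, row in sheet.iterrows():
        line = i + 2  # header is line 1
        if row.isna().any():
            raise FormatError(f"sample sheet {path} line {line}: missing field")
        if row["region"] not in REGIONS:
            raise FormatError(f"sample sheet {path} line {line}: bad region {row['region']!r}")
        if row["material"] not in MATERIALS:
            raise FormatError(f"sample sheet {path} line {line}: bad material {row['material']!r}")
        if row["strand"] not in STRANDS:
            raise FormatError(f"sample sheet {path} line {line}: bad strand {row['strand']!r}")
    if sheet["record_id"].duplicated().any():
        dups = sheet.loc[sheet["record_id"].duplicated(), "record_id"].tolist()
        raise FormatError(f"sample sheet {path}: duplicate record ids {dups}")
    return sheet


def write_sample_sheet(records: Iterable[SequenceRecord], path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "strain": r.strain,
            "region": r.region,
            "material": r.material,
            "strand": r.strand,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def attach_metadata(
    records: list[SequenceRecord],
    sheet: pd.DataFrame | Mapping[str, tuple],
    strict: bool = True,
    orient_antisense: bool = False,
) -> list[SequenceRecord]:
    """Annotate records with sample-sheet metadata.

    In strict mode any record without a sheet row (or sheet row without a
    record) is an error; in lenient mode unmatched records are dropped with a
    log message.  With ``orient_antisense`` antisense records are
    reverse-complemented so downstream analysis sees one orientation.
    """
    if isinstance(sheet, pd.DataFrame):
        meta = {
            row["record_id"]: (row["strain"], row["region"], row["material"], row["strand"])
            for _, row in sheet.iterrows()
        }
    else:
        meta = dict(sheet)

    out: list[SequenceRecord] = []
    missing: list[str] = []
    for rec in records:
        if rec.record_id not in meta:
            missing.append(rec.record_id)
            continue
        strain, region, material, strand = meta[rec.record_id]
        residues, oriented = rec.residues, False
        if orient_antisense and strand == "antisense":
            residues, oriented = reverse_complement(residues), True
        out.append(
            SequenceRecord(rec.record_id, residues, strain=strain, region=region,
                           material=material, strand=strand, oriented=oriented)
        )
    if missing:
        if strict:
            raise FormatError(f"records without sample-sheet rows: {', '.join(missing)}")
        logger.warning("dropped %d records without sample-sheet rows: %s",
                       len(missing), ", ".join(missing))
    extra = set(meta) - {r.record_id for r in records}
    if extra and strict:
        raise FormatError(f"sample-sheet rows without records: {', '.join(sorted(extra))}")
    return out


def write_bed(calls: Iterable, path: str | Path) -> None:
    """Write intron calls as BED6 on the named consensus.

    Coordinates are 0-based half-open; the score column carries the splice-site
    PWM score when available (0 otherwise) and the strand column records the
    transcript orientation (``+`` because calls are made on pre-oriented
    transcripts).
    """
    with open(path, "w", newline="\n") as fh:
        for c in calls:
            score = getattr(c, "score", 0.0) or 0.0
            fh.write(
                f"{c.reference_id}\t{c.donor_pos}\t{c.acceptor_pos}\t"
                f"{c.transcript_id}\t{score:g}\t+\n"
            )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio TreeNode as Newick (supports as internal labels)."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def config_hash(config: Mapping) -> str:
    """Stable SHA-256 over a JSON-canonicalized configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path: str | Path, config: Mapping, seed: int | None,
                   extra: Mapping | None = None) -> dict:
    manifest = {
        "config": dict(config),
        "config_hash": config_hash(config),
        "seed": seed,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def write_outputs(outdir: str | Path, *, tables: Mapping[str, pd.DataFrame] | None = None,
                  trees: Mapping[str, object] | None = None,
                  introns: Iterable | None = None,
                  config: Mapping | None = None, seed: int | None = None,
                  force: bool = False) -> list[Path]:
    """Write a result bundle under ``outdir``; refuse to clobber without force."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def target(name: str) -> Path:
        p = outdir / name
        if p.exists() and not force:
            raise FileExistsError(f"{p} exists; pass force=True to overwrite")
        written.append(p)
        return p

    for name, df in (tables or {}).items():
        write_table(df, target(f"{name}.tsv"))
    for name, tree in (trees or {}).items():
        write_newick(tree, target(f"{name}.nwk"))
    if introns is not None:
        write_bed(introns, target("introns.bed"))
    if config is not None:
        write_manifest(target("manifest.json"), config, seed)
    return written
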