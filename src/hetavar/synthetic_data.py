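"""Synthetic clone libraries with known ground truth.

The generator emulates the statistical structure of amplicon clone libraries
from a telomeric retrotransposon: K subfamilies of genomic copies whose
within-subfamily gap-excluded divergence sits well below a clustering
threshold and whose between-subfamily divergence sits well above it, indel
polymorphism producing amplicon size variation, antisense transcripts
carrying a small set of conserved GT..AG splice variants mixed with
unspliced molecules, never-spliced sense transcripts, occasional
"intermediate" sequences falling between subfamilies, and qPCR Ct tables
encoding a known between-strain copy-number ratio.

Sequences are generated on a star topology — a random root, per-subfamily
consensi mutated from the root at half the target inter-subfamily
divergence, and members mutated from their consensus at half the target
intra-subfamily divergence — which gives direct control over expected
pairwise distances.  Substitutions are uniform over the three alternative
bases; indels are geometric-length (p = 0.5) insertions/deletions.  Splice
junction dinucleotides are planted in the root and protected from mutation,
mirroring the strong junction conservation seen in real antisense
transcripts.  Every record's consensus-to-member coordinate map is kept so
intron excision from indel-bearing members is exact.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import decode
from .errors import ConfigurationError
from .seq_io import SequenceRecord

DEFAULT_STRAINS = ("Oregon-R", "GIII")
DEFAULT_REGION = "3UTR"
DEFAULT_TRANSCRIPT_ERROR = 0.001
INTERMEDIATE = "intermediate"
UNSPLICED = "unspliced"

# base codes: A=0 C=1 G=2 T=3
_G, _T, _A = 2, 3, 0


@dataclasses.dataclass
class SpliceVariantSpec:
    """A planted splice form: ordered, non-overlapping intron intervals in
    0-based half-open consensus coordinates (transcript orientation)."""

    variant_id: str
    introns: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        self.introns = tuple((int(d), int(a)) for d, a in self.introns)
        prev_end = -1
        for d, a in self.introns:
            if d >= a:
                raise ConfigurationError(f"{self.variant_id}: donor {d} >= acceptor {a}")
            if d <= prev_end:
                raise ConfigurationError(f"{self.variant_id}: introns overlap or are unsorted")
            prev_end = a
        if not self.introns:
            raise ConfigurationError(f"{self.variant_id}: no introns (use the "
                                     f"'{UNSPLICED}' mixture key instead)")

    def validate_against(self, region_length: int, min_intron_length: int = 1) -> None:
        for d, a in self.introns:
            if a > region_length:
                raise ConfigurationError(
                    f"{self.variant_id}: intron [{d},{a}) extends past region "
                    f"length {region_length}"
                )
            if a - d < min_intron_length:
                raise ConfigurationError(
                    f"{self.variant_id}: intron [{d},{a}) shorter than "
                    f"{min_intron_length} nt"
                )


@dataclasses.dataclass
class GeneratorConfig:
    """Parameters of the synthetic genomic library."""

    n_subfamilies: int = 9
    members_per_subfamily: int | Mapping[str, int] = 5
    region_length: int = 500
    intra_divergence: float = 0.04
    inter_divergence: float = 0.30
    indel_rate: float = 0.002
    n_intermediates: int = 0
    seed: int = 0
    region: str = DEFAULT_REGION
    recoverable: bool = True
    threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.n_subfamilies < 1:
            raise ConfigurationError("n_subfamilies must be >= 1")
        if self.region_length < 1:
            raise ConfigurationError("region_length must be >= 1")
        if not (0 <= self.intra_divergence < 0.5):
            raise ConfigurationError("intra_divergence must be in [0, 0.5)")
        if not (0 < self.inter_divergence <= 0.75):
            raise ConfigurationError("inter_divergence must be in (0, 0.75]")
        if self.indel_rate < 0:
            raise ConfigurationError("indel_rate must be >= 0")
        if self.n_intermediates < 0:
            raise ConfigurationError("n_intermediates must be >= 0")
        counts = self.members_map()
        if any(c < 1 for c in counts.values()):
            raise ConfigurationError("members_per_subfamily must be positive")
        if self.recoverable and not (
            self.intra_divergence < self.threshold < self.inter_divergence
        ):
            raise ConfigurationError(
                "recoverable configs need intra_divergence < threshold < "
                "inter_divergence"
            )

    def members_map(self) -> dict[str, int]:
        if isinstance(self.members_per_subfamily, Mapping):
            return dict(self.members_per_subfamily)
        return {DEFAULT_STRAINS[0]: int(self.members_per_subfamily)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["members_per_subfamily"] = self.members_map()
        return d


@dataclasses.dataclass
class TruthTable:
    """Ground truth for generated records.

    ``records`` has one row per record (record_id, strain, subfamily,
    variant, material, strand).  ``consensi`` are the per-subfamily consensus
    sequences, ``coord_maps`` map consensus coordinates to member coordinates
    for every genomic member (so planted junctions can be located in members
    that carry indels), and the global fields record the planted copy ratio
    and splice-fraction mixture where applicable.
    """

    records: pd.DataFrame
    consensi: dict[str, str] = dataclasses.field(default_factory=dict)
    coord_maps: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    variant_specs: dict[str, SpliceVariantSpec] = dataclasses.field(default_factory=dict)
    copy_ratio: float | None = None
    splice_fractions: dict[str, float] | None = None

    def subfamily_of(self, record_id: str) -> str:
        row = self.records.loc[self.records["record_id"] == record_id]
        return str(row["subfamily"].iloc[0])

    def genomic_members(self, subfamily: str) -> list[str]:
        df = self.records
        mask = (df["subfamily"] == subfamily) & (df["material"] == "genomic")
        return df.loc[mask, "record_id"].tolist()

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()


# ---------------------------------------------------------------------------
# mutation machinery


def _mutate_substitutions(codes: np.ndarray, rate: float, rng,
                          protected: np.ndarray) -> np.ndarray:
    out = codes.copy()
    if rate <= 0:
        return out
    hit = (rng.random(len(codes)) < rate) & ~protected
    idx = np.flatnonzero(hit)
    # uniform over the three alternative bases
    shift = rng.integers(1, 4, size=idx.size)
    out[idx] = (out[idx] + shift) % 4
    return out


def _apply_indels(codes: np.ndarray, rate: float, rng,
                  no_indel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply geometric-length indels; return (new codes, coordinate map).

    ``no_indel`` marks positions that deletions may not touch and at which
    insertions may not be placed (junction neighbourhoods).  The returned
    map has length ``len(codes) + 1``; ``map[i]`` is the output coordinate
    of input position i (for deleted positions, of the next retained base).
    """
    L = len(codes)
    coord = np.zeros(L + 1, dtype=np.int64)
    if rate <= 0:
        coord[:] = np.arange(L + 1)
        return codes.copy(), coord
    events = rng.random(L) < rate
    out: list[int] = []
    skip_until = 0
    for i in range(L):
        if i >= skip_until and events[i] and not no_indel[i]:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                # deletion of [i, i+length) unless it touches a protected base
                end = min(i + length, L)
                if not no_indel[i:end].any():
                    skip_until = end
            else:
                out.extend(int(b) for b in rng.integers(0, 4, size=length))
        coord[i] = len(out)
        if i >= skip_until:
            out.append(int(codes[i]))
    coord[L] = len(out)
    return np.array(out, dtype=codes.dtype), coord


# conserved neighbourhood kept around planted junctions, emulating the
# observation that splice sites are conserved well beyond the GT/AG
# dinucleotides while the surrounding sequence diverges freely: no
# substitutions within +/-8 nt of a junction boundary, and no indels within
# +/-30 nt (an indel abutting a junction would be indistinguishable from an
# alternative splice form)
JUNCTION_CONSERVED_FLANK = 8
JUNCTION_INDEL_FREE_FLANK = 30


def _junction_masks(region_length: int,
                    specs: Sequence[SpliceVariantSpec]) -> tuple[np.ndarray, np.ndarray]:
    """(protected-from-substitution, no-indel) masks around planted junctions."""
    protected = np.zeros(region_length, dtype=bool)
    no_indel = np.zeros(region_length, dtype=bool)
    w, wi = JUNCTION_CONSERVED_FLANK, JUNCTION_INDEL_FREE_FLANK
    for spec in specs:
        for d, a in spec.introns:
            protected[max(d - w, 0):d + w] = True
            protected[max(a - w, 0):min(a + w, region_length)] = True
            no_indel[max(d - wi, 0):d + wi] = True
            no_indel[max(a - wi, 0):min(a + wi, region_length)] = True
    return protected, no_indel


def _plant_junctions(root: np.ndarray, specs: Sequence[SpliceVariantSpec]) -> None:
    for spec in specs:
        for d, a in spec.introns:
            root[d], root[d + 1] = _G, _T
            root[a - 2], root[a - 1] = _A, _G


# ---------------------------------------------------------------------------
# generators


def generate_subfamily_genomes(
    config: GeneratorConfig,
    variant_specs: Sequence[SpliceVariantSpec] = (),
) -> tuple[list[SequenceRecord], TruthTable]:
    """Generate genomic members of K subfamilies (plus intermediates).

    Deterministic given the config seed.  When ``variant_specs`` are given,
    canonical GT/AG junction dinucleotides are planted in the root and
    protected from mutation in every descendant, so all members carry
    usable splice sites.
    """
    rng = np.random.default_rng(config.seed)
    L = config.region_length
    for spec in variant_specs:
        spec.validate_against(L)
    protected, no_indel = _junction_masks(L, variant_specs)

    root = rng.integers(0, 4, size=L).astype(np.uint8)
    _plant_junctions(root, variant_specs)

    subfam_names = [f"S{k + 1}" for k in range(config.n_subfamilies)]
    consensi = {
        name: _mutate_substitutions(root, config.inter_divergence / 2, rng, protected)
        for name in subfam_names
    }

    records: list[SequenceRecord] = []
    rows: list[dict] = []
    coord_maps: dict[str, np.ndarray] = {}
    counter = 0
    for name in subfam_names:
        for strain, n_members in config.members_map().items():
            for _ in range(n_members):
                counter += 1
                member = _mutate_substitutions(
                    consensi[name], config.intra_divergence / 2, rng, protected
                )
                member, coord = _apply_indels(member, config.indel_rate, rng, no_indel)
                rid = f"{strain}_{config.region}_g{counter:03d}"
                records.append(
                    SequenceRecord(rid, decode(member), strain=strain,
                                   region=config.region, material="genomic",
                                   strand="na")
                )
                coord_maps[rid] = coord
                rows.append({"record_id": rid, "strain": strain,
                             "subfamily": name, "variant": "",
                             "material": "genomic", "strand": "na"})

    # intermediates: recombinants of two consensi, landing between subfamilies
    strain0 = next(iter(config.members_map()))
    for k in range(config.n_intermediates):
        if config.n_subfamilies < 2:
            raise ConfigurationError("intermediates need at least 2 subfamilies")
        c1 = consensi[subfam_names[k % config.n_subfamilies]]
        c2 = consensi[subfam_names[(k + 1) % config.n_subfamilies]]
        half = L // 2
        chimera = np.concatenate([c1[:half], c2[half:]])
        counter += 1
        rid = f"{strain0}_{config.region}_g{counter:03d}"
        records.append(
            SequenceRecord(rid, decode(chimera), strain=strain0,
                           region=config.region, material="genomic", strand="na")
        )
        coord_maps[rid] = np.arange(L + 1, dtype=np.int64)
        rows.append({"record_id": rid, "strain": strain0,
                     "subfamily": INTERMEDIATE, "variant": "",
                     "material": "genomic", "strand": "na"})

    truth = TruthTable(
        records=pd.DataFrame(rows),
        consensi={n: decode(c) for n, c in consensi.items()},
        coord_maps=coord_maps,
        variant_specs={s.variant_id: s for s in variant_specs},
    )
    return records, truth


def _largest_remainder(proportions: Mapping[str, float], total: int) -> dict[str, int]:
    keys = sorted(proportions)
    raw = {k: proportions[k] * total for k in keys}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def generate_transcripts(
    genomes: Sequence[SequenceRecord],
    truth: TruthTable,
    per_subfamily_counts: Mapping[str, int],
    strand: str,
    variant_specs: Sequence[SpliceVariantSpec] = (),
    variant_mixture: Mapping[str, float] | None = None,
    seed: int = 0,
    strain: str = DEFAULT_STRAINS[0],
    error_rate: float = DEFAULT_TRANSCRIPT_ERROR,
    region: str | None = None,
) -> tuple[list[SequenceRecord], TruthTable]:
    """Generate transcripts as copies of genomic members, optionally spliced.

    ``per_subfamily_counts`` fixes how many transcripts derive from each true
    subfamily; ``variant_mixture`` gives the proportions of each variant (and
    ``"unspliced"``), realized as exact largest-remainder counts over the
    whole pool and shuffled with the seed.  Sense transcripts are never
    spliced: a sense call with any spliced proportion is rejected.
    Transcripts are error-mutated at ``error_rate`` per site (set 0 for
    exact-recovery experiments).
    """
    if strand not in ("sense", "antisense"):
        raise ConfigurationError("strand must be 'sense' or 'antisense'")
    mixture = dict(variant_mixture) if variant_mixture else {UNSPLICED: 1.0}
    total_prop = sum(mixture.values())
    if abs(total_prop - 1.0) > 1e-9:
        raise ConfigurationError(f"variant mixture sums to {total_prop}, not 1")
    if any(p < 0 for p in mixture.values()):
        raise ConfigurationError("variant mixture proportions must be >= 0")
    spliced_share = sum(p for k, p in mixture.items() if k != UNSPLICED)
    if strand == "sense" and spliced_share > 0:
        raise ConfigurationError("sense transcripts are never spliced; use "
                                 "{'unspliced': 1.0}")
    specs = {s.variant_id: s for s in variant_specs} or dict(truth.variant_specs)
    for key in mixture:
        if key != UNSPLICED and key not in specs:
            raise ConfigurationError(f"no SpliceVariantSpec for mixture key {key!r}")

    by_id = {r.record_id: r for r in genomes}
    region = region or next(iter(by_id.values())).region or DEFAULT_REGION
    rng = np.random.default_rng(seed)

    subfam_plan: list[str] = []
    for fam in sorted(per_subfamily_counts):
        members = truth.genomic_members(fam)
        if not members:
            raise ConfigurationError(f"no genomic members for subfamily {fam!r}")
        subfam_plan.extend([fam] * int(per_subfamily_counts[fam]))
    n_total = len(subfam_plan)
    if n_total == 0:
        raise ConfigurationError("no transcripts requested")

    variant_counts = _largest_remainder(mixture, n_total)
    variant_plan = [v for v in sorted(variant_counts) for _ in range(variant_counts[v])]
    rng.shuffle(variant_plan)

    records: list[SequenceRecord] = []
    rows: list[dict] = []
    for i, (fam, variant) in enumerate(zip(subfam_plan, variant_plan), start=1):
        parent_id = str(rng.choice(truth.genomic_members(fam)))
        parent = by_id[parent_id]
        seq_codes = np.array(
            ["ACGTN".index(c) for c in parent.residues], dtype=np.uint8
        )
        if variant != UNSPLICED:
            coord = truth.coord_maps[parent_id]
            spec = specs[variant]
            for d, a in sorted(spec.introns, reverse=True):
                md, ma = int(coord[d]), int(coord[a])
                seq_codes = np.concatenate([seq_codes[:md], seq_codes[ma:]])
        if error_rate > 0:
            none_protected = np.zeros(len(seq_codes), dtype=bool)
            seq_codes = _mutate_substitutions(seq_codes, error_rate, rng, none_protected)
        rid = f"{strain}_{region}_{strand}_t{i:03d}"
        records.append(
            SequenceRecord(rid, decode(seq_codes), strain=strain, region=region,
                           material="RNA", strand=strand)
        )
        rows.append({"record_id": rid, "strain": strain, "subfamily": fam,
                     "variant": variant, "material": "RNA", "strand": strand})

    realized = pd.Series([r["variant"] for r in rows]).value_counts(normalize=True)
    out_truth = TruthTable(
        records=pd.DataFrame(rows),
        consensi=dict(truth.consensi),
        variant_specs=specs,
        splice_fractions={k: float(v) for k, v in realized.items()},
    )
    return records, out_truth


def generate_qpcr_run(
    copy_ratio: float,
    reference_ct: float = 16.0,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
    strains: tuple[str, str] = DEFAULT_STRAINS,
    element_ct_baseline: float = 24.0,
) -> pd.DataFrame:
    """Ct table for two strains x (element, reference gene).

    The second strain's element Ct is lowered by log2(copy_ratio) relative
    to the first at equal reference-gene Ct, so the ΔΔCt analysis should
    recover ``copy_ratio``.  Gaussian replicate noise at ``noise_sd``.
    """
    if copy_ratio <= 0:
        raise ConfigurationError("copy_ratio must be positive")
    if replicates < 1:
        raise ConfigurationError("need at least 1 replicate")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    from .quant import ELEMENT, REFERENCE

    means = {
        (strains[0], ELEMENT): element_ct_baseline,
        (strains[0], REFERENCE): reference_ct,
        (strains[1], ELEMENT): element_ct_baseline - float(np.log2(copy_ratio)),
        (strains[1], REFERENCE): reference_ct,
    }
    rows = []
    for (strain, target), mean in means.items():
        for rep in range(1, replicates + 1):
            ct = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"strain": strain, "target": target,
                         "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)


def generate_error_test_fixture(
    n_clones: int,
    length: int,
    n_errors: int,
    seed: int | None = None,
) -> tuple[SequenceRecord, list[SequenceRecord]]:
    """Reference plus clones differing by exactly ``n_errors`` substitutions
    spread over distinct (clone, position) sites."""
    if n_clones < 1 or length < 1:
        raise ConfigurationError("need at least one clone and one base")
    if n_errors < 0 or n_errors > n_clones * length:
        raise ConfigurationError("n_errors must be in [0, n_clones * length]")
    rng = np.random.default_rng(seed)
    ref = rng.integers(0, 4, size=length).astype(np.uint8)
    clones = np.tile(ref, (n_clones, 1))
    sites = rng.choice(n_clones * length, size=n_errors, replace=False)
    for site in sites:
        c, p = divmod(int(site), length)
        clones[c, p] = (clones[c, p] + int(rng.integers(1, 4))) % 4
    ref_rec = SequenceRecord("reference", decode(ref))
    clone_recs = [
        SequenceRecord(f"clone{{:0{len(str(n_clones))}d}}".format(i + 1), decode(clones[i]))
        for i in range(n_clones)
    ]
    return ref_rec, clone_recs


def write_dataset(outdir, records: Sequence[SequenceRecord], truth: TruthTable,
                  qpcr: pd.DataFrame | None = None) -> None:
    """Write the generated dataset: FASTA (70-col), sample sheet TSV, truth
    TSV and optional qPCR CSV."""
    from pathlib import Path

    from .seq_io import write_fasta, write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(records, outdir / "sequences.fasta")
    write_sample_sheet(records, outdir / "sample_sheet.tsv")
    truth.records.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if qpcr is not None:
        qpcr.to_csv(outdir / "qpcr.csv", index=False)
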