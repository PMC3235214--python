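"""Pairwise and progressive alignment, gap-excluded distances, consensus.

The distance that drives subfamily classification is the *gap-excluded
p-distance*: the proportion of mismatched positions counted only over
alignment columns where both sequences carry an unambiguous base
(``A/C/G/T``).  Columns containing a gap or an ``N`` are excluded from both
numerator and denominator, so Sanger ambiguities and indel polymorphism do
not inflate divergence.  No substitution-model correction is applied — the
classification threshold is phrased as a raw percentage of nucleotide
changes.

Pairwise alignments are optimal affine-gap global alignments (Gotoh), default
scoring +1 match / -1 mismatch / -4 gap open / -1 gap extend, a regime that
favours long co-linear blocks between copies that are ~90-99% identical.
``N`` is scored 0 against everything.  The multiple aligner is a classic
progressive scheme: average-linkage guide tree on pairwise distances,
profile-profile merges with the same affine DP.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import _dp
from .errors import AnalysisError
from .seq_io import SequenceRecord

GAP_CODE = 5
_CODE = {c: i for i, c in enumerate("ACGTN-")}
_CODE["-"] = GAP_CODE
_DECODE = np.array(list("ACGTN-"))

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP_OPEN = -4.0
DEFAULT_GAP_EXTEND = -1.0


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:
        raise AnalysisError(f"invalid residue {exc.args[0]!r}") from exc


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


def _substitution_matrix(match: float, mismatch: float) -> np.ndarray:
    sub = np.full((5, 5), mismatch)
    np.fill_diagonal(sub, match)
    sub[4, :] = 0.0  # N is ambiguity, scored neutrally
    sub[:, 4] = 0.0
    return sub


@dataclasses.dataclass
class PairwiseAlignment:
    """A global alignment of two sequences: equal-length gapped strings."""

    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise AnalysisError("alignment rows have unequal length")

    def columns(self):
        return zip(self.gapped_a, self.gapped_b)


@dataclasses.dataclass
class MultipleAlignment:
    """Ordered gapped rows of equal length."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AnalysisError("MSA rows have unequal length")
        if len(self.ids) != len(self.rows):
            raise AnalysisError("MSA ids/rows mismatch")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.array([encode(r) for r in self.rows], dtype=np.uint8)

    def row(self, rec_id: str) -> str:
        return self.rows[self.ids.index(rec_id)]


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric gap-excluded distance matrix; NaN marks undefined pairs
    (zero comparable columns)."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise AnalysisError("distance matrix shape does not match ids")

    def __getitem__(self, pair) -> float:
        i, j = (self.ids.index(p) if isinstance(p, str) else p for p in pair)
        return float(self.data[i, j])

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(k) for k in keep]
        return DistanceMatrix(list(keep), self.data[np.ix_(idx, idx)].copy())

    def to_skbio(self):
        from skbio import DistanceMatrix as SkbioDM

        if np.isnan(self.data).any():
            raise AnalysisError(
                "distance matrix has undefined entries; re-align the pairs "
                "in pairwise mode before tree building"
            )
        return SkbioDM(self.data, ids=self.ids)


def global_align(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two sequences.

    A gap of length L costs ``gap_open + (L-1) * gap_extend``.  Traceback
    tie-breaking is deterministic: diagonal, then up (gap in ``b``), then
    left (gap in ``a``).
    """
    if not a or not b:
        raise AnalysisError("cannot align an empty sequence")
    ea, eb = encode(a), encode(b)
    sub = _substitution_matrix(match, mismatch)
    S = sub[ea[:, None], eb[None, :]]
    score, state, TM, TX, TY = _dp.gotoh_fill(S, gap_open, gap_extend)
    moves = _dp.gotoh_traceback(state, TM, TX, TY)
    out_a, out_b = [], []
    i = j = 0
    for mv in moves:
        if mv == _dp.M:
            out_a.append(a[i])
            out_b.append(b[j])
            i += 1
            j += 1
        elif mv == _dp.X:
            out_a.append(a[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(b[j])
            j += 1
    return PairwiseAlignment("".join(out_a), "".join(out_b), float(score))


def gap_excluded_distance(aln: PairwiseAlignment) -> float:
    """Mismatch fraction over columns where both rows have an A/C/G/T base.

    Returns NaN when the pair shares no comparable column.
    """
    ea = encode(aln.gapped_a)
    eb = encode(aln.gapped_b)
    comparable = (ea < 4) & (eb < 4)
    n = int(comparable.sum())
    if n == 0:
        return float("nan")
    mismatches = int((ea[comparable] != eb[comparable]).sum())
    return mismatches / n


def gap_inclusive_distance(aln: PairwiseAlignment) -> float:
    """Sensitivity-analysis variant: gapped columns count as differences.

    Columns where either row is 'N' are still excluded; columns where
    exactly one row is gapped count as mismatches.  Always >= the
    gap-excluded distance for the same alignment.
    """
    ea = encode(aln.gapped_a)
    eb = encode(aln.gapped_b)
    informative = (ea != 4) & (eb != 4)
    n = int(informative.sum())
    if n == 0:
        return float("nan")
    different = int((ea[informative] != eb[informative]).sum())
    return different / n


def pair_distance(a: str, b: str, gap_inclusive: bool = False, **scoring) -> float:
    if a == b:
        return 0.0
    aln = global_align(a, b, **scoring)
    if gap_inclusive:
        return gap_inclusive_distance(aln)
    return gap_excluded_distance(aln)


def distance_matrix(
    records: Sequence[SequenceRecord],
    mode: str = "pairwise",
    msa: MultipleAlignment | None = None,
    **scoring,
) -> DistanceMatrix:
    """Gap-excluded distance matrix over records.

    ``pairwise`` mode aligns every pair from scratch (the default used for
    subfamily classification); ``msa`` mode reads shared columns off a
    multiple alignment.
    """
    if len(records) < 2:
        raise AnalysisError("need at least 2 records for a distance matrix")
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise AnalysisError("duplicate record ids in distance matrix input")
    n = len(ids)
    if mode == "pairwise":
        data = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pair_distance(records[i].residues, records[j].residues, **scoring)
                data[i, j] = data[j, i] = d
        return DistanceMatrix(ids, data)
    if mode == "msa":
        if msa is None:
            raise AnalysisError("msa mode requires a MultipleAlignment")
        order = [msa.ids.index(i) for i in ids]
        return msa_distance_matrix(msa, order=order, ids=ids)
    raise AnalysisError(f"unknown distance mode {mode!r}")


def msa_distance_matrix(
    msa: MultipleAlignment,
    order: Sequence[int] | None = None,
    ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    mat = msa.matrix()
    if order is not None:
        mat = mat[list(order)]
        ids = list(ids)  # type: ignore[arg-type]
    else:
        ids = list(msa.ids)
    return DistanceMatrix(ids, matrix_p_distances(mat))


def matrix_p_distances(mat: np.ndarray) -> np.ndarray:
    """Pairwise-deletion p-distances over the rows of an encoded MSA matrix."""
    n = mat.shape[0]
    good = mat < 4
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = good[i] & good[j]
            tot = int(comp.sum())
            if tot == 0:
                data[i, j] = data[j, i] = np.nan
            else:
                mm = int((mat[i, comp] != mat[j, comp]).sum())
                data[i, j] = data[j, i] = mm / tot
    return data


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _profile_counts(rows: np.ndarray) -> np.ndarray:
    """Per-column counts of A,C,G,T (4 x L); gaps and N contribute nothing."""
    L = rows.shape[1]
    counts = np.zeros((4, L))
    for b in range(4):
        counts[b] = (rows == b).sum(axis=0)
    return counts


def _profile_score_matrix(rows_a, rows_b, match, mismatch) -> np.ndarray:
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na, nb = ca.sum(axis=0), cb.sum(axis=0)
    same = ca.T @ cb  # (La, Lb) expected identical pairs
    total = np.outer(na, nb)
    S = match * same + mismatch * (total - same)
    denom = rows_a.shape[0] * rows_b.shape[0]
    return S / denom


def _merge(rows_a: np.ndarray, rows_b: np.ndarray, match, mismatch,
           gap_open, gap_extend) -> tuple[np.ndarray, np.ndarray]:
    S = _profile_score_matrix(rows_a, rows_b, match, mismatch)
    _, state, TM, TX, TY = _dp.gotoh_fill(S, gap_open, gap_extend)
    moves = _dp.gotoh_traceback(state, TM, TX, TY)
    La = len(moves)
    out_a = np.full((rows_a.shape[0], La), GAP_CODE, dtype=np.uint8)
    out_b = np.full((rows_b.shape[0], La), GAP_CODE, dtype=np.uint8)
    i = j = 0
    for k, mv in enumerate(moves):
        if mv in (_dp.M, _dp.X):
            out_a[:, k] = rows_a[:, i]
            i += 1
        if mv in (_dp.M, _dp.Y):
            out_b[:, k] = rows_b[:, j]
            j += 1
    return out_a, out_b


def progressive_msa(
    records: Sequence[SequenceRecord],
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MultipleAlignment:
    """Progressive multiple alignment (guide tree -> profile merges).

    Deterministic given the input set: the guide order comes from
    average-linkage clustering of pairwise gap-excluded distances with
    id-based tie-breaking, and profile merges reuse the pairwise DP.
    """
    if len(records) < 2:
        raise AnalysisError("need at least 2 records for an MSA")
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    dm = distance_matrix(records, mode="pairwise", match=match,
                         mismatch=mismatch, gap_open=gap_open,
                         gap_extend=gap_extend)
    # order rows deterministically (by id) before building the guide tree so
    # that input permutations cannot change the merge order
    order = sorted(range(len(records)), key=lambda i: records[i].record_id)
    sub = dm.data[np.ix_(order, order)]
    sub = np.nan_to_num(sub, nan=1.0)
    Z = linkage(squareform(sub, checks=False), method="average")

    profiles: dict[int, tuple[list[int], np.ndarray]] = {}
    for k, i in enumerate(order):
        profiles[k] = ([i], encode(records[i].residues)[None, :])
    n = len(records)
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        members_a, rows_a = profiles.pop(ia)
        members_b, rows_b = profiles.pop(ib)
        ra, rb = _merge(rows_a, rows_b, match, mismatch, gap_open, gap_extend)
        profiles[n + step] = (members_a + members_b, np.vstack([ra, rb]))
    (members, rows), = profiles.values()
    # restore original input order
    ordered = sorted(range(len(members)), key=lambda k: members[k])
    ids = [records[members[k]].record_id for k in ordered]
    out_rows = [decode(rows[k]) for k in ordered]
    return MultipleAlignment(ids, out_rows)


# ---------------------------------------------------------------------------
# consensus / identity profile


@dataclasses.dataclass
class IdentityProfile:
    """Per-column modal residue and identity fraction of an MSA.

    ``identity[k]`` is the share of non-gap residues in column k equal to the
    modal residue; NaN (and a flag) for all-gap columns.
    """

    consensus: str
    identity: np.ndarray
    all_gap: np.ndarray


def identity_profile(msa: MultipleAlignment) -> IdentityProfile:
    mat = msa.matrix()
    L = mat.shape[1]
    cons = []
    ident = np.full(L, np.nan)
    all_gap = np.zeros(L, dtype=bool)
    for k in range(L):
        col = mat[:, k]
        nongap = col[col != GAP_CODE]
        if nongap.size == 0:
            cons.append("-")
            all_gap[k] = True
            continue
        counts = np.bincount(nongap, minlength=5)
        best = int(np.argmax(counts))  # argmax takes the first max: alphabetical
        cons.append(_DECODE[best])
        ident[k] = counts[best] / nongap.size
    return IdentityProfile("".join(cons), ident, all_gap)


def consensus_sequence(msa: MultipleAlignment, min_coverage: float = 0.5) -> str:
    """Ungapped consensus: modal base of each column kept when at least
    ``min_coverage`` of rows are non-gap there."""
    mat = msa.matrix()
    n_rows = mat.shape[0]
    out = []
    for k in range(mat.shape[1]):
        col = mat[:, k]
        nongap = col[col != GAP_CODE]
        if nongap.size / n_rows < min_coverage:
            continue
        bases = nongap[nongap < 4]
        if bases.size == 0:
            out.append("N")
            continue
        counts = np.bincount(bases, minlength=4)
        out.append(_DECODE[int(np.argmax(counts))])
    return "".join(out)


def read_alignment_fasta(path) -> MultipleAlignment:
    """Import an externally computed MSA (e.g. MAFFT output) from FASTA."""
    from .seq_io import read_fasta

    recs = read_fasta(path, allow_gaps=True)
    return MultipleAlignment([r.record_id for r in recs],
                             [r.residues for r in recs])
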