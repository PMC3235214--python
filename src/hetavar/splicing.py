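"""Intron detection and splice-variant classification in antisense transcripts.

A transcript is aligned to a reference consensus with a four-state affine DP
whose fourth state models intron-scale deletions: the state's opening
penalty equals the cost an ordinary affine gap would accumulate over
``min_intron_length`` bases, and its per-base extension is near zero, so the
aligner switches to the intron state exactly for deletions longer than the
configured minimum.  Every reference-side deletion of at least that length
becomes an intron call; boundaries are slid up to 5 nt (where the flanking
sequence makes the placement ambiguous) toward the canonical ``GT..AG``
dinucleotides.

Transcripts are then grouped into splice variants — transcripts sharing the
same ordered set of junctions up to a small positional tolerance — and
variants are named SV1, SV2, ... by descending frequency.  A log-odds
position weight matrix built from the called donor and acceptor windows
provides a splice-site score.

All coordinates are 0-based half-open on the reference consensus, in
transcript orientation.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _dp
from .align import (DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, DEFAULT_MATCH,
                    DEFAULT_MISMATCH, _substitution_matrix, encode)
from .errors import AnalysisError
from .seq_io import SequenceRecord
from .subfamily import STRATUM_KEYS

DEFAULT_MIN_INTRON = 40
DEFAULT_TOLERANCE = 3
UNSPLICED = "unspliced"
MAX_JUNCTION_SLIDE = 5


@dataclasses.dataclass(frozen=True)
class IntronCall:
    """One detected intron on a reference consensus (transcript orientation)."""

    transcript_id: str
    reference_id: str
    donor_pos: int      # first intronic base (0-based)
    acceptor_pos: int   # one past the last intronic base
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    canonical: bool

    @property
    def interval(self) -> tuple[int, int]:
        return (self.donor_pos, self.acceptor_pos)

    def __post_init__(self):
        if self.acceptor_pos <= self.donor_pos:
            raise AnalysisError("intron end before start")


@dataclasses.dataclass
class SpliceVariant:
    """A catalogued splice form: an ordered set of junction intervals."""

    variant_id: str
    introns: tuple[tuple[int, int], ...]
    members: list[str]

    @property
    def n_members(self) -> int:
        return len(self.members)


def call_introns(
    transcript: SequenceRecord | str,
    reference_consensus: str,
    min_intron_length: int = DEFAULT_MIN_INTRON,
    reference_id: str = "consensus",
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[IntronCall]:
    """Detect introns in one transcript against a reference consensus.

    Returns calls sorted by donor position; an unspliced transcript yields
    an empty list.  A transcript more than 10% longer than the reference is
    rejected (it is presumably mislabelled or in the wrong orientation).
    """
    if isinstance(transcript, SequenceRecord):
        tid, tseq = transcript.record_id, transcript.residues
    else:
        tid, tseq = "transcript", transcript
    ref = reference_consensus
    if len(tseq) > 1.1 * len(ref):
        raise AnalysisError(
            f"transcript {tid} is >10% longer than the reference; "
            "check orientation/region labels"
        )
    # intron state opens at the cost an ordinary gap reaches at
    # min_intron_length, with near-free extension beyond it
    intron_open = gap_open + (min_intron_length - 1) * gap_extend
    intron_extend = -0.01
    er, et = encode(ref), encode(tseq)
    sub = _substitution_matrix(match, mismatch)
    S = sub[er[:, None], et[None, :]]
    _, state, TM, TX, TY, TN = _dp.intron_fill(
        S, gap_open, gap_extend, intron_open, intron_extend
    )
    moves = _dp.intron_traceback(state, TM, TX, TY, TN)

    # collect maximal runs of reference-consumed / transcript-gap columns
    calls: list[IntronCall] = []
    ref_pos = 0
    run_start, run_len = None, 0
    for mv in moves + [_dp.M]:  # sentinel flushes a trailing run
        if mv in (_dp.X, _dp.N):
            if run_start is None:
                run_start = ref_pos
                run_len = 0
            run_len += 1
            ref_pos += 1
        else:
            if run_start is not None and run_len >= min_intron_length:
                calls.append(_make_call(tid, reference_id, ref,
                                        run_start, run_start + run_len))
            run_start, run_len = None, 0
            if mv in (_dp.M,):
                ref_pos += 1
    return sorted(calls, key=lambda c: c.donor_pos)


def _make_call(tid: str, ref_id: str, ref: str, donor: int, acceptor: int) -> IntronCall:
    donor, acceptor = _slide_to_canonical(ref, donor, acceptor)
    d_dnt = ref[donor:donor + 2]
    a_dnt = ref[acceptor - 2:acceptor]
    return IntronCall(
        transcript_id=tid,
        reference_id=ref_id,
        donor_pos=donor,
        acceptor_pos=acceptor,
        donor_dinucleotide=d_dnt,
        acceptor_dinucleotide=a_dnt,
        canonical=(d_dnt == "GT" and a_dnt == "AG"),
    )


def _slide_to_canonical(ref: str, donor: int, acceptor: int) -> tuple[int, int]:
    """Shift an intron placement toward canonical GT..AG.

    Alignment places an intron boundary ambiguously when the flanking exon
    bases mismatch or repeat; both boundaries are therefore slid jointly
    (intron length preserved) by up to 5 nt and the canonical placement with
    the smallest shift wins.  With no canonical option in range the original
    placement stands.
    """
    def canonical(d: int, a: int) -> bool:
        return ref[d:d + 2] == "GT" and ref[a - 2:a] == "AG"

    def in_bounds(d: int, a: int) -> bool:
        return d >= 0 and a <= len(ref)

    if canonical(donor, acceptor):
        return donor, acceptor
    for dist in range(1, MAX_JUNCTION_SLIDE + 1):
        for s in (-dist, dist):
            d, a = donor + s, acceptor + s
            if in_bounds(d, a) and canonical(d, a):
                return d, a
    return donor, acceptor


def excise(sequence: str, introns: Sequence[tuple[int, int]]) -> str:
    """Remove intron intervals (0-based half-open, non-overlapping) from a
    sequence."""
    out, prev = [], 0
    for d, a in sorted(introns):
        if d < prev:
            raise AnalysisError("overlapping introns")
        out.append(sequence[prev:d])
        prev = a
    out.append(sequence[prev:])
    return "".join(out)


# ---------------------------------------------------------------------------
# variant classification


def classify_variants(
    calls_by_transcript: Mapping[str, Sequence[IntronCall]],
    position_tolerance: int = DEFAULT_TOLERANCE,
) -> tuple[list[SpliceVariant], dict[str, str]]:
    """Group transcripts into splice variants by their junction sets.

    Two junction sets are the same variant when they have the same number of
    introns and every boundary agrees within ``position_tolerance`` nt.
    Grouping is greedy centroid merging in descending group size; variant
    ids SV1, SV2, ... are assigned by descending total frequency (ties by
    leftmost donor).  Transcripts without calls are labelled "unspliced".
    """
    exact: dict[tuple, list[str]] = {}
    unspliced: list[str] = []
    for tid, calls in calls_by_transcript.items():
        if not calls:
            unspliced.append(tid)
            continue
        key = tuple(sorted(c.interval for c in calls))
        exact.setdefault(key, []).append(tid)

    # greedy merge: biggest exact groups found a centroid, the rest join the
    # first centroid they match within tolerance
    order = sorted(exact.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    centroids: list[tuple[tuple, list[str]]] = []
    for key, tids in order:
        merged = False
        for c_key, c_tids in centroids:
            if _same_variant(key, c_key, position_tolerance):
                c_tids.extend(tids)
                merged = True
                break
        if not merged:
            centroids.append((key, list(tids)))

    centroids.sort(key=lambda kv: (-len(kv[1]), kv[0][0][0]))
    catalogue: list[SpliceVariant] = []
    labels: dict[str, str] = {tid: UNSPLICED for tid in unspliced}
    for rank, (key, tids) in enumerate(centroids, start=1):
        vid = f"SV{rank}"
        catalogue.append(SpliceVariant(vid, key, sorted(tids)))
        for tid in tids:
            labels[tid] = vid
    return catalogue, labels


def _same_variant(a: tuple, b: tuple, tol: int) -> bool:
    if len(a) != len(b):
        return False
    return all(
        abs(d1 - d2) <= tol and abs(a1 - a2) <= tol
        for (d1, a1), (d2, a2) in zip(a, b)
    )


# ---------------------------------------------------------------------------
# splice-site PWM


@dataclasses.dataclass
class SpliceSitePWM:
    """Per-position log-odds matrices for donor and acceptor windows.

    Windows are given relative to the junction: the donor window
    ``(-3, +6)`` covers the last 3 exonic and first 6 intronic bases, the
    acceptor window ``(-14, +3)`` the last 14 intronic and first 3 exonic
    bases.  Log-odds are against the background base composition of the
    consensus, with a pseudocount.
    """

    donor: np.ndarray           # (4, donor window length)
    acceptor: np.ndarray        # (4, acceptor window length)
    donor_window: tuple[int, int]
    acceptor_window: tuple[int, int]
    background: np.ndarray

    def information_content(self, which: str) -> np.ndarray:
        mat = self.donor if which == "donor" else self.acceptor
        probs = self.background[:, None] * np.exp2(mat)
        probs = probs / probs.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ic = 2.0 + np.nansum(probs * np.log2(probs), axis=0)
        return ic

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site, mat, (lo, hi) in (
            ("donor", self.donor, self.donor_window),
            ("acceptor", self.acceptor, self.acceptor_window),
        ):
            for k, offset in enumerate(range(lo, hi)):
                rows.append(
                    {"site": site, "offset": offset}
                    | {b: mat[i, k] for i, b in enumerate("ACGT")}
                )
        return pd.DataFrame(rows)


def _window(consensus: str, pos: int, lo: int, hi: int) -> str | None:
    start, end = pos + lo, pos + hi
    if start < 0 or end > len(consensus):
        return None
    return consensus[start:end]


def donor_window_seq(consensus, call, window=(-3, 6)):
    return _window(consensus, call.donor_pos, *window)


def acceptor_window_seq(consensus, call, window=(-14, 3)):
    return _window(consensus, call.acceptor_pos, *window)


def build_splice_pwm(
    consensus: str,
    calls: Sequence[IntronCall],
    donor_window: tuple[int, int] = (-3, 6),
    acceptor_window: tuple[int, int] = (-14, 3),
    pseudocount: float = 0.5,
) -> SpliceSitePWM:
    """Log-odds PWM from the canonical intron calls' junction windows."""
    canon = [c for c in calls if c.canonical]
    if len(canon) < 2:
        raise AnalysisError("need at least 2 canonical calls to train a PWM")
    if pseudocount <= 0:
        raise AnalysisError("pseudocount must be positive")

    comp = np.array([consensus.count(b) for b in "ACGT"], dtype=float)
    background = comp / comp.sum()

    def matrix(windows: list[str], width: int) -> np.ndarray:
        counts = np.full((4, width), pseudocount)
        for w in windows:
            for k, ch in enumerate(w):
                if ch in "ACGT":
                    counts["ACGT".index(ch), k] += 1
        probs = counts / counts.sum(axis=0, keepdims=True)
        return np.log2(probs / background[:, None])

    d_wins = [w for c in canon if (w := donor_window_seq(consensus, c, donor_window))]
    a_wins = [w for c in canon if (w := acceptor_window_seq(consensus, c, acceptor_window))]
    if not d_wins or not a_wins:
        raise AnalysisError("junction windows fall outside the consensus")
    return SpliceSitePWM(
        donor=matrix(d_wins, donor_window[1] - donor_window[0]),
        acceptor=matrix(a_wins, acceptor_window[1] - acceptor_window[0]),
        donor_window=donor_window,
        acceptor_window=acceptor_window,
        background=background,
    )


def score_splice_site(pwm_matrix: np.ndarray, window: str) -> float:
    """Sum of per-position log-odds; higher is more site-like."""
    if len(window) != pwm_matrix.shape[1]:
        raise AnalysisError(
            f"window length {len(window)} does not match PWM width "
            f"{pwm_matrix.shape[1]}"
        )
    total = 0.0
    for k, ch in enumerate(window):
        if ch in "ACGT":
            total += float(pwm_matrix["ACGT".index(ch), k])
    return total


# ---------------------------------------------------------------------------
# usage tables


def usage_tables(
    labels: Mapping[str, str],
    subfamily_labels: Mapping[str, str],
    records: Sequence[SequenceRecord],
) -> dict[str, pd.DataFrame]:
    """Splice-usage summaries.

    Returns three tidy tables:

    * ``spliced_fraction`` — per strain: total transcripts, spliced count and
      spliced percentage;
    * ``variant_usage`` — per strain and variant: count, percentage of all
      antisense transcripts, and percentage of spliced transcripts;
    * ``variant_by_subfamily`` — variant x subfamily counts.
    """
    meta = {r.record_id: r for r in records}
    rows = []
    for tid, var in labels.items():
        r = meta.get(tid)
        rows.append(
            {
                "transcript_id": tid,
                "variant": var,
                "strain": r.strain if r else None,
                "subfamily": subfamily_labels.get(tid, "unassigned"),
            }
        )
    df = pd.DataFrame(rows)

    frac_rows = []
    for strain, grp in df.groupby("strain", dropna=False):
        n = len(grp)
        n_spliced = int((grp["variant"] != UNSPLICED).sum())
        frac_rows.append(
            {
                "strain": strain,
                "n_transcripts": n,
                "n_spliced": n_spliced,
                "spliced_percent": 100.0 * n_spliced / n if n else float("nan"),
            }
        )
    spliced_fraction = pd.DataFrame(frac_rows)

    usage_rows = []
    variants = sorted(
        (v for v in df["variant"].unique() if v != UNSPLICED),
        key=lambda v: int(v[2:]) if v.startswith("SV") and v[2:].isdigit() else 0,
    )
    for strain, grp in df.groupby("strain", dropna=False):
        n_all = len(grp)
        n_spliced = int((grp["variant"] != UNSPLICED).sum())
        for var in variants + [UNSPLICED]:
            c = int((grp["variant"] == var).sum())
            usage_rows.append(
                {
                    "strain": strain,
                    "variant": var,
                    "count": c,
                    "percent_of_all": 100.0 * c / n_all if n_all else float("nan"),
                    "percent_of_spliced": (
                        100.0 * c / n_spliced
                        if (n_spliced and var != UNSPLICED)
                        else float("nan")
                    ),
                }
            )
    variant_usage = pd.DataFrame(usage_rows)

    by_subfam = (
        df.groupby(["variant", "subfamily"]).size().reset_index(name="count")
        if not df.empty
        else pd.DataFrame(columns=["variant", "subfamily", "count"])
    )
    return {
        "spliced_fraction": spliced_fraction,
        "variant_usage": variant_usage,
        "variant_by_subfamily": by_subfam,
    }
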