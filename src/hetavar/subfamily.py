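"""Subfamily classification under a diameter rule, and abundance tables.

A subfamily is a set of copies in which *every* pair differs by no more than
the threshold (default 10%) of gap-excluded nucleotide changes.  Complete-
linkage agglomerative clustering is the scheme whose clusters provably
satisfy exactly that diameter bound, so the partition is built by merging in
ascending complete-linkage distance order and stopping at the threshold.

Transcripts (or any query sequences) are then assigned to the genomic
subfamily whose farthest member is still within the threshold; sequences
that fit no subfamily stay "unassigned" — these materialize the isolated
intermediate copies seen between subfamilies in real data.
"""

from __future__ import annotations

import dataclasses
import itertools
import string
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import DistanceMatrix, pair_distance
from .errors import AnalysisError
from .seq_io import SequenceRecord

DEFAULT_THRESHOLD = 0.10

UNASSIGNED = "unassigned"

STRATUM_KEYS = ["strain", "region", "material", "strand"]


def _letters():
    """A, B, ..., Z, AA, AB, ..."""
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


@dataclasses.dataclass
class SubfamilyPartition:
    """Threshold partition of genomic copies into lettered subfamilies."""

    threshold: float
    labels: dict[str, str]  # record_id -> subfamily letter

    @property
    def subfamilies(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels.values():
            if lab not in seen:
                seen.append(lab)
        return sorted(seen, key=_label_sort_key)

    def members(self, label: str) -> list[str]:
        return sorted(r for r, l in self.labels.items() if l == label)

    @property
    def n_subfamilies(self) -> int:
        return len(set(self.labels.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["record_id", "subfamily"]
        )


def _label_sort_key(label: str):
    return (len(label), label)


def complete_linkage_partition(
    dm: DistanceMatrix, threshold: float = DEFAULT_THRESHOLD
) -> SubfamilyPartition:
    """Agglomerative complete-linkage clustering cut at ``threshold``.

    Merging proceeds in ascending complete-linkage distance, ties broken on
    the lexicographically smallest (min-member-id, min-member-id) pair, and
    stops when the next merge would exceed the threshold, so every emitted
    cluster satisfies the diameter rule.  Undefined (NaN) distances are
    treated as greater than the threshold.

    Labels are letters ordered by descending member count (ties by the
    lexicographically smallest member id).
    """
    n = len(dm.ids)
    if n == 0:
        raise AnalysisError("empty distance matrix")
    D = np.array(dm.data, dtype=float)
    D[np.isnan(D)] = np.inf

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    link = D.copy()  # complete-linkage distance between live clusters
    np.fill_diagonal(link, np.inf)

    def cluster_key(c: int) -> str:
        return min(dm.ids[i] for i in clusters[c])

    while len(clusters) > 1:
        live = sorted(clusters)
        best = (np.inf, None)
        for ai in range(len(live)):
            for bi in range(ai + 1, len(live)):
                a, b = live[ai], live[bi]
                d = link[a, b]
                if d > threshold:
                    continue
                key = tuple(sorted((cluster_key(a), cluster_key(b))))
                cand = (d, key, (a, b))
                if best[1] is None or cand[:2] < best[:2]:
                    best = cand
        if best[1] is None:
            break
        _, _, (a, b) = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        link[a, :] = np.maximum(link[a, :], link[b, :])
        link[:, a] = link[a, :]
        link[a, a] = np.inf
        link[b, :] = np.inf
        link[:, b] = np.inf

    groups = sorted(
        clusters.values(),
        key=lambda g: (-len(g), min(dm.ids[i] for i in g)),
    )
    labels: dict[str, str] = {}
    for letter, group in zip(_letters(), groups):
        for i in group:
            labels[dm.ids[i]] = letter
    part = SubfamilyPartition(threshold=threshold, labels=labels)
    _assert_diameter(part, dm)
    return part


def _assert_diameter(part: SubfamilyPartition, dm: DistanceMatrix) -> None:
    """Post-hoc check of the diameter rule on every emitted subfamily."""
    index = {r: i for i, r in enumerate(dm.ids)}
    for label in part.subfamilies:
        members = part.members(label)
        for a, b in itertools.combinations(members, 2):
            d = dm.data[index[a], index[b]]
            if np.isnan(d) or d > part.threshold + 1e-12:
                raise AnalysisError(
                    f"diameter rule violated in subfamily {label}: "
                    f"d({a},{b})={d}"
                )


def relabel_with_references(
    partition: SubfamilyPartition,
    reference_labels: Mapping[str, str],
) -> SubfamilyPartition:
    """Harmonize subfamily letters with previously named reference copies.

    ``reference_labels`` maps record ids of reference sequences (which must
    have been clustered as part of the partition) to their prior letters.
    Each cluster containing exactly one distinct prior letter adopts it;
    clusters containing conflicting references raise; remaining clusters
    keep fresh letters that do not collide with the adopted ones.
    """
    adopted: dict[str, str] = {}
    for label in partition.subfamilies:
        prior = {reference_labels[m] for m in partition.members(label)
                 if m in reference_labels}
        if len(prior) > 1:
            raise AnalysisError(
                f"cluster {label} contains references with conflicting "
                f"prior labels: {sorted(prior)}"
            )
        if prior:
            adopted[label] = prior.pop()
    if len(set(adopted.values())) != len(adopted):
        raise AnalysisError("two clusters adopted the same prior label")
    fresh = (l for l in _letters() if l not in adopted.values())
    rename = {
        label: adopted.get(label, None) for label in partition.subfamilies
    }
    for label in partition.subfamilies:
        if rename[label] is None:
            rename[label] = next(fresh)
    new_labels = {rid: rename[lab] for rid, lab in partition.labels.items()}
    return SubfamilyPartition(threshold=partition.threshold, labels=new_labels)


@dataclasses.dataclass
class Assignment:
    """Query-to-subfamily assignment.

    ``label`` is a subfamily letter or ``"unassigned"``; ``distance`` is the
    distance to the closest member of the chosen subfamily (NaN when
    unassigned); ``max_distance`` the complete-linkage distance used for the
    decision.
    """

    labels: dict[str, str]
    distances: dict[str, float]
    max_distances: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "record_id": rid,
                "subfamily": self.labels[rid],
                "linkage_distance": self.distances[rid],
                "max_distance": self.max_distances[rid],
            }
            for rid in sorted(self.labels)
        ]
        return pd.DataFrame(rows)


def assign_queries(
    partition: SubfamilyPartition,
    genomic_records: Sequence[SequenceRecord],
    query_records: Sequence[SequenceRecord],
    threshold: float | None = None,
    **scoring,
) -> Assignment:
    """Assign each query to the subfamily minimizing the complete-linkage
    (max-to-any-member) distance, among subfamilies where that distance is
    within the threshold; otherwise "unassigned".

    Ties are broken by smaller mean distance, then label order.
    """
    threshold = partition.threshold if threshold is None else threshold
    by_id = {r.record_id: r for r in genomic_records}
    collisions = {q.record_id for q in query_records} & set(by_id)
    if collisions:
        raise AnalysisError(f"query ids collide with genomic ids: {sorted(collisions)}")

    members = {
        lab: [by_id[m] for m in partition.members(lab) if m in by_id]
        for lab in partition.subfamilies
    }
    labels: dict[str, str] = {}
    distances: dict[str, float] = {}
    max_distances: dict[str, float] = {}
    for q in query_records:
        best = None  # (max_d, mean_d, label_key, label, min_d)
        for lab in partition.subfamilies:
            ds = [
                pair_distance(q.residues, m.residues, **scoring)
                for m in members[lab]
            ]
            ds = [d for d in ds if not np.isnan(d)] or [np.inf]
            max_d, mean_d, min_d = max(ds), float(np.mean(ds)), min(ds)
            if max_d > threshold:
                continue
            cand = (max_d, mean_d, _label_sort_key(lab), lab, min_d)
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is None:
            labels[q.record_id] = UNASSIGNED
            distances[q.record_id] = float("nan")
            max_distances[q.record_id] = float("nan")
        else:
            labels[q.record_id] = best[3]
            distances[q.record_id] = best[4]
            max_distances[q.record_id] = best[0]
    return Assignment(labels, distances, max_distances)


def abundance_table(
    labels: Mapping[str, str],
    records: Sequence[SequenceRecord],
    all_subfamilies: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Counts and within-stratum proportions per subfamily.

    A stratum is a (strain, region, material, strand) combination; zero rows
    are emitted for subfamilies absent from a stratum so that, e.g., the
    absence of a subfamily from one strain is explicit.  Proportions are NaN
    in empty strata.
    """
    meta = {r.record_id: r for r in records}
    rows = []
    for rid, lab in labels.items():
        r = meta.get(rid)
        if r is None:
            raise AnalysisError(f"no metadata for record {rid}")
        rows.append(
            {
                "record_id": rid,
                "subfamily": lab,
                "strain": r.strain,
                "region": r.region,
                "material": r.material,
                "strand": r.strand,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=STRATUM_KEYS + ["subfamily", "count", "proportion"]
        )
    subfams = list(all_subfamilies) if all_subfamilies is not None else sorted(
        df["subfamily"].unique(), key=_label_sort_key
    )
    strata = df[STRATUM_KEYS].drop_duplicates()
    out = []
    for _, st in strata.iterrows():
        mask = (df[STRATUM_KEYS] == st.values).all(axis=1)
        sub = df[mask]
        total = len(sub)
        counts = sub["subfamily"].value_counts()
        for fam in subfams:
            c = int(counts.get(fam, 0))
            out.append(
                dict(st) | {
                    "subfamily": fam,
                    "count": c,
                    "proportion": (c / total) if total else float("nan"),
                }
            )
        # queries that matched no subfamily still appear in their stratum
        extra = set(counts.index) - set(subfams)
        for fam in sorted(extra):
            c = int(counts.get(fam, 0))
            out.append(
                dict(st) | {
                    "subfamily": fam,
                    "count": c,
                    "proportion": c / total,
                }
            )
    result = pd.DataFrame(out)
    # invariant: proportions sum to 1 within every non-empty stratum
    sums = result.dropna(subset=["proportion"]).groupby(STRATUM_KEYS)["proportion"].sum()
    if not np.allclose(sums.values, 1.0, atol=1e-9):
        raise AnalysisError("stratum proportions do not sum to 1")
    return result
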