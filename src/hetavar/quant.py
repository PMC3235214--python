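"""Relative copy number from qPCR, sampling coverage, polymerase fidelity.

Copy number is quantified by the ΔΔCt method: per strain the element's mean
Ct is normalized against a single-copy reference gene (actin), and the
between-strain ratio is ``E^(ΔCt_baseline - ΔCt_strain)`` with the
amplification efficiency E fixed at 2 (one doubling per cycle).  An
efficiency parameter is exposed for sensitivity analysis; standard-curve
calibration is out of scope.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .align import global_align, encode
from .errors import AnalysisError
from .seq_io import SequenceRecord

ELEMENT = "element"
REFERENCE = "reference_gene"

QPCR_COLUMNS = ["strain", "target", "replicate", "ct"]


def _validate_qpcr(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise AnalysisError(f"qPCR table lacks columns: {', '.join(missing)}")
    if (table["ct"] <= 0).any():
        raise AnalysisError("Ct values must be positive")
    return table


def relative_copy_number(
    table: pd.DataFrame,
    baseline_strain: str,
    efficiency: float = 2.0,
) -> pd.Series:
    """Per-strain copy number relative to ``baseline_strain`` (ΔΔCt).

    Requires both the element and the reference-gene target for every
    strain; the baseline strain's ratio is 1 by construction.
    """
    table = _validate_qpcr(table)
    strains = table["strain"].unique()
    if baseline_strain not in strains:
        raise AnalysisError(f"baseline strain {baseline_strain!r} absent from table")
    delta_ct = {}
    for strain in strains:
        sub = table[table["strain"] == strain]
        cts = {t: sub.loc[sub["target"] == t, "ct"] for t in (ELEMENT, REFERENCE)}
        for target, vals in cts.items():
            if vals.empty:
                raise AnalysisError(f"strain {strain!r} lacks target {target!r}")
        delta_ct[strain] = float(cts[ELEMENT].mean() - cts[REFERENCE].mean())
    base = delta_ct[baseline_strain]
    ratios = {s: float(efficiency ** (base - d)) for s, d in delta_ct.items()}
    return pd.Series(ratios, name="relative_copy_number")


def coverage_ratio(n_sequences_analyzed: int, estimated_copy_number: float) -> float:
    """How many times over the estimated copy number was sampled by cloning."""
    if estimated_copy_number <= 0:
        raise AnalysisError("estimated copy number must be positive")
    if n_sequences_analyzed < 0:
        raise AnalysisError("sequence count cannot be negative")
    if n_sequences_analyzed == 0:
        warnings.warn("coverage computed from zero sequences", stacklevel=2)
        return 0.0
    return n_sequences_analyzed / estimated_copy_number


def polymerase_error_rate(
    reference: SequenceRecord | str,
    clones: Sequence[SequenceRecord | str],
    count_indels: bool = False,
    **scoring,
) -> tuple[int, float]:
    """Fidelity control: substitutions between re-sequenced clones and their
    known reference.

    Each clone is globally aligned to the reference; substitutions are
    counted over comparable (both-base) columns and the rate is total
    substitutions per compared nucleotide.  Indels are counted separately
    and only folded into the error count with ``count_indels``.
    """
    ref = reference.residues if isinstance(reference, SequenceRecord) else reference
    if not clones:
        raise AnalysisError("no clones supplied")
    n_sub = n_indel = n_compared = 0
    for clone in clones:
        seq = clone.residues if isinstance(clone, SequenceRecord) else clone
        if len(seq) < 0.5 * len(ref):
            raise AnalysisError("clone shorter than 50% of the reference")
        aln = global_align(ref, seq, **scoring)
        ea, eb = encode(aln.gapped_a), encode(aln.gapped_b)
        comparable = (ea < 4) & (eb < 4)
        n_compared += int(comparable.sum())
        n_sub += int((ea[comparable] != eb[comparable]).sum())
        gap = 5
        n_indel += int(((ea == gap) ^ (eb == gap)).sum())
    n_errors = n_sub + (n_indel if count_indels else 0)
    rate = n_errors / n_compared if n_compared else float("nan")
    return n_errors, rate
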