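"""Alignment operations: end-truncation, haplotype collapsing, polymorphic
sites, and inter-sequence distances.

Missing-data policy (complete deletion): sites containing ``-`` or ``N`` in
any retained sequence are removed before pairwise-difference statistics, and
a column counts as segregating only if it shows >= 2 distinct non-missing
states.  Coordinates are 0-based internally, 1-based in reports.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    AlignmentError,
    HaplotypeTable,
    PopulationPartition,
    SequenceAlignment,
)

_GAP = b"-"
_N = b"N"


def truncate_gapped_ends(aln: SequenceAlignment) -> SequenceAlignment:
    """Drop leading/trailing columns that contain any gap.

    Interior gapped columns are kept untouched; only the terminal runs of
    gap-containing columns are removed.
    """
    mat = aln.to_matrix()
    has_gap = (mat == _GAP).any(axis=0)
    clean = np.flatnonzero(~has_gap)
    if clean.size == 0:
        raise AlignmentError("every column contains a gap; nothing left")
    start, stop = int(clean[0]), int(clean[-1]) + 1
    if start == 0 and stop == aln.length:
        return aln
    return SequenceAlignment(
        sample_ids=list(aln.sample_ids),
        sequences=[s[start:stop] for s in aln.sequences],
    )


def collapse_haplotypes(
    aln: SequenceAlignment, part: PopulationPartition
) -> HaplotypeTable:
    """Merge identical sequences into haplotypes with per-population counts.

    Haplotype order is first occurrence in the alignment.
    """
    pops = part.populations
    pop_index = {p: j for j, p in enumerate(pops)}
    hap_index: dict[str, int] = {}
    haplotypes: list[str] = []
    counts_rows: list[np.ndarray] = []
    for sid, seq in zip(aln.sample_ids, aln.sequences):
        if seq not in hap_index:
            hap_index[seq] = len(haplotypes)
            haplotypes.append(seq)
            counts_rows.append(np.zeros(len(pops), dtype=int))
        counts_rows[hap_index[seq]][pop_index[part.assignments[sid]]] += 1
    return HaplotypeTable(
        haplotype_sequences=haplotypes,
        counts=np.vstack(counts_rows),
        populations=pops,
    )


def segregating_sites(aln: SequenceAlignment) -> tuple[int, list[int]]:
    """Count polymorphic columns (>= 2 distinct non-missing states).

    Gaps and N are ignored when counting states; a column where only one
    non-missing state remains is not segregating.  Returns (count, 0-based
    positions).
    """
    if aln.n < 2:
        raise AlignmentError("need >= 2 sequences to count segregating sites")
    mat = aln.to_matrix().view(np.uint8)
    valid = (mat != ord("-")) & (mat != ord("N"))
    # a column is segregating iff min != max over its non-missing states
    lo = np.where(valid, mat, 255).min(axis=0)
    hi = np.where(valid, mat, 0).max(axis=0)
    seg = valid.any(axis=0) & (lo != hi)
    positions = np.flatnonzero(seg).tolist()
    return len(positions), positions


def complete_deletion(aln: SequenceAlignment) -> np.ndarray:
    """(n, L') matrix after removing every column containing '-' or 'N'."""
    mat = aln.to_matrix()
    keep = ~(((mat == _GAP) | (mat == _N)).any(axis=0))
    return mat[:, keep]


def hamming_distance_matrix(aln: SequenceAlignment) -> np.ndarray:
    """Pairwise number of differences after complete deletion."""
    mat = complete_deletion(aln)
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1 :] = (mat[i + 1 :, :] != mat[i, :]).sum(axis=1)
    return d + d.T


def k2p_distance_matrix(aln: SequenceAlignment) -> np.ndarray:
    """Kimura two-parameter distances (per alignment, in substitutions).

    d = -L/2 * ln((1-2P-Q) * sqrt(1-2Q)) with P, Q the transition and
    transversion proportions over complete-deletion sites; scaled by the
    number of compared sites so values are in expected substitutions per
    sequence, comparable with Hamming counts.
    """
    mat = complete_deletion(aln)
    n, L = mat.shape
    if L == 0:
        return np.zeros((n, n))
    purine = (mat == b"A") | (mat == b"G")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = mat[i] != mat[j]
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int((diff & (purine[i] != purine[j])).sum())
            P, Q = ts / L, tv / L
            arg = (1 - 2 * P - Q) * np.sqrt(max(1 - 2 * Q, 1e-12))
            if arg <= 0:
                dist = np.inf
            else:
                dist = -0.5 * np.log(arg) * L
            d[i, j] = d[j, i] = dist
    return d
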