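"""Pairwise alignment and the gap-aware Jukes-Cantor distance.

The distance definition is the load-bearing piece: observed dissimilarity
``p`` is computed over an aligned pair with terminal gaps ignored and each
maximal internal gap run counted as a single evolutionary event, then
corrected with the Jukes-Cantor formula d = -(3/4)ln(1 - (4/3)p).
"""

from __future__ import annotations

import warnings
from math import log

import numpy as np
from Bio import Align

#: cap applied when p reaches the Jukes-Cantor pole at 3/4
JC_MAX_DISTANCE = 5.0

GAP = "-"


class IncomparablePairError(ValueError):
    """Raised when an aligned pair shares no comparable columns."""


def _set_gap_attr(aligner: Align.PairwiseAligner, attr: str, value: float) -> None:
    # attribute names were renamed across Biopython releases
    legacy = {
        "open_internal_gap_score": "internal_open_gap_score",
        "extend_internal_gap_score": "internal_extend_gap_score",
        "open_end_gap_score": "end_open_gap_score",
        "extend_end_gap_score": "end_extend_gap_score",
        "open_end_insertion_score": "target_end_open_gap_score",
        "extend_end_insertion_score": "target_end_extend_gap_score",
        "open_end_deletion_score": "query_end_open_gap_score",
        "extend_end_deletion_score": "query_end_extend_gap_score",
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            setattr(aligner, attr, value)
        except AttributeError:
            setattr(aligner, legacy[attr], value)


def make_aligner(
    mode: str = "overlap",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    """Configure a global DNA aligner.

    Modes
    -----
    ``overlap``
        Terminal gaps free on both sequences (semi-global); for comparing
        two fragments of the same region.
    ``fragment``
        Terminal gaps free only for reference overhang: the first (tag)
        sequence must be fully consumed.  This is the blast-like semantics
        for scanning a short tag against a long reference - without it, an
        unrelated reference can win with a tiny chance overlap at one end.
    ``global``
        Terminal gaps penalized like internal ones on both sequences.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    _set_gap_attr(aligner, "open_internal_gap_score", gap_open)
    _set_gap_attr(aligner, "extend_internal_gap_score", gap_extend)
    if mode == "overlap":
        _set_gap_attr(aligner, "open_end_gap_score", 0.0)
        _set_gap_attr(aligner, "extend_end_gap_score", 0.0)
    elif mode == "fragment":
        # gaps in the target (tag) row = unaligned reference bases: free
        _set_gap_attr(aligner, "open_end_insertion_score", 0.0)
        _set_gap_attr(aligner, "extend_end_insertion_score", 0.0)
        # gaps in the query (reference) row = unaligned tag bases: penalized
        _set_gap_attr(aligner, "open_end_deletion_score", gap_open)
        _set_gap_attr(aligner, "extend_end_deletion_score", gap_extend)
    elif mode == "global":
        _set_gap_attr(aligner, "open_end_gap_score", gap_open)
        _set_gap_attr(aligner, "extend_end_gap_score", gap_extend)
    else:
        raise ValueError(f"unknown aligner mode {mode!r}")
    return aligner


_DEFAULT_ALIGNER = make_aligner("overlap")


def align_pair(
    a: str, b: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[str, str]:
    """Return the two gapped rows of the best free-end-gap global alignment."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = (aligner or _DEFAULT_ALIGNER).align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _span(row: str) -> tuple[int, int]:
    """Column span [start, end) outside the row's terminal gap runs."""
    n = len(row)
    start = 0
    while start < n and row[start] == GAP:
        start += 1
    end = n
    while end > start and row[end - 1] == GAP:
        end -= 1
    return start, end


def gap_aware_p(a_aligned: str, b_aligned: str) -> float:
    """Observed dissimilarity of an aligned pair.

    Columns inside either row's terminal gap runs are ignored.  Within the
    remaining span, base-base columns each count one compared event (one
    difference if mismatched) and each maximal internal gap run in one row
    counts exactly one event and one difference.  Columns gapped in both
    rows are skipped and do not split a gap run.

    Raises
    ------
    IncomparablePairError
        If no column is comparable (zero events).
    """
    if len(a_aligned) != len(b_aligned):
        raise ValueError("aligned rows differ in length")
    sa, ea = _span(a_aligned)
    sb, eb = _span(b_aligned)
    start, end = max(sa, sb), min(ea, eb)

    events = 0
    diffs = 0
    in_gap_a = False
    in_gap_b = False
    for i in range(start, end):
        ca, cb = a_aligned[i], b_aligned[i]
        if ca == GAP and cb == GAP:
            continue  # shared gap column: ignored, does not break a run
        if ca == GAP:
            in_gap_b = False
            if not in_gap_a:
                in_gap_a = True
                events += 1
                diffs += 1
        elif cb == GAP:
            in_gap_a = False
            if not in_gap_b:
                in_gap_b = True
                events += 1
                diffs += 1
        else:
            in_gap_a = in_gap_b = False
            events += 1
            if ca != cb:
                diffs += 1
    if events == 0:
        raise IncomparablePairError(
            "aligned pair shares no comparable columns (disjoint spans)"
        )
    return diffs / events


def jukes_cantor(p: float, max_distance: float = JC_MAX_DISTANCE) -> float:
    """Jukes-Cantor correction d = -(3/4)ln(1 - (4/3)p).

    Saturated pairs (p >= 3/4, where the correction diverges) are capped at
    ``max_distance`` with a warning so that downstream clustering stays
    total.
    """
    if p < 0:
        raise ValueError(f"p must be non-negative, got {p}")
    if p >= 0.75:
        warnings.warn(
            f"observed dissimilarity p={p:.4f} is at or beyond the "
            f"Jukes-Cantor pole; capping distance at {max_distance}",
            stacklevel=2,
        )
        return max_distance
    return min(-0.75 * log(1.0 - p * 4.0 / 3.0), max_distance)


_FRAGMENT_ALIGNER = make_aligner("fragment")


def pairwise_similarity(
    tag: str, reference: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Gap-aware similarity 1 - p of a tag aligned as a reference fragment.

    The tag must be fully consumed; only reference overhang is free, so a
    tag equal to an internal window of a long reference scores 1.0 while
    chance end-overlaps with unrelated references score poorly.  A pair
    whose best alignment has no overlapping columns gets similarity 0.
    """
    ra, rb = align_pair(tag, reference, aligner or _FRAGMENT_ALIGNER)
    try:
        return 1.0 - gap_aware_p(ra, rb)
    except IncomparablePairError:
        return 0.0


# ---------------------------------------------------------------------------
# star alignment
# ---------------------------------------------------------------------------


def star_alignment(
    seqs: list[str],
    center_index: int = 0,
    aligner: Align.PairwiseAligner | None = None,
    min_overlap: int = 25,
) -> list[str]:
    """Build a multiple alignment by aligning every sequence to one center.

    Each sequence is pairwise-aligned to ``seqs[center_index]`` with free
    end gaps; the pairwise gap patterns in the center row are merged into a
    master profile, and every row is re-expanded onto it.  This stands in
    for an external MSA tool; the distance definition, not the aligner, is
    what downstream code depends on.

    Highly divergent sequences can best-align to the center by a short
    chance overlap hanging off one end; any pair overlapping fewer than
    ``min_overlap`` columns is re-aligned with penalized end gaps so every
    row spans the center region.
    """
    if not seqs:
        return []
    if len(seqs) == 1:
        return list(seqs)
    center = seqs[center_index]
    L = len(center)
    fallback = make_aligner("global")

    # per-sequence: list of (insertions before center position i) for
    # i in 0..L, plus the center-coordinate run of the aligned row
    per_seq: list[list[list[str]]] = []
    for idx, s in enumerate(seqs):
        if idx == center_index:
            per_seq.append([[] for _ in range(L + 1)] )
            continue
        rc, rs = align_pair(center, s, aligner)
        overlap = sum(1 for cc, cs in zip(rc, rs) if cc != GAP and cs != GAP)
        if overlap < min(min_overlap, len(center), len(s)):
            rc, rs = align_pair(center, s, fallback)
        slots: list[list[str]] = [[] for _ in range(L + 1)]
        pos = 0  # number of center bases consumed
        for cc, cs in zip(rc, rs):
            if cc == GAP:
                slots[pos].append(cs)
            else:
                slots[pos].append(None)  # placeholder for the aligned char
                slots[pos][-1] = cs  # char aligned to center base `pos`
                pos += 1
        per_seq.append(slots)

    # slots[i] for a non-center row: inserted chars before center base i,
    # then (except slots[L]) exactly one char aligned to center base i.
    ins_len = [0] * (L + 1)
    for idx in range(len(seqs)):
        if idx == center_index:
            continue
        slots = per_seq[idx]
        for i in range(L + 1):
            n_ins = len(slots[i]) - (1 if i < L else 0)
            ins_len[i] = max(ins_len[i], n_ins)

    rows: list[str] = []
    for idx in range(len(seqs)):
        out: list[str] = []
        if idx == center_index:
            for i in range(L + 1):
                out.append(GAP * ins_len[i])
                if i < L:
                    out.append(center[i])
        else:
            slots = per_seq[idx]
            for i in range(L + 1):
                aligned_char = slots[i][-1] if i < L else None
                inserted = slots[i][:-1] if i < L else slots[i]
                out.append("".join(inserted).rjust(ins_len[i], GAP))
                if i < L:
                    out.append(aligned_char)
        rows.append("".join(out))
    return rows


def pairwise_distance_values(
    seqs: list[str],
    score_gate_frac: float = 0.25,
    far_distance: float = JC_MAX_DISTANCE,
) -> np.ndarray:
    """All-pairs gap-aware JC distances from per-pair alignments.

    Each close pair is aligned individually (overlap mode) and scored with
    `gap_aware_p` + `jukes_cantor`.  A fast score pass gates out clearly
    distant pairs - anything scoring below ``score_gate_frac`` of the
    shorter length is assigned ``far_distance`` without an exact
    alignment.  The gate only affects pairs whose corrected distance is
    far beyond any OTU cutoff in use.
    """
    n = len(seqs)
    values = np.zeros((n, n))
    aligner = make_aligner("overlap")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saturation warnings on far pairs
        for i in range(n):
            for j in range(i + 1, n):
                a, b = seqs[i], seqs[j]
                if a == b:
                    continue
                gate = score_gate_frac * min(len(a), len(b))
                if aligner.score(a, b) < gate:
                    d = far_distance
                else:
                    try:
                        d = jukes_cantor(gap_aware_p(*align_pair(a, b, aligner)))
                    except IncomparablePairError:
                        d = far_distance
                values[i, j] = values[j, i] = d
    return values


# ---------------------------------------------------------------------------
# vectorized distances over an alignment
# ---------------------------------------------------------------------------

_ENC = np.zeros(128, dtype=np.uint8)
for _i, _c in enumerate("ACGTN", start=1):
    _ENC[ord(_c)] = _i  # 0 encodes the gap


def encode_alignment(rows: list[str]) -> np.ndarray:
    """Encode equal-length aligned rows as a uint8 matrix (gap = 0)."""
    if not rows:
        return np.zeros((0, 0), dtype=np.uint8)
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("alignment rows differ in length")
    buf = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return _ENC[buf].reshape(len(rows), L)


def gap_aware_p_encoded(x: np.ndarray, y: np.ndarray) -> float:
    """`gap_aware_p` on encoded rows; used for all-pairs distance matrices."""
    nzx = np.flatnonzero(x)
    nzy = np.flatnonzero(y)
    if nzx.size == 0 or nzy.size == 0:
        raise IncomparablePairError("row is all gaps")
    start = max(nzx[0], nzy[0])
    end = min(nzx[-1], nzy[-1]) + 1
    if start >= end:
        raise IncomparablePairError("aligned pair shares no comparable columns")
    xs = x[start:end]
    ys = y[start:end]
    both = (xs > 0) & (ys > 0)
    n_bases = int(both.sum())
    diffs = int((xs[both] != ys[both]).sum())
    events = n_bases
    # internal gap runs in one row opposite bases in the other; columns
    # gapped in both rows are dropped first so they cannot split a run
    keep = (xs > 0) | (ys > 0)
    if not keep.all():
        xs, ys = xs[keep], ys[keep]
    for row in (xs == 0, ys == 0):
        if row.any():
            n_runs = int(row[0]) + int((row[1:] & ~row[:-1]).sum())
            events += n_runs
            diffs += n_runs
    if events == 0:
        raise IncomparablePairError("aligned pair shares no comparable columns")
    return diffs / events
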