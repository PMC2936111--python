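"""Rank-thresholded majority-rule taxonomy and cluster assignment.

Each tag is compared against every reference (optionally after a shared
k-mer prefilter), the nearest set is taken as all hits within a small
divergence window of the best hit, and labels are assigned coarse-to-fine
wherever the best similarity clears the rank's threshold and a majority of
the nearest set agrees.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd

from .alignment import make_aligner, pairwise_similarity
from .fileio import (
    EMPTY_TAXONOMY,
    RANKS,
    ReferenceDB,
    TagRecord,
    TaxonomyPath,
)

STATUS_ASSIGNED = "assigned"
STATUS_LOW_SIMILARITY = "unassigned_low_similarity"
STATUS_NO_CANDIDATES = "no_candidates"


@dataclass(frozen=True)
class CandidateHit:
    ref_id: str
    similarity: float


@dataclass(frozen=True)
class AssignmentThresholds:
    """Similarity thresholds per rank plus the majority and window rules.

    Defaults: genus 95%, family 90%, order 85%, class 80%, phylum 75%;
    cluster membership at 75%; a label needs agreement from at least 60% of
    the nearest set, which spans 0.1% divergence below the best hit.
    Comparisons are inclusive (>=).
    """

    genus: float = 0.95
    family: float = 0.90
    order: float = 0.85
    class_: float = 0.80
    phylum: float = 0.75
    cluster: float = 0.75
    majority: float = 0.60
    nearest_window: float = 0.001

    def __post_init__(self) -> None:
        if not (self.genus >= self.family >= self.order >= self.class_ >= self.phylum):
            raise ValueError("rank thresholds must not increase with depth")
        if not 0 < self.majority <= 1:
            raise ValueError("majority must be in (0, 1]")

    def for_rank(self, rank: str) -> float:
        return getattr(self, "class_" if rank == "class" else rank)


@dataclass(frozen=True)
class AssignmentResult:
    tag_id: str
    best_similarity: float
    nearest_set_size: int
    labels: TaxonomyPath
    cluster_label: str | None
    status: str

    @property
    def assigned_depth(self) -> int:
        return self.labels.depth


# ---------------------------------------------------------------------------
# candidate search
# ---------------------------------------------------------------------------


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class KmerIndex:
    """Shared-k-mer prefilter over a reference database.

    Ranks references by the number of tag k-mers they contain and keeps the
    top ``keep`` for exact scoring.  With ``keep`` at least the database
    size this is a no-op, so the search stays exhaustive at desk scale.
    """

    def __init__(self, db: ReferenceDB, k: int = 8):
        self.k = k
        self.db = db
        self._ref_kmers = {r.ref_id: _kmers(r.sequence, k) for r in db}

    def top(self, tag_seq: str, keep: int = 500) -> list[str]:
        tag_k = _kmers(tag_seq, self.k)
        scored = sorted(
            ((len(tag_k & kmers), rid) for rid, kmers in self._ref_kmers.items()),
            key=lambda t: (-t[0], t[1]),
        )
        return [rid for _, rid in scored[:keep]]


def find_candidates(
    tag: TagRecord | str,
    db: ReferenceDB,
    n_hits: int = 100,
    prefilter: KmerIndex | None = None,
    prefilter_keep: int = 500,
    aligner=None,
) -> list[CandidateHit]:
    """The ``n_hits`` most similar references, sorted by similarity.

    Similarity is the gap-aware identity of the best free-end-gap pairwise
    alignment.  Ties are broken by lexicographic ref_id for determinism.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    seq = tag.sequence if isinstance(tag, TagRecord) else tag
    if prefilter is not None:
        ref_ids = prefilter.top(seq, keep=prefilter_keep)
        refs = [db[rid] for rid in ref_ids]
    else:
        refs = list(db)
    aligner = aligner or make_aligner("fragment")
    hits = [
        CandidateHit(r.ref_id, pairwise_similarity(seq, r.sequence, aligner))
        for r in refs
    ]
    hits.sort(key=lambda h: (-h.similarity, h.ref_id))
    return hits[:n_hits]


def select_nearest_set(
    hits: list[CandidateHit], window: float = 0.001
) -> list[CandidateHit]:
    """All hits within ``window`` divergence of the best hit."""
    if not hits:
        return []
    best = hits[0].similarity
    return [h for h in hits if best - h.similarity <= window + 1e-12]


# ---------------------------------------------------------------------------
# majority-rule assignment
# ---------------------------------------------------------------------------


def assign_taxonomy(
    nearest: list[CandidateHit],
    db: ReferenceDB,
    thresholds: AssignmentThresholds = AssignmentThresholds(),
    tag_id: str = "",
) -> AssignmentResult:
    """Assign rank labels coarse-to-fine by inclusive-threshold majority rule.

    At each rank the winning label must (i) have best-hit similarity at or
    above the rank threshold, (ii) be carried — together with the already
    assigned coarser labels — by at least the majority fraction of ALL
    nearest-set members (members unannotated at the rank count against the
    majority), and (iii) nest under the previously assigned rank.
    Assignment stops at the first failing rank, keeping labels
    prefix-complete.
    """
    if not nearest:
        return AssignmentResult(tag_id, 0.0, 0, EMPTY_TAXONOMY, None, STATUS_NO_CANDIDATES)
    best = nearest[0].similarity
    n = len(nearest)
    paths = [db[h.ref_id].taxonomy for h in nearest]

    if best < thresholds.phylum:
        return AssignmentResult(tag_id, best, n, EMPTY_TAXONOMY, None, STATUS_LOW_SIMILARITY)

    assigned: list[str] = []
    for depth, rank in enumerate(RANKS):
        if best < thresholds.for_rank(rank):
            break
        prefix = tuple(assigned)
        votes = Counter(
            p[depth]
            for p in paths
            if p[depth] and tuple(p.labels[:depth]) == prefix
        )
        if not votes:
            break
        label, count = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if count / n < thresholds.majority:
            break
        assigned.append(label)

    labels = TaxonomyPath(tuple(assigned) + ("",) * (len(RANKS) - len(assigned)))
    return AssignmentResult(tag_id, best, n, labels, None, STATUS_ASSIGNED)


def assign_cluster(
    nearest: list[CandidateHit],
    db: ReferenceDB,
    thresholds: AssignmentThresholds = AssignmentThresholds(),
) -> str | None:
    """Majority-rule cluster label, or None.

    Requires best similarity at or above the cluster threshold and a
    majority of ALL nearest-set members carrying the same label; members
    without any cluster label count against the majority.
    """
    if not nearest:
        return None
    best = nearest[0].similarity
    if best < thresholds.cluster:
        return None
    labels = [db[h.ref_id].cluster_label for h in nearest]
    votes = Counter(lab for lab in labels if lab is not None)
    if not votes:
        return None
    label, count = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    if count / len(nearest) < thresholds.majority:
        return None
    return label


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------


def assign_tag(
    tag: TagRecord,
    db: ReferenceDB,
    thresholds: AssignmentThresholds = AssignmentThresholds(),
    n_hits: int = 100,
    prefilter: KmerIndex | None = None,
    aligner=None,
) -> AssignmentResult:
    hits = find_candidates(tag, db, n_hits=n_hits, prefilter=prefilter, aligner=aligner)
    nearest = select_nearest_set(hits, thresholds.nearest_window)
    result = assign_taxonomy(nearest, db, thresholds, tag_id=tag.tag_id)
    cluster = assign_cluster(nearest, db, thresholds)
    return replace(result, cluster_label=cluster)


def assign_tags(
    tags: list[TagRecord],
    db: ReferenceDB,
    thresholds: AssignmentThresholds = AssignmentThresholds(),
    n_hits: int = 100,
    use_prefilter: bool = True,
    prefilter_k: int = 8,
    prefilter_keep: int = 500,
) -> list[AssignmentResult]:
    """Assign a batch of tags, caching results per distinct sequence."""
    prefilter = KmerIndex(db, k=prefilter_k) if use_prefilter else None
    aligner = make_aligner("fragment")
    cache: dict[str, AssignmentResult] = {}
    out: list[AssignmentResult] = []
    for tag in tags:
        hit = cache.get(tag.sequence)
        if hit is None:
            hits = find_candidates(
                tag, db, n_hits=n_hits, prefilter=prefilter,
                prefilter_keep=prefilter_keep, aligner=aligner,
            )
            nearest = select_nearest_set(hits, thresholds.nearest_window)
            res = assign_taxonomy(nearest, db, thresholds, tag_id=tag.tag_id)
            hit = replace(res, cluster_label=assign_cluster(nearest, db, thresholds))
            cache[tag.sequence] = hit
        out.append(replace(hit, tag_id=tag.tag_id))
    return out


def assignments_to_frame(results: list[AssignmentResult]) -> pd.DataFrame:
    """Tabular form of assignment results (one row per tag)."""
    rows = []
    for r in results:
        row = {
            "tag_id": r.tag_id,
            "best_similarity": round(r.best_similarity, 6),
            "nearest_set_size": r.nearest_set_size,
        }
        for rank, label in zip(RANKS, r.labels):
            row[rank] = label
        row["cluster"] = r.cluster_label or ""
        row["status"] = r.status
        rows.append(row)
    cols = ["tag_id", "best_similarity", "nearest_set_size", *RANKS, "cluster", "status"]
    return pd.DataFrame(rows, columns=cols)
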