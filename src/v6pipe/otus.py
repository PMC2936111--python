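"""Dereplication, gap-aware JC distance matrices and furthest-neighbour OTUs.

Clustering follows the classic furthest-neighbour (complete linkage)
convention: distances are processed in ascending order and two clusters
merge only once every cross-pair distance between them has been seen, i.e.
a merge at height h requires max cross-pair distance <= h.  A partition at
cutoff c is the state after all merges with height <= c; similarity level
s corresponds to cutoff 1 - s on the corrected-distance scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import (
    encode_alignment,
    gap_aware_p_encoded,
    jukes_cantor,
    pairwise_distance_values,
)
from .fileio import DistanceMatrix, SampleManifest, TagRecord

# re-exported building blocks of the distance definition
from .alignment import gap_aware_p, jukes_cantor  # noqa: F811,F401


@dataclass(frozen=True)
class UniqueSeq:
    """A dereplicated sequence with its tag membership."""

    useq_id: str
    sequence: str
    members: tuple[tuple[str, str], ...]  # (tag_id, sample_id)

    @property
    def weight(self) -> int:
        return len(self.members)


@dataclass
class OtuPartition:
    """A disjoint clustering of unique sequences at one distance cutoff."""

    cutoff: float
    clusters: list[list[str]]  # lists of useq_ids
    representatives: list[str]  # one per cluster, aligned with `clusters`

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    @property
    def similarity_level(self) -> float:
        return 1.0 - self.cutoff


@dataclass
class OtuTable:
    """OTU x sample count matrix at one cutoff, with representative sequences."""

    cutoff: float
    counts: pd.DataFrame  # index otu_id, columns sample_id
    representative_seqs: dict[str, str]  # otu_id -> sequence

    @property
    def n_otus(self) -> int:
        return len(self.counts)

    def abundance_vector(self, samples: list[str] | None = None) -> np.ndarray:
        """Per-OTU total counts (optionally over a subset of samples), nonzero only."""
        sub = self.counts if samples is None else self.counts[samples]
        totals = sub.sum(axis=1).to_numpy()
        return totals[totals > 0]


def dereplicate(tags: list[TagRecord]) -> list[UniqueSeq]:
    """Collapse identical sequences, keeping tag/sample membership.

    Output is ordered by descending weight, ties broken by sequence, and
    ids are assigned U000001... in that order.  The sum of weights equals
    the number of input tags.
    """
    groups: dict[str, list[tuple[str, str]]] = {}
    for t in tags:
        groups.setdefault(t.sequence, []).append((t.tag_id, t.sample_id))
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        UniqueSeq(f"U{i:06d}", seq, tuple(members))
        for i, (seq, members) in enumerate(ordered, start=1)
    ]


def distance_matrix(
    useqs: list[UniqueSeq],
    aligned: dict[str, str] | None = None,
) -> DistanceMatrix:
    """Gap-aware Jukes-Cantor distance matrix over unique sequences.

    ``aligned`` maps useq_id to an aligned (gapped) row from an external
    MSA, in which case every entry is computed from those rows; if
    omitted, each pair is aligned individually (free end gaps) before the
    gap-aware distance is taken - exact for every pair near an OTU cutoff.
    """
    labels = [u.useq_id for u in useqs]
    if aligned is not None:
        missing = [l for l in labels if l not in aligned]
        if missing:
            raise ValueError(f"alignment missing useq(s): {missing[:5]}")
        rows = [aligned[l] for l in labels]
        enc = encode_alignment(rows)
        n = len(labels)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    p = gap_aware_p_encoded(enc[i], enc[j])
                except Exception as exc:
                    raise type(exc)(
                        f"incomparable pair ({labels[i]}, {labels[j]}): {exc}"
                    ) from None
                values[i, j] = values[j, i] = jukes_cantor(p)
    else:
        values = pairwise_distance_values([u.sequence for u in useqs])
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# furthest-neighbour clustering
# ---------------------------------------------------------------------------


def _complete_linkage_merges(m: DistanceMatrix, max_height: float):
    """Merge events [(height, cluster_a, cluster_b)] up to max_height.

    Ascending edge sweep: clusters merge at the height of their largest
    cross-pair distance, exactly when all cross pairs have been seen.
    Ties are processed in lexicographic label order for determinism.
    """
    labels = m.labels
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    edges = sorted(
        (m.values[idx[a], idx[b]], a, b)
        for a, b in itertools.combinations(sorted(labels), 2)
    )
    cluster_of = {lab: i for i, lab in enumerate(labels)}
    size = {i: 1 for i in range(n)}
    seen: dict[tuple[int, int], int] = {}
    merges: list[tuple[float, int, int, int]] = []  # height, a, b, new
    next_id = n
    for d, a, b in edges:
        if d > max_height:
            break
        ca, cb = cluster_of[a], cluster_of[b]
        if ca == cb:
            continue
        key = (ca, cb) if ca < cb else (cb, ca)
        seen[key] = seen.get(key, 0) + 1
        if seen[key] == size[ca] * size[cb]:
            new = next_id
            next_id += 1
            merges.append((d, ca, cb, new))
            # fold pair counters of the merged clusters into the new one
            for other in list(size):
                if other in (ca, cb):
                    continue
                total = seen.pop((min(ca, other), max(ca, other)), 0) + seen.pop(
                    (min(cb, other), max(cb, other)), 0
                )
                if total:
                    seen[(min(new, other), max(new, other))] = total
            seen.pop(key, None)
            size[new] = size.pop(ca) + size.pop(cb)
            for lab, c in cluster_of.items():
                if c in (ca, cb):
                    cluster_of[lab] = new
    return merges, n


def cluster_furthest_neighbor(
    m: DistanceMatrix,
    cutoffs: list[float],
    weights: dict[str, int] | None = None,
) -> list[OtuPartition]:
    """Partitions of the labels at each distance cutoff (complete linkage).

    The representative of a cluster is its highest-weight member (ties by
    lexicographic label); with no weights, the lexicographically smallest
    member.
    """
    if any(c < 0 for c in cutoffs):
        raise ValueError("cutoffs must be non-negative")
    merges, n = _complete_linkage_merges(m, max_height=max(cutoffs, default=0.0))
    partitions = []
    for cutoff in cutoffs:
        members: dict[int, list[str]] = {i: [lab] for i, lab in enumerate(m.labels)}
        for h, ca, cb, new in merges:
            if h > cutoff:
                break
            members[new] = members.pop(ca) + members.pop(cb)
        clusters = []
        for mem in members.values():
            mem = sorted(mem)
            if weights:
                rep = min(mem, key=lambda l: (-weights.get(l, 1), l))
            else:
                rep = mem[0]
            clusters.append((mem, rep))
        clusters.sort(key=lambda cr: cr[0][0])
        partitions.append(
            OtuPartition(
                cutoff=cutoff,
                clusters=[mem for mem, _ in clusters],
                representatives=[rep for _, rep in clusters],
            )
        )
    return partitions


def expand_to_table(
    part: OtuPartition,
    useqs: list[UniqueSeq],
    manifest: SampleManifest | None = None,
    sample_ids: list[str] | None = None,
) -> OtuTable:
    """Map a unique-sequence partition back to per-sample tag counts."""
    by_id = {u.useq_id: u for u in useqs}
    if sample_ids is None:
        if manifest is not None:
            sample_ids = manifest.sample_ids
        else:
            sample_ids = sorted({s for u in useqs for _, s in u.members})
    rows = {}
    reps = {}
    for k, (cluster, rep) in enumerate(zip(part.clusters, part.representatives), 1):
        otu_id = f"OTU{k:05d}"
        counts = dict.fromkeys(sample_ids, 0)
        for useq_id in cluster:
            for _, sample in by_id[useq_id].members:
                if sample not in counts:
                    raise KeyError(f"sample {sample!r} not in table columns")
                counts[sample] += 1
        rows[otu_id] = counts
        reps[otu_id] = by_id[rep].sequence
    counts_df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    if counts_df.empty:
        counts_df = pd.DataFrame(columns=sample_ids, dtype=int)
    counts_df.index.name = "otu_id"
    return OtuTable(cutoff=part.cutoff, counts=counts_df.astype(int), representative_seqs=reps)


def partitions_frame(partitions: list[OtuPartition]) -> pd.DataFrame:
    """Long-form listing (cutoff, otu index, members) for all partitions."""
    rows = []
    for part in partitions:
        for k, (cluster, rep) in enumerate(
            zip(part.clusters, part.representatives), 1
        ):
            rows.append(
                {
                    "cutoff": part.cutoff,
                    "otu_id": f"OTU{k:05d}",
                    "representative": rep,
                    "n_members": len(cluster),
                    "members": ",".join(cluster),
                }
            )
    return pd.DataFrame(rows, columns=["cutoff", "otu_id", "representative", "n_members", "members"])
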