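"""Per-sample taxon profiles, Bray-Curtis similarity, cluster occurrence
and the vertical-vs-seawater transmission classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fileio import RANKS, SampleManifest
from .taxonomy import AssignmentResult

BASIS_ALL = "all_tags"
BASIS_ASSIGNED = "assigned_tags"

CALL_EXCLUSIVE = "sponge_exclusive"
CALL_SEAWATER = "also_in_seawater"

UNASSIGNED = "unassigned"


@dataclass
class TaxonProfile:
    """Relative abundances (percent) of taxa at one rank for one sample."""

    sample_id: str
    rank: str
    abundances: dict[str, float]  # taxon label -> percent
    basis: str
    unassigned_pct: float

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if total > 100 + 1e-6:
            raise ValueError(
                f"profile {self.sample_id}: abundances sum to {total} > 100"
            )


@dataclass
class ClusterOccurrence:
    """Cluster x sample tag-count matrix plus per-group labelled fractions."""

    counts: pd.DataFrame  # index cluster_label, columns sample_id
    relative: pd.DataFrame  # counts / per-sample total tags, in percent
    group_fraction: pd.Series  # per group: labelled tags / total tags
    manifest: SampleManifest


@dataclass(frozen=True)
class TransmissionCall:
    cluster_label: str
    detected_in: frozenset[str]
    call: str


def taxon_profiles(
    assignments: dict[str, list[AssignmentResult]],
    rank: str,
    basis: str = BASIS_ALL,
) -> list[TaxonProfile]:
    """Percent composition per sample at one rank.

    ``assignments`` maps sample_id to that sample's per-tag results.  With
    basis "all_tags" percentages are over every tag in the sample (so
    labelled percentages plus the unassigned bucket sum to 100); with
    "assigned_tags" they are over tags labelled at the rank.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if basis not in (BASIS_ALL, BASIS_ASSIGNED):
        raise ValueError(f"unknown basis {basis!r}")
    depth = RANKS.index(rank)
    profiles = []
    for sample_id, results in assignments.items():
        labels = [r.labels[depth] for r in results]
        counted: dict[str, int] = {}
        n_unassigned = 0
        for lab in labels:
            if lab:
                counted[lab] = counted.get(lab, 0) + 1
            else:
                n_unassigned += 1
        denom = len(labels) if basis == BASIS_ALL else sum(counted.values())
        abundances = {
            lab: 100.0 * c / denom for lab, c in sorted(counted.items())
        } if denom else {}
        unassigned_pct = 100.0 * n_unassigned / len(labels) if labels else 0.0
        profiles.append(
            TaxonProfile(sample_id, rank, abundances, basis, unassigned_pct)
        )
    return profiles


def profiles_frame(profiles: list[TaxonProfile]) -> pd.DataFrame:
    """Taxon x sample percent matrix (unassigned bucket as its own row)."""
    data = {}
    for p in profiles:
        col = dict(p.abundances)
        col[UNASSIGNED] = p.unassigned_pct
        data[p.sample_id] = col
    df = pd.DataFrame(data).fillna(0.0)
    labels = sorted(l for l in df.index if l != UNASSIGNED)
    if UNASSIGNED in df.index:
        labels.append(UNASSIGNED)
    df = df.loc[labels]
    df.index.name = "taxon"
    return df


def display_truncate(df: pd.DataFrame, floor: float = 0.4) -> pd.DataFrame:
    """Display rule for stacked-bar plots: values in (0, floor) shown as floor.

    Data outputs are never truncated; this helper is applied only when
    rendering, so vanishingly rare taxa remain visible in a plot.
    """
    out = df.copy()
    mask = (out > 0) & (out < floor)
    return out.mask(mask, floor)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis similarity (percent): 100 (1 - sum|x-y| / sum(x+y))."""
    num = np.abs(x - y).sum()
    den = (x + y).sum()
    if den == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero profiles")
    return 100.0 * (1.0 - num / den)


def bray_curtis_matrix(
    profiles: list[TaxonProfile], sqrt_transform: bool = False
) -> pd.DataFrame:
    """Symmetric sample x sample Bray-Curtis similarity matrix (percent).

    Profiles must share rank and basis; the taxon label set is the union,
    with absent taxa at zero.
    """
    if not profiles:
        raise ValueError("no profiles given")
    ranks = {p.rank for p in profiles}
    bases = {p.basis for p in profiles}
    if len(ranks) > 1 or len(bases) > 1:
        raise ValueError("profiles mix ranks or bases")
    labels = sorted({lab for p in profiles for lab in p.abundances})
    mat = np.array(
        [[p.abundances.get(lab, 0.0) for lab in labels] for p in profiles]
    )
    if sqrt_transform:
        mat = np.sqrt(mat)
    samples = [p.sample_id for p in profiles]
    n = len(samples)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = bray_curtis(mat[i], mat[j])
            except ValueError:
                raise ValueError(
                    f"Bray-Curtis undefined for all-zero profiles "
                    f"({samples[i]}, {samples[j]})"
                ) from None
            out[i, j] = out[j, i] = s
    return pd.DataFrame(out, index=samples, columns=samples)


def cluster_occurrence(
    assignments: dict[str, list[AssignmentResult]],
    manifest: SampleManifest,
) -> ClusterOccurrence:
    """Cluster-label x sample counts; all-zero rows are dropped.

    Also reports, per sample group, the fraction of tags carrying any
    cluster label.
    """
    samples = manifest.sample_ids
    unknown = sorted(set(assignments) - set(samples))
    if unknown:
        raise ValueError(f"sample(s) not in manifest: {unknown}")
    counts: dict[str, dict[str, int]] = {}
    totals = {s: 0 for s in samples}
    labelled = {s: 0 for s in samples}
    for sample_id in samples:
        for r in assignments.get(sample_id, []):
            totals[sample_id] += 1
            if r.cluster_label:
                labelled[sample_id] += 1
                row = counts.setdefault(r.cluster_label, dict.fromkeys(samples, 0))
                row[sample_id] += 1
    df = pd.DataFrame.from_dict(counts, orient="index", columns=samples)
    if df.empty:
        df = pd.DataFrame(columns=samples, dtype=int)
    df = df.sort_index()
    df.index.name = "cluster"
    total_series = pd.Series(totals)
    rel = 100.0 * df.div(total_series.replace(0, np.nan), axis=1).fillna(0.0)
    group_frac = {}
    for group in ("adult", "larvae", "seawater"):
        g_samples = manifest.samples_in_group(group)
        g_total = sum(totals[s] for s in g_samples)
        g_lab = sum(labelled[s] for s in g_samples)
        group_frac[group] = g_lab / g_total if g_total else 0.0
    return ClusterOccurrence(
        counts=df.astype(int),
        relative=rel,
        group_fraction=pd.Series(group_frac),
        manifest=manifest,
    )


def classify_transmission(
    occ: ClusterOccurrence, min_count: int = 1
) -> tuple[list[TransmissionCall], dict[str, float]]:
    """Classify each cluster as sponge-exclusive or also-in-seawater.

    A cluster is "detected" in a group if at least ``min_count`` tags were
    assigned to it in at least one sample of that group.  A cluster never
    detected in seawater is called sponge-exclusive (consistent with
    vertical transmission); a single seawater tag is enough to flip the
    call.
    """
    calls = []
    for cluster, row in occ.counts.iterrows():
        detected = frozenset(
            group
            for group in ("adult", "larvae", "seawater")
            if any(
                row[s] >= min_count for s in occ.manifest.samples_in_group(group)
            )
        )
        if not detected:
            continue
        call = CALL_EXCLUSIVE if "seawater" not in detected else CALL_SEAWATER
        calls.append(TransmissionCall(cluster, detected, call))
    n_detected = len(calls)
    n_seawater = sum(1 for c in calls if c.call == CALL_SEAWATER)
    n_exclusive = n_detected - n_seawater
    summary = {
        "n_detected": n_detected,
        "n_also_in_seawater": n_seawater,
        "n_sponge_exclusive": n_exclusive,
        "pct_sponge_exclusive": 100.0 * n_exclusive / n_detected if n_detected else 0.0,
    }
    return calls, summary


def transmission_frame(calls: list[TransmissionCall]) -> pd.DataFrame:
    rows = [
        {
            "cluster": c.cluster_label,
            "in_adult": "adult" in c.detected_in,
            "in_larvae": "larvae" in c.detected_in,
            "in_seawater": "seawater" in c.detected_in,
            "call": c.call,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["cluster", "in_adult", "in_larvae", "in_seawater", "call"]
    )
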