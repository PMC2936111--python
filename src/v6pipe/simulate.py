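"""Synthetic reference databases, communities and tag datasets.

Generates a rank-structured reference database (a stand-in for a curated
16S database), habitat-specific communities with lognormal rank abundance,
larval samples modelled as adult communities plus a seawater contamination
fraction, rare sponge taxa seeded into seawater at very low abundance, and
per-read sequencing error - all with known ground truth, so every pipeline
stage can be validated end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fileio import (
    ManifestEntry,
    ReferenceDB,
    ReferenceRecord,
    SampleManifest,
    TagRecord,
    TaxonomyPath,
    write_fasta,
    write_manifest,
    write_reference_db,
    write_table,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

RANK_NAMES = ("phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class ErrorModel:
    """Flat per-base substitution and indel rates (454-style, simplified)."""

    sub_rate: float = 0.002
    indel_rate: float = 0.001

    def __post_init__(self) -> None:
        if not (0 <= self.sub_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("error rates must be in [0, 1]")


@dataclass
class ScenarioSpec:
    """Parameters of a full synthetic study.

    Mirrors the study design: three sponge species with three adult
    replicates each, three larval samples (larvae of the first species,
    modelled as the adult community mixed with a seawater contamination
    fraction f), four seawater replicates, and a configurable fraction of
    sponge-associated cluster taxa seeded into seawater at rare abundance.
    """

    n_species: int = 3
    n_adult_replicates: int = 3
    n_larvae: int = 3
    n_seawater: int = 4
    taxa_per_sponge: int = 25
    taxa_seawater: int = 40
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.2
    tags_per_sample: int = 400
    contamination_fraction: float = 0.2
    rare_shared_fraction: float = 0.5
    rare_abundance: float = 2e-3
    error_model: ErrorModel = field(default_factory=ErrorModel)
    # reference database shape
    n_phyla: int = 6
    branching: tuple[int, int, int, int, int] = (2, 2, 1, 2, 2)
    mutation_rates: tuple[float, ...] = (0.16, 0.09, 0.06, 0.045, 0.04, 0.008)
    seq_len: int = 160
    cluster_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contamination_fraction", "rare_shared_fraction", "cluster_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tags_per_sample < 1:
            raise ValueError("tags_per_sample must be >= 1")
        if not 0 < self.rare_abundance < 1:
            raise ValueError("rare_abundance must be in (0, 1)")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    communities: dict[str, dict[str, float]]  # sample -> ref_id -> rel. abundance
    tag_sources: pd.DataFrame  # tag_id, sample_id, source_ref, cluster, ranks...
    cluster_status: dict[str, str]  # cluster label -> designed transmission call
    seeded_clusters: list[str]


@dataclass
class Scenario:
    spec: ScenarioSpec
    refdb: ReferenceDB
    manifest: SampleManifest
    tags: dict[str, list[TagRecord]]  # sample_id -> tags
    truth: GroundTruth

    def all_tags(self) -> list[TagRecord]:
        return [t for sample in self.manifest.sample_ids for t in self.tags[sample]]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for e in self.manifest:
            fasta = f"{e.sample_id}.fasta"
            write_fasta(
                out / fasta,
                [(t.tag_id, t.sequence) for t in self.tags[e.sample_id]],
            )
            entries.append(
                ManifestEntry(e.sample_id, e.group, e.species, e.replicate, fasta)
            )
        write_manifest(SampleManifest(entries), out / "manifest.tsv")
        write_reference_db(self.refdb, out / "refdb.tsv")
        write_table(self.truth.tag_sources, out / "truth_tags.tsv", index=False)
        comm = pd.DataFrame(self.truth.communities).fillna(0.0)
        comm.index.name = "ref_id"
        write_table(comm, out / "truth_communities.tsv")
        status = pd.DataFrame(
            sorted(self.truth.cluster_status.items()), columns=["cluster", "true_status"]
        )
        write_table(status, out / "truth_cluster_status.tsv", index=False)


# ---------------------------------------------------------------------------
# sequence evolution helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        choices = BASES[BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def simulate_reference_db(
    n_phyla: int = 6,
    branching: tuple[int, ...] = (2, 2, 1, 2, 2),
    mutation_rates: tuple[float, ...] = (0.16, 0.09, 0.06, 0.045, 0.04, 0.008),
    seq_len: int = 160,
    cluster_fraction: float = 0.3,
    seed: int = 0,
) -> ReferenceDB:
    """Evolve a reference database down a fixed-shape taxonomy tree.

    One ancestral sequence is mutated per level: the first mutation rate
    separates phyla from the ancestor, the following rates separate
    classes, orders, families, genera and finally individual references
    within a genus.  Rates must be non-increasing with depth (coarser
    ranks are more divergent).  A ``cluster_fraction`` of genera receive
    sponge-specific cluster labels SC01, SC02, ...
    """
    if len(branching) != 5 or len(mutation_rates) != 6:
        raise ValueError("need 5 branching factors and 6 mutation rates")
    if any(a < b for a, b in zip(mutation_rates, mutation_rates[1:])):
        raise ValueError("mutation rates must not increase with rank depth")
    if mutation_rates[0] > 0.35:
        warnings.warn(
            "phylum-level mutation rate may push inter-phylum distances "
            "past Jukes-Cantor saturation",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, seq_len)

    records: list[ReferenceRecord] = []
    genus_labels: list[str] = []
    genus_refs: dict[str, list[int]] = {}

    # tree levels: phylum, class, order, family, genus; branching[:4] gives
    # children per class..genus level, branching[4] the refs per genus
    def descend(seq: np.ndarray, depth: int, name: str, path: list[str]) -> None:
        if depth == 5:  # leaves: individual references within a genus
            genus = path[-1]
            for r in range(branching[4]):
                leaf = _mutate(seq, mutation_rates[5], rng)
                records.append(
                    ReferenceRecord(
                        ref_id=f"{name}.r{r + 1}",
                        sequence=leaf.tobytes().decode("ascii"),
                        taxonomy=TaxonomyPath(tuple(path)),
                        cluster_label=None,
                    )
                )
                genus_refs.setdefault(genus, []).append(len(records) - 1)
            return
        for c in range(branching[depth - 1]):
            child_seq = _mutate(seq, mutation_rates[depth], rng)
            child_name = f"{name}.{'cofg'[depth - 1]}{c + 1}"
            child_path = path + [child_name]
            if depth == 4:
                genus_labels.append(child_name)
            descend(child_seq, depth + 1, child_name, child_path)

    for c in range(n_phyla):
        phylum_seq = _mutate(ancestor, mutation_rates[0], rng)
        pname = f"p{c + 1}"
        descend(phylum_seq, 1, pname, [pname])

    n_clusters = int(round(cluster_fraction * len(genus_labels)))
    labelled = sorted(
        rng.choice(len(genus_labels), size=n_clusters, replace=False).tolist()
    )
    for k, gi in enumerate(labelled, start=1):
        genus = genus_labels[gi]
        for ridx in genus_refs[genus]:
            rec = records[ridx]
            records[ridx] = ReferenceRecord(
                rec.ref_id, rec.sequence, rec.taxonomy, f"SC{k:02d}"
            )
    return ReferenceDB(records)


# ---------------------------------------------------------------------------
# tag generation
# ---------------------------------------------------------------------------


def apply_errors(
    seq: str, model: ErrorModel, rng: np.random.Generator
) -> str:
    """Per-base substitutions and indels at the model's flat rates."""
    out: list[str] = []
    for ch in seq:
        if model.indel_rate and rng.random() < model.indel_rate:
            if rng.random() < 0.5:
                out.append("ACGT"[rng.integers(0, 4)])  # insertion before base
                out.append(ch)
            # else: deletion - drop the base
            continue
        if model.sub_rate and rng.random() < model.sub_rate:
            others = "ACGT".replace(ch, "") or "ACGT"
            out.append(others[rng.integers(0, len(others))])
        else:
            out.append(ch)
    return "".join(out)


def _draw_window(
    ref_seq: str, rng: np.random.Generator, v6_start: int = 49, n_starts: int = 4
) -> str:
    """A 50-60 nt window of the reference's V6 region."""
    length = int(rng.integers(50, 61))
    start = int(rng.integers(v6_start, v6_start + n_starts))
    start = min(start, len(ref_seq) - length)
    return ref_seq[start : start + length]


def simulate_sample(
    community: dict[str, float],
    refdb: ReferenceDB,
    n_tags: int,
    error_model: ErrorModel,
    seed: int | np.random.Generator,
    sample_id: str = "S1",
) -> tuple[list[TagRecord], pd.DataFrame]:
    """Draw ``n_tags`` reads from a community (multinomial over references).

    Each tag is a 50-60 nt window of its source reference's V6 region with
    substitution and indel errors applied.  Returns the tags and a ground
    truth table mapping each tag to its source.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    refs = sorted(community)
    probs = np.array([community[r] for r in refs], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("community has no positive abundances")
    probs = probs / probs.sum()
    draws = rng.multinomial(n_tags, probs)
    tags: list[TagRecord] = []
    truth_rows = []
    i = 0
    for ref_id, count in zip(refs, draws):
        rec = refdb[ref_id]
        for _ in range(count):
            i += 1
            tag_id = f"{sample_id}_t{i:06d}"
            window = _draw_window(rec.sequence, rng)
            seq = apply_errors(window, error_model, rng)
            if not seq:
                seq = window  # pathological all-deleted read; keep the window
            tags.append(TagRecord(tag_id, sample_id, seq))
            truth_rows.append(
                {
                    "tag_id": tag_id,
                    "sample_id": sample_id,
                    "source_ref": ref_id,
                    "cluster": rec.cluster_label or "",
                    **{r: rec.taxonomy.label(r) for r in RANK_NAMES},
                }
            )
    order = rng.permutation(len(tags))
    tags = [tags[k] for k in order]
    truth = pd.DataFrame([truth_rows[k] for k in order])
    return tags, truth


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------


def _lognormal_community(
    refs: list[str], mu: float, sigma: float, rng: np.random.Generator
) -> dict[str, float]:
    ab = rng.lognormal(mu, sigma, size=len(refs))
    ab = ab / ab.sum()
    return dict(zip(refs, ab))


def build_scenario(spec: ScenarioSpec) -> Scenario:
    """Generate the full multi-sample dataset with ground truth.

    Adult communities are lognormal over species-specific taxon sets;
    larvae (of the first species) are (1 - f) adult + f seawater; the
    seawater community holds its own cluster-free taxa plus a
    ``rare_shared_fraction`` of the sponge-associated clusters seeded at
    ``rare_abundance``.  A cluster's designed transmission status is
    sponge-exclusive exactly when it was not seeded into seawater.
    """
    rng = np.random.default_rng(spec.seed)
    refdb = simulate_reference_db(
        n_phyla=spec.n_phyla,
        branching=spec.branching,
        mutation_rates=spec.mutation_rates,
        seq_len=spec.seq_len,
        cluster_fraction=spec.cluster_fraction,
        seed=int(rng.integers(2**31)),
    )
    ref_ids = [r.ref_id for r in refdb]
    cluster_of = {r.ref_id: r.cluster_label for r in refdb}

    # species-specific adult communities
    species_names = [f"sponge{s + 1}" for s in range(spec.n_species)]
    adult_comm: dict[str, dict[str, float]] = {}
    available = list(ref_ids)
    for sp in species_names:
        chosen = rng.choice(available, size=min(spec.taxa_per_sponge, len(available)),
                            replace=False).tolist()
        adult_comm[sp] = _lognormal_community(
            sorted(chosen), spec.lognormal_mu, spec.lognormal_sigma, rng
        )
        available = [r for r in available if r not in adult_comm[sp]]

    sponge_refs = {r for comm in adult_comm.values() for r in comm}
    sponge_clusters = sorted(
        {cluster_of[r] for r in sponge_refs if cluster_of[r]}
    )

    # seawater: cluster-free native taxa ...
    sea_pool = [r for r in available if cluster_of[r] is None]
    natives = sorted(
        rng.choice(sea_pool, size=min(spec.taxa_seawater, len(sea_pool)),
                   replace=False).tolist()
    )
    sea_comm = _lognormal_community(
        natives, spec.lognormal_mu, spec.lognormal_sigma, rng
    )
    # ... plus rare seeding of sponge clusters
    n_seeded = int(round(spec.rare_shared_fraction * len(sponge_clusters)))
    seeded = sorted(
        rng.choice(sponge_clusters, size=n_seeded, replace=False).tolist()
    ) if n_seeded else []
    seed_mass = 0.0
    for label in seeded:
        candidates = sorted(
            r for r in sponge_refs if cluster_of[r] == label
        )
        chosen_ref = candidates[int(rng.integers(0, len(candidates)))]
        sea_comm[chosen_ref] = sea_comm.get(chosen_ref, 0.0) + spec.rare_abundance
        seed_mass += spec.rare_abundance
    scale = (1.0 - seed_mass)
    for r in natives:
        sea_comm[r] *= scale

    cluster_status = {
        label: ("also_in_seawater" if label in seeded else "sponge_exclusive")
        for label in sponge_clusters
    }

    # larvae of the first species: adult community + contamination
    f = spec.contamination_fraction
    larval_comm: dict[str, float] = {}
    for source, mass in ((adult_comm[species_names[0]], 1.0 - f), (sea_comm, f)):
        if mass == 0.0:
            continue
        for r, p in source.items():
            larval_comm[r] = larval_comm.get(r, 0.0) + mass * p

    entries: list[ManifestEntry] = []
    communities: dict[str, dict[str, float]] = {}
    for sp in species_names:
        for rep in range(1, spec.n_adult_replicates + 1):
            sid = f"{sp}_a{rep}"
            entries.append(ManifestEntry(sid, "adult", sp, rep))
            communities[sid] = adult_comm[sp]
    for rep in range(1, spec.n_larvae + 1):
        sid = f"{species_names[0]}_l{rep}"
        entries.append(ManifestEntry(sid, "larvae", species_names[0], rep))
        communities[sid] = larval_comm
    for rep in range(1, spec.n_seawater + 1):
        sid = f"seawater_w{rep}"
        entries.append(ManifestEntry(sid, "seawater", "", rep))
        communities[sid] = sea_comm
    manifest = SampleManifest(entries)

    tags: dict[str, list[TagRecord]] = {}
    truth_frames = []
    for e in entries:
        sample_tags, truth = simulate_sample(
            communities[e.sample_id],
            refdb,
            spec.tags_per_sample,
            spec.error_model,
            rng,
            sample_id=e.sample_id,
        )
        tags[e.sample_id] = sample_tags
        truth_frames.append(truth)

    truth = GroundTruth(
        communities=communities,
        tag_sources=pd.concat(truth_frames, ignore_index=True),
        cluster_status=cluster_status,
        seeded_clusters=seeded,
    )
    return Scenario(spec=spec, refdb=refdb, manifest=manifest, tags=tags, truth=truth)
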