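"""End-to-end orchestration: qc -> assign -> otu -> diversity -> compare ->
transmission, as one reproducible run with a config echo and stage logging."""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import community as comm
from . import diversity as div
from .fileio import (
    read_fasta,
    read_manifest,
    read_reference_db,
    qc_filter_tags,
    write_distance_matrix,
    write_table,
)
from .otus import cluster_furthest_neighbor, dereplicate, distance_matrix, expand_to_table
from .taxonomy import AssignmentThresholds, assign_tags, assignments_to_frame


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run; every field has a default."""

    manifest: str = "manifest.tsv"
    refdb: str = "refdb.tsv"
    out_dir: str = "run"
    min_len: int = 50
    max_n: int = 0
    n_hits: int = 100
    nearest_window: float = 0.001
    majority: float = 0.60
    otu_levels: tuple[float, ...] = (0.95, 0.90, 0.80)
    rare_cutoff: int = 10
    profile_ranks: tuple[str, ...] = ("phylum", "class")
    min_count: int = 1
    rarefaction_points: int = 20
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = cls(**data)
        base = Path(path).parent
        for attr in ("manifest", "refdb"):
            p = Path(getattr(cfg, attr))
            if not p.is_absolute():
                setattr(cfg, attr, str(base / p))
        return cfg


def _log(msg: str) -> None:
    stamp = time.strftime("%H:%M:%S")
    print(f"[{stamp}] {msg}", file=sys.stderr)


def _thresholds(cfg: RunConfig) -> AssignmentThresholds:
    return AssignmentThresholds(majority=cfg.majority, nearest_window=cfg.nearest_window)


def _pool_key(entry) -> str:
    if entry.group == "seawater":
        return "seawater"
    return f"{entry.species}_{entry.group}"


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage, writing TSV outputs and a per-stage count log.

    Deterministic given the config; aborts before writing anything if an
    input path is missing.
    """
    manifest_path, refdb_path = Path(cfg.manifest), Path(cfg.refdb)
    for p in (manifest_path, refdb_path):
        if not p.exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")
    manifest = read_manifest(manifest_path)
    refdb = read_reference_db(refdb_path)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_rows = []

    # --- stage 1: read + QC ------------------------------------------------
    tags_by_sample = {}
    qc_rows = []
    for e in manifest:
        fasta = Path(e.fasta)
        if not fasta.is_absolute():
            fasta = manifest_path.parent / fasta
        raw = read_fasta(fasta, sample_id=e.sample_id)
        kept, removed = qc_filter_tags(raw, min_len=cfg.min_len, max_n=cfg.max_n)
        tags_by_sample[e.sample_id] = kept
        qc_rows.append(
            {"sample_id": e.sample_id, "input": len(raw), "kept": len(kept),
             "removed": len(removed)}
        )
    qc_df = pd.DataFrame(qc_rows)
    write_table(qc_df, out / "qc_report.tsv", index=False)
    n_kept = int(qc_df["kept"].sum())
    counts_rows.append({"stage": "qc", "count": n_kept,
                        "detail": f"kept of {int(qc_df['input'].sum())} input"})
    _log(f"qc: kept {n_kept} of {int(qc_df['input'].sum())} tags")

    # --- stage 2: taxonomy assignment -------------------------------------
    all_tags = [t for e in manifest for t in tags_by_sample[e.sample_id]]
    manifest.resolve(all_tags)
    th = _thresholds(cfg)
    results = assign_tags(all_tags, refdb, th, n_hits=cfg.n_hits)
    assign_df = assignments_to_frame(results)
    sample_of = {t.tag_id: t.sample_id for t in all_tags}
    assign_df.insert(1, "sample_id", assign_df["tag_id"].map(sample_of))
    write_table(assign_df, out / "assignments.tsv", index=False)
    by_sample = {s: [] for s in manifest.sample_ids}
    for tag, res in zip(all_tags, results):
        by_sample[tag.sample_id].append(res)
    n_assigned = int((assign_df["phylum"] != "").sum())
    counts_rows.append({"stage": "assign", "count": n_assigned,
                        "detail": f"phylum-assigned of {len(all_tags)} kept"})
    _log(f"assign: {n_assigned}/{len(all_tags)} tags assigned at phylum level")

    # --- stage 3: OTUs + diversity per pool --------------------------------
    pools: dict[str, list[str]] = {}
    for e in manifest:
        pools.setdefault(_pool_key(e), []).append(e.sample_id)
    cutoffs = sorted({round(1.0 - s, 10) for s in cfg.otu_levels})
    richness_vectors: dict[str, div.AbundanceVector] = {}
    rarefaction_rows = []
    otu_count_rows = []
    for pool, samples in sorted(pools.items()):
        pool_tags = [t for s in samples for t in tags_by_sample[s]]
        if not pool_tags:
            continue
        useqs = dereplicate(pool_tags)
        dm = distance_matrix(useqs)
        write_distance_matrix(dm, out / f"distances_{pool}.phylip", "phylip-lower")
        weights = {u.useq_id: u.weight for u in useqs}
        parts = cluster_furthest_neighbor(dm, cutoffs, weights=weights)
        for part in parts:
            table = expand_to_table(part, useqs, sample_ids=samples)
            level = int(round(part.similarity_level * 100))
            write_table(table.counts, out / f"otu_table_{pool}_{level}.tsv")
            otu_count_rows.append(
                {"pool": pool, "similarity_level": part.similarity_level,
                 "n_otus": part.n_otus, "n_tags": len(pool_tags)}
            )
            if abs(part.similarity_level - 0.95) < 1e-9:
                vec = div.AbundanceVector.from_counts(
                    table.counts.sum(axis=1).tolist()
                )
                richness_vectors[pool] = vec
                for depth, es in div.rarefaction_curve(
                    vec, div.auto_depths(vec.n, cfg.rarefaction_points)
                ):
                    rarefaction_rows.append(
                        {"pool": pool, "depth": depth, "expected_otus": round(es, 4)}
                    )
        _log(f"otu[{pool}]: {len(pool_tags)} tags, {len(useqs)} unique, "
             f"{parts[0].n_otus} OTUs at cutoff {cutoffs[0]}")
    write_table(pd.DataFrame(otu_count_rows), out / "otu_counts.tsv", index=False)
    write_table(pd.DataFrame(rarefaction_rows), out / "rarefaction.tsv", index=False)
    write_table(
        div.richness_summary(richness_vectors, cfg.rare_cutoff),
        out / "richness.tsv", index=False,
    )
    counts_rows.append({"stage": "otu", "count": sum(r["n_otus"] for r in otu_count_rows),
                        "detail": "OTUs summed over pools and levels"})

    # --- stage 4: community comparison -------------------------------------
    for rank in cfg.profile_ranks:
        profiles = comm.taxon_profiles(by_sample, rank)
        write_table(comm.profiles_frame(profiles), out / f"profile_{rank}.tsv")
        bc = comm.bray_curtis_matrix(profiles)
        write_table(bc, out / f"bray_curtis_{rank}.tsv")
    _log(f"compare: profiles + Bray-Curtis at ranks {cfg.profile_ranks}")

    # --- stage 5: clusters + transmission ----------------------------------
    occ = comm.cluster_occurrence(by_sample, manifest)
    write_table(occ.counts, out / "cluster_occurrence.tsv")
    write_table(occ.relative, out / "cluster_occurrence_pct.tsv")
    calls, summary = comm.classify_transmission(occ, min_count=cfg.min_count)
    write_table(comm.transmission_frame(calls), out / "transmission.tsv", index=False)
    with open(out / "transmission_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    counts_rows.append({"stage": "transmission", "count": summary["n_detected"],
                        "detail": f"{summary['pct_sponge_exclusive']:.1f}% exclusive"})
    _log(f"transmission: {summary['n_detected']} clusters detected, "
         f"{summary['pct_sponge_exclusive']:.1f}% sponge-exclusive")

    write_table(pd.DataFrame(counts_rows), out / "stage_counts.tsv", index=False)
    with open(out / "run_config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=str)
    return out
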