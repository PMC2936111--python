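"""Readers, writers and quality control for all external representations.

Formats handled here: FASTA tag/reference sequence files, the sample
manifest TSV, the 4-column reference database TSV, PHYLIP distance
matrices (square and lower-triangle) and generic TSV tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "order", "family", "genus")

VALID_GROUPS = ("adult", "larvae", "seawater")

_DNA = set("ACGTN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class ValidationError(ValueError):
    """Raised when a parsed record violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TagRecord:
    """One quality-controlled short V6 read tied to a sample."""

    tag_id: str
    sample_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"tag {self.tag_id!r}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValidationError(
                f"tag {self.tag_id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyPath:
    """Ordered rank labels phylum..genus; a (possibly empty) suffix may be unset.

    Prefix-complete: an empty label is never followed by a non-empty one.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(RANKS):
            raise ValidationError(
                f"taxonomy path needs {len(RANKS)} labels, got {len(self.labels)}"
            )
        seen_empty = False
        for lab in self.labels:
            if lab == "":
                seen_empty = True
            elif seen_empty:
                raise ValidationError(
                    f"taxonomy path {self.labels} has a gap before a named rank"
                )

    @classmethod
    def from_string(cls, text: str) -> "TaxonomyPath":
        parts = [p.strip() for p in text.split(";")]
        if len(parts) > len(RANKS):
            raise ValidationError(f"too many ranks in {text!r}")
        parts += [""] * (len(RANKS) - len(parts))
        return cls(tuple(parts))

    def to_string(self) -> str:
        return ";".join(self.labels)

    def label(self, rank: str) -> str:
        return self.labels[RANKS.index(rank)]

    @property
    def depth(self) -> int:
        """Number of assigned (non-empty) ranks."""
        return sum(1 for lab in self.labels if lab)

    def __getitem__(self, i: int) -> str:
        return self.labels[i]

    def __iter__(self):
        return iter(self.labels)


EMPTY_TAXONOMY = TaxonomyPath(("",) * len(RANKS))


@dataclass(frozen=True)
class ReferenceRecord:
    ref_id: str
    sequence: str
    taxonomy: TaxonomyPath
    cluster_label: str | None = None


@dataclass
class ReferenceDB:
    """Reference 16S sequences with rank taxonomy and optional cluster labels."""

    records: list[ReferenceRecord]

    def __post_init__(self) -> None:
        ids = [r.ref_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate ref_id(s): {dupes}")
        for r in self.records:
            if r.taxonomy.label("phylum") == "":
                raise ValidationError(
                    f"reference {r.ref_id!r} lacks a phylum annotation"
                )
        self._by_id = {r.ref_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, ref_id: str) -> ReferenceRecord:
        return self._by_id[ref_id]


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    group: str
    species: str
    replicate: int
    fasta: str = ""

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: group must be one of {VALID_GROUPS}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


@dataclass
class SampleManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in manifest")
        self._by_id = {e.sample_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> ManifestEntry:
        return self._by_id[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def group_of(self, sample_id: str) -> str:
        try:
            return self._by_id[sample_id].group
        except KeyError:
            raise ValidationError(f"sample_id {sample_id!r} not in manifest") from None

    def samples_in_group(self, group: str) -> list[str]:
        return [e.sample_id for e in self.entries if e.group == group]

    def resolve(self, tags: Iterable[TagRecord]) -> None:
        """Fail loudly if any tag's sample_id is not a manifest entry."""
        missing = sorted({t.sample_id for t in tags} - set(self._by_id))
        if missing:
            raise ValidationError(f"sample_id(s) not in manifest: {missing}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if n and not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix is not symmetric")
        if n and not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(
    path: str | os.PathLike,
    sample_id: str | None = None,
) -> list[TagRecord]:
    """Read tags from a FASTA file, in file order.

    The first whitespace-delimited token of each header is the tag_id.  The
    sample is taken from ``sample_id`` if given, otherwise from a
    ``sample=<id>`` field in the header.  Sequences are uppercased and U is
    normalized to T.
    """
    records: list[TagRecord] = []
    seen: set[str] = set()
    tag_id: str | None = None
    tag_sample = ""
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        nonlocal tag_id, chunks
        if tag_id is None:
            return
        seq = _normalize_seq("".join(chunks))
        if not seq:
            raise FastaParseError(f"{path}: record {tag_id!r} has no sequence "
                                  f"(before line {lineno})")
        records.append(TagRecord(tag_id, tag_sample, seq))
        tag_id, chunks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                tag_id = header.split()[0]
                if tag_id in seen:
                    raise FastaParseError(
                        f"{path}:{lineno}: duplicate tag_id {tag_id!r}"
                    )
                seen.add(tag_id)
                tag_sample = sample_id or ""
                if sample_id is None:
                    for tok in header.split()[1:]:
                        if tok.startswith("sample="):
                            tag_sample = tok[len("sample="):]
            else:
                if tag_id is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(line)
        _flush(lineno if records or tag_id else 0)
    return records


def read_aligned_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a gapped (aligned) FASTA as {record id: aligned row}."""
    rows: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    rows[name] = _normalize_seq("".join(chunks))
                name = line[1:].split()[0]
                if not name:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                if name in rows:
                    raise FastaParseError(f"{path}:{lineno}: duplicate id {name!r}")
                chunks = []
            else:
                if name is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(line)
    if name is not None:
        rows[name] = _normalize_seq("".join(chunks))
    lengths = {len(v) for v in rows.values()}
    if len(lengths) > 1:
        raise ValidationError(f"{path}: aligned rows differ in length {sorted(lengths)}")
    return rows


def write_fasta(
    path: str | os.PathLike,
    records: Iterable[tuple[str, str]],
    width: int = 80,
) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def qc_filter_tags(
    tags: Sequence[TagRecord],
    min_len: int = 50,
    max_n: int = 0,
) -> tuple[list[TagRecord], list[TagRecord]]:
    """Partition tags into (kept, removed).

    A tag is kept iff its length is at least ``min_len`` (primer-trimmed
    reads shorter than that are treated as low quality) and it contains at
    most ``max_n`` ambiguous (N) bases.
    """
    kept, removed = [], []
    for t in tags:
        if t.length >= min_len and t.sequence.count("N") <= max_n:
            kept.append(t)
        else:
            removed.append(t)
    return kept, removed


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLS = ["sample_id", "group", "species", "replicate", "fasta"]


def read_manifest(path: str | os.PathLike) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLS[:4] if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path}: missing column(s) {missing}")
    entries = [
        ManifestEntry(
            sample_id=row["sample_id"],
            group=row["group"],
            species=row.get("species", ""),
            replicate=int(row["replicate"]),
            fasta=row.get("fasta", ""),
        )
        for _, row in df.iterrows()
    ]
    return SampleManifest(entries)


def write_manifest(manifest: SampleManifest, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            (e.sample_id, e.group, e.species, e.replicate, e.fasta)
            for e in manifest
        ],
        columns=_MANIFEST_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference database
# ---------------------------------------------------------------------------

_REFDB_COLS = ["ref_id", "taxonomy", "cluster_label", "sequence"]


def read_reference_db(path: str | os.PathLike) -> ReferenceDB:
    """Read a 4-column reference TSV: ref_id, taxonomy, cluster_label, sequence.

    Taxonomy is semicolon-delimited phylum..genus; an empty cluster_label
    means the reference carries no cluster annotation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REFDB_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"reference db {path}: missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            tax = TaxonomyPath.from_string(row["taxonomy"])
        except ValidationError as exc:
            raise ValidationError(f"reference {row['ref_id']!r}: {exc}") from None
        records.append(
            ReferenceRecord(
                ref_id=row["ref_id"],
                sequence=_normalize_seq(row["sequence"]),
                taxonomy=tax,
                cluster_label=row["cluster_label"] or None,
            )
        )
    return ReferenceDB(records)


def write_reference_db(db: ReferenceDB, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            (r.ref_id, r.taxonomy.to_string(), r.cluster_label or "", r.sequence)
            for r in db
        ],
        columns=_REFDB_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# distance matrices (PHYLIP)
# ---------------------------------------------------------------------------

_DIALECTS = ("phylip-square", "phylip-lower")


def write_distance_matrix(
    m: DistanceMatrix, path: str | os.PathLike, dialect: str = "phylip-square"
) -> None:
    """Write a PHYLIP-format distance matrix at 6-decimal precision."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if len(m) == 0:
        raise ValidationError("refusing to write a 0-label distance matrix")
    with open(path, "w") as fh:
        fh.write(f"{len(m)}\n")
        for i, label in enumerate(m.labels):
            row = m.values[i, :i] if dialect == "phylip-lower" else m.values[i]
            cells = "\t".join(f"{v:.6f}" for v in row)
            fh.write(f"{label}\t{cells}".rstrip() + "\n")


def read_distance_matrix(
    path: str | os.PathLike, dialect: str = "phylip-square"
) -> DistanceMatrix:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    with open(path) as fh:
        header = fh.readline().strip()
        try:
            n = int(header.split()[0])
        except (ValueError, IndexError):
            raise FastaParseError(f"{path}:1: bad PHYLIP header {header!r}") from None
        labels: list[str] = []
        values = np.zeros((n, n))
        for i in range(n):
            parts = fh.readline().split()
            if not parts:
                raise FastaParseError(f"{path}: truncated matrix at row {i + 1}")
            labels.append(parts[0])
            row = [float(x) for x in parts[1:]]
            if dialect == "phylip-lower":
                if len(row) != i:
                    raise FastaParseError(
                        f"{path}: row {i + 1} has {len(row)} values, expected {i}"
                    )
                values[i, :i] = row
                values[:i, i] = row
            else:
                if len(row) != n:
                    raise FastaParseError(
                        f"{path}: row {i + 1} has {len(row)} values, expected {n}"
                    )
                values[i] = row
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# generic tables
# ---------------------------------------------------------------------------


def write_table(
    df: pd.DataFrame, path: str | os.PathLike, index: bool = True, precision: int = 6
) -> None:
    """Write a DataFrame as TSV with a header row and fixed float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=f"%.{precision}f")


def read_table(path: str | os.PathLike, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
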