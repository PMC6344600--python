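"""Shared data model, input readers, and report writers.

Conventions
-----------
* Internal gene coordinates are 0-based half-open; GFF3 input/output is
  1-based inclusive.  Conversion happens only at the file boundary.
* Protein sequences are uppercased; trailing stop symbols (``*``) are
  stripped; non-canonical letters (B, Z, U, J, O) are mapped to ``X``,
  which never matches a constrained motif position.
* Gene read coverage is inherited from the gene's contig (reads are
  mapped to contigs, not genes).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

UNBINNED = "unbinned"

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUOUS = {ord(c): "X" for c in "BZUJO"}


class ValidationError(ValueError):
    """An input violated a data-model invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A predicted protein; the unit every detector consumes."""

    protein_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"protein {self.protein_id!r} has empty sequence")
        bad = set(self.sequence) - CANONICAL_AA - {"X"}
        if bad:
            raise ValidationError(
                f"protein {self.protein_id!r} has non-canonical letters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene locus on a contig; ``gene_id`` links to ``protein_id``."""

    gene_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    rank: int   # ordinal position on the contig, left to right

    def __post_init__(self):
        if self.start < 0 or self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: strand must be + or -")


def to_gff_interval(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


def from_gff_interval(start1: int, end1: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start1 - 1, end1


class CoverageTable:
    """Mean read coverage (depth) per contig."""

    def __init__(self, depths: Mapping[str, float]):
        self._depths: dict[str, float] = {}
        for contig, depth in depths.items():
            depth = float(depth)
            if depth < 0:
                raise ValidationError(f"negative coverage for contig {contig!r}")
            self._depths[str(contig)] = depth

    def __getitem__(self, contig_id: str) -> float:
        return self._depths[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._depths

    def __len__(self) -> int:
        return len(self._depths)

    def items(self):
        return self._depths.items()

    def gene_coverage(self, feature: GeneFeature) -> float:
        """Coverage of a gene, inherited from its contig."""
        return self._depths[feature.contig_id]

    def validate_contigs(self, features: Iterable[GeneFeature]) -> None:
        missing = sorted({f.contig_id for f in features} - self._depths.keys())
        if missing:
            raise ValidationError(
                f"contigs without coverage entries: {', '.join(missing)}"
            )


class MAGAssignment:
    """Contig -> MAG membership with optional MAG-level metadata.

    Contigs absent from the table resolve to the reserved ``unbinned``
    value.  Metadata rows carry a taxon label and an envelope type
    (``diderm``/``monoderm``; default diderm).
    """

    def __init__(
        self,
        assignments: Mapping[str, str] | None = None,
        mag_meta: Mapping[str, Mapping[str, str]] | None = None,
    ):
        self._map = {str(k): str(v) for k, v in (assignments or {}).items()}
        self._meta = {k: dict(v) for k, v in (mag_meta or {}).items()}

    def mag_of(self, contig_id: str) -> str:
        return self._map.get(contig_id, UNBINNED)

    def mags(self) -> set[str]:
        return set(self._map.values()) - {UNBINNED}

    def is_monoderm(self, mag_id: str) -> bool:
        return self._meta.get(mag_id, {}).get("envelope", "diderm") == "monoderm"

    def taxon(self, mag_id: str) -> str:
        return self._meta.get(mag_id, {}).get("taxon", "")

    def items(self):
        return self._map.items()


@dataclass
class MetagenomeData:
    """One metagenome's full input bundle, validated and cross-linked."""

    metagenome_id: str
    proteins: list[ProteinRecord]
    features: list[GeneFeature]
    coverage: CoverageTable
    mags: MAGAssignment
    housekeeping: set[str]
    localization_annotations: dict[str, str] = field(default_factory=dict)
    precomputed_hits: pd.DataFrame | None = None

    def __post_init__(self):
        ids = [p.protein_id for p in self.proteins]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate protein IDs in metagenome")
        self.coverage.validate_contigs(self.features)
        feature_ids = {f.gene_id for f in self.features}
        missing = sorted(self.housekeeping - feature_ids)
        if missing:
            raise ValidationError(
                f"housekeeping gene_ids absent from gene features: {', '.join(missing)}"
            )

    def protein_by_id(self) -> dict[str, ProteinRecord]:
        return {p.protein_id: p for p in self.proteins}

    def feature_by_id(self) -> dict[str, GeneFeature]:
        return {f.gene_id: f for f in self.features}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def clean_protein_sequence(raw: str) -> str:
    """Uppercase, strip trailing stops, map ambiguity codes to X."""
    seq = raw.upper().rstrip("*")
    return seq.translate(_AMBIGUOUS)


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read predicted proteins from a FASTA file.

    Duplicate IDs are rejected; sequences are normalized via
    :func:`clean_protein_sequence`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate protein ID {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, clean_protein_sequence(str(rec.seq))))
    return records


def read_gene_features(path) -> list[GeneFeature]:
    """Read CDS/gene features from GFF3 and assign per-contig ranks.

    Coordinates are converted to the internal 0-based half-open
    convention; ranks are assigned per contig by ascending start (ties
    broken by gene_id for determinism).
    """
    import gffutils

    raw: list[tuple[str, str, int, int, str]] = []
    if os.path.getsize(path) == 0:
        return []
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="error", id_spec="ID",
    )
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        gene_id = feat.attributes.get("ID", [None])[0]
        if gene_id is None:
            raise ValidationError(f"feature at {feat.seqid}:{feat.start} lacks ID")
        if feat.start > feat.end:
            raise ValidationError(f"gene {gene_id!r}: start > end in GFF3")
        start, end = from_gff_interval(feat.start, feat.end)
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        raw.append((gene_id, feat.seqid, start, end, strand))
    return assign_ranks(raw)


def assign_ranks(rows: Iterable[tuple[str, str, int, int, str]]) -> list[GeneFeature]:
    """Build GeneFeatures with per-contig left-to-right ranks."""
    by_contig: dict[str, list[tuple[str, str, int, int, str]]] = {}
    for row in rows:
        by_contig.setdefault(row[1], []).append(row)
    features: list[GeneFeature] = []
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda r: (r[2], r[0]))
        for rank, (gid, cid, start, end, strand) in enumerate(ordered):
            features.append(GeneFeature(gid, cid, start, end, strand, rank))
    return features


def read_tables(
    coverage_path, mag_path=None, housekeeping_path=None
) -> tuple[CoverageTable, MAGAssignment, set[str]]:
    """Read the coverage, MAG-membership, and housekeeping-marker TSVs."""
    cov_df = pd.read_csv(coverage_path, sep="\t", dtype={0: str})
    if cov_df.shape[1] < 2:
        raise ValidationError(f"coverage table {coverage_path} needs >= 2 columns")
    coverage = CoverageTable(dict(zip(cov_df.iloc[:, 0], cov_df.iloc[:, 1])))

    assignments: dict[str, str] = {}
    mag_meta: dict[str, dict[str, str]] = {}
    if mag_path is not None:
        mag_df = pd.read_csv(mag_path, sep="\t", dtype=str).fillna("")
        for _, row in mag_df.iterrows():
            contig, mag = row.iloc[0], row.iloc[1]
            assignments[contig] = mag or UNBINNED
            meta = {}
            if "taxon" in mag_df.columns and row["taxon"]:
                meta["taxon"] = row["taxon"]
            if "envelope" in mag_df.columns and row["envelope"]:
                meta["envelope"] = row["envelope"]
            if meta and mag and mag != UNBINNED:
                mag_meta.setdefault(mag, {}).update(meta)
    mags = MAGAssignment(assignments, mag_meta)

    housekeeping: set[str] = set()
    if housekeeping_path is not None:
        hk_df = pd.read_csv(housekeeping_path, sep="\t", dtype=str)
        housekeeping = set(hk_df.iloc[:, 0])
    return coverage, mags, housekeeping


def read_localization_table(path) -> dict[str, str]:
    """Read an externally computed localization TSV (protein_id, compartment)."""
    from .localization import COMPARTMENTS

    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        pid, comp = row.iloc[0], row.iloc[1]
        if comp not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {comp!r} for protein {pid!r}"
            )
        out[pid] = comp
    return out


def load_metagenome(
    metagenome_id: str,
    fasta_path,
    gff_path,
    coverage_path,
    mag_path=None,
    housekeeping_path=None,
    localization_path=None,
    hits_path=None,
) -> MetagenomeData:
    """Assemble a validated :class:`MetagenomeData` from files."""
    proteins = read_protein_fasta(fasta_path)
    features = read_gene_features(gff_path)
    coverage, mags, hk = read_tables(coverage_path, mag_path, housekeeping_path)
    loc = read_localization_table(localization_path) if localization_path else {}
    hits = None
    if hits_path is not None:
        from .homology import read_hits_table

        hits = read_hits_table(hits_path)
    return MetagenomeData(
        metagenome_id, proteins, features, coverage, mags, hk,
        localization_annotations=loc, precomputed_hits=hits,
    )


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

CALL_COLUMNS = [
    "gene_id", "contig_id", "mag_id", "call_class", "cluster_id",
    "cluster_type", "family", "heme_count", "compartment", "evidence",
]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_reports(
    calls_df: pd.DataFrame,
    mag_summary: pd.DataFrame,
    metagenome_summary: pd.DataFrame,
    out_dir,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
    input_paths: Mapping[str, str] | None = None,
    extra_tables: Mapping[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write all report TSVs plus a run-metadata JSON.

    Re-running on identical inputs and config produces byte-identical
    files: all tables are sorted on their key columns and the metadata
    JSON is serialized with sorted keys and no timestamps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    calls_df = calls_df.reindex(columns=CALL_COLUMNS)
    written: dict[str, Path] = {}
    for name, df in [
        ("eet_calls", calls_df),
        ("mag_summary", mag_summary),
        ("metagenome_summary", metagenome_summary),
        *(extra_tables or {}).items(),
    ]:
        path = out_dir / f"{name}.tsv"
        _write_tsv(df, path)
        written[name] = path

    meta = {
        "config": config or {},
        "seed": seed,
        "input_checksums": {
            name: file_sha256(p) for name, p in sorted((input_paths or {}).items())
        },
        "n_calls": int(len(calls_df)),
    }
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")
    written["run_metadata"] = meta_path
    return written


def read_calls_table(path) -> pd.DataFrame:
    """Read back an ``eet_calls.tsv`` (round-trip counterpart of write_reports)."""
    df = pd.read_csv(
        path, sep="\t", dtype={c: str for c in CALL_COLUMNS if c != "heme_count"},
        keep_default_na=False,
    )
    if list(df.columns) != CALL_COLUMNS:
        raise ValidationError(f"unexpected columns in calls table {path}")
    df["heme_count"] = df["heme_count"].astype(int)
    return df
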