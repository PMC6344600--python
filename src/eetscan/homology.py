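"""Local-alignment homology search against bundled EET reference families.

The reference set covers the porin-cytochrome conduit (PCC) families
(MtrABC from *Shewanella*; MtoAB and PioAB, its Fe(II)-oxidizing
relatives; OmbB-OmaB-OmcB from *Geobacter*), outer-surface multiheme
cytochromes (OmcE/OmcS/OmcZ), the Cyc2 monoheme Fe(II) oxidase, and a
generic non-PCC porin.  The bundled sequences are synthetic stand-ins
with the hallmark architecture of each family (heme-motif counts,
signal peptides, lengths); users reproducing published searches should
supply their own references or a precomputed hit table.

Scoring is optimal local alignment (Smith-Waterman) under BLOSUM62 with
affine gaps: a gap of length L costs ``gap_open + (L-1) * gap_extend``.
Identity is identical residues divided by alignment columns (gaps
included); coverages are the aligned span divided by sequence length.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_model import ProteinRecord, ValidationError, clean_protein_sequence

ROLES = ("porin", "periplasmic_MHC", "extracellular_MHC", "outer_surface_MHC", "cyc2")

#: Family -> functional role within an EET system.
ROLE_BY_FAMILY: dict[str, str] = {
    "MtrB": "porin", "MtoB": "porin", "PioB": "porin", "OmbB": "porin",
    "porin_other": "porin",
    "MtrA": "periplasmic_MHC", "MtoA": "periplasmic_MHC",
    "PioA": "periplasmic_MHC", "OmaB": "periplasmic_MHC",
    "MtrC": "extracellular_MHC", "OmcB": "extracellular_MHC",
    "OmcE": "outer_surface_MHC", "OmcS": "outer_surface_MHC",
    "OmcZ": "outer_surface_MHC",
    "Cyc2": "cyc2",
}

#: Families whose presence makes a porin+MHC pair a known PCC type.
KNOWN_PCC_FAMILIES = frozenset(
    {"MtrA", "MtrB", "MtrC", "MtoA", "MtoB", "PioA", "PioB", "OmaB", "OmbB", "OmcB"}
)


@dataclass(frozen=True)
class ReferenceEntry:
    family: str
    role: str
    sequence: str
    source_tag: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of a query against one reference family."""

    query_id: str
    family: str
    role: str
    score: float
    identity: float
    query_coverage: float
    reference_coverage: float
    query_interval: tuple[int, int]  # 0-based half-open on the query
    # aligned blocks ((qstart, qend), (rstart, rend)) from the traceback;
    # empty for precomputed hits read from a table
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = ()


def load_references() -> list[ReferenceEntry]:
    """Load the bundled synthetic reference FASTA and its sidecar TSV."""
    data = importlib.resources.files("eetscan") / "data"
    sidecar = pd.read_csv(str(data / "references_synthetic.tsv"), sep="\t", dtype=str)
    meta = {r["ref_id"]: r for _, r in sidecar.iterrows()}
    refs = []
    for rec in SeqIO.parse(str(data / "references_synthetic.fasta"), "fasta"):
        row = meta[rec.id]
        refs.append(
            ReferenceEntry(
                family=row["family"], role=row["role"],
                sequence=clean_protein_sequence(str(rec.seq)),
                source_tag=row["source_tag"],
            )
        )
    return refs


def make_aligner(params: Mapping) -> PairwiseAligner:
    h = params["homology"]
    return PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load(h["matrix"]),
        open_gap_score=-float(h["gap_open"]),
        extend_gap_score=-float(h["gap_extend"]),
    )


@lru_cache(maxsize=4)
def _cached_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    return PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load(matrix),
        open_gap_score=-gap_open,
        extend_gap_score=-gap_extend,
    )


def _aligner_from_params(params: Mapping) -> PairwiseAligner:
    h = params["homology"]
    return _cached_aligner(h["matrix"], float(h["gap_open"]), float(h["gap_extend"]))


def _hit_from_alignment(
    query_id: str, query: str, reference: str, family: str, role: str, aln
) -> AlignmentHit:
    blocks = tuple(
        ((int(q0), int(q1)), (int(r0), int(r1)))
        for (q0, q1), (r0, r1) in zip(aln.aligned[0], aln.aligned[1])
    )
    matches = 0
    aligned_cols = 0
    for (q0, q1), (r0, r1) in blocks:
        aligned_cols += q1 - q0
        matches += sum(
            1 for a, b in zip(query[q0:q1], reference[r0:r1]) if a == b
        )
    q_span = (blocks[0][0][0], blocks[-1][0][1]) if blocks else (0, 0)
    r_span = (blocks[0][1][0], blocks[-1][1][1]) if blocks else (0, 0)
    q_len = q_span[1] - q_span[0]
    r_len = r_span[1] - r_span[0]
    aln_len = q_len + r_len - aligned_cols  # columns incl. gaps
    return AlignmentHit(
        query_id=query_id, family=family, role=role,
        score=float(aln.score),
        identity=matches / aln_len if aln_len else 0.0,
        query_coverage=q_len / len(query),
        reference_coverage=r_len / len(reference),
        query_interval=q_span,
        blocks=blocks,
    )


def local_align(
    query: str,
    reference: str,
    params: Mapping,
    *,
    query_id: str = "",
    family: str = "",
    role: str = "",
) -> AlignmentHit:
    """Optimal local alignment of two protein sequences.

    Returns a zero-score hit with an empty alignment when no positive-
    scoring local alignment exists.
    """
    if not query or not reference:
        raise ValidationError("local_align requires non-empty sequences")
    aligner = _aligner_from_params(params)
    score = aligner.score(query, reference)
    if score <= 0:
        return AlignmentHit(query_id, family, role, 0.0, 0.0, 0.0, 0.0, (0, 0))
    aln = aligner.align(query, reference)[0]
    return _hit_from_alignment(query_id, query, reference, family, role, aln)


def search_references(
    protein: ProteinRecord,
    refs: list[ReferenceEntry],
    params: Mapping,
) -> dict[str, AlignmentHit]:
    """Best above-threshold hit per role for one protein.

    A hit is retained when identity >= ``min_identity`` and query
    coverage >= ``min_query_cov``.  Alignments scoring below
    ``min_score`` are discarded without a traceback.
    """
    h = params["homology"]
    aligner = _aligner_from_params(params)
    best: dict[str, AlignmentHit] = {}
    for ref in refs:
        score = aligner.score(protein.sequence, ref.sequence)
        if score < h["min_score"] or score <= 0:
            continue
        aln = aligner.align(protein.sequence, ref.sequence)[0]
        hit = _hit_from_alignment(
            protein.protein_id, protein.sequence, ref.sequence,
            ref.family, ref.role, aln,
        )
        if hit.identity < h["min_identity"] or hit.query_coverage < h["min_query_cov"]:
            continue
        prev = best.get(ref.role)
        if prev is None or (hit.score, hit.family) > (prev.score, prev.family):
            best[ref.role] = hit
    return best


def search_all(
    proteins: Iterable[ProteinRecord],
    refs: list[ReferenceEntry],
    params: Mapping,
    precomputed: pd.DataFrame | None = None,
) -> dict[str, dict[str, AlignmentHit]]:
    """Role-indexed best hits for every protein.

    When a precomputed hit table is supplied it replaces the alignment
    search verbatim (the table is assumed to be pre-thresholded by the
    external search stack, except that this function re-applies the
    identity/coverage thresholds for consistency).
    """
    if precomputed is not None:
        return _hits_from_table(precomputed, proteins, params)
    return {p.protein_id: search_references(p, refs, params) for p in proteins}


HITS_COLUMNS = ["query_id", "family", "identity", "query_coverage", "score"]


def read_hits_table(path) -> pd.DataFrame:
    """Read an externally computed homology-hit TSV.

    Required columns: query_id, family, identity, query_coverage,
    score.  Optional q_start/q_end give the aligned query interval
    (0-based half-open); when absent the full query is assumed.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HITS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"hits table missing columns: {missing}")
    unknown = set(df["family"]) - set(ROLE_BY_FAMILY)
    if unknown:
        raise ValidationError(f"hits table has unknown families: {sorted(unknown)}")
    return df


def _hits_from_table(
    df: pd.DataFrame, proteins: Iterable[ProteinRecord], params: Mapping
) -> dict[str, dict[str, AlignmentHit]]:
    h = params["homology"]
    lengths = {p.protein_id: p.length for p in proteins}
    out: dict[str, dict[str, AlignmentHit]] = {pid: {} for pid in lengths}
    for _, row in df.iterrows():
        qid = str(row["query_id"])
        if qid not in lengths:
            continue
        identity = float(row["identity"])
        qcov = float(row["query_coverage"])
        if identity < h["min_identity"] or qcov < h["min_query_cov"]:
            continue
        family = str(row["family"])
        role = ROLE_BY_FAMILY[family]
        if "q_start" in row.index and not pd.isna(row["q_start"]):
            interval = (int(row["q_start"]), int(row["q_end"]))
        else:
            interval = (0, lengths[qid])
        hit = AlignmentHit(
            qid, family, role, float(row["score"]), identity, qcov,
            float(row.get("reference_coverage", 0.0) or 0.0), interval,
        )
        prev = out[qid].get(role)
        if prev is None or (hit.score, hit.family) > (prev.score, prev.family):
            out[qid][role] = hit
    return out
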