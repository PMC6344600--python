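"""Combine motif, homology, localization, and gene-neighborhood evidence
into putative EET gene calls.

Three call classes are produced:

* ``pcc_component`` — members of a porin-cytochrome conduit (PCC)
  cluster: a porin gene adjacent (within ``max_gene_gap`` intervening
  genes) to a secreted multiheme cytochrome, optionally joined by an
  extracellular MHC.  Clusters are typed ``known_family`` when any
  member is homologous to MtrAB(C)/MtoAB/PioAB/OmbB-OmaB-OmcB, and
  ``novel_organization`` when only the gene organization matches —
  the signature that lets unknown conduit systems be flagged.
* ``outer_surface_mhc`` — multiheme cytochromes on the outer membrane,
  extracellular space, or cell wall that are not part of any PCC.
* ``cyc2`` — monoheme cytochromes with the Cyc2 architecture: a single
  N-terminal heme motif and a C-terminal region homologous to Cyc2
  references (a proxy for the C-terminal porin fold).

Calls are a partition: a gene belongs to at most one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .homology import KNOWN_PCC_FAMILIES, AlignmentHit
from .io_model import CALL_COLUMNS, GeneFeature, MAGAssignment, ProteinRecord
from .localization import LocalizationCall
from .motif_scan import HemeScan, MHCCall

_FAMILY_GROUP = {
    "MtrA": "MtrAB", "MtrB": "MtrAB", "MtrC": "MtrAB",
    "MtoA": "MtoAB", "MtoB": "MtoAB",
    "PioA": "PioAB", "PioB": "PioAB",
    "OmaB": "OmbB-OmaB-OmcB", "OmbB": "OmbB-OmaB-OmcB", "OmcB": "OmbB-OmaB-OmcB",
}

OUTER_COMPARTMENTS = frozenset({"outer_membrane", "extracellular", "cell_wall"})


@dataclass(frozen=True)
class PCCCluster:
    cluster_id: str
    contig_id: str
    porin_gene: str
    periplasmic_mhc_gene: str
    periplasmic_heme_count: int
    extracellular_mhc_gene: str | None
    cluster_type: str  # "known_family" | "novel_organization"
    family: str        # group label, "" for novel clusters
    member_ranks: tuple[int, ...]
    porin_mhc_gap_bp: int

    def members(self) -> tuple[str, ...]:
        out = [self.porin_gene, self.periplasmic_mhc_gene]
        if self.extracellular_mhc_gene:
            out.append(self.extracellular_mhc_gene)
        return tuple(out)


@dataclass(frozen=True)
class EETGeneCall:
    gene_id: str
    call_class: str  # "pcc_component" | "outer_surface_mhc" | "cyc2"
    heme_count: int
    compartment: str
    families: tuple[str, ...]
    cluster_id: str = ""
    cluster_type: str = ""
    family: str = ""


def _has_porin_evidence(hits: Mapping[str, AlignmentHit]) -> bool:
    return "porin" in hits


def _known_families(hits: Mapping[str, AlignmentHit]) -> set[str]:
    return {h.family for h in hits.values() if h.family in KNOWN_PCC_FAMILIES}


def detect_pcc_clusters(
    features: Iterable[GeneFeature],
    mhc_calls: Mapping[str, MHCCall],
    localizations: Mapping[str, LocalizationCall],
    hits: Mapping[str, Mapping[str, AlignmentHit]],
    params: Mapping,
) -> list[PCCCluster]:
    """Scan each contig's gene order for porin + secreted-MHC pairs.

    Greedy leftmost assembly: porin candidates are visited in rank
    order; each pairs with its nearest eligible MHC (ties broken by
    smaller start coordinate); each gene joins at most one cluster.
    An extracellular-family MHC within the same window joins the
    cluster as its third member.
    """
    p = params["pcc"]
    gap = p["max_gene_gap"]
    mhc_min = p["pcc_mhc_min"]
    if mhc_min is None:
        mhc_min = params["mhc"]["mhc_min"]

    def is_peri_candidate(gene_id: str) -> bool:
        call = mhc_calls.get(gene_id)
        loc = localizations.get(gene_id)
        if call is None or loc is None or call.heme_count < mhc_min:
            return False
        if not loc.has_signal_peptide:
            return False
        return "extracellular_MHC" not in hits.get(gene_id, {})

    def is_ext_candidate(gene_id: str) -> bool:
        call = mhc_calls.get(gene_id)
        return (
            call is not None
            and call.heme_count >= mhc_min
            and "extracellular_MHC" in hits.get(gene_id, {})
        )

    by_contig: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig_id, []).append(f)

    clusters: list[PCCCluster] = []
    for contig in sorted(by_contig):
        genes = sorted(by_contig[contig], key=lambda g: g.rank)
        used: set[str] = set()
        serial = 0
        for porin in genes:
            if porin.gene_id in used:
                continue
            if not _has_porin_evidence(hits.get(porin.gene_id, {})):
                continue
            cands = [
                g for g in genes
                if g.gene_id != porin.gene_id
                and g.gene_id not in used
                and abs(g.rank - porin.rank) <= gap + 1
                and is_peri_candidate(g.gene_id)
                and (not p["strand_required"] or g.strand == porin.strand)
            ]
            if not cands:
                continue
            peri = min(cands, key=lambda g: (abs(g.rank - porin.rank), g.start))
            used.update((porin.gene_id, peri.gene_id))

            ext_cands = [
                g for g in genes
                if g.gene_id not in used
                and (
                    abs(g.rank - porin.rank) <= gap + 1
                    or abs(g.rank - peri.rank) <= gap + 1
                )
                and is_ext_candidate(g.gene_id)
                and (not p["strand_required"] or g.strand == porin.strand)
            ]
            ext = None
            if ext_cands:
                ext = min(
                    ext_cands,
                    key=lambda g: (
                        min(abs(g.rank - porin.rank), abs(g.rank - peri.rank)),
                        g.start,
                    ),
                )
                used.add(ext.gene_id)

            members = [porin, peri] + ([ext] if ext else [])
            fams: set[str] = set()
            for m in members:
                fams |= _known_families(hits.get(m.gene_id, {}))
            if fams:
                cluster_type = "known_family"
                groups = sorted({_FAMILY_GROUP[f] for f in fams})
                family = "+".join(groups) + "-like"
            else:
                cluster_type = "novel_organization"
                family = ""

            left, right = (porin, peri) if porin.start <= peri.start else (peri, porin)
            clusters.append(
                PCCCluster(
                    cluster_id=f"{contig}.pcc{serial}",
                    contig_id=contig,
                    porin_gene=porin.gene_id,
                    periplasmic_mhc_gene=peri.gene_id,
                    periplasmic_heme_count=mhc_calls[peri.gene_id].heme_count,
                    extracellular_mhc_gene=ext.gene_id if ext else None,
                    cluster_type=cluster_type,
                    family=family,
                    member_ranks=tuple(sorted(m.rank for m in members)),
                    porin_mhc_gap_bp=max(0, right.start - left.end),
                )
            )
            serial += 1
    return clusters


def call_outer_surface_mhcs(
    mhc_calls: Mapping[str, MHCCall],
    localizations: Mapping[str, LocalizationCall],
    clusters: Iterable[PCCCluster],
    hits: Mapping[str, Mapping[str, AlignmentHit]] | None = None,
) -> list[EETGeneCall]:
    """MHCs on the outer surface that are not members of any PCC."""
    clustered = {g for c in clusters for g in c.members()}
    hits = hits or {}
    out: list[EETGeneCall] = []
    for pid in sorted(mhc_calls):
        call = mhc_calls[pid]
        loc = localizations.get(pid)
        if not call.is_mhc or pid in clustered or loc is None:
            continue
        if loc.compartment not in OUTER_COMPARTMENTS:
            continue
        fams = tuple(sorted(h.family for h in hits.get(pid, {}).values()))
        out.append(
            EETGeneCall(pid, "outer_surface_mhc", call.heme_count,
                        loc.compartment, fams)
        )
    return out


def call_cyc2(
    proteins: Iterable[ProteinRecord],
    scans: Mapping[str, HemeScan],
    hits: Mapping[str, Mapping[str, AlignmentHit]],
    params: Mapping,
) -> list[EETGeneCall]:
    """Cyc2-like calls: one N-terminal heme motif plus C-terminal
    homology to Cyc2 references within the allowed length range."""
    p = params["cyc2"]
    out: list[EETGeneCall] = []
    for prot in sorted(proteins, key=lambda x: x.protein_id):
        if not (p["len_min"] <= prot.length <= p["len_max"]):
            continue
        scan = scans.get(prot.protein_id)
        if scan is None or scan.heme_count != 1:
            continue
        if scan.positions[0] >= p["n_term_window"]:
            continue
        hit = hits.get(prot.protein_id, {}).get("cyc2")
        if hit is None:
            continue
        half = prot.length // 2
        q0, q1 = hit.query_interval
        cterm_aligned = max(0, q1 - max(q0, half))
        cterm_len = prot.length - half
        if cterm_len == 0 or cterm_aligned / cterm_len < p["cterm_cov"]:
            continue
        out.append(
            EETGeneCall(prot.protein_id, "cyc2", 1, "outer_membrane",
                        (hit.family,))
        )
    return out


def assemble_calls(
    clusters: Iterable[PCCCluster],
    outer_calls: Iterable[EETGeneCall],
    cyc2_calls: Iterable[EETGeneCall],
    mhc_calls: Mapping[str, MHCCall],
    localizations: Mapping[str, LocalizationCall],
    hits: Mapping[str, Mapping[str, AlignmentHit]],
) -> list[EETGeneCall]:
    """Unified call list; PCC membership wins any class overlap."""
    calls: dict[str, EETGeneCall] = {}
    for c in clusters:
        for gid in c.members():
            mhc = mhc_calls.get(gid)
            loc = localizations.get(gid)
            fams = tuple(sorted(h.family for h in hits.get(gid, {}).values()))
            calls[gid] = EETGeneCall(
                gid, "pcc_component",
                mhc.heme_count if mhc else 0,
                loc.compartment if loc else "unknown",
                fams, cluster_id=c.cluster_id,
                cluster_type=c.cluster_type, family=c.family,
            )
    for call in list(outer_calls) + list(cyc2_calls):
        calls.setdefault(call.gene_id, call)
    return [calls[k] for k in sorted(calls)]


def calls_dataframe(
    calls: Iterable[EETGeneCall],
    features_by_id: Mapping[str, GeneFeature],
    mags: MAGAssignment,
) -> pd.DataFrame:
    """Flatten calls into the ``eet_calls.tsv`` schema."""
    from .io_model import ValidationError

    rows = []
    for c in calls:
        feat = features_by_id.get(c.gene_id)
        if feat is None:
            raise ValidationError(
                f"call for {c.gene_id!r} references no known gene feature"
            )
        contig = feat.contig_id
        rows.append(
            {
                "gene_id": c.gene_id,
                "contig_id": contig,
                "mag_id": mags.mag_of(contig) if contig else "",
                "call_class": c.call_class,
                "cluster_id": c.cluster_id,
                "cluster_type": c.cluster_type,
                "family": c.family,
                "heme_count": c.heme_count,
                "compartment": c.compartment,
                "evidence": ";".join(c.families) if c.families else "organization",
            }
        )
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df.sort_values(["contig_id", "gene_id"], kind="stable").reset_index(drop=True)


def calls_from_dataframe(df: pd.DataFrame) -> list[EETGeneCall]:
    """Rebuild :class:`EETGeneCall` objects from the calls table
    (round-trip counterpart of :func:`calls_dataframe`)."""
    out = []
    for _, row in df.iterrows():
        evidence = row["evidence"]
        families = () if evidence == "organization" else tuple(evidence.split(";"))
        out.append(
            EETGeneCall(
                gene_id=row["gene_id"],
                call_class=row["call_class"],
                heme_count=int(row["heme_count"]),
                compartment=row["compartment"],
                families=families,
                cluster_id=row["cluster_id"],
                cluster_type=row["cluster_type"],
                family=row["family"],
            )
        )
    return out
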