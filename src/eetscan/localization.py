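"""Subcellular localization from annotations and a transparent heuristic.

Real secretion/localization predictors are deliberately not rebuilt
here.  Instead there are two paths, in strict precedence order:

1. a user-supplied annotation table (any external predictor's output),
2. homology-implied roles (a porin or extracellular-family hit places
   the protein in the outer membrane / extracellular space),
3. a deterministic signal-peptide heuristic for self-contained runs:
   a classic tripartite signal peptide is approximated as a positively
   charged n-region (at least one K/R) followed by a hydrophobic
   h-region (a run of >= ``h_min`` residues from {A,F,I,L,M,V,W}),
   all within the first ``n_region_len`` residues.

For MAGs flagged as monoderm (Gram-positive envelope), secreted
multiheme cytochromes are mapped to the cell wall rather than the
periplasm, mirroring cell-wall electron transfer in monoderms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io_model import ProteinRecord, ValidationError

COMPARTMENTS = (
    "cytoplasmic", "periplasmic", "outer_membrane", "extracellular",
    "cell_wall", "unknown",
)

HYDROPHOBIC = set("AFILMVW")
BASIC = set("KR")

#: homology role -> implied compartment
_ROLE_COMPARTMENT = {
    "porin": "outer_membrane",
    "extracellular_MHC": "extracellular",
    "outer_surface_MHC": "outer_membrane",
    "cyc2": "outer_membrane",
}


@dataclass(frozen=True)
class LocalizationCall:
    protein_id: str
    compartment: str
    has_signal_peptide: bool
    evidence: str  # "annotation" | "homology" | "heuristic"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")


def predict_signal_peptide(protein: ProteinRecord, params: Mapping) -> bool:
    """Deterministic signal-peptide heuristic (see module docstring).

    Proteins shorter than ``min_protein_len`` never carry a signal
    peptide under this rule.
    """
    p = params["localization"]
    seq = protein.sequence
    if len(seq) < p["min_protein_len"]:
        return False
    h_min = p["h_min"]
    limit = min(p["n_region_len"], len(seq))
    for start in range(1, limit - h_min + 1):
        window = seq[start : start + h_min]
        if all(c in HYDROPHOBIC for c in window) and any(
            c in BASIC for c in seq[:start]
        ):
            return True
    return False


def assign_localization(
    protein: ProteinRecord,
    signal: bool,
    annotation: str | None,
    hits: Mapping[str, object],
    *,
    is_mhc: bool = False,
    monoderm: bool = False,
) -> LocalizationCall:
    """Resolve one protein's compartment by strict precedence.

    Precedence: user annotation > homology-implied role > heuristic
    (signal peptide => periplasmic, else cytoplasmic).  In monoderm
    (Gram-positive) genomes a secreted MHC is assigned to the cell
    wall, since those organisms have no outer membrane or periplasm.
    """
    if annotation is not None:
        if annotation not in COMPARTMENTS:
            raise ValidationError(
                f"protein {protein.protein_id!r}: unknown compartment "
                f"annotation {annotation!r}"
            )
        compartment = annotation
        if monoderm and is_mhc and compartment in (
            "periplasmic", "outer_membrane", "extracellular",
        ):
            compartment = "cell_wall"
        return LocalizationCall(protein.protein_id, compartment, signal, "annotation")

    for role in ("extracellular_MHC", "outer_surface_MHC", "cyc2", "porin"):
        if role in hits:
            compartment = _ROLE_COMPARTMENT[role]
            if monoderm and is_mhc:
                compartment = "cell_wall"
            return LocalizationCall(protein.protein_id, compartment, signal, "homology")

    if signal:
        compartment = "cell_wall" if (monoderm and is_mhc) else "periplasmic"
    else:
        compartment = "cytoplasmic"
    return LocalizationCall(protein.protein_id, compartment, signal, "heuristic")


def localize_all(
    proteins,
    features_by_id,
    mags,
    annotations: Mapping[str, str],
    hits_by_protein: Mapping[str, Mapping[str, object]],
    mhc_calls: Mapping[str, object],
    params: Mapping,
) -> dict[str, LocalizationCall]:
    """Localization calls for a whole metagenome, keyed by protein_id."""
    out: dict[str, LocalizationCall] = {}
    for p in proteins:
        feat = features_by_id.get(p.protein_id)
        monoderm = False
        if feat is not None:
            monoderm = mags.is_monoderm(mags.mag_of(feat.contig_id))
        call = mhc_calls.get(p.protein_id)
        out[p.protein_id] = assign_localization(
            p,
            predict_signal_peptide(p, params),
            annotations.get(p.protein_id),
            hits_by_protein.get(p.protein_id, {}),
            is_mhc=bool(call and call.is_mhc),
            monoderm=monoderm,
        )
    return out
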