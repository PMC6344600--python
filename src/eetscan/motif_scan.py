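"""Heme-binding motif scanning and multiheme-cytochrome classification.

Heme c attaches covalently at the CXXCH sequence signature; counting
occurrences of the motif per protein estimates its heme number.  A
protein with at least ``mhc_min`` motifs (default 5) is treated as a
multiheme c-type cytochrome (MHC), and MHCs are reported in two
heme-count bins split at ``bin_split`` (default 10).

Matching rules: the two cysteines and the histidine are exact; the
spacer positions match any residue including ``X``; ``X`` never matches
a constrained (C/H) position.  Every matching start index is counted,
so overlapping motifs contribute independently — counts are therefore
deterministic and independent of scan order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_model import ProteinRecord

BIN_LOW = "5-10"
BIN_HIGH = ">10"


@dataclass(frozen=True)
class MotifSet:
    """Spacer lengths k for the heme-binding pattern C-X{k}-C-H."""

    spacers: tuple[int, ...] = (2,)

    def __post_init__(self):
        if not self.spacers:
            raise ValueError("MotifSet needs at least one spacer length")
        if any(k < 1 for k in self.spacers):
            raise ValueError("spacer lengths must be >= 1")

    @classmethod
    def from_params(cls, params: dict) -> "MotifSet":
        return cls(tuple(params["motif"]["spacers"]))

    def pattern_lengths(self) -> dict[int, int]:
        """Map spacer k -> total motif length (C + k + C + H)."""
        return {k: k + 3 for k in self.spacers}


@dataclass(frozen=True)
class HemeScan:
    """Motif start positions (0-based) and the resulting heme count."""

    protein_id: str
    positions: tuple[int, ...]

    @property
    def heme_count(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MHCCall:
    protein_id: str
    heme_count: int
    is_mhc: bool
    bin: str | None
    passes_8: bool


def _motif_regexes(motifs: MotifSet) -> list[re.Pattern]:
    # lookahead so overlapping matches are all reported
    return [re.compile(rf"(?=C.{{{k}}}CH)") for k in sorted(set(motifs.spacers))]


def scan_heme_motifs(protein: ProteinRecord, motifs: MotifSet = MotifSet()) -> HemeScan:
    """Find every start index at which some C-X{k}-C-H pattern matches.

    ``X`` in the sequence matches only spacer slots (``.`` in the
    regex); the literal C and H slots require the exact letter.
    """
    positions: set[int] = set()
    for rx in _motif_regexes(motifs):
        positions.update(m.start() for m in rx.finditer(protein.sequence))
    return HemeScan(protein.protein_id, tuple(sorted(positions)))


def classify_mhc(scan: HemeScan, params: dict) -> MHCCall:
    """Apply the heme-count thresholds to one scan."""
    t = params["mhc"]
    n = scan.heme_count
    is_mhc = n >= t["mhc_min"]
    if not is_mhc:
        bin_label = None
    elif n <= t["bin_split"]:
        bin_label = BIN_LOW
    else:
        bin_label = BIN_HIGH
    return MHCCall(scan.protein_id, n, is_mhc, bin_label, n >= t["emph_min"])


def scan_proteins(
    proteins: Iterable[ProteinRecord], motifs: MotifSet, params: dict
) -> tuple[dict[str, HemeScan], dict[str, MHCCall]]:
    """Scan and classify a whole protein set; keyed by protein_id."""
    scans: dict[str, HemeScan] = {}
    calls: dict[str, MHCCall] = {}
    for p in proteins:
        s = scan_heme_motifs(p, motifs)
        scans[p.protein_id] = s
        calls[p.protein_id] = classify_mhc(s, params)
    return scans, calls
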