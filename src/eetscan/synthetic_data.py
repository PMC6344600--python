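"""Synthetic metagenomes with planted, certified ground truth.

The generator emits the full input bundle of the pipeline — protein
FASTA, GFF3 gene coordinates, contig coverage, MAG membership,
housekeeping markers, an optional localization table — together with a
truth table describing every planted item, so that detection precision
and recall can be measured exactly.

Planted classes
---------------
* multiheme cytochromes with exact, certified heme-motif counts
  (half secreted, half cytoplasmic);
* known-family PCC operons: mutated copies of the bundled MtrAB(C),
  MtoAB, PioAB, and OmbB-OmaB-OmcB references placed at adjacent ranks;
* novel-organization operons: a porin homologous only to a generic
  (non-PCC) porin reference next to a secreted random-sequence MHC —
  detectable only through gene organization;
* Cyc2-like genes: mutated copies of the Cyc2 reference (single
  N-terminal heme motif, C-terminal porin-like region);
* outer-surface MHCs: OmcS/OmcZ homologs, annotation-backed
  extracellular MHCs, and cell-wall MHCs in a monoderm MAG;
* decoys that must *not* be called: 4-heme near-MHCs, lone porins,
  secreted-looking MHC genes without signal peptides, porin/MHC pairs
  separated by too many genes, and cysteine-rich non-motif proteins.

Every planted protein is certified at generation time by an
independent brute-force motif scan, the signal-peptide rule, and —
where class truth depends on it — a homology search; items failing
certification are resampled (rejection sampling keeps planted counts
exact rather than adjusting truth post hoc).  Outputs are byte-for-byte
deterministic given the seed.

Coverage is lognormal per contig multiplied by a per-MAG abundance
factor.  The defaults (sigma 0.25 within a genome, 0.2 between MAGs)
keep within-genome coverage realistic while letting a designed
gene-density gradient across metagenomes, rather than abundance noise,
dominate between-metagenome contrasts.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .config import default_params
from .homology import (
    KNOWN_PCC_FAMILIES, ReferenceEntry, load_references, search_references,
)
from .io_model import (
    UNBINNED, CoverageTable, MAGAssignment, MetagenomeData, ProteinRecord,
    assign_ranks, to_gff_interval,
)
from .localization import predict_signal_peptide
from .motif_scan import MotifSet


class GenerationError(RuntimeError):
    """Rejection sampling failed; the requested composition is infeasible."""


# ---------------------------------------------------------------------------
# Low-level sequence builders
# ---------------------------------------------------------------------------

# background residue frequencies, C/H-depleted so accidental heme motifs
# are rare and rejection sampling converges quickly
_BG_AA = "ARNDCQEGHILKMFPSTWYV"
_BG_WEIGHTS = (
    0.083, 0.055, 0.040, 0.054, 0.003, 0.039, 0.067, 0.072, 0.005, 0.059,
    0.096, 0.058, 0.024, 0.038, 0.047, 0.066, 0.053, 0.011, 0.029, 0.068,
)
_SPACER_AA = "ADEFGKLNPQRSTVY"  # residues used inside motif spacers
_HYDRO = "AFILMVW"

DEFAULT_SPACERS = (2,)


def brute_heme_positions(seq: str, spacers: Sequence[int] = DEFAULT_SPACERS) -> tuple[int, ...]:
    """Independent exhaustive window scan for C-X{k}-C-H start positions."""
    positions = set()
    for k in spacers:
        for i in range(len(seq) - (k + 3) + 1):
            if seq[i] == "C" and seq[i + k + 1] == "C" and seq[i + k + 2] == "H":
                positions.add(i)
    return tuple(sorted(positions))


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choices(_BG_AA, weights=_BG_WEIGHTS, k=length))


def signal_prefix(rng: random.Random) -> str:
    """An N-terminus satisfying the signal-peptide heuristic: M, a basic
    n-region, then a >=8-residue hydrophobic h-region and a short cap."""
    n_region = "".join(rng.choices("KR", k=rng.randint(1, 2)))
    h_region = "".join(rng.choices(_HYDRO, k=rng.randint(8, 11)))
    return "M" + n_region + h_region + "A"


def insert_motifs(
    rng: random.Random, seq: str, n: int, lo: int, hi: int, spacing: int = 7
) -> str:
    """Overwrite ``n`` non-overlapping CXXCH motifs at positions in
    [lo, hi); raises GenerationError when the window is too small."""
    if n == 0:
        return seq
    span = hi - lo
    if span < n * spacing:
        raise GenerationError(f"window {span} too small for {n} motifs")
    stride = span // n
    chars = list(seq)
    for i in range(n):
        pos = lo + i * stride + rng.randrange(stride - 5)
        x1, x2 = rng.choice(_SPACER_AA), rng.choice(_SPACER_AA)
        chars[pos : pos + 5] = ["C", x1, x2, "C", "H"]
    return "".join(chars)


def mutate_sequence(
    rng: random.Random,
    seq: str,
    target_identity: float,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Point-mutate toward ``target_identity``, never writing C or H (so
    no new heme motifs can appear) and never touching protected sites."""
    free = [i for i in range(len(seq)) if i not in protected]
    n_mut = min(len(free), int(round((1.0 - target_identity) * len(seq))))
    chars = list(seq)
    for i in rng.sample(free, n_mut):
        choices = [a for a in _SPACER_AA if a != chars[i]]
        chars[i] = rng.choice(choices)
    return "".join(chars)


# ---------------------------------------------------------------------------
# Config and truth
# ---------------------------------------------------------------------------

#: heme counts of the standalone planted MHCs in the default metagenome
DEFAULT_MHC_HEME_COUNTS: tuple[int, ...] = (
    5, 5, 5, 5, 6, 6, 6, 6, 7, 7, 7, 7, 8, 8, 8, 8, 9, 9, 9, 9,
    10, 10, 10, 10, 11, 11, 11, 11, 12, 12, 12, 13, 13, 14, 14, 15,
    16, 17, 18, 19, 20, 21, 22, 24, 26, 28, 30, 35, 40, 51,
)

_KNOWN_VARIANTS = (
    ("MtrB", "MtrA", None),
    ("MtrB", "MtrA", "MtrC"),
    ("MtoB", "MtoA", None),
    ("PioB", "PioA", None),
    ("OmbB", "OmaB", "OmcB"),
    ("MtrB", "MtrA", None),
)

_HK_MARKERS = (
    "rpoB", "gyrB", "recA", "rplB", "rpsC", "dnaK", "infB", "secY",
    "rpoA", "pyrG", "rplC", "rpsE",
)

_TAXA = (
    "Gallionella-like", "Ferrovum-like", "Albidiferax-like",
    "Geothrix-like", "Methylotenera-like", "Bacteroidetes-like",
    "Verrucomicrobia-like", "Desulfobulbus-like", "Ignavibacteriaceae-like",
    "Solirubrobacterales-like",
)


@dataclass(frozen=True)
class SynthConfig:
    """Composition of one synthetic metagenome (all counts pre-scaling)."""

    seed: int
    metagenome_id: str = "synthetic"
    mhc_heme_counts: tuple[int, ...] = DEFAULT_MHC_HEME_COUNTS
    mhc_signal_fraction: float = 0.5
    n_pcc_known: int = 6
    n_pcc_novel: int = 6
    novel_mhc_heme_counts: tuple[int, ...] = (6, 7, 8, 9, 10, 12)
    n_cyc2: int = 6
    n_outer_surface: int = 6
    n_cell_wall_mhc: int = 3
    n_decoy_near_mhc: int = 10
    n_decoy_lone_porin: int = 8
    n_decoy_mhc_no_signal: int = 8
    n_decoy_distant_pair: int = 4
    n_decoy_cys_rich: int = 6
    n_background: int = 80
    n_housekeeping: int = 20
    n_mags: int = 8
    target_identity: float = 0.70
    coverage_mu: float = 2.5
    coverage_sigma: float = 0.25
    mag_sigma: float = 0.20
    unbinned_fraction: float = 0.12
    background_len_range: tuple[int, int] = (120, 300)
    genes_per_background_contig: tuple[int, int] = (4, 8)
    density_multiplier: float = 1.0
    max_tries: int = 80
    motif_spacers: tuple[int, ...] = DEFAULT_SPACERS

    def scaled(self) -> "SynthConfig":
        """Apply the EET-density multiplier to the planted-class counts."""
        m = self.density_multiplier
        if m == 1.0:
            return self

        def sc(n: int) -> int:
            return int(round(n * m))

        reps = math.ceil(m)
        hemes = (self.mhc_heme_counts * reps)[: sc(len(self.mhc_heme_counts))]
        novel = (self.novel_mhc_heme_counts * reps)[: max(sc(self.n_pcc_novel), 1)]
        return replace(
            self,
            mhc_heme_counts=hemes,
            n_pcc_known=sc(self.n_pcc_known),
            n_pcc_novel=sc(self.n_pcc_novel),
            novel_mhc_heme_counts=novel,
            n_cyc2=sc(self.n_cyc2),
            n_outer_surface=sc(self.n_outer_surface),
            n_cell_wall_mhc=sc(self.n_cell_wall_mhc),
            density_multiplier=1.0,
        )


@dataclass
class TruthTable:
    """Ground truth for one generated metagenome."""

    genes: pd.DataFrame  # gene_id, contig_id, mag_id, kind, heme_count, truth_cluster
    clusters: list[tuple[frozenset, str]]  # (member gene_ids, cluster_type)

    def mhc_ids(self, mhc_min: int = 5) -> set[str]:
        df = self.genes
        return set(df.loc[df["heme_count"] >= mhc_min, "gene_id"])

    def ids_of(self, *kinds: str) -> set[str]:
        df = self.genes
        return set(df.loc[df["kind"].isin(kinds), "gene_id"])

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        clusters: dict[str, list[str]] = {}
        types: dict[str, str] = {}
        for _, row in df.iterrows():
            tc = row["truth_cluster"]
            if tc:
                clusters.setdefault(tc, []).append(row["gene_id"])
                types[tc] = (
                    "known_family" if row["kind"] == "pcc_known"
                    else "novel_organization"
                )
        return cls(df, [(frozenset(v), types[k]) for k, v in sorted(clusters.items())])


# ---------------------------------------------------------------------------
# Planted-gene makers (each certifies its own invariants, resampling on
# failure so planted counts stay exact)
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    seq: str
    kind: str
    heme_count: int
    truth_cluster: str = ""
    annotation: str | None = None
    marker: str = ""
    gene_id: str = ""


class _Maker:
    def __init__(self, cfg: SynthConfig, params: dict, refs: list[ReferenceEntry]):
        self.cfg = cfg
        self.params = params
        self.refs = refs
        self.rng = random.Random(cfg.seed)
        self.ref_by_family = {r.family: r for r in refs}
        self._role_cache: dict[str, dict] = {}

    # -- certification helpers ------------------------------------------
    def _hits(self, seq: str) -> dict:
        if seq not in self._role_cache:
            self._role_cache[seq] = search_references(
                ProteinRecord("q", seq), self.refs, self.params
            )
        return self._role_cache[seq]

    def _no_call_relevant_hits(self, seq: str) -> bool:
        """No hit that could alter the planted class: localization-implying
        roles, or any known-PCC family (which would flip a cluster's type)."""
        hits = self._hits(seq)
        if any(
            r in hits for r in ("porin", "extracellular_MHC", "outer_surface_MHC", "cyc2")
        ):
            return False
        return not any(h.family in KNOWN_PCC_FAMILIES for h in hits.values())

    def _signal(self, seq: str) -> bool:
        return predict_signal_peptide(ProteinRecord("q", seq), self.params)

    def _certify(self, build: Callable[[], str], check: Callable[[str], bool], what: str) -> str:
        for _ in range(self.cfg.max_tries):
            seq = build()
            if check(seq):
                return seq
        raise GenerationError(
            f"rejection sampling failed for {what!r} after {self.cfg.max_tries} tries; "
            "adjust the composition (e.g. lengths or counts)"
        )

    # -- concrete makers -------------------------------------------------
    def background(self, length: int | None = None, *, need_no_porin_hit: bool = False) -> str:
        lo, hi = self.cfg.background_len_range
        n = length or self.rng.randint(lo, hi)

        def check(seq: str) -> bool:
            if brute_heme_positions(seq, self.cfg.motif_spacers):
                return False
            if need_no_porin_hit and "porin" in self._hits(seq):
                return False
            return True

        return self._certify(lambda: "M" + random_protein(self.rng, n - 1), check, "background")

    def mhc(self, hemes: int, signal: bool, *, monoderm: bool = False) -> str:
        body_len = max(120, hemes * 10 + 60)

        def build() -> str:
            prefix = signal_prefix(self.rng) if signal else "M" + random_protein(self.rng, 24)
            body = random_protein(self.rng, body_len)
            body = insert_motifs(self.rng, body, hemes, 10, body_len - 6)
            return prefix + body

        def check(seq: str) -> bool:
            if len(brute_heme_positions(seq, self.cfg.motif_spacers)) != hemes:
                return False
            if self._signal(seq) != signal:
                return False
            return self._no_call_relevant_hits(seq)

        return self._certify(build, check, f"{hemes}-heme MHC")

    def family_homolog(
        self, family: str, *, expect_roles: tuple[str, ...],
        forbid_roles: tuple[str, ...] = (), require_signal: bool | None = None,
        allow_known: bool = True,
    ) -> tuple[str, int]:
        ref = self.ref_by_family[family]
        hemes = len(brute_heme_positions(ref.sequence, self.cfg.motif_spacers))
        protected = set(range(min(35, len(ref.sequence))))
        for pos in brute_heme_positions(ref.sequence, self.cfg.motif_spacers):
            protected.update(range(pos, pos + 5))

        def build() -> str:
            return mutate_sequence(
                self.rng, ref.sequence, self.cfg.target_identity, frozenset(protected)
            )

        def check(seq: str) -> bool:
            if len(brute_heme_positions(seq, self.cfg.motif_spacers)) != hemes:
                return False
            if require_signal is not None and self._signal(seq) != require_signal:
                return False
            hits = self._hits(seq)
            if any(r not in hits or hits[r].family != family for r in expect_roles):
                return False
            if any(r in hits for r in forbid_roles):
                return False
            if not allow_known and any(
                h.family in KNOWN_PCC_FAMILIES for h in hits.values()
            ):
                return False
            return True

        return self._certify(build, check, f"{family} homolog"), hemes

    def cyc2_like(self) -> str:
        seq, _ = self.family_homolog("Cyc2", expect_roles=("cyc2",))
        # re-check the Cyc2 architecture constraints post-mutation
        p = self.params["cyc2"]
        pos = brute_heme_positions(seq, self.cfg.motif_spacers)
        hit = self._hits(seq)["cyc2"]
        half = len(seq) // 2
        q0, q1 = hit.query_interval
        cov = max(0, q1 - max(q0, half)) / (len(seq) - half)
        if not (
            len(pos) == 1
            and pos[0] < p["n_term_window"]
            and p["len_min"] <= len(seq) <= p["len_max"]
            and cov >= p["cterm_cov"]
        ):
            raise GenerationError("Cyc2 homolog failed architecture certification")
        return seq

    def cys_rich(self) -> str:
        lo, hi = self.cfg.background_len_range

        def build() -> str:
            n = self.rng.randint(lo, hi)
            chars = list("M" + random_protein(self.rng, n - 1))
            for _ in range(max(4, n // 12)):
                chars[self.rng.randrange(1, n)] = self.rng.choice("CCH")
            return "".join(chars)

        return self._certify(
            build,
            lambda s: not brute_heme_positions(s, self.cfg.motif_spacers),
            "cysteine-rich decoy",
        )


# ---------------------------------------------------------------------------
# Metagenome assembly
# ---------------------------------------------------------------------------

def _build_units(mk: _Maker, cfg: SynthConfig) -> list[dict]:
    """Units are groups of genes that must share a contig; each unit gets
    its own contig so planted neighborhoods cannot collide."""
    rng = mk.rng
    units: list[dict] = []

    def filler() -> _Gene:
        return _Gene(mk.background(need_no_porin_hit=True), "filler", 0)

    def with_fillers(genes: list[_Gene], hint: str = "") -> dict:
        pre = [filler() for _ in range(rng.randint(0, 1))]
        post = [filler() for _ in range(rng.randint(0, 1))]
        return {"genes": pre + genes + post, "hint": hint}

    # standalone MHCs (the largest one lands on an unbinned contig,
    # echoing big conduit cytochromes turning up outside any bin)
    max_hemes = max(cfg.mhc_heme_counts, default=0)
    unbinned_done = False
    for i, hemes in enumerate(cfg.mhc_heme_counts):
        signal = (i % 2 == 0) if cfg.mhc_signal_fraction == 0.5 else (
            rng.random() < cfg.mhc_signal_fraction
        )
        hint = ""
        if hemes == max_hemes and not unbinned_done:
            hint, unbinned_done = "unbinned", True
        units.append(with_fillers([_Gene(mk.mhc(hemes, signal), "mhc", hemes)], hint))

    # known-family PCC operons
    for i in range(cfg.n_pcc_known):
        porin_fam, peri_fam, ext_fam = _KNOWN_VARIANTS[i % len(_KNOWN_VARIANTS)]
        tc = f"pcc_known_{i}"
        porin_seq, _ = mk.family_homolog(porin_fam, expect_roles=("porin",))
        peri_seq, peri_hemes = mk.family_homolog(
            peri_fam, expect_roles=("periplasmic_MHC",),
            forbid_roles=("extracellular_MHC",), require_signal=True,
        )
        genes = [
            _Gene(porin_seq, "pcc_known", 0, tc),
            _Gene(peri_seq, "pcc_known", peri_hemes, tc),
        ]
        if ext_fam:
            ext_seq, ext_hemes = mk.family_homolog(
                ext_fam, expect_roles=("extracellular_MHC",)
            )
            genes.append(_Gene(ext_seq, "pcc_known", ext_hemes, tc))
        units.append(with_fillers(genes))

    # novel-organization PCC operons: generic porin + random secreted MHC
    for i in range(cfg.n_pcc_novel):
        tc = f"pcc_novel_{i}"
        porin_seq, _ = mk.family_homolog(
            "porin_other", expect_roles=("porin",), allow_known=False
        )
        hemes = cfg.novel_mhc_heme_counts[i % len(cfg.novel_mhc_heme_counts)]
        mhc_seq = mk.mhc(hemes, True)
        units.append(
            with_fillers(
                [
                    _Gene(porin_seq, "pcc_novel", 0, tc),
                    _Gene(mhc_seq, "pcc_novel", hemes, tc),
                ]
            )
        )

    # Cyc2-like genes
    for _ in range(cfg.n_cyc2):
        units.append(with_fillers([_Gene(mk.cyc2_like(), "cyc2", 1)]))

    # outer-surface MHCs: homology-backed and annotation-backed
    for i in range(cfg.n_outer_surface):
        if i % 3 == 2:
            hemes = rng.choice((6, 8, 11, 12))
            g = _Gene(
                mk.mhc(hemes, rng.random() < 0.5), "outer_surface", hemes,
                annotation="extracellular",
            )
        else:
            fam = "OmcS" if i % 3 == 0 else "OmcZ"
            seq, hemes = mk.family_homolog(fam, expect_roles=("outer_surface_MHC",))
            g = _Gene(seq, "outer_surface", hemes)
        units.append(with_fillers([g]))

    # cell-wall MHCs: one gene cluster in a monoderm (Gram-positive) MAG
    if cfg.n_cell_wall_mhc:
        genes = []
        for i in range(cfg.n_cell_wall_mhc):
            hemes = (7, 15, 9, 6, 11)[i % 5]
            genes.append(_Gene(mk.mhc(hemes, True), "cell_wall", hemes))
        units.append({"genes": genes, "hint": "monoderm"})

    # decoys
    for _ in range(cfg.n_decoy_lone_porin):
        seq, _ = mk.family_homolog("porin_other", expect_roles=("porin",), allow_known=False)
        units.append(with_fillers([_Gene(seq, "decoy_lone_porin", 0)]))
    for _ in range(cfg.n_decoy_distant_pair):
        seq, _ = mk.family_homolog("porin_other", expect_roles=("porin",), allow_known=False)
        hemes = rng.choice((6, 8, 10))
        units.append(
            with_fillers(
                [
                    _Gene(seq, "decoy_distant_pair", 0),
                    filler(), filler(),
                    _Gene(mk.mhc(hemes, True), "decoy_distant_pair", hemes),
                ]
            )
        )
    return units


def _build_background_pool(mk: _Maker, cfg: SynthConfig) -> list[_Gene]:
    rng = mk.rng
    pool: list[_Gene] = []
    for i in range(cfg.n_housekeeping):
        pool.append(
            _Gene(
                mk.background(length=rng.randint(200, 420)), "housekeeping", 0,
                marker=_HK_MARKERS[i % len(_HK_MARKERS)],
            )
        )
    for _ in range(cfg.n_background):
        pool.append(_Gene(mk.background(), "background", 0))
    for _ in range(cfg.n_decoy_near_mhc):
        pool.append(_Gene(mk.mhc(4, rng.random() < 0.5), "decoy_near_mhc", 4))
    for _ in range(cfg.n_decoy_mhc_no_signal):
        hemes = rng.choice((5, 6, 7, 9, 11, 13))
        pool.append(_Gene(mk.mhc(hemes, False), "decoy_mhc_no_signal", hemes))
    for _ in range(cfg.n_decoy_cys_rich):
        pool.append(_Gene(mk.cys_rich(), "decoy_cys_rich", 0))
    rng.shuffle(pool)
    return pool


def generate_synthetic_metagenome(
    config: SynthConfig,
    out_dir: str | Path | None = None,
    params: dict | None = None,
) -> tuple[MetagenomeData, TruthTable, dict[str, Path]]:
    """Generate one synthetic metagenome.

    Returns the in-memory dataset, the truth table, and (when
    ``out_dir`` is given) the paths of the emitted files.
    """
    cfg = config.scaled()
    params = params or default_params()
    refs = load_references()
    mk = _Maker(cfg, params, refs)
    rng = mk.rng

    units = _build_units(mk, cfg)
    pool = _build_background_pool(mk, cfg)

    # chunk the background pool into multi-gene contigs
    contigs: list[dict] = list(units)
    i = 0
    lo, hi = cfg.genes_per_background_contig
    while i < len(pool):
        n = rng.randint(lo, hi)
        contigs.append({"genes": pool[i : i + n], "hint": ""})
        i += n

    # contig ids, gene ids, coordinates
    mid = cfg.metagenome_id
    fasta_order: list[_Gene] = []
    feature_rows = []
    for ci, contig in enumerate(contigs):
        contig_id = f"{mid}_c{ci + 1:04d}"
        contig["contig_id"] = contig_id
        pos = rng.randint(30, 200)
        for gi, gene in enumerate(contig["genes"]):
            gene.gene_id = f"{contig_id}_g{gi + 1}"
            length_nt = 3 * len(gene.seq) + 3
            strand = rng.choice("+-")
            feature_rows.append((gene.gene_id, contig_id, pos, pos + length_nt, strand))
            pos += length_nt + rng.randint(20, 200)
            fasta_order.append(gene)

    # MAG assignment: one contig to each MAG first (so none is empty),
    # then hints, then a random unbinned fraction, remainder round-robin
    mag_ids = [f"{mid}_mag{i + 1:02d}" for i in range(cfg.n_mags)]
    monoderm_mag = f"{mid}_mag{cfg.n_mags + 1:02d}" if cfg.n_cell_wall_mhc else None
    assignments: dict[str, str] = {}
    free = []
    for contig in contigs:
        if contig["hint"] == "monoderm" and monoderm_mag:
            assignments[contig["contig_id"]] = monoderm_mag
        elif contig["hint"] == "unbinned":
            assignments[contig["contig_id"]] = UNBINNED
        else:
            free.append(contig["contig_id"])
    rng.shuffle(free)
    for mag, contig_id in zip(mag_ids, free):
        assignments[contig_id] = mag
    for contig_id in free[len(mag_ids):]:
        if rng.random() < cfg.unbinned_fraction:
            assignments[contig_id] = UNBINNED
        else:
            assignments[contig_id] = rng.choice(mag_ids)

    all_mags = mag_ids + ([monoderm_mag] if monoderm_mag else [])
    mag_meta = {
        mag: {
            "taxon": _TAXA[i % len(_TAXA)],
            "envelope": "monoderm" if mag == monoderm_mag else "diderm",
        }
        for i, mag in enumerate(all_mags)
    }

    # coverage: lognormal per contig times a per-MAG abundance factor
    mag_mult = {mag: rng.lognormvariate(0.0, cfg.mag_sigma) for mag in all_mags}
    coverage: dict[str, float] = {}
    for contig in contigs:
        contig_id = contig["contig_id"]
        mult = mag_mult.get(assignments[contig_id])
        if mult is None:  # unbinned contigs draw their own factor
            mult = rng.lognormvariate(0.0, cfg.mag_sigma)
        coverage[contig_id] = rng.lognormvariate(cfg.coverage_mu, cfg.coverage_sigma) * mult

    proteins = [ProteinRecord(g.gene_id, g.seq) for g in fasta_order]
    features = assign_ranks(feature_rows)
    housekeeping = {g.gene_id for g in fasta_order if g.kind == "housekeeping"}
    annotations = {
        g.gene_id: g.annotation for g in fasta_order if g.annotation is not None
    }
    data = MetagenomeData(
        metagenome_id=mid,
        proteins=proteins,
        features=features,
        coverage=CoverageTable(coverage),
        mags=MAGAssignment(assignments, mag_meta),
        housekeeping=housekeeping,
        localization_annotations=annotations,
    )

    # truth table (final certification: independent scan of every protein)
    truth_rows = []
    clusters: dict[str, list[str]] = {}
    cluster_kind: dict[str, str] = {}
    for g in fasta_order:
        observed = len(brute_heme_positions(g.seq, cfg.motif_spacers))
        if observed != g.heme_count:
            raise GenerationError(
                f"certification failure: {g.gene_id} has {observed} motifs, "
                f"planted {g.heme_count}"
            )
        contig_id = g.gene_id.rsplit("_g", 1)[0]
        truth_rows.append(
            {
                "gene_id": g.gene_id,
                "contig_id": contig_id,
                "mag_id": assignments[contig_id],
                "kind": g.kind,
                "heme_count": g.heme_count,
                "truth_cluster": g.truth_cluster,
                "marker": g.marker,
            }
        )
        if g.truth_cluster:
            clusters.setdefault(g.truth_cluster, []).append(g.gene_id)
            cluster_kind[g.truth_cluster] = g.kind
    truth = TruthTable(
        pd.DataFrame(truth_rows),
        [
            (frozenset(members),
             "known_family" if cluster_kind[tc] == "pcc_known" else "novel_organization")
            for tc, members in sorted(clusters.items())
        ],
    )

    paths: dict[str, Path] = {}
    if out_dir is not None:
        paths = _write_bundle(Path(out_dir), data, truth, fasta_order, mag_meta)
    return data, truth, paths


def _write_bundle(
    out_dir: Path,
    data: MetagenomeData,
    truth: TruthTable,
    genes: list[_Gene],
    mag_meta: dict,
) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    mid = data.metagenome_id
    paths = {
        "fasta": out_dir / f"{mid}.faa",
        "gff": out_dir / f"{mid}.gff3",
        "coverage": out_dir / f"{mid}.coverage.tsv",
        "mags": out_dir / f"{mid}.mags.tsv",
        "housekeeping": out_dir / f"{mid}.housekeeping.tsv",
        "localization": out_dir / f"{mid}.localization.tsv",
        "truth": out_dir / f"{mid}.truth.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for p in data.proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for f in data.features:
            s1, e1 = to_gff_interval(f.start, f.end)
            fh.write(
                f"{f.contig_id}\teetscan_sim\tCDS\t{s1}\t{e1}\t.\t{f.strand}\t0\t"
                f"ID={f.gene_id}\n"
            )
    with open(paths["coverage"], "w") as fh:
        fh.write("contig_id\tcoverage\n")
        for contig, depth in data.coverage.items():
            fh.write(f"{contig}\t{depth:.6f}\n")
    with open(paths["mags"], "w") as fh:
        fh.write("contig_id\tmag_id\ttaxon\tenvelope\n")
        for contig, mag in data.mags.items():
            meta = mag_meta.get(mag, {})
            fh.write(
                f"{contig}\t{mag}\t{meta.get('taxon', '')}\t"
                f"{meta.get('envelope', '')}\n"
            )
    with open(paths["housekeeping"], "w") as fh:
        fh.write("gene_id\tmarker\n")
        for g in genes:
            if g.kind == "housekeeping":
                fh.write(f"{g.gene_id}\t{g.marker}\n")
    with open(paths["localization"], "w") as fh:
        fh.write("protein_id\tcompartment\n")
        for g in genes:
            if g.annotation is not None:
                fh.write(f"{g.gene_id}\t{g.annotation}\n")
    truth.to_tsv(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Three-metagenome preset and evaluation
# ---------------------------------------------------------------------------

#: base composition for the three-lake gradient preset (multiplier 1)
GRADIENT_BASE = dict(
    mhc_heme_counts=(5, 6, 8, 10, 11, 12),
    n_pcc_known=1,
    n_pcc_novel=1,
    novel_mhc_heme_counts=(8,),
    n_cyc2=3,
    n_outer_surface=2,
    n_cell_wall_mhc=0,
    n_decoy_near_mhc=2,
    n_decoy_lone_porin=2,
    n_decoy_mhc_no_signal=2,
    n_decoy_distant_pair=1,
    n_decoy_cys_rich=1,
    n_background=25,
    n_housekeeping=12,
    n_mags=4,
)


def three_lake_configs(
    seed: int, multipliers: Sequence[float] = (1.0, 2.0, 4.0)
) -> list[SynthConfig]:
    """Three metagenomes emulating an oxic clear-water epilimnion
    (ME-like), a humic-bog epilimnion (TE-like), and a humic-bog
    hypolimnion (TH-like) via an EET-gene-density gradient."""
    names = ("ME_like", "TE_like", "TH_like")
    return [
        SynthConfig(
            seed=(seed * 10 + i) % (2**31), metagenome_id=names[i],
            density_multiplier=m, **GRADIENT_BASE,
        )
        for i, m in enumerate(multipliers)
    ]


def evaluate_calls(result, truth: TruthTable, mhc_min: int = 5) -> dict[str, dict]:
    """Precision/recall of the pipeline's calls against planted truth.

    ``result`` is a pipeline result carrying ``mhc_calls``, ``clusters``
    and ``calls``.  PCC clusters match only on exact member composition
    and cluster type.  Classes with neither truth nor predictions score
    precision = recall = 1.0.
    """
    def prf(pred: set, true: set) -> dict:
        tp = len(pred & true)
        fp = len(pred - true)
        fn = len(true - pred)
        return {
            "precision": tp / (tp + fp) if (tp + fp) else 1.0,
            "recall": tp / (tp + fn) if (tp + fn) else 1.0,
            "tp": tp, "fp": fp, "fn": fn,
            "false_items": sorted(
                x if isinstance(x, str) else "+".join(sorted(x[0]))
                for x in (pred - true)
            ),
        }

    known_ids = set(truth.genes["gene_id"])
    for c in result.calls:
        if c.gene_id not in known_ids:
            raise KeyError(f"call references unknown gene {c.gene_id!r}")

    pred_mhc = {pid for pid, c in result.mhc_calls.items() if c.is_mhc}
    pred_clusters = {
        (frozenset(c.members()), c.cluster_type) for c in result.clusters
    }
    true_clusters = {(m, t) for m, t in truth.clusters}
    pred_outer = {c.gene_id for c in result.calls if c.call_class == "outer_surface_mhc"}
    pred_cyc2 = {c.gene_id for c in result.calls if c.call_class == "cyc2"}

    return {
        "mhc": prf(pred_mhc, truth.mhc_ids(mhc_min)),
        "pcc": prf(pred_clusters, true_clusters),
        "pcc_known": prf(
            {c for c in pred_clusters if c[1] == "known_family"},
            {c for c in true_clusters if c[1] == "known_family"},
        ),
        "pcc_novel": prf(
            {c for c in pred_clusters if c[1] == "novel_organization"},
            {c for c in true_clusters if c[1] == "novel_organization"},
        ),
        "outer_surface_mhc": prf(
            pred_outer, truth.ids_of("outer_surface", "cell_wall")
        ),
        "cyc2": prf(pred_cyc2, truth.ids_of("cyc2")),
    }
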