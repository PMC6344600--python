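"""Housekeeping-normalized abundances and the summary tables.

A gene's abundance is its contig's mean read coverage divided by the
average coverage of the metagenome's single-copy conserved housekeeping
genes; the quotient is dimensionless (1.0 means "as abundant as an
average single-copy gene") and invariant under global rescaling of
coverage, so values are comparable across metagenomes sequenced to
different depths.

Metagenome summaries report *sums* of normalized abundances per gene
class and heme-count bin — the aggregate abundance of the class, which
makes metagenome totals exactly additive over the per-MAG breakdown.
MAG summaries report the *mean* over that MAG's EET genes, an estimate
of the organism's own relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping

import pandas as pd

from .eet_calls import EETGeneCall
from .io_model import (
    UNBINNED, CoverageTable, GeneFeature, MAGAssignment, ValidationError,
)
from .motif_scan import BIN_HIGH, BIN_LOW, MHCCall


@dataclass(frozen=True)
class NormalizedAbundance:
    gene_id: str
    raw_coverage: float
    denominator: float
    value: float


def housekeeping_denominator(
    features_by_id: Mapping[str, GeneFeature],
    coverage: CoverageTable,
    housekeeping: set[str],
    params: Mapping,
) -> float:
    """Average (contig-inherited) coverage of the housekeeping genes."""
    if not housekeeping:
        raise ValidationError("housekeeping set is empty; cannot normalize")
    depths = []
    for gid in sorted(housekeeping):
        feat = features_by_id.get(gid)
        if feat is None:
            raise ValidationError(f"housekeeping gene {gid!r} has no feature")
        depths.append(coverage.gene_coverage(feat))
    stat = params["abundance"]["hk_stat"]
    denom = median(depths) if stat == "median" else sum(depths) / len(depths)
    if denom <= 0:
        raise ValidationError("housekeeping denominator is zero")
    return denom


def normalize_abundance(
    gene: GeneFeature,
    coverage: CoverageTable,
    denominator: float,
) -> NormalizedAbundance:
    raw = coverage.gene_coverage(gene)
    return NormalizedAbundance(gene.gene_id, raw, denominator, raw / denominator)


def compute_abundances(
    features: Iterable[GeneFeature],
    coverage: CoverageTable,
    housekeeping: set[str],
    params: Mapping,
) -> dict[str, NormalizedAbundance]:
    """Normalized abundance for every gene, keyed by gene_id."""
    features = list(features)
    by_id = {f.gene_id: f for f in features}
    denom = housekeeping_denominator(by_id, coverage, housekeeping, params)
    return {f.gene_id: normalize_abundance(f, coverage, denom) for f in features}


# series labels used in the tidy breakdown and the metagenome summary
SERIES = (
    "mhc_all_5_10", "mhc_all_gt10",
    "mhc_eet_5_10", "mhc_eet_gt10",
    "cyc2",
)


def tidy_gene_table(
    mhc_calls: Mapping[str, MHCCall],
    calls: Iterable[EETGeneCall],
    abundances: Mapping[str, NormalizedAbundance],
    features_by_id: Mapping[str, GeneFeature],
    mags: MAGAssignment,
) -> pd.DataFrame:
    """Long-format per-gene table: one row per (gene, series) membership.

    Every summary in this module is a group-by over this table, which
    is also the plotting-ready tidy output.
    """
    eet_mhc_ids = {
        c.gene_id
        for c in calls
        if c.call_class in ("pcc_component", "outer_surface_mhc")
        and mhc_calls.get(c.gene_id) is not None
        and mhc_calls[c.gene_id].is_mhc
    }
    cyc2_ids = {c.gene_id for c in calls if c.call_class == "cyc2"}

    rows = []
    for gid in sorted(set(mhc_calls) | cyc2_ids):
        feat = features_by_id.get(gid)
        if feat is None:
            continue
        mag = mags.mag_of(feat.contig_id)
        ab = abundances[gid].value
        call = mhc_calls.get(gid)
        if call is not None and call.is_mhc:
            suffix = "5_10" if call.bin == BIN_LOW else "gt10"
            rows.append((gid, mag, f"mhc_all_{suffix}", ab))
            if gid in eet_mhc_ids:
                rows.append((gid, mag, f"mhc_eet_{suffix}", ab))
        if gid in cyc2_ids:
            rows.append((gid, mag, "cyc2", ab))
    return pd.DataFrame(rows, columns=["gene_id", "mag_id", "series", "value"])


@dataclass(frozen=True)
class MetagenomeSummary:
    metagenome_id: str
    mhc_all_5_10: float
    mhc_all_gt10: float
    mhc_eet_5_10: float
    mhc_eet_gt10: float
    cyc2: float
    n_mhc: int
    n_pcc_known: int
    n_pcc_novel: int
    n_outer_surface: int
    n_cyc2: int

    def to_row(self) -> dict:
        return {
            "metagenome_id": self.metagenome_id,
            "mhc_all_5_10": self.mhc_all_5_10,
            "mhc_all_gt10": self.mhc_all_gt10,
            "mhc_eet_5_10": self.mhc_eet_5_10,
            "mhc_eet_gt10": self.mhc_eet_gt10,
            "cyc2": self.cyc2,
            "n_mhc": self.n_mhc,
            "n_pcc_known": self.n_pcc_known,
            "n_pcc_novel": self.n_pcc_novel,
            "n_outer_surface": self.n_outer_surface,
            "n_cyc2": self.n_cyc2,
        }


def summarize_metagenome(
    metagenome_id: str,
    tidy: pd.DataFrame,
    mhc_calls: Mapping[str, MHCCall],
    calls: Iterable[EETGeneCall],
    clusters,
) -> MetagenomeSummary:
    """Per-metagenome aggregate abundances (panel-style summary)."""
    calls = list(calls)
    sums = tidy.groupby("series")["value"].sum() if len(tidy) else pd.Series(dtype=float)

    def total(series: str) -> float:
        return float(sums.get(series, 0.0))

    return MetagenomeSummary(
        metagenome_id=metagenome_id,
        mhc_all_5_10=total("mhc_all_5_10"),
        mhc_all_gt10=total("mhc_all_gt10"),
        mhc_eet_5_10=total("mhc_eet_5_10"),
        mhc_eet_gt10=total("mhc_eet_gt10"),
        cyc2=total("cyc2"),
        n_mhc=sum(1 for c in mhc_calls.values() if c.is_mhc),
        n_pcc_known=sum(1 for c in clusters if c.cluster_type == "known_family"),
        n_pcc_novel=sum(1 for c in clusters if c.cluster_type == "novel_organization"),
        n_outer_surface=sum(1 for c in calls if c.call_class == "outer_surface_mhc"),
        n_cyc2=sum(1 for c in calls if c.call_class == "cyc2"),
    )


def summarize_mags(
    calls: Iterable[EETGeneCall],
    abundances: Mapping[str, NormalizedAbundance],
    features_by_id: Mapping[str, GeneFeature],
    mags: MAGAssignment,
) -> pd.DataFrame:
    """One row per MAG with at least one EET call, plus the unbinned row.

    The reported value is the arithmetic mean of the MAG's EET genes'
    normalized abundances (genes of one genome share its coverage, so
    the mean estimates that organism's relative abundance).
    """
    per_mag: dict[str, list[EETGeneCall]] = {}
    for c in calls:
        feat = features_by_id.get(c.gene_id)
        if feat is None:
            continue
        per_mag.setdefault(mags.mag_of(feat.contig_id), []).append(c)

    rows = []
    mag_ids = sorted(per_mag.keys() - {UNBINNED}) + [UNBINNED]
    for mag in mag_ids:
        members = per_mag.get(mag, [])
        values = [abundances[c.gene_id].value for c in members]
        classes = {c.call_class for c in members}
        cluster_types = {c.cluster_type for c in members}
        rows.append(
            {
                "mag_id": mag,
                "taxon": mags.taxon(mag),
                "n_eet_genes": len(members),
                "mean_normalized_abundance": (
                    sum(values) / len(values) if values else 0.0
                ),
                "has_pcc_known": "known_family" in cluster_types,
                "has_pcc_novel": "novel_organization" in cluster_types,
                "has_outer_surface_mhc": "outer_surface_mhc" in classes,
                "has_cyc2": "cyc2" in classes,
            }
        )
    return pd.DataFrame(rows)


def mag_fraction_with_eet(mag_summary: pd.DataFrame, mags: MAGAssignment) -> float:
    """Fraction of binned MAGs carrying at least one putative EET gene."""
    all_mags = mags.mags()
    if not all_mags:
        return 0.0
    with_eet = set(mag_summary.loc[mag_summary["n_eet_genes"] > 0, "mag_id"])
    return len((with_eet - {UNBINNED}) & all_mags) / len(all_mags)
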