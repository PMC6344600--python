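"""Orchestration: scan -> call -> quantify -> report, per metagenome.

``analyze_metagenome`` is the library entry point; it is a pure
composition of the module operations, so pipeline output always equals
manual chaining of the stages.  ``run_scan_pipeline`` adds file I/O:
it loads one or more input bundles, runs the analysis, and writes the
per-metagenome reports plus a cross-metagenome comparison table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import abundance as ab
from . import eet_calls as ec
from .config import default_params, merge_params
from .homology import ReferenceEntry, load_references, search_all
from .io_model import (
    MetagenomeData, ValidationError, load_metagenome, write_reports,
)
from .localization import localize_all
from .motif_scan import MotifSet, scan_proteins

log = logging.getLogger("eetscan")


@dataclass
class MetagenomeResult:
    """Everything computed for one metagenome."""

    data: MetagenomeData
    params: dict
    scans: dict
    mhc_calls: dict
    hits: dict
    localizations: dict
    clusters: list
    calls: list
    abundances: dict
    tidy: pd.DataFrame
    summary: ab.MetagenomeSummary
    mag_summary: pd.DataFrame
    calls_df: pd.DataFrame

    def mhc_scan_df(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": pid,
                "heme_count": c.heme_count,
                "is_mhc": c.is_mhc,
                "bin": c.bin or "",
            }
            for pid, c in sorted(self.mhc_calls.items())
        ]
        return pd.DataFrame(rows, columns=["protein_id", "heme_count", "is_mhc", "bin"])


def analyze_metagenome(
    data: MetagenomeData,
    params: dict | None = None,
    refs: list[ReferenceEntry] | None = None,
) -> MetagenomeResult:
    """Run the full detection and quantification chain on one metagenome."""
    params = params or default_params()
    refs = refs if refs is not None else load_references()
    features_by_id = data.feature_by_id()

    motifs = MotifSet.from_params(params)
    scans, mhc_calls = scan_proteins(data.proteins, motifs, params)
    log.info("%s: %d proteins, %d MHCs", data.metagenome_id, len(data.proteins),
             sum(1 for c in mhc_calls.values() if c.is_mhc))

    hits = search_all(data.proteins, refs, params, precomputed=data.precomputed_hits)
    localizations = localize_all(
        data.proteins, features_by_id, data.mags,
        data.localization_annotations, hits, mhc_calls, params,
    )

    clusters = ec.detect_pcc_clusters(
        data.features, mhc_calls, localizations, hits, params
    )
    outer = ec.call_outer_surface_mhcs(mhc_calls, localizations, clusters, hits)
    cyc2 = ec.call_cyc2(data.proteins, scans, hits, params)
    calls = ec.assemble_calls(clusters, outer, cyc2, mhc_calls, localizations, hits)
    log.info(
        "%s: %d PCC clusters, %d outer-surface MHCs, %d Cyc2-like",
        data.metagenome_id, len(clusters), len(outer), len(cyc2),
    )

    abundances = ab.compute_abundances(
        data.features, data.coverage, data.housekeeping, params
    )
    tidy = ab.tidy_gene_table(mhc_calls, calls, abundances, features_by_id, data.mags)
    summary = ab.summarize_metagenome(
        data.metagenome_id, tidy, mhc_calls, calls, clusters
    )
    mag_summary = ab.summarize_mags(calls, abundances, features_by_id, data.mags)
    calls_df = ec.calls_dataframe(calls, features_by_id, data.mags)
    return MetagenomeResult(
        data, params, scans, mhc_calls, hits, localizations, clusters,
        calls, abundances, tidy, summary, mag_summary, calls_df,
    )


@dataclass
class RunConfig:
    """One pipeline invocation over one or more input bundles."""

    metagenomes: list[dict]  # each: metagenome_id + input paths
    out_dir: str | Path
    params: dict = field(default_factory=default_params)
    seed: int | None = None

    _PATH_KEYS = ("fasta", "gff", "coverage", "mags", "housekeeping",
                  "localization", "hits")

    def validate(self) -> None:
        ids = [m["metagenome_id"] for m in self.metagenomes]
        if len(ids) != len(set(ids)):
            raise ValidationError("metagenome_ids must be unique")
        missing = []
        for m in self.metagenomes:
            for key in self._PATH_KEYS:
                p = m.get(key)
                if p is not None and not Path(p).exists():
                    missing.append(f"{m['metagenome_id']}:{key}={p}")
        if missing:
            raise ValidationError("missing input files: " + ", ".join(missing))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            metagenomes=raw["metagenomes"],
            out_dir=raw.get("out_dir", "eetscan_out"),
            params=merge_params(raw.get("params")),
            seed=raw.get("seed"),
        )


def run_scan_pipeline(config: RunConfig) -> dict[str, MetagenomeResult]:
    """Run every metagenome in the config and write all reports.

    Reports land in ``out_dir/<metagenome_id>/``; a combined
    ``metagenome_comparison.tsv`` is written at the top level.
    """
    config.validate()
    refs = load_references()
    out_dir = Path(config.out_dir)
    results: dict[str, MetagenomeResult] = {}
    for m in config.metagenomes:
        mid = m["metagenome_id"]
        try:
            data = load_metagenome(
                mid, m["fasta"], m["gff"], m["coverage"],
                m.get("mags"), m.get("housekeeping"),
                m.get("localization"), m.get("hits"),
            )
            result = analyze_metagenome(data, config.params, refs)
        except Exception as exc:
            raise type(exc)(f"[{mid}] {exc}") from exc
        results[mid] = result
        write_reports(
            result.calls_df,
            result.mag_summary,
            pd.DataFrame([result.summary.to_row()]),
            out_dir / mid,
            config=config.params,
            seed=config.seed,
            input_paths={k: m[k] for k in RunConfig._PATH_KEYS if m.get(k)},
            extra_tables={
                "mhc_scan": result.mhc_scan_df(),
                "gene_abundance_tidy": result.tidy,
            },
        )

    comparison = pd.DataFrame(
        [results[m["metagenome_id"]].summary.to_row() for m in config.metagenomes]
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    comparison.to_csv(
        out_dir / "metagenome_comparison.tsv", sep="\t", index=False,
        lineterminator="\n",
    )
    return results
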