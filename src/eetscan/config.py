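"""Parameter blocks and config file handling.

Every threshold used anywhere in the pipeline lives in one nested
dictionary so that reports can embed the fully resolved configuration.
Values can be overridden from a YAML file or programmatically; unknown
keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import copy
from typing import Any, Mapping

import yaml

#: All tunable parameters with their defaults.  See docs/methods.md for
#: the rationale behind each value.
DEFAULTS: dict[str, dict[str, Any]] = {
    "motif": {
        # spacer lengths k for the heme-binding pattern C-X{k}-C-H;
        # the canonical motif is CXXCH (k=2).  CX3CH/CX4CH variants can
        # be enabled by adding 3 and/or 4.
        "spacers": [2],
    },
    "mhc": {
        "mhc_min": 5,     # >= mhc_min heme motifs => multiheme cytochrome
        "emph_min": 8,    # secondary, more stringent reporting threshold
        "bin_split": 10,  # heme-count bins: [mhc_min, bin_split], (bin_split, inf)
    },
    "homology": {
        "matrix": "BLOSUM62",
        "gap_open": 11,    # cost of the first residue of a gap
        "gap_extend": 1,   # cost of each further gap residue
        "min_identity": 0.30,
        "min_query_cov": 0.50,
        # raw-score floor below which no traceback is attempted; local
        # alignments this weak never satisfy the identity+coverage
        # thresholds for realistic protein lengths
        "min_score": 50,
    },
    "localization": {
        "h_min": 7,          # minimum hydrophobic run length (h-region)
        "n_region_len": 45,  # signal peptide must start within this many residues
        "min_protein_len": 30,
    },
    "pcc": {
        "max_gene_gap": 1,        # intervening genes allowed between porin and MHC
        "strand_required": False,
        # minimum heme count for the periplasmic MHC member; None means
        # inherit mhc.mhc_min
        "pcc_mhc_min": None,
    },
    "cyc2": {
        "n_term_window": 60,  # the single heme motif must start in this prefix
        "cterm_cov": 0.40,    # Cyc2 hit must cover this fraction of the C-terminal half
        "len_min": 150,
        "len_max": 800,
    },
    "abundance": {
        # statistic over housekeeping-gene coverages used as the
        # normalization denominator ("mean" per the source convention;
        # "median" available for outlier-heavy assemblies)
        "hk_stat": "mean",
    },
}


def default_params() -> dict[str, dict[str, Any]]:
    """A deep copy of the default parameter blocks."""
    return copy.deepcopy(DEFAULTS)


def merge_params(overrides: Mapping[str, Mapping[str, Any]] | None) -> dict:
    """Merge ``overrides`` onto the defaults, validating keys.

    Raises ``KeyError`` for any section or key not present in
    :data:`DEFAULTS`.
    """
    params = default_params()
    if not overrides:
        return params
    for section, block in overrides.items():
        if section not in params:
            raise KeyError(f"unknown config section: {section!r}")
        if not isinstance(block, Mapping):
            raise TypeError(f"config section {section!r} must be a mapping")
        for key, value in block.items():
            if key not in params[section]:
                raise KeyError(f"unknown config key: {section}.{key}")
            params[section][key] = value
    return params


def load_params(path) -> dict:
    """Load parameter overrides from a YAML file and merge with defaults."""
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    return merge_params(overrides)
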