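"""Declarative pipeline configuration.

A single nested key/value structure (YAML on disk) holds every threshold
used anywhere in the pipeline, each defaulting to the published value of
the processing protocol it implements (QC read/saturation cutoffs, DEG
thresholds, module-score parameters, ...).  ``load_config`` merges a user
file over the defaults; unknown keys are rejected so typos fail loudly.
"""
from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "qc": {
        "min_raw_reads": 10000,
        "min_saturation": 0.5,
        "min_gene_frac": 0.05,
        "loq_detect_frac": 0.05,
        "loq_epsilon": 0.5,
        "pca_k_mads": 4.0,
        "apply_pca_filter": False,
        "gene_frac_above_loq": False,
    },
    "dea": {
        "alpha": 0.05,
        "lfc_min": 0.58,
        "log_pseudocount": 1.0,
    },
    "signatures": {
        "source_mask": "CD68",
        "contaminant_mask": "CD20",
        "top_k": 50,
    },
    "scoring": {
        "standardize": True,
        "min_gene_overlap": 0.5,
        "module_n_bins": 25,
        "module_n_ctrl": 100,
        "module_score_threshold": 0.1,
        "sc_min_genes_per_cell": 200,
        "sc_max_mito_frac": 0.1,
        "sc_min_cells_per_gene": 3,
    },
    "survival": {
        "tie_method": "efron",
        "alpha": 0.05,
    },
    "association": {
        "alternative": "two-sided",
    },
    "simulate": {
        "n_genes": 1500,
        "n_neg_probes": 100,
        "aois_per_stratum": 12,
        "n_dlbcl_patients": 30,
        "n_rlt_patients": 10,
        "n_patients": 400,
        "frac_planted": 0.05,
        "frac_contaminant": 0.1,
        "lfc_magnitude": 1.5,
        "nb_dispersion": 0.1,
        "size_factor_sd": 0.3,
        "batch_sd": 0.1,
        "n_batches": 2,
        "censor_frac": 0.3,
        "hazard_coef": 0.42,
        "duplicate_core_frac": 0.27,
        "label_assoc": 1.0,
    },
    "pipeline": {
        "outdir": "dspsig_out",
        "stages": [
            "simulate",
            "preprocess",
            "validate-masks",
            "dea",
            "derive-sig",
            "score",
            "survive",
            "associate",
            "enrich",
        ],
    },
}


class ConfigError(KeyError):
    pass


def _merge(base: dict, override: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        dotted = f"{prefix}{key}"
        if key not in base:
            raise ConfigError(f"unknown config key {dotted!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {dotted!r} must be a section")
            out[key] = _merge(base[key], value, prefix=f"{dotted}.")
        else:
            out[key] = value
    return out


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def load_config(path=None) -> dict:
    """Load YAML config merged over defaults; ``None`` returns defaults."""
    if path is None:
        return default_config()
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return _merge(DEFAULTS, user)


def get(config: dict, dotted: str):
    """Fetch ``section.key`` from a config, erroring with the full key name."""
    node = config
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"missing config key {dotted!r}")
        node = node[part]
    return node
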