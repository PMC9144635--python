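"""Canonical study conditions for the four benchmark experiments.

These presets pin down the dataset configurations, mechanisms, rates,
methods and repeat counts that the package's own validation (tests and the
reproduction script) runs.  Desk-scale sizes are chosen so each experiment
finishes in minutes on one CPU; the methods note documents the choices.

All presets are pure functions of a single integer seed.
"""

from __future__ import annotations

from typing import Any

from .benchmark import BenchmarkConfig
from .synthetic import BioSimConfig, ReplicateSimConfig

__all__ = [
    "accuracy_config",
    "association_config",
    "regression_config",
    "consistency_config",
    "indepth_config",
]

#: light random-forest settings for repeated benchmark cells; the registry
#: default (100 trees) is for one-off imputation runs
_RF_BENCH = {"n_trees": 30, "max_iter": 5}


def accuracy_config(seed: int) -> BenchmarkConfig:
    """Complete-table accuracy ranking: 150 x 60 technical replicates,
    10% mixture missingness, 20 repeats, six methods spanning the
    model-based / substitution divide."""
    return BenchmarkConfig(
        dataset=ReplicateSimConfig(seed=seed),
        mechanisms=("mix",),
        rates=(0.10,),
        methods=("rf", "grr", "bpca", "mean", "zero", "hm"),
        method_params={"rf": dict(_RF_BENCH)},
        n_repeats=20,
        seed=seed,
    )


def association_config(seed: int) -> BenchmarkConfig:
    """RMSE-vs-CV and RMSE-vs-missingness associations on biological data.

    Technical replicates carry no cross-metabolite structure, so
    per-metabolite error there depends on CV but not on how many of the
    metabolite's cells were removed; the missingness association needs a
    correlated biological table and a spread of rates.
    """
    return BenchmarkConfig(
        dataset=BioSimConfig(seed=seed, n_metabolites=60),
        mechanisms=("mix",),
        rates=(0.05, 0.10, 0.20, 0.30, 0.40),
        methods=("rf", "grr", "bpca"),
        method_params={"rf": dict(_RF_BENCH)},
        n_repeats=2,
        seed=seed,
    )


def regression_config(seed: int) -> BenchmarkConfig:
    """Downstream regression bias: 45-sample biological cohort (age 6-23,
    30% of metabolites age-affected), mixture missingness at 10% and 20%,
    the three top-accuracy methods."""
    return BenchmarkConfig(
        dataset=BioSimConfig(seed=seed),
        mechanisms=("mix",),
        rates=(0.10, 0.20),
        methods=("rf", "grr", "bpca"),
        method_params={"rf": dict(_RF_BENCH)},
        n_repeats=3,
        seed=seed,
    )


def consistency_config(seed: int) -> BenchmarkConfig:
    """Internal-consistency bias: biological cohort with pronounced shared
    covariance (3 latent factors, sd 0.3) so Cronbach's alpha over
    metabolite items is well-defined; mixture at 10% and 20%."""
    return BenchmarkConfig(
        dataset=BioSimConfig(seed=seed, n_metabolites=60, n_factors=3, factor_sd=0.3),
        mechanisms=("mix",),
        rates=(0.10, 0.20),
        methods=("bpca", "rf", "grr"),
        method_params={"rf": dict(_RF_BENCH)},
        n_repeats=10,
        seed=seed,
    )


def indepth_config(seed: int) -> tuple[BenchmarkConfig, dict[str, Any]]:
    """Single-value insertion protocol on a naturally incomplete table.

    The table emulates a full peak table: a dominant sample-level latent
    (near-duplicate features), noise CVs 5-35% rank-coupled to natural
    dropout (poor peaks are both noisier and more often missing), and ~30%
    overall natural missingness with soft detection-limit censoring.
    Returns (config, extras) where extras feed run_indepth_single_value.
    """
    dataset = BioSimConfig(
        seed=seed,
        n_metabolites=40,
        baseline_missing_rate=0.3,
        noise_cv_range=(0.05, 0.35),
        n_factors=2,
        factor_sd=0.15,
        block_size=40,
        block_sd=0.25,
        censor_sharpness=1.0,
        cv_missing_coupling=0.7,
    )
    config = BenchmarkConfig(
        dataset=dataset,
        mechanisms=("mix",),
        rates=(0.10,),
        methods=("rf",),
        method_params={"rf": {"n_trees": 20, "max_iter": 3}},
        n_repeats=1,
        seed=seed,
    )
    extras = {
        "n_iter": 300,
        "max_missing_pct": 75.0,
        "sweep_rates": (0.10, 0.30, 0.50, 0.70),
        "sweep_repeats": 2,
        "method": "rf",
    }
    return config, extras
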