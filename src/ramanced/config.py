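"""Run configuration: strict YAML parsing into typed blocks.

Unknown keys are fatal everywhere — a misspelled parameter never silently
falls back to a default. Every defaulted field is echoed back fully
resolved in the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .models import ModelConfig
from .nn import TrainSettings
from .preprocess import PreprocessConfig
from .synth import CohortSpec, PeakModel, WavenumberGrid, build_default_peak_set

__all__ = ["RunConfig", "load_config"]

_COHORT_KEYS = {
    "n_ced",
    "n_control",
    "replicates_per_patient",
    "grid",
    "peaks",
    "baseline_coeffs",
    "broad_background_amplitude",
    "broad_background_center",
    "broad_background_sigma",
    "replicate_noise_sd",
    "patient_noise_sd",
    "patient_scale_sigma",
    "noise_model",
    "seed",
}
_PRE_KEYS = {
    "airpls",
    "airpls_lambda",
    "airpls_max_iter",
    "airpls_ratio",
    "smoothing",
    "sg_window",
    "sg_polyorder",
    "fft_mode",
    "fft_cutoff",
    "normalization",
    "average",
}
_PCA_KEYS = {"retained_variance_target", "zscore"}
_EVAL_KEYS = {"test_fraction", "k", "bootstrap", "run_cv", "specificity_mode", "split_seed"}
_MODEL_KEYS = {
    "family",
    "conv_filters",
    "kernel_sizes",
    "dropout_rate",
    "residual_units",
    "shrinkage_reduction",
    "knn_k",
    "svm_kernel",
    "svm_c",
    "training",
}
_TRAIN_KEYS = {
    "epochs",
    "batch_size",
    "learning_rate",
    "optimizer",
    "patience",
    "min_delta",
    "validation_fraction",
    "seed",
}
_TOP_KEYS = {"cohort", "preprocess", "pca", "models", "evaluation", "output_dir", "seed"}


def _check_keys(block: dict, allowed: set[str], context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {context}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})"
        )


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pca: dict = field(
        default_factory=lambda: {"retained_variance_target": 0.85, "zscore": True}
    )
    models: list[ModelConfig] = field(
        default_factory=lambda: [ModelConfig(family=f) for f in
                                 ("svm", "knn", "cnn", "resnet", "drsn", "mcnn")]
    )
    evaluation: dict = field(
        default_factory=lambda: {
            "test_fraction": 0.3,
            "k": 5,
            "bootstrap": 1000,
            "run_cv": True,
            "specificity_mode": "standard",
            "split_seed": 0,
        }
    )
    output_dir: str = "runs"
    seed: int = 0

    def resolved(self) -> dict:
        """Fully resolved config (every default filled in) for the manifest."""
        from .synth import _spec_to_dict

        return {
            "cohort": _spec_to_dict(self.cohort),
            "preprocess": vars(self.preprocess) | {},
            "pca": dict(self.pca),
            "models": [
                {
                    "family": m.family,
                    "conv_filters": list(m.conv_filters),
                    "kernel_sizes": list(m.kernel_sizes),
                    "dropout_rate": m.dropout_rate,
                    "residual_units": m.residual_units,
                    "shrinkage_reduction": m.shrinkage_reduction,
                    "knn_k": m.knn_k,
                    "svm_kernel": m.svm_kernel,
                    "svm_c": m.svm_c,
                    "training": vars(m.training) | {},
                }
                for m in self.models
            ],
            "evaluation": dict(self.evaluation),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }


def _cohort_from_block(block: dict) -> CohortSpec:
    _check_keys(block, _COHORT_KEYS, "cohort")
    kwargs = dict(block)
    if "grid" in kwargs:
        grid = kwargs.pop("grid")
        _check_keys(grid, {"start", "stop", "step"}, "cohort.grid")
        kwargs["grid"] = WavenumberGrid(**grid)
    if "peaks" in kwargs:
        peaks = kwargs.pop("peaks")
        if peaks == "default":
            kwargs["peaks"] = tuple(build_default_peak_set())
        else:
            kwargs["peaks"] = tuple(PeakModel(**p) for p in peaks)
    if "baseline_coeffs" in kwargs:
        kwargs["baseline_coeffs"] = tuple(kwargs["baseline_coeffs"])
    return CohortSpec(**kwargs)


def _models_from_block(entries: list, global_seed: int) -> list[ModelConfig]:
    configs = []
    for i, entry in enumerate(entries):
        _check_keys(entry, _MODEL_KEYS, f"models[{i}]")
        kwargs = dict(entry)
        training = kwargs.pop("training", {})
        _check_keys(training, _TRAIN_KEYS, f"models[{i}].training")
        training.setdefault("seed", global_seed)
        for tup in ("conv_filters", "kernel_sizes"):
            if tup in kwargs:
                kwargs[tup] = tuple(kwargs[tup])
        configs.append(ModelConfig(training=TrainSettings(**training), **kwargs))
    return configs


def load_config(source: str | Path | dict | None, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file or dict; ``seed`` overrides.

    Missing blocks take their defaults; unknown keys raise a configuration
    error naming the key and its context.
    """
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{source}: configuration root must be a mapping")
    _check_keys(data, _TOP_KEYS, "configuration")

    global_seed = seed if seed is not None else int(data.get("seed", 0))
    cohort_block = dict(data.get("cohort", {}))
    cohort_block.setdefault("seed", global_seed)
    cohort = _cohort_from_block(cohort_block)

    pre_block = dict(data.get("preprocess", {}))
    _check_keys(pre_block, _PRE_KEYS, "preprocess")
    if "fft_cutoff" in pre_block and isinstance(pre_block["fft_cutoff"], list):
        pre_block["fft_cutoff"] = tuple(pre_block["fft_cutoff"])
    preprocess = PreprocessConfig(**pre_block)

    pca_block = dict(data.get("pca", {}))
    _check_keys(pca_block, _PCA_KEYS, "pca")
    pca = {"retained_variance_target": 0.85, "zscore": True} | pca_block

    eval_block = dict(data.get("evaluation", {}))
    _check_keys(eval_block, _EVAL_KEYS, "evaluation")
    evaluation = {
        "test_fraction": 0.3,
        "k": 5,
        "bootstrap": 1000,
        "run_cv": True,
        "specificity_mode": "standard",
        "split_seed": global_seed,
    } | eval_block

    if "models" in data:
        models = _models_from_block(data["models"], global_seed)
    else:
        models = [
            ModelConfig(family=f, training=TrainSettings(seed=global_seed))
            for f in ("svm", "knn", "cnn", "resnet", "drsn", "mcnn")
        ]

    return RunConfig(
        cohort=cohort,
        preprocess=preprocess,
        pca=pca,
        models=models,
        evaluation=evaluation,
        output_dir=str(data.get("output_dir", "runs")),
        seed=global_seed,
    )
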