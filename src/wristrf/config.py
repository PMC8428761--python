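"""End-to-end pipeline configuration and driver.

A :class:`PipelineConfig` bundles everything needed to reproduce one
experiment: the synthetic-cohort parameters (or a path to a measured
cohort file), the feature recipe, classifier hyperparameters, the fold
count and fusion schemes, and the master seed. :func:`run_pipeline`
executes simulate/load -> assemble -> cross-validate and writes a results
JSON that echoes the fully resolved configuration, so any reported number
can be regenerated from its own results file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import Cohort, CohortError, read_cohort
from .evaluation import FUSION_SCHEMES, run_cv
from .features import FeatureRecipe
from .mlp import ClassifierConfig
from .synthetic import SimulationParams, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("wristrf")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one full screening-analysis run."""

    simulation: SimulationParams = field(default_factory=SimulationParams)
    cohort_path: str | None = None  # when set, load instead of simulating
    cohort_dialect: str = "packed_csv"
    recipe: FeatureRecipe = field(default_factory=FeatureRecipe)
    dropout_rate: float = 0.5
    epochs: int = 1000
    l2_weights: float = 1e-4
    learning_rate: float = 1e-3
    k: int = 7
    schemes: tuple[str, ...] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim_kwargs = dict(raw.get("simulation", {}))
        for key in ("age_range_g1", "age_range_g2", "bmi_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        recipe_raw = dict(raw.get("recipe", {}))
        recipe = FeatureRecipe(
            encoding=recipe_raw.get("encoding", "complex_reim"),
            arm_mode=recipe_raw.get("arm_mode", "separate"),
            include_circumference=recipe_raw.get("circumference", True),
            normalize_eq1=recipe_raw.get("normalize", False),
        )
        classifier_raw = dict(raw.get("classifier", {}))
        schemes = raw.get("schemes")
        seed = int(raw.get("seed", 0))
        return cls(
            simulation=SimulationParams(**sim_kwargs),
            cohort_path=raw.get("cohort_path"),
            cohort_dialect=raw.get("cohort_dialect", "packed_csv"),
            recipe=recipe,
            dropout_rate=float(classifier_raw.get("dropout_rate", 0.5)),
            epochs=int(classifier_raw.get("epochs", 1000)),
            l2_weights=float(classifier_raw.get("l2_weights", 1e-4)),
            learning_rate=float(classifier_raw.get("learning_rate", 1e-3)),
            k=int(raw.get("k", 7)),
            schemes=tuple(schemes) if schemes else None,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schemes"] = list(self.schemes) if self.schemes else None
        return d

    def classifier_template(self) -> ClassifierConfig:
        # n_in is a placeholder; run_cv overrides it with the recipe's length
        return ClassifierConfig(
            n_in=201,
            dropout_rate=self.dropout_rate,
            epochs=self.epochs,
            l2_weights=self.l2_weights,
            learning_rate=self.learning_rate,
            seed=self.seed,
        )


def _load_or_simulate(config: PipelineConfig) -> Cohort:
    if config.cohort_path is not None:
        path = Path(config.cohort_path)
        if not path.exists():
            raise CohortError(f"cohort file not found: {path}")
        logger.info("loading cohort from %s (%s)", path, config.cohort_dialect)
        return read_cohort(path, dialect=config.cohort_dialect)
    # the pipeline master seed drives every stochastic stage, simulation included
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    logger.info(
        "simulating cohort: %d + %d subjects, seed=%d",
        sim.n_group1, sim.n_group2, sim.seed,
    )
    return simulate_cohort(sim)


def run_pipeline(config: PipelineConfig, out_path=None) -> dict:
    """Execute the full analysis and return (and optionally write) results.

    The results dict embeds the resolved config; serialization uses sorted
    keys and fixed float formatting, so identical configs give
    byte-identical output files.
    """
    cohort = _load_or_simulate(config)
    logger.info(
        "assembling features (%s/%s) and running %d-fold CV, seed=%d",
        config.recipe.encoding, config.recipe.arm_mode, config.k, config.seed,
    )
    result = run_cv(
        cohort,
        config.recipe,
        classifier_config=config.classifier_template(),
        k=config.k,
        seed=config.seed,
        schemes=config.schemes,
    )
    payload = {
        "config": config.to_dict(),
        "n_subjects": len(cohort),
        "provenance": cohort.provenance,
        "results": result.to_dict(),
    }
    if out_path is not None:
        text = json.dumps(payload, indent=1, sort_keys=True)
        Path(out_path).write_text(text + "\n")
        logger.info("results written to %s", out_path)
    return payload
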