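"""End-to-end workflow: featurize -> train -> generate -> evaluate.

A :class:`RunConfig` fully describes a run (corpus, featurization, model
hyperparameters, search settings, reward objective, seed) and round-trips
through YAML unchanged; unknown keys are rejected so a typo cannot
silently fall back to a default. :func:`run_pipeline` executes the stages
and writes a checkpoint, the generated molecules with per-molecule
provenance, a benchmark report, and a manifest (config hash + seed) that
makes the run exactly repeatable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chem_graph import ConfigurationError, FeatureConfig, read_molecule_file, \
    write_smiles_file
from .evaluation import distribution_benchmark
from .fixtures import make_fixture_set
from .mcts import MCTSConfig, generate
from .rewards import RewardSpec
from .vgae import GraphVAE

logger = logging.getLogger(__name__)

_VGAE_KEYS = {"latent_dim", "hidden_dim", "n_conv_layers", "learning_rate",
              "batch_size", "epochs", "validation_fraction"}
_FEATURE_KEYS = {"allowed_elements", "bond_types", "max_atoms", "max_degree"}
_MCTS_KEYS = {f.name for f in dataclasses.fields(MCTSConfig)} - {"seed"}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Serializable description of one full run."""

    seed: int = 0
    objective: str = "qed"
    normalize: str | None = None
    input_path: str | None = None      # None -> use the fixture generator
    input_format: str = "smiles"
    n_fixture_molecules: int = 500
    n_feature_maps: int = 20
    out_dir: str = "runs/out"
    log_level: str = "INFO"
    feature: dict = field(default_factory=dict)   # FeatureConfig overrides
    vgae: dict = field(default_factory=dict)      # GraphVAE overrides
    mcts: dict = field(default_factory=dict)      # MCTSConfig overrides

    def __post_init__(self):
        for key in self.feature:
            if key not in _FEATURE_KEYS:
                raise ConfigurationError(f"unknown feature key {key!r}")
        for key in self.vgae:
            if key not in _VGAE_KEYS:
                raise ConfigurationError(f"unknown vgae key {key!r}")
        for key in self.mcts:
            if key not in _MCTS_KEYS:
                raise ConfigurationError(f"unknown mcts key {key!r}")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    # ---- derived objects ----------------------------------------------
    def feature_config(self) -> FeatureConfig:
        d = FeatureConfig().to_dict()
        d.update(self.feature)
        return FeatureConfig.from_dict(d)

    def mcts_config(self) -> MCTSConfig:
        return MCTSConfig(seed=self.seed, **self.mcts)

    def reward_spec(self) -> RewardSpec:
        return RewardSpec(self.objective, normalize=self.normalize)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_corpus(config: RunConfig) -> list:
    if config.input_path is None:
        return make_fixture_set(config.n_fixture_molecules, seed=config.seed)
    mols, skipped = read_molecule_file(config.input_path, config.input_format)
    if skipped:
        logger.info("skipped %d unparseable records", skipped)
    if not mols:
        raise StageError("corpus", "empty", f"no molecules in {config.input_path}")
    return mols


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a dict of artifact paths."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    try:
        corpus = load_corpus(config)
    except (OSError, ConfigurationError) as exc:
        raise StageError("corpus", "io", str(exc)) from exc
    write_smiles_file(out / "training.smi", corpus)
    artifacts["training"] = out / "training.smi"

    try:
        model = GraphVAE(feature_config=config.feature_config(),
                         seed=config.seed, **config.vgae)
        model.fit(corpus)
    except Exception as exc:
        raise StageError("train", "fit_failed", str(exc)) from exc
    model.save(out / "checkpoint.npz")
    artifacts["checkpoint"] = out / "checkpoint.npz"
    with open(out / "loss_history.json", "w") as fh:
        json.dump(model.loss_history_, fh, indent=1)

    try:
        table = generate(model, config.reward_spec(), config.mcts_config(),
                         config.n_feature_maps, seed=config.seed)
    except Exception as exc:
        raise StageError("generate", "search_failed", str(exc)) from exc
    if table.empty:
        raise StageError("generate", "no_molecules",
                         "no feature map reached minimum_depth")
    write_smiles_file(out / "molecules.smi", table["smiles"])
    table.to_csv(out / "provenance.csv", index=False)
    artifacts["molecules"] = out / "molecules.smi"
    artifacts["provenance"] = out / "provenance.csv"

    try:
        report = distribution_benchmark(list(table["smiles"]), corpus)
    except Exception as exc:
        raise StageError("evaluate", "benchmark_failed", str(exc)) from exc
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    artifacts["report"] = out / "report.json"

    manifest = {"config": config.to_dict(), "config_hash": config.config_hash(),
                "seed": config.seed}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
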