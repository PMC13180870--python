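"""End-to-end orchestration: curate → GAN → fidelity → classify → screen.

One global seed drives every stage through fixed offsets (stage seed =
global seed + offset), so stages are individually re-runnable and the whole
run is reproducible: re-running the same config reproduces identical
artifact checksums (single-threaded mode).  Every run writes a JSON manifest
recording the config echo, stage seeds, per-stage row counts, the leakage
certificate and a SHA-256 checksum of each artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .classifier import (
    ActivityClassifier,
    GbtConfig,
    SplitSpec,
    augment_training,
    cross_validate,
    split_real,
)
from .errors import ValidationError
from .fidelity import fidelity_report
from .gan import CganConfig, ConditionalGAN
from .screening import screen
from .synthetic import FixtureSpec, ScreeningLibrarySpec, make_screening_fixture, make_training_fixture
from .tables import LABEL_COL, write_csv

log = logging.getLogger(__name__)

# stage seed offsets from the global seed
SEED_OFFSETS = {
    "fixture": 1,
    "gan": 2,
    "sample": 3,
    "split": 4,
    "gbt": 5,
    "library": 6,
    "fidelity": 7,
}


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (demo mode: fixtures generated in-run)."""

    outdir: str = "runs/demo"
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    library: ScreeningLibrarySpec | None = field(default_factory=ScreeningLibrarySpec)
    gan: CganConfig = field(default_factory=CganConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    gbt: GbtConfig = field(default_factory=GbtConfig)
    n_synthetic_per_class: int = 50
    threshold: float = 0.5
    cv_folds: int = 0  # 0 disables cross-validation
    run_tsne: bool = True
    seed: int = 42

    def stage_seed(self, stage: str) -> int:
        return self.seed + SEED_OFFSETS[stage]


def load_config(path) -> RunConfig:
    """Read a hierarchical YAML config; missing keys take package defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    nested = {
        "fixture": FixtureSpec,
        "library": ScreeningLibrarySpec,
        "gan": CganConfig,
        "split": SplitSpec,
        "gbt": GbtConfig,
    }
    for key, value in raw.items():
        if key in nested:
            if key == "fixture" and "integer_columns" in (value or {}):
                value["integer_columns"] = frozenset(value["integer_columns"])
            kwargs[key] = nested[key](**value) if value is not None else None
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def _config_echo(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {f.name: convert(getattr(config, f.name)) for f in dataclasses.fields(config)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``<outdir>/manifest.json``)."""
    if not 0 < config.threshold < 1:
        raise ValidationError("screening threshold must lie in (0, 1)")
    config.split  # SplitSpec validated at construction; re-raise early if replaced badly
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    manifest: dict = {"config": _config_echo(config), "stage_seeds": {}, "counts": {}}

    def record(name: str, path: Path) -> None:
        artifacts[name] = path

    # --- stage 1: training data (demo fixtures)
    fixture_spec = replace(config.fixture, seed=config.stage_seed("fixture"))
    manifest["stage_seeds"]["fixture"] = fixture_spec.seed
    log.info("stage fixture: generating %d+%d compounds", fixture_spec.n_active, fixture_spec.n_inactive)
    real = make_training_fixture(fixture_spec)
    manifest["counts"]["real"] = len(real)
    write_csv(real, outdir / "real_descriptors.csv")
    record("real_descriptors", outdir / "real_descriptors.csv")

    # --- stage 2: GAN training
    gan_cfg = replace(config.gan, seed=config.stage_seed("gan"))
    manifest["stage_seeds"]["gan"] = gan_cfg.seed
    log.info("stage gan: training %d epochs", gan_cfg.epochs)
    gan_results = ConditionalGAN(real, gan_cfg).fit()
    gan_results.loss_history.to_csv(outdir / "gan_loss_history.csv", index=False)
    record("gan_loss_history", outdir / "gan_loss_history.csv")

    # --- stage 3: synthetic samples
    sample_seed = config.stage_seed("sample")
    manifest["stage_seeds"]["sample"] = sample_seed
    synthetic = gan_results.sample_balanced(config.n_synthetic_per_class, sample_seed)
    manifest["counts"]["synthetic"] = len(synthetic)
    write_csv(synthetic, outdir / "synthetic_descriptors.csv")
    record("synthetic_descriptors", outdir / "synthetic_descriptors.csv")

    # --- stage 4: fidelity diagnostics
    fid_seed = config.stage_seed("fidelity")
    manifest["stage_seeds"]["fidelity"] = fid_seed
    log.info("stage fidelity: real vs synthetic diagnostics")
    report = fidelity_report(real, synthetic, seed=fid_seed, tsne=config.run_tsne)
    report.distributions.to_csv(outdir / "fidelity_distributions.csv", index=False)
    record("fidelity_distributions", outdir / "fidelity_distributions.csv")
    manifest["fidelity"] = report.summary()

    # --- stage 5: leakage-safe split + augmentation
    split_spec = replace(config.split, seed=config.stage_seed("split"))
    manifest["stage_seeds"]["split"] = split_spec.seed
    train, validation, test = split_real(real, split_spec)
    combined, certificate = augment_training(train, synthetic, validation, test)
    manifest["counts"].update(
        train_real=len(train),
        validation=len(validation),
        test=len(test),
        train_combined=len(combined),
    )
    manifest["leakage_certificate"] = certificate

    # --- stage 6: classifier
    gbt_cfg = replace(config.gbt, seed=config.stage_seed("gbt"))
    manifest["stage_seeds"]["gbt"] = gbt_cfg.seed
    log.info("stage classifier: %d boosting rounds", gbt_cfg.n_estimators)
    clf_results = ActivityClassifier(combined, validation, gbt_cfg).fit()
    clf_results.logloss_curves.to_csv(outdir / "logloss_curves.csv", index=False)
    record("logloss_curves", outdir / "logloss_curves.csv")
    eval_report = clf_results.evaluate(test, config.threshold)
    (outdir / "eval_report.json").write_text(json.dumps(eval_report.to_dict(), sort_keys=True, default=float))
    record("eval_report", outdir / "eval_report.json")
    manifest["evaluation"] = {
        k: v
        for k, v in eval_report.to_dict().items()
        if not k.startswith("calibration")
    }

    if config.cv_folds >= 2:
        cv = cross_validate(real, synthetic, k=config.cv_folds, config=gbt_cfg, seed=split_spec.seed)
        manifest["cross_validation"] = {
            "folds": list(cv.fold_accuracies),
            "mean": cv.mean,
            "sd": cv.sd,
        }

    # --- stage 7: screening
    if config.library is not None:
        lib_spec = replace(config.library, seed=config.stage_seed("library"))
        manifest["stage_seeds"]["library"] = lib_spec.seed
        library, truth = make_screening_fixture(lib_spec, fixture_spec)
        write_csv(library, outdir / "screening_library.csv")
        record("screening_library", outdir / "screening_library.csv")
        result = screen(clf_results, library, config.threshold)
        result.scored.to_csv(outdir / "screening_scores.csv", index=False)
        record("screening_scores", outdir / "screening_scores.csv")
        result.dropped.to_csv(outdir / "screening_dropped.csv", index=False)
        record("screening_dropped", outdir / "screening_dropped.csv")
        truth.to_csv(outdir / "screening_hidden_truth.csv")
        manifest["counts"].update(
            library=len(library), scored=result.n_scored, dropped=result.n_dropped,
            predicted_active=result.n_predicted_active,
        )
        scored_truth = truth.loc[result.scored["compound_id"]]
        manifest["screening_recovered_active_fraction"] = float(
            (scored_truth == "active").mean()
        )
        manifest["screening_predicted_active_fraction"] = (
            result.n_predicted_active / result.n_scored if result.n_scored else None
        )

    manifest["checksums"] = {name: _sha256(path) for name, path in sorted(artifacts.items())}
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2, default=float))
    log.info("pipeline complete: %s", outdir / "manifest.json")
    return manifest
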