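"""End-to-end orchestration: generate → train → clean (×3) → evaluate.

Each stage writes resumable artifacts to the output directory; re-running
with the same configuration skips stages whose outputs already exist, and
deleting an intermediate regenerates only the downstream stages.  Every
artifact carries a metadata sidecar echoing the configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Mapping

import yaml

from blinkclean import baselines, cnn, evaluation, synthgen
from blinkclean.config import GeneratorConfig, ICAConfig, TrainConfig
from blinkclean.io import load_dataset, read_recording, save_dataset, write_recording

log = logging.getLogger("blinkclean")


@dataclass(frozen=True)
class RunConfig:
    """Flat key-value configuration for the full pipeline.

    Unknown keys are rejected; the instance is echoed into every output's
    metadata sidecar.
    """

    out_dir: str = "blinkclean_run"
    seed: int = 20220211
    recording_format: str = "csv"      # "csv" or "edf"
    n_windows: int = 10_000            # training-set size
    epochs: int = 5
    batch_size: int = 128
    learning_rate: float = 1e-3
    test_duration: float = 60.0        # held-out recording length, s
    n_components: int = 15
    n_remove: int = 2
    highpass_cutoff: float = 1.0
    filter_order: int = 6
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.recording_format not in {"csv", "edf"}:
            raise ValueError("recording_format must be 'csv' or 'edf'")
        if self.n_windows <= 0 or self.epochs <= 0:
            raise ValueError("n_windows and epochs must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        loaded = yaml.safe_load(Path(path).read_text())
        if not isinstance(loaded, Mapping):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(loaded)


def run_pipeline(config: RunConfig) -> "evaluation.MetricReport":
    """Run all stages; returns the final metric report.

    Stage outputs (under ``config.out_dir``):

    * ``clean.<fmt>``, ``contaminated.<fmt>`` — held-out test recording pair
    * ``dataset.npz`` — paired training windows
    * ``model.npz`` / ``model.json`` — trained denoiser
    * ``cleaned_{cnn,ica,reg}.<fmt>`` — per-method cleaned recordings
    * ``report.csv`` — per-channel-per-method statistics
    """
    logging.basicConfig(
        level=getattr(logging, config.verbosity.upper(), logging.INFO),
        format="%(asctime)s %(name)s [%(levelname)s] %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = config.recording_format
    gen_config = GeneratorConfig(seed=config.seed)
    echo = {"run_config": config.to_dict()}

    # -- stage 1: generate the held-out test recording ----------------------
    clean_path = out / f"clean.{fmt}"
    cont_path = out / f"contaminated.{fmt}"
    if clean_path.exists() and cont_path.exists():
        log.info("[generate] outputs exist, skipping")
        clean = read_recording(clean_path)
        contaminated = read_recording(cont_path)
    else:
        log.info("[generate] %.0f s test recording, seed %d",
                 config.test_duration, config.seed)
        clean, contaminated, _ = synthgen.generate_recording(
            config.test_duration, gen_config, config.seed)
        clean.meta.update(echo)
        contaminated.meta.update(echo)
        write_recording(clean, clean_path)
        write_recording(contaminated, cont_path)

    # -- stage 2: generate the training dataset -----------------------------
    dataset_path = out / "dataset.npz"
    if dataset_path.exists():
        log.info("[dataset] output exists, skipping")
        dataset = load_dataset(dataset_path)
    else:
        log.info("[dataset] %d paired windows, seed %d",
                 config.n_windows, config.seed + 1)
        dataset = synthgen.generate_dataset(config.n_windows, gen_config,
                                            config.seed + 1)
        dataset.meta.update(echo)
        save_dataset(dataset, dataset_path)

    # -- stage 3: train the denoiser ----------------------------------------
    model_path = out / "model"
    train_config = TrainConfig(epochs=config.epochs,
                               batch_size=config.batch_size,
                               learning_rate=config.learning_rate,
                               seed=config.seed)
    if model_path.with_suffix(".npz").exists():
        log.info("[train] model exists, skipping")
        trained = cnn.load_model(model_path)
    else:
        log.info("[train] %d epochs, batch %d, seed %d",
                 train_config.epochs, train_config.batch_size,
                 train_config.seed)
        model = cnn.build_model(seed=train_config.seed)
        trained = cnn.train(model, dataset, train_config)
        cnn.save_model(trained, model_path)

    # -- stage 4: clean with all three methods ------------------------------
    cleaned: dict[str, "object"] = {}
    ref = gen_config.reference_channel
    for method in ("cnn", "ica", "reg"):
        path = out / f"cleaned_{method}.{fmt}"
        if path.exists():
            log.info("[clean:%s] output exists, skipping", method)
            cleaned[method] = read_recording(path)
            continue
        log.info("[clean:%s] cleaning test recording", method)
        if method == "cnn":
            rec = cnn.clean_recording(trained, contaminated, ref)
        elif method == "ica":
            ica_config = ICAConfig(n_components=config.n_components,
                                   n_remove=config.n_remove,
                                   highpass_cutoff=config.highpass_cutoff,
                                   filter_order=config.filter_order,
                                   seed=config.seed)
            rec, _ = baselines.ica_clean(contaminated, ica_config, ref)
        else:
            rec = baselines.regression_clean(contaminated, ref).cleaned
        rec.meta.update(echo)
        write_recording(rec, path)
        cleaned[method] = rec

    # -- stage 5: evaluate ---------------------------------------------------
    log.info("[evaluate] computing the five statistics per channel/method")
    report = evaluation.compare_methods(clean, contaminated, cleaned, ref)
    report.provenance.update(echo)
    report.to_csv(out / "report.csv")
    (out / "report.txt").write_text(report.summary() + "\n")
    log.info("[evaluate] report written to %s", out / "report.csv")
    return report
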