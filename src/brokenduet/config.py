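"""Run configuration, serialization and the pipeline orchestrator."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .erp import extract_lfps, peristimulus_erp
from .experiments import SimulationProtocol, run_simulation
from .filtering import FilterSettings
from .listener import PrecisionConfig

__all__ = ["RunConfig", "run_pipeline", "ValidationError"]


class ValidationError(ValueError):
    """A configuration failed validation before any computation."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run.

    Round-trips losslessly through YAML/JSON; the seed and a content hash
    of the config are recorded in every output.
    """

    label: str = "A"
    n_samples: int = 4096
    period: int | None = None
    schedule_start: int = 1
    noise_sd: float = 0.0
    time_step: float = 1.0
    speaker_init: tuple = (0.8, -3.0, 0.0)
    listener_init: tuple = (-0.8, 3.0, 0.0)
    internal_log_precision: float | None = None
    external_log_precision: float | None = None
    lobe_prior_mean: float = 1.0
    lobe_prior_log_precision: float = -1.0
    state_order: int = 6
    cause_order: int = 2
    smoothness: float = 0.5
    inner_iterations: int = 8
    burn_in_fraction: float = 0.10
    seed: int = 0
    out_dir: str = "runs"
    with_erp: bool = False
    erp_window: tuple = (-5, 25)
    erp_upsample: int = 10

    def __post_init__(self):
        if self.label.upper() not in {"A", "B", "C", "D", "CUSTOM"}:
            raise ValidationError(
                f"unknown simulation label {self.label!r}; expected A-D or custom"
            )
        if self.label.upper() == "CUSTOM" and (
            self.internal_log_precision is None
            or self.external_log_precision is None
        ):
            raise ValidationError(
                "custom label requires explicit internal/external log-precisions"
            )
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not (0 <= self.burn_in_fraction < 1):
            raise ValidationError("burn_in_fraction must be in [0, 1)")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["speaker_init"] = list(self.speaker_init)
        d["listener_init"] = list(self.listener_init)
        d["erp_window"] = list(self.erp_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("speaker_init", "listener_init", "erp_window"):
            if k in d:
                d[k] = tuple(d[k])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path) -> None:
        p = Path(path)
        if p.suffix in (".yaml", ".yml"):
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            p.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def content_hash(self) -> str:
        """Hash of the scientific content (everything except the output path)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- derived objects ----------------------------------------------------
    def precision_config(self) -> PrecisionConfig:
        if self.label.upper() == "CUSTOM":
            return PrecisionConfig(
                float(self.internal_log_precision),
                float(self.external_log_precision),
                "custom",
            )
        return PrecisionConfig.from_label(self.label)

    def protocol(self) -> SimulationProtocol:
        return SimulationProtocol(
            n_samples=self.n_samples,
            period=self.period,
            schedule_start=self.schedule_start,
            noise_sd=self.noise_sd,
            time_step=self.time_step,
            speaker_init=tuple(self.speaker_init),
            listener_init=tuple(self.listener_init),
            burn_in_fraction=self.burn_in_fraction,
            state_order=self.state_order,
            cause_order=self.cause_order,
            lobe_prior_mean=self.lobe_prior_mean,
            lobe_prior_log_precision=self.lobe_prior_log_precision,
            filter_settings=FilterSettings(inner_iterations=self.inner_iterations),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute generate -> invert -> metrics (-> ERP) and write artifacts.

    Returns (and writes) a manifest listing every produced file with its
    content hash, plus the seed and config hash.  Idempotent for a fixed
    config.  Stage failures are recorded per stage in the manifest rather
    than silently discarded; the first failing stage stops the pipeline.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    prefix = f"{config.label.upper()}_{chash}"
    manifest: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "label": config.label.upper(),
        "stages": {},
        "files": {},
    }

    config.to_file(out / f"{prefix}_config.json")
    manifest["files"]["config"] = str(out / f"{prefix}_config.json")

    try:
        result = run_simulation(
            config.precision_config(), config.protocol(), seed=config.seed
        )
        manifest["stages"]["simulate"] = "ok"
    except Exception as exc:
        manifest["stages"]["simulate"] = f"failed: {exc}"
        (out / f"{prefix}_manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    percept_path = out / f"{prefix}_percept.csv"
    result.percept.to_csv(percept_path, schedule=result.schedule)
    traj_path = out / f"{prefix}_speaker.csv"
    result.speaker.to_csv(traj_path)
    post_path = out / f"{prefix}_posterior.csv"
    result.posterior.to_csv(post_path)
    metrics = {
        "label": result.label,
        "seed": config.seed,
        "config_hash": chash,
        "internal_log_precision": result.config.internal_log_precision,
        "external_log_precision": result.config.external_log_precision,
        "speaker_init": list(config.speaker_init),
        "listener_init": list(config.listener_init),
        "n_samples": config.n_samples,
        "period": config.period,
        "log_mse": result.log_mse,
        "lobe_recovered": result.lobe_recovered,
        "lobe_belief": result.lobe_belief,
    }
    metrics_path = out / f"{prefix}_metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
    manifest["stages"]["metrics"] = "ok"

    files = {
        "percept": percept_path,
        "speaker": traj_path,
        "posterior": post_path,
        "metrics": metrics_path,
    }

    if config.with_erp:
        try:
            if len(result.schedule.switch_indices) == 0:
                raise ValueError(
                    "ERP stage requires a switching schedule (set period)"
                )
            erp = peristimulus_erp(
                extract_lfps(result.posterior),
                result.schedule,
                window=tuple(config.erp_window),
                upsample=config.erp_upsample,
            )
            erp_path = out / f"{prefix}_erp.csv"
            erp.to_csv(erp_path)
            files["erp"] = erp_path
            manifest["stages"]["erp"] = "ok"
        except Exception as exc:
            manifest["stages"]["erp"] = f"failed: {exc}"

    for key, path in files.items():
        manifest["files"][key] = str(path)
        manifest.setdefault("hashes", {})[key] = _sha256(Path(path))

    (out / f"{prefix}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
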