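"""End-to-end orchestration: simulate -> (voltage -> detect) -> bursts -> report.

A run is driven by a RunConfig (YAML-loadable), executes every configured
condition, writes all stage outputs under an output directory, and records
a manifest with the echoed config, software version, per-file SHA-256
checksums and timestamps. Spike-level runs are byte-deterministic for a
fixed seed (timestamps excluded, which live only in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import __version__
from .bursts import BurstParams, detect_bursts
from .detection import DetectionParams, RecordingConfig, detect_all
from .io import (
    write_bursts_csv,
    write_ground_truth_json,
    write_ibi_csv,
    write_json,
    write_spike_csv,
    write_voltage_h5,
)
from .netstats import compare_conditions, culture_summary
from .synthetic import (
    SimulationParams,
    builtin_fixtures,
    generate_spike_trains,
    make_default_template,
    synthesize_voltage,
)

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline"]

logger = logging.getLogger("burstnet")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Settings for one reproducible pipeline run.

    ``conditions`` maps condition names to SimulationParams; names matching
    the built-in fixtures may be listed without parameters. ``mode`` is
    "spike_level" (generator output feeds burst analysis directly) or
    "voltage_level" (voltage is synthesized and spikes re-detected, which
    exercises the threshold detector; use short durations / few electrodes
    for tractable volumes).
    """

    seed: int = 0
    conditions: dict[str, SimulationParams] = field(default_factory=dict)
    detection: DetectionParams = field(default_factory=DetectionParams)
    bursts: BurstParams = field(default_factory=BurstParams)
    output_dir: str = "burstnet_run"
    mode: str = "spike_level"
    noise_sd_uv: float = 10.0
    snr: float = 6.0

    def __post_init__(self) -> None:
        if self.mode not in ("spike_level", "voltage_level"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None, output_dir=None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        fixtures = builtin_fixtures()
        conditions: dict[str, SimulationParams] = {}
        for name, block in (raw.get("conditions") or {}).items():
            if block is None or block == {} or block == "fixture":
                if name not in fixtures:
                    raise KeyError(f"unknown condition fixture {name!r}")
                conditions[name] = fixtures[name]
            else:
                base = fixtures.get(name, SimulationParams(condition_label=name))
                conditions[name] = replace(base, condition_label=name, **block)
        det = DetectionParams(**(raw.get("detection") or {}))
        bur = BurstParams(**(raw.get("bursts") or {}))
        return cls(
            seed=seed if seed is not None else int(raw.get("seed", 0)),
            conditions=conditions,
            detection=det,
            bursts=bur,
            output_dir=str(output_dir or raw.get("output_dir", "burstnet_run")),
            mode=raw.get("mode", "spike_level"),
            noise_sd_uv=float(raw.get("noise_sd_uv", 10.0)),
            snr=float(raw.get("snr", 6.0)),
        )


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict[str, str]  # path -> sha256
    started_at: float = 0.0
    finished_at: float = 0.0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def condition_seed(base_seed: int, index: int) -> int:
    """Stable per-condition child seed, kept below 2**31."""
    return (base_seed * 1_000_003 + 7919 * (index + 1)) % (2**31)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every configured condition and write a comparison report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=_config_dict(config),
        version=__version__,
        outputs={},
        started_at=time.time(),
    )
    summaries = []
    stage = "setup"
    try:
        for i, (name, params) in enumerate(sorted(config.conditions.items())):
            seed = condition_seed(config.seed, i)
            params = replace(params, seed=seed)
            cdir = out / name
            cdir.mkdir(exist_ok=True)

            stage = f"simulate[{name}]"
            logger.info("stage=%s seed=%d", stage, seed)
            trains, gt = generate_spike_trains(params)
            write_spike_csv(trains, cdir / "spikes.csv")
            write_ground_truth_json(gt, cdir / "ground_truth.json")

            if config.mode == "voltage_level":
                stage = f"voltage[{name}]"
                rec_cfg = RecordingConfig(
                    n_electrodes=params.n_electrodes, duration_s=params.duration_s
                )
                template = make_default_template(
                    rec_cfg.sampling_rate_hz,
                    peak_uv=-config.snr * config.noise_sd_uv,
                )
                rec = synthesize_voltage(
                    trains, template, config.noise_sd_uv, rec_cfg, seed=seed
                )
                write_voltage_h5(rec, cdir / "voltage.h5")
                stage = f"detect[{name}]"
                result = detect_all(rec, config.detection)
                trains = result.trains
                write_spike_csv(trains, cdir / "spikes_detected.csv")

            stage = f"bursts[{name}]"
            burst_trains = [detect_bursts(t, config.bursts) for t in trains]
            write_bursts_csv(burst_trains, cdir / "bursts.csv")
            write_ibi_csv(burst_trains, cdir / "ibis.csv")

            stage = f"summary[{name}]"
            summ = culture_summary(
                burst_trains=burst_trains,
                condition_label=name,
                div=params.div,
            )
            logger.info(
                "stage=%s n_bursts=%d active=%d",
                stage,
                summ.n_bursts,
                summ.n_active_electrodes,
            )
            summaries.append(summ)

        stage = "compare"
        report = {
            "seed": config.seed,
            "mode": config.mode,
            "summaries": {s.condition_label: s.to_dict() for s in summaries},
        }
        comparable = [s for s in summaries if s.n_bursts >= 2]
        if len(comparable) >= 2:
            report["comparisons"] = compare_conditions(comparable)
            by_div: dict = {}
            for s in comparable:
                by_div.setdefault(s.div, []).append(s)
            report["per_div"] = {
                str(div): compare_conditions(group)
                for div, group in by_div.items()
                if len(group) >= 2
            }
        elif len(summaries) >= 2:
            report["comparisons"] = None  # too few bursts in some culture
        write_json(report, out / "summary.json")
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise PipelineError(stage, exc) from exc

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.outputs[str(p.relative_to(out))] = _sha256(p)
    manifest.finished_at = time.time()
    write_json(dataclasses.asdict(manifest), out / "manifest.json")
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["conditions"] = {
        name: dataclasses.asdict(p) for name, p in config.conditions.items()
    }
    return d
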