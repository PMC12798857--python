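"""Pipeline orchestration: simulate -> clean -> metrics -> capture-effect
-> survival, driven by a single config with one master seed.

Every stage reads and writes plain CSV/JSON under the run directory, and a
manifest records config and file hashes so a rerun with the same config is
reproducible and completed stages can be skipped. Per-stage RNG streams
derive from the master seed by stable hashing, so toggling one stage never
shifts another's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import capture_effect as ce
from . import survival as sv
from .metrics import movement_metric_table
from .simulate import SimulationConfig, simulate_cohort
from .spaceuse import space_use_series
from .telemetry import build_deployments, read_collar_data

log = logging.getLogger(__name__)

STAGES = ("simulate", "clean", "metrics", "spaceuse", "capture_effect",
          "survival", "report")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str = "run"
    seed: int = 1
    stages: tuple[str, ...] = STAGES
    fixes_csv: str | None = None      # external input; None => simulate
    metadata_csv: str | None = None
    sim: dict = field(default_factory=dict)          # SimulationConfig kwargs
    clean: dict = field(default_factory=dict)        # build_deployments kwargs
    metrics: tuple[str, ...] = ("distance", "displacement")
    spaceuse_metrics: tuple[str, ...] = ("range_size", "overlap")
    alpha: float = 0.05
    survival_covariates: tuple[str, ...] = ("method", "sex", "season")
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["metrics"] = list(self.metrics)
        d["spaceuse_metrics"] = list(self.spaceuse_metrics)
        d["survival_covariates"] = list(self.survival_covariates)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage RNG seed below 2^31 derived from the master."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


def _load_manifest(out: Path) -> dict:
    mpath = out / "manifest.json"
    if mpath.exists():
        return json.loads(mpath.read_text())
    return {"stages": {}}


def _save_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))


def run_pipeline(config: RunConfig, resume: bool = True) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(out) if resume else {"stages": {}}
    if manifest.get("config_hash") not in (None, config.config_hash()):
        manifest = {"stages": {}}  # config changed: start over
    manifest["config_hash"] = config.config_hash()
    manifest["config"] = config.to_dict()
    from . import __version__
    manifest["version"] = __version__

    if config.fixes_csv is not None:
        for p in (config.fixes_csv, config.metadata_csv):
            if p is None or not Path(p).exists():
                raise PipelineError(f"input path missing: {p}")

    def done(stage: str) -> bool:
        entry = manifest["stages"].get(stage)
        if not entry:
            return False
        return all(Path(f).exists() and _sha256(Path(f)) == h
                   for f, h in entry["outputs"].items())

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs}}
        _save_manifest(out, manifest)

    try:
        for stage in config.stages:
            if stage not in STAGES:
                raise PipelineError(f"unknown stage {stage!r}")
            if resume and done(stage):
                log.info("stage %s: up to date, skipped", stage)
                continue
            outputs = _run_stage(stage, config, out)
            record(stage, outputs)
    except Exception as exc:  # machine-readable failure in the manifest
        manifest["error"] = {"stage": stage, "message": str(exc)}
        _save_manifest(out, manifest)
        raise
    return out


def _deployments(config: RunConfig, out: Path):
    fixes_csv = config.fixes_csv or out / "fixes.csv"
    meta_csv = config.metadata_csv or out / "metadata.csv"
    fixes, meta = read_collar_data(fixes_csv, meta_csv)
    return build_deployments(fixes, meta, **config.clean), meta


def _run_stage(stage: str, config: RunConfig, out: Path) -> list[Path]:
    if stage == "simulate":
        if config.fixes_csv is not None:
            return []  # external data: nothing to simulate
        sim_cfg = SimulationConfig(**{"seed": config.stage_seed("simulate"),
                                      **config.sim})
        cohort = simulate_cohort(sim_cfg)
        cohort.write(out)
        return [out / "fixes.csv", out / "metadata.csv", out / "truth.csv"]

    if stage == "clean":
        deployments, _ = _deployments(config, out)
        cleaned = pd.concat([d.fixes for d in deployments if not d.fixes.empty],
                            ignore_index=True)
        cleaned = cleaned.copy()
        for col in ("timestamp_utc", "timestamp_local"):
            if col in cleaned.columns:
                cleaned[col] = cleaned[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        cleaned.to_csv(out / "cleaned_fixes.csv", index=False)
        dep_rows = [{
            "deployment_id": d.deployment_id, "method": d.method,
            "sex": d.sex, "capture_season": d.capture_season,
            "thermal_season": d.thermal_season,
            "capture_time_local": d.capture_time_local.isoformat(),
            "end_date": d.end_date.isoformat() if d.end_date is not None else "",
            "eligible_movement": d.eligible_movement,
            "eligible_survival": d.eligible_survival,
        } for d in deployments]
        pd.DataFrame(dep_rows).to_csv(out / "deployments.csv", index=False)
        return [out / "cleaned_fixes.csv", out / "deployments.csv"]

    if stage == "metrics":
        deployments, _ = _deployments(config, out)
        table = movement_metric_table(deployments, metrics=config.metrics)
        table.to_csv(out / "metrics.csv", index=False)
        return [out / "metrics.csv"]

    if stage == "spaceuse":
        deployments, _ = _deployments(config, out)
        values = {}
        for dep in deployments:
            if not dep.eligible_movement:
                continue
            sizes, overlaps = space_use_series(dep)
            values[(dep.deployment_id, "range_size")] = sizes
            values[(dep.deployment_id, "overlap")] = overlaps
        table = movement_metric_table(
            deployments, metrics=config.spaceuse_metrics,
            space_use_values=values)
        table.to_csv(out / "spaceuse.csv", index=False)
        return [out / "spaceuse.csv"]

    if stage == "capture_effect":
        series = pd.read_csv(out / "metrics.csv",
                             dtype={"day": str})
        sus = out / "spaceuse.csv"
        if sus.exists():
            series = pd.concat([series, pd.read_csv(sus, dtype={"day": str})],
                               ignore_index=True)
        meta = pd.read_csv(out / "deployments.csv").rename(
            columns={})
        outputs = []
        for metric in series["metric"].unique():
            fit = ce.analyze_metric(series, meta, metric, alpha=config.alpha)
            base = out / f"capture_effect_{metric}"
            fit.wald.to_csv(f"{base}_wald.csv", index=False)
            fit.contrasts.to_csv(f"{base}_contrasts.csv", index=False)
            outputs_seasonal = fit.seasonal is not None
            if outputs_seasonal:
                fit.seasonal.to_csv(f"{base}_seasonal.csv", index=False)
            spans = {" | ".join(map(str, k)): v for k, v in fit.spans.items()}
            report = {
                "metric": metric,
                "transform": fit.transform.kind,
                "sigma2_deployment": fit.model.sigma2_b,
                "sigma2_residual": fit.model.sigma2_e,
                "wald": fit.wald.to_dict(orient="records"),
                "altered_day_spans": spans,
            }
            Path(f"{base}.json").write_text(json.dumps(report, indent=2))
            outputs += [Path(f"{base}_wald.csv"),
                        Path(f"{base}_contrasts.csv"), Path(f"{base}.json")]
            if outputs_seasonal:
                outputs.append(Path(f"{base}_seasonal.csv"))
        return outputs

    if stage == "survival":
        deployments, _ = _deployments(config, out)
        records = sv.build_survival_records(deployments)
        records.to_csv(out / "survival_records.csv", index=False)
        fit = sv.analyze_survival(records,
                                  covariates=config.survival_covariates)
        km_rows = [dict(group="overall", level="", **r)
                   for r in fit.km_overall.table.to_dict(orient="records")]
        for cov, fits in fit.km_by.items():
            for lv, kf in fits.items():
                km_rows += [dict(group=cov, level=str(lv), **r)
                            for r in kf.table.to_dict(orient="records")]
        pd.DataFrame(km_rows).to_csv(out / "survival_km.csv", index=False)
        result = {
            "n_records": int(len(records)),
            "n_events": int(records["event"].sum()),
            "s31_overall": fit.km_overall.survival_at(31),
            "s31_se": fit.km_overall.se_at(31),
            "s31_by": {cov: {str(lv): kf.survival_at(31)
                             for lv, kf in fits.items()}
                       for cov, fits in fit.km_by.items()},
        }
        if fit.cox is not None:
            result["cox"] = {
                "coefficients": dict(zip(fit.cox.names,
                                         fit.cox.beta.tolist())),
                "hazard_ratios": dict(zip(fit.cox.names,
                                          fit.cox.hazard_ratios.tolist())),
                "wald": fit.wald.to_dict(orient="records"),
                "c_index": fit.c_index, "c_index_se": fit.c_index_se,
                "schoenfeld": (fit.schoenfeld.to_dict(orient="records")
                               if fit.schoenfeld is not None else None),
            }
        (out / "survival.json").write_text(json.dumps(result, indent=2))
        return [out / "survival_records.csv", out / "survival_km.csv",
                out / "survival.json"]

    if stage == "report":
        path = make_report(out)
        return [path]

    raise PipelineError(f"unknown stage {stage!r}")


def make_report(run_dir) -> Path:
    """Assemble a single human-readable report from a run directory.

    Regenerating the report from the same manifests is idempotent; missing
    stages are listed rather than failing.
    """
    out = Path(run_dir)
    lines = ["# postcapture run report", ""]
    missing = []

    surv = out / "survival.json"
    if surv.exists():
        s = json.loads(surv.read_text())
        lines += ["## Survival (31-day window)",
                  f"records: {s['n_records']}  events: {s['n_events']}",
                  f"overall S(31) = {s['s31_overall']:.2f} "
                  f"± {s['s31_se']:.2f} SE"]
        for cov, levels in s["s31_by"].items():
            parts = ", ".join(f"{lv}: {v:.2f}" for lv, v in levels.items())
            lines.append(f"  by {cov}: {parts}")
        if "cox" in s:
            lines.append(f"Cox C-index = {s['cox']['c_index']:.2f} "
                         f"± {s['cox']['c_index_se']:.2f} SE")
            for w in s["cox"]["wald"]:
                lines.append(f"  {w['term']}: chi2={w['chi2']:.2f} "
                             f"df={w['df']} p={w['p']:.3f}")
        lines.append("")
    else:
        missing.append("survival")

    found_ce = False
    for f in sorted(out.glob("capture_effect_*.json")):
        found_ce = True
        r = json.loads(f.read_text())
        lines += [f"## Capture effect: {r['metric']} "
                  f"({r['transform']} transform)"]
        for w in r["wald"]:
            lines.append(f"  {w['term']}: chi2={w['chi2']:.2f} "
                         f"df={w['df']} p={w['p']:.3f}")
        for grp, span in r["altered_day_spans"].items():
            lines.append(f"  altered span [{grp}]: {span['span']} days "
                         f"(artifact days: {span['artifact_days']})")
        lines.append("")
    if not found_ce:
        missing.append("capture_effect")

    if missing:
        if len(missing) == 2 and not surv.exists():
            lines.append("no stages complete" if not any(
                (out / n).exists() for n in ("metrics.csv",)) else "")
        lines.append(f"missing stages: {', '.join(missing)}")
    path = out / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
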