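"""End-to-end scenario runs with deterministic outputs.

Orchestrates simulate -> filter/aggregate -> thresholds -> posterior ->
statistics -> recovery curves from a single YAML configuration, writing tidy
delimited tables plus a JSON run manifest whose config digest changes iff
any configuration value changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import fit_posterior_model, make_log_bins
from .stats import fit_adaptation_curve, paired_pre_post_test, rank_sum_min_test
from .synthetic import SCENARIOS, generate_cohort, cohort_to_frame
from .thresholds import bootstrap_thresholds, per_bird_minimum, recovery_curve
from .types import BirdTimeline, ConfigurationError, EffectSpec, GeneratorConfig

__all__ = [
    "ConfigValidationError",
    "ReportError",
    "RunManifest",
    "default_config_path",
    "load_config",
    "run_pipeline",
    "report_summary",
]

logger = logging.getLogger("songwelfare")

STAGES = ("simulate", "thresholds", "posterior", "stats", "recovery")

#: Manipulation-event kind whose recovery curve each scenario contributes.
_RECOVERY_KINDS = {
    "white_noise": "wn_onset",
    "surgery": "surgery",
    "tethering": "tethering_onset",
}


class ConfigValidationError(ValueError):
    """Configuration violates the schema; lists the offending keys."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(self.problems))


class ReportError(RuntimeError):
    """A report was requested over missing output files."""


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Inventory of one pipeline run: config digest, seeds, outputs."""

    config_digest: str
    seed: int
    stage_seeds: Mapping[str, int]
    scenarios: tuple[str, ...]
    stages: tuple[str, ...]
    outputs: Mapping[str, str]  # filename -> sha256 of contents
    version: str = __version__

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["stage_seeds"] = dict(self.stage_seeds)
        payload["outputs"] = dict(self.outputs)
        payload["scenarios"] = list(self.scenarios)
        payload["stages"] = list(self.stages)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            config_digest=payload["config_digest"],
            seed=payload["seed"],
            stage_seeds=payload["stage_seeds"],
            scenarios=tuple(payload["scenarios"]),
            stages=tuple(payload["stages"]),
            outputs=payload["outputs"],
            version=payload.get("version", "unknown"),
        )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config_path() -> Path:
    return Path(str(resources.files("songwelfare").joinpath("data/defaults.yaml")))


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigValidationError` naming every offending key.
    """
    path = Path(path) if path is not None else default_config_path()
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigValidationError(["top level must be a mapping"])
    problems: list[str] = []

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        problems.append("seed: must be a non-negative integer")

    gen_kwargs = dict(raw.get("generator", {}))
    effects_raw = raw.get("effects", {})
    effect_specs: dict[str, EffectSpec] = {}
    for name, spec in dict(effects_raw).items():
        try:
            effect_specs[name] = EffectSpec(**spec)
        except (TypeError, ConfigurationError) as exc:
            problems.append(f"effects.{name}: {exc}")
    config = None
    try:
        config = GeneratorConfig(
            **gen_kwargs, effect_specs=effect_specs, seed=seed if isinstance(seed, int) else 0
        )
    except (TypeError, ConfigurationError) as exc:
        # name the offending generator key when the value violates a bound
        bad = [
            k for k, v in gen_kwargs.items()
            if isinstance(v, (int, float)) and v < 0
        ]
        label = f"generator.{bad[0]}" if bad else "generator"
        problems.append(f"{label}: {exc}")

    scenarios = raw.get("scenarios", {})
    for name, sc in dict(scenarios).items():
        if name not in SCENARIOS:
            problems.append(f"scenarios.{name}: unknown scenario")
            continue
        n = sc.get("n_birds") if isinstance(sc, dict) else None
        if not isinstance(n, int) or n < 1:
            problems.append(f"scenarios.{name}.n_birds: must be a positive integer")

    thr = dict(raw.get("thresholds", {}))
    for key, cond in [
        ("n_boot_birds", lambda v: isinstance(v, int) and v >= 1),
        ("days_per_bird", lambda v: isinstance(v, int) and v >= 1),
    ]:
        if key in thr and not cond(thr[key]):
            problems.append(f"thresholds.{key}: must be a positive integer")
    for x in thr.get("confidences", []):
        if not (isinstance(x, (int, float)) and 50 < x < 100):
            problems.append("thresholds.confidences: values must lie in (50, 100)")

    post = dict(raw.get("posterior", {}))
    if "i_min" in post and "i_max" in post and post["i_min"] >= post["i_max"]:
        problems.append("posterior.i_min: must be < posterior.i_max")

    if problems:
        raise ConfigValidationError(problems)

    return {
        "seed": seed,
        "generator": config,
        "scenarios": {k: dict(v) for k, v in scenarios.items()},
        "thresholds": {
            "confidences": [float(x) for x in thr.get("confidences", [95.0, 99.0, 99.5])],
            "n_boot_birds": thr.get("n_boot_birds", 100_000),
            "days_per_bird": thr.get("days_per_bird", 10),
        },
        "posterior": {
            "i_min": post.get("i_min", 0),
            "i_max": post.get("i_max", 4),
            "include_zero_bin": post.get("include_zero_bin", True),
        },
        "recovery": {
            "threshold_confidence": float(
                raw.get("recovery", {}).get("threshold_confidence", 99.0)
            ),
            "max_days": int(raw.get("recovery", {}).get("max_days", 8)),
        },
        "_raw": raw,
    }


def _config_digest(raw: Mapping[str, Any]) -> str:
    canonical = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") >> 1


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _write(path: Path, text: str, outputs: dict[str, str]) -> None:
    path.write_text(text, encoding="utf-8")
    outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _frame_text(frame: pd.DataFrame) -> str:
    return frame.to_csv(index=False, float_format="%.10g")


def run_pipeline(
    config_path: str | Path | None,
    out_dir: str | Path,
    *,
    stages: Sequence[str] | None = None,
    seed_override: int | None = None,
) -> RunManifest:
    """Run the configured scenarios end to end; deterministic given the config.

    Writes cohort tables, a threshold report, the posterior model, statistics
    tables, recovery curves, and ``manifest.json`` into ``out_dir``.  A rerun
    with the same configuration produces bit-identical outputs.
    """
    cfg = load_config(config_path)
    stages = tuple(stages or STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigValidationError([f"stages: unknown stage {s!r}" for s in unknown])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seed = seed_override if seed_override is not None else cfg["seed"]
    raw = dict(cfg["_raw"])
    raw["seed"] = seed
    digest = _config_digest(raw)
    gen: GeneratorConfig = cfg["generator"]
    stage_seeds = {s: _stage_seed(seed, s) for s in STAGES}
    outputs: dict[str, str] = {}

    # -- simulate ---------------------------------------------------------
    cohorts: dict[str, list[BirdTimeline]] = {}
    for name, sc in cfg["scenarios"].items():
        cohorts[name] = generate_cohort(
            name,
            sc["n_birds"],
            _stage_seed(stage_seeds["simulate"], name),
            config=gen,
        )
        logger.info("simulated %s: %d birds", name, sc["n_birds"])
    if "simulate" in stages:
        for name, cohort in cohorts.items():
            _write(
                out / f"cohort_{name}.csv",
                _frame_text(cohort_to_frame(cohort)),
                outputs,
            )

    # -- thresholds -------------------------------------------------------
    thresholds = None
    if {"thresholds", "recovery"} & set(stages) and "baseline" in cohorts:
        t = cfg["thresholds"]
        thresholds = bootstrap_thresholds(
            cohorts["baseline"],
            confidences=t["confidences"],
            n_boot_birds=t["n_boot_birds"],
            days_per_bird=t["days_per_bird"],
            seed=stage_seeds["thresholds"],
        )
        if "thresholds" in stages:
            _write(out / "thresholds.json", thresholds.to_json() + "\n", outputs)
            rows = pd.DataFrame(
                {
                    "confidence": sorted(thresholds.thresholds),
                    "W_x": [
                        thresholds.thresholds[x]
                        for x in sorted(thresholds.thresholds)
                    ],
                }
            )
            _write(out / "thresholds.csv", _frame_text(rows), outputs)
            logger.info("thresholds: %s", thresholds.thresholds)

    # -- posterior --------------------------------------------------------
    if "posterior" in stages and "baseline" in cohorts:
        p = cfg["posterior"]
        bins = make_log_bins(p["i_min"], p["i_max"], p["include_zero_bin"])
        manip = []
        for name in ("surgery", "tethering"):
            if name not in cohorts:
                continue
            kind = _RECOVERY_KINDS[name]
            for tl in cohorts[name]:
                e = tl.event_of_kind(kind)
                if e is None:
                    continue
                first_full = e.onset_day + (1 if name == "surgery" else 0)
                c = tl.count_on(first_full)
                if c is not None and not c.partial_day:
                    manip.append(c.motif_count)
        base = [
            c.motif_count
            for tl in cohorts["baseline"]
            for c in tl.full_day_counts()
        ]
        if manip:
            model = fit_posterior_model(manip, base, bins)
            _write(out / "posterior.json", model.to_json() + "\n", outputs)
            rows = pd.DataFrame(
                {
                    "bin_lo": model.bin_edges[:-1],
                    "bin_hi": model.bin_edges[1:],
                    "n_m1": model.counts_m1,
                    "n_m0": model.counts_m0,
                    "posterior_m1": model.posterior,
                }
            )
            _write(out / "posterior.csv", _frame_text(rows), outputs)

    # -- stats ------------------------------------------------------------
    if "stats" in stages:
        rows = []
        for name, kind in _RECOVERY_KINDS.items():
            if name not in cohorts:
                continue
            pre, post = [], []
            for tl in cohorts[name]:
                e = tl.event_of_kind(kind)
                if e is None:
                    continue
                pre_vals = [
                    c.motif_count
                    for c in tl.counts
                    if c.day_index < e.onset_day and not c.partial_day
                ]
                first_full = e.onset_day + (1 if kind in ("surgery",) else 0)
                c1 = tl.count_on(first_full)
                if pre_vals and c1 is not None:
                    pre.append(float(np.mean(pre_vals)))
                    post.append(float(c1.motif_count))
            if len(pre) >= 2:
                res = paired_pre_post_test(pre, post)
                rows.append(
                    {
                        "test": f"paired_t_{name}",
                        "n": len(pre),
                        "statistic": res.statistic,
                        "df": res.df,
                        "p_value": res.p_value,
                        "effect": res.mean_ratio,
                    }
                )
        if "white_noise" in cohorts and "baseline" in cohorts:
            wn_min = per_bird_minimum(
                [tl for tl in cohorts["white_noise"]], window=(0, 10**6)
            )
            base_min = per_bird_minimum(cohorts["baseline"])
            p = rank_sum_min_test(list(wn_min.values()), list(base_min.values()))
            rows.append(
                {
                    "test": "rank_sum_minima_wn_vs_baseline",
                    "n": len(wn_min) + len(base_min),
                    "statistic": float("nan"),
                    "df": -1,
                    "p_value": p,
                    "effect": float("nan"),
                }
            )
        if "isolation" in cohorts:
            plateaus = []
            for tl in cohorts["isolation"]:
                try:
                    plateaus.append(fit_adaptation_curve(tl).plateau)
                except Exception:  # non-convergence on a pathological bird
                    continue
            if plateaus:
                rows.append(
                    {
                        "test": "adaptation_plateau_mean",
                        "n": len(plateaus),
                        "statistic": float(np.mean(plateaus)),
                        "df": -1,
                        "p_value": float("nan"),
                        "effect": float(np.mean(plateaus)),
                    }
                )
        if rows:
            _write(out / "stats.csv", _frame_text(pd.DataFrame(rows)), outputs)

    # -- recovery ---------------------------------------------------------
    if "recovery" in stages and thresholds is not None:
        conf = cfg["recovery"]["threshold_confidence"]
        w = thresholds.thresholds[conf]
        rows = []
        for name, kind in _RECOVERY_KINDS.items():
            if name not in cohorts:
                continue
            curve = recovery_curve(
                cohorts[name], kind, w, cfg["recovery"]["max_days"]
            )
            for d, f, n in curve.points:
                rows.append(
                    {
                        "manipulation": name,
                        "day": d,
                        "fraction_below": f,
                        "n_birds": n,
                    }
                )
        if rows:
            _write(out / "recovery.csv", _frame_text(pd.DataFrame(rows)), outputs)

    manifest = RunManifest(
        config_digest=digest,
        seed=seed,
        stage_seeds=stage_seeds,
        scenarios=tuple(cfg["scenarios"]),
        stages=stages,
        outputs=outputs,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report_summary(manifest: RunManifest, out_dir: str | Path) -> str:
    """Human-readable report over a run's outputs.

    Emits the welfare-threshold table, per-scenario day-1 effect ratios, the
    posterior-by-bin table (undefined bins marked), and the first day each
    scenario's below-threshold fraction drops under 50 %.  Values are read
    back from the written tables, so the report cannot drift from them.
    """
    out = Path(out_dir)
    missing = [
        name for name in manifest.outputs if not (out / name).exists()
    ]
    if missing:
        raise ReportError(f"missing output files: {', '.join(sorted(missing))}")

    lines = [
        "songwelfare run report",
        f"  config digest: {manifest.config_digest[:16]}",
        f"  seed: {manifest.seed}",
        "",
    ]
    if "thresholds.csv" in manifest.outputs:
        thr = pd.read_csv(out / "thresholds.csv")
        lines.append("Welfare thresholds (motifs/day):")
        for _, row in thr.iterrows():
            lines.append(f"  W_{row['confidence']:g} = {row['W_x']:g}")
        lines.append("")
    if "stats.csv" in manifest.outputs:
        stats = pd.read_csv(out / "stats.csv")
        lines.append("Cohort statistics:")
        for _, row in stats.iterrows():
            lines.append(
                f"  {row['test']}: n={row['n']}, statistic={row['statistic']:.4g}, "
                f"p={row['p_value']:.4g}, effect={row['effect']:.4g}"
            )
        lines.append("")
    if "posterior.csv" in manifest.outputs:
        post = pd.read_csv(out / "posterior.csv")
        lines.append("Posterior P(recent manipulation | singing rate):")
        for _, row in post.iterrows():
            val = (
                "undefined"
                if pd.isna(row["posterior_m1"])
                else f"{row['posterior_m1']:.3f}"
            )
            lines.append(
                f"  [{row['bin_lo']:g}, {row['bin_hi']:g}): {val}  "
                f"(n1={int(row['n_m1'])}, n0={int(row['n_m0'])})"
            )
        lines.append("")
    if "recovery.csv" in manifest.outputs:
        rec = pd.read_csv(out / "recovery.csv")
        lines.append("Recovery (first day with < 50 % of birds below threshold):")
        for name, grp in rec.groupby("manipulation"):
            below = grp[grp["fraction_below"] < 0.5]
            day = int(below["day"].min()) if len(below) else None
            lines.append(
                f"  {name}: day {day}" if day is not None else f"  {name}: > max day"
            )
        lines.append("")
    return "\n".join(lines)
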