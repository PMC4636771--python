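"""Run orchestration and rendering of parameter / results tables.

`run_analysis` executes the Monte Carlo analysis for the configured
practice models, writes a results-table text summary per practice (rows:
annual programme cost, cost per woman screened, cost per HSIL case
detected, abnormal smears detected, HSIL smears detected, false negative
smears reported, no diagnosis / lost to care; columns: spatula, broom,
incremental value / % / 95 % CI), the raw per-trial CSV, a JSON summary
and a manifest from which the run can be re-executed exactly.

Currency is rendered to cents, counts as rounded integers and percent
changes as whole percents.
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

from . import __version__
from .parameters import (
    ParameterRegistry,
    default_registry,
    load_parameters,
    sample_trial_matrix,
)
from .psa import DEFAULT_N_TRIALS, PsaResult, run_psa
from .tree import DEFAULT_MAX_ROUNDS

__all__ = [
    "RunConfig",
    "run_analysis",
    "render_summary_table",
    "render_parameter_table",
]

log = logging.getLogger("cervicost")

#: (summary-table row label, per-trial column stem, kind) in print order
TABLE_ROWS = (
    ("Annual programme cost", "programme_cost", "currency"),
    ("Cost per woman screened", "cost_per_woman", "currency"),
    ("Cost per HSIL case detected", "cost_per_hsil", "currency"),
    ("Abnormal smears detected", "abnormal_detected", "count"),
    ("HSIL smears detected", "hsil_detected", "count"),
    ("False negative smears reported", "false_negatives", "count"),
    ("No diagnosis (lost to care)", "lost_to_care", "count"),
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    practice: str = "both"  # guidelines | typical | both
    devices: tuple[str, ...] = ("spatula", "broom")
    n_trials: int = DEFAULT_N_TRIALS
    seed: int = 0
    max_rounds: int | None = DEFAULT_MAX_ROUNDS
    interval_mode: str = "ci_of_mean"  # or "percentile"
    include_false_positives: bool = False
    output_dir: str = "cervicost-output"
    params_file: str | None = None  # None -> packaged default registry

    def __post_init__(self) -> None:
        if self.practice not in ("guidelines", "typical", "both"):
            raise ValueError(f"unknown practice {self.practice!r}")
        if not self.devices:
            raise ValueError("devices must be non-empty")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.interval_mode not in ("ci_of_mean", "percentile"):
            raise ValueError(f"unknown interval_mode {self.interval_mode!r}")

    @property
    def practices(self) -> tuple[str, ...]:
        return ("guidelines", "typical") if self.practice == "both" else (self.practice,)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_manifest(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        return cls(**payload["config"])


def _fmt(value: float, kind: str) -> str:
    if value != value:  # NaN
        return ""
    if kind == "currency":
        return f"$ {value:,.2f}"
    return f"{value:,.0f}"


def _row_cells(result: PsaResult, stem: str, kind: str, interval_mode: str) -> dict:
    cols = result.trials
    have_ci = result.n_trials >= 2
    cells = {}
    for dev in ("spatula", "broom"):
        x = cols[f"{dev}_{stem}"].dropna().to_numpy()
        cells[dev] = float(x.mean()) if x.size else float("nan")
    d = cols[f"d_{stem}"].dropna().to_numpy()
    cells["difference"] = float(d.mean()) if d.size else float("nan")
    base = cells["spatula"]
    cells["percent"] = cells["difference"] / base if base else float("nan")
    if have_ci and d.size >= 2:
        s = result.mean_ci(f"d_{stem}")
        cells["ci"] = s.interval(interval_mode)
    else:
        cells["ci"] = None
    return cells


def render_summary_table(result: PsaResult, interval_mode: str = "ci_of_mean") -> str:
    """Results-table text for one practice model."""
    title = {
        "guidelines": "Guidelines (intended practice)",
        "typical": "Typical practice",
    }[result.practice]
    header = (
        f"{title} — {result.n_trials} Monte Carlo trials, seed {result.seed}\n"
        f"{'Metric':<32}{'Spatula':>16}{'Broom':>16}"
        f"{'Diff':>14}{'%':>6}  {'95 % CI':>26}"
    )
    lines = [header, "-" * len(header.splitlines()[-1])]
    for label, stem, kind in TABLE_ROWS:
        c = _row_cells(result, stem, kind, interval_mode)
        if c["ci"] is None:
            ci_txt = ""
        else:
            lo, hi = c["ci"]
            ci_txt = f"({_fmt(lo, kind)}, {_fmt(hi, kind)})"
        pct = "" if c["percent"] != c["percent"] else f"{100 * c['percent']:+.0f}%"
        lines.append(
            f"{label:<32}{_fmt(c['spatula'], kind):>16}{_fmt(c['broom'], kind):>16}"
            f"{_fmt(c['difference'], kind):>14}{pct:>6}  {ci_txt:>26}"
        )
    return "\n".join(lines)


def summary_payload(result: PsaResult, interval_mode: str = "ci_of_mean") -> dict:
    """JSON-serializable summary mirroring the rendered table."""
    out = {"practice": result.practice, "n_trials": result.n_trials, "seed": result.seed,
           "excluded_ratio_trials": result.n_excluded_ratio, "rows": {}}
    for label, stem, kind in TABLE_ROWS:
        c = _row_cells(result, stem, kind, interval_mode)
        out["rows"][label] = {
            "spatula": c["spatula"],
            "broom": c["broom"],
            "difference": c["difference"],
            "percent_change": c["percent"],
            "ci_95": list(c["ci"]) if c["ci"] is not None else None,
        }
    return out


def render_parameter_table(registry: ParameterRegistry) -> str:
    """Human-readable dump of every parameter spec."""
    rows = [
        {
            "name": s.name,
            "distribution": s.distribution,
            "mean": s.mean,
            "low95": "" if s.low95 is None else s.low95,
            "high95": "" if s.high95 is None else s.high95,
            "units": s.units,
            "source": s.source,
        }
        for s in registry
    ]
    frame = pd.DataFrame(rows, columns=["name", "distribution", "mean", "low95", "high95", "units", "source"])
    return frame.to_string(index=False)


def _single_trial_result(registry, practice, seed, cfg) -> PsaResult:
    # degenerate 1-trial run: means only, no interval
    from .psa import run_psa as _run  # noqa: F401  (kept simple: sample 2, keep 1)
    values = sample_trial_matrix(registry, seed, 1)
    from .economics import CostSet, cost_cohort, incremental
    from .tree import device_from_parameters, evaluate_cohort

    costs = CostSet.from_parameters({k: float(v[0]) for k, v in values.items()})
    single = {k: float(v[0]) for k, v in values.items()}
    data = {}
    econ = {}
    for dev in ("spatula", "broom"):
        profile = device_from_parameters(single, dev)
        out = evaluate_cohort(
            single, profile, practice,
            max_rounds=cfg.max_rounds,
            include_false_positives=cfg.include_false_positives,
        )
        econ[dev] = cost_cohort(out, costs, profile)
        data[f"{dev}_programme_cost"] = [econ[dev].programme_cost]
        data[f"{dev}_cost_per_woman"] = [econ[dev].cost_per_woman]
        data[f"{dev}_cost_per_hsil"] = [econ[dev].cost_per_hsil_detected]
        data[f"{dev}_abnormal_detected"] = [out.detected_abnormal_total]
        data[f"{dev}_hsil_detected"] = [out.detected_hsil]
        data[f"{dev}_false_negatives"] = [out.false_negatives_reported]
        data[f"{dev}_lost_to_care"] = [out.lost_to_care]
        data[f"{dev}_expected_smears"] = [out.expected_smears_per_woman]
    inc = incremental(econ["spatula"], econ["broom"])
    for col, m in (
        ("d_programme_cost", "programme_cost"),
        ("d_cost_per_woman", "cost_per_woman"),
        ("d_cost_per_hsil", "cost_per_hsil_detected"),
        ("d_abnormal_detected", "abnormal_detected"),
        ("d_hsil_detected", "hsil_detected"),
        ("d_false_negatives", "false_negatives"),
        ("d_lost_to_care", "lost_to_care"),
    ):
        data[col] = [inc.difference[m]]
    trials = pd.DataFrame(data)
    trials.index.name = "trial"
    return PsaResult(practice=practice, n_trials=1, seed=seed, trials=trials,
                     n_excluded_ratio=0)


def run_analysis(config: RunConfig, registry: ParameterRegistry | None = None) -> dict:
    """Execute the configured analysis and write the report bundle.

    Returns ``{"results": {practice: PsaResult}, "manifest": dict,
    "output_dir": Path}``.  Fails fast on an unwritable output path or an
    invalid parameter file.
    """
    if registry is None:
        registry = (
            default_registry()
            if config.params_file is None
            else load_parameters(config.params_file)
        )
    out_dir = Path(config.output_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / ".write-test").write_text("")
        (out_dir / ".write-test").unlink()
    except OSError as exc:
        raise OSError(f"output path {out_dir} is not writable: {exc}") from exc

    registry_yaml = registry.to_yaml()
    manifest = {
        "package": "cervicost",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "registry_sha256": hashlib.sha256(registry_yaml.encode()).hexdigest(),
    }
    results: dict[str, PsaResult] = {}
    for practice in config.practices:
        log.info("running %s practice: %d trials (seed %d)",
                 practice, config.n_trials, config.seed)
        if config.n_trials == 1:
            log.warning("n_trials=1: confidence intervals cannot be computed")
            res = _single_trial_result(registry, practice, config.seed, config)
        else:
            res = run_psa(
                registry,
                practice,
                n_trials=config.n_trials,
                seed=config.seed,
                max_rounds=config.max_rounds,
                include_false_positives=config.include_false_positives,
            )
        results[practice] = res
        res.to_csv(out_dir / f"trials_{practice}.csv")
        (out_dir / f"summary_{practice}.txt").write_text(
            render_summary_table(res, config.interval_mode) + "\n"
        )
        (out_dir / f"summary_{practice}.json").write_text(
            json.dumps(summary_payload(res, config.interval_mode), indent=2) + "\n"
        )
        log.info("%s practice done (%d degenerate ratio trials excluded)",
                 practice, res.n_excluded_ratio)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out_dir / "parameters.yaml").write_text(registry_yaml)
    return {"results": results, "manifest": manifest, "output_dir": out_dir}
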