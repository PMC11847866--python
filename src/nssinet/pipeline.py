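"""End-to-end analysis pipeline with config, manifest and exports.

Runs, in order: descriptive statistics; the eight symptom-band x
high-suicide-risk 2x2 associations; the adjusted logistic Model 1/2/3
ladder for severe depression and severe anxiety; the Kendall tau matrix
over the four screened indicators; the 25-node correlation network with
thresholded centralities, layout and rankings; the bootstrap stability
summary; and the sensitivity-based sample-size curve.  All randomness is
driven by per-stage seeds derived from one master seed, so every output
is byte-reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (
    AssociationError,
    ModelSpec,
    SeparationError,
    crosstab,
    fit_logistic,
    format_p,
    kendall_matrix,
    odds_ratio_ci,
)
from .cohort import (
    VARIABLE_LEVELS,
    CohortTable,
    describe,
    indicator,
    one_hot_encode,
    read_cohort_csv,
    write_cohort_csv,
)
from .network import (
    LayoutParams,
    centralities,
    correlation_matrix,
    rank_nodes,
    spring_layout,
    write_graphml,
    write_json,
)
from .stability import bootstrap_centralities, build_true_model, recommend_sample_size
from .synthetic import SyntheticConfig, calibrate_copula, default_paper_config, generate_cohort

#: Per-stage seed offsets (master seed + 7919 * offset, mod 2^31).
STAGE_SEED_OFFSETS = {"simulate": 0, "layout": 1, "bootstrap": 2, "samplesize": 3}


def stage_seed(master_seed: int, stage: str) -> int:
    return (master_seed + 7919 * STAGE_SEED_OFFSETS[stage]) % (2**31)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Pipeline inputs; exactly one of ``input_csv`` / ``synthetic``."""

    output_dir: str = "nssinet_out"
    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    denominator: int | None = None  # rate denominator; default = cohort n
    theta: float = 0.2
    bootstrap_B: int = 1000
    seed: int = 0
    power_delta: float = 0.6
    power_tau: float = 0.8
    power_R: int = 100
    power_n_grid: tuple[int, ...] = tuple(range(100, 2001, 100))
    export_replicates: bool = False

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("set exactly one of input_csv / synthetic")


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    files: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    if echo.get("synthetic") is not None:
        syn = echo["synthetic"]
        syn.pop("latent_correlation", None)
    return echo


BAND_EXPOSURES = [
    ("depression_band", lev) for lev in VARIABLE_LEVELS["depression_band"]
] + [("anxiety_band", lev) for lev in VARIABLE_LEVELS["anxiety_band"]]

TAU_SCREEN_INDICATORS = {
    "severe_depression": ("depression_band", "severe"),
    "severe_anxiety": ("anxiety_band", "severe"),
    "low_self_concept": ("self_concept", "low"),
    "father_college": ("father_edu", "college_university"),
}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written).

    Any stage error aborts with the stage name after writing a partial
    manifest to the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.seed, s) for s in STAGE_SEED_OFFSETS}
    manifest = RunManifest(_config_echo(config), __version__, seeds)
    files: list[Path] = []

    def finish_stage(name: str, t0: float, n_rows: int | None = None) -> None:
        manifest.stages[name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            **({"rows": n_rows} if n_rows is not None else {}),
        }

    def abort(stage: str, exc: Exception) -> PipelineError:
        manifest.warnings.append(f"aborted at stage {stage}: {exc}")
        _finalize(manifest, files, out)
        return PipelineError(stage, str(exc))

    # ---- load / simulate
    t0 = time.perf_counter()
    try:
        if config.input_csv is not None:
            cohort = read_cohort_csv(config.input_csv)
        else:
            syn_cfg = dataclasses.replace(config.synthetic, seed=seeds["simulate"])
            if syn_cfg.latent_correlation is None:
                syn_cfg = calibrate_copula(syn_cfg)
            cohort, report = generate_cohort(syn_cfg)
            path = out / "cohort.csv"
            write_cohort_csv(cohort, path)
            files.append(path)
            path = out / "generator_report.json"
            report.to_json(path)
            files.append(path)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise abort("input", exc) from exc
    finish_stage("input", t0, cohort.n)

    # ---- descriptives
    t0 = time.perf_counter()
    try:
        summary = describe(cohort, config.denominator)
        path = out / "descriptives.csv"
        summary.table.to_csv(path, index=False)
        files.append(path)
        quart = pd.DataFrame(
            {"quartile": list(summary.age_quartiles), "age_years": list(summary.age_quartiles.values())}
        )
        path = out / "age_quartiles.csv"
        quart.to_csv(path, index=False)
        files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise abort("descriptives", exc) from exc
    finish_stage("descriptives", t0)

    # ---- 2x2 associations
    t0 = time.perf_counter()
    try:
        if cohort.df["suicide_high"].isna().all():
            raise AssociationError("suicide_high is missing for every row")
        rows = []
        for var, lev in BAND_EXPOSURES:
            table = crosstab(cohort, (var, lev), ("suicide_high", "high"))
            row = {"exposure": f"{var}={lev}", "a": table.a, "b": table.b,
                   "c": table.c, "d": table.d, "n": table.n}
            try:
                res = odds_ratio_ci(table)
                row.update(
                    chi_square=round(res.chi_square, 3),
                    odds_ratio=round(res.odds_ratio, 3),
                    ci_low=round(res.ci_low, 3),
                    ci_high=round(res.ci_high, 3),
                    p=format_p(res.p),
                )
            except AssociationError as exc:
                row.update(chi_square=None, odds_ratio=None, ci_low=None,
                           ci_high=None, p=None)
                manifest.warnings.append(f"association {var}={lev}: {exc}")
            rows.append(row)
        path = out / "associations_2x2.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise abort("associations", exc) from exc
    finish_stage("associations", t0)

    # ---- logistic models 1-3
    t0 = time.perf_counter()
    try:
        rows = []
        ladder = [
            (("depression_band", "severe"), ("anxiety_band", "severe")),
            (("anxiety_band", "severe"), ("depression_band", "severe")),
        ]
        for exposure, other in ladder:
            for model in (1, 2, 3):
                spec = ModelSpec(exposure, model, other if model == 3 else None)
                base = {"exposure": f"{exposure[0]}={exposure[1]}", "model": model}
                try:
                    fit = fit_logistic(cohort, spec)
                    ci = fit.conf_int()
                    base.update(
                        odds_ratio=round(float(fit.odds_ratios[1]), 2),
                        ci_low=round(float(ci[1, 0]), 2),
                        ci_high=round(float(ci[1, 1]), 2),
                        converged=fit.converged,
                        n_used=fit.n_used,
                    )
                except (AssociationError, SeparationError) as exc:
                    base.update(odds_ratio=None, ci_low=None, ci_high=None,
                                converged=False, n_used=None)
                    manifest.warnings.append(
                        f"logistic {base['exposure']} model {model}: {exc}"
                    )
                rows.append(base)
        path = out / "logistic_models.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise abort("logistic", exc) from exc
    finish_stage("logistic", t0)

    # ---- Kendall screening matrix
    t0 = time.perf_counter()
    try:
        cols = {
            name: indicator(cohort, var, cat).to_numpy()
            for name, (var, cat) in TAU_SCREEN_INDICATORS.items()
        }
        taus, ps = kendall_matrix(cols)
        stars = taus.round(3).astype(str)
        for i in taus.index:
            for j in taus.columns:
                if i != j:
                    p = ps.loc[i, j]
                    stars.loc[i, j] += "**" if p < 0.01 else ("*" if p < 0.05 else "")
        path = out / "kendall_matrix.csv"
        stars.to_csv(path)
        files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise abort("kendall", exc) from exc
    finish_stage("kendall", t0)

    # ---- network + centralities
    t0 = time.perf_counter()
    try:
        encoded = one_hot_encode(cohort)
        net = correlation_matrix(encoded).threshold(config.theta)
        cent = centralities(net)
        layout = spring_layout(net, LayoutParams(seed=seeds["layout"]))
        path = out / "centralities.csv"
        cent.table().to_csv(path, index=False)
        files.append(path)
        path = out / "network.graphml"
        write_graphml(net, path, layout.positions)
        files.append(path)
        path = out / "network.json"
        write_json(net, path, layout.positions)
        files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise abort("network", exc) from exc
    finish_stage("network", t0)

    # ---- bootstrap stability
    t0 = time.perf_counter()
    try:
        boot = bootstrap_centralities(
            cohort, B=config.bootstrap_B, theta=config.theta, seed=seeds["bootstrap"]
        )
        if boot.zero_variance_replicates:
            manifest.warnings.append(
                f"{boot.zero_variance_replicates}/{boot.B} bootstrap replicates "
                "had a zero-variance node (treated as r=0)"
            )
        path = out / "bootstrap_means.csv"
        boot.means_table().to_csv(path, index=False)
        files.append(path)
        if config.export_replicates:
            path = out / "bootstrap_replicates.csv"
            boot.long_table().to_csv(path, index=False)
            files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise abort("bootstrap", exc) from exc
    finish_stage("bootstrap", t0)

    # ---- sample-size curve
    t0 = time.perf_counter()
    try:
        true_model = build_true_model(
            net.n_nodes, max(net.density, 1.0 / net.n_nodes), seed=seeds["samplesize"]
        )
        result = recommend_sample_size(
            true_model,
            delta=config.power_delta,
            tau=config.power_tau,
            R=config.power_R,
            n_grid=config.power_n_grid,
            seed=seeds["samplesize"],
            theta=config.theta,
        )
        path = out / "sample_size.json"
        with open(path, "w") as fh:
            json.dump(
                {
                    "delta": result.delta,
                    "tau": result.tau,
                    "R": result.R,
                    "true_model_density": result.true_model.density,
                    "n_grid": list(result.n_grid),
                    "g": result.g.tolist(),
                    "g_smoothed": result.g_smoothed.tolist(),
                    "recommended_n": result.recommended_n,
                },
                fh,
                indent=1,
            )
        files.append(path)
    except Exception as exc:  # noqa: BLE001
        raise abort("samplesize", exc) from exc
    finish_stage("samplesize", t0)

    _finalize(manifest, files, out)
    return manifest


def _finalize(manifest: RunManifest, files: list[Path], out: Path) -> None:
    manifest.files = {f.name: _sha256(f) for f in files if f.exists()}
    manifest.to_json(out / "manifest.json")


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from YAML/JSON."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    syn = raw.pop("synthetic", None)
    if syn is not None:
        if syn is True or syn == {}:
            syn_cfg = default_paper_config()
        else:
            base = default_paper_config()
            syn_cfg = dataclasses.replace(base, **syn)
        raw["synthetic"] = syn_cfg
    if "power_n_grid" in raw:
        raw["power_n_grid"] = tuple(raw["power_n_grid"])
    return PipelineConfig(**raw)
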