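"""Study orchestration: total effect, double screen, mediation, reports.

One configuration file drives the whole analysis: bidirectional MR between
exposure and outcome (the total effect c and its reverse check), a screen of
every candidate trait against the exposure and against the outcome, Venn
intersection of the two screens, mediator qualification, and the a*b / c'
decomposition for each nominated trait. Every stochastic stage consumes a
seed derived by hashing the single global seed with the stage name, so
re-running an identical config reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._utils import config_hash, derive_seed, sha256_file
from .analysis import DirectionResult, EstimatorSettings, analyze_direction
from .estimators import write_estimates
from .exceptions import AnalysisError, ConfigError, DataError
from .instruments import LDTable, SelectionConfig, read_ld_table
from .mediation import MediationResult, decompose, qualify_mediator, write_mediation
from .plots import forest_plot, funnel_plot, leave_one_out_plot, scatter_plot
from .screening import (
    ScreenConfig,
    intersect_screens,
    screen_traits,
    write_screen_report,
    write_venn,
)
from .sumstats import SumStats, read_sumstats


@dataclass
class PipelineConfig:
    """Validated study configuration (paths checked at load time)."""

    exposure: Path
    outcome: Path
    outdir: Path
    ld: Path | None = None
    trait_manifest: Path | None = None
    seed: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    settings: EstimatorSettings = field(default_factory=EstimatorSettings)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    alpha: float = 0.05
    make_plots: bool = True

    def as_dict(self) -> dict:
        return {
            "exposure": str(self.exposure),
            "outcome": str(self.outcome),
            "outdir": str(self.outdir),
            "ld": str(self.ld) if self.ld else None,
            "trait_manifest": str(self.trait_manifest) if self.trait_manifest else None,
            "seed": self.seed,
            "selection": vars(self.selection),
            "settings": vars(self.settings),
            "screen": {
                "alpha": self.screen.alpha,
                "pleiotropy_alpha": self.screen.pleiotropy_alpha,
                "bh_correct": self.screen.bh_correct,
                "selection": vars(self.screen.selection),
                "settings": vars(self.screen.settings),
            },
            "alpha": self.alpha,
            "make_plots": self.make_plots,
        }


def load_config(path: str | Path, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML pipeline configuration; CLI overrides take precedence."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    return build_config(raw, base_dir=path.parent)


def build_config(raw: dict, base_dir: Path | None = None) -> PipelineConfig:
    base = base_dir or Path(".")

    def _resolve(key, required=True):
        value = raw.get(key)
        if value is None:
            if required:
                raise ConfigError(f"config missing required path {key!r}")
            return None
        p = Path(value)
        if not p.is_absolute():
            p = base / p
        return p

    exposure = _resolve("exposure")
    outcome = _resolve("outcome")
    outdir = _resolve("outdir")
    ld = _resolve("ld", required=False)
    manifest = _resolve("trait_manifest", required=False)
    for p in (exposure, outcome, ld, manifest):
        if p is not None and not p.exists():
            raise ConfigError(f"configured path does not exist: {p}")

    selection = SelectionConfig(**raw.get("selection", {}))
    settings = EstimatorSettings(**raw.get("settings", {}))
    screen_raw = dict(raw.get("screen", {}))
    screen_selection = SelectionConfig(**screen_raw.pop("selection", vars(selection)))
    screen_settings_raw = screen_raw.pop("settings", None)
    screen_kwargs = dict(screen_raw, selection=screen_selection)
    if screen_settings_raw is not None:
        screen_kwargs["settings"] = EstimatorSettings(**screen_settings_raw)
    screen = ScreenConfig(**screen_kwargs)
    try:
        return PipelineConfig(
            exposure=exposure,
            outcome=outcome,
            outdir=outdir,
            ld=ld,
            trait_manifest=manifest,
            seed=int(raw.get("seed", 0)),
            selection=selection,
            settings=settings,
            screen=screen,
            alpha=float(raw.get("alpha", 0.05)),
            make_plots=bool(raw.get("make_plots", True)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def read_trait_manifest(path: str | Path, base_dir: Path | None = None) -> dict[str, SumStats]:
    """Read the `trait_id path` TSV manifest and load every trait file."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    for col in ("trait_id", "path"):
        if col not in frame.columns:
            raise ConfigError(f"trait manifest {path}: missing column {col!r}")
    base = base_dir or path.parent
    traits: dict[str, SumStats] = {}
    for row in frame.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise DataError(f"trait file does not exist: {p}")
        traits[str(row.trait_id)] = read_sumstats(p, trait=str(row.trait_id)).stats
    return traits


def _load_inputs(config: PipelineConfig):
    exposure = read_sumstats(config.exposure, trait=config.exposure.stem).stats
    outcome = read_sumstats(config.outcome, trait=config.outcome.stem).stats
    ld = read_ld_table(config.ld) if config.ld else LDTable()
    return exposure, outcome, ld


def _failing_filter(direction: DirectionResult) -> str:
    """Name the selection step that eliminated every candidate SNP."""
    if "no_instruments_after_steiger" in direction.warnings:
        return "steiger"
    report = direction.selection_report
    if len(report) == 0:
        return "empty_input"
    # report the pipeline-latest disposition class actually present
    labels = {"p_fail": "p_threshold", "weak_F": "f_min"}
    for name in ("ambiguous", "absent_in_outcome", "weak_F", "palindromic", "p_fail"):
        if (report["disposition"] == name).any():
            return labels.get(name, name)
    return "selection"


def _write_direction(direction: DirectionResult, outdir: Path, tag: str) -> dict[str, Path]:
    paths: dict[str, Path] = {}
    est_path = outdir / f"estimates_{tag}.tsv"
    write_estimates(direction.estimates, est_path, direction.exposure, direction.outcome)
    paths["estimates"] = est_path
    instr_path = outdir / f"instruments_{tag}.tsv"
    direction.instruments.to_csv(instr_path, sep="\t", index=False, na_rep="NA")
    paths["instruments"] = instr_path
    sel_path = outdir / f"selection_{tag}.tsv"
    direction.selection_report.to_csv(sel_path, sep="\t", index=False)
    paths["selection"] = sel_path
    sens = direction.sensitivity
    if sens is not None:
        sens_path = outdir / f"sensitivity_{tag}.tsv"
        sens.summary_frame().to_csv(sens_path, sep="\t", index=False, na_rep="NA")
        paths["sensitivity"] = sens_path
        if sens.loo is not None:
            loo_path = outdir / f"leave_one_out_{tag}.tsv"
            sens.loo.to_csv(loo_path, sep="\t", index=False)
            paths["leave_one_out"] = loo_path
        if sens.funnel is not None:
            funnel_path = outdir / f"funnel_{tag}.tsv"
            sens.funnel.to_csv(funnel_path, sep="\t", index=False)
            paths["funnel"] = funnel_path
    if direction.steiger is not None:
        steiger_path = outdir / f"steiger_{tag}.tsv"
        direction.steiger.to_csv(steiger_path, sep="\t", index=False)
        paths["steiger"] = steiger_path
    return paths


def run_total_effect(config: PipelineConfig) -> dict[str, DirectionResult]:
    """Bidirectional exposure <-> outcome analysis with the full battery.

    Raises :class:`AnalysisError` naming the failing filter when no
    instrument survives selection in the forward direction.
    """
    exposure, outcome, ld = _load_inputs(config)
    config.outdir.mkdir(parents=True, exist_ok=True)
    forward = analyze_direction(
        exposure, outcome, ld=ld, selection=config.selection,
        settings=config.settings, seed=derive_seed(config.seed, "total:forward"),
    )
    if not forward.estimable:
        raise AnalysisError(
            f"no instruments survived selection ({_failing_filter(forward)}) "
            f"for {exposure.trait} -> {outcome.trait}"
        )
    reverse = analyze_direction(
        outcome, exposure, ld=ld, selection=config.selection,
        settings=config.settings, seed=derive_seed(config.seed, "total:reverse"),
    )
    _write_direction(forward, config.outdir, "forward")
    _write_direction(reverse, config.outdir, "reverse")
    return {"forward": forward, "reverse": reverse}


@dataclass
class RunManifest:
    """Record of one full-study run: config hash, outputs, timings, warnings."""

    config_hash: str
    version: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, seconds: float, outputs: dict[str, Path]) -> None:
        self.stages.append(
            {
                "name": name,
                "seconds": round(seconds, 3),
                "outputs": {str(k): sha256_file(v) for k, v in outputs.items()},
            }
        )

    def write(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "version": self.version,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def run_full_study(config: PipelineConfig) -> RunManifest:
    """Execute the complete study and write every report under ``outdir``."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config.as_dict()), version=__version__, seed=config.seed
    )
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        t0 = time.perf_counter()
        exposure, outcome, ld = _load_inputs(config)
        traits = (
            read_trait_manifest(config.trait_manifest)
            if config.trait_manifest
            else {}
        )
        if not traits:
            manifest.warnings.append("empty_trait_manifest")
        manifest.add_stage("load", time.perf_counter() - t0, {})

        # --- total effect (bidirectional) ---
        t0 = time.perf_counter()
        total = run_total_effect(config)
        outputs = {
            f"{tag}:{name}": p
            for tag in ("forward", "reverse")
            for name, p in _write_direction(total[tag], outdir, tag).items()
        }
        for tag in ("forward", "reverse"):
            manifest.warnings.extend(
                f"total:{tag}:{w}" for w in total[tag].warnings
            )
        manifest.add_stage("total_effect", time.perf_counter() - t0, outputs)
        c_estimate = total["forward"].primary

        # --- double screen ---
        t0 = time.perf_counter()
        screen_a = screen_traits(
            exposure, traits, ld=ld, config=config.screen,
            seed=derive_seed(config.seed, "screen:exposure"),
        )
        screen_b = {
            trait_id: _screen_against_outcome(stats, outcome, ld, config, trait_id)
            for trait_id, stats in traits.items()
        }
        screen_a_path = outdir / "screen_exposure.tsv"
        screen_b_path = outdir / "screen_outcome.tsv"
        write_screen_report(screen_a, screen_a_path)
        write_screen_report(screen_b, screen_b_path)
        manifest.add_stage(
            "screens",
            time.perf_counter() - t0,
            {"screen_exposure": screen_a_path, "screen_outcome": screen_b_path},
        )

        # --- intersection + mediation ---
        t0 = time.perf_counter()
        venn = intersect_screens(screen_a, screen_b)
        venn_path = outdir / "venn.txt"
        write_venn(venn, venn_path)
        mediation_results: list[MediationResult] = []
        for trait_id in venn:
            qual = qualify_mediator(
                screen_a[trait_id], screen_b[trait_id], c_estimate.beta,
                alpha=config.screen.alpha,
            )
            a_est = screen_a[trait_id].forward.primary
            b_est = screen_b[trait_id].forward.primary
            mediation_results.append(
                decompose(
                    c_estimate, a_est, b_est,
                    exposure=exposure.trait, mediator=trait_id,
                    outcome=outcome.trait, qualified=qual.qualified,
                )
            )
        mediation_path = outdir / "mediation.tsv"
        write_mediation(mediation_results, mediation_path)
        manifest.add_stage(
            "mediation",
            time.perf_counter() - t0,
            {"venn": venn_path, "mediation": mediation_path},
        )

        # --- plots (from the TSVs already written) ---
        if config.make_plots:
            t0 = time.perf_counter()
            plot_outputs = {
                "forest": forest_plot(
                    outdir / "estimates_forward.tsv", outdir / "forest_forward.png"
                ),
                "scatter": scatter_plot(
                    outdir / "instruments_forward.tsv",
                    outdir / "estimates_forward.tsv",
                    outdir / "scatter_forward.png",
                ),
            }
            if (outdir / "funnel_forward.tsv").exists():
                plot_outputs["funnel"] = funnel_plot(
                    outdir / "funnel_forward.tsv",
                    outdir / "funnel_forward.png",
                    beta_ivw=c_estimate.beta,
                )
            if (outdir / "leave_one_out_forward.tsv").exists():
                plot_outputs["leave_one_out"] = leave_one_out_plot(
                    outdir / "leave_one_out_forward.tsv",
                    outdir / "loo_forward.png",
                )
            manifest.add_stage("plots", time.perf_counter() - t0, plot_outputs)

        manifest.write(outdir / "manifest.json")
        return manifest
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        manifest.warnings.append(f"FAILED: {exc}")
        manifest.write(outdir / "manifest.json")
        raise


def _screen_against_outcome(trait_stats, outcome, ld, config: PipelineConfig, trait_id):
    from .screening import screen_pair

    return screen_pair(
        trait_stats, outcome, ld=ld, config=config.screen,
        seed=derive_seed(config.seed, "screen:outcome"), trait_id=trait_id,
    )
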