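"""End-to-end orchestration: bank -> stimuli -> plays -> simulation ->
difference metrics -> survival models, from a single serializable config.

Every stage draws from a seed derived deterministically from the master
seed, so a run is fully reproducible from (config, master_seed).  A
manifest records the config fingerprint, per-stage seeds, artifact paths,
library versions and wall-clock per stage.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ckio
from .errors import ValidationError
from .metrics import DifferenceVector, compute_differences, standardize_and_mdps
from .stimuli import (
    StimulusSet,
    assemble_play_exp1,
    assemble_play_exp2,
    build_exp1_stimuli,
    build_exp2_stimuli,
)
from .survival import (
    EXP1_CUTPOINTS,
    EXP2_CUTPOINTS,
    TrialOutcome,
    add_condition_period_design,
    add_metric_interaction_design,
    compare_aic,
    distance_quartile_strata,
    episodes_to_frame,
    fit_cox,
    hits_timeouts_table,
    km_estimate,
    odds_ratio,
    split_episodes,
)
from .synthetic import (
    CategorySpec,
    ObserverParams,
    default_category_specs,
    default_observer_exp1,
    default_observer_exp2,
    exp2_category_specs,
    generate_background_bank,
    recovery_observer_exp1,
    simulate_plays,
)

METRIC_COLUMNS = ("s_pattern", "s_color", "s_luminance", "mdps")


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    experiment: int
    category_specs: tuple[CategorySpec, ...]
    n_per_category: int
    image_size: int
    n_plays: int
    observer: ObserverParams
    cutpoints: tuple[float, ...]
    master_seed: int
    output_dir: str | None = None
    n_pairs: int | None = None  # two-background design only
    screen: tuple[int, int] = (1280, 800)
    standardization_scope: str = "run"
    driving_metric: str = "mdps"
    reference_condition: str | None = None
    write_images: bool = False
    keep_blend_images: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValidationError("experiment must be 1 or 2")
        if self.experiment == 1 and (self.n_pairs is None or self.n_pairs < 1):
            raise ValidationError("two-background runs need n_pairs >= 1")
        if self.n_plays < 1 or self.n_per_category < 1:
            raise ValidationError("counts must be >= 1")
        if self.driving_metric not in METRIC_COLUMNS:
            raise ValidationError(
                f"driving_metric must be one of {METRIC_COLUMNS}"
            )

    @property
    def reference(self) -> str:
        if self.reference_condition is not None:
            return self.reference_condition
        return "50" if self.experiment == 1 else "S"

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["category_specs"] = [s.to_json_dict() for s in self.category_specs]
        d["observer"] = self.observer.to_json_dict()
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["category_specs"] = tuple(
            CategorySpec.from_json_dict(s) for s in d["category_specs"]
        )
        d["observer"] = ObserverParams.from_json_dict(d["observer"])
        d["cutpoints"] = tuple(d["cutpoints"])
        d["screen"] = tuple(d["screen"])
        return cls(**d)

    def fingerprint(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_exp1_config(
    master_seed: int,
    n_pairs: int = 60,
    n_plays: int = 200,
    image_size: int = 192,
    output_dir: str | None = None,
    observer: ObserverParams | None = None,
) -> RunConfig:
    return RunConfig(
        experiment=1,
        category_specs=default_category_specs(),
        n_per_category=32,
        image_size=image_size,
        n_pairs=n_pairs,
        n_plays=n_plays,
        observer=observer or default_observer_exp1(),
        cutpoints=EXP1_CUTPOINTS,
        master_seed=master_seed,
        output_dir=output_dir,
    )


def default_exp2_config(
    master_seed: int,
    n_plays: int = 200,
    image_size: int = 192,
    output_dir: str | None = None,
    observer: ObserverParams | None = None,
) -> RunConfig:
    return RunConfig(
        experiment=2,
        category_specs=exp2_category_specs(),
        n_per_category=30,
        image_size=image_size,
        n_plays=n_plays,
        observer=observer or default_observer_exp2(),
        cutpoints=EXP2_CUTPOINTS,
        master_seed=master_seed,
        output_dir=output_dir,
    )


@dataclass
class RunManifest:
    """Reproducibility record of a completed run."""

    config_fingerprint: str
    seeds: dict
    artifacts: dict
    versions: dict
    wall_clock: dict
    counts: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return asdict(self)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _versions() -> dict:
    import lifelines
    import scipy
    import skimage

    from . import __version__

    return dict(
        camokit=__version__,
        numpy=np.__version__,
        scipy=scipy.__version__,
        pandas=pd.__version__,
        skimage=skimage.__version__,
        lifelines=lifelines.__version__,
    )


def pair_difference_vectors(
    stimuli: StimulusSet, bank_by_id: dict
) -> list[DifferenceVector]:
    """Raw difference vectors for every image pair of a two-background
    stimulus set, in pair order."""
    return [
        compute_differences(bank_by_id[a], bank_by_id[b], pair_id)
        for pair_id, a, b in stimuli.pairs
    ]


def attach_pair_metrics(
    play_specs, stimuli: StimulusSet, metrics_by_pair: dict, driving: str
) -> None:
    """Fill each trial's covariates with the standardized metrics of its
    target's source pair; ``driving`` selects the observer's bg_diff."""
    for spec in play_specs:
        for t in spec.trials:
            pair_id = stimuli.target_pair.get(t.target_id)
            if pair_id is None:
                raise ValidationError(
                    f"target {t.target_id} has no source pair"
                )
            v = metrics_by_pair[pair_id]
            t.covariates.update(
                s_color=v.s_color,
                s_pattern=v.s_pattern,
                s_luminance=v.s_luminance,
                mdps=v.mdps,
                bg_diff=getattr(v, driving) if driving != "mdps" else v.mdps,
            )


def build_play_specs(
    stimuli: StimulusSet,
    config: RunConfig,
    rng: np.random.Generator,
    metrics_by_pair: dict | None = None,
) -> list:
    assemble = assemble_play_exp1 if config.experiment == 1 else assemble_play_exp2
    specs = [
        assemble(stimuli, config.screen, rng, play_id=f"play{i:05d}")
        for i in range(config.n_plays)
    ]
    if config.experiment == 1 and metrics_by_pair is not None:
        attach_pair_metrics(specs, stimuli, metrics_by_pair, config.driving_metric)
    return specs


def fit_condition_models(
    outcomes: list[TrialOutcome],
    cutpoints,
    reference: str,
    strata: str | None = None,
    concordance: bool = True,
):
    """The standard model pair: full (time-phase x condition + trial
    number) versus reduced (trial number only), cluster-robust by play."""
    frame = episodes_to_frame(split_episodes(outcomes, cutpoints))
    frame, cond_cols = add_condition_period_design(frame, reference)
    full = fit_cox(
        frame,
        cond_cols + ["trial_index"],
        strata=strata,
        concordance=concordance,
    )
    reduced = fit_cox(
        frame, ["trial_index"], strata=strata, concordance=False
    )
    return full, reduced, frame, cond_cols


def run_metric_interaction_suite(
    outcomes: list[TrialOutcome],
    cutpoints,
    reference: str = "50",
    metrics: tuple[str, ...] = METRIC_COLUMNS,
) -> pd.DataFrame:
    """Fit condition-only and condition x metric models and rank by AIC.

    Returns one row per model with AIC and the difference to the best
    (lowest-AIC) model; the best model has delta_aic = 0.
    """
    frame = episodes_to_frame(split_episodes(outcomes, cutpoints))
    missing = [m for m in metrics if m not in frame.columns or frame[m].isna().any()]
    if missing:
        raise ValidationError(
            f"trials lack usable metric columns: {missing}"
        )
    frame, cond_cols = add_condition_period_design(frame, reference)
    base_cols = cond_cols + ["trial_index"]
    rows = []
    fit0 = fit_cox(frame, base_cols, concordance=False)
    rows.append(
        dict(
            model="condition_only",
            metric=None,
            aic=fit0.aic,
            log_partial_likelihood=fit0.log_partial_likelihood,
            n_params=len(base_cols) - len(fit0.pinned),
        )
    )
    for m in metrics:
        dfm, mcols = add_metric_interaction_design(frame, m, reference)
        fit = fit_cox(dfm, base_cols + mcols, concordance=False)
        rows.append(
            dict(
                model=f"condition_x_{m}",
                metric=m,
                aic=fit.aic,
                log_partial_likelihood=fit.log_partial_likelihood,
                n_params=len(base_cols + mcols) - len(fit.pinned),
            )
        )
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table = table.sort_values("aic", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def run_experiment(config: RunConfig) -> RunManifest:
    """Execute the full pipeline for one config; writes artifacts when
    ``config.output_dir`` is set and returns the run manifest."""
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    seeds = {
        s: stage_seed(config.master_seed, s)
        for s in ("bank", "stimuli", "plays", "simulate")
    }
    artifacts: dict = {}
    wall: dict = {}
    counts: dict = {}

    t0 = time.perf_counter()
    bank = generate_background_bank(
        config.category_specs,
        config.n_per_category,
        config.image_size,
        config.image_size,
        seeds["bank"],
    )
    wall["bank"] = time.perf_counter() - t0
    counts["bank_images"] = len(bank)
    bank_by_id = {img.image_id: img for img in bank}

    t0 = time.perf_counter()
    rng_stim = np.random.default_rng(seeds["stimuli"])
    if config.experiment == 1:
        stimuli = build_exp1_stimuli(
            bank, config.n_pairs, rng_stim,
            keep_blend_images=config.keep_blend_images,
        )
    else:
        stimuli = build_exp2_stimuli(
            bank, rng_stim, keep_blend_images=config.keep_blend_images
        )
    wall["stimuli"] = time.perf_counter() - t0
    counts["blends"] = len(stimuli.blends)
    counts["targets"] = len(stimuli.targets)

    t0 = time.perf_counter()
    metrics_by_pair: dict | None = None
    metric_vectors: list[DifferenceVector] = []
    if config.experiment == 1:
        metric_vectors = standardize_and_mdps(
            pair_difference_vectors(stimuli, bank_by_id)
        )
        metrics_by_pair = {v.pair_id: v for v in metric_vectors}
    wall["metrics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rng_plays = np.random.default_rng(seeds["plays"])
    specs = build_play_specs(stimuli, config, rng_plays, metrics_by_pair)
    wall["plays"] = time.perf_counter() - t0
    counts["plays"] = len(specs)

    t0 = time.perf_counter()
    rng_sim = np.random.default_rng(seeds["simulate"])
    outcomes = simulate_plays(specs, config.observer, rng_sim)
    wall["simulate"] = time.perf_counter() - t0
    counts["trials"] = len(outcomes)
    counts["detections"] = int(sum(o.event for o in outcomes))

    t0 = time.perf_counter()
    strata = None
    if config.experiment == 2:
        outcomes = distance_quartile_strata(outcomes)
        strata = "distance_stratum"
    full, reduced, frame, _ = fit_condition_models(
        outcomes, config.cutpoints, config.reference, strata=strata
    )
    delta_aic = compare_aic(full, reduced)
    conditions = sorted({o.condition for o in outcomes})
    km_curves = [km_estimate(outcomes, c) for c in conditions]
    or_results = {}
    for c in conditions:
        if c == config.reference:
            continue
        tab = hits_timeouts_table(outcomes, c, config.reference)
        or_results[f"{c}_vs_{config.reference}"] = odds_ratio(tab)
    suite = None
    if config.experiment == 1:
        suite = run_metric_interaction_suite(
            outcomes, config.cutpoints, config.reference
        )
    wall["survival"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if out_dir:
        ckio.bank_manifest(bank).to_csv(out_dir / "bank_manifest.csv", index=False)
        artifacts["bank_manifest"] = str(out_dir / "bank_manifest.csv")
        ckio.stimulus_manifest(stimuli).to_csv(
            out_dir / "stimulus_manifest.csv", index=False
        )
        artifacts["stimulus_manifest"] = str(out_dir / "stimulus_manifest.csv")
        ckio.play_specs_to_frame(specs).to_csv(
            out_dir / "play_specs.csv", index=False
        )
        artifacts["play_specs"] = str(out_dir / "play_specs.csv")
        trials = ckio.outcomes_to_frame(outcomes)
        trials.to_csv(out_dir / "trials.csv", index=False)
        artifacts["trials"] = str(out_dir / "trials.csv")
        if metric_vectors:
            pd.DataFrame([asdict(v) for v in metric_vectors]).to_csv(
                out_dir / "metrics.csv", index=False
            )
            artifacts["metrics"] = str(out_dir / "metrics.csv")
        ckio.save_json(ckio.coxfit_to_dict(full), out_dir / "fit_full.json")
        artifacts["fit_full"] = str(out_dir / "fit_full.json")
        ckio.save_json(ckio.coxfit_to_dict(reduced), out_dir / "fit_reduced.json")
        artifacts["fit_reduced"] = str(out_dir / "fit_reduced.json")
        ckio.save_json(
            dict(delta_aic=delta_aic, full_aic=full.aic, reduced_aic=reduced.aic),
            out_dir / "aic_comparison.json",
        )
        artifacts["aic_comparison"] = str(out_dir / "aic_comparison.json")
        ckio.km_curves_to_frame(km_curves).to_csv(
            out_dir / "km_curves.csv", index=False
        )
        artifacts["km_curves"] = str(out_dir / "km_curves.csv")
        ckio.save_json(
            {k: ckio.or_to_dict(v) for k, v in or_results.items()},
            out_dir / "odds_ratios.json",
        )
        artifacts["odds_ratios"] = str(out_dir / "odds_ratios.json")
        if suite is not None:
            suite.to_csv(out_dir / "metric_suite.csv", index=False)
            artifacts["metric_suite"] = str(out_dir / "metric_suite.csv")
        if config.write_images:
            img_dir = out_dir / "bank"
            img_dir.mkdir(exist_ok=True)
            for img in bank:
                ckio.write_png(img, img_dir / f"{img.image_id}.png")
            tgt_dir = out_dir / "targets"
            tgt_dir.mkdir(exist_ok=True)
            for t in stimuli.targets:
                ckio.write_target_png(t, tgt_dir / f"{t.target_id}.png")
            artifacts["bank_images"] = str(img_dir)
            artifacts["target_images"] = str(tgt_dir)
    wall["write"] = time.perf_counter() - t0

    manifest = RunManifest(
        config_fingerprint=config.fingerprint(),
        seeds=seeds,
        artifacts=artifacts,
        versions=_versions(),
        wall_clock=wall,
        counts=counts,
    )
    if out_dir:
        ckio.save_json(manifest.to_json_dict(), out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# simulation studies


def _truth_terms(observer: ObserverParams, cutpoints, reference: str, conditions) -> dict:
    from .survival import period_labels

    labels = period_labels(tuple(cutpoints))
    truth = {}
    for c in sorted(conditions):
        if c == reference:
            continue
        for p, lab in enumerate(labels):
            truth[f"cond[{c}]:{lab}"] = observer.cond_log_hr[p].get(
                c, 0.0
            ) - observer.cond_log_hr[p].get(reference, 0.0)
    truth["trial_index"] = observer.beta_trial
    return truth


def _crossover_ok(fit, cond_cols, labels) -> bool:
    """Do the fitted phase-wise condition effects show the
    generalist-early / specialist-late sign pattern (specialist detection
    hazard above the generalist reference before the first cut, below it
    after the last)?"""
    early = [c for c in cond_cols if c.endswith(labels[0])]
    late = [c for c in cond_cols if c.endswith(labels[-1])]
    return all(fit.coefficients[c] > 0 for c in early) and all(
        fit.coefficients[c] < 0 for c in late
    )


def run_recovery_study(
    config: RunConfig,
    n_replicates: int,
    output_dir: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate-and-refit study of the phase-wise condition model.

    One stimulus set is built from the config; each replicate assembles
    ``config.n_plays`` fresh plays, simulates outcomes under
    ``config.observer`` and refits the full model.  Reports per-term
    estimates, robust CIs, 95% CI coverage of the generating values, bias
    and RMSE, plus the fraction of replicates reproducing the crossover
    sign pattern.
    """
    from .survival import period_labels

    seeds = {s: stage_seed(config.master_seed, s) for s in ("bank", "stimuli")}
    bank = generate_background_bank(
        config.category_specs,
        config.n_per_category,
        config.image_size,
        config.image_size,
        seeds["bank"],
    )
    bank_by_id = {img.image_id: img for img in bank}
    rng_stim = np.random.default_rng(seeds["stimuli"])
    if config.experiment == 1:
        stimuli = build_exp1_stimuli(
            bank, config.n_pairs, rng_stim, keep_blend_images=False
        )
        metrics_by_pair = {
            v.pair_id: v
            for v in standardize_and_mdps(
                pair_difference_vectors(stimuli, bank_by_id)
            )
        }
    else:
        stimuli = build_exp2_stimuli(bank, rng_stim, keep_blend_images=False)
        metrics_by_pair = None

    conditions = sorted({t.condition for t in stimuli.targets})
    truth = _truth_terms(
        config.observer, config.cutpoints, config.reference, conditions
    )
    labels = period_labels(tuple(config.cutpoints))

    rows = []
    crossover_hits = 0
    for rep in range(n_replicates):
        rep_seed = stage_seed(config.master_seed, f"replicate:{rep}")
        rng = np.random.default_rng(rep_seed)
        specs = build_play_specs(stimuli, config, rng, metrics_by_pair)
        outcomes = simulate_plays(specs, config.observer, rng)
        full, _, _, cond_cols = fit_condition_models(
            outcomes, config.cutpoints, config.reference, concordance=False
        )
        if _crossover_ok(full, cond_cols, labels):
            crossover_hits += 1
        for term, true_val in truth.items():
            est = full.coefficients[term]
            se = full.robust_se[term]
            covered = (
                not math.isinf(se)
                and abs(est - true_val) <= 1.959963984540054 * se
            )
            rows.append(
                dict(
                    replicate=rep,
                    term=term,
                    truth=true_val,
                    estimate=est,
                    robust_se=se,
                    covered=bool(covered),
                )
            )
    report = pd.DataFrame(rows)
    per_term = (
        report.groupby("term")
        .apply(
            lambda g: pd.Series(
                dict(
                    coverage=g["covered"].mean(),
                    bias=(g["estimate"] - g["truth"]).mean(),
                    rmse=float(
                        np.sqrt(((g["estimate"] - g["truth"]) ** 2).mean())
                    ),
                )
            ),
            include_groups=False,
        )
        .reset_index()
    )
    summary = dict(
        n_replicates=n_replicates,
        n_plays=config.n_plays,
        per_term=per_term.to_dict(orient="records"),
        min_coverage=float(per_term["coverage"].min()),
        crossover_fraction=crossover_hits / n_replicates,
    )
    if output_dir:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "recovery_report.csv", index=False)
        ckio.save_json(summary, out / "recovery_summary.json")
    return report, summary


def metric_effect_observer_exp1(
    driving_early: float = 0.9, driving_late: float = -0.9
) -> ObserverParams:
    """Observer whose condition effect is driven purely through the
    background-difference covariate (for metric-identification studies)."""
    return ObserverParams(
        phase_cuts=EXP1_CUTPOINTS,
        base_log_hazard=(math.log(0.5), math.log(0.35), math.log(0.08)),
        beta_mdps=(
            {"25": driving_early, "75": driving_early},
            {},
            {"25": driving_late, "75": driving_late},
        ),
        beta_trial=math.log(1.015),
        beta_dist=0.0,
        frailty_sd=0.5,
    )


def run_metric_identification_study(
    config: RunConfig,
    n_replicates: int,
) -> tuple[pd.DataFrame, dict]:
    """How often does AIC rank the truly active difference metric's model
    best?  The observer's bg_diff covariate is ``config.driving_metric``;
    per replicate the interaction suite is refitted on fresh plays.
    """
    if config.experiment != 1:
        raise ValidationError("metric identification uses the two-background design")
    seeds = {s: stage_seed(config.master_seed, s) for s in ("bank", "stimuli")}
    bank = generate_background_bank(
        config.category_specs,
        config.n_per_category,
        config.image_size,
        config.image_size,
        seeds["bank"],
    )
    bank_by_id = {img.image_id: img for img in bank}
    rng_stim = np.random.default_rng(seeds["stimuli"])
    stimuli = build_exp1_stimuli(
        bank, config.n_pairs, rng_stim, keep_blend_images=False
    )
    metrics_by_pair = {
        v.pair_id: v
        for v in standardize_and_mdps(pair_difference_vectors(stimuli, bank_by_id))
    }
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(stage_seed(config.master_seed, f"suite:{rep}"))
        specs = build_play_specs(stimuli, config, rng, metrics_by_pair)
        outcomes = simulate_plays(specs, config.observer, rng)
        table = run_metric_interaction_suite(
            outcomes, config.cutpoints, config.reference
        )
        best = table.iloc[0]
        rows.append(
            dict(replicate=rep, best_model=best["model"], best_metric=best["metric"])
        )
    report = pd.DataFrame(rows)
    frac = (
        (report["best_metric"] == config.driving_metric).mean()
        if len(report)
        else math.nan
    )
    summary = dict(
        n_replicates=n_replicates,
        driving_metric=config.driving_metric,
        fraction_best=float(frac),
        best_counts=report["best_model"].value_counts().to_dict(),
    )
    return report, summary
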