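"""Synthetic substrate banks and a virtual detection-time observer.

The background generator is a stand-in for photographed substrate types
(leaves, bark, grass, ...): each category is a 1/f^beta phase-randomized
noise texture on the L* channel, with a category mean CIELAB color, a
per-image jitter of that mean, a target L* contrast and an optional
luminance-histogram skew.  The model is deliberately minimal — it spans
exactly the axes the background-difference metrics respond to (color,
luminance, spatial frequency), not photorealism.

The virtual observer detects targets with a piecewise-constant hazard:
phase-specific log baselines plus log-linear effects of target condition,
background difference, trial number and screen distance, with a play-level
log-normal frailty standing in for participant/device heterogeneity.
Detection times are drawn by inversion from the implied piecewise
exponential and censored at the 15-s slide timeout.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor

from .errors import DimensionError, ValidationError
from .images import RasterImage
from .stimuli import PlaySpec
from .survival import TrialOutcome

__all__ = [
    "CategorySpec",
    "ObserverParams",
    "PlayRecord",
    "generate_background",
    "generate_background_bank",
    "detection_hazard",
    "simulate_detection_time",
    "simulate_play",
    "simulate_plays",
    "default_category_specs",
    "exp2_category_specs",
    "default_observer_exp1",
    "default_observer_exp2",
    "recovery_observer_exp1",
]


@dataclass
class CategorySpec:
    """Generative parameters of one substrate category.

    Parameters
    ----------
    name
        Category label.
    mean_lab
        Category-mean CIELAB color (L* in [0, 100], a*, b* in [-128, 127]).
    lab_jitter
        Per-image standard deviation of the category mean, per channel.
    spectral_slope
        Exponent beta of the 1/f^beta amplitude falloff of the L* texture.
    contrast
        Target standard deviation of the L* channel; 0 yields a constant
        image.
    luminance_skew
        Shape parameter of the monotone transform that skews the luminance
        histogram (0 = symmetric).
    """

    name: str
    mean_lab: tuple[float, float, float]
    lab_jitter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spectral_slope: float = 1.5
    contrast: float = 10.0
    luminance_skew: float = 0.0

    def __post_init__(self) -> None:
        L, a, b = self.mean_lab
        if not (0.0 <= L <= 100.0 and -128.0 <= a <= 127.0 and -128.0 <= b <= 127.0):
            raise ValidationError(f"mean_lab {self.mean_lab} outside gamut bounds")
        if any(j < 0 for j in self.lab_jitter):
            raise ValidationError("lab_jitter must be nonnegative")
        if self.contrast < 0:
            raise ValidationError("contrast must be nonnegative")

    def to_json_dict(self) -> dict:
        return dict(
            name=self.name,
            mean_lab=list(self.mean_lab),
            lab_jitter=list(self.lab_jitter),
            spectral_slope=self.spectral_slope,
            contrast=self.contrast,
            luminance_skew=self.luminance_skew,
        )

    @classmethod
    def from_json_dict(cls, d: dict) -> "CategorySpec":
        return cls(
            name=d["name"],
            mean_lab=tuple(d["mean_lab"]),
            lab_jitter=tuple(d.get("lab_jitter", (0.0, 0.0, 0.0))),
            spectral_slope=float(d.get("spectral_slope", 1.5)),
            contrast=float(d.get("contrast", 10.0)),
            luminance_skew=float(d.get("luminance_skew", 0.0)),
        )


def default_category_specs() -> tuple[CategorySpec, ...]:
    """Eight categories emulating the range of natural and man-made
    substrates used in the two-background design."""
    return (
        CategorySpec("bark", (35.0, 8.0, 18.0), (3.0, 2.0, 2.0), 1.6, 10.0, 0.2),
        CategorySpec("brick", (48.0, 28.0, 20.0), (3.0, 2.0, 2.0), 1.7, 9.0, 0.3),
        CategorySpec("grass", (55.0, -30.0, 35.0), (3.0, 2.0, 2.0), 1.2, 11.0, 0.0),
        CategorySpec("leaves", (45.0, -25.0, 25.0), (3.0, 2.0, 2.0), 1.4, 12.0, -0.3),
        CategorySpec("pebbles", (60.0, 2.0, 8.0), (3.0, 2.0, 2.0), 1.5, 14.0, 0.1),
        CategorySpec("sand", (75.0, 5.0, 22.0), (3.0, 2.0, 2.0), 1.8, 6.0, 0.4),
        CategorySpec("shrubs", (40.0, -18.0, 20.0), (3.0, 2.0, 2.0), 1.3, 13.0, -0.2),
        CategorySpec("stone", (65.0, 1.0, 5.0), (3.0, 2.0, 2.0), 1.9, 8.0, 0.0),
    )


def exp2_category_specs() -> tuple[CategorySpec, ...]:
    """The four naturalistic categories of the four-background design."""
    keep = {"leaves", "bark", "grass", "shrubs"}
    return tuple(s for s in default_category_specs() if s.name in keep)


def _radial_frequency(height: int, width: int) -> np.ndarray:
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    return np.hypot(fy, fx)


def generate_background(
    spec: CategorySpec, width: int, height: int, seed: int
) -> RasterImage:
    """Generate one synthetic background image; pure function of
    (spec, dimensions, seed)."""
    if width < 2 or height < 2:
        raise DimensionError(f"dimensions must be >= 2, got {width}x{height}")
    if not isinstance(spec, CategorySpec):
        raise ValidationError("spec must be a CategorySpec")
    rng = np.random.default_rng(seed)
    mean = np.asarray(spec.mean_lab, float) + np.asarray(
        spec.lab_jitter, float
    ) * rng.standard_normal(3)
    mean[0] = float(np.clip(mean[0], 0.0, 100.0))

    if spec.contrast == 0.0:
        L = np.full((height, width), mean[0])
    else:
        noise = rng.standard_normal((height, width))
        F = np.fft.fft2(noise)
        f = _radial_frequency(height, width)
        shaping = np.zeros_like(f)
        nz = f > 0
        shaping[nz] = f[nz] ** (-spec.spectral_slope)
        field_ = np.real(np.fft.ifft2(F * shaping))
        field_ -= field_.mean()
        field_ /= field_.std()
        if spec.luminance_skew != 0.0:
            s = spec.luminance_skew
            field_ = np.expm1(s * field_) / s
            field_ -= field_.mean()
            field_ /= field_.std()
        L = mean[0] + spec.contrast * field_

    lab = np.empty((height, width, 3))
    lab[..., 0] = np.clip(L, 0.0, 100.0)
    lab[..., 1] = mean[1]
    lab[..., 2] = mean[2]
    with warnings.catch_warnings():
        # out-of-gamut Lab values are clipped by design
        warnings.filterwarnings("ignore", message="Conversion from CIE-LAB")
        rgb = np.clip(skcolor.lab2rgb(lab), 0.0, 1.0)
    return RasterImage(
        rgb, image_id=f"{spec.name}_{seed}", category=spec.name, seed=seed
    )


def derive_image_seed(master_seed: int, category_index: int, replicate: int) -> int:
    """Counter-based per-image seed so banks reproduce piecemeal."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(category_index, replicate))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_background_bank(
    specs,
    n_per_category: int,
    width: int,
    height: int,
    seed: int,
) -> list[RasterImage]:
    """Generate ``len(specs) * n_per_category`` categorized images with
    unique ids and per-image seeds derived from the master seed."""
    specs = list(specs)
    if not specs:
        raise ValidationError("at least one category spec is required")
    if n_per_category < 1:
        raise ValidationError("n_per_category must be >= 1")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("category names must be unique")
    bank = []
    for ci, spec in enumerate(specs):
        for r in range(n_per_category):
            img_seed = derive_image_seed(seed, ci, r)
            img = generate_background(spec, width, height, img_seed)
            img.image_id = f"{spec.name}_{r:03d}"
            bank.append(img)
    return bank


# ---------------------------------------------------------------------------
# virtual observer


def _zeros_per_phase(n: int):
    return tuple({} for _ in range(n))


@dataclass
class ObserverParams:
    """Piecewise log-linear detection-hazard parameters.

    The hazard of detecting the target at time ``t`` in phase ``p(t)``
    (phases delimited by ``phase_cuts``; right-continuous, so a time equal
    to a cut belongs to the later phase) is::

        exp( base_log_hazard[p]
             + cond_log_hr[p][condition]
             + beta_mdps[p][condition] * bg_diff
             + beta_trial * trial_index
             + beta_dist * distance_norm )   [events/s]

    multiplied by the play's frailty.  ``beta_mdps`` maps each condition to
    its slope per unit standardized background difference, encoding the
    condition-contrast-signed interaction; conditions absent from a mapping
    contribute 0.
    """

    phase_cuts: tuple[float, ...]
    base_log_hazard: tuple[float, ...]
    cond_log_hr: tuple[dict, ...] = None
    beta_mdps: tuple[dict, ...] = None
    beta_trial: float = 0.0
    beta_dist: float = 0.0
    censor_time: float = 15.0
    frailty_sd: float = 0.5

    def __post_init__(self) -> None:
        self.phase_cuts = tuple(float(c) for c in self.phase_cuts)
        if any(b <= a for a, b in zip(self.phase_cuts, self.phase_cuts[1:])):
            raise ValidationError("phase_cuts must be strictly increasing")
        if self.censor_time <= 0:
            raise ValidationError("censor_time must be positive")
        if self.phase_cuts and (
            self.phase_cuts[0] <= 0 or self.phase_cuts[-1] >= self.censor_time
        ):
            raise ValidationError("phase_cuts must lie in (0, censor_time)")
        n = self.n_phases
        self.base_log_hazard = tuple(float(b) for b in self.base_log_hazard)
        if len(self.base_log_hazard) != n:
            raise ValidationError(
                f"base_log_hazard needs {n} entries (one per phase)"
            )
        if self.cond_log_hr is None:
            self.cond_log_hr = _zeros_per_phase(n)
        if self.beta_mdps is None:
            self.beta_mdps = _zeros_per_phase(n)
        self.cond_log_hr = tuple(dict(d) for d in self.cond_log_hr)
        self.beta_mdps = tuple(dict(d) for d in self.beta_mdps)
        if len(self.cond_log_hr) != n or len(self.beta_mdps) != n:
            raise ValidationError("per-phase mappings need one entry per phase")
        for mapping in (*self.cond_log_hr, *self.beta_mdps):
            for v in mapping.values():
                if not math.isfinite(float(v)):
                    raise ValidationError("log hazard-ratio terms must be finite")
        if self.frailty_sd < 0:
            raise ValidationError("frailty_sd must be nonnegative")

    @property
    def n_phases(self) -> int:
        return len(self.phase_cuts) + 1

    def phase_of(self, t: float) -> int:
        return bisect_right(self.phase_cuts, t)

    def to_json_dict(self) -> dict:
        return dict(
            phase_cuts=list(self.phase_cuts),
            base_log_hazard=list(self.base_log_hazard),
            cond_log_hr=[dict(d) for d in self.cond_log_hr],
            beta_mdps=[dict(d) for d in self.beta_mdps],
            beta_trial=self.beta_trial,
            beta_dist=self.beta_dist,
            censor_time=self.censor_time,
            frailty_sd=self.frailty_sd,
        )

    @classmethod
    def from_json_dict(cls, d: dict) -> "ObserverParams":
        return cls(
            phase_cuts=tuple(d["phase_cuts"]),
            base_log_hazard=tuple(d["base_log_hazard"]),
            cond_log_hr=tuple(d.get("cond_log_hr") or ()) or None,
            beta_mdps=tuple(d.get("beta_mdps") or ()) or None,
            beta_trial=float(d.get("beta_trial", 0.0)),
            beta_dist=float(d.get("beta_dist", 0.0)),
            censor_time=float(d.get("censor_time", 15.0)),
            frailty_sd=float(d.get("frailty_sd", 0.5)),
        )


def default_observer_exp1() -> ObserverParams:
    """Observer calibrated to the marginal two-background results:
    generalists (condition 50) enjoy ~7% higher survival in the first
    1.5 s, then specialists ~20% higher survival after 2.5 s, and
    detection speeds up by ~1.5% per trial.  The condition effects here
    are marginal (averaged over background difference); a background-
    difference-driven observer lives in
    ``camokit.pipeline.metric_effect_observer_exp1`` and the two are not
    combined, which would double-count the condition contrast."""
    g7 = math.log(1.07)
    s20 = math.log(0.80)
    return ObserverParams(
        phase_cuts=(1.5, 2.5),
        base_log_hazard=(math.log(0.5), math.log(0.35), math.log(0.08)),
        cond_log_hr=({"25": g7, "75": g7}, {}, {"25": s20, "75": s20}),
        beta_trial=math.log(1.015),
        beta_dist=-0.7,
        censor_time=15.0,
        frailty_sd=0.5,
    )


def default_observer_exp2() -> ObserverParams:
    """Observer calibrated to the four-background results: specialists (S)
    are easier to find than G2/G4 generalists for roughly the first two
    thirds of a trial, then harder in the final phase."""
    s = 0.15
    return ObserverParams(
        phase_cuts=(0.6, 1.2, 1.4, 2.0, 10.5),
        base_log_hazard=tuple(
            math.log(h) for h in (0.45, 0.40, 0.40, 0.35, 0.09, 0.05)
        ),
        cond_log_hr=(
            {"S": s},
            {"S": s},
            {"S": s},
            {"S": s},
            {"S": s},
            {"S": -0.30},
        ),
        beta_trial=math.log(1.006),
        beta_dist=-0.7,
        censor_time=15.0,
        frailty_sd=0.5,
    )


def recovery_observer_exp1() -> ObserverParams:
    """Generating conditions for the parameter-recovery study: a
    generalist-early / specialist-late crossover in the condition effect
    plus the trial-number drift, with no frailty, distance or
    background-difference effect so the fitted model family matches the
    generative one term for term."""
    return ObserverParams(
        phase_cuts=(1.5, 2.5),
        base_log_hazard=(math.log(0.5), math.log(0.35), math.log(0.08)),
        cond_log_hr=(
            {"25": math.log(1.07), "75": math.log(1.07)},
            {},
            {"25": math.log(0.80), "75": math.log(0.80)},
        ),
        beta_trial=math.log(1.015),
        beta_dist=0.0,
        censor_time=15.0,
        frailty_sd=0.0,
    )


def _required_covariates(params: ObserverParams) -> set[str]:
    need = set()
    if any(v != 0 for d in params.cond_log_hr for v in d.values()):
        need.add("condition")
    if any(v != 0 for d in params.beta_mdps for v in d.values()):
        need.update(("condition", "bg_diff"))
    if params.beta_trial != 0.0:
        need.add("trial_index")
    if params.beta_dist != 0.0:
        need.add("distance_norm")
    return need


def _log_hazard_phase(
    phase: int, covariates: dict, params: ObserverParams
) -> float:
    cond = covariates.get("condition")
    lh = params.base_log_hazard[phase]
    lh += params.cond_log_hr[phase].get(cond, 0.0)
    lh += params.beta_mdps[phase].get(cond, 0.0) * float(
        covariates.get("bg_diff", 0.0)
    )
    lh += params.beta_trial * float(covariates.get("trial_index", 0.0))
    lh += params.beta_dist * float(covariates.get("distance_norm", 0.0))
    return lh


def detection_hazard(
    t: float, covariates: dict, params: ObserverParams
) -> float:
    """Instantaneous detection hazard (events/s) at time ``t``.

    Piecewise constant between phase cuts; right-continuous at the cuts."""
    if not (0.0 <= t < params.censor_time):
        raise ValidationError(
            f"t must lie in [0, {params.censor_time}), got {t}"
        )
    missing = _required_covariates(params) - set(covariates)
    if missing:
        raise ValidationError(f"covariates missing terms: {sorted(missing)}")
    return math.exp(_log_hazard_phase(params.phase_of(t), covariates, params))


def _phase_bounds(params: ObserverParams) -> np.ndarray:
    return np.array([0.0, *params.phase_cuts, params.censor_time])


def sample_piecewise_exponential(
    log_hazards: np.ndarray,
    params: ObserverParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Inversion sampling from the piecewise-exponential detection-time
    distribution for an (n, n_phases) array of log hazards.

    Returns (times, events); censored rows get (censor_time, 0)."""
    bounds = _phase_bounds(params)
    dur = np.diff(bounds)
    h = np.exp(log_hazards)
    cum = np.cumsum(h * dur[None, :], axis=1)
    n = h.shape[0]
    target = rng.exponential(size=n)
    total = cum[:, -1]
    detected = target < total
    phase = (target[:, None] >= cum).sum(axis=1)
    phase_c = np.minimum(phase, len(dur) - 1)
    prev = np.where(phase_c > 0, np.take_along_axis(
        cum, np.maximum(phase_c - 1, 0)[:, None], axis=1
    )[:, 0], 0.0)
    prev = np.where(phase_c > 0, prev, 0.0)
    h_at = np.take_along_axis(h, phase_c[:, None], axis=1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = bounds[phase_c] + (target - prev) / h_at
    times = np.where(detected, t, params.censor_time)
    return times, detected.astype(int)


def simulate_detection_time(
    covariates: dict, params: ObserverParams, rng: np.random.Generator
) -> tuple[float, int]:
    """Draw one (time, event) pair; event 0 means the 15-s timeout."""
    missing = _required_covariates(params) - set(covariates)
    if missing:
        raise ValidationError(f"covariates missing terms: {sorted(missing)}")
    logh = np.array(
        [
            [
                _log_hazard_phase(p, covariates, params)
                for p in range(params.n_phases)
            ]
        ]
    )
    t, ev = sample_piecewise_exponential(logh, params, rng)
    return float(t[0]), int(ev[0])


@dataclass
class PlayRecord:
    """All trial outcomes of one simulated play."""

    play_id: str
    outcomes: list[TrialOutcome]
    frailty: float


def _play_log_hazards(
    spec: PlaySpec, params: ObserverParams
) -> np.ndarray:
    n = len(spec.trials)
    logh = np.empty((n, params.n_phases))
    for i, trial in enumerate(spec.trials):
        cov = dict(trial.covariates)
        cov.setdefault("condition", trial.condition)
        cov.setdefault("trial_index", trial.trial_index)
        for p in range(params.n_phases):
            logh[i, p] = _log_hazard_phase(p, cov, params)
    return logh


def simulate_play(
    play_spec: PlaySpec, params: ObserverParams, rng: np.random.Generator
) -> PlayRecord:
    """Simulate every trial of a play under a shared log-normal frailty."""
    frailty = (
        math.exp(params.frailty_sd * rng.standard_normal())
        if params.frailty_sd > 0
        else 1.0
    )
    logh = _play_log_hazards(play_spec, params) + math.log(frailty)
    times, events = sample_piecewise_exponential(logh, params, rng)
    outcomes = []
    for trial, t, ev in zip(play_spec.trials, times, events):
        cov = trial.covariates
        extras = {
            k: v
            for k, v in cov.items()
            if k not in ("distance_norm", "bg_diff")
        }
        outcomes.append(
            TrialOutcome(
                play_id=play_spec.play_id,
                trial_index=trial.trial_index,
                condition=trial.condition,
                time=float(t),
                event=int(ev),
                distance=float(trial.radius),
                mdps=cov.get("mdps", cov.get("bg_diff")),
                experiment=play_spec.experiment,
                background_id=trial.background_id,
                target_id=trial.target_id,
                extras=extras,
            )
        )
    return PlayRecord(play_id=play_spec.play_id, outcomes=outcomes, frailty=frailty)


def simulate_plays(
    play_specs: list[PlaySpec],
    params: ObserverParams,
    rng: np.random.Generator,
) -> list[TrialOutcome]:
    """Simulate a batch of plays; flat list of outcomes in play order."""
    out: list[TrialOutcome] = []
    for spec in play_specs:
        out.extend(simulate_play(spec, params, rng).outcomes)
    return out
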