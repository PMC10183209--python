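"""File formats: manifests, trial tables, PNG export, JSON configs.

All tabular artifacts are plain CSV; images are 8-bit PNG (targets as RGBA
with the triangle mask in the alpha channel); parameter documents are JSON.
The trial-table dialect is shared by the simulator and the survival stage:

    play_id, experiment, trial_index, condition, background_id, target_id,
    time_s, event, distance_px, mdps [, s_color, s_pattern, s_luminance]
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .images import RasterImage
from .stimuli import PlaySpec, StimulusSet, TriangleTarget
from .survival import CoxFit, KMCurve, ORResult, TrialOutcome

TRIAL_COLUMNS = [
    "play_id",
    "experiment",
    "trial_index",
    "condition",
    "background_id",
    "target_id",
    "time_s",
    "event",
    "distance_px",
    "mdps",
]


def write_png(img: RasterImage, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.clip(img.pixels, 0, 1) * 255).round().astype(np.uint8))


def write_target_png(target: TriangleTarget, path: str | Path) -> None:
    """Write a target as RGBA, mask in the alpha channel."""
    rgba = np.zeros((*target.mask.shape, 4), dtype=np.uint8)
    rgba[..., :3] = (np.clip(target.patch, 0, 1) * 255).round().astype(np.uint8)
    rgba[..., 3] = np.where(target.mask, 255, 0)
    iio.imwrite(Path(path), rgba)


def bank_manifest(bank: list[RasterImage]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                image_id=img.image_id,
                category=img.category,
                seed=img.seed,
                width=img.width,
                height=img.height,
            )
            for img in bank
        ]
    )


def stimulus_manifest(stimuli: StimulusSet) -> pd.DataFrame:
    target_by_blend = {t.source_blend: t for t in stimuli.targets}
    rows = []
    for b in stimuli.blends:
        t = target_by_blend.get(b.blend_id)
        rows.append(
            dict(
                blend_id=b.blend_id,
                source_ids="|".join(b.source_ids),
                weights="|".join(f"{w:g}" for w in b.weights),
                clip_fraction=b.clip_fraction,
                target_id=t.target_id if t else "",
                anchor_row=t.anchor[0] if t else "",
                anchor_col=t.anchor[1] if t else "",
                condition=t.condition if t else "",
            )
        )
    # targets cut from a shared source (specialists) get their own rows
    seen = {r["target_id"] for r in rows}
    for t in stimuli.targets:
        if t.target_id in seen:
            continue
        rows.append(
            dict(
                blend_id=t.source_blend,
                source_ids="",
                weights="",
                clip_fraction="",
                target_id=t.target_id,
                anchor_row=t.anchor[0],
                anchor_col=t.anchor[1],
                condition=t.condition,
            )
        )
    return pd.DataFrame(rows)


def play_specs_to_frame(specs: list[PlaySpec]) -> pd.DataFrame:
    rows = []
    for spec in specs:
        for t in spec.trials:
            rows.append(
                dict(
                    play_id=spec.play_id,
                    trial_index=t.trial_index,
                    condition=t.condition,
                    background_id=t.background_id,
                    target_id=t.target_id,
                    x=t.placement[0],
                    y=t.placement[1],
                    radius=t.radius,
                )
            )
    return pd.DataFrame(rows)


def outcomes_to_frame(outcomes: list[TrialOutcome]) -> pd.DataFrame:
    rows = []
    extra_keys = sorted(
        {k for o in outcomes for k in o.extras if k not in TRIAL_COLUMNS}
    )
    for o in outcomes:
        row = dict(
            play_id=o.play_id,
            experiment=o.experiment,
            trial_index=o.trial_index,
            condition=o.condition,
            background_id=o.background_id,
            target_id=o.target_id,
            time_s=o.time,
            event=o.event,
            distance_px=o.distance,
            mdps=o.mdps,
        )
        for k in extra_keys:
            row[k] = o.extras.get(k)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_outcomes(df: pd.DataFrame) -> list[TrialOutcome]:
    extra_keys = [c for c in df.columns if c not in TRIAL_COLUMNS]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        mdps = d.get("mdps")
        out.append(
            TrialOutcome(
                play_id=str(d["play_id"]),
                trial_index=int(d["trial_index"]),
                condition=str(d["condition"]),
                time=float(d["time_s"]),
                event=int(d["event"]),
                distance=float(d["distance_px"]),
                mdps=None if mdps is None or (isinstance(mdps, float) and math.isnan(mdps)) else float(mdps),
                experiment=int(d.get("experiment", 1)),
                background_id=d.get("background_id"),
                target_id=d.get("target_id"),
                extras={k: d[k] for k in extra_keys if d.get(k) is not None},
            )
        )
    return out


def coxfit_to_dict(fit: CoxFit) -> dict:
    def clean(x):
        if isinstance(x, float) and not math.isfinite(x):
            return None if math.isnan(x) else ("inf" if x > 0 else "-inf")
        return x

    return dict(
        terms=list(fit.terms),
        coefficients={k: clean(v) for k, v in fit.coefficients.items()},
        robust_se={k: clean(v) for k, v in fit.robust_se.items()},
        naive_se={k: clean(v) for k, v in fit.naive_se.items()},
        hr={k: clean(v) for k, v in fit.hr.items()},
        ci95={k: [clean(v[0]), clean(v[1])] for k, v in fit.ci95.items()},
        log_partial_likelihood=fit.log_partial_likelihood,
        aic=fit.aic,
        concordance=clean(fit.concordance),
        n_events=fit.n_events,
        n_episodes=fit.n_episodes,
        n_clusters=fit.n_clusters,
        n_iterations=fit.n_iterations,
        data_fingerprint=fit.data_fingerprint,
        pinned=list(fit.pinned),
    )


def or_to_dict(res: ORResult) -> dict:
    return dict(
        or_value=res.or_value,
        ci95=list(res.ci95),
        chi2=None if math.isnan(res.chi2) else res.chi2,
        p=None if math.isnan(res.p) else res.p,
        table=res.table.tolist(),
        haldane=res.haldane,
    )


def km_curves_to_frame(curves: list[KMCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for t, s in zip(c.times, c.survival):
            rows.append(dict(group=c.group, time=t, survival=s))
    return pd.DataFrame(rows)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
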