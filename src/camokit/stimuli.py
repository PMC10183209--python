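"""Stimulus construction for background-matching search experiments.

Targets are built by blending pairs (or quadruples) of background images in
the Fourier domain and cutting a triangular "moth" patch from the blend.
Blending combines, per color channel, a linear mixture of the two amplitude
spectra with a circular (resultant-vector) mixture of the two phase spectra,
so the blend inherits the spatial-frequency content of both parents in
proportion to the weights even when the parents are out of phase.

Two designs are supported:

* the two-background design, where each image pair yields blends containing
  25%, 50% and 75% of background A (specialist on B / generalist /
  specialist on A), and
* the four-background design with specialist (S), two-background generalist
  (G2) and four-background generalist (G4) targets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import DimensionError, ValidationError
from .images import RasterImage

TRIANGLE_WIDTH = 150
TRIANGLE_HEIGHT = 75

#: Blend weights of the two-background design (proportion of background A).
EXP1_WEIGHTS = (0.25, 0.50, 0.75)

_PHASE_EPS = 1e-12


def check_blend_weight(w: float) -> float:
    """Validate a blend weight (proportion of background A) in [0, 1]."""
    w = float(w)
    if not (0.0 <= w <= 1.0) or not math.isfinite(w):
        raise ValidationError(f"blend weight must lie in [0, 1], got {w}")
    return w


@dataclass
class BlendedBackground:
    """A background produced by Fourier-domain blending.

    ``image`` may be ``None`` when pixel data has been dropped to save
    memory (metadata-only bookkeeping); ``source_ids`` and ``weights``
    always record the provenance.
    """

    image: RasterImage | None
    source_ids: tuple[str, ...]
    weights: tuple[float, ...]
    blend_id: str
    clip_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.source_ids = tuple(self.source_ids)
        self.weights = tuple(float(w) for w in self.weights)
        if len(self.source_ids) != len(self.weights):
            raise ValidationError("source_ids and weights must match in length")
        if len(self.weights) not in (1, 2, 4):
            raise ValidationError("blends must have 1, 2 or 4 sources")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("blend weights must sum to 1")


@dataclass
class TriangleTarget:
    """A 150 x 75 px triangular patch cut from a blended background.

    ``patch`` is the 75 x 150 x 3 bounding box; pixels outside ``mask``
    hold the sentinel value 0 and become transparent in RGBA output.
    ``anchor`` is the (row, col) of the patch's top-left pixel in the
    source image, 0-based.
    """

    patch: np.ndarray
    mask: np.ndarray
    source_blend: str
    anchor: tuple[int, int]
    target_id: str
    condition: str | None = None

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.patch.shape != (TRIANGLE_HEIGHT, TRIANGLE_WIDTH, 3):
            raise DimensionError(
                f"patch must be {TRIANGLE_HEIGHT}x{TRIANGLE_WIDTH}x3, "
                f"got {self.patch.shape}"
            )
        if self.mask.shape != (TRIANGLE_HEIGHT, TRIANGLE_WIDTH):
            raise DimensionError("mask shape must match the patch bounding box")
        self.anchor = (int(self.anchor[0]), int(self.anchor[1]))


@dataclass
class TrialSpec:
    """One slide of a play: a target shown at a position on a background."""

    trial_index: int
    condition: str
    background_id: str
    target_id: str
    placement: tuple[float, float]
    radius: float
    covariates: dict = field(default_factory=dict)

    def validate_radius(self, screen: tuple[int, int]) -> None:
        cx, cy = screen[0] / 2.0, screen[1] / 2.0
        r = math.hypot(self.placement[0] - cx, self.placement[1] - cy)
        if abs(r - self.radius) > 0.5:
            raise ValidationError(
                f"recorded radius {self.radius:.2f} disagrees with placement "
                f"distance {r:.2f}"
            )


@dataclass
class PlaySpec:
    """An ordered sequence of trials viewed by one participant."""

    play_id: str
    trials: tuple[TrialSpec, ...]
    experiment: int = 1

    def __post_init__(self) -> None:
        self.trials = tuple(self.trials)
        expected = {1: 12, 2: 36}.get(self.experiment)
        if expected is not None and len(self.trials) != expected:
            raise ValidationError(
                f"experiment {self.experiment} plays must have {expected} "
                f"trials, got {len(self.trials)}"
            )


@dataclass
class StimulusSet:
    """All blends and targets built for one experiment run."""

    experiment: int
    blends: list[BlendedBackground]
    targets: list[TriangleTarget]
    #: target_id -> raw background image ids the target may be displayed on
    #: (the source pair in the two-background design).
    target_backgrounds: dict[str, tuple[str, ...]]
    #: category -> bank image ids (used to sample display backgrounds in the
    #: four-background design).
    bank_categories: dict[str, tuple[str, ...]]
    #: two-background design only: (pair_id, image_id_a, image_id_b)
    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    #: target_id -> pair_id (two-background design)
    target_pair: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        blend_ids = [b.blend_id for b in self.blends]
        if len(set(blend_ids)) != len(blend_ids):
            raise ValidationError("duplicate blend_id in stimulus set")
        target_ids = [t.target_id for t in self.targets]
        if len(set(target_ids)) != len(target_ids):
            raise ValidationError("duplicate target_id in stimulus set")
        cuts = {(t.source_blend, t.anchor) for t in self.targets}
        if len(cuts) != len(self.targets):
            raise ValidationError("two targets share (source_blend, anchor)")

    def targets_by_condition(self) -> dict[str, list[TriangleTarget]]:
        out: dict[str, list[TriangleTarget]] = {}
        for t in self.targets:
            out.setdefault(t.condition or "", []).append(t)
        return out


@lru_cache(maxsize=1)
def triangle_mask() -> np.ndarray:
    """The fixed isosceles triangle mask, rasterized by pixel-center
    inclusion: 150-px base along the top edge, apex at bottom-center."""
    rows = np.arange(TRIANGLE_HEIGHT)[:, None]
    cols = np.arange(TRIANGLE_WIDTH)[None, :]
    # pixel centers (r + .5, c + .5); edges col = row and col = 150 - row
    mask = (cols >= rows) & (cols <= TRIANGLE_WIDTH - 1 - rows)
    mask.setflags(write=False)
    return mask


def _unit_phase(F: np.ndarray) -> np.ndarray:
    """e^{i arg F}, with zero-magnitude coefficients mapped to 1 (phase 0)."""
    mag = np.abs(F)
    out = np.ones_like(F)
    nz = mag > 0
    out[nz] = F[nz] / mag[nz]
    return out


def _blend_channel(ca: np.ndarray, cb: np.ndarray, w: float) -> np.ndarray:
    Fa = np.fft.fft2(ca)
    Fb = np.fft.fft2(cb)
    amp = w * np.abs(Fa) + (1.0 - w) * np.abs(Fb)
    ua = _unit_phase(Fa)
    ub = _unit_phase(Fb)
    resultant = w * ua + (1.0 - w) * ub
    mag = np.abs(resultant)
    degenerate = mag < _PHASE_EPS
    unit = np.empty_like(resultant)
    ok = ~degenerate
    unit[ok] = resultant[ok] / mag[ok]
    # deterministic tie-break when the two phases cancel exactly
    unit[degenerate] = ua[degenerate] if w >= 0.5 else ub[degenerate]
    return np.real(np.fft.ifft2(amp * unit))


def fourier_blend(
    a: RasterImage,
    b: RasterImage,
    w: float,
    blend_id: str | None = None,
) -> BlendedBackground:
    """Blend two equally sized images in the Fourier domain.

    Per channel the amplitude spectra are mixed linearly
    (``w|F_a| + (1-w)|F_b|``) and the phases circularly (argument of
    ``w e^{i phi_a} + (1-w) e^{i phi_b}``); the inverse transform's
    imaginary residue is discarded and the result clipped to [0, 1].
    The fraction of clipped pixels is recorded on the result.
    """
    w = check_blend_weight(w)
    if a.shape != b.shape:
        raise ValidationError(
            f"blend inputs must share dimensions, got {a.shape} vs {b.shape}"
        )
    out = np.empty_like(a.pixels)
    for c in range(3):
        out[..., c] = _blend_channel(a.pixels[..., c], b.pixels[..., c], w)
    clipped = float(np.mean((out < 0.0) | (out > 1.0)))
    out = np.clip(out, 0.0, 1.0)
    if blend_id is None:
        blend_id = f"{a.image_id}+{b.image_id}@{w:g}"
    image = RasterImage(out, image_id=blend_id)
    return BlendedBackground(
        image=image,
        source_ids=(a.image_id, b.image_id),
        weights=(w, 1.0 - w),
        blend_id=blend_id,
        clip_fraction=clipped,
    )


def fourier_blend_equal4(
    ab: BlendedBackground,
    cd: BlendedBackground,
    blend_id: str | None = None,
) -> BlendedBackground:
    """Blend two 50% pair-blends equally into a four-source blend."""
    for half in (ab, cd):
        if len(half.source_ids) != 2 or any(
            abs(x - 0.5) > 1e-9 for x in half.weights
        ):
            raise ValidationError("inputs must be 50% two-source blends")
        if half.image is None:
            raise ValidationError("input blends must retain pixel data")
    if set(ab.source_ids) & set(cd.source_ids):
        raise ValidationError("the four sources must be distinct")
    if blend_id is None:
        blend_id = f"{ab.blend_id}+{cd.blend_id}@0.5"
    mixed = fourier_blend(ab.image, cd.image, 0.5, blend_id=blend_id)
    return BlendedBackground(
        image=mixed.image,
        source_ids=ab.source_ids + cd.source_ids,
        weights=(0.25, 0.25, 0.25, 0.25),
        blend_id=blend_id,
        clip_fraction=mixed.clip_fraction,
    )


def as_single_source(img: RasterImage, blend_id: str | None = None) -> BlendedBackground:
    """Wrap a raw image as a one-source blend so targets can be cut from it."""
    return BlendedBackground(
        image=img,
        source_ids=(img.image_id,),
        weights=(1.0,),
        blend_id=blend_id or f"raw_{img.image_id}",
    )


def extract_triangle(
    src: BlendedBackground,
    rng: np.random.Generator,
    target_id: str | None = None,
) -> TriangleTarget:
    """Cut a triangular target at a uniformly random anchor of ``src``."""
    if src.image is None:
        raise ValidationError("source blend has no pixel data")
    h, w = src.image.shape
    if w < TRIANGLE_WIDTH or h < TRIANGLE_HEIGHT:
        raise DimensionError(
            f"source must be at least {TRIANGLE_WIDTH}x{TRIANGLE_HEIGHT}, "
            f"got {w}x{h}"
        )
    row = int(rng.integers(0, h - TRIANGLE_HEIGHT + 1))
    col = int(rng.integers(0, w - TRIANGLE_WIDTH + 1))
    patch = src.image.pixels[
        row : row + TRIANGLE_HEIGHT, col : col + TRIANGLE_WIDTH
    ].copy()
    mask = triangle_mask()
    patch[~mask] = 0.0
    return TriangleTarget(
        patch=patch,
        mask=mask.copy(),
        source_blend=src.blend_id,
        anchor=(row, col),
        target_id=target_id or f"t_{src.blend_id}",
    )


def _group_by_category(bank: list[RasterImage]) -> dict[str, list[RasterImage]]:
    cats: dict[str, list[RasterImage]] = {}
    for img in bank:
        if img.category is None:
            raise ValidationError(f"bank image {img.image_id} has no category")
        cats.setdefault(img.category, []).append(img)
    return cats


def build_exp1_stimuli(
    bank: list[RasterImage],
    n_pairs: int,
    rng: np.random.Generator,
    keep_blend_images: bool = True,
) -> StimulusSet:
    """Build the two-background stimulus set.

    Draws ``n_pairs`` distinct image pairs from two distinct categories and,
    per pair, produces blends at 25/50/75% of background A with one
    triangular target each (3 blends and 3 targets per pair).
    """
    cats = _group_by_category(bank)
    names = sorted(cats)
    if len(names) < 2:
        raise ValidationError("two-background design needs >= 2 categories")
    max_pairs = sum(
        len(cats[x]) * len(cats[y]) for x, y in itertools.combinations(names, 2)
    )
    if n_pairs < 1 or n_pairs > max_pairs:
        raise ValidationError(
            f"n_pairs must lie in [1, {max_pairs}] for this bank, got {n_pairs}"
        )
    seen: set[frozenset[str]] = set()
    blends: list[BlendedBackground] = []
    targets: list[TriangleTarget] = []
    target_backgrounds: dict[str, tuple[str, ...]] = {}
    pairs: list[tuple[str, str, str]] = []
    target_pair: dict[str, str] = {}
    k = 0
    while k < n_pairs:
        ci, cj = rng.choice(len(names), size=2, replace=False)
        a = cats[names[ci]][int(rng.integers(len(cats[names[ci]])))]
        b = cats[names[cj]][int(rng.integers(len(cats[names[cj]])))]
        key = frozenset((a.image_id, b.image_id))
        if key in seen:
            continue
        seen.add(key)
        pair_id = f"pair{k:04d}"
        pairs.append((pair_id, a.image_id, b.image_id))
        for w in EXP1_WEIGHTS:
            cond = f"{int(round(w * 100))}"
            blend_id = f"{pair_id}_w{cond}"
            blend = fourier_blend(a, b, w, blend_id=blend_id)
            target = extract_triangle(blend, rng, target_id=f"t_{blend_id}")
            target.condition = cond
            if not keep_blend_images:
                blend.image = None
            blends.append(blend)
            targets.append(target)
            target_backgrounds[target.target_id] = (a.image_id, b.image_id)
            target_pair[target.target_id] = pair_id
        k += 1
    bank_categories = {
        name: tuple(img.image_id for img in cats[name]) for name in names
    }
    return StimulusSet(
        experiment=1,
        blends=blends,
        targets=targets,
        target_backgrounds=target_backgrounds,
        bank_categories=bank_categories,
        pairs=pairs,
        target_pair=target_pair,
    )


def _two_partner_assignment(
    n: int, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """Assign each of n left images two distinct partners from n right
    images so that every right image is also used exactly twice."""
    for _ in range(max_tries):
        perm = np.concatenate([rng.permutation(n), rng.permutation(n)])
        partners = perm.reshape(2, n).T  # row i: the two partners of left i
        if np.all(partners[:, 0] != partners[:, 1]):
            return partners
    raise ValidationError("could not build a valid pairing")  # pragma: no cover


def build_exp2_stimuli(
    bank: list[RasterImage],
    rng: np.random.Generator,
    keep_blend_images: bool = True,
) -> StimulusSet:
    """Build the four-background stimulus set (S, G2 and G4 targets).

    Requires a bank of exactly 4 categories x 30 images.  Specialist targets
    are cut straight from the raw images (3 per image); G2 targets from 50%
    blends of every category pair (60 per pair); G4 targets from equal
    four-way blends in which every bank image participates exactly 12 times.
    """
    cats = _group_by_category(bank)
    names = sorted(cats)
    if len(names) != 4 or any(len(cats[n]) != 30 for n in names):
        raise ValidationError(
            "four-background design needs exactly 4 categories x 30 images"
        )
    blends: list[BlendedBackground] = []
    targets: list[TriangleTarget] = []
    target_backgrounds: dict[str, tuple[str, ...]] = {}

    def add_target(src: BlendedBackground, tid: str, condition: str) -> None:
        for _ in range(100):
            t = extract_triangle(src, rng, target_id=tid)
            if all(
                (t.source_blend, t.anchor) != (u.source_blend, u.anchor)
                for u in targets
            ):
                break
        t.condition = condition
        targets.append(t)
        target_backgrounds[tid] = tuple(src.source_ids)

    # specialists: three triangles per raw image
    for name in names:
        for img in cats[name]:
            src = as_single_source(img, blend_id=f"S_{img.image_id}")
            blends.append(src)
            for j in range(3):
                add_target(src, f"t_S_{img.image_id}_{j}", "S")

    # G2: 50% blends for every unordered category pair
    for x, y in itertools.combinations(names, 2):
        partners = _two_partner_assignment(30, rng)
        for i, xi in enumerate(cats[x]):
            for j in partners[i]:
                yj = cats[y][int(j)]
                blend_id = f"G2_{xi.image_id}_{yj.image_id}"
                blend = fourier_blend(xi, yj, 0.5, blend_id=blend_id)
                tid = f"t_{blend_id}"
                add_target(blend, tid, "G2")
                if not keep_blend_images:
                    blend.image = None
                blends.append(blend)

    # G4: equal four-way blends, every image used 12 times
    pair_a, pair_b = (names[0], names[1]), (names[2], names[3])
    for _ in range(1000):
        slots = {
            n: rng.permutation(np.repeat(np.arange(30), 12)) for n in names
        }
        quads = list(
            zip(slots[names[0]], slots[names[1]], slots[names[2]], slots[names[3]])
        )
        if len(set(quads)) == len(quads):
            break
    else:  # pragma: no cover
        raise ValidationError("could not build distinct four-way combinations")
    for i, (qa, qb, qc, qd) in enumerate(quads):
        a, b = cats[pair_a[0]][int(qa)], cats[pair_a[1]][int(qb)]
        c, d = cats[pair_b[0]][int(qc)], cats[pair_b[1]][int(qd)]
        ab = fourier_blend(a, b, 0.5)
        cd = fourier_blend(c, d, 0.5)
        g4 = fourier_blend_equal4(ab, cd, blend_id=f"G4_{i:03d}")
        tid = f"t_G4_{i:03d}"
        add_target(g4, tid, "G4")
        if not keep_blend_images:
            g4.image = None
        blends.append(g4)

    bank_categories = {
        name: tuple(img.image_id for img in cats[name]) for name in names
    }
    return StimulusSet(
        experiment=2,
        blends=blends,
        targets=targets,
        target_backgrounds=target_backgrounds,
        bank_categories=bank_categories,
    )


def _placement_extents(
    screen: tuple[int, int], target_size: tuple[int, int]
) -> tuple[float, float]:
    sw, sh = screen
    tw, th = target_size
    rx = (sw - tw) / 2.0
    ry = (sh - th) / 2.0
    if rx <= 0 or ry <= 0:
        raise ValidationError(
            f"screen {screen} cannot hold a {tw}x{th} target away from center"
        )
    return rx, ry


def max_radius(
    screen: tuple[int, int],
    target_size: tuple[int, int] = (TRIANGLE_WIDTH, TRIANGLE_HEIGHT),
) -> float:
    """Largest center distance keeping the target fully on-screen for at
    least one angle (the diagonal of the valid-placement rectangle)."""
    rx, ry = _placement_extents(screen, target_size)
    return math.hypot(rx, ry)


def sample_radius(
    screen: tuple[int, int],
    rng: np.random.Generator,
    target_size: tuple[int, int] = (TRIANGLE_WIDTH, TRIANGLE_HEIGHT),
) -> float:
    """Draw a center distance with density proportional to r on [0, r_max].

    Larger distances are up-weighted (equivalently, placements are
    area-uniform in radius) so targets rarely sit near the screen center.
    """
    r_max = max_radius(screen, target_size)
    return r_max * math.sqrt(float(rng.random()))


def place_at_radius(
    screen: tuple[int, int],
    r: float,
    rng: np.random.Generator,
    target_size: tuple[int, int] = (TRIANGLE_WIDTH, TRIANGLE_HEIGHT),
) -> tuple[float, float]:
    """Place a target center at distance ``r`` from the screen center,
    uniformly over the angles that keep it fully on-screen."""
    rx, ry = _placement_extents(screen, target_size)
    if r > math.hypot(rx, ry):
        raise ValidationError("radius exceeds the on-screen maximum")
    cx, cy = screen[0] / 2.0, screen[1] / 2.0
    if r == 0.0:
        return (cx, cy)
    alpha = math.acos(min(1.0, rx / r)) if r > rx else 0.0
    beta = math.asin(min(1.0, ry / r)) if r > ry else math.pi / 2.0
    quadrant = int(rng.integers(4))
    phi = alpha + (beta - alpha) * float(rng.random())
    theta = (phi, math.pi - phi, math.pi + phi, 2.0 * math.pi - phi)[quadrant]
    return (cx + r * math.cos(theta), cy + r * math.sin(theta))


def _shuffled_trials(
    raw: list[dict], rng: np.random.Generator
) -> tuple[TrialSpec, ...]:
    order = rng.permutation(len(raw))
    out = []
    for idx, j in enumerate(order, start=1):
        d = raw[int(j)]
        out.append(TrialSpec(trial_index=idx, **d))
    return tuple(out)


def assemble_play_exp1(
    stimuli: StimulusSet,
    screen: tuple[int, int],
    rng: np.random.Generator,
    play_id: str = "play0",
) -> PlaySpec:
    """Assemble one two-background play: 6 targets (2 per condition), each
    shown on both of its source backgrounds at a shared radius."""
    by_cond = stimuli.targets_by_condition()
    r_max = max_radius(screen)
    raw: list[dict] = []
    for cond in ("25", "50", "75"):
        pool = by_cond.get(cond, [])
        if len(pool) < 2:
            raise ValidationError(f"need >= 2 targets of condition {cond}")
        pick = rng.choice(len(pool), size=2, replace=False)
        for t in (pool[int(i)] for i in pick):
            r = sample_radius(screen, rng)
            for bg_id in stimuli.target_backgrounds[t.target_id]:
                x, y = place_at_radius(screen, r, rng)
                raw.append(
                    dict(
                        condition=cond,
                        background_id=bg_id,
                        target_id=t.target_id,
                        placement=(x, y),
                        radius=r,
                        covariates={"distance_norm": r / r_max},
                    )
                )
    return PlaySpec(play_id=play_id, trials=_shuffled_trials(raw, rng), experiment=1)


def assemble_play_exp2(
    stimuli: StimulusSet,
    screen: tuple[int, int],
    rng: np.random.Generator,
    play_id: str = "play0",
) -> PlaySpec:
    """Assemble one four-background play: 9 targets (3 per type), each shown
    once on a randomly chosen image of every category."""
    by_cond = stimuli.targets_by_condition()
    r_max = max_radius(screen)
    raw: list[dict] = []
    for cond in ("S", "G2", "G4"):
        pool = by_cond.get(cond, [])
        if len(pool) < 3:
            raise ValidationError(f"need >= 3 targets of type {cond}")
        pick = rng.choice(len(pool), size=3, replace=False)
        for t in (pool[int(i)] for i in pick):
            for cat in sorted(stimuli.bank_categories):
                ids = stimuli.bank_categories[cat]
                bg_id = ids[int(rng.integers(len(ids)))]
                r = sample_radius(screen, rng)
                x, y = place_at_radius(screen, r, rng)
                raw.append(
                    dict(
                        condition=cond,
                        background_id=bg_id,
                        target_id=t.target_id,
                        placement=(x, y),
                        radius=r,
                        covariates={"distance_norm": r / r_max},
                    )
                )
    return PlaySpec(play_id=play_id, trials=_shuffled_trials(raw, rng), experiment=2)
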