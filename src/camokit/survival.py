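"""Time-to-detection survival analysis.

Trial outcomes (detection time or 15-s timeout) are expanded into
counting-process episodes at user-chosen cutpoints so that condition
effects can vary by time phase, then fitted with a Cox proportional-hazards
model: Breslow partial likelihood maximized by Newton iteration, with a
cluster-robust (score-residual sandwich) variance aggregated at the play
level to account for repeated trials by the same participant.  Models are
compared by AIC on the partial likelihood; Kaplan-Meier curves and
hits/timeouts odds ratios summarize overall performance.
"""

from __future__ import annotations

import hashlib
import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConvergenceError,
    ModelSpecError,
    ValidationError,
)

DEFAULT_CENSOR_TIME = 15.0

#: Time-phase boundaries used by the two- and four-background analyses.
EXP1_CUTPOINTS = (1.5, 2.5)
EXP2_CUTPOINTS = (0.6, 1.2, 1.4, 2.0, 10.5)

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# domain types


@dataclass
class TrialOutcome:
    """The final response of one search trial."""

    play_id: str
    trial_index: int
    condition: str
    time: float
    event: int
    distance: float
    mdps: float | None = None
    experiment: int = 1
    background_id: str | None = None
    target_id: str | None = None
    distance_stratum: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValidationError("detection time must be positive")
        if self.event not in (0, 1):
            raise ValidationError("event must be 0 (timeout) or 1 (detected)")


@dataclass
class EpisodeRow:
    """One (tstart, tstop] interval of a trial in counting-process form."""

    play_id: str
    tstart: float
    tstop: float
    event: int
    period: str
    period_index: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tstart < self.tstop:
            raise ValidationError("episodes require tstart < tstop")


@dataclass
class CoxFit:
    """A fitted proportional-hazards model."""

    terms: tuple[str, ...]
    coefficients: dict
    robust_se: dict
    naive_se: dict
    hr: dict
    ci95: dict
    log_partial_likelihood: float
    aic: float
    concordance: float
    n_events: int
    n_episodes: int
    n_clusters: int
    n_iterations: int
    data_fingerprint: str
    pinned: tuple[str, ...] = ()

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            lo, hi = self.ci95[t]
            rows.append(
                dict(
                    term=t,
                    coef=self.coefficients[t],
                    robust_se=self.robust_se[t],
                    hr=self.hr[t],
                    ci_low=lo,
                    ci_high=hi,
                )
            )
        return pd.DataFrame(rows)


@dataclass
class ORResult:
    """Survival odds ratio for a 2x2 hits/timeouts table."""

    or_value: float
    ci95: tuple[float, float]
    chi2: float
    p: float
    table: np.ndarray
    haldane: bool = False


@dataclass
class KMCurve:
    """Product-limit survivor estimate for one condition."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray
    n: int


# ---------------------------------------------------------------------------
# episode splitting


def period_labels(cutpoints: tuple[float, ...]) -> list[str]:
    """Human-readable labels for the phases delimited by ``cutpoints``."""
    cuts = list(cutpoints)
    labels = []
    lo = 0.0
    for c in cuts:
        labels.append(f"{lo:g}-{c:g}")
        lo = c
    labels.append(f"{lo:g}+")
    return labels


def _check_cutpoints(cutpoints) -> tuple[float, ...]:
    cuts = tuple(float(c) for c in cutpoints)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ValidationError("cutpoints must be strictly increasing")
    if cuts and (cuts[0] <= 0 or cuts[-1] >= DEFAULT_CENSOR_TIME):
        raise ValidationError(
            f"cutpoints must lie in (0, {DEFAULT_CENSOR_TIME})"
        )
    return cuts


def split_episodes(
    outcomes: list[TrialOutcome], cutpoints
) -> list[EpisodeRow]:
    """Expand each outcome into one episode per phase intersected with
    (0, time].  Total exposure and event counts are conserved exactly."""
    cuts = _check_cutpoints(cutpoints)
    labels = period_labels(cuts)
    episodes: list[EpisodeRow] = []
    for out in outcomes:
        edges = [0.0] + [c for c in cuts if c < out.time] + [out.time]
        n_ep = len(edges) - 1
        for i in range(n_ep):
            lo, hi = edges[i], edges[i + 1]
            idx = bisect_left(cuts, hi)
            cov = {
                "condition": out.condition,
                "trial_index": out.trial_index,
                "distance": out.distance,
                "mdps": out.mdps,
                "experiment": out.experiment,
                "distance_stratum": out.distance_stratum,
            }
            cov.update(out.extras)
            episodes.append(
                EpisodeRow(
                    play_id=out.play_id,
                    tstart=lo,
                    tstop=hi,
                    event=int(out.event) if i == n_ep - 1 else 0,
                    period=labels[idx],
                    period_index=idx,
                    covariates=cov,
                )
            )
    return episodes


def episodes_to_frame(episodes: list[EpisodeRow]) -> pd.DataFrame:
    """Flatten episodes into the tabular layout the fitter consumes."""
    rows = []
    for ep in episodes:
        row = dict(
            play_id=ep.play_id,
            tstart=ep.tstart,
            tstop=ep.tstop,
            event=ep.event,
            period=ep.period,
            period_index=ep.period_index,
        )
        row.update(ep.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design helpers


def add_condition_period_design(
    df: pd.DataFrame, reference: str
) -> tuple[pd.DataFrame, list[str]]:
    """Add period-specific treatment-contrast dummies for condition
    (reference condition omitted), one column per (condition, period)."""
    df = df.copy()
    conds = sorted(set(df["condition"].astype(str)))
    if reference not in conds:
        raise ValidationError(f"reference condition {reference!r} not present")
    periods = sorted(set(df["period"]), key=lambda p: df.loc[df["period"] == p, "period_index"].iloc[0])
    cols = []
    for c in conds:
        if c == reference:
            continue
        for p in periods:
            name = f"cond[{c}]:{p}"
            df[name] = (
                (df["condition"].astype(str) == c) & (df["period"] == p)
            ).astype(float)
            cols.append(name)
    return df, cols


def add_metric_interaction_design(
    df: pd.DataFrame, metric: str, reference: str
) -> tuple[pd.DataFrame, list[str]]:
    """Add per-period main effects of a background-difference metric and its
    interactions with the (non-reference) condition dummies."""
    df = df.copy()
    if metric not in df.columns:
        raise ValidationError(f"metric column {metric!r} missing")
    if df[metric].isna().any():
        raise ValidationError(f"metric column {metric!r} has missing values")
    conds = sorted(set(df["condition"].astype(str)))
    periods = sorted(set(df["period"]), key=lambda p: df.loc[df["period"] == p, "period_index"].iloc[0])
    cols = []
    vals = df[metric].astype(float)
    for p in periods:
        in_p = (df["period"] == p).astype(float)
        name = f"{metric}:{p}"
        df[name] = vals * in_p
        cols.append(name)
        for c in conds:
            if c == reference:
                continue
            name = f"{metric}:cond[{c}]:{p}"
            df[name] = vals * in_p * (df["condition"].astype(str) == c).astype(float)
            cols.append(name)
    return df, cols


# ---------------------------------------------------------------------------
# Cox partial-likelihood machinery


class _Stratum:
    """Pre-sorted arrays for one stratum of counting-process data."""

    def __init__(self, ts, te, ev, X):
        self.ts = ts
        self.te = te
        self.ev = ev.astype(bool)
        self.X = X
        n, p = X.shape
        iu = np.triu_indices(p)
        self.iu = iu
        self.Xp = X[:, iu[0]] * X[:, iu[1]]  # (n, p(p+1)/2)
        self.order_stop = np.argsort(te, kind="stable")
        self.order_start = np.argsort(ts, kind="stable")
        ev_times = te[self.ev]
        self.ut, inverse = np.unique(ev_times, return_inverse=True)
        self.d = np.bincount(inverse, minlength=len(self.ut)).astype(float)
        Xev = X[self.ev]
        self.s_events = np.zeros((len(self.ut), p))
        np.add.at(self.s_events, inverse, Xev)
        self.sum_x_events = Xev.sum(axis=0)
        self.event_rows = np.flatnonzero(self.ev)
        self.event_ut_pos = inverse  # position of each event row's time in ut

    def n_events(self) -> int:
        return int(self.ev.sum())


def _suffix_sums(values_sorted: np.ndarray) -> np.ndarray:
    """suffix[i] = sum of values_sorted[i:], with suffix[n] = 0."""
    out = np.zeros((values_sorted.shape[0] + 1,) + values_sorted.shape[1:])
    out[:-1] = np.cumsum(values_sorted[::-1], axis=0)[::-1]
    return out


def _risk_sums(sd: _Stratum, weights: np.ndarray) -> tuple:
    """S0, S1, S2 (upper-tri) at every unique event time.

    A row is at risk at event time t iff tstart < t <= tstop; the sums are
    computed as (sum over tstop >= t) minus (sum over tstart >= t) using
    suffix cumulative sums of the two sorted orders.
    """
    w = weights
    cols = np.column_stack([w, w[:, None] * sd.X, w[:, None] * sd.Xp])

    te_sorted = sd.te[sd.order_stop]
    suf_stop = _suffix_sums(cols[sd.order_stop])
    idx_stop = np.searchsorted(te_sorted, sd.ut, side="left")
    A = suf_stop[idx_stop]

    ts_sorted = sd.ts[sd.order_start]
    suf_start = _suffix_sums(cols[sd.order_start])
    idx_start = np.searchsorted(ts_sorted, sd.ut, side="left")
    B = suf_start[idx_start]

    S = A - B
    p = sd.X.shape[1]
    S0 = np.maximum(S[:, 0], 1e-300)
    S1 = S[:, 1 : 1 + p]
    S2u = S[:, 1 + p :]
    return S0, S1, S2u


def _stratum_ll_grad_hess(sd: _Stratum, beta: np.ndarray, shift: float):
    eta = sd.X @ beta
    w = np.exp(eta - shift)
    S0, S1, S2u = _risk_sums(sd, w)
    log_s0 = np.log(S0) + shift
    ll = float(sd.sum_x_events @ beta - sd.d @ log_s0)
    xbar = S1 / S0[:, None]
    grad = sd.sum_x_events - sd.d @ xbar
    p = sd.X.shape[1]
    Hu = (sd.d[:, None] * (S2u / S0[:, None])).sum(axis=0)
    Hu -= (sd.d[:, None] * (xbar[:, sd.iu[0]] * xbar[:, sd.iu[1]])).sum(axis=0)
    info = np.zeros((p, p))
    info[sd.iu] = Hu
    info = info + info.T - np.diag(np.diag(info))
    return ll, grad, info


def _stratum_score_residuals(sd: _Stratum, beta: np.ndarray, shift: float):
    """Per-row score residuals of the Breslow partial likelihood."""
    eta = sd.X @ beta
    w = np.exp(eta - shift)
    S0, S1, _ = _risk_sums(sd, w)
    xbar = S1 / S0[:, None]
    # prefix sums over event times (ascending) of d/S0 and d*xbar/S0;
    # note S0 here absorbs exp(-shift), so scale back when multiplying by w
    g0 = sd.d / S0
    g1 = (sd.d / S0)[:, None] * xbar
    F0 = np.concatenate([[0.0], np.cumsum(g0)])
    F1 = np.vstack([np.zeros(sd.X.shape[1]), np.cumsum(g1, axis=0)])
    hi = np.searchsorted(sd.ut, sd.te, side="right")
    lo = np.searchsorted(sd.ut, sd.ts, side="right")
    C0 = F0[hi] - F0[lo]
    C1 = F1[hi] - F1[lo]
    U = -w[:, None] * (sd.X * C0[:, None] - C1)
    U[sd.event_rows] += sd.X[sd.event_rows] - xbar[sd.event_ut_pos]
    return U


class _Fenwick:
    """Binary indexed tree of counts over rank indices 1..n."""

    def __init__(self, n: int):
        self.n = n
        self.tree = np.zeros(n + 1, dtype=np.int64)

    def add(self, i: int, delta: int) -> None:
        i += 1
        while i <= self.n:
            self.tree[i] += delta
            i += i & (-i)

    def prefix(self, i: int) -> int:
        # count of entries with rank index <= i (0-based); i = -1 -> 0
        s = 0
        i += 1
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return int(s)


def _stratum_concordance(sd: _Stratum, eta: np.ndarray):
    """(concordant + 0.5*ties, comparable) pair counts, Harrell-style over
    the risk sets of the counting process; tied event times incomparable."""
    uniq_eta, rank = np.unique(eta, return_inverse=True)
    K = len(uniq_eta)
    bit = _Fenwick(K)
    stop_order = sd.order_stop[::-1]  # descending tstop
    start_order = sd.order_start[::-1]  # descending tstart
    i_stop = 0
    i_start = 0
    num = 0.0
    den = 0
    rows_at = {}
    for pos, r in enumerate(sd.event_rows):
        rows_at.setdefault(sd.ut[sd.event_ut_pos[pos]], []).append(r)
    for t in sd.ut[::-1]:
        while i_stop < len(stop_order) and sd.te[stop_order[i_stop]] >= t:
            bit.add(int(rank[stop_order[i_stop]]), 1)
            i_stop += 1
        while i_start < len(start_order) and sd.ts[start_order[i_start]] >= t:
            bit.add(int(rank[start_order[i_start]]), -1)
            i_start += 1
        in_risk = bit.prefix(K - 1)
        co = rows_at[t]
        co_ranks = sorted(int(rank[r]) for r in co)
        for r in co:
            ri = int(rank[r])
            less = bit.prefix(ri - 1)
            eq = bit.prefix(ri) - less
            co_less = sum(1 for cr in co_ranks if cr < ri)
            co_eq = sum(1 for cr in co_ranks if cr == ri)
            num += (less - co_less) + 0.5 * (eq - co_eq)
            den += in_risk - len(co)
    return num, den


def _data_fingerprint(df: pd.DataFrame, start, stop, event, cluster) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(df[start].to_numpy(float)).tobytes())
    h.update(np.ascontiguousarray(df[stop].to_numpy(float)).tobytes())
    h.update(np.ascontiguousarray(df[event].to_numpy(np.int64)).tobytes())
    h.update("|".join(df[cluster].astype(str)).encode())
    return h.hexdigest()[:16]


def fit_cox(
    df: pd.DataFrame,
    covariates: list[str],
    *,
    cluster: str = "play_id",
    strata: str | None = None,
    start: str = "tstart",
    stop: str = "tstop",
    event: str = "event",
    concordance: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxFit:
    """Fit a Cox model on counting-process episodes.

    Maximizes the Breslow partial likelihood (summed over strata when
    ``strata`` names a column) by Newton iteration to gradient sup-norm
    below ``tol``; variance is the clustered score-residual sandwich over
    ``cluster``.  Covariate columns constant across all rows cannot be
    estimated and are pinned at coefficient 0 with infinite standard error.
    """
    covariates = list(covariates)
    if df.empty:
        raise ValidationError("no episodes to fit")
    df = df.reset_index(drop=True)
    for col in covariates:
        if col not in df.columns:
            raise ValidationError(f"covariate column {col!r} missing")
    ev_all = df[event].to_numpy()
    if int(ev_all.sum()) < 1:
        raise ValidationError("at least one event is required")

    Xfull = df[covariates].to_numpy(float)
    if not np.isfinite(Xfull).all():
        raise ValidationError("covariates must be finite")
    variable = [
        j for j in range(Xfull.shape[1]) if np.ptp(Xfull[:, j]) > 0.0
    ]
    pinned = tuple(covariates[j] for j in range(Xfull.shape[1]) if j not in variable)
    est_terms = [covariates[j] for j in variable]
    X = Xfull[:, variable]
    p = X.shape[1]

    group_keys = (
        [(None, df)] if strata is None else list(df.groupby(strata, sort=True))
    )
    strata_data = []
    for _, g in group_keys:
        ev = g[event].to_numpy(float)
        if ev.sum() == 0:
            continue  # a stratum without events contributes nothing
        strata_data.append(
            _Stratum(
                g[start].to_numpy(float),
                g[stop].to_numpy(float),
                ev,
                X[g.index.to_numpy()] if strata is not None else X,
            )
        )
    if not strata_data:
        raise ValidationError("no stratum contains an event")

    beta = np.zeros(p)
    ll = None
    n_iter = 0
    if p > 0:
        for n_iter in range(1, max_iter + 1):
            shift = float(np.max([np.max(sd.X @ beta) for sd in strata_data]))
            ll = 0.0
            grad = np.zeros(p)
            info = np.zeros((p, p))
            for sd in strata_data:
                l, g_, i_ = _stratum_ll_grad_hess(sd, beta, shift)
                ll += l
                grad += g_
                info += i_
            if np.max(np.abs(grad)) < tol:
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ModelSpecError(
                    "singular information matrix: design is rank deficient"
                ) from exc
            # cap the step (guards monotone-likelihood separation) and
            # step-halve to guarantee a finite ascent
            big = np.max(np.abs(step))
            if big > 5.0:
                step = step * (5.0 / big)
            new_beta = beta + step
            accepted = False
            for _ in range(30):
                shift2 = float(
                    np.max([np.max(sd.X @ new_beta) for sd in strata_data])
                )
                new_ll = sum(
                    _stratum_ll_grad_hess(sd, new_beta, shift2)[0]
                    for sd in strata_data
                )
                if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                    accepted = True
                    break
                new_beta = beta + (new_beta - beta) / 2.0
            if not accepted:
                break  # no finite ascent direction remains
            stalled = abs(new_ll - ll) <= 1e-10 * (abs(ll) + 1.0)
            beta = new_beta
            if stalled:
                # partial likelihood stationary to near machine precision;
                # the gradient cannot be resolved further in float64
                break
        else:
            raise ConvergenceError(
                f"Newton iteration did not converge in {max_iter} steps "
                f"(gradient sup-norm {np.max(np.abs(grad)):.3e})"
            )

    # final quantities at the optimum
    shift = float(np.max([np.max(sd.X @ beta) for sd in strata_data])) if p else 0.0
    ll = 0.0
    info = np.zeros((p, p))
    for sd in strata_data:
        l, _, i_ = _stratum_ll_grad_hess(sd, beta, shift)
        ll += l
        info += i_

    n_episodes = len(df)
    n_events = int(ev_all.sum())
    cluster_labels = df[cluster].astype(str).to_numpy()
    n_clusters = len(set(cluster_labels))

    if p > 0:
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ModelSpecError(
                "singular information matrix: design is rank deficient"
            ) from exc
        # clustered sandwich: sum score residuals within plays
        U = np.zeros((n_episodes, p))
        if strata is None:
            U = _stratum_score_residuals(strata_data[0], beta, shift)
        else:
            for (_, g), sd in zip(
                [kg for kg in group_keys if kg[1][event].sum() > 0], strata_data
            ):
                U[g.index.to_numpy()] = _stratum_score_residuals(sd, beta, shift)
        ug = pd.DataFrame(U)
        ug["_c"] = cluster_labels
        Uc = ug.groupby("_c", sort=False).sum().to_numpy()
        meat = Uc.T @ Uc
        vrobust = info_inv @ meat @ info_inv
        robust_se_vec = np.sqrt(np.maximum(np.diag(vrobust), 0.0))
        naive_se_vec = np.sqrt(np.maximum(np.diag(info_inv), 0.0))
    else:
        robust_se_vec = np.zeros(0)
        naive_se_vec = np.zeros(0)

    conc = math.nan
    if concordance:
        eta_all = X @ beta if p else np.zeros(n_episodes)
        num = 0.0
        den = 0
        if strata is None:
            num, den = _stratum_concordance(strata_data[0], eta_all)
        else:
            for (_, g), sd in zip(
                [kg for kg in group_keys if kg[1][event].sum() > 0], strata_data
            ):
                n_, d_ = _stratum_concordance(sd, eta_all[g.index.to_numpy()])
                num += n_
                den += d_
        conc = num / den if den else math.nan

    coefficients = {t: 0.0 for t in covariates}
    robust_se = {t: math.inf for t in covariates}
    naive_se = {t: math.inf for t in covariates}
    for j, t in enumerate(est_terms):
        coefficients[t] = float(beta[j])
        robust_se[t] = float(robust_se_vec[j])
        naive_se[t] = float(naive_se_vec[j])
    hr = {t: math.exp(coefficients[t]) for t in covariates}
    ci95 = {}
    for t in covariates:
        se = robust_se[t]
        if math.isinf(se):
            ci95[t] = (0.0, math.inf)
        else:
            ci95[t] = (
                math.exp(coefficients[t] - Z95 * se),
                math.exp(coefficients[t] + Z95 * se),
            )

    aic = -2.0 * ll + 2.0 * len(est_terms)
    return CoxFit(
        terms=tuple(covariates),
        coefficients=coefficients,
        robust_se=robust_se,
        naive_se=naive_se,
        hr=hr,
        ci95=ci95,
        log_partial_likelihood=float(ll),
        aic=float(aic),
        concordance=float(conc) if conc == conc else math.nan,
        n_events=n_events,
        n_episodes=n_episodes,
        n_clusters=n_clusters,
        n_iterations=n_iter,
        data_fingerprint=_data_fingerprint(df, start, stop, event, cluster),
        pinned=pinned,
    )


def compare_aic(full: CoxFit, reduced: CoxFit) -> float:
    """AIC(full) - AIC(reduced); negative values favor the full model.

    Both fits must come from the same episode data."""
    if full.data_fingerprint != reduced.data_fingerprint:
        raise ValidationError("fits were made on different episode data")
    return full.aic - reduced.aic


# ---------------------------------------------------------------------------
# descriptive statistics


def km_estimate(outcomes: list[TrialOutcome], group: str) -> KMCurve:
    """Kaplan-Meier survivor curve for one condition, with the censoring
    (timeout) times recorded for plotting."""
    from lifelines import KaplanMeierFitter

    times = np.array([o.time for o in outcomes if o.condition == group])
    events = np.array([o.event for o in outcomes if o.condition == group])
    if times.size == 0:
        raise ValidationError(f"no outcomes in group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KMCurve(
        group=group,
        times=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        censor_times=np.sort(times[events == 0]),
        n=len(times),
    )


def odds_ratio(table) -> ORResult:
    """Survival odds ratio from a 2x2 table of (hits, timeouts) counts.

    Rows are (condition, reference); ``or_value > 1`` means the condition
    survives (times out) more often than the reference.  Zero cells receive
    the Haldane +0.5 correction for the OR and its Wald interval; the
    chi-square test (no continuity correction) uses the raw counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any():
        raise ValidationError("counts must be nonnegative")
    haldane = bool((t == 0).any())
    tc = t + 0.5 if haldane else t
    or_value = (tc[0, 1] * tc[1, 0]) / (tc[0, 0] * tc[1, 1])
    se = math.sqrt((1.0 / tc).sum())
    log_or = math.log(or_value)
    ci = (math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se))
    if t.sum(axis=0).min() > 0 and t.sum(axis=1).min() > 0:
        chi2, p = stats.chi2_contingency(t, correction=False)[:2]
    else:
        chi2, p = math.nan, math.nan
    return ORResult(
        or_value=float(or_value),
        ci95=ci,
        chi2=float(chi2),
        p=float(p),
        table=np.asarray(table),
        haldane=haldane,
    )


def hits_timeouts_table(
    outcomes: list[TrialOutcome], condition: str, reference: str
) -> np.ndarray:
    """2x2 (hits, timeouts) counts for a condition versus a reference."""
    rows = []
    for c in (condition, reference):
        sub = [o for o in outcomes if o.condition == c]
        hits = sum(o.event for o in sub)
        rows.append([hits, len(sub) - hits])
    return np.asarray(rows, dtype=int)


def distance_quartile_strata(
    outcomes: list[TrialOutcome],
) -> list[TrialOutcome]:
    """Label each outcome with the sample quartile (type-7) of its screen
    distance; values tied with a boundary fall in the lower stratum."""
    d = np.array([o.distance for o in outcomes], dtype=float)
    if len(np.unique(d)) < 4:
        raise ValidationError("need at least 4 distinct distances")
    qs = np.quantile(d, [0.25, 0.5, 0.75])
    idx = np.searchsorted(qs, d, side="left")
    out = []
    for o, i in zip(outcomes, idx):
        o2 = TrialOutcome(
            play_id=o.play_id,
            trial_index=o.trial_index,
            condition=o.condition,
            time=o.time,
            event=o.event,
            distance=o.distance,
            mdps=o.mdps,
            experiment=o.experiment,
            background_id=o.background_id,
            target_id=o.target_id,
            distance_stratum=f"Q{int(i) + 1}",
            extras=dict(o.extras),
        )
        out.append(o2)
    return out
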