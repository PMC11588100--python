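"""Signal-detection and curve-fitting analyses of detection trial tables.

Provides d' computation with extreme-rate correction, per-participant
performance curves, piecewise-linear "elbow" fits (rise then exact
plateau) with grid search over the breakpoint, participant bootstrap for
the elbow location, the delay-benefit statistic, permutation tests on
group differences, and greedy asymptote matching of participant groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# d-prime
# ---------------------------------------------------------------------------

def _corrected_rate(k: np.ndarray, n: np.ndarray, correction: str) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("zero trials in a rate computation")
    if correction == "half":
        r = k / n
        r = np.where(r <= 0, 1 / (2 * n), r)
        r = np.where(r >= 1, 1 - 1 / (2 * n), r)
    elif correction == "loglinear":
        r = (k + 0.5) / (n + 1)
    else:
        raise ValueError(f"unknown correction: {correction}")
    return r


def compute_dprime(hits, n_signal, fas, n_noise, correction: str = "half"):
    """d' = z(hit rate) - z(false-alarm rate), extreme rates corrected.

    The default correction replaces rates of 0 and 1 by 1/(2N) and
    1 - 1/(2N); a log-linear rule is available.  Accepts scalars or
    arrays (broadcast).
    """
    h = _corrected_rate(hits, n_signal, correction)
    f = _corrected_rate(fas, n_noise, correction)
    out = norm.ppf(h) - norm.ppf(f)
    return float(out) if np.isscalar(hits) else out


# ---------------------------------------------------------------------------
# performance curves
# ---------------------------------------------------------------------------

@dataclass
class PerformanceCurve:
    """Group-mean d' per condition with between-participant SE."""

    onsets_ms: np.ndarray
    dprime: np.ndarray        # (n_groups, n_onsets) or (n_onsets,)
    se: np.ndarray
    group_labels: list = None
    n_participants: int = 0


def participant_dprime(
    table: pd.DataFrame,
    condition_cols=("onset_ms", "snr_db"),
    correction: str = "half",
) -> pd.DataFrame:
    """Per-participant d' per condition, using a single false-alarm rate
    per participant pooled over that participant's background-only trials.

    Returns a tidy frame (participant_id, *condition_cols, dprime).
    Participants lacking background-only trials or missing conditions are
    excluded with a logged warning.
    """
    condition_cols = list(condition_cols)
    sig = table[table["foreground_present"]]
    noi = table[~table["foreground_present"]]
    fa = noi.groupby("participant_id")["response"].agg(["sum", "count"])
    hit = sig.groupby(["participant_id", *condition_cols])["response"].agg(
        ["sum", "count"]
    )
    n_cond = sig.groupby(condition_cols).ngroups
    rows = []
    for pid, g in hit.groupby(level=0):
        if pid not in fa.index:
            logger.warning("participant %s has no background-only trials; excluded", pid)
            continue
        if len(g) < n_cond:
            logger.warning("participant %s missing conditions; excluded", pid)
            continue
        f_k, f_n = fa.loc[pid, "sum"], fa.loc[pid, "count"]
        d = compute_dprime(
            g["sum"].to_numpy(), g["count"].to_numpy(),
            np.full(len(g), f_k), np.full(len(g), f_n),
        )
        for (keys, dp) in zip(g.index, d):
            rows.append((pid, *keys[1:], dp))
    return pd.DataFrame(rows, columns=["participant_id", *condition_cols, "dprime"])


def dprime_by_onset(table: pd.DataFrame, correction: str = "half"):
    """(onsets, participants x onsets d' matrix), averaged over any other
    condition dimensions (e.g. SNR) within participant."""
    pd_ = participant_dprime(table, ("onset_ms", "snr_db"), correction)
    avg = pd_.groupby(["participant_id", "onset_ms"])["dprime"].mean().unstack()
    onsets = avg.columns.to_numpy(dtype=float)
    return onsets, avg.to_numpy()


def performance_curve(
    table: pd.DataFrame,
    group_col: str = "snr_db",
    correction: str = "half",
) -> PerformanceCurve:
    """Group-mean d' vs onset (one curve per level of ``group_col``),
    with SE across participants.  A single participant yields NaN SE and a
    logged warning."""
    pdm = participant_dprime(table, ("onset_ms", group_col), correction)
    n_p = pdm["participant_id"].nunique()
    if n_p == 0:
        raise ValueError("no usable participants")
    if n_p == 1:
        logger.warning("single participant: SE undefined")
    piv = pdm.pivot_table(
        index="participant_id", columns=[group_col, "onset_ms"], values="dprime"
    )
    mean = piv.mean(axis=0)
    se = piv.std(axis=0, ddof=1) / np.sqrt(n_p)
    groups = mean.index.get_level_values(0).unique()
    onsets = np.sort(mean.index.get_level_values(1).unique().to_numpy(dtype=float))
    dp = np.vstack([mean[g].reindex(onsets).to_numpy() for g in groups])
    se_m = np.vstack([se[g].reindex(onsets).to_numpy() for g in groups])
    return PerformanceCurve(onsets, dp, se_m, list(groups), n_p)


def model_dprime_table(
    model_table: pd.DataFrame, correction: str = "half"
) -> pd.DataFrame:
    """Condition d' for an observer-model trial table.

    Uses one pooled false-alarm rate over all background-only trials and
    a hit rate per (onset, SNR) condition.  Raises on empty conditions.
    """
    noi = model_table[~model_table["foreground_present"]]
    sig = model_table[model_table["foreground_present"]]
    if len(noi) == 0 or len(sig) == 0:
        raise ValueError("need both foreground and background-only trials")
    fk, fn = int(noi["decision"].sum()), len(noi)
    grp = sig.groupby(["onset_ms", "snr_db"])["decision"].agg(["sum", "count"])
    if (grp["count"] == 0).any():
        raise ValueError("a condition has zero trials")
    d = compute_dprime(
        grp["sum"].to_numpy(), grp["count"].to_numpy(),
        np.full(len(grp), fk), np.full(len(grp), fn), correction,
    )
    out = grp.reset_index()[["onset_ms", "snr_db"]]
    out["dprime"] = d
    out.attrs["false_alarm_rate"] = fk / fn
    return out


# ---------------------------------------------------------------------------
# elbow fitting
# ---------------------------------------------------------------------------

@dataclass
class ElbowFit:
    """Two-segment fit f(t) = a + b * min(t, elbow_ms); flat after the elbow."""

    a: float
    b: float
    elbow_ms: float
    rss: float

    @property
    def plateau(self) -> float:
        return self.a + self.b * self.elbow_ms

    def __call__(self, t):
        return self.a + self.b * np.minimum(np.asarray(t, dtype=float), self.elbow_ms)


def _elbow_candidates(onsets: np.ndarray, step: float) -> np.ndarray:
    t0, t1 = float(np.min(onsets)), float(np.max(onsets))
    return np.arange(t0, t1 + step / 2, step)


def fit_elbow_batch(
    onsets: np.ndarray, values: np.ndarray, candidates: np.ndarray = None,
    step: float = 5.0,
):
    """Vectorized elbow fits for many curves sharing one onset grid.

    ``values`` is (m, n_onsets).  For each breakpoint candidate the (a, b)
    pair is solved in closed form; the smallest-RSS candidate wins, ties
    resolved toward the smallest breakpoint.  Returns (a, b, elbow, rss)
    arrays of length m.
    """
    onsets = np.asarray(onsets, dtype=float)
    V = np.atleast_2d(np.asarray(values, dtype=float))
    if len(onsets) < 4:
        raise ValueError("elbow fit needs >= 4 distinct onsets")
    if candidates is None:
        candidates = _elbow_candidates(onsets, step)
    X = np.minimum(onsets[None, :], np.asarray(candidates, dtype=float)[:, None])
    n = len(onsets)
    Sx = X.sum(axis=1)
    Sxx = (X * X).sum(axis=1)
    Sy = V.sum(axis=1)
    Syy = (V * V).sum(axis=1)
    Sxy = X @ V.T                      # (C, m)
    den = n * Sxx - Sx * Sx            # (C,)
    ok = den > 1e-12 * np.maximum(Sxx, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (n * Sxy - Sx[:, None] * Sy[None, :]) / den[:, None]
    b[~ok] = 0.0
    a = (Sy[None, :] - b * Sx[:, None]) / n
    rss = (
        Syy[None, :]
        + n * a * a + b * b * Sxx[:, None] + 2 * a * b * Sx[:, None]
        - 2 * a * Sy[None, :] - 2 * b * Sxy
    )
    rss = np.maximum(rss, 0.0)
    best = np.argmin(rss, axis=0)      # first (= smallest candidate) on ties
    idx = np.arange(V.shape[0])
    return (
        a[best, idx], b[best, idx],
        np.asarray(candidates, dtype=float)[best], rss[best, idx],
    )


def fit_elbow(
    onsets, values, candidates=None, step: float = 5.0
) -> ElbowFit:
    """Least-squares elbow fit of a single curve (see fit_elbow_batch)."""
    a, b, te, rss = fit_elbow_batch(onsets, np.asarray(values)[None, :],
                                    candidates, step)
    return ElbowFit(float(a[0]), float(b[0]), float(te[0]), float(rss[0]))


def delay_benefit(fit: ElbowFit, t_min_ms: float = 250.0) -> float:
    """Plateau minus fitted value at the earliest probed onset:
    b * (elbow - t_min)."""
    return float(fit.plateau - fit(t_min_ms))


# ---------------------------------------------------------------------------
# bootstrap / permutation
# ---------------------------------------------------------------------------

@dataclass
class BootstrapElbow:
    ci_low_ms: float
    ci_high_ms: float
    sd_ms: float
    median_ms: float
    point_ms: float
    samples_ms: np.ndarray


def bootstrap_elbow_matrix(
    onsets: np.ndarray, mat: np.ndarray, n_boot: int = 1000, seed: int = 0,
    ci: float = 95.0, step: float = 5.0,
) -> BootstrapElbow:
    """Percentile bootstrap over participants of the elbow location.

    ``mat`` is the participants x onsets d' matrix; each replicate
    resamples rows with replacement and refits the mean curve.
    """
    rng = np.random.default_rng(seed)
    P = mat.shape[0]
    idx = rng.integers(0, P, size=(n_boot, P))
    curves = mat[idx].mean(axis=1)                 # (n_boot, n_onsets)
    _, _, te, _ = fit_elbow_batch(onsets, curves, step=step)
    point = fit_elbow(onsets, mat.mean(axis=0), step=step).elbow_ms
    lo, hi = np.percentile(te, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return BootstrapElbow(float(lo), float(hi), float(np.std(te, ddof=1)),
                          float(np.median(te)), float(point), te)


def bootstrap_elbow(
    table: pd.DataFrame, n_boot: int = 1000, seed: int = 0, ci: float = 95.0,
    step: float = 5.0,
) -> BootstrapElbow:
    """Bootstrap CI for the elbow point from a trial table (d' averaged
    over SNR within participant before fitting)."""
    onsets, mat = dprime_by_onset(table)
    if mat.shape[0] < 10:
        raise ValueError("bootstrap requires >= 10 participants")
    return bootstrap_elbow_matrix(onsets, mat, n_boot, seed, ci, step)


def _group_stat(onsets, mat, statistic: str, t_min: float, step: float) -> float:
    fit = fit_elbow(onsets, mat.mean(axis=0), step=step)
    if statistic == "elbow_ms":
        return fit.elbow_ms
    if statistic == "delay_benefit":
        return delay_benefit(fit, t_min)
    raise ValueError(f"unknown statistic: {statistic}")


@dataclass
class PermutationResult:
    observed_diff: float
    p_value: float
    null_diffs: np.ndarray


def permutation_diff_test_matrix(
    onsets: np.ndarray, matA: np.ndarray, matB: np.ndarray,
    statistic: str = "delay_benefit", n_perm: int = 1000, seed: int = 0,
    t_min: float = 250.0, step: float = 5.0,
) -> PermutationResult:
    """Two-sided permutation test of a group difference in elbow location
    or delay benefit; participant-to-group labels are shuffled and the
    statistic recomputed on the permuted group-mean curves.  p uses
    (k + 1) / (n_perm + 1) smoothing."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    nA, nB = matA.shape[0], matB.shape[0]
    if nA < 2 or nB < 2:
        raise ValueError("need >= 2 participants per group to permute")
    obs = (_group_stat(onsets, matA, statistic, t_min, step)
           - _group_stat(onsets, matB, statistic, t_min, step))
    pool = np.vstack([matA, matB])
    rng = np.random.default_rng(seed)
    # vectorized: permuted mean curves for both groups, then batch elbow fits
    curvesA = np.empty((n_perm, len(onsets)))
    curvesB = np.empty((n_perm, len(onsets)))
    for i in range(n_perm):
        perm = rng.permutation(nA + nB)
        curvesA[i] = pool[perm[:nA]].mean(axis=0)
        curvesB[i] = pool[perm[nA:]].mean(axis=0)
    aA, bA, teA, _ = fit_elbow_batch(onsets, curvesA, step=step)
    aB, bB, teB, _ = fit_elbow_batch(onsets, curvesB, step=step)
    if statistic == "elbow_ms":
        null = teA - teB
    else:
        null = bA * (teA - t_min) - bB * (teB - t_min)
    k = int(np.sum(np.abs(null) >= abs(obs)))
    return PermutationResult(float(obs), (k + 1) / (n_perm + 1), null)


def permutation_diff_test(
    tableA: pd.DataFrame, tableB: pd.DataFrame,
    statistic: str = "delay_benefit", n_perm: int = 1000, seed: int = 0,
    t_min: float = 250.0, step: float = 5.0,
) -> PermutationResult:
    """Trial-table front end of permutation_diff_test_matrix; the two
    tables must hold disjoint participant sets."""
    pa = set(tableA["participant_id"].unique())
    pb = set(tableB["participant_id"].unique())
    if pa & pb:
        raise ValueError("participant sets must be disjoint")
    oA, mA = dprime_by_onset(tableA)
    oB, mB = dprime_by_onset(tableB)
    if not np.array_equal(oA, oB):
        raise ValueError("onset grids differ between groups")
    return permutation_diff_test_matrix(oA, mA, mB, statistic, n_perm, seed,
                                        t_min, step)


# ---------------------------------------------------------------------------
# asymptote matching
# ---------------------------------------------------------------------------

def match_asymptote(
    onsets: np.ndarray, matA: np.ndarray, matB: np.ndarray,
    late_onsets=(1500.0, 2000.0, 2500.0), tol: float = 0.05,
    min_group: int = 2,
):
    """Greedily equalize late-onset (asymptotic) performance across groups.

    Repeatedly drops, from the better-performing group, the participant
    with the most extreme late-onset mean in the direction of that group's
    advantage, until the group means of d' at ``late_onsets`` differ by
    less than ``tol``.  Returns (kept_indices_A, kept_indices_B, gap).
    Raises if a group would shrink below ``min_group`` first.
    """
    cols = np.isin(onsets, np.asarray(late_onsets, dtype=float))
    if not cols.any():
        raise ValueError("late_onsets not found in onset grid")
    lateA = matA[:, cols].mean(axis=1)
    lateB = matB[:, cols].mean(axis=1)
    keepA = list(range(len(lateA)))
    keepB = list(range(len(lateB)))
    while True:
        gap = lateA[keepA].mean() - lateB[keepB].mean()
        if abs(gap) < tol:
            return np.array(keepA), np.array(keepB), float(gap)
        better, late = (keepA, lateA) if gap > 0 else (keepB, lateB)
        if len(better) <= min_group:
            raise ValueError(
                f"cannot match asymptotes to tol={tol}; achieved gap {gap:.3f}"
            )
        better.remove(max(better, key=lambda i: late[i]))
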