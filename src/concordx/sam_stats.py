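"""Two-class unpaired Significance Analysis of Microarrays (SAM).

A from-scratch implementation of the moderated relative-difference
statistic with a permutation null:

* per gene, d = (mean_treated - mean_control) / (s + s0), where s is
  the pooled standard error of the two-group difference and s0 a small
  positive "fudge factor" stabilising low-variance genes;
* s0 is chosen from percentiles of the s distribution by minimising the
  coefficient of variation of the d spread across s-quantile windows;
* expected order statistics d-bar(i) come from permuting class labels
  (exhaustively when the number of distinct label splits is small);
* for each half-width delta on a grid, genes beyond the first crossing
  of |d - d-bar| >= delta are called, and the false discovery rate is
  estimated as (median permutation false positives x pi0) / #called;
* the calling threshold is the smallest delta whose (monotonised) FDR
  estimate is at or below the target.

pi0, the null-gene proportion, is estimated from the fraction of
observed d values inside the interquartile range of the permuted d
distribution, capped to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["SamResult", "sam_statistic", "pooled_scatter", "choose_s0", "sam_call"]

EXHAUSTIVE_LIMIT = 10_000


def _as_array(values) -> tuple[np.ndarray, list]:
    if isinstance(values, pd.DataFrame):
        return values.to_numpy(dtype=float), list(values.index)
    arr = np.asarray(values, dtype=float)
    return arr, list(range(arr.shape[0]))


def _check_labels(labels, n_cols: int) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.shape[0] != n_cols:
        raise ValueError(f"{lab.shape[0]} labels for {n_cols} samples")
    uniq = np.unique(lab)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {list(uniq)}")
    binary = (lab == uniq[1]).astype(bool)
    if binary.sum() < 2 or (~binary).sum() < 2:
        raise ValueError("each class needs >= 2 samples")
    return binary


def pooled_scatter(values, labels) -> np.ndarray:
    """Gene-specific scatter s: pooled standard error of the mean difference."""
    arr, _ = _as_array(values)
    treated = _check_labels(labels, arr.shape[1])
    a, b = arr[:, treated], arr[:, ~treated]
    n1, n2 = a.shape[1], b.shape[1]
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def sam_statistic(values, labels, s0: float = 0.0) -> np.ndarray:
    """Relative difference d = (mean_treated - mean_control) / (s + s0).

    ``labels``: the lexicographically larger label is "treated". With
    s0 = 0 this is exactly the pooled-variance t statistic.
    """
    arr, _ = _as_array(values)
    treated = _check_labels(labels, arr.shape[1])
    diff = arr[:, treated].mean(axis=1) - arr[:, ~treated].mean(axis=1)
    s = pooled_scatter(arr, labels)
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return d


def choose_s0(values, labels, n_windows: int = 100) -> float:
    """Fudge factor minimising the CV of the d spread across s windows.

    Candidates are the 0th..100th percentiles of s in steps of 5. For
    each candidate the genes are binned into ``n_windows`` s-quantile
    windows; the spread of d inside each window is its median absolute
    deviation; the candidate with the smallest coefficient of variation
    of those spreads wins. Deterministic. Falls back to median(s) when
    the s distribution is degenerate.
    """
    arr, _ = _as_array(values)
    if arr.shape[0] < 50:
        warnings.warn("choose_s0 on < 50 probes is unstable", RuntimeWarning, stacklevel=2)
    s = pooled_scatter(arr, labels)
    if np.ptp(s) == 0 or not np.isfinite(s).all():
        warnings.warn("degenerate scatter distribution; s0 = median(s)", RuntimeWarning,
                      stacklevel=2)
        return float(np.median(s))
    alphas = np.arange(0, 101, 5) / 100.0
    n_windows = max(2, min(n_windows, arr.shape[0] // 5))
    # s-quantile window assignment is fixed across candidates
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    best_alpha, best_cv = 0.5, math.inf
    for alpha in alphas:
        s0 = float(np.quantile(s, alpha))
        d = sam_statistic(arr, labels, s0=s0)
        spreads = []
        for w in range(n_windows):
            dw = d[window == w]
            if len(dw) >= 2:
                spreads.append(np.median(np.abs(dw - np.median(dw))) / 0.64)
        spreads = np.asarray(spreads)
        if len(spreads) < 2 or spreads.mean() == 0:
            continue
        cv = spreads.std(ddof=1) / spreads.mean()
        if cv < best_cv - 1e-12:
            best_cv, best_alpha = cv, alpha
    return float(np.quantile(s, best_alpha))


def _label_splits(labels: np.ndarray, n_perm: int, seed) -> tuple[np.ndarray, bool]:
    """Boolean matrix of treated-sample assignments, one row per split."""
    n = labels.shape[0]
    n_treated = int(labels.sum())
    total = math.comb(n, n_treated)
    if total <= EXHAUSTIVE_LIMIT:
        splits = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(combinations(range(n), n_treated)):
            splits[i, list(combo)] = True
        return splits, True
    rng = np.random.default_rng(seed)
    splits = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        splits[i, rng.choice(n, size=n_treated, replace=False)] = True
    return splits, False


@dataclass
class SamResult:
    """Outcome of a SAM run at a chosen delta."""

    d: pd.Series                 # observed statistic per gene
    dbar: np.ndarray             # expected order statistics (ascending)
    s0: float
    pi0: float
    delta: float | None          # None when no grid delta met the target
    fdr_at_delta: float | None
    called_up: list
    called_down: list
    delta_table: pd.DataFrame    # delta, n_called, median_fp, fdr (monotonised)
    n_permutations: int
    exhaustive: bool
    seed: int | None
    target_fdr: float = 0.10

    @property
    def called(self) -> list:
        return list(self.called_up) + list(self.called_down)

    def directions(self) -> dict:
        out = {g: "up" for g in self.called_up}
        out.update({g: "down" for g in self.called_down})
        return out


def _cutpoints(d_sorted: np.ndarray, dbar: np.ndarray, delta: float) -> tuple[float, float]:
    """First-crossing cut rule: smallest d with d - dbar >= delta (upper),
    largest d with dbar - d >= delta (lower)."""
    diff = d_sorted - dbar
    up_idx = np.nonzero(diff >= delta)[0]
    cutup = d_sorted[up_idx[0]] if len(up_idx) else math.inf
    low_idx = np.nonzero(diff <= -delta)[0]
    cutlow = d_sorted[low_idx[-1]] if len(low_idx) else -math.inf
    return cutup, cutlow


def sam_call(
    values,
    labels,
    target_fdr: float = 0.10,
    n_perm: int = 500,
    seed: int | None = None,
    s0: float | None = None,
    n_delta: int = 100,
) -> SamResult:
    """Full SAM run: statistic, permutation null, delta search at target FDR.

    Label splits are enumerated exhaustively when there are at most
    10,000 of them (then the result does not depend on ``seed``);
    otherwise ``n_perm`` random splits are drawn.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 (or exhaustive)")
    arr, ids = _as_array(values)
    treated = _check_labels(labels, arr.shape[1])
    if s0 is None:
        s0 = choose_s0(arr, labels)
    if s0 < 0:
        raise ValueError(f"s0 must be >= 0, got {s0}")

    d = sam_statistic(arr, labels, s0=s0)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]

    splits, exhaustive = _label_splits(treated, n_perm, seed)
    b = splits.shape[0]
    perm_sorted = np.empty((b, arr.shape[0]))
    for i in range(b):
        perm_sorted[i] = np.sort(sam_statistic(arr, splits[i], s0=s0))
    dbar = perm_sorted.mean(axis=0)

    q25, q75 = np.quantile(perm_sorted, [0.25, 0.75])
    pi0 = float(np.clip(((d > q25) & (d < q75)).sum() / (0.5 * len(d)), 0.0, 1.0))

    max_spread = float(np.max(np.abs(d_sorted - dbar))) if len(d) else 0.0
    deltas = np.linspace(0.0, max_spread, n_delta)

    n_called = np.zeros(n_delta, dtype=int)
    med_fp = np.zeros(n_delta)
    fdr_raw = np.zeros(n_delta)
    cuts = [( _cutpoints(d_sorted, dbar, dl)) for dl in deltas]
    cutups = np.array([c[0] for c in cuts])
    cutlows = np.array([c[1] for c in cuts])
    # per permutation row (sorted), count values beyond each cut via searchsorted
    # beyond-cut counts are unions: when the cut regions overlap at tiny
    # delta a value must not be counted twice
    fp = np.zeros((b, n_delta))
    p = arr.shape[0]
    finite_up = np.where(np.isfinite(cutups), cutups, np.inf)
    finite_low = np.where(np.isfinite(cutlows), cutlows, -np.inf)
    for i in range(b):
        row = perm_sorted[i]
        inside = np.searchsorted(row, finite_up, side="left") - np.searchsorted(
            row, finite_low, side="right"
        )
        fp[i] = p - np.clip(inside, 0, None)
    med_fp = np.median(fp, axis=0)
    for k, dl in enumerate(deltas):
        beyond = (d_sorted >= cutups[k]) | (d_sorted <= cutlows[k])
        n_called[k] = int(beyond.sum())
        fdr_raw[k] = (med_fp[k] * pi0 / n_called[k]) if n_called[k] > 0 else 0.0
    fdr_mono = np.minimum.accumulate(fdr_raw)

    table = pd.DataFrame(
        {"delta": deltas, "n_called": n_called, "median_fp": med_fp, "fdr": fdr_mono}
    )

    ids_sorted = [ids[i] for i in order]
    chosen = None
    for k in range(n_delta):
        if fdr_mono[k] <= target_fdr and n_called[k] > 0:
            chosen = k
            break
    if chosen is None:
        called_up: list = []
        called_down: list = []
        delta = None
        fdr_at = None
    else:
        delta = float(deltas[chosen])
        fdr_at = float(fdr_mono[chosen])
        up_mask = d_sorted >= cutups[chosen]
        down_mask = d_sorted <= cutlows[chosen]
        overlap = up_mask & down_mask  # only when the cut regions overlap
        if overlap.any():
            up_mask = up_mask & ~(overlap & (d_sorted < 0))
            down_mask = down_mask & ~(overlap & (d_sorted >= 0))
        called_up = [g for g, m in zip(ids_sorted, up_mask) if m]
        called_down = [g for g, m in zip(ids_sorted, down_mask) if m]

    return SamResult(
        d=pd.Series(d, index=ids),
        dbar=dbar,
        s0=float(s0),
        pi0=pi0,
        delta=delta,
        fdr_at_delta=fdr_at,
        called_up=called_up,
        called_down=called_down,
        delta_table=table,
        n_permutations=b,
        exhaustive=exhaustive,
        seed=seed,
        target_fdr=target_fdr,
    )
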