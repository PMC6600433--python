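"""Spot-level miRNA array preprocessing.

The chain, applied to a batch of GenePix-style spot tables:

1. spot intensity = foreground median - background median;
2. per-array detection threshold T = 10% trimmed mean of the
   negative-control spot intensities + 5 x background-region SD (raw
   units), carried into log2 as log2(T);
3. log2 transform (non-positive intensities become missing);
4. per-array normalization factor N = 20% trimmed mean of the log2 spot
   intensities over the probes detected (above T) in every array;
5. normalization: subtract the array's N, add back the grand mean of N;
6. triplicate collapse: per probe per array, mean of unflagged spots;
7. detection filter: keep probes above T in all samples of at least one
   treatment group.

Trimmed means remove the trim fraction from each tail, truncating
fractional tail counts (the scipy convention). Threshold comparisons
are strict (> T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .synthetic_data import SpotTable

__all__ = [
    "DetectionThreshold",
    "ProbeIntensityMatrix",
    "spot_intensity",
    "detection_threshold",
    "log2_transform",
    "normalization_factor",
    "normalize",
    "collapse_triplicates",
    "detection_filter",
    "preprocess_mirna",
]


@dataclass(frozen=True)
class DetectionThreshold:
    array_id: str
    t_raw: float
    t_log2: float


@dataclass
class ProbeIntensityMatrix:
    """Probe x array mean log2 intensities after triplicate collapse."""

    values: pd.DataFrame            # probes x arrays, NaN where no spot survived
    n_spots: pd.DataFrame           # contributing (unflagged, non-missing) spot counts
    thresholds: dict[str, float]    # array id -> T on the same (normalized) log2 scale


def spot_intensity(spots: pd.DataFrame) -> pd.Series:
    """Background-subtracted raw intensity per spot (may be <= 0)."""
    return spots["F_Median"] - spots["B_Median"]


def detection_threshold(
    array: SpotTable, trim: float = 0.10, k_sd: float = 5.0
) -> DetectionThreshold:
    """T = trimmed mean of negative-control intensities + k_sd x background SD."""
    ctrl = array.spots[array.spots["ControlType"] == 1]
    if len(ctrl) == 0:
        raise ValueError(f"array {array.array_id}: no negative-control spots")
    intensities = spot_intensity(ctrl).to_numpy(dtype=float)
    t_raw = float(trim_mean(intensities, trim) + k_sd * array.background_sd)
    if t_raw <= 0:
        raise ValueError(
            f"array {array.array_id}: detection threshold {t_raw} <= 0, cannot log-transform"
        )
    return DetectionThreshold(array_id=array.array_id, t_raw=t_raw, t_log2=float(np.log2(t_raw)))


def log2_transform(values) -> np.ndarray | pd.Series | pd.DataFrame:
    """log2 of positive values; non-positive values become NaN."""
    arr = np.asarray(values, dtype=float)
    out = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def _probe_spot_log2(array: SpotTable) -> pd.DataFrame:
    """Non-control spots with log2 intensity; flagged spots retained but marked."""
    spots = array.spots[array.spots["ControlType"] == 0].copy()
    spots["log2_intensity"] = log2_transform(spot_intensity(spots))
    return spots


def normalization_factor(
    arrays: list[SpotTable],
    thresholds: dict[str, DetectionThreshold],
    trim: float = 0.20,
) -> dict[str, float]:
    """Per-array N = trimmed mean of log2 spot intensities on the common-detected probe set.

    A probe counts as detected in an array when the mean of its unflagged
    log2 spot intensities exceeds that array's T (log2). The common set is
    probes detected in every array.
    """
    per_array: dict[str, pd.DataFrame] = {}
    detected_sets: list[set[str]] = []
    for arr in arrays:
        spots = _probe_spot_log2(arr)
        per_array[arr.array_id] = spots
        ok = spots[(spots["Flags"] == 0) & spots["log2_intensity"].notna()]
        probe_means = ok.groupby("Name")["log2_intensity"].mean()
        detected_sets.append(set(probe_means.index[probe_means > thresholds[arr.array_id].t_log2]))
    common = set.intersection(*detected_sets) if detected_sets else set()
    if not common:
        counts = ", ".join(f"{a.array_id}: {len(s)}" for a, s in zip(arrays, detected_sets))
        raise ValueError(f"no probe is detected in all arrays (per-array detected counts: {counts})")
    factors: dict[str, float] = {}
    for arr in arrays:
        spots = per_array[arr.array_id]
        sel = spots[
            spots["Name"].isin(common) & (spots["Flags"] == 0) & spots["log2_intensity"].notna()
        ]
        factors[arr.array_id] = float(trim_mean(sel["log2_intensity"].to_numpy(), trim))
    return factors


def normalize(
    arrays: list[SpotTable],
    thresholds: dict[str, DetectionThreshold],
    factors: dict[str, float],
) -> tuple[dict[str, pd.DataFrame], dict[str, float]]:
    """Center each array at the grand-mean N; thresholds move with the data.

    Returns per-array spot frames (with a ``normalized`` column) and the
    per-array normalized log2 thresholds.
    """
    grand = float(np.mean(list(factors.values())))
    out: dict[str, pd.DataFrame] = {}
    t_norm: dict[str, float] = {}
    for arr in arrays:
        spots = _probe_spot_log2(arr)
        spots["normalized"] = spots["log2_intensity"] - factors[arr.array_id] + grand
        out[arr.array_id] = spots
        t_norm[arr.array_id] = thresholds[arr.array_id].t_log2 - factors[arr.array_id] + grand
    return out, t_norm


def collapse_triplicates(
    normalized: dict[str, pd.DataFrame], thresholds_norm: dict[str, float]
) -> ProbeIntensityMatrix:
    """Mean over unflagged, non-missing spots per probe per array."""
    means, counts = {}, {}
    for array_id, spots in normalized.items():
        ok = spots[(spots["Flags"] == 0) & spots["normalized"].notna()]
        means[array_id] = ok.groupby("Name")["normalized"].mean()
        counts[array_id] = ok.groupby("Name")["normalized"].size()
    all_probes = sorted(set().union(*(spots["Name"].unique() for spots in normalized.values())))
    values = pd.DataFrame(means).reindex(all_probes)
    n_spots = pd.DataFrame(counts).reindex(all_probes).fillna(0).astype(int)
    return ProbeIntensityMatrix(values=values, n_spots=n_spots, thresholds=dict(thresholds_norm))


def detection_filter(
    matrix: ProbeIntensityMatrix, design: dict[str, str] | pd.Series
) -> list[str]:
    """Probes above T in every sample of at least one treatment group.

    ``design`` maps array id -> treatment group. Missing cells count as
    not-above. Comparison is strict.
    """
    design = pd.Series(design)
    if design.empty:
        raise ValueError("design has no samples: every treatment group is empty")
    unknown = set(design.index) - set(matrix.values.columns)
    if unknown:
        raise ValueError(f"design names arrays absent from the matrix: {sorted(unknown)}")
    groups = design.groupby(design).groups
    for g, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"treatment group {g!r} is empty")
    t = pd.Series(matrix.thresholds)
    above = matrix.values.gt(t, axis=1) & matrix.values.notna()
    retained = []
    for probe in matrix.values.index:
        row = above.loc[probe]
        if any(bool(row[list(members)].all()) for members in groups.values()):
            retained.append(probe)
    return retained


def preprocess_mirna(
    arrays: list[SpotTable],
    design: dict[str, str] | None = None,
    trim_neg: float = 0.10,
    k_sd: float = 5.0,
    trim_norm: float = 0.20,
) -> tuple[ProbeIntensityMatrix, list[str], pd.DataFrame]:
    """Full chain; returns the collapsed matrix, the detected probe list,
    and a per-array QC frame (T raw/log2, N, detected count)."""
    if design is None:
        design = {a.array_id: a.group for a in arrays}
    thresholds = {a.array_id: detection_threshold(a, trim=trim_neg, k_sd=k_sd) for a in arrays}
    factors = normalization_factor(arrays, thresholds, trim=trim_norm)
    normalized, t_norm = normalize(arrays, thresholds, factors)
    matrix = collapse_triplicates(normalized, t_norm)
    retained = detection_filter(matrix, design)
    above = matrix.values.gt(pd.Series(matrix.thresholds), axis=1)
    qc = pd.DataFrame(
        {
            "T_raw": {a: thresholds[a].t_raw for a in thresholds},
            "T_log2": {a: thresholds[a].t_log2 for a in thresholds},
            "N": pd.Series(factors),
            "n_detected": above.sum(axis=0),
        }
    )
    qc.index.name = "array_id"
    return matrix, retained, qc
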