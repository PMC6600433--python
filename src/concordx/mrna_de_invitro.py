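"""In vitro two-channel array DE: masking, filtering, imputation, SAM.

The input is a long feature table (one row per probe x sample) carrying
the log2 ratio and per-channel QC columns. The chain:

1. mask unreliable values to NA (control spots; saturated or
   non-uniform on either channel; not above background on at least one
   channel), each with a reason code;
2. drop probes with fewer than ``min_present`` present values across
   the collated table;
3. average replicate probes per gene-level probe (NA-omitting);
4. impute remaining NAs by k-nearest-neighbour over probes (Euclidean
   distance over co-present samples, rescaled by the co-present
   fraction);
5. per contrast, call significance with two-class unpaired SAM at the
   target FDR, then intersect with |fold change| >= fc where the fold
   change comes from PRE-imputation group means (NA-omitting).

SAM runs on the imputed matrix (it needs complete data); fold changes
and directions never see imputed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .mrna_de_invivo import DEResult
from .sam_stats import SamResult, sam_call

__all__ = [
    "QC_COLUMNS",
    "REASONS",
    "mask_unreliable",
    "filter_min_present",
    "average_replicate_probes",
    "knn_impute",
    "de_invitro_contrast",
    "de_invitro",
]

QC_COLUMNS = (
    "ControlType",
    "Saturated_ch1",
    "Saturated_ch2",
    "NonUniform_ch1",
    "NonUniform_ch2",
    "AboveBG_ch1",
    "AboveBG_ch2",
)

REASONS = ("control spot", "saturated", "non-uniform outlier", "not above background", "present")


def mask_unreliable(feature_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NA-mask unreliable values; returns (wide value matrix, reason matrix).

    Rules, in priority order: control spot; saturated on either channel;
    non-uniform outlier on either channel; not above background on at
    least one channel. Everything else is "present".
    """
    missing = [c for c in QC_COLUMNS if c not in feature_table.columns]
    if missing:
        raise ValueError(f"feature table lacks QC column(s): {missing}")
    t = feature_table
    reason = np.full(len(t), "present", dtype=object)
    above = (t["AboveBG_ch1"].astype(bool)) | (t["AboveBG_ch2"].astype(bool))
    reason[~above.to_numpy()] = "not above background"
    nonuni = t["NonUniform_ch1"].astype(bool) | t["NonUniform_ch2"].astype(bool)
    reason[nonuni.to_numpy()] = "non-uniform outlier"
    sat = t["Saturated_ch1"].astype(bool) | t["Saturated_ch2"].astype(bool)
    reason[sat.to_numpy()] = "saturated"
    reason[t["ControlType"].astype(bool).to_numpy()] = "control spot"

    masked = t[["probe", "sample", "value"]].copy()
    masked["reason"] = reason
    masked.loc[masked["reason"] != "present", "value"] = np.nan
    values = masked.pivot(index="probe", columns="sample", values="value")
    reasons = masked.pivot(index="probe", columns="sample", values="reason")
    return values, reasons


def filter_min_present(values: pd.DataFrame, min_present: int = 10) -> tuple[list, int]:
    """Retain probes with at least ``min_present`` non-NA values."""
    present = values.notna().sum(axis=1)
    keep = values.index[present >= min_present]
    return list(keep), int(len(values) - len(keep))


def average_replicate_probes(
    values: pd.DataFrame, probe_to_gene: dict | pd.Series | None = None
) -> pd.DataFrame:
    """NA-omitting mean over replicate probes of the same target."""
    if probe_to_gene is None:
        return values
    mapping = pd.Series(probe_to_gene)
    groups = values.index.map(mapping)
    return values.groupby(groups, sort=True).mean()


def knn_impute(values: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Replace each NA by the mean of the k nearest probes at that sample.

    Distances are NaN-aware Euclidean over co-present samples, rescaled
    by the fraction of co-present columns. Present values pass through
    untouched.
    """
    n_usable = int((values.notna().sum(axis=1) > 0).sum())
    if k >= n_usable:
        raise ValueError(f"k={k} >= {n_usable} probes with data")
    if not values.isna().any().any():
        return values.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    out = imputer.fit_transform(values.to_numpy(dtype=float))
    return pd.DataFrame(out, index=values.index, columns=values.columns)


@dataclass
class InVitroContrast:
    """SAM + pre-imputation fold change for one treated-vs-control contrast."""

    contrast: str
    sam: SamResult
    table: pd.DataFrame  # log2fc, fold_change, direction, sam_called, called, excluded


def de_invitro_contrast(
    imputed: pd.DataFrame,
    pre_imputation: pd.DataFrame,
    treated: list,
    control: list,
    fdr: float = 0.10,
    fc: float = 1.5,
    n_perm: int = 500,
    seed: int | None = None,
    contrast: str = "",
) -> InVitroContrast:
    """Call one contrast: SAM on imputed data, FC gate on pre-imputation data."""
    labels = np.array([1] * len(treated) + [0] * len(control))
    sam = sam_call(imputed[treated + control], labels, target_fdr=fdr, n_perm=n_perm, seed=seed)

    m_t = pre_imputation[treated].mean(axis=1, skipna=True)
    m_c = pre_imputation[control].mean(axis=1, skipna=True)
    lfc = m_t - m_c
    excluded = lfc.isna()  # a group all-NA for this probe: no defensible fold change
    fold = np.sign(lfc) * 2.0 ** lfc.abs()
    fold = fold.where(lfc != 0, 1.0)
    direction = pd.Series(np.where(lfc >= 0, "up", "down"), index=lfc.index)

    sam_called = pd.Series(False, index=pre_imputation.index)
    sam_called.loc[[g for g in sam.called if g in sam_called.index]] = True
    called = sam_called & (fold.abs() >= fc) & ~excluded
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "fold_change": fold,
            "direction": direction,
            "sam_called": sam_called,
            "called": called,
            "excluded": excluded,
        }
    )
    return InVitroContrast(contrast=contrast, sam=sam, table=table)


def de_invitro(
    feature_table: pd.DataFrame,
    design: pd.DataFrame,
    control_group: str = "DM",
    treated_group: str = "MWCNT",
    strata: tuple[str, ...] = ("cell_type", "time"),
    min_present: int = 10,
    k: int = 10,
    fdr: float = 0.10,
    fc: float = 1.5,
    n_perm: int = 500,
    seed: int | None = None,
    probe_to_gene: dict | None = None,
) -> dict[tuple, DEResult]:
    """Full in vitro chain over every stratum (default: cell type x time).

    Masking, the min-present filter, replicate averaging and imputation
    run once on the collated table; SAM and the fold-change gate run per
    stratum against its own control samples. Returns one ``DEResult``
    per stratum keyed by the stratum tuple.
    """
    values, _ = mask_unreliable(feature_table)
    keep, _ = filter_min_present(values, min_present=min_present)
    values = values.loc[keep]
    values = average_replicate_probes(values, probe_to_gene)
    imputed = knn_impute(values, k=k)

    results: dict[tuple, DEResult] = {}
    for key, sub in design.groupby(list(strata), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        treated = [s for s in sub.index[sub["group"] == treated_group] if s in values.columns]
        control = [s for s in sub.index[sub["group"] == control_group] if s in values.columns]
        if len(treated) < 2 or len(control) < 2:
            raise ValueError(f"stratum {key}: needs >= 2 samples per class")
        res = de_invitro_contrast(
            imputed,
            values,
            treated,
            control,
            fdr=fdr,
            fc=fc,
            n_perm=n_perm,
            seed=seed,
            contrast="_".join(str(k_) for k_ in key),
        )
        table = res.table.rename(columns={"sam_called": "sam_significant"})
        table["p"] = np.nan  # SAM is permutation-based; no per-probe p-value
        table["q"] = np.nan
        results[key] = DEResult(contrast=res.contrast, table=table)
    return results
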