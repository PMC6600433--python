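"""In vivo differential expression: variance filter + per-contrast ANOVA.

Each treatment group is compared with the vehicle (DM) control of the
same time point by a two-group one-way ANOVA — the F statistic is the
square of the pooled-variance t statistic. Calls require all three of
p < alpha, Benjamini-Hochberg q <= fdr (within contrast), and linear
fold change >= fc in either direction.

The variance filter removes probes whose across-sample variance EXCEEDS
the cutoff. That direction is deliberate: it mirrors the upstream QC
rule this pipeline reproduces, where the rule was vacuous on real data
(all probes fell below the cutoff); here it is a config value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import ExprMatrix

__all__ = ["DEResult", "variance_filter", "contrast_test", "call_de", "de_invivo"]


@dataclass
class DEResult:
    """Per-probe calls for one contrast (treated group vs control)."""

    contrast: str
    table: pd.DataFrame  # columns: log2fc, fold_change, direction, p, q, called

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["called"]]

    def write(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "contrast", self.contrast)
        out.to_csv(path, sep="\t")


def variance_filter(values: pd.DataFrame, cutoff: float = 0.2) -> tuple[list[str], int]:
    """Retain probes with across-sample variance <= cutoff.

    Returns (retained probe ids, number removed). Sample variance uses
    ddof=1; NaNs are ignored.
    """
    if values.shape[1] < 2:
        raise ValueError("variance filter needs >= 2 samples")
    var = values.var(axis=1, ddof=1, skipna=True)
    keep = var.index[var <= cutoff]
    return list(keep), int(len(values) - len(keep))


def contrast_test(
    values: pd.DataFrame, treated: list[str], control: list[str]
) -> pd.DataFrame:
    """Two-group one-way ANOVA per probe; F = pooled-t squared.

    Returns a frame with log2fc (mean treated - mean control), signed
    linear fold_change, direction, and the F-test p-value. Probes with
    zero pooled variance get p = 1 with a warning.
    """
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("each side of the contrast needs >= 2 samples")
    a = values[treated].to_numpy(dtype=float)
    b = values[control].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    ss1 = ((a - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((b - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    pooled = (ss1 + ss2) / df
    lfc = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = lfc**2 / (pooled * (1.0 / n1 + 1.0 / n2))
    p = stats.f.sf(f, 1, df)
    degenerate = pooled == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} probe(s) with zero pooled variance; p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.where(degenerate, 1.0, p)
    direction = np.where(lfc >= 0, "up", "down")
    fold = np.sign(lfc) * 2.0 ** np.abs(lfc)
    fold = np.where(lfc == 0, 1.0, fold)
    return pd.DataFrame(
        {"log2fc": lfc, "fold_change": fold, "direction": direction, "p": p},
        index=values.index,
    )


def call_de(
    stats_table: pd.DataFrame,
    alpha: float = 0.05,
    fdr: float = 0.10,
    fc: float = 1.5,
    contrast: str = "",
) -> DEResult:
    """Apply the three-rule calling: p < alpha, BH q <= fdr, |FC| >= fc."""
    table = stats_table.copy()
    _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["q"] = q
    table["called"] = (
        (table["p"] < alpha) & (table["q"] <= fdr) & (table["fold_change"].abs() >= fc)
    )
    return DEResult(contrast=contrast, table=table)


def de_invivo(
    matrix: ExprMatrix,
    control_group: str,
    treatment_groups: list[str] | None = None,
    alpha: float = 0.05,
    fdr: float = 0.10,
    fc: float = 1.5,
    variance_cutoff: float = 0.2,
    apply_variance_filter: bool = False,
) -> dict[str, DEResult]:
    """Run every (treatment group vs control) contrast on one matrix.

    The matrix is assumed to hold samples from a single time point and
    compartment; the caller loops over those strata. The variance filter
    is off by default (it is a QC knob, not part of every design).
    """
    values = matrix.values
    if apply_variance_filter:
        keep, _ = variance_filter(values, cutoff=variance_cutoff)
        values = values.loc[keep]
    if treatment_groups is None:
        treatment_groups = [
            g for g in matrix.design["group"].unique() if g != control_group
        ]
    control = matrix.samples_in_group(control_group)
    results: dict[str, DEResult] = {}
    for g in treatment_groups:
        treated = matrix.samples_in_group(g)
        st = contrast_test(values, treated, control)
        results[g] = call_de(st, alpha=alpha, fdr=fdr, fc=fc, contrast=f"{g}_vs_{control_group}")
    return results
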