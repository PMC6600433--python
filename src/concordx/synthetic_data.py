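"""Synthetic microarray experiments with known planted effects.

Three generators cover the data shapes the pipeline consumes:

* spot-level miRNA arrays (GenePix-style tables, triplicate spots,
  negative controls, quality flags),
* probe-level log2 mRNA expression matrices (in vivo: complete;
  in vitro: log-ratios with missing values),
* human-mouse ortholog maps with the three relation classes.

Every generator is deterministic given its seed and returns the planted
ground truth alongside the data, so downstream stages can be scored for
recovery without any external downloads.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "SpotTable",
    "ExprMatrix",
    "ConfigurationError",
    "simulate_spot_arrays",
    "simulate_expr_matrix",
    "simulate_ortholog_map",
    "simulate_concordance_experiment",
    "ConcordanceSim",
]


class ConfigurationError(ValueError):
    """Raised when a simulation config field is out of its valid range."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic array experiment.

    ``groups`` lists (stratum label, n samples); a stratum is a treatment
    group (in vivo: dose x time; in vitro: cell/culture/exposure/time).
    ``planted_effects`` are (probe id, stratum label, log2 fold change)
    triples applied on top of the probe baseline in that stratum only.
    Intensity units: ``background_mean``/``background_sd`` are raw scanner
    counts; ``noise_sd`` and planted shifts are log2 units.
    """

    n_probes: int
    groups: Sequence[tuple[str, int]]
    n_negative_controls: int = 16
    spots_per_probe: int = 3
    planted_effects: Sequence[tuple[str, str, float]] = ()
    noise_sd: float = 0.25
    background_mean: float = 100.0
    background_sd: float = 10.0
    flag_rate: float = 0.0
    na_rate: float = 0.0
    frac_undetectable: float = 0.0
    baseline_log2_range: tuple[float, float] = (6.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_negative_controls", "spots_per_probe"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.groups:
            raise ConfigurationError("groups must be non-empty")
        for label, n in self.groups:
            if n <= 0:
                raise ConfigurationError(f"group {label!r} has non-positive size {n}")
        for name in ("flag_rate", "na_rate", "frac_undetectable"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        labels = {lab for lab, _ in self.groups}
        probes = set(self.probe_ids())
        for probe, stratum, _ in self.planted_effects:
            if stratum not in labels:
                raise ConfigurationError(f"planted effect stratum {stratum!r} not in groups")
            if probe not in probes:
                raise ConfigurationError(f"planted probe {probe!r} not in probe universe")

    def probe_ids(self) -> list[str]:
        return [f"probe_{i:05d}" for i in range(self.n_probes)]

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: per-stratum up/down gene sets."""

    up: dict[str, set[str]] = field(default_factory=dict)
    down: dict[str, set[str]] = field(default_factory=dict)

    def add(self, stratum: str, probe: str, lfc: float) -> None:
        target = self.up if lfc > 0 else self.down
        target.setdefault(stratum, set()).add(probe)

    def validate(self) -> None:
        for stratum in set(self.up) | set(self.down):
            overlap = self.up.get(stratum, set()) & self.down.get(stratum, set())
            if overlap:
                raise ValueError(f"up/down overlap in {stratum!r}: {sorted(overlap)}")


@dataclass
class SpotTable:
    """One array's spot-level measurements in a GenePix-like layout.

    ``spots`` columns: Block, Row, Column, Name, F_Median, B_Median,
    Flags (1 = poor quality), ControlType (1 = negative control).
    ``background_sd`` is the scanner's non-spot-area background SD (raw).
    """

    array_id: str
    group: str
    spots: pd.DataFrame
    background_sd: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# array_id={self.array_id}\n")
            fh.write(f"# group={self.group}\n")
            fh.write(f"# background_sd={self.background_sd!r}\n")
            self.spots.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpotTable":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            spots = pd.read_csv(fh, sep="\t")
        return cls(
            array_id=meta["array_id"],
            group=meta.get("group", ""),
            spots=spots,
            background_sd=float(meta["background_sd"]),
        )


@dataclass
class ExprMatrix:
    """Probes x samples log2 expression with sample design metadata.

    Missing values are NaN in ``values``; in vivo matrices are complete.
    ``design`` is indexed by sample id and carries at least a ``group``
    column (plus time/compartment/cell-type columns as appropriate).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.design.index[self.design["group"] == group])

    def write(self, matrix_path, design_path) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        self.design.to_csv(design_path)

    @classmethod
    def read(cls, matrix_path, design_path) -> "ExprMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, index_col=0)
        return cls(values=values, design=design)


def _stable_token(t) -> int:
    if isinstance(t, str):
        return zlib.crc32(t.encode()) % (2**31)
    return int(t)


def _rng_for(seed: int, *tokens) -> np.random.Generator:
    """Deterministic child RNG from a root seed and string/int tokens."""
    key = tuple(_stable_token(t) for t in tokens)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_spot_arrays(config: SimConfig) -> tuple[list[SpotTable], PlantedTruth]:
    """Generate one spot-level array per sample with triplicate spots.

    Raw foreground = background draw + 2**(log2 baseline + planted shift
    + Gaussian noise); negative-control spots carry background plus a
    faint non-specific signal. Flags are Bernoulli per spot. A
    ``frac_undetectable`` fraction of probes is planted at the
    negative-control signal level to exercise the detection filter.
    """
    root = np.random.default_rng(config.seed)
    probes = config.probe_ids()
    baseline = root.uniform(*config.baseline_log2_range, size=config.n_probes)
    n_low = int(round(config.frac_undetectable * config.n_probes))
    # lowest-index probes are demoted to control-level signal
    low_idx = np.arange(n_low)
    baseline[low_idx] = np.log2(2.0)  # ~2 raw counts: indistinguishable from background

    effects: dict[str, dict[str, float]] = {}
    truth = PlantedTruth()
    for probe, stratum, lfc in config.planted_effects:
        effects.setdefault(stratum, {})[probe] = lfc
        truth.add(stratum, probe, lfc)
    truth.validate()

    arrays: list[SpotTable] = []
    array_no = 0
    for group, n_samples in config.groups:
        for rep in range(n_samples):
            rng = _rng_for(config.seed, "spots", array_no)
            array_id = f"array_{array_no:03d}"
            shift = effects.get(group, {})
            n_spots = config.n_probes * config.spots_per_probe + config.n_negative_controls
            bg = np.clip(
                rng.normal(config.background_mean, config.background_sd, size=n_spots), 0, None
            )
            rows = []
            si = 0
            for pi, probe in enumerate(probes):
                mu = baseline[pi] + shift.get(probe, 0.0)
                for s in range(config.spots_per_probe):
                    signal = 2.0 ** (mu + rng.normal(0.0, config.noise_sd))
                    rows.append((1, pi + 1, s + 1, probe, bg[si] + signal, bg[si], 0))
                    si += 1
            for c in range(config.n_negative_controls):
                signal = 2.0 ** rng.normal(1.0, config.noise_sd)
                rows.append((1, 0, c + 1, f"neg_ctrl_{c:03d}", bg[si] + signal, bg[si], 1))
                si += 1
            spots = pd.DataFrame(
                rows,
                columns=["Block", "Row", "Column", "Name", "F_Median", "B_Median", "ControlType"],
            )
            spots["Flags"] = (rng.uniform(size=len(spots)) < config.flag_rate).astype(int)
            spots = spots[
                ["Block", "Row", "Column", "Name", "F_Median", "B_Median", "Flags", "ControlType"]
            ]
            bg_sd = float(np.std(bg, ddof=1)) if len(bg) > 1 else config.background_sd
            arrays.append(
                SpotTable(array_id=array_id, group=group, spots=spots, background_sd=bg_sd)
            )
            array_no += 1
    return arrays, truth


def simulate_expr_matrix(
    config: SimConfig, design: Literal["invivo", "invitro"] = "invivo"
) -> tuple[ExprMatrix, PlantedTruth]:
    """Generate a probe-level log2 expression matrix with planted shifts.

    In vivo matrices mimic RMA-style absolute log2 intensities (complete,
    gene baselines ~N(8, 2)); in vitro matrices are log-ratios against a
    universal reference (baseline 0) and may carry NA at ``na_rate``.
    """
    if design not in ("invivo", "invitro"):
        raise ConfigurationError(f"unknown design {design!r}")
    if design == "invivo" and config.na_rate > 0:
        raise ConfigurationError("in vivo matrices are complete; na_rate must be 0")

    rng = np.random.default_rng(config.seed)
    probes = config.probe_ids()
    if design == "invivo":
        baseline = rng.normal(8.0, 2.0, size=config.n_probes)
    else:
        baseline = np.zeros(config.n_probes)

    effects: dict[str, np.ndarray] = {}
    truth = PlantedTruth()
    index = {p: i for i, p in enumerate(probes)}
    for probe, stratum, lfc in config.planted_effects:
        effects.setdefault(stratum, np.zeros(config.n_probes))[index[probe]] += lfc
        truth.add(stratum, probe, lfc)
    truth.validate()

    cols, groups = [], []
    blocks = []
    for group, n_samples in config.groups:
        shift = effects.get(group, np.zeros(config.n_probes))
        block = (
            baseline[:, None]
            + shift[:, None]
            + rng.normal(0.0, config.noise_sd, size=(config.n_probes, n_samples))
        )
        if config.na_rate > 0:
            mask = rng.uniform(size=block.shape) < config.na_rate
            block = np.where(mask, np.nan, block)
        blocks.append(block)
        for rep in range(n_samples):
            cols.append(f"{group}_s{rep}")
            groups.append(group)
    values = pd.DataFrame(np.hstack(blocks), index=probes, columns=cols)
    design_df = pd.DataFrame({"group": groups}, index=pd.Index(cols, name="sample"))
    return ExprMatrix(values=values, design=design_df), truth


def simulate_ortholog_map(
    n_one_to_one: int,
    n_one_to_many: int = 0,
    n_many_to_many: int = 0,
    seed: int = 0,
    fan_out: int = 2,
) -> pd.DataFrame:
    """Build an ortholog table (human_symbol, mouse_symbol, relation).

    one-to-many clusters have one human symbol mapped to ``fan_out``
    mouse symbols; many-to-many clusters are complete bipartite on
    ``fan_out`` symbols each side. Symbols are disjoint across clusters.
    """
    for name, v in (
        ("n_one_to_one", n_one_to_one),
        ("n_one_to_many", n_one_to_many),
        ("n_many_to_many", n_many_to_many),
    ):
        if v < 0:
            raise ConfigurationError(f"{name} must be >= 0, got {v}")
    if fan_out < 2:
        raise ConfigurationError(f"fan_out must be >= 2, got {fan_out}")
    rows = []
    for i in range(n_one_to_one):
        rows.append((f"HUM1TO1_{i:05d}", f"Mus1to1_{i:05d}", "one-to-one"))
    for i in range(n_one_to_many):
        for j in range(fan_out):
            rows.append((f"HUM1TOM_{i:05d}", f"Mus1tom_{i:05d}_{j}", "one-to-many"))
    for i in range(n_many_to_many):
        for a in range(fan_out):
            for b in range(fan_out):
                rows.append((f"HUMMTOM_{i:05d}_{a}", f"Musmtom_{i:05d}_{b}", "many-to-many"))
    df = pd.DataFrame(rows, columns=["human_symbol", "mouse_symbol", "relation"])
    # deterministic shuffle so row order never encodes the relation class
    rng = np.random.default_rng(seed)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


@dataclass
class ConcordanceSim:
    """A full cross-species synthetic experiment plus its ground truth.

    ``truth_records`` holds the exact set of (gene, compartment,
    cell_type, invivo_time, direction) tuples a perfect concordance
    analysis should emit.
    """

    invivo: dict[tuple[str, str], ExprMatrix]  # (compartment, time) -> matrix
    invitro_table: pd.DataFrame  # long feature table with QC columns
    invitro_design: pd.DataFrame
    orthologs: pd.DataFrame
    truth_records: set[tuple[str, str, str, str, str]]
    mwcnt_groups: tuple[str, ...]
    control_group: str


def _human_symbol(i: int) -> str:
    return f"GENE{i:05d}"


def _mouse_symbol(i: int) -> str:
    return f"Gene{i:05d}"


def simulate_concordance_experiment(
    n_genes: int = 2000,
    n_concordant: int = 12,
    n_discordant: int = 10,
    n_invivo_only: int = 10,
    n_invitro_only: int = 10,
    lfc: float = 1.5,
    noise_sd: float = 0.2,
    n_invivo: int = 8,
    n_invitro: int = 3,
    compartments: Sequence[str] = ("lung",),
    invivo_times: Sequence[str] = ("1mo",),
    cell_types: Sequence[str] = ("SAEC", "HMVEC"),
    invitro_times: Sequence[str] = ("6h", "24h"),
    na_rate: float = 0.03,
    seed: int = 0,
) -> ConcordanceSim:
    """Plant concordant genes plus discordant / one-sided decoys.

    Each concordant gene is shifted by +-``lfc`` in every mouse
    compartment/time (one MWCNT dose group vs DM) and, with the same
    sign, in one human cell type at every in vitro time. Discordant
    decoys get opposite signs across species; one-sided decoys are
    planted on a single side only. All remaining genes are null.
    """
    rng = np.random.default_rng(seed)
    total_planted = n_concordant + n_discordant + n_invivo_only + n_invitro_only
    if total_planted > n_genes:
        raise ConfigurationError("more planted genes than genes")

    idx = rng.permutation(n_genes)
    conc = idx[:n_concordant]
    disc = idx[n_concordant : n_concordant + n_discordant]
    vivo_only = idx[n_concordant + n_discordant : n_concordant + n_discordant + n_invivo_only]
    vitro_only = idx[n_concordant + n_discordant + n_invivo_only : total_planted]

    sign = {int(i): (1.0 if rng.uniform() < 0.5 else -1.0) for i in idx[:total_planted]}
    conc_cell = {int(i): cell_types[int(rng.integers(len(cell_types)))] for i in conc}
    vitro_only_cell = {int(i): cell_types[int(rng.integers(len(cell_types)))] for i in vitro_only}

    control, dose = "DM", "MWCNT_10ug"

    invivo: dict[tuple[str, str], ExprMatrix] = {}
    for comp in compartments:
        for t in invivo_times:
            planted = []
            for i in conc:
                planted.append((f"probe_{i:05d}", dose, sign[int(i)] * lfc))
            for i in disc:
                planted.append((f"probe_{i:05d}", dose, sign[int(i)] * lfc))
            for i in vivo_only:
                planted.append((f"probe_{i:05d}", dose, sign[int(i)] * lfc))
            cfg = SimConfig(
                n_probes=n_genes,
                groups=[(control, n_invivo), (dose, n_invivo)],
                planted_effects=planted,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
            )
            mat, _ = simulate_expr_matrix(cfg, design="invivo")
            # rename probes to mouse gene symbols
            mat.values.index = [_mouse_symbol(i) for i in range(n_genes)]
            mat.design["time"] = t
            mat.design["compartment"] = comp
            invivo[(comp, t)] = mat

    # in vitro: one collated feature table across cell types / times
    frames, designs = [], []
    for cell in cell_types:
        for t in invitro_times:
            planted = []
            for i in conc:
                if conc_cell[int(i)] == cell:
                    planted.append((f"probe_{i:05d}", "MWCNT", sign[int(i)] * lfc))
            for i in disc:
                planted.append((f"probe_{i:05d}", "MWCNT", -sign[int(i)] * lfc))
            for i in vitro_only:
                if vitro_only_cell[int(i)] == cell:
                    planted.append((f"probe_{i:05d}", "MWCNT", sign[int(i)] * lfc))
            cfg = SimConfig(
                n_probes=n_genes,
                groups=[("DM", n_invitro), ("MWCNT", n_invitro)],
                planted_effects=planted,
                noise_sd=noise_sd,
                na_rate=0.0,  # NA is injected via the QC columns below
                seed=int(rng.integers(2**31)),
            )
            mat, _ = simulate_expr_matrix(cfg, design="invitro")
            mat.values.index = [_human_symbol(i) for i in range(n_genes)]
            mat.values.columns = [f"{cell}_{t}_{c}" for c in mat.values.columns]
            d = mat.design.copy()
            d.index = mat.values.columns
            d.index.name = "sample"
            d["cell_type"] = cell
            d["culture"] = "co"
            d["time"] = t
            frames.append(mat.values)
            designs.append(d)
    values = pd.concat(frames, axis=1)
    design = pd.concat(designs, axis=0)

    # long feature table with QC columns; "not above background" carries na_rate
    long = values.stack(future_stack=True).rename("value").reset_index()
    long.columns = ["probe", "sample", "value"]
    n = len(long)
    long["ControlType"] = 0
    long["Saturated_ch1"] = 0
    long["Saturated_ch2"] = 0
    long["NonUniform_ch1"] = 0
    long["NonUniform_ch2"] = 0
    below = rng.uniform(size=n) < na_rate
    long["AboveBG_ch1"] = (~below).astype(int)
    long["AboveBG_ch2"] = 0  # reference channel dim: "at least one channel" rule decides

    truth_records: set[tuple[str, str, str, str, str]] = set()
    for i in conc:
        d = "up" if sign[int(i)] > 0 else "down"
        for comp in compartments:
            for t in invivo_times:
                truth_records.add((_human_symbol(i), comp, conc_cell[int(i)], t, d))

    orthologs = pd.DataFrame(
        {
            "human_symbol": [_human_symbol(i) for i in range(n_genes)],
            "mouse_symbol": [_mouse_symbol(i) for i in range(n_genes)],
            "relation": "one-to-one",
        }
    )
    return ConcordanceSim(
        invivo=invivo,
        invitro_table=long,
        invitro_design=design,
        orthologs=orthologs,
        truth_records=truth_records,
        mwcnt_groups=(dose,),
        control_group=control,
    )
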