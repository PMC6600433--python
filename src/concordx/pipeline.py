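"""End-to-end orchestration: simulate -> preprocess -> DE -> concordance.

One structured YAML config drives a full synthetic run. A single
top-level seed is supplied; each stage derives its own seed from it via
a CRC-based hash of the stage name, so any stage can be re-run in
isolation and reproduce its output. The run emits a manifest (config
hash, per-stage seeds, row counts) and is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import mirna_preprocess, mrna_de_invitro, mrna_de_invivo, ortholog_concordance
from .synthetic_data import SimConfig, simulate_concordance_experiment, simulate_spot_arrays

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; paper-derived thresholds are defaults."""

    out_dir: str = "concordx_run"
    seed: int = 0
    # generator scale
    n_genes: int = 600
    n_concordant: int = 8
    n_discordant: int = 6
    n_invivo_only: int = 6
    n_invitro_only: int = 6
    lfc: float = 1.5
    noise_sd: float = 0.2
    n_invivo: int = 8
    n_invitro: int = 3
    # miRNA spot-array demo stage
    n_mirna_probes: int = 300
    mirna_groups: tuple = (("DM", 4), ("MWCNT_10ug", 4))
    # thresholds
    alpha: float = 0.05
    fdr: float = 0.10
    fc: float = 1.5
    variance_cutoff: float = 0.2
    min_present: int = 10
    knn_k: int = 10
    trim_neg: float = 0.10
    k_sd: float = 5.0
    trim_norm: float = 0.20
    n_perm: int = 500
    doses: list | None = None

    def __post_init__(self) -> None:
        checks = {
            "alpha": 0 < self.alpha < 1,
            "fdr": 0 < self.fdr < 1,
            "fc": self.fc >= 1,
            "min_present": self.min_present >= 1,
            "knn_k": self.knn_k >= 1,
            "trim_neg": 0 <= self.trim_neg < 0.5,
            "trim_norm": 0 <= self.trim_norm < 0.5,
            "k_sd": self.k_sd >= 0,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"config field(s) out of range: {bad}")
        self.mirna_groups = tuple((str(g), int(n)) for g, n in self.mirna_groups)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._plain(), fh, sort_keys=True)

    def _plain(self) -> dict:
        d = asdict(self)
        d["mirna_groups"] = [list(g) for g in self.mirna_groups]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self._plain(), sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Documented derivation of per-stage seeds from the top-level seed."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on synthetic data; return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.digest(), "seeds": {}, "counts": {}, "stages": []}

    def stage(name: str) -> int:
        s = stage_seed(config.seed, name)
        manifest["seeds"][name] = s
        manifest["stages"].append(name)
        return s

    try:
        # --- simulate the cross-species mRNA experiment -------------------
        s = stage("simulate")
        sim = simulate_concordance_experiment(
            n_genes=config.n_genes,
            n_concordant=config.n_concordant,
            n_discordant=config.n_discordant,
            n_invivo_only=config.n_invivo_only,
            n_invitro_only=config.n_invitro_only,
            lfc=config.lfc,
            noise_sd=config.noise_sd,
            n_invivo=config.n_invivo,
            n_invitro=config.n_invitro,
            seed=s,
        )
        manifest["counts"]["simulate_genes"] = config.n_genes

        # --- miRNA spot-array demo stage ----------------------------------
        s = stage("mirna_spots")
        mirna_cfg = SimConfig(
            n_probes=config.n_mirna_probes,
            groups=list(config.mirna_groups),
            noise_sd=0.25,
            flag_rate=0.02,
            frac_undetectable=0.1,
            seed=s,
        )
        arrays, _ = simulate_spot_arrays(mirna_cfg)
        matrix, retained, qc = mirna_preprocess.preprocess_mirna(
            arrays,
            trim_neg=config.trim_neg,
            k_sd=config.k_sd,
            trim_norm=config.trim_norm,
        )
        qc.to_csv(out / "mirna_qc.tsv", sep="\t")
        matrix.values.loc[retained].to_csv(out / "mirna_matrix.tsv", sep="\t")
        manifest["counts"]["mirna_probes_in"] = config.n_mirna_probes
        manifest["counts"]["mirna_probes_detected"] = len(retained)
        manifest["counts"]["mirna_probes_removed"] = config.n_mirna_probes - len(retained)

        # --- in vivo DE ----------------------------------------------------
        stage("de_invivo")
        invivo_results = {}
        n_called_invivo = 0
        for (comp, t), mat in sim.invivo.items():
            res = mrna_de_invivo.de_invivo(
                mat,
                control_group=sim.control_group,
                alpha=config.alpha,
                fdr=config.fdr,
                fc=config.fc,
                variance_cutoff=config.variance_cutoff,
            )
            for dose, de in res.items():
                invivo_results[(comp, t, dose)] = de
                n_called_invivo += int(de.table["called"].sum())
                de.write(out / f"de_invivo_{comp}_{t}_{dose}.tsv")
        manifest["counts"]["invivo_called"] = n_called_invivo

        # --- in vitro DE ---------------------------------------------------
        s = stage("de_invitro")
        invitro_results = mrna_de_invitro.de_invitro(
            sim.invitro_table,
            sim.invitro_design,
            min_present=config.min_present,
            k=config.knn_k,
            fdr=config.fdr,
            fc=config.fc,
            n_perm=config.n_perm,
            seed=s,
        )
        n_called_invitro = 0
        for key, de in invitro_results.items():
            n_called_invitro += int(de.table["called"].sum())
            de.write(out / ("de_invitro_" + "_".join(map(str, key)) + ".tsv"))
        manifest["counts"]["invitro_called"] = n_called_invitro

        # --- orthologs + concordance --------------------------------------
        s = stage("concordance")
        pairing = ortholog_concordance.resolve_orthologs(sim.orthologs, seed=s)
        result = ortholog_concordance.find_concordant(
            invivo_results, invitro_results, pairing, doses=config.doses
        )
        result.records.to_csv(out / "concordant_records.tsv", sep="\t", index=False)
        summary = ortholog_concordance.summarize_sets(result.records)
        manifest["counts"]["concordant_records"] = int(len(result.records))
        manifest["counts"]["orthologs_resolved"] = int(len(pairing))

        summary_rows = [
            {"compartment": comp, "cell_type": cell, **stats}
            for (comp, cell), stats in summary["per_pair"].items()
        ]
        pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)
        manifest["truth_records"] = sorted(map(list, sim.truth_records))
        manifest["emitted_records"] = sorted(
            result.records[
                ["gene", "compartment", "cell_type", "invivo_time", "direction"]
            ].itertuples(index=False, name=None)
        )
    except Exception as exc:  # halt with the failing stage named
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        (out / "FAILED").write_text(f"stage {failed}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
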