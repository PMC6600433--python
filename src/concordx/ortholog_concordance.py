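"""Cross-species concordance: ortholog resolution and direction matching.

A gene is concordant for (mouse compartment, human cell type, in vivo
time point) when its mouse ortholog is significantly changed in that
compartment at that time (in any MWCNT dose group), the human gene is
significantly changed in that cell type at any in vitro time point, and
the directions agree. Genes whose direction conflicts across dose
groups (or across in vitro time points) are excluded and logged.

One-to-many / many-to-many ortholog clusters are resolved to a single
human-mouse pair drawn uniformly with a stated seed; one-to-one records
pass through verbatim. Matching is by symbol, case-insensitive, with
uppercase canonical output. miRNA concordance reuses the same engine
with harmonised miRNA names (species prefix stripped, "miR-" casing
unified, mature-arm suffixes preserved) as the matching key.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .mrna_de_invivo import DEResult

__all__ = [
    "resolve_orthologs",
    "find_concordant",
    "summarize_sets",
    "harmonize_mirna",
    "load_fixture_records",
    "ConcordanceResult",
]

RELATIONS = ("one-to-one", "one-to-many", "many-to-many")


def _cluster_rng(seed: int, key: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(key.encode()) % 2**31,))
    )


def resolve_orthologs(ortholog_map: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Collapse the raw map to a one-to-one human<->mouse pairing.

    One-to-one records are kept verbatim (conflicting duplicates are a
    hard error). Each ambiguous cluster — a connected component of the
    bipartite symbol graph over one-to-many / many-to-many records —
    contributes exactly one of its pairs, drawn uniformly from a
    deterministic per-cluster stream derived from ``seed``. Row order
    never affects the outcome.
    """
    if ortholog_map.empty:
        raise ValueError("ortholog map is empty")
    required = {"human_symbol", "mouse_symbol", "relation"}
    if not required.issubset(ortholog_map.columns):
        raise ValueError(f"ortholog map needs columns {sorted(required)}")
    bad = set(ortholog_map["relation"]) - set(RELATIONS)
    if bad:
        raise ValueError(f"unknown relation class(es): {sorted(bad)}")

    one = ortholog_map[ortholog_map["relation"] == "one-to-one"]
    one = one.drop_duplicates(subset=["human_symbol", "mouse_symbol"])
    for col in ("human_symbol", "mouse_symbol"):
        dup = one[col][one[col].duplicated()]
        if len(dup):
            raise ValueError(
                f"conflicting one-to-one records sharing {col}: {sorted(set(dup))}"
            )

    multi = ortholog_map[ortholog_map["relation"] != "one-to-one"]
    resolved = [one[["human_symbol", "mouse_symbol"]]]
    if len(multi):
        # union-find over the bipartite symbol graph
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x: str, y: str) -> None:
            parent.setdefault(x, x)
            parent.setdefault(y, y)
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[max(rx, ry)] = min(rx, ry)

        for h, m in zip(multi["human_symbol"], multi["mouse_symbol"]):
            union(f"h:{h}", f"m:{m}")
        cluster_of = {
            (h, m): find(f"h:{h}") for h, m in zip(multi["human_symbol"], multi["mouse_symbol"])
        }
        clusters: dict[str, list[tuple[str, str]]] = {}
        for pair, root in cluster_of.items():
            clusters.setdefault(root, []).append(pair)
        picks = []
        for root in sorted(clusters):
            pairs = sorted(set(clusters[root]))
            rng = _cluster_rng(seed, root)
            picks.append(pairs[int(rng.integers(len(pairs)))])
        resolved.append(pd.DataFrame(picks, columns=["human_symbol", "mouse_symbol"]))
    out = pd.concat(resolved, ignore_index=True)
    return out.sort_values(["human_symbol", "mouse_symbol"]).reset_index(drop=True)


_MIRNA_PREFIX = re.compile(r"^(hsa|mmu|rno)-", re.IGNORECASE)


def harmonize_mirna(name: str) -> str:
    """Canonical cross-species miRNA name: strip species prefix, unify casing.

    'mmu-mir-183' -> 'miR-183'; mature-arm suffixes (-3p/-5p) are kept.
    """
    name = _MIRNA_PREFIX.sub("", name.strip())
    name = re.sub(r"^mir-", "miR-", name, flags=re.IGNORECASE)
    name = re.sub(r"^let-", "let-", name, flags=re.IGNORECASE)
    return name


@dataclass
class ConcordanceResult:
    records: pd.DataFrame  # gene, compartment, cell_type, invivo_time, invitro_times, direction
    excluded: pd.DataFrame  # symbol, side, reason


def _called_directions(table: pd.DataFrame) -> dict[str, str]:
    sub = table[table["called"]]
    return dict(zip(sub.index.astype(str), sub["direction"]))


def find_concordant(
    invivo: dict[tuple[str, str, str], DEResult],
    invitro: dict[tuple[str, str], DEResult],
    pairing: pd.DataFrame | dict | None,
    doses: list[str] | None = None,
    exclude_dose_substring: str = "asbestos",
) -> ConcordanceResult:
    """Match significant mouse and human calls by resolved ortholog pair.

    ``invivo`` is keyed by (compartment, time point, dose group);
    ``invitro`` by (cell type, time point). ``pairing`` is a resolved
    ortholog frame (or mouse->human dict); ``None`` matches identical
    (case-insensitive) symbols — used for miRNA after harmonisation.
    In vivo calls pool over MWCNT dose groups (all by default, the
    asbestos positive control excluded); direction conflicts across
    doses, or across in vitro time points, exclude the gene.
    """
    if isinstance(pairing, pd.DataFrame):
        mouse_to_human = {
            str(m).upper(): str(h).upper()
            for h, m in zip(pairing["human_symbol"], pairing["mouse_symbol"])
        }
    elif isinstance(pairing, dict):
        mouse_to_human = {str(m).upper(): str(h).upper() for m, h in pairing.items()}
    else:
        mouse_to_human = None

    excluded_rows: list[tuple[str, str, str]] = []

    # mouse side: (compartment, time) -> gene -> direction, pooled over doses
    mouse: dict[tuple[str, str], dict[str, str]] = {}
    for (comp, time, dose) in sorted(invivo):
        if exclude_dose_substring and exclude_dose_substring.lower() in str(dose).lower():
            continue
        if doses is not None and dose not in doses:
            continue
        dirs = _called_directions(invivo[(comp, time, dose)].table)
        bucket = mouse.setdefault((comp, time), {})
        for gene, d in dirs.items():
            gene_u = gene.upper()
            if gene_u in bucket and bucket[gene_u] != d:
                bucket[gene_u] = "conflict"
            else:
                bucket.setdefault(gene_u, d)
    for (comp, time), bucket in mouse.items():
        for gene in [g for g, d in bucket.items() if d == "conflict"]:
            excluded_rows.append((gene, f"invivo:{comp}:{time}", "direction conflict across doses"))
            del bucket[gene]

    # human side: cell type -> gene -> (direction, times where called)
    human: dict[str, dict[str, tuple[str, list[str]]]] = {}
    for (cell, time) in sorted(invitro):
        dirs = _called_directions(invitro[(cell, time)].table)
        bucket = human.setdefault(cell, {})
        for gene, d in dirs.items():
            gene_u = gene.upper()
            if gene_u in bucket:
                prev_d, times = bucket[gene_u]
                if prev_d != d and prev_d != "conflict":
                    bucket[gene_u] = ("conflict", times)
                elif prev_d == d:
                    bucket[gene_u] = (d, times + [time])
            else:
                bucket[gene_u] = (d, [time])
    for cell, bucket in human.items():
        for gene in [g for g, (d, _) in bucket.items() if d == "conflict"]:
            excluded_rows.append((gene, f"invitro:{cell}", "direction conflict across time points"))
            del bucket[gene]

    rows = []
    for (comp, time), mbucket in sorted(mouse.items()):
        for mgene, mdir in sorted(mbucket.items()):
            hgene = mouse_to_human.get(mgene) if mouse_to_human is not None else mgene
            if hgene is None:
                continue
            for cell, hbucket in sorted(human.items()):
                if hgene in hbucket:
                    hdir, times = hbucket[hgene]
                    if hdir == mdir:
                        rows.append(
                            (hgene, comp, cell, time, ";".join(sorted(times)), mdir)
                        )
    records = pd.DataFrame(
        rows,
        columns=["gene", "compartment", "cell_type", "invivo_time", "invitro_times", "direction"],
    )
    excluded = pd.DataFrame(excluded_rows, columns=["symbol", "side", "reason"])
    return ConcordanceResult(records=records, excluded=excluded)


def summarize_sets(records: pd.DataFrame) -> dict:
    """Set-algebra summaries over concordant records.

    Returns per (compartment, cell type) record/direction counts and
    per-time tallies, the unique-gene union per compartment, and the
    cross-compartment intersection (genes concordant in every
    compartment present, with a single consistent direction).
    """
    out: dict = {"per_pair": {}, "unique_by_compartment": {}, "per_time": {}}
    for (comp, cell), sub in records.groupby(["compartment", "cell_type"], sort=True):
        out["per_pair"][(comp, cell)] = {
            "records": int(len(sub)),
            "up": int((sub["direction"] == "up").sum()),
            "down": int((sub["direction"] == "down").sum()),
            "unique_genes": int(sub["gene"].nunique()),
        }
        for t, tsub in sub.groupby("invivo_time"):
            out["per_time"][(comp, cell, t)] = int(len(tsub))
    compartments = sorted(records["compartment"].unique())
    gene_sets = {}
    for comp in compartments:
        sub = records[records["compartment"] == comp]
        gene_sets[comp] = set(sub["gene"])
        out["unique_by_compartment"][comp] = len(gene_sets[comp])
    if len(compartments) >= 2:
        inter = set.intersection(*gene_sets.values())
        consistent = set()
        for gene in inter:
            dirs = set(records.loc[records["gene"] == gene, "direction"])
            if len(dirs) == 1:
                consistent.add(gene)
        out["cross_compartment_intersection"] = sorted(consistent)
    else:
        out["cross_compartment_intersection"] = []
    return out


def load_fixture_records(kind: str = "mrna") -> pd.DataFrame:
    """Packaged concordant-record tables (transcribed reference lists).

    ``kind``: 'mrna' (four compartment x cell-type tables) or 'mirna'
    (two tables). Columns: gene, compartment, cell_type, invivo_time,
    direction.
    """
    if kind == "mrna":
        names = ["table1.tsv", "table2.tsv", "table3.tsv", "table4.tsv"]
    elif kind == "mirna":
        names = ["table5.tsv", "table6.tsv"]
    else:
        raise ValueError(f"kind must be 'mrna' or 'mirna', got {kind!r}")
    frames = []
    for name in names:
        with resources.files("concordx").joinpath("fixtures").joinpath(name).open() as fh:
            frames.append(pd.read_csv(fh, sep="\t"))
    df = pd.concat(frames, ignore_index=True)
    return df[["gene", "compartment", "cell_type", "invivo_time", "direction"]]
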