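"""Summary statistics and the end-to-end driver.

``family_summary`` reproduces the per-family bookkeeping behind
frequency-of-SDGH style figures: how many domain instances a family has,
how many proteins carry it, what fraction of those proteins are
single-domain, and the histogram of exact architecture strings.
``magh_report`` lists multi-activity proteins with their synergy typing.
``end_to_end`` chains annotation, architecture reconstruction, network
building and the summaries into one deterministic, rerunnable output
directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .architecture import (
    FamilyCatalog,
    ProteinArchitecture,
    _roles,
    build_architectures,
    write_architecture_table,
)
from .network import build_network, filter_min_weight, write_edge_list, write_graphml
from .pipeline import PipelineConfig, RunStats, run_sequential
from .profiles import ProfileHMM
from .scan import write_hit_table


def family_summary(
    architectures: list[ProteinArchitecture], catalog: FamilyCatalog | None = None
) -> pd.DataFrame:
    """One row per observed family.

    Columns: family, n_domains (instances), n_proteins (proteins with >= 1
    instance), sdgh_fraction (fraction of those proteins labelled SDGH),
    architecture_histogram (dict arch_string -> protein count).  Ordered by
    n_domains descending, then family name.
    """
    rows: dict[str, dict] = {}
    for arch in architectures:
        fams = arch.families
        for f in fams:
            row = rows.setdefault(
                f,
                {
                    "family": f,
                    "n_domains": 0,
                    "n_proteins": 0,
                    "_sdgh": 0,
                    "architecture_histogram": {},
                },
            )
            row["n_domains"] += 1
        for f in set(fams):
            row = rows[f]
            row["n_proteins"] += 1
            if arch.class_label == "SDGH":
                row["_sdgh"] += 1
            hist = row["architecture_histogram"]
            hist[arch.arch_string] = hist.get(arch.arch_string, 0) + 1
    out = []
    for row in rows.values():
        row["sdgh_fraction"] = (
            row.pop("_sdgh") / row["n_proteins"] if row["n_proteins"] else 0.0
        )
        out.append(row)
    out.sort(key=lambda r: (-r["n_domains"], r["family"]))
    return pd.DataFrame(
        out,
        columns=[
            "family",
            "n_domains",
            "n_proteins",
            "sdgh_fraction",
            "architecture_histogram",
        ],
    )


def write_family_summary(df: pd.DataFrame, path) -> None:
    df = df.copy()
    df["architecture_histogram"] = df["architecture_histogram"].map(
        lambda h: ";".join(f"{k}={v}" for k, v in sorted(h.items()))
    )
    df.to_csv(path, sep="\t", index=False)


def magh_report(
    architectures: list[ProteinArchitecture], catalog: FamilyCatalog
) -> pd.DataFrame:
    """Table of multi-activity proteins, most catalytic domains first."""
    rows = []
    for arch in architectures:
        if arch.class_label != "MAGH":
            continue
        roles = _roles(arch.domains, catalog, None)
        n_cat = sum(r in ("catalytic_GH", "catalytic_CE") for r in roles)
        synergy = ";".join(f"{a}:{b}={t}" for (a, b), t in arch.synergy_calls)
        rows.append([arch.protein_id, arch.arch_string, n_cat, synergy])
    rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(
        rows, columns=["protein_id", "arch_string", "n_catalytic", "synergy_calls"]
    )


def config_digest(cfg: PipelineConfig) -> str:
    d = asdict(cfg)
    d["target_accessions"] = sorted(d["target_accessions"])
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def end_to_end(
    proteins: dict[str, str],
    models: list[ProfileHMM],
    catalog: FamilyCatalog,
    cfg: PipelineConfig,
    outdir,
    tolerance_fraction: float = 0.5,
    min_edge_weight: int = 2,
):
    """Annotate -> architectures -> network -> summaries, writing all
    declared outputs under ``outdir``.  Returns the architectures, the
    unfiltered network and the run statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stats = RunStats()
    hit_sets = run_sequential(proteins, models, cfg, stats)
    all_hits = [h for hits in hit_sets.values() for h in hits]
    warnings: list[str] = []
    archs = build_architectures(all_hits, catalog, tolerance_fraction, warnings)
    net = build_network(archs)
    filtered = filter_min_weight(net, min_edge_weight)

    write_hit_table(all_hits, outdir / "hits.tsv")
    write_architecture_table(archs, catalog, outdir / "architectures.tsv")
    write_edge_list(net, outdir / "edges.csv")
    write_graphml(filtered, outdir / "network.graphml")
    write_family_summary(family_summary(archs, catalog), outdir / "family_summary.tsv")
    magh_report(archs, catalog).to_csv(outdir / "magh.tsv", sep="\t", index=False)
    with open(outdir / "warnings.txt", "w") as fh:
        for w in warnings:
            fh.write(w + "\n")
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"config_digest\t{config_digest(cfg)}\n")
        fh.write(f"seed\t{cfg.seed}\n")
        fh.write(f"stage1_evalue\t{cfg.stage1_evalue}\n")
        fh.write(f"stage2_evalue\t{cfg.stage2_evalue}\n")
        fh.write(f"n_proteins\t{stats.n_proteins}\n")
        fh.write(f"stage1_candidates\t{stats.n_candidates}\n")
        fh.write(f"stage1_calls\t{stats.stage1_calls}\n")
        fh.write(f"stage2_calls\t{stats.stage2_calls}\n")
    return archs, net, stats
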