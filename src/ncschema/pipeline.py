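"""End-to-end orchestration: structures + alignment + assays -> design report.

Stages: contacts -> recombination graph -> block partition -> chimera library
-> (optional) informative subset -> additive model fits -> predictions and
ranking. Every intermediate artifact is written to the output directory and
the configuration is echoed verbatim for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import (block_design, chimera_library, contact_graph, stability_model,
               structure_io)
from .chimera_library import parse_code
from .stability_model import StabilityRecord

log = logging.getLogger("ncschema")


@dataclass
class PipelineConfig:
    structure1: str
    structure2: str
    alignment: str
    outdir: str
    stability_csv: str | None = None
    chain1: str | None = None
    chain2: str | None = None
    cutoff: float = 4.5
    k: int = 8
    balance_tolerance: float = 0.3
    seed: int = 0
    restarts: int = 20
    E_ceiling: float = float("inf")
    subset_n: int = 0
    include_adjacent: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("config field 'cutoff' must be positive")
        if self.k < 1:
            raise ValueError("config field 'k' must be >= 1")
        if not 0 <= self.balance_tolerance < 1:
            raise ValueError("config field 'balance_tolerance' must be in [0, 1)")
        if self.restarts < 1:
            raise ValueError("config field 'restarts' must be >= 1")
        if self.subset_n < 0:
            raise ValueError("config field 'subset_n' must be >= 0")
        for field in ("structure1", "structure2", "alignment"):
            path = getattr(self, field)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"config field '{field}': no such file: {path}")
        if self.stability_csv and not Path(self.stability_csv).exists():
            raise FileNotFoundError(
                f"config field 'stability_csv': no such file: {self.stability_csv}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _read_stability_records(path: str) -> list[StabilityRecord]:
    df = pd.read_csv(path, dtype={"code": str})
    records = []
    for _, row in df.iterrows():
        records.append(StabilityRecord(
            name=str(row["name"]), code=parse_code(str(row["code"])),
            t50=float(row["T50"]) if "T50" in df and pd.notna(row.get("T50")) else None,
            ta50=float(row["TA50"]) if "TA50" in df and pd.notna(row.get("TA50")) else None,
        ))
    return records


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return a summary dict (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    summary: dict = {"seed": config.seed}

    load = _stage("load-inputs")(lambda: (
        structure_io.load_structure(config.structure1, config.chain1, "P1"),
        structure_io.load_structure(config.structure2, config.chain2, "P2"),
        structure_io.load_alignment(config.alignment),
    ))
    p1, p2, aln = load()
    map1 = structure_io.map_columns(aln, p1, 1)
    map2 = structure_io.map_columns(aln, p2, 2)
    structure_io.write_column_report(aln, map1, map2, out / "column_map.tsv")

    contacts = _stage("contacts")(lambda: (
        contact_graph.compute_contacts(p1, config.cutoff),
        contact_graph.compute_contacts(p2, config.cutoff),
    ))
    cmap1, cmap2 = contacts()
    summary["contacts_P1"] = len(cmap1)
    summary["contacts_P2"] = len(cmap2)

    graph = _stage("recombination-graph")(contact_graph.build_recombination_graph)(
        cmap1, cmap2, aln, map1, map2, include_adjacent=config.include_adjacent)
    contact_graph.write_edge_list(graph, str(out / "recombination_graph.tsv"))
    summary["graph_nodes"] = graph.number_of_nodes()
    summary["graph_edges"] = graph.number_of_edges()
    summary["graph_total_weight"] = contact_graph.total_weight(graph)

    assignment = _stage("partition")(block_design.partition_blocks)(
        graph, config.k, config.balance_tolerance, config.seed, config.restarts)
    block_design.write_assignment(assignment, aln, map1, map2, str(out / "blocks.tsv"))
    design = block_design.summarize_design(assignment, graph, aln)
    summary["design"] = {"mean_E": design.mean_E, "mean_m": design.mean_m,
                         "cut_weight": design.cut_weight,
                         "block_sizes": design.block_sizes}
    (out / "design_summary.json").write_text(json.dumps(summary["design"], indent=2))

    library = _stage("library")(chimera_library.enumerate_library)(assignment, graph, aln)
    chimera_library.write_library_csv(library, str(out / "library.csv"))
    structure_io.write_fasta(
        ((c.name, chimera_library.assemble_sequence(c.code, assignment, aln))
         for c in library.chimeras),
        out / "library.fasta")
    summary["library_size"] = len(library)

    if config.subset_n:
        subset = _stage("subset")(chimera_library.select_informative_subset)(
            library, config.subset_n, config.E_ceiling)
        chimera_library.write_library_csv(library, str(out / "subset.csv"), subset)
        summary["subset"] = [c.name for c in subset]

    if config.stability_csv:
        records = _stage("read-assays")(_read_stability_records)(config.stability_csv)
        models = {}
        for trait in stability_model.TRAITS:
            if all(r.trait(trait) is None for r in records):
                continue
            model = _stage(f"fit-{trait}")(stability_model.fit_additive_model)(records, trait)
            models[trait] = model
            (out / f"model_{trait}.json").write_text(json.dumps(model.to_dict(), indent=2))
            stability_model.block_contribution_table(model).to_csv(
                out / f"blocks_{trait}.csv", index=False)
            summary[f"r2_{trait}"] = model.r_squared
        if len(models) == 2:
            ranked = _stage("rank")(stability_model.rank_candidates)(
                models["T50"], models["TA50"], library.chimeras, config.E_ceiling)
            ranked.to_csv(out / "ranked_candidates.csv", index=False)
            summary["top_candidate"] = ranked.iloc[0]["name"]

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
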