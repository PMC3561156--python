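"""End-to-end orchestration: prepare -> decompose -> tree -> census -> CSF ->
overlap -> cluster -> treemap, with every intermediate written to disk.

All numbers in the report bundle are recomputable from the emitted TSVs; the
run log records seeds, versions and per-stage attrition counts.  A rerun
with an identical config and seed reproduces every CSV/JSON byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .chem_io import (
    LibrarySpec,
    MW_CUTOFF_DA,
    deduplicate,
    filter_by_mw,
    match_mw_distribution,
    read_library,
    standardize_library,
    subsample_random,
    write_library,
)
from .clustering import DEFAULT_TARGET_AVG_SIZE, cluster_scaffolds, layout_treemap, treemap_svg
from .decompose import decompose
from .diversity import count_frequencies, coverage_at, csf_curve, plot_csf
from .scaffold_tree import build_chain, level_census
from .similarity import DEFAULT_CUTOFFS, cross_library_overlap, overlap_frame

logger = logging.getLogger(__name__)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")

_REPRESENTATIONS = ("murcko", "graph_framework", "ring", "ring_assembly",
                    "bridge_assembly", "linker", "side_chain")


@dataclass
class RunConfig:
    libraries: list[tuple[str, str, str]]   # (name, path, format)
    max_mw: float = MW_CUTOFF_DA
    dedup: bool = True
    equalize_sizes: bool = False
    mw_match_reference: Optional[str] = None
    levels: list[int] = field(default_factory=lambda: [1, 2])
    top_n: int = 1000
    cutoff_grid: tuple[float, ...] = DEFAULT_CUTOFFS
    target_avg_cluster_size: int = DEFAULT_TARGET_AVG_SIZE
    seed: int = 0
    out_dir: str = "scaffoldscope_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["libraries"] = [tuple(entry) for entry in raw["libraries"]]
        if "cutoff_grid" in raw:
            raw["cutoff_grid"] = tuple(raw["cutoff_grid"])
        return cls(**raw)


def _prepare(lib: LibrarySpec, config: RunConfig, log: dict) -> LibrarySpec:
    stage = {"parsed": len(lib)}
    lib = standardize_library(lib)
    stage["standardized"] = len(lib)
    lib = filter_by_mw(lib, config.max_mw)
    stage["mw_filtered"] = len(lib)
    if config.dedup:
        lib = deduplicate(lib)
    stage["deduplicated"] = len(lib)
    log[lib.name] = stage
    return lib


def run_pipeline(config: RunConfig,
                 libraries: Optional[list[LibrarySpec]] = None) -> dict:
    """Execute the full analysis; returns a summary dict (also written to disk).

    ``libraries`` may be passed directly (e.g. synthetic ones); otherwise
    they are read from the paths in the config.
    """
    if not config.libraries and not libraries:
        raise ValueError("at least one library is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    if libraries is None:
        libraries = []
        for name, path, fmt in config.libraries:
            try:
                libraries.append(read_library(path, format=fmt, name=name))
            except Exception as exc:
                raise RuntimeError(f"stage 'read' failed for library {name!r}: {exc}") from exc

    prepared: dict[str, LibrarySpec] = {}
    for lib in libraries:
        prepared[lib.name] = _prepare(lib, config, run_log["stages"])

    if config.mw_match_reference is not None:
        ref = prepared[config.mw_match_reference]
        for name in list(prepared):
            if name == config.mw_match_reference:
                continue
            if len(prepared[name]) > len(ref):
                matched, ks = match_mw_distribution(
                    prepared[name], ref, n=len(ref), seed=config.seed
                )
                run_log["stages"][name]["mw_matched_ks"] = round(ks, 4)
                prepared[name] = matched
    if config.equalize_sizes:
        n_min = min(len(lib) for lib in prepared.values())
        for name in list(prepared):
            if len(prepared[name]) > n_min:
                prepared[name] = subsample_random(prepared[name], n_min, config.seed)

    summary: dict = {"libraries": {}}
    scaffold_sets: dict[str, dict[str, list[str]]] = {}
    csf_curves: dict[int | str, dict] = {}

    for name, lib in prepared.items():
        lib_dir = out / name
        lib_dir.mkdir(exist_ok=True)
        write_library(lib, lib_dir / "prepared.smi", lib_dir / "prepared.tsv")
        n_mols = len(lib)

        # --- decomposition ------------------------------------------------
        frag_rows = []
        fragments: dict[str, list[tuple[str, str]]] = {r: [] for r in _REPRESENTATIONS}
        chains = []
        for rec in lib.records:
            dec = decompose(rec.mol)
            if dec.murcko is not None:
                fragments["murcko"].append((rec.id, dec.murcko))
                fragments["graph_framework"].append((rec.id, dec.graph_framework))
            for label, multi in (("ring", dec.rings), ("ring_assembly", dec.ring_assemblies),
                                 ("bridge_assembly", dec.bridge_assemblies),
                                 ("linker", dec.linkers), ("side_chain", dec.side_chains)):
                for smi in multi:
                    fragments[label].append((rec.id, smi))
            chains.append(build_chain(rec.mol, rec.id))
        for label in _REPRESENTATIONS:
            for mol_id, smi in fragments[label]:
                frag_rows.append((mol_id, label, smi))
        pd.DataFrame(frag_rows, columns=["molecule_id", "representation", "fragment_smiles"]) \
            .to_csv(lib_dir / "fragments.tsv", sep="\t", index=False)

        frag_summary = {
            label: {"total": len(fragments[label]),
                    "unique": len({s for _, s in fragments[label]})}
            for label in _REPRESENTATIONS
        }
        (lib_dir / "fragment_summary.json").write_text(json.dumps(frag_summary, indent=1))

        # --- scaffold tree --------------------------------------------------
        chain_rows = [
            (ch.molecule_id, k, smi)
            for ch in chains if ch is not None
            for k, smi in enumerate(ch.levels)
        ]
        pd.DataFrame(chain_rows, columns=["molecule_id", "level", "scaffold_smiles"]) \
            .to_csv(lib_dir / "scaffold_tree.tsv", sep="\t", index=False)
        census = level_census(chains)
        census.to_csv(lib_dir / "level_census.csv", index=False)

        # --- frequency tables & CSF ----------------------------------------
        tables = {"murcko": count_frequencies(fragments["murcko"], n_mols, "murcko")}
        for k in config.levels:
            pairs = [
                (ch.molecule_id, ch.levels[k])
                for ch in chains if ch is not None and k < ch.n_levels
            ]
            tables[f"level{k}"] = count_frequencies(pairs, n_mols, f"level{k}")
        for rep, table in tables.items():
            curve = csf_curve(table, config.top_n) if table.counts else None
            if curve is not None:
                curve.to_frame().to_csv(lib_dir / f"csf_{rep}.csv", index=False)
                csf_curves.setdefault(rep, {})[name] = curve
        scaffold_sets[name] = {rep: sorted(t.counts) for rep, t in tables.items()}

        summary["libraries"][name] = {
            "n_molecules": n_mols,
            "fragments": frag_summary,
            "level_census": census.to_dict(orient="records"),
            "csf": {
                rep: {"top10": round(coverage_at(t, 10), 2),
                      "top100": round(coverage_at(t, 100), 2),
                      "top1000": round(coverage_at(t, 1000), 2),
                      "unique": t.n_unique}
                for rep, t in tables.items() if t.counts
            },
        }

        # --- clustering + treemap (Level-1 scaffolds) -----------------------
        lvl1 = tables.get("level1")
        if lvl1 is not None and lvl1.counts:
            model = cluster_scaffolds(sorted(lvl1.counts),
                                      config.target_avg_cluster_size, seed=config.seed)
            model.to_frame().to_csv(lib_dir / "clusters.csv", index=False)
            layout = layout_treemap(model, lvl1)
            (lib_dir / "treemap.json").write_text(layout.to_json())
            treemap_svg(layout, str(lib_dir / "treemap.svg"))
            summary["libraries"][name]["n_clusters"] = model.n_clusters

    # --- CSF comparison plots ----------------------------------------------
    for rep, curves in csf_curves.items():
        if len(curves) >= 1:
            plot_csf(curves, str(out / f"csf_{rep}.svg"),
                     title=f"Cumulative scaffold frequency — {rep}", top_n=config.top_n)

    # --- pairwise overlap ----------------------------------------------------
    names = sorted(prepared)
    if len(names) < 2:
        logger.info("single library: overlap tables skipped")
    else:
        for rep in ["murcko"] + [f"level{k}" for k in config.levels]:
            overlap_tables = []
            for a in names:
                for b in names:
                    if a == b:
                        continue
                    overlap_tables.append(
                        cross_library_overlap(
                            scaffold_sets[a].get(rep, []), scaffold_sets[b].get(rep, []),
                            name_a=a, name_b=b, cutoffs=config.cutoff_grid,
                        )
                    )
            frame = overlap_frame(overlap_tables)
            frame.to_csv(out / f"overlap_{rep}.csv")
            summary[f"overlap_{rep}"] = {c: dict(frame.loc[:, c]) for c in frame.columns}

    (out / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True, default=_json_default))
    return summary


__all__ = ["RunConfig", "run_pipeline"]
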