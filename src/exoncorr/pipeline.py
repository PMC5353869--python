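"""End-to-end orchestration: pairs -> pseudo-gtf -> ratios -> associate -> map -> enrich.

A single YAML configuration names all inputs and thresholds; every stage
persists its output under the run directory, and a manifest records inputs,
seed, per-stage outputs with content hashes, timings and collected warnings,
so a run is reproducible and each stage re-runnable from its persisted inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import load_gtf
from .association import AssociationConfig, select_associated
from .conservation import (
    load_blast_table,
    load_ortholog_table,
    partition_by_orthology,
    reciprocal_filter,
    require_internal,
    restrict_to_exons,
)
from .correspondence import (
    NegativeControlConfig,
    build_map,
    paired_status_rows,
    shuffle_control,
)
from .enrichment import (
    annotate_depths,
    foreground_genes,
    load_dag,
    load_gene_terms,
    report_top_terms,
    term_enrichment,
)
from .errors import ConfigurationError, PipelineError
from .plotting import plot_map
from .pseudo_annotation import build_pseudo_transcripts, write_pseudo_gtf
from .splicing_quant import (
    SmootherConfig,
    build_ratio_matrix,
    cassette_filter,
    load_fpkm_table,
    load_sample_table,
)

logger = logging.getLogger(__name__)

_INPUT_KEYS = [
    "blast_fw", "blast_rv", "fly_gtf", "worm_gtf", "orthologs",
    "fpkm_fly", "fpkm_worm", "samples_fly", "samples_worm",
]

_DEFAULT_PARAMS = {
    "evalue_max": 1e-5,
    "z_high": 1.5,
    "z_low": -1.5,
    "span": 0.3,
    "degree": 2,
    "pair_set": "a",
    "run_control": True,
    "n_shuffles": 100,
    "p_max": 1e-30,
    "depth_eq": 3,
    "top_n": 5,
    "make_pseudo_gtf": True,
    "seed": 0,
}


@dataclass
class RunConfig:
    inputs: dict[str, str]
    outdir: Path
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = dict(_DEFAULT_PARAMS)
        params.update(raw.get("params") or {})
        return cls(inputs=dict(raw["inputs"]), outdir=Path(raw["outdir"]), params=params)

    def __post_init__(self):
        self.params = {**_DEFAULT_PARAMS, **self.params}
        if self.params["pair_set"] not in ("a", "b", "both"):
            raise ConfigurationError("pair_set must be one of a | b | both")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require_inputs(config: RunConfig, stage: str, keys: list[str]) -> None:
    for key in keys:
        path = config.inputs.get(key)
        if path is None or not Path(path).exists():
            raise PipelineError(stage, f"missing input '{key}' ({path})")


def run_all(config: RunConfig) -> dict:
    """Execute all stages and return (and persist) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict = {
        "version": __version__,
        "seed": p["seed"],
        "params": {k: v for k, v in p.items()},
        "inputs": dict(config.inputs),
        "stages": [],
        "outputs": {},
        "warnings": [],
        "timings": {},
    }

    def record(stage: str, t0: float, outputs: dict[str, Path]) -> None:
        manifest["stages"].append(stage)
        manifest["timings"][stage] = round(time.monotonic() - t0, 3)
        for name, path in outputs.items():
            manifest["outputs"][f"{stage}/{name}"] = {
                "path": str(path),
                "sha256": _sha256(Path(path)),
            }

    # -- stage: pairs --------------------------------------------------------
    t0 = time.monotonic()
    stage = "pairs"
    _require_inputs(config, stage, ["blast_fw", "blast_rv", "fly_gtf", "worm_gtf", "orthologs"])
    try:
        fly_ann = load_gtf(config.inputs["fly_gtf"])
        worm_ann = load_gtf(config.inputs["worm_gtf"])
        fw = load_blast_table(config.inputs["blast_fw"])
        rv = load_blast_table(config.inputs["blast_rv"])
        pairs = reciprocal_filter(fw, rv, p["evalue_max"])
        pairs = require_internal(pairs, fly_ann, worm_ann)
        pairs_path = outdir / "pairs.tsv"
        pairs.to_csv(pairs_path, sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise PipelineError(stage, str(exc)) from exc
    record(stage, t0, {"pairs": pairs_path})

    # -- stage: pseudo_gtf ---------------------------------------------------
    t0 = time.monotonic()
    stage = "pseudo_gtf"
    outputs: dict[str, Path] = {}
    if p["make_pseudo_gtf"]:
        try:
            for name, ann in (("fly", fly_ann), ("worm", worm_ann)):
                path = outdir / f"pseudo_{name}.gtf"
                write_pseudo_gtf(build_pseudo_transcripts(ann), ann, path)
                outputs[name] = path
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc
    record(stage, t0, outputs)

    # -- stage: ratios -------------------------------------------------------
    t0 = time.monotonic()
    stage = "ratios"
    _require_inputs(config, stage, ["fpkm_fly", "fpkm_worm", "samples_fly", "samples_worm"])
    try:
        outputs = {}
        smoother = SmootherConfig(span=p["span"], degree=p["degree"])
        matrices, n_cassette = {}, {}
        for name in ("fly", "worm"):
            quants = load_fpkm_table(config.inputs[f"fpkm_{name}"])
            meta = load_sample_table(config.inputs[f"samples_{name}"])
            keep = cassette_filter(quants)
            n_cassette[name] = len(keep)
            quants = quants[quants["exon_id"].isin(keep)]
            matrices[name] = build_ratio_matrix(quants, meta, smoother)
            path = outdir / f"ratios_{name}.tsv"
            matrices[name].values.to_csv(path, sep="\t")
            outputs[name] = path
        pairs = restrict_to_exons(
            pairs,
            set(matrices["fly"].exon_ids),
            set(matrices["worm"].exon_ids),
        )
        pairs_path = outdir / "pairs_cassette.tsv"
        pairs.to_csv(pairs_path, sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    record(stage, t0, {**outputs, "pairs_cassette": pairs_path})

    # -- stage: associate ----------------------------------------------------
    t0 = time.monotonic()
    stage = "associate"
    try:
        assoc_cfg = AssociationConfig(z_high=p["z_high"], z_low=p["z_low"])
        assoc, outputs = {}, {}
        for name in ("fly", "worm"):
            assoc[name] = select_associated(matrices[name], assoc_cfg)
            rows = [
                (a.sample_id, exon, status)
                for a in assoc[name]
                for exon, status in sorted(a.members)
            ]
            path = outdir / f"assoc_{name}.tsv"
            pd.DataFrame(rows, columns=["sample_id", "exon_id", "status"]).to_csv(
                path, sep="\t", index=False
            )
            outputs[name] = path
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    record(stage, t0, outputs)

    # -- stage: map ----------------------------------------------------------
    t0 = time.monotonic()
    stage = "map"
    try:
        outputs = {}
        set_a, set_b = partition_by_orthology(
            pairs, load_ortholog_table(config.inputs["orthologs"]), fly_ann, worm_ann
        )
        chosen = {"a": [("a", set_a)], "b": [("b", set_b)],
                  "both": [("a", set_a), ("b", set_b)]}[p["pair_set"]]
        for label, table in chosen:
            if table.m == 0:
                manifest["warnings"].append(f"pair set ({label}) empty; map skipped")
                continue
            rows = paired_status_rows(table.pairs)
            cmap = build_map(assoc["fly"], assoc["worm"], "between", rows=rows)
            path = outdir / f"map_between_set_{label}.tsv"
            cmap.to_frame().to_csv(path, sep="\t")
            outputs[f"between_set_{label}"] = path
            png = outdir / f"map_between_set_{label}.png"
            plot_map(cmap, png, title=f"fly vs worm stages, pair set ({label})")
            outputs[f"between_set_{label}_png"] = png
            if p["run_control"]:
                ctrl = shuffle_control(
                    rows, assoc["fly"], assoc["worm"],
                    NegativeControlConfig(n_shuffles=p["n_shuffles"], seed=p["seed"]),
                )
                for kind, arr in (("mean", ctrl.mean), ("sd", ctrl.sd)):
                    cpath = outdir / f"control_{kind}_set_{label}.tsv"
                    pd.DataFrame(arr, index=ctrl.row_labels, columns=ctrl.col_labels).to_csv(
                        cpath, sep="\t"
                    )
                    outputs[f"control_{kind}_set_{label}"] = cpath
        for name in ("fly", "worm"):
            cmap = build_map(assoc[name], assoc[name], "within", n_cassette=n_cassette[name])
            path = outdir / f"map_within_{name}.tsv"
            cmap.to_frame().to_csv(path, sep="\t")
            outputs[f"within_{name}"] = path
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    record(stage, t0, outputs)

    # -- stage: enrich -------------------------------------------------------
    t0 = time.monotonic()
    stage = "enrich"
    try:
        outputs = {}
        if "gene_terms" in config.inputs:
            terms = load_gene_terms(config.inputs["gene_terms"])
            dag = load_dag(config.inputs["dag"]) if "dag" in config.inputs else None
            for name, ann in (("fly", fly_ann), ("worm", worm_ann)):
                exon_to_gene = dict(zip(ann.exons["exon_id"], ann.exons["gene_id"]))
                universe = ann.gene_ids()
                for status in ("HIGH", "LOW"):
                    fg = set()
                    for aset in assoc[name]:
                        fg |= foreground_genes(aset, status, exon_to_gene)
                    results = term_enrichment(fg, terms, universe)
                    if dag is not None:
                        results = annotate_depths(results, dag)
                    table = report_top_terms(
                        results, p_max=p["p_max"],
                        depth_eq=p["depth_eq"], top_n=p["top_n"],
                    )
                    path = outdir / f"enrichment_{name}_{status.lower()}.tsv"
                    table.to_csv(path, sep="\t", index=False)
                    outputs[f"{name}_{status.lower()}"] = path
        else:
            manifest["warnings"].append("no gene_terms input; enrichment skipped")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    record(stage, t0, outputs)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
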