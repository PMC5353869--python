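"""Synthetic two-species splicing datasets with planted stage correspondence.

Generates everything the pipeline consumes — exon annotations, reciprocal
BLAST-like hit tables, an ortholog table, per-exon inclusion/skipping FPKM
series over ordered developmental stages, and a small term ontology — plus a
truth table sufficient to score recovery.

A fraction of the conserved exon pairs carry *signal*: their log I/S ratio is
shifted by ``effect_size`` (up for HIGH exons, down for LOW) in a contiguous
3-stage window centered on a planted fly stage, and, in the worm partner, on
the worm stage linked to it by a configurable fly->worm correspondence
function (two parallel piecewise-linear patterns by default).  FPKM pairs are
derived by fixing FPKM_S from a log-normal baseline and solving
FPKM_I = (FPKM_S + 1) * exp(ratio) - 1 (clipped at 0), which makes the
planted ratio exact under the pipeline's ratio definition.  A fraction of
exons get FPKM_S identically zero so the cassette filter has something to do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, load_gtf, write_gtf
from .conservation import BLAST6_COLUMNS
from .errors import ConfigurationError

__all__ = ["SimConfig", "SimTruth", "SimBundle", "default_correspondence", "generate",
           "write_bundle", "read_bundle"]

_EXON_LEN = 120
_INTRON_LEN = 80
_TX_SPACING = 2000


def default_correspondence(n_fly_stages: int, n_worm_stages: int) -> tuple[int, ...]:
    """Two parallel piecewise-linear patterns.

    The first half of the fly stage axis sweeps the whole worm axis, and the
    second half sweeps it again — mimicking the two-parallel-pattern geometry
    of fly/worm life-cycle alignments.
    """
    half = n_fly_stages // 2
    out = []
    for t in range(n_fly_stages):
        if t < half:
            pos = t / max(half - 1, 1)
        else:
            pos = (t - half) / max(n_fly_stages - half - 1, 1)
        out.append(int(round(pos * (n_worm_stages - 1))))
    return tuple(out)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic bundle.

    Defaults reproduce the standard evaluation regime: 20 fly and 24 worm
    stages, M = 2000 conserved pairs of which 40% carry a planted
    inclusion/skipping shift of 2.5 log units against additive stage noise of
    sd 0.5, with a two-segment piecewise-linear stage correspondence.
    """

    n_fly_stages: int = 20
    n_worm_stages: int = 24
    n_pairs: int = 2000
    frac_signal: float = 0.4
    frac_one_to_many: float = 0.05
    frac_non_cassette: float = 0.1
    frac_orthologous: float = 1.0
    frac_reciprocal_fail: float = 0.0
    n_terminal_pairs: int = 0
    correspondence: tuple[int, ...] | None = None
    effect_size: float = 2.5
    noise_sd: float = 0.5
    fpkm_log_mean: float = 4.0
    fpkm_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_signal", "frac_one_to_many", "frac_non_cassette",
                     "frac_orthologous", "frac_reciprocal_fail"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")
        if self.noise_sd < 0 or self.fpkm_log_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        m = self.n_pairs
        n_bg = m - round(self.frac_signal * m) - round(self.frac_non_cassette * m)
        if n_bg < 0:
            raise ConfigurationError("frac_signal + frac_non_cassette exceed 1")
        if 2 * round(self.frac_one_to_many * m) + round(self.frac_reciprocal_fail * m) > n_bg:
            raise ConfigurationError(
                "not enough background pairs for one-to-many and reciprocal-fail roles"
            )
        corr = self.resolved_correspondence()
        if len(corr) != self.n_fly_stages or any(
            not (0 <= w < self.n_worm_stages) for w in corr
        ):
            raise ConfigurationError("correspondence must map every fly stage to a worm stage")

    def resolved_correspondence(self) -> tuple[int, ...]:
        if self.correspondence is not None:
            return tuple(int(w) for w in self.correspondence)
        return default_correspondence(self.n_fly_stages, self.n_worm_stages)


@dataclass
class SimTruth:
    """Ground truth of the planted structure.

    ``pairs`` has one row per conserved pair: IDs, parent genes, role
    (signal / background / non_cassette), orthology and reciprocal-evidence
    flags, one-to-many flag, and the planted (fly stage, worm stage, status)
    for signal pairs (-1 / "" otherwise).
    """

    pairs: pd.DataFrame
    correspondence: tuple[int, ...]
    n_terminal_pairs: int = 0

    @property
    def signal_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["role"] == "signal"]

    def n_non_cassette(self) -> int:
        return int((self.pairs["role"] == "non_cassette").sum())

    def planted_assoc(self, species: str) -> dict[int, set[tuple[str, str]]]:
        """Planted associated exons per stage index: stage -> {(exon, status)}."""
        col_exon = "fly_exon_id" if species == "fly" else "worm_exon_id"
        col_stage = "planted_fly_stage" if species == "fly" else "planted_worm_stage"
        out: dict[int, set] = {}
        for r in self.signal_pairs.itertuples():
            stage = int(getattr(r, col_stage))
            out.setdefault(stage, set()).add((getattr(r, col_exon), r.planted_status))
        return out


@dataclass
class SimBundle:
    """Everything the pipeline consumes for a two-species toy study, plus truth."""

    config: SimConfig
    fly_annotation: Annotation
    worm_annotation: Annotation
    blast_fw: pd.DataFrame  # fly query, worm subject
    blast_rv: pd.DataFrame  # worm query, fly subject
    orthologs: pd.DataFrame
    fpkm_fly: pd.DataFrame
    fpkm_worm: pd.DataFrame
    samples_fly: pd.DataFrame
    samples_worm: pd.DataFrame
    gene_terms: pd.DataFrame
    dag_edges: pd.DataFrame
    truth: SimTruth


def _species_annotation(chrom: str, exon_names: list[tuple[str, str, str]],
                        genes: list[str], txs: list[str]) -> Annotation:
    rows, tx_exons = [], {}
    for j, ((left, mid, right), gene, tx) in enumerate(zip(exon_names, genes, txs)):
        start0 = 1 + j * _TX_SPACING
        coords = [
            (left, start0, start0 + _EXON_LEN - 1),
            (mid, start0 + _EXON_LEN + _INTRON_LEN, start0 + 2 * _EXON_LEN + _INTRON_LEN - 1),
            (right, start0 + 2 * (_EXON_LEN + _INTRON_LEN),
             start0 + 3 * _EXON_LEN + 2 * _INTRON_LEN - 1),
        ]
        for eid, s, e in coords:
            rows.append((eid, gene, chrom, s, e, "+"))
        tx_exons[tx] = [left, mid, right]
    exons = (
        pd.DataFrame(rows, columns=["exon_id", "gene_id", "chrom", "start", "end", "strand"])
        .drop_duplicates(subset="exon_id")
        .reset_index(drop=True)
    )
    return Annotation(exons=exons, transcript_exons=tx_exons)


def _blast_rows(rng, queries, subjects, evalues):
    n = len(queries)
    return pd.DataFrame(
        {
            "qseqid": queries,
            "sseqid": subjects,
            "pident": np.round(rng.uniform(80, 100, n), 1),
            "length": np.full(n, _EXON_LEN),
            "mismatch": rng.integers(0, 10, n),
            "gapopen": np.zeros(n, dtype=int),
            "qstart": np.ones(n, dtype=int),
            "qend": np.full(n, _EXON_LEN),
            "sstart": np.ones(n, dtype=int),
            "send": np.full(n, _EXON_LEN),
            "evalue": evalues,
            "bitscore": np.round(rng.uniform(100, 250, n), 1),
        }
    )[BLAST6_COLUMNS]


def generate(config: SimConfig) -> SimBundle:
    """Generate a complete synthetic bundle; fixed seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    m = config.n_pairs
    corr = config.resolved_correspondence()

    n_sig = round(config.frac_signal * m)
    n_noncas = round(config.frac_non_cassette * m)
    n_o2m = round(config.frac_one_to_many * m)
    n_rf = round(config.frac_reciprocal_fail * m)

    roles = np.array(["background"] * m, dtype=object)
    roles[:n_sig] = "signal"
    roles[n_sig : n_sig + n_noncas] = "non_cassette"
    background = [i for i in range(m) if roles[i] == "background"]

    fly_exon = np.array([f"FE{i:05d}" for i in range(m)], dtype=object)
    worm_exon = np.array([f"WE{i:05d}" for i in range(m)], dtype=object)
    one_to_many = np.zeros(m, dtype=bool)
    for k in range(n_o2m):
        donor, dup = background[2 * k], background[2 * k + 1]
        worm_exon[dup] = worm_exon[donor]
        one_to_many[donor] = one_to_many[dup] = True
    reciprocal_ok = np.ones(m, dtype=bool)
    for idx in background[2 * n_o2m : 2 * n_o2m + n_rf]:
        reciprocal_ok[idx] = False

    # orthology: signal pairs always orthologous so the conserved set carries signal
    n_orth = round(config.frac_orthologous * m)
    is_orth = np.zeros(m, dtype=bool)
    is_orth[:n_sig] = True
    extra = max(n_orth - n_sig, 0)
    non_sig = [i for i in range(m) if roles[i] != "signal"]
    is_orth[non_sig[:extra]] = True

    # planted stages and statuses, balanced across the fly stage axis
    planted_fly = np.full(m, -1)
    planted_worm = np.full(m, -1)
    planted_status = np.array([""] * m, dtype=object)
    for s in range(n_sig):
        t_f = s % config.n_fly_stages
        planted_fly[s] = t_f
        planted_worm[s] = corr[t_f]
        planted_status[s] = "HIGH" if s % 2 == 0 else "LOW"

    # genes & annotation: one 3-exon transcript per (unique) target exon
    fly_gene = np.array([f"FG{i:05d}" for i in range(m)], dtype=object)
    fly_tx = [f"FT{i:05d}" for i in range(m)]
    fly_names = [(f"FE{i:05d}L", fly_exon[i], f"FE{i:05d}R") for i in range(m)]
    fly_ann = _species_annotation("chrF", fly_names, list(fly_gene), fly_tx)

    worm_unique: list[int] = []
    seen: set[str] = set()
    worm_owner: dict[str, int] = {}
    for i in range(m):
        if worm_exon[i] not in seen:
            seen.add(worm_exon[i])
            worm_unique.append(i)
            worm_owner[worm_exon[i]] = i
    worm_gene_of_exon = {worm_exon[i]: f"WG{i:05d}" for i in worm_unique}
    worm_gene = np.array([worm_gene_of_exon[worm_exon[i]] for i in range(m)], dtype=object)
    worm_names = [(f"WE{i:05d}L", worm_exon[i], f"WE{i:05d}R") for i in worm_unique]
    worm_ann = _species_annotation(
        "chrW", worm_names,
        [worm_gene_of_exon[worm_exon[i]] for i in worm_unique],
        [f"WT{i:05d}" for i in worm_unique],
    )

    orthologs = pd.DataFrame(
        {"fly_gene_id": fly_gene[is_orth], "worm_gene_id": worm_gene[is_orth]}
    ).drop_duplicates().reset_index(drop=True)

    # BLAST evidence: both directions for every pair; failed pairs miss the cutoff
    # in the reverse direction; optional terminal-exon decoys pass reciprocity but
    # fail the internal-exon requirement downstream.
    ev_fw = 10.0 ** rng.uniform(-40, -8, m)
    ev_rv = 10.0 ** rng.uniform(-40, -8, m)
    ev_rv[~reciprocal_ok] = 10.0 ** rng.uniform(-4, -1, (~reciprocal_ok).sum())
    fw = _blast_rows(rng, list(fly_exon), list(worm_exon), ev_fw)
    rv = _blast_rows(rng, list(worm_exon), list(fly_exon), ev_rv)
    if config.n_terminal_pairs:
        tq = [f"FE{k:05d}L" for k in range(config.n_terminal_pairs)]
        ts = [f"WE{worm_unique[k]:05d}L" for k in range(config.n_terminal_pairs)]
        ev_t = 10.0 ** rng.uniform(-30, -10, config.n_terminal_pairs)
        fw = pd.concat([fw, _blast_rows(rng, tq, ts, ev_t)], ignore_index=True)
        rv = pd.concat([rv, _blast_rows(rng, ts, tq, ev_t)], ignore_index=True)

    # target log-ratio series: per-exon constant baseline + planted window + noise
    def ratio_matrix(n_stages, exon_rows, planted_stage, status_of):
        n_ex = len(exon_rows)
        base = rng.normal(0.0, 0.5, n_ex)
        r = np.tile(base[:, None], (1, n_stages))
        if config.noise_sd > 0:
            r = r + rng.normal(0.0, config.noise_sd, (n_ex, n_stages))
        for row, i in enumerate(exon_rows):
            t = planted_stage[i]
            if t < 0:
                continue
            lo, hi = max(t - 1, 0), min(t + 1, n_stages - 1)
            sign = 1.0 if status_of[i] == "HIGH" else -1.0
            r[row, lo : hi + 1] += sign * config.effect_size
        return r

    fly_rows = list(range(m))
    fly_ratio = ratio_matrix(config.n_fly_stages, fly_rows, planted_fly, planted_status)
    worm_ratio = ratio_matrix(config.n_worm_stages, worm_unique, planted_worm, planted_status)

    def fpkm_table(prefix, n_stages, exon_rows, exon_ids_of, ratio, roles_of):
        samples = [f"{prefix}{t + 1:02d}" for t in range(n_stages)]
        n_ex = len(exon_rows)
        s_fpkm = rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd, (n_ex, n_stages))
        i_fpkm = np.maximum((s_fpkm + 1.0) * np.exp(ratio) - 1.0, 0.0)
        for row, i in enumerate(exon_rows):
            if roles_of[i] == "non_cassette":
                s_fpkm[row] = 0.0
                i_fpkm[row] = rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sd, n_stages)
        recs = []
        for row, i in enumerate(exon_rows):
            for t, sample in enumerate(samples):
                recs.append((exon_ids_of[i], sample, i_fpkm[row, t], s_fpkm[row, t]))
        return (
            pd.DataFrame(recs, columns=["exon_id", "sample_id", "fpkm_I", "fpkm_S"]),
            pd.DataFrame({"sample_id": samples, "class": "stage",
                          "stage_rank": np.arange(1, n_stages + 1)}),
        )

    fpkm_fly, samples_fly = fpkm_table("FS", config.n_fly_stages, fly_rows, fly_exon,
                                       fly_ratio, roles)
    fpkm_worm, samples_worm = fpkm_table("WS", config.n_worm_stages, worm_unique, worm_exon,
                                         worm_ratio, roles)

    # small term ontology: root -> 3 children -> 6 grandchildren; signal genes share a term
    dag_edges = pd.DataFrame(
        [("T:0000", f"T:000{i}") for i in (1, 2, 3)]
        + [(f"T:000{1 + i % 3}", f"T:001{i}") for i in range(6)],
        columns=["parent", "child"],
    )
    term_rows = []
    for i in range(m):
        term = "T:0010" if roles[i] == "signal" else f"T:001{1 + i % 5}"
        term_rows.append((fly_gene[i], term))
        term_rows.append((worm_gene[i], term))
    gene_terms = (
        pd.DataFrame(term_rows, columns=["gene_id", "term_id"])
        .drop_duplicates()
        .reset_index(drop=True)
    )
    gene_terms["term_name"] = gene_terms["term_id"]
    gene_terms["namespace"] = "biological_process"

    truth_pairs = pd.DataFrame(
        {
            "pair_index": np.arange(m),
            "fly_exon_id": fly_exon,
            "worm_exon_id": worm_exon,
            "fly_gene_id": fly_gene,
            "worm_gene_id": worm_gene,
            "role": roles,
            "is_orthologous": is_orth,
            "reciprocal_ok": reciprocal_ok,
            "is_one_to_many": one_to_many,
            "planted_fly_stage": planted_fly,
            "planted_worm_stage": planted_worm,
            "planted_status": planted_status,
        }
    )
    truth = SimTruth(pairs=truth_pairs, correspondence=corr,
                     n_terminal_pairs=config.n_terminal_pairs)

    return SimBundle(
        config=config,
        fly_annotation=fly_ann,
        worm_annotation=worm_ann,
        blast_fw=fw,
        blast_rv=rv,
        orthologs=orthologs,
        fpkm_fly=fpkm_fly,
        fpkm_worm=fpkm_worm,
        samples_fly=samples_fly,
        samples_worm=samples_worm,
        gene_terms=gene_terms,
        dag_edges=dag_edges,
        truth=truth,
    )


_FILES = {
    "blast_fw": "blast_fw.tsv",
    "blast_rv": "blast_rv.tsv",
    "orthologs": "orthologs.tsv",
    "fpkm_fly": "fpkm_fly.tsv",
    "fpkm_worm": "fpkm_worm.tsv",
    "samples_fly": "samples_fly.tsv",
    "samples_worm": "samples_worm.tsv",
    "gene_terms": "gene_terms.tsv",
    "dag_edges": "dag_edges.tsv",
}


def write_bundle(bundle: SimBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; re-reading reproduces the tables.

    Layout: fly.gtf / worm.gtf, outfmt-6 blast_fw/rv.tsv (headerless), the
    TSV tables, truth_pairs.tsv and truth.json.  Returns name -> path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    out["fly_gtf"] = directory / "fly.gtf"
    write_gtf(bundle.fly_annotation, out["fly_gtf"])
    out["worm_gtf"] = directory / "worm.gtf"
    write_gtf(bundle.worm_annotation, out["worm_gtf"])

    for attr, fname in _FILES.items():
        path = directory / fname
        df = getattr(bundle, attr)
        header = attr not in ("blast_fw", "blast_rv")
        df.to_csv(path, sep="\t", index=False, header=header)
        out[attr] = path

    out["truth_pairs"] = directory / "truth_pairs.tsv"
    bundle.truth.pairs.to_csv(out["truth_pairs"], sep="\t", index=False)
    out["truth"] = directory / "truth.json"
    with open(out["truth"], "w") as fh:
        json.dump(
            {
                "correspondence": list(bundle.truth.correspondence),
                "n_terminal_pairs": bundle.truth.n_terminal_pairs,
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in vars(bundle.config).items()
                },
            },
            fh,
            indent=1,
        )
    return out


def read_bundle(directory: str | Path) -> SimBundle:
    """Reconstruct a bundle from :func:`write_bundle` output."""
    from .conservation import load_blast_table

    directory = Path(directory)
    with open(directory / "truth.json") as fh:
        meta = json.load(fh)
    cfg_raw = dict(meta["config"])
    if cfg_raw.get("correspondence") is not None:
        cfg_raw["correspondence"] = tuple(cfg_raw["correspondence"])
    config = SimConfig(**cfg_raw)
    truth_pairs = pd.read_csv(
        directory / "truth_pairs.tsv", sep="\t",
        dtype={"planted_status": str}, keep_default_na=False,
    )
    truth_pairs["planted_status"] = truth_pairs["planted_status"].fillna("")
    tables = {}
    for attr, fname in _FILES.items():
        path = directory / fname
        if attr in ("blast_fw", "blast_rv"):
            tables[attr] = load_blast_table(path)
        else:
            tables[attr] = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    tables["orthologs"] = pd.read_csv(
        directory / _FILES["orthologs"], sep="\t", dtype=str
    )
    return SimBundle(
        config=config,
        fly_annotation=load_gtf(directory / "fly.gtf"),
        worm_annotation=load_gtf(directory / "worm.gtf"),
        truth=SimTruth(
            pairs=truth_pairs,
            correspondence=tuple(meta["correspondence"]),
            n_terminal_pairs=int(meta["n_terminal_pairs"]),
        ),
        **tables,
    )
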