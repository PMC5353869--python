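"""Shared fixtures: synthetic bundles and end-to-end products."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import exoncorr as xc
from exoncorr.association import select_associated
from exoncorr.conservation import restrict_to_exons
from exoncorr.correspondence import paired_status_rows
from exoncorr.splicing_quant import SmootherConfig, build_ratio_matrix, cassette_filter


@pytest.fixture(scope="session")
def small_bundle():
    """A small fully-featured bundle exercising every generator role."""
    cfg = xc.SimConfig(
        n_pairs=100,
        n_fly_stages=8,
        n_worm_stages=10,
        frac_signal=0.3,
        frac_one_to_many=0.05,
        frac_non_cassette=0.2,
        frac_orthologous=0.6,
        frac_reciprocal_fail=0.05,
        n_terminal_pairs=3,
        seed=3,
    )
    return xc.generate(cfg)


@dataclass
class PipelineProducts:
    bundle: xc.SimBundle
    matrices: dict
    assoc: dict  # species -> list[AssociatedExonSet]
    rows: object  # PairedStatusRows over cassette-retained reciprocal pairs
    between_map: xc.CorrespondenceMap


def _run_products(bundle: xc.SimBundle) -> PipelineProducts:
    matrices, assoc = {}, {}
    for name, fpkm, samp in (
        ("fly", bundle.fpkm_fly, bundle.samples_fly),
        ("worm", bundle.fpkm_worm, bundle.samples_worm),
    ):
        keep = cassette_filter(fpkm)
        matrices[name] = build_ratio_matrix(
            fpkm[fpkm["exon_id"].isin(keep)], samp, SmootherConfig()
        )
        assoc[name] = select_associated(matrices[name])
    pairs = restrict_to_exons(
        bundle.truth.pairs[bundle.truth.pairs["reciprocal_ok"]],
        set(matrices["fly"].exon_ids),
        set(matrices["worm"].exon_ids),
    )
    rows = paired_status_rows(pairs.reset_index(drop=True))
    cmap = xc.build_map(assoc["fly"], assoc["worm"], "between", rows=rows)
    return PipelineProducts(bundle, matrices, assoc, rows, cmap)


@pytest.fixture(scope="session")
def study_bundle():
    """The standard evaluation bundle: default SimConfig conditions, seed 7."""
    return xc.generate(xc.SimConfig(seed=7))


@pytest.fixture(scope="session")
def study_products(study_bundle):
    """Ratio matrices, associated exons and between-species map for the study bundle."""
    return _run_products(study_bundle)
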