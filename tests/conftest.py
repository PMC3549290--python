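"""Shared fixtures.

The default synthetic bundle (seed 1) is generated once per session and the
full pipeline is run on it once; most recovery and report tests read from
these two session-scoped fixtures instead of regenerating data.
"""

from __future__ import annotations

import json
import os

import pytest

from cisnat import RunConfig, SimulationConfig, run, write_fixture

BUNDLE_SEED = 1


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default fixture bundle: paths, ground truth and the config used."""
    out = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig(seed=BUNDLE_SEED)
    paths = write_fixture(config, str(out))
    with open(paths["truth"]) as fh:
        truth = json.load(fh)
    return {"dir": str(out), "paths": paths, "truth": truth, "config": config}


@pytest.fixture(scope="session")
def run_config(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    cfg = bundle["config"]
    return RunConfig(
        gff3=bundle["paths"]["annotation"],
        bed_by_condition={
            c: bundle["paths"][f"smallrna_{c}"] for c in cfg.conditions
        },
        expression_tsv=bundle["paths"]["expression"],
        domain_map=bundle["paths"]["domains"],
        control_condition=cfg.control_condition,
        out_dir=str(out),
    )


@pytest.fixture(scope="session")
def run_result(run_config):
    """Full pipeline result on the default bundle (computed once)."""
    return run(run_config)


def small_config(seed: int = 7) -> SimulationConfig:
    """A reduced generator config for tests that need fast regeneration."""
    return SimulationConfig(
        seed=seed,
        n_enclosed=4,
        n_convergent=4,
        n_divergent=4,
        one_to_two_subtypes=("enclosed+convergent",),
        n_one_to_three=1,
        n_two_to_two=1,
        n_one_to_four=0,
        n_same_strand_decoys=1,
        n_threshold_decoys=1,
        n_excluded_biotype_decoys=1,
        n_isoform_decoys=1,
        n_structural_rnas=4,
        n_transposons=1,
        reads_per_pair=40,
        n_background_reads=10,
        n_excluded_reads=8,
        n_out_of_range_reads=4,
        n_organelle_reads=4,
    )
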