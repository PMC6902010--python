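from pathlib import Path

import pytest

from mkscan.pipeline import RunConfig, run_all
from mkscan.synthetic_data import SimulationConfig, simulate_dataset

_PATH_KEYS = {
    "gff": "gff",
    "genome_fasta": "genome",
    "vcf": "vcf",
    "cds_a_fasta": "cds_a",
    "cds_b_fasta": "cds_b",
    "hits_ab": "hits_ab",
    "hits_ba": "hits_ba",
    "labels_tsv": "labels",
    "metabolites_tsv": "metabolites",
}


def run_config_for(paths: dict, out_dir: Path, seed: int = 0, **overrides) -> RunConfig:
    """Build a RunConfig pointing at a simulated dataset's files."""
    kwargs = {field: str(paths[key]) for field, key in _PATH_KEYS.items()}
    kwargs.update(out_dir=str(out_dir), seed=seed, **overrides)
    return RunConfig(**kwargs)


def simulate_and_run(config: SimulationConfig, base_dir: Path, seed: int | None = None):
    """Simulate a dataset and run the full pipeline on it."""
    paths = simulate_dataset(config, base_dir / "data")
    rc = run_config_for(paths, base_dir / "results", seed=config.seed if seed is None else seed)
    outputs = run_all(rc)
    return paths, outputs


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small but complete synthetic dataset shared across tests."""
    base = tmp_path_factory.mktemp("tiny")
    config = SimulationConfig(n_genes=30, n_accessions=10, codons_min=60, codons_max=120, seed=5)
    paths = simulate_dataset(config, base)
    return config, paths


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_dataset, tmp_path_factory):
    """Full pipeline outputs on the tiny dataset."""
    config, paths = tiny_dataset
    out = tmp_path_factory.mktemp("tiny_results")
    rc = run_config_for(paths, out, seed=config.seed)
    return run_all(rc)
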