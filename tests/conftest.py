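import json
from pathlib import Path

import pandas as pd
import pytest

from mgdrn.pipeline import RunConfig, run_pipeline
from mgdrn.synergy import SynergyModule
from mgdrn.synthetic import SyntheticConfig, SyntheticDataset, generate_dataset


@pytest.fixture(scope="session")
def default_dataset() -> SyntheticDataset:
    """The reference synthetic fixture at seed 1."""
    return generate_dataset(SyntheticConfig(seed=1))


def small_config(seed: int, **overrides) -> SyntheticConfig:
    """A fast, reduced variant of the reference fixture for unit tests."""
    params = dict(
        n_genes=60, n_mirnas=12, n_normal_samples=30, n_tumor_samples=30,
        n_true_edges=40, n_dysregulated_edges=24,
        decoy_pair_count=40, multi_source_decoy_count=4,
        pathway_count=20, pathway_size=12,
        planted_modules=((2, 4),), module_targets_per_mirna=6,
        module_pathway_overlap=4, n_free_de_genes=6, seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def run_on_dataset(dataset: SyntheticDataset, workdir: Path,
                   **config_overrides) -> tuple[dict, RunConfig]:
    """Write a dataset to disk and run the full pipeline on it."""
    data_dir = workdir / "data"
    manifest = dataset.write(data_dir)
    params = dict(
        gene_expression=manifest["gene_expression"],
        mirna_expression=manifest["mirna_expression"],
        conditions=manifest["conditions"],
        prediction_tables=[
            manifest[f"predictions/{t.source_name}"]
            for t in dataset.prediction_tables
        ],
        source_names=[t.source_name for t in dataset.prediction_tables],
        mature_map=manifest["mature_map"],
        gmt=manifest["pathways"],
        output_dir=str(workdir / "out"),
    )
    params.update(config_overrides)
    config = RunConfig(**params)
    return run_pipeline(config), config


def read_mgdrn_pairs(outdir: str | Path) -> set[tuple[str, str]]:
    edges = pd.read_csv(Path(outdir) / "mgdrn_edges.tsv", sep="\t")
    return set(zip(edges["mirna"], edges["gene"]))


def read_modules(outdir: str | Path) -> list[SynergyModule]:
    payload = json.loads((Path(outdir) / "modules.json").read_text())
    return [
        SynergyModule(frozenset(m["mirnas"]), frozenset(m["pathways"]),
                      m["density"])
        for m in payload
    ]
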