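import filecmp
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from isocat import RunConfig, SimulationConfig, run_all, write_bundle
from isocat.simulate import GrowthParams


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast panel for unit tests: few short genes, quick growth grid."""
    defaults = dict(
        seed=seed,
        n_degraders=2,
        n_nondegraders=2,
        genes_per_strain=20,
        cluster_size=4,
        cluster_start_rank=9,
        protein_length=60,
        growth=GrowthParams(t_max=24.0, dt=1.0, n_replicates=4),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def run_config_for(data: Path, seed: int) -> RunConfig:
    return RunConfig(
        seed=seed,
        inputs={
            "proteins": str(data / "proteins.faa"),
            "genes": str(data / "genes.tsv"),
            "phenotypes": str(data / "phenotypes.tsv"),
            "counts": str(data / "counts.tsv"),
            "design": str(data / "design.tsv"),
            "growth": str(data / "growth.tsv"),
            "peaks": str(data / "peaks.tsv"),
        },
    )


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """Full-size synthetic study at seed 1 (the panel-scale conditions):
    5 degraders + 5 non-degraders + reference, 200 genes, planted cluster
    of 8, background divergence 0.05, cluster lost in all non-degraders,
    induction log2FC 3, mean count 1000."""
    root = tmp_path_factory.mktemp("study")
    data = root / "data"
    truth = write_bundle(data, SimulationConfig(seed=1))
    return {"root": root, "data": data, "truth": truth}


@pytest.fixture(scope="session")
def study_run(study_bundle):
    """One full pipeline run over the seed-1 study bundle."""
    outdir = study_bundle["root"] / "out"
    cfg = run_config_for(study_bundle["data"], seed=1)
    report = run_all(cfg, outdir)
    return {"report": report, "outdir": outdir, **study_bundle}


def dirs_byte_identical(d1: Path, d2: Path) -> bool:
    names1 = sorted(p.name for p in Path(d1).iterdir())
    names2 = sorted(p.name for p in Path(d2).iterdir())
    if names1 != names2:
        return False
    return all(filecmp.cmp(Path(d1) / n, Path(d2) / n, shallow=False) for n in names1)
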