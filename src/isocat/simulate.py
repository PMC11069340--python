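"""Synthetic strain panels, counts, growth curves and peak lists.

The generator plants a ground-truth catabolic gene cluster so every
pipeline stage can be scored without external data:

* a reference strain (the RNA-seq strain, a degrader) carries the
  cluster; additional degraders carry orthologs diverged at a low rate;
  non-degraders lose each cluster gene with a configurable probability
  and any retained copy is strongly diverged;
* background genes diverge at a common background rate in all strains;
* RNA-seq counts are negative-binomial with log-normal library sizes,
  and cluster genes are induced (mean multiplied by 2**log2fc) in the
  treated condition;
* growth curves are logistic with Gaussian read noise, the growth rate
  of non-degraders reduced in proportion to dose;
* the peak list holds one [M-H]- ion per pathway-intermediate formula
  with ppm-scale mass noise plus uniform decoy peaks.

Mutation is i.i.d. per-residue substitution to a uniformly random
different residue (no indels), so the expected best-hit identity of a
gene diverged at rate p is exactly 100*(1-p) — the conservation tests
exploit this closed form.  Everything is deterministic under a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CountMatrix,
    GeneRecord,
    PhenotypeRecord,
    StrainPanel,
    write_counts,
    write_fasta,
    write_gene_table,
    write_phenotypes,
    write_tsv,
)
from .errors import ConfigError
from .masses import mz_deprotonated, parse_formula

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Pathway-intermediate formulas planted by default: the
#: mono-hydroxylated isoflavone (C15H10O5) and the two B-ring-retaining
#: ring-cleavage products (C10H10O3, C10H10O4).
DEFAULT_INTERMEDIATES = ("C15H10O5", "C10H10O3", "C10H10O4")

DEFAULT_DOSES = (0.0, 10.0, 30.0, 100.0)

_CLUSTER_PRODUCTS = (
    "FAD-binding monooxygenase",
    "cupin-domain oxidoreductase",
    "glyoxalase family protein",
    "alpha/beta fold hydrolase",
    "ring-cleavage dioxygenase",
    "MFS transporter",
    "LysR-family transcriptional regulator",
    "aldehyde dehydrogenase",
)


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth from a fixed inoculum, plus Gaussian read noise.

    Curves follow OD(t) = K / (1 + exp(-r (t - t_infl))) where the
    inflection time is set by the inoculum density: all cultures start
    at the same OD, so t_infl = ln(K/x0 - 1) / r and a dose-reduced
    rate both flattens and delays the curve (as in a real plate assay).
    ``lag`` is the inflection time of the uninhibited curve; it fixes
    the inoculum via x0 = K / (1 + exp(rate * lag)).
    """

    carrying_capacity: float = 1.0  # OD600
    rate: float = 0.5  # 1/h
    lag: float = 10.0  # h (inflection point at the uninhibited rate)
    inhibition_slope: float = 0.006  # fractional rate loss per uM, non-degraders
    noise_sd: float = 0.02  # OD600
    t_max: float = 48.0  # h
    dt: float = 0.5  # h (plate-reader interval)
    n_replicates: int = 6


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_degraders: int = 5  # degrader strains besides the reference
    n_nondegraders: int = 5
    genes_per_strain: int = 200
    cluster_size: int = 8
    cluster_start_rank: int = 97  # 1-based rank of the first cluster gene
    protein_length: int = 200
    background_divergence: float = 0.05
    cluster_divergence_in_degraders: float = 0.05
    cluster_loss_prob_in_nondegraders: float = 1.0
    #: extra divergence applied to cluster genes a non-degrader retains
    retained_cluster_extra_divergence: float = 0.25
    induction_log2fc: float = 3.0
    nb_dispersion: float = 0.05
    mean_count: float = 1000.0
    n_replicates: int = 3  # RNA-seq replicates per condition
    library_size_sigma: float = 0.2
    growth: GrowthParams = field(default_factory=GrowthParams)
    ms_ppm_sigma: float = 2.0
    n_decoy_peaks: int = 30
    reference_strain_id: str = "VREF"

    def __post_init__(self) -> None:
        for name in (
            "background_divergence",
            "cluster_divergence_in_degraders",
        ):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if not (0 <= self.cluster_loss_prob_in_nondegraders <= 1):
            raise ConfigError("cluster_loss_prob_in_nondegraders must be in [0, 1]")
        if self.cluster_size < 1 or self.cluster_start_rank < 1:
            raise ConfigError("cluster_size and cluster_start_rank must be >= 1")
        if self.cluster_start_rank + self.cluster_size - 1 > self.genes_per_strain:
            raise ConfigError("planted cluster does not fit inside the gene range")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.mean_count <= 0:
            raise ConfigError("mean_count must be positive")
        if self.ms_ppm_sigma < 0:
            raise ConfigError("ms_ppm_sigma must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth, sufficient for precision/recall scoring."""

    cluster_locus_ids: tuple[str, ...]
    replicon_id: str
    cluster_start_rank: int
    degraders: tuple[str, ...]
    nondegraders: tuple[str, ...]
    reference_strain_id: str

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            cluster_locus_ids=tuple(d["cluster_locus_ids"]),
            replicon_id=d["replicon_id"],
            cluster_start_rank=int(d["cluster_start_rank"]),
            degraders=tuple(d["degraders"]),
            nondegraders=tuple(d["nondegraders"]),
            reference_strain_id=d["reference_strain_id"],
        )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def mutate_protein(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability p to a uniform other residue."""
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    idx = np.searchsorted(AMINO_ACIDS, arr)
    hit = rng.random(arr.size) < p
    k = int(hit.sum())
    if k:
        repl = rng.integers(0, len(AMINO_ACIDS) - 1, size=k)
        repl = repl + (repl >= idx[hit])  # skip the current residue
        arr[hit] = AMINO_ACIDS[repl]
    return "".join(arr)


def simulate_panel(config: SimulationConfig) -> tuple[StrainPanel, TruthRecord]:
    """Generate the strain panel with a planted cluster in the degraders."""
    rng = np.random.default_rng(config.seed)
    G, L = config.genes_per_strain, config.protein_length
    cluster_ranks = set(
        range(config.cluster_start_rank, config.cluster_start_rank + config.cluster_size)
    )
    replicon = "chr1"
    gene_span = 3 * L + 200  # bp of CDS plus intergenic spacing

    ref_records = []
    for rank in range(1, G + 1):
        start = (rank - 1) * gene_span + 1
        in_cluster = rank in cluster_ranks
        product = (
            _CLUSTER_PRODUCTS[(rank - config.cluster_start_rank) % len(_CLUSTER_PRODUCTS)]
            if in_cluster
            else "hypothetical protein"
        )
        ref_records.append(
            GeneRecord(
                strain_id=config.reference_strain_id,
                locus_id=f"g{rank:04d}",
                replicon_id=replicon,
                start=start,
                end=start + 3 * L - 1,
                strand="+" if rng.random() < 0.5 else "-",
                protein_seq=_random_protein(rng, L),
                product=product,
            )
        )

    degraders = [f"D{i + 1:02d}" for i in range(config.n_degraders)]
    nondegraders = [f"N{i + 1:02d}" for i in range(config.n_nondegraders)]
    genes: dict[str, list[GeneRecord]] = {config.reference_strain_id: ref_records}
    retained_div = min(
        config.background_divergence + config.retained_cluster_extra_divergence, 0.9
    )

    for strain in degraders + nondegraders:
        is_degrader = strain in degraders
        recs = []
        for rank, ref in enumerate(ref_records, start=1):
            in_cluster = rank in cluster_ranks
            if in_cluster and not is_degrader:
                if rng.random() < config.cluster_loss_prob_in_nondegraders:
                    continue  # whole-gene loss
                p = retained_div
            elif in_cluster:
                p = config.cluster_divergence_in_degraders
            else:
                p = config.background_divergence
            recs.append(
                dataclasses.replace(
                    ref, strain_id=strain, protein_seq=mutate_protein(ref.protein_seq, p, rng)
                )
            )
        genes[strain] = recs

    phenotypes = {
        config.reference_strain_id: PhenotypeRecord(
            config.reference_strain_id, degrader=True, isolation_source="legume"
        )
    }
    for strain in degraders:
        source = "legume" if rng.random() < 0.75 else "non-legume plant"
        phenotypes[strain] = PhenotypeRecord(strain, degrader=True, isolation_source=source)
    for strain in nondegraders:
        source = "soil" if rng.random() < 0.75 else "other"
        phenotypes[strain] = PhenotypeRecord(strain, degrader=False, isolation_source=source)

    panel = StrainPanel(
        reference_strain_id=config.reference_strain_id, genes=genes, phenotypes=phenotypes
    )
    truth = TruthRecord(
        cluster_locus_ids=tuple(f"g{r:04d}" for r in sorted(cluster_ranks)),
        replicon_id=replicon,
        cluster_start_rank=config.cluster_start_rank,
        degraders=tuple(degraders),
        nondegraders=tuple(nondegraders),
        reference_strain_id=config.reference_strain_id,
    )
    return panel, truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial via gamma-Poisson; dispersion 0 is exactly Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    panel: StrainPanel, config: SimulationConfig, truth: TruthRecord | None = None
) -> CountMatrix:
    """Two-condition NB counts for the reference strain's genes."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    genes = [g.locus_id for g in panel.reference_genes()]
    if truth is None:
        cluster = set(
            f"g{r:04d}"
            for r in range(
                config.cluster_start_rank, config.cluster_start_rank + config.cluster_size
            )
        )
    else:
        cluster = set(truth.cluster_locus_ids)
    n_rep = max(2, config.n_replicates)
    samples = [f"treated_{i + 1}" for i in range(n_rep)] + [
        f"control_{i + 1}" for i in range(n_rep)
    ]
    lib = np.exp(rng.normal(0.0, config.library_size_sigma, size=len(samples)))
    base = np.full(len(genes), config.mean_count)
    induced = np.array([g in cluster for g in genes])
    fold = 2.0 ** config.induction_log2fc
    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        mu = base * lib[j]
        if sample.startswith("treated"):
            mu = np.where(induced, mu * fold, mu)
        counts[:, j] = _nb_draw(rng, mu, config.nb_dispersion)
    design = pd.DataFrame(
        {
            "condition": ["treated"] * n_rep + ["control"] * n_rep,
            "replicate": list(range(1, n_rep + 1)) * 2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples), design=design
    )


def simulate_growth(
    panel: StrainPanel,
    doses: Sequence[float] = DEFAULT_DOSES,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Long-format logistic growth curves, inhibited in non-degraders."""
    config = config or SimulationConfig()
    if any(d < 0 for d in doses):
        raise ConfigError("doses must be non-negative")
    if 0 not in [float(d) for d in doses]:
        raise ConfigError("doses must include the 0 uM control")
    gp = config.growth
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    times = np.arange(0.0, gp.t_max + gp.dt / 2, gp.dt)
    x0 = gp.carrying_capacity / (1.0 + np.exp(gp.rate * gp.lag))  # inoculum OD
    rows = []
    for strain in panel.strain_ids:
        degrader = panel.phenotypes[strain].degrader if strain in panel.phenotypes else True
        for dose in doses:
            r_eff = gp.rate
            if not degrader:
                r_eff = gp.rate * max(0.0, 1.0 - gp.inhibition_slope * dose)
            if r_eff > 0:
                t_infl = np.log(gp.carrying_capacity / x0 - 1.0) / r_eff
                clean = gp.carrying_capacity / (1.0 + np.exp(-r_eff * (times - t_infl)))
            else:
                clean = np.full_like(times, x0)  # fully arrested culture
            for rep in range(1, gp.n_replicates + 1):
                od = np.clip(clean + rng.normal(0.0, gp.noise_sd, size=times.size), 0.0, None)
                rows.append(
                    pd.DataFrame(
                        {
                            "strain_id": strain,
                            "dose_uM": float(dose),
                            "replicate": rep,
                            "time_h": times,
                            "od600": od,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def simulate_peaks(
    intermediate_formulas: Sequence[str] = DEFAULT_INTERMEDIATES,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Peak list with one [M-H]- ion per formula plus uniform decoys."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    rows = []
    for i, text in enumerate(intermediate_formulas):
        theo = mz_deprotonated(parse_formula(text))
        mz = theo * (1.0 + rng.normal(0.0, config.ms_ppm_sigma) * 1e-6)
        rows.append(
            {
                "rt_min": 10.0 + 2.0 * i,
                "mz": mz,
                "intensity": float(np.exp(rng.normal(12.0, 0.5))),
            }
        )
    for _ in range(config.n_decoy_peaks):
        rows.append(
            {
                "rt_min": float(rng.uniform(1.0, 20.0)),
                "mz": float(rng.uniform(50.0, 350.0)),
                "intensity": float(np.exp(rng.normal(9.0, 1.0))),
            }
        )
    return (
        pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])
        .sort_values(["rt_min", "mz"], kind="stable")
        .reset_index(drop=True)
    )


def write_bundle(
    outdir: str | Path,
    config: SimulationConfig,
    doses: Sequence[float] = DEFAULT_DOSES,
    intermediate_formulas: Sequence[str] = DEFAULT_INTERMEDIATES,
) -> TruthRecord:
    """Generate everything and write the exact input formats the readers expect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, truth = simulate_panel(config)
    counts = simulate_counts(panel, config, truth)
    growth = simulate_growth(panel, doses, config)
    peaks = simulate_peaks(intermediate_formulas, config)

    proteins = {
        f"{g.strain_id}|{g.locus_id}": g.protein_seq
        for strain in panel.strain_ids
        for g in panel.genes[strain]
    }
    write_fasta(proteins, outdir / "proteins.faa")
    write_gene_table(
        [g for strain in panel.strain_ids for g in panel.genes[strain]],
        outdir / "genes.tsv",
    )
    write_phenotypes(panel.phenotypes, outdir / "phenotypes.tsv")
    write_counts(counts, outdir / "counts.tsv", outdir / "design.tsv")
    write_tsv(growth, outdir / "growth.tsv")
    write_tsv(peaks, outdir / "peaks.tsv")
    truth.to_json(outdir / "truth.json")
    return truth
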