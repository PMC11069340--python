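"""End-to-end orchestration: config loading, stage wiring, run report.

Stages compose via files: every stage writes the documented TSV/JSON
outputs into the run directory, and ``report.json`` collects the
machine-readable summary (config echo, seed, top hotspots, enrichment,
growth tests, peak annotations).  Reports are deterministic under a
fixed seed and config — no timestamps are written.
"""

from __future__ import annotations

import dataclasses
import importlib.metadata
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import Bio
import numpy
import pandas
import scipy

from . import conservation as cons_mod
from . import expression, growth, masses, screen
from .core import (
    StrainPanel,
    build_panel,
    read_counts,
    read_fasta,
    read_gene_table,
    read_growth,
    read_peaks,
    read_phenotypes,
    write_tsv,
)
from .errors import ConfigError, FormatError


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a pipeline run (echoed into the report)."""

    seed: int = 0
    reference_strain_id: str = "VREF"
    inputs: dict[str, str] = field(default_factory=dict)
    expression: dict[str, Any] = field(
        default_factory=lambda: {"pseudocount": 1.0}
    )
    screen: dict[str, Any] = field(
        default_factory=lambda: {
            "log2fc_threshold": 1.0,
            "conserved_identity_min": 50.0,
            "conserved_coverage_min": 50.0,
            "conserved_fraction_degraders": 1.0,
            "nonconserved_identity_max": 30.0,
            "nonconserved_fraction_nondegraders": 1.0,
            "presence_min_fraction": 0.5,
            "trait_sources": ["legume", "non-legume plant"],
        }
    )
    hotspot: dict[str, Any] = field(
        default_factory=lambda: {"min_run": 4, "max_gap": 2}
    )
    alignment: dict[str, Any] = field(
        default_factory=lambda: {
            "matrix": "BLOSUM62",
            "gap_open": 10.0,
            "gap_extend": 1.0,
            "min_coverage": 50.0,
            "min_score": 0.0,
            "prefilter_k": 5,
        }
    )
    growth: dict[str, Any] = field(
        default_factory=lambda: {"index_variant": "one_minus_ratio", "alpha": 0.05}
    )
    mass: dict[str, Any] = field(
        default_factory=lambda: {
            "tol_ppm": 10.0,
            "electron_correction": False,
            "formulas": ["C15H10O5", "C10H10O3", "C10H10O4"],
        }
    )


_TOP_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML run config; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    defaults = RunConfig()
    merged: dict[str, Any] = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in raw:
            merged[f.name] = getattr(defaults, f.name)
        elif isinstance(getattr(defaults, f.name), dict):
            section = dict(getattr(defaults, f.name))
            extra = set(raw[f.name]) - set(section) if f.name != "inputs" else set()
            if extra:
                raise ConfigError(f"unknown key(s) in [{f.name}]: {sorted(extra)}")
            section.update(raw[f.name])
            merged[f.name] = section
        else:
            merged[f.name] = raw[f.name]
    cfg = RunConfig(**merged)
    for name, p in cfg.inputs.items():
        if not Path(p).exists():
            raise FormatError(f"input file for {name!r} not found: {p}")
    return cfg


def _require_input(cfg: RunConfig, key: str) -> str:
    if key not in cfg.inputs:
        raise ConfigError(f"config is missing required input {key!r}")
    return cfg.inputs[key]


def load_panel(cfg: RunConfig) -> StrainPanel:
    proteins = read_fasta(_require_input(cfg, "proteins"))
    records = read_gene_table(_require_input(cfg, "genes"), proteins)
    phenotypes = read_phenotypes(_require_input(cfg, "phenotypes"))
    return build_panel(records, phenotypes, cfg.reference_strain_id)


def _jsonable(x: Any) -> Any:
    """Make report values strict-JSON safe (inf/nan become strings)."""
    if isinstance(x, float):
        if x != x:
            return "nan"
        if x in (float("inf"), float("-inf")):
            return "inf" if x > 0 else "-inf"
        return x
    if isinstance(x, (numpy.integer,)):
        return int(x)
    if isinstance(x, (numpy.floating,)):
        return _jsonable(float(x))
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def _hotspot_dict(h: screen.Hotspot) -> dict[str, Any]:
    return {
        "replicon_id": h.replicon_id,
        "start_rank": h.start_rank,
        "end_rank": h.end_rank,
        "locus_ids": list(h.locus_ids),
        "n_candidates": h.n_candidates,
        "span": h.span,
        "score": h.score,
    }


def _enrichment_dict(e: screen.EnrichmentResult) -> dict[str, Any]:
    return {
        "contingency": [list(r) for r in e.contingency],
        "odds_ratio": _jsonable(e.odds_ratio),
        "p_two_sided": e.p_two_sided,
    }


def cluster_presence(
    cons: cons_mod.ConservationMatrix,
    hotspot: screen.Hotspot,
    identity_min: float,
    coverage_min: float,
    min_fraction: float,
) -> dict[str, bool]:
    """Call the cluster present in a strain when it conserves enough hotspot genes."""
    out = {}
    for strain in cons.strain_ids:
        ok = 0
        for locus in hotspot.locus_ids:
            ident = cons.identity.loc[locus, strain]
            cov = cons.coverage.loc[locus, strain]
            if pandas.notna(ident) and ident >= identity_min and cov >= coverage_min:
                ok += 1
        out[strain] = ok / len(hotspot.locus_ids) >= min_fraction
    return out


def run_screen(cfg: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Expression screen -> conservation -> candidate/hotspot/enrichment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = load_panel(cfg)

    cm = read_counts(_require_input(cfg, "counts"), _require_input(cfg, "design"))
    fc = expression.fold_change_table(
        cm,
        pseudocount=cfg.expression["pseudocount"],
        log2fc_threshold=cfg.screen["log2fc_threshold"],
    )
    write_tsv(fc.rename_axis("gene_id").reset_index(), outdir / "foldchange.tsv")

    al = cfg.alignment
    consmat = cons_mod.conservation_matrix(
        panel,
        min_coverage=al["min_coverage"],
        min_score=al["min_score"],
        matrix=al["matrix"],
        gap_open=al["gap_open"],
        gap_extend=al["gap_extend"],
        prefilter_k=al["prefilter_k"],
    )
    write_tsv(consmat.to_long(), outdir / "conservation.tsv")

    criteria = screen.ScreenCriteria(
        log2fc_threshold=cfg.screen["log2fc_threshold"],
        conserved_identity_min=cfg.screen["conserved_identity_min"],
        conserved_coverage_min=cfg.screen["conserved_coverage_min"],
        conserved_fraction_degraders=cfg.screen["conserved_fraction_degraders"],
        nonconserved_identity_max=cfg.screen["nonconserved_identity_max"],
        nonconserved_fraction_nondegraders=cfg.screen[
            "nonconserved_fraction_nondegraders"
        ],
    )
    cand = screen.candidate_table(
        fc, consmat, panel.phenotypes, criteria, panel.reference_strain_id
    )
    write_tsv(cand.reset_index(), outdir / "candidates.tsv")

    flags = screen.flags_by_replicon(panel.reference_genes(), cand["candidate"].to_dict())
    hotspots = screen.find_hotspots(
        flags, min_run=cfg.hotspot["min_run"], max_gap=cfg.hotspot["max_gap"]
    )
    with open(outdir / "hotspots.json", "w") as fh:
        json.dump([_hotspot_dict(h) for h in hotspots], fh, indent=2, sort_keys=True)
        fh.write("\n")

    enrichment = None
    if hotspots:
        presence = cluster_presence(
            consmat,
            hotspots[0],
            cfg.screen["conserved_identity_min"],
            cfg.screen["conserved_coverage_min"],
            cfg.screen["presence_min_fraction"],
        )
        trait = {
            s: panel.phenotypes[s].isolation_source in cfg.screen["trait_sources"]
            for s in presence
            if s in panel.phenotypes
        }
        presence = {s: presence[s] for s in trait}
        enrichment = screen.trait_enrichment(presence, trait)
        with open(outdir / "enrichment.json", "w") as fh:
            json.dump(_enrichment_dict(enrichment), fh, indent=2, sort_keys=True)
            fh.write("\n")

    report = {
        "tool": "isocat",
        "version": importlib.metadata.version("isocat"),
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "biopython": Bio.__version__,
        },
        "seed": cfg.seed,
        "config": _jsonable(dataclasses.asdict(cfg)),
        "expression": {
            "n_genes": int(len(fc)),
            "n_upregulated": int(fc["upregulated"].sum()),
        },
        "conservation": {
            "n_genes": len(consmat.gene_ids),
            "n_strains": len(consmat.strain_ids),
        },
        "screen": {
            "n_candidates": int(cand["candidate"].sum()),
            "hotspots": [_hotspot_dict(h) for h in hotspots],
            "enrichment": _enrichment_dict(enrichment) if enrichment else None,
        },
    }
    _write_report(report, outdir)
    return report


def run_all(cfg: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """run_screen plus the growth-assay and mass-annotation stages."""
    outdir = Path(outdir)
    report = run_screen(cfg, outdir)

    growth_df = read_growth(_require_input(cfg, "growth"))
    results, tests = growth.analyze_growth(
        growth_df,
        index_variant=cfg.growth["index_variant"],
        alpha=cfg.growth["alpha"],
    )
    write_tsv(results, outdir / "growth_results.tsv")
    write_tsv(tests, outdir / "growth_tests.tsv")
    report["growth"] = {
        "n_strains": int(results["strain_id"].nunique()),
        "n_tests": int(len(tests)),
        "n_significant": int(tests["significant"].sum()) if len(tests) else 0,
        "tests": _jsonable(tests.to_dict(orient="records")),
    }

    peaks = read_peaks(_require_input(cfg, "peaks"))
    annotations = masses.annotate_peaks(
        peaks,
        cfg.mass["formulas"],
        tol_ppm=cfg.mass["tol_ppm"],
        electron_correction=cfg.mass["electron_correction"],
    )
    write_tsv(annotations, outdir / "annotations.tsv")
    report["mass"] = {
        "n_peaks": int(len(peaks)),
        "annotations": _jsonable(annotations.to_dict(orient="records")),
    }
    _write_report(report, outdir)
    return report


def _write_report(report: dict[str, Any], outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Minimal structural schema validation for report.json


def report_schema() -> dict[str, Any]:
    path = Path(__file__).with_name("report_schema.json")
    with open(path) as fh:
        return json.load(fh)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def validate_report(report: Any, schema: dict[str, Any] | None = None, path: str = "$") -> None:
    """Check a report against the shipped structural schema; raises FormatError."""
    if schema is None:
        schema = report_schema()
    typ = schema.get("type")
    if typ:
        allowed = typ if isinstance(typ, list) else [typ]
        if not any(
            (report is None and t == "null") or (t != "null" and isinstance(report, _TYPES[t]))
            for t in allowed
        ):
            raise FormatError(f"{path}: expected {typ}, got {type(report).__name__}")
        if isinstance(report, bool) and "boolean" not in allowed:
            raise FormatError(f"{path}: expected {typ}, got bool")
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                raise FormatError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{path}.{key}")
    if isinstance(report, list) and "items" in schema:
        for i, item in enumerate(report):
            validate_report(item, schema["items"], f"{path}[{i}]")
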