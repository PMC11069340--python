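"""Domain types and readers/writers for the formats every stage touches.

Coordinates are 1-based and inclusive on both ends (GFF3 convention).
Strand is recorded but the screen itself is strand-agnostic.  The "rank"
of a gene used by hotspot detection is its position in coordinate order
within its replicon, not a base-pair coordinate.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import FormatError

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GENE_TABLE_COLUMNS = [
    "strain_id",
    "locus_id",
    "replicon_id",
    "start",
    "end",
    "strand",
    "product",
]

GROWTH_COLUMNS = ["strain_id", "dose_uM", "replicate", "time_h", "od600"]
PEAK_COLUMNS = ["rt_min", "mz", "intensity"]


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene of one strain."""

    strain_id: str
    locus_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    protein_seq: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FormatError(f"gene {self.locus_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise FormatError(
                f"gene {self.locus_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.locus_id}: unknown strand {self.strand!r}")
        if not self.protein_seq:
            raise FormatError(f"gene {self.locus_id}: empty protein sequence")
        bad = set(self.protein_seq) - PROTEIN_ALPHABET
        if bad:
            raise FormatError(
                f"gene {self.locus_id}: illegal residue(s) {sorted(bad)} in protein"
            )


@dataclass(frozen=True)
class PhenotypeRecord:
    """Binary degrader phenotype plus isolation source of a strain."""

    strain_id: str
    degrader: bool
    isolation_source: str = "other"


@dataclass
class StrainPanel:
    """A panel of strains: proteomes with coordinates plus phenotypes."""

    reference_strain_id: str
    genes: dict[str, list[GeneRecord]]
    phenotypes: dict[str, PhenotypeRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference_strain_id not in self.genes:
            raise FormatError(
                f"reference strain {self.reference_strain_id!r} has no genes in the panel"
            )
        for strain, recs in self.genes.items():
            seen: set[str] = set()
            for rec in recs:
                if rec.strain_id != strain:
                    raise FormatError(
                        f"gene {rec.locus_id} filed under strain {strain} but labelled {rec.strain_id}"
                    )
                if rec.locus_id in seen:
                    raise FormatError(f"duplicate locus {rec.locus_id} in strain {strain}")
                seen.add(rec.locus_id)
            recs.sort(key=lambda r: (r.replicon_id, r.start, r.locus_id))
        for strain in self.phenotypes:
            if strain in self.genes and not self.genes[strain]:
                raise FormatError(f"phenotyped strain {strain} has no genes")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.genes)

    def reference_genes(self) -> list[GeneRecord]:
        return self.genes[self.reference_strain_id]

    def proteome(self, strain_id: str) -> dict[str, str]:
        """locus_id -> protein sequence for one strain."""
        return {g.locus_id: g.protein_seq for g in self.genes[strain_id]}

    def degraders(self, include_reference: bool = False) -> list[str]:
        out = [
            s
            for s, p in self.phenotypes.items()
            if p.degrader and (include_reference or s != self.reference_strain_id)
        ]
        return out

    def nondegraders(self) -> list[str]:
        return [s for s, p in self.phenotypes.items() if not p.degrader]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with a two-condition design."""

    counts: pd.DataFrame  # index = gene_ids, columns = sample_ids, int
    design: pd.DataFrame  # index = sample_ids, columns = condition, replicate

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise FormatError(f"samples missing from design: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts are not allowed")
        conds = set(self.design.loc[list(self.counts.columns), "condition"])
        bad = conds - {"treated", "control"}
        if bad:
            raise FormatError(f"unknown condition label(s): {sorted(bad)}")
        for cond in ("treated", "control"):
            if cond not in conds:
                raise FormatError(f"no sample with condition {cond!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [
            s
            for s in self.counts.columns
            if self.design.loc[s, "condition"] == condition
        ]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path_or_text: str | Path) -> dict[str, str]:
    """Parse FASTA into an insertion-ordered id -> sequence map.

    Accepts either a path or raw FASTA text (text is recognised by a
    leading ``>``).  Sequences are uppercased with whitespace stripped;
    duplicate IDs and empty sequences are format errors.
    """
    if isinstance(path_or_text, str) and path_or_text.lstrip().startswith(">"):
        handle: io.TextIOBase | io.StringIO = io.StringIO(path_or_text)
    else:
        handle = open(path_or_text)
    out: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in out:
                raise FormatError(f"duplicate ID {rec.id}")
            seq = str(rec.seq).replace(" ", "").upper()
            if not seq:
                raise FormatError(f"empty sequence for ID {rec.id}")
            out[rec.id] = seq
    finally:
        handle.close()
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene tables


def _protein_key(strain_id: str, locus_id: str) -> str:
    return f"{strain_id}|{locus_id}"


def read_gene_table(path: str | Path, proteins: Mapping[str, str]) -> list[GeneRecord]:
    """Read a TSV gene table; protein sequences come from a separate map.

    ``proteins`` keys may be either ``strain|locus`` (a combined panel
    FASTA) or bare locus ids (a single-strain FASTA).  Records are
    returned sorted by (strain, replicon, start).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene table {path}: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        key = _protein_key(row.strain_id, row.locus_id)
        seq = proteins.get(key) or proteins.get(row.locus_id)
        if seq is None:
            raise FormatError(f"no protein sequence for {key}")
        records.append(
            GeneRecord(
                strain_id=row.strain_id,
                locus_id=row.locus_id,
                replicon_id=row.replicon_id,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                protein_seq=seq,
                product="" if pd.isna(row.product) else str(row.product),
            )
        )
    records.sort(key=lambda r: (r.strain_id, r.replicon_id, r.start, r.locus_id))
    return records


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "strain_id": r.strain_id,
            "locus_id": r.locus_id,
            "replicon_id": r.replicon_id,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "product": r.product,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def _gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3(
    path: str | Path, strain_id: str, proteins: Mapping[str, str]
) -> list[GeneRecord]:
    """Read CDS features (with ``locus_tag``) from a GFF3 file for one strain."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != "CDS":
                continue
            at = _gff3_attributes(attrs)
            locus = at.get("locus_tag") or at.get("ID")
            if not locus:
                raise FormatError(f"{path}:{lineno}: CDS without locus_tag")
            key = _protein_key(strain_id, locus)
            seq = proteins.get(key) or proteins.get(locus)
            if seq is None:
                raise FormatError(f"no protein sequence for {key}")
            records.append(
                GeneRecord(
                    strain_id=strain_id,
                    locus_id=locus,
                    replicon_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    protein_seq=seq,
                    product=at.get("product", ""),
                )
            )
    records.sort(key=lambda r: (r.strain_id, r.replicon_id, r.start, r.locus_id))
    return records


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(path: str | Path) -> dict[str, PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("strain_id", "degrader", "isolation_source"):
        if col not in df.columns:
            raise FormatError(f"phenotype table {path}: missing column {col}")
    out = {}
    for row in df.itertuples(index=False):
        val = str(row.degrader).strip().lower()
        if val not in {"true", "false", "yes", "no", "1", "0"}:
            raise FormatError(f"strain {row.strain_id}: degrader must be boolean, got {row.degrader!r}")
        out[row.strain_id] = PhenotypeRecord(
            strain_id=row.strain_id,
            degrader=val in {"true", "yes", "1"},
            isolation_source=row.isolation_source,
        )
    return out


def write_phenotypes(phenos: Mapping[str, PhenotypeRecord], path: str | Path) -> None:
    rows = [
        {"strain_id": p.strain_id, "degrader": p.degrader, "isolation_source": p.isolation_source}
        for p in phenos.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_panel(
    records: Iterable[GeneRecord],
    phenotypes: Mapping[str, PhenotypeRecord],
    reference_strain_id: str,
) -> StrainPanel:
    genes: dict[str, list[GeneRecord]] = {}
    for rec in records:
        genes.setdefault(rec.strain_id, []).append(rec)
    return StrainPanel(
        reference_strain_id=reference_strain_id,
        genes=genes,
        phenotypes=dict(phenotypes),
    )


# ---------------------------------------------------------------------------
# Counts


def read_counts(path: str | Path, design_path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any():
            raise FormatError(f"negative count in sample {col}")
        if not (vals == vals.round()).all():
            raise FormatError(f"non-integer count in sample {col}")
        df[col] = vals.astype(int)
    design = pd.read_csv(design_path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in ("sample_id", "condition", "replicate"):
        if col not in design.columns:
            raise FormatError(f"design table {design_path}: missing column {col}")
    design = design.set_index("sample_id")
    missing = [s for s in df.columns if s not in design.index]
    if missing:
        raise FormatError(f"samples missing from design: {missing}")
    return CountMatrix(counts=df, design=design)


def write_counts(cm: CountMatrix, counts_path: str | Path, design_path: str | Path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.design.rename_axis("sample_id").to_csv(design_path, sep="\t")


# ---------------------------------------------------------------------------
# Growth and peaks (long-format TSVs)


def read_growth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"growth table {path}: missing column(s) {missing}")
    if (df["dose_uM"] < 0).any():
        raise FormatError("negative dose in growth table")
    if (df["od600"] < 0).any():
        raise FormatError("negative OD600 in growth table")
    return df


def read_peaks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"peak list {path}: missing column(s) {missing}")
    if (df["mz"] <= 0).any():
        raise FormatError("non-positive m/z in peak list")
    if (df["rt_min"] < 0).any():
        raise FormatError("negative retention time in peak list")
    if (df["intensity"] < 0).any():
        raise FormatError("negative intensity in peak list")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    os.makedirs(os.path.dirname(os.fspath(path)) or ".", exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
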