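"""Phenotype-stratified conservation: best-hit identity/coverage per strain.

For every reference gene and every panel strain we find the strain
protein whose global alignment to the reference gives the highest
percent identity among hits with adequate coverage.  Global affine-gap
alignment (Gotoh) with BLOSUM62, gap cost ``gap_open + gap_extend * L``
and penalized end gaps stands in for a local BLASTP search: the screen
needs a consistent conservation score, not BLAST's exact numbers.

Identity is counted over both-non-gap columns; ``X`` never counts as
identical (conservative).  Coverage is the fraction of reference
residues paired with a non-gap.  Best-hit search prefilters each
strain's proteome by edit distance (edlib) and aligns only the top
candidates, which keeps panel-scale matrices fast without changing the
best hit in practice; set ``prefilter_k=None`` for exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .core import PROTEIN_ALPHABET, GeneRecord, StrainPanel
from .errors import FormatError

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0
DEFAULT_MIN_COVERAGE = 50.0
#: A best hit must score above this to count as present at all.  A local
#: search (BLASTP) simply reports no hit between unrelated proteins; a
#: global aligner always returns *some* alignment, so hits with
#: non-positive score (no better than aligning nothing) are discarded.
DEFAULT_MIN_SCORE = 0.0
DEFAULT_PREFILTER_K = 5


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    coverage_pct: float


@dataclass
class ConservationMatrix:
    """Reference-gene x strain best-hit identity/coverage/locus tables.

    Cells of ``identity``/``coverage`` are NaN where no hit passed the
    coverage floor; ``best_hit`` holds the winning locus id or None.
    """

    identity: pd.DataFrame
    coverage: pd.DataFrame
    best_hit: pd.DataFrame
    min_coverage: float

    @property
    def gene_ids(self) -> list[str]:
        return list(self.identity.index)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.identity.columns)

    def present(self, gene_id: str, strain_id: str) -> bool:
        return self.best_hit.loc[gene_id, strain_id] is not None

    def to_long(self) -> pd.DataFrame:
        rows = []
        for g in self.gene_ids:
            for s in self.strain_ids:
                rows.append(
                    {
                        "gene_id": g,
                        "strain_id": s,
                        "identity_pct": self.identity.loc[g, s],
                        "coverage_pct": self.coverage.loc[g, s],
                        "best_hit_locus": self.best_hit.loc[g, s] or "",
                    }
                )
        return pd.DataFrame(rows)


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Gap of length L costs gap_open + gap_extend * L (BLAST convention);
    # end gaps are penalized at the same rate.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise FormatError(f"empty sequence {label}")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise FormatError(f"illegal character(s) {sorted(bad)} in sequence {label}")


def global_align(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences under affine gaps."""
    _check_sequence(a, "a")
    _check_sequence(b, "b")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    identity, coverage = identity_and_coverage_from_strings(aligned_a, aligned_b, len(a))
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        identity_pct=identity,
        coverage_pct=coverage,
    )


def identity_and_coverage_from_strings(
    aligned_a: str, aligned_b: str, ref_length: int
) -> tuple[float, float]:
    """Percent identity over both-non-gap columns; reference coverage.

    ``X`` counts as a mismatch against everything, including ``X``.
    Zero aligned columns yields identity 0 by convention.
    """
    if len(aligned_a) != len(aligned_b):
        raise FormatError("aligned strings differ in length")
    pairs = ident = covered = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            pairs += 1
            covered += 1
            if ca == cb and ca != "X":
                ident += 1
    identity = 100.0 * ident / pairs if pairs else 0.0
    coverage = 100.0 * covered / ref_length if ref_length else 0.0
    return identity, coverage


def identity_and_coverage(alignment: AlignmentResult, ref_length: int) -> tuple[float, float]:
    return identity_and_coverage_from_strings(
        alignment.aligned_a, alignment.aligned_b, ref_length
    )


def best_hit(
    query: str,
    targets: dict[str, str],
    min_coverage: float,
    min_score: float = DEFAULT_MIN_SCORE,
    aligner_kwargs: dict | None = None,
    prefilter_k: int | None = DEFAULT_PREFILTER_K,
) -> tuple[str, AlignmentResult] | None:
    """Best target by identity among hits with coverage >= ``min_coverage``
    and score > ``min_score``.

    Ties on identity break to the lexicographically lowest locus id.
    Returns None when no target qualifies.
    """
    if not targets:
        return None
    kwargs = aligner_kwargs or {}
    if prefilter_k is not None and len(targets) > prefilter_k:
        dist = {
            locus: edlib.align(query, seq, task="distance")["editDistance"]
            for locus, seq in targets.items()
        }
        chosen = sorted(dist, key=lambda l: (dist[l], l))[:prefilter_k]
        targets = {l: targets[l] for l in chosen}
    best: tuple[float, str, AlignmentResult] | None = None
    for locus in sorted(targets):
        res = global_align(query, targets[locus], **kwargs)
        if res.coverage_pct < min_coverage or res.score <= min_score:
            continue
        if best is None or res.identity_pct > best[0]:
            best = (res.identity_pct, locus, res)
    if best is None:
        return None
    return best[1], best[2]


def conservation_matrix(
    panel: StrainPanel,
    reference_genes: list[GeneRecord] | None = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_score: float = DEFAULT_MIN_SCORE,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    prefilter_k: int | None = DEFAULT_PREFILTER_K,
) -> ConservationMatrix:
    """Best-hit identity and coverage of each reference gene in each strain."""
    if reference_genes is None:
        reference_genes = panel.reference_genes()
    ref_ids = {g.locus_id for g in panel.reference_genes()}
    for g in reference_genes:
        if g.locus_id not in ref_ids:
            raise FormatError(f"gene {g.locus_id} is not a reference-strain gene")
    strains = panel.strain_ids
    gene_ids = [g.locus_id for g in reference_genes]
    identity = pd.DataFrame(index=gene_ids, columns=strains, dtype=float)
    coverage = pd.DataFrame(index=gene_ids, columns=strains, dtype=float)
    hits = pd.DataFrame(index=gene_ids, columns=strains, dtype=object)
    kwargs = {"matrix": matrix, "gap_open": gap_open, "gap_extend": gap_extend}
    proteomes = {s: panel.proteome(s) for s in strains}
    for gene in reference_genes:
        for strain in strains:
            if strain == panel.reference_strain_id:
                # self-hit is exact by construction
                identity.loc[gene.locus_id, strain] = 100.0
                coverage.loc[gene.locus_id, strain] = 100.0
                hits.loc[gene.locus_id, strain] = gene.locus_id
                continue
            found = best_hit(
                gene.protein_seq,
                proteomes[strain],
                min_coverage=min_coverage,
                min_score=min_score,
                aligner_kwargs=kwargs,
                prefilter_k=prefilter_k,
            )
            if found is None:
                hits.loc[gene.locus_id, strain] = None
            else:
                locus, res = found
                identity.loc[gene.locus_id, strain] = res.identity_pct
                coverage.loc[gene.locus_id, strain] = res.coverage_pct
                hits.loc[gene.locus_id, strain] = locus
    return ConservationMatrix(
        identity=identity, coverage=coverage, best_hit=hits, min_coverage=min_coverage
    )
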