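"""Three-criteria candidate screen, hotspot detection, trait enrichment.

A reference gene is a candidate when it is (1) upregulated under the
substrate, (2) conserved in (a configurable fraction of) the degrader
strains, and (3) poorly conserved or absent in (a fraction of) the
non-degrader strains.  Candidates are then scanned along each replicon
for hotspots: maximal runs of candidate genes tolerating short gaps.
Trait enrichment (cluster presence versus e.g. legume association) uses
a two-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .conservation import ConservationMatrix
from .core import GeneRecord, PhenotypeRecord
from .errors import ConfigError, FormatError

#: Relative slack on the point-probability comparison in the two-sided
#: Fisher test (guards against floating-point ties, as in mainstream
#: implementations).
FISHER_RELATIVE_TOL = 1e-7


@dataclass(frozen=True)
class ScreenCriteria:
    """Numeric cutoffs for the three screening criteria.

    The screen's published form names no cutoffs; these defaults are
    package choices that separate the bimodal identity structure the
    simulator plants, and every one of them is a config key.
    """

    log2fc_threshold: float = 1.0
    conserved_identity_min: float = 50.0
    conserved_coverage_min: float = 50.0
    conserved_fraction_degraders: float = 1.0
    nonconserved_identity_max: float = 30.0
    nonconserved_fraction_nondegraders: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.conserved_fraction_degraders <= 1):
            raise ConfigError("conserved_fraction_degraders must be in (0, 1]")
        if not (0 <= self.nonconserved_fraction_nondegraders <= 1):
            raise ConfigError("nonconserved_fraction_nondegraders must be in [0, 1]")
        if self.nonconserved_identity_max >= self.conserved_identity_min:
            raise ConfigError(
                "nonconserved_identity_max must be below conserved_identity_min"
            )


@dataclass(frozen=True)
class Hotspot:
    replicon_id: str
    start_rank: int  # 1-based gene rank within the replicon
    end_rank: int
    locus_ids: tuple[str, ...]  # candidate loci inside the trimmed span
    n_candidates: int
    span: int  # genes in the span, gaps included

    @property
    def score(self) -> int:
        return self.n_candidates


@dataclass(frozen=True)
class EnrichmentResult:
    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


def candidate_table(
    fc: pd.DataFrame,
    cons: ConservationMatrix,
    phenotypes: Mapping[str, PhenotypeRecord],
    criteria: ScreenCriteria,
    reference_strain_id: str | None = None,
) -> pd.DataFrame:
    """Evaluate the three criteria per gene.

    Conservation fractions are computed over the phenotyped strains in
    the matrix, excluding the reference strain (its column is trivially
    a perfect hit).  Returns columns ``upregulated``,
    ``frac_conserved_degraders``, ``frac_nonconserved_nondegraders``,
    ``candidate``.
    """
    if not phenotypes:
        raise FormatError("no phenotyped strains")
    strains = [
        s for s in cons.strain_ids if s in phenotypes and s != reference_strain_id
    ]
    degraders = [s for s in strains if phenotypes[s].degrader]
    nondegraders = [s for s in strains if not phenotypes[s].degrader]
    if not degraders or not nondegraders:
        raise FormatError("need at least one degrader and one non-degrader strain")
    genes = [g for g in cons.gene_ids if g in fc.index]
    if not genes:
        raise FormatError("fold-change table and conservation matrix share no genes")

    ident = cons.identity.loc[genes]
    cov = cons.coverage.loc[genes]
    conserved = (ident[degraders] >= criteria.conserved_identity_min) & (
        cov[degraders] >= criteria.conserved_coverage_min
    )
    # absent (NaN identity) or weakly similar in a non-degrader
    weak = ident[nondegraders].isna() | (
        ident[nondegraders] < criteria.nonconserved_identity_max
    )
    frac_cons = conserved.mean(axis=1)
    frac_weak = weak.mean(axis=1)
    up = fc.loc[genes, "log2fc"] >= criteria.log2fc_threshold
    out = pd.DataFrame(
        {
            "upregulated": up,
            "frac_conserved_degraders": frac_cons,
            "frac_nonconserved_nondegraders": frac_weak,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    out["candidate"] = (
        out["upregulated"]
        & (out["frac_conserved_degraders"] >= criteria.conserved_fraction_degraders)
        & (
            out["frac_nonconserved_nondegraders"]
            >= criteria.nonconserved_fraction_nondegraders
        )
    )
    return out


def classify_candidates(
    fc: pd.DataFrame,
    cons: ConservationMatrix,
    phenotypes: Mapping[str, PhenotypeRecord],
    criteria: ScreenCriteria,
    reference_strain_id: str | None = None,
) -> dict[str, bool]:
    """gene_id -> is it a screen candidate."""
    table = candidate_table(fc, cons, phenotypes, criteria, reference_strain_id)
    return table["candidate"].to_dict()


def _runs(flags: Sequence[bool], min_run: int, max_gap: int) -> list[tuple[int, int, int]]:
    """Maximal candidate runs as (start_idx, end_idx, n_candidates), 0-based."""
    groups: list[list[int]] = []
    for i, f in enumerate(flags):
        if not f:
            continue
        if groups and i - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [(g[0], g[-1], len(g)) for g in groups if len(g) >= min_run]


def find_hotspots(
    flags: Sequence[bool] | Mapping[str, Sequence[tuple[str, bool]]],
    min_run: int = 4,
    max_gap: int = 2,
) -> list[Hotspot]:
    """Detect hotspots: runs of >= ``min_run`` candidates with gaps <= ``max_gap``.

    ``flags`` is either a plain boolean sequence (a single replicon,
    loci named by rank) or a mapping replicon -> ordered list of
    (locus_id, flag).  Hotspot boundaries are trimmed to candidate
    genes; results sort by score (candidate count) descending, then
    replicon, then start rank.
    """
    if min_run < 1:
        raise ConfigError("min_run must be >= 1")
    if max_gap < 0:
        raise ConfigError("max_gap must be >= 0")
    if isinstance(flags, Mapping):
        per_replicon = {
            rep: ([l for l, _ in pairs], [bool(f) for _, f in pairs])
            for rep, pairs in flags.items()
        }
    else:
        per_replicon = {
            "replicon": ([str(i + 1) for i in range(len(flags))], [bool(f) for f in flags])
        }
    hotspots = []
    for rep, (loci, fl) in per_replicon.items():
        for start, end, count in _runs(fl, min_run, max_gap):
            hotspots.append(
                Hotspot(
                    replicon_id=rep,
                    start_rank=start + 1,
                    end_rank=end + 1,
                    locus_ids=tuple(loci[i] for i in range(start, end + 1) if fl[i]),
                    n_candidates=count,
                    span=end - start + 1,
                )
            )
    hotspots.sort(key=lambda h: (-h.score, h.replicon_id, h.start_rank))
    return hotspots


def flags_by_replicon(
    reference_genes: Sequence[GeneRecord], candidates: Mapping[str, bool]
) -> dict[str, list[tuple[str, bool]]]:
    """Arrange candidate flags in coordinate-rank order per replicon."""
    out: dict[str, list[tuple[str, bool]]] = {}
    for g in sorted(reference_genes, key=lambda g: (g.replicon_id, g.start)):
        out.setdefault(g.replicon_id, []).append(
            (g.locus_id, bool(candidates.get(g.locus_id, False)))
        )
    return out


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> EnrichmentResult:
    """Two-sided Fisher exact test by the point-probability method.

    p is the sum of hypergeometric probabilities (margins fixed) of all
    tables whose point probability does not exceed the observed one
    (with a small relative slack).  The odds ratio is the unconditioned
    ad/bc, +inf when bc = 0 and ad > 0, NaN when both products vanish.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(int(x) != x for x in cells):
        raise FormatError("contingency table entries must be integers")
    a, b, c, d = (int(x) for x in cells)
    if min(a, b, c, d) < 0:
        raise FormatError("contingency table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise FormatError("contingency table is empty")
    row1, col1 = a + b, a + c
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    # normalizing by the pmf sum removes float round-off in the total
    # probability (an all-inclusive sum is exactly 1)
    p = pmf[pmf <= p_obs * (1 + FISHER_RELATIVE_TOL)].sum() / pmf.sum()
    p = float(min(1.0, p))
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(contingency=((a, b), (c, d)), odds_ratio=odds, p_two_sided=p)


def trait_enrichment(
    presence: Mapping[str, bool], trait: Mapping[str, bool]
) -> EnrichmentResult:
    """Fisher test of cluster presence against a binary strain trait."""
    if not presence:
        raise FormatError("empty strain universe")
    if set(presence) != set(trait):
        raise FormatError("presence and trait maps must cover the same strains")
    a = sum(1 for s in presence if presence[s] and trait[s])
    b = sum(1 for s in presence if presence[s] and not trait[s])
    c = sum(1 for s in presence if not presence[s] and trait[s])
    d = sum(1 for s in presence if not presence[s] and not trait[s])
    return fisher_exact_2x2([[a, b], [c, d]])
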