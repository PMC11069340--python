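"""Exact-mass annotation of catabolic intermediates.

Theoretical monoisotopic [M-H]- m/z values are computed from molecular
formulas and matched to observed negative-mode peaks within a ppm
tolerance.  Deuterium (symbol ``D``) is a first-class element so that
isotope-labelling mass-shift arguments (e.g. a d2- or d4-labelled
intermediate giving products two or four mass units heavier) can be
reproduced computationally.

The deprotonated ion is computed as M - m(H atom) by default.  The
physically stricter convention (remove a proton, i.e. M - m(H) + m(e))
is available via ``electron_correction=True``; the default reproduces
the 4-decimal calculated masses conventionally printed for small
phenolics (e.g. C15H10O5 -> 269.0450).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import FormatError

#: Monoisotopic atomic masses (u); C is exactly 12 by definition.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "D": 2.01410178,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
}

HYDROGEN_ATOM_MASS = MONOISOTOPIC_MASS["H"]
PROTON_MASS = 1.00727646
#: Mass gained per H -> D substitution.
DEUTERIUM_SHIFT = MONOISOTOPIC_MASS["D"] - MONOISOTOPIC_MASS["H"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element -> count map over {C, H, D, N, O, S, P}."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "Formula":
        clean = {}
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormatError(f"unknown element {el!r}")
            if n < 0:
                raise FormatError(f"negative count for {el}")
            if n > 0:
                clean[el] = n
        if not clean:
            raise FormatError("formula must contain at least one atom")
        # Hill order: C, H, then remaining symbols alphabetically.
        order = [e for e in ("C", "H") if e in clean]
        order += sorted(e for e in clean if e not in ("C", "H"))
        return cls(counts=tuple((e, clean[e]) for e in order))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def count(self, element: str) -> int:
        return self.as_dict().get(element, 0)

    def __str__(self) -> str:
        return "".join(f"{e}{n if n != 1 else ''}" for e, n in self.counts)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``C15H10O5`` or ``C10H6D4O3``."""
    text = text.strip()
    if not text:
        raise FormatError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormatError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        if not m.group(0):
            break
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormatError(f"unknown element {el!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormatError(f"zero count for {el} in formula {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormatError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return Formula.from_counts(counts)


def monoisotopic_mass(formula: Formula) -> float:
    """Sum of monoisotopic atomic masses, in Da."""
    return sum(n * MONOISOTOPIC_MASS[e] for e, n in formula.counts)


def mz_deprotonated(formula: Formula, electron_correction: bool = False) -> float:
    """Theoretical [M-H]- m/z (full precision; round with :func:`round_report`)."""
    if formula.count("H") < 1:
        raise FormatError(f"cannot deprotonate {formula}: no hydrogen")
    delta = PROTON_MASS if electron_correction else HYDROGEN_ATOM_MASS
    return monoisotopic_mass(formula) - delta


def round_report(value: float, decimals: int = 4) -> float:
    """Half-up rounding for report fields (matches printed m/z precision)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def ppm_error(observed: float, theoretical: float) -> float:
    if theoretical <= 0:
        raise FormatError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def label_shift(formula: Formula, n_deuterium: int) -> tuple[Formula, float, int]:
    """Replace ``n_deuterium`` H atoms by D.

    Returns the labelled formula, the exact mass shift in Da, and the
    nominal (integer) shift — the "n mass units higher" a labelled
    substrate propagates into its reaction products.
    """
    if n_deuterium < 0:
        raise FormatError("n_deuterium must be non-negative")
    counts = formula.as_dict()
    if counts.get("H", 0) < n_deuterium:
        raise FormatError(
            f"{formula} has only {counts.get('H', 0)} H; cannot label {n_deuterium}"
        )
    if n_deuterium == 0:
        return formula, 0.0, 0
    counts["H"] -= n_deuterium
    counts["D"] = counts.get("D", 0) + n_deuterium
    return Formula.from_counts(counts), n_deuterium * DEUTERIUM_SHIFT, n_deuterium


def annotate_peaks(
    peaks: pd.DataFrame,
    candidates: list[Formula | str],
    tol_ppm: float,
    electron_correction: bool = False,
) -> pd.DataFrame:
    """Match observed peaks to candidate formulas within ``tol_ppm``.

    Every (peak, formula) pair within tolerance is reported — a peak may
    match several formulas, and ambiguity is reported rather than
    resolved.  Result is sorted by |ppm error|.
    """
    if tol_ppm <= 0:
        raise FormatError("tol_ppm must be positive")
    formulas = [parse_formula(f) if isinstance(f, str) else f for f in candidates]
    rows = []
    for f in formulas:
        theo = mz_deprotonated(f, electron_correction=electron_correction)
        for peak in peaks.itertuples(index=False):
            err = ppm_error(peak.mz, theo)
            if abs(err) <= tol_ppm:
                rows.append(
                    {
                        "rt_min": peak.rt_min,
                        "observed_mz": peak.mz,
                        "formula": str(f),
                        "theoretical_mz": round_report(theo),
                        "ppm_error": err,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["rt_min", "observed_mz", "formula", "theoretical_mz", "ppm_error"]
    )
    return out.reindex(out["ppm_error"].abs().sort_values(kind="stable").index).reset_index(
        drop=True
    )
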