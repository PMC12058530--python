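"""rDNA array copy-number accounting and NOR status.

Nucleolar organizer regions (NORs) are the rDNA arrays of acrocentric short
arms (or a Y long arm). Copy number is estimated from the assembled array
span divided by the repeat unit length (about 45 kb in hominoids), rounded
half-up — exact on assemblies whose arrays are tandem unit multiples. A
chromosome is NOR+ when it carries an rDNA array of at least ``min_units``
estimated copies; even single-unit arrays count by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up
from .satarch import is_rdna_family

DEFAULT_UNIT_BP = 45_000


@dataclass
class RdnaArray:
    chrom: str
    start: int
    end: int
    haplotype: str = ""
    unit_bp: int = DEFAULT_UNIT_BP

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def copies(self) -> int:
        return count_rdna_units(self.span, self.unit_bp)


def count_rdna_units(array_span_bp: int, unit_length_bp: int = DEFAULT_UNIT_BP) -> int:
    """Copy number = span / unit length, rounded half-up to an integer."""
    if unit_length_bp <= 0:
        raise ValueError("unit length must be > 0")
    if array_span_bp < 0:
        raise ValueError("array span must be >= 0")
    return int(round_half_up(array_span_bp / unit_length_bp, 0))


def classify_nor(chrom_arrays: pd.DataFrame, min_units: int = 1,
                 unit_bp: int = DEFAULT_UNIT_BP) -> str:
    """``NOR+`` iff the chromosome carries an rDNA-class array with at least
    ``min_units`` estimated copies, else ``NOR-``.

    ``chrom_arrays`` holds the classified arrays of one chromosome; rDNA
    arrays are recognized by ``cls == 'rdna'`` or family ``rDNA``.
    """
    if chrom_arrays.empty:
        return "NOR-"
    if "cls" in chrom_arrays.columns:
        rd = chrom_arrays[chrom_arrays["cls"] == "rdna"]
    else:
        rd = chrom_arrays[chrom_arrays["family"].map(is_rdna_family)]
    for r in rd.itertuples():
        if count_rdna_units(r.end - r.start, unit_bp) >= min_units:
            return "NOR+"
    return "NOR-"


def rdna_table(arrays: pd.DataFrame, unit_bp: int = DEFAULT_UNIT_BP) -> pd.DataFrame:
    """Per-array rDNA copy numbers from a classified array table."""
    if arrays.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "haplotype",
                                     "unit_bp", "copies"])
    if "cls" in arrays.columns:
        rd = arrays[arrays["cls"] == "rdna"].copy()
    else:
        rd = arrays[arrays["family"].map(is_rdna_family)].copy()
    rd["unit_bp"] = unit_bp
    rd["copies"] = [count_rdna_units(e - s, unit_bp)
                    for s, e in zip(rd["start"], rd["end"])]
    if "haplotype" not in rd.columns:
        rd["haplotype"] = ""
    return rd[["chrom", "start", "end", "haplotype", "unit_bp", "copies"]]


def total_rdna(arrays: pd.DataFrame, group_by: str = "haplotype"):
    """Sum estimated copies per haplotype or for the whole diploid.

    ``arrays`` needs ``copies`` and, for per-haplotype totals, a
    ``haplotype`` column. ``group_by`` is ``'haplotype'`` or ``'diploid'``.
    """
    if arrays.empty:
        return 0 if group_by == "diploid" else pd.Series(dtype=int)
    if group_by == "diploid":
        return int(arrays["copies"].sum())
    if group_by == "haplotype":
        return arrays.groupby("haplotype")["copies"].sum().astype(int)
    raise ValueError("group_by must be 'haplotype' or 'diploid'")


__all__ = [
    "RdnaArray", "DEFAULT_UNIT_BP",
    "count_rdna_units", "classify_nor", "rdna_table", "total_rdna",
]
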