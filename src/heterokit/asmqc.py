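"""Assembly QC: telomere detection, T2T classification, gap accounting and
summary tables.

A chromosome is telomere-to-telomere (T2T) when it is gapless and carries a
telomere at both ends. Gaps are runs of N; gaps falling inside an annotated
rDNA array are exempted from the "non-rDNA issues" count because rDNA array
interiors are left unresolved by design in complete-genome assemblies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_sorted_disjoint, round_half_up
from .synthio import revcomp

# ---------------------------------------------------------------------------
# telomere detection
# ---------------------------------------------------------------------------


def _exact_runs(sequence: str, motif: str) -> list[tuple[int, int]]:
    """Maximal runs of exact tandem copies of the motif (>= 1 copy)."""
    pat = re.compile(f"(?:{motif})+")
    return [(m.start(), m.end()) for m in pat.finditer(sequence)]


def _divergent_runs(sequence: str, motif: str, max_divergence: float,
                    window: int = 100) -> list[tuple[int, int]]:
    """Runs where sliding `window`-mers are <= max_divergence away from a
    tandem motif tiling: positions covered by any exact motif occurrence are
    counted as matching, windows with >= (1 - max_divergence) matching
    positions are accepted and merged."""
    n = len(sequence)
    covered = np.zeros(n, dtype=bool)
    start = 0
    while True:
        i = sequence.find(motif, start)
        if i < 0:
            break
        covered[i : i + len(motif)] = True
        start = i + 1
    if n < window:
        frac = covered.mean() if n else 0.0
        return [(0, n)] if frac >= 1 - max_divergence else []
    csum = np.concatenate([[0], np.cumsum(covered)])
    win_match = (csum[window:] - csum[:-window]) / window   # window start i
    ok = win_match >= (1.0 - max_divergence)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j + 1 < ok.size and ok[j + 1]:
                j += 1
            runs.append((i, j + window))
            i = j + 1
        else:
            i += 1
    return runs


def detect_telomeres(
    sequence: str,
    motif: str = "TTAGGG",
    min_run_bp: int = 2_000,
    max_offset_bp: int = 10_000,
    max_divergence: float = 0.0,
) -> list[tuple[int, int]]:
    """Find telomere intervals at the sequence termini.

    Candidate runs are maximal tandem repeats of the motif or its reverse
    complement (exact by default; with ``max_divergence`` > 0, sliding
    100-mers with at most that mismatch fraction are tolerated). A run
    qualifies for a terminus when it is at least ``min_run_bp`` long and its
    nearer end lies within ``max_offset_bp`` of that terminus. At most one
    interval is reported per terminus (the one closest to it); a run
    satisfying both terminus conditions is reported for both.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if len(motif) != 6:
        raise ValueError("telomere motif must be a 6-mer")
    sequence = sequence.upper()
    runs: list[tuple[int, int]] = []
    for m in {motif, revcomp(motif)}:
        if max_divergence > 0:
            runs.extend(_divergent_runs(sequence, m, max_divergence))
        else:
            runs.extend(_exact_runs(sequence, m))
    runs = [r for r in runs if r[1] - r[0] >= min_run_bp]
    L = len(sequence)
    out: list[tuple[int, int]] = []
    five = [r for r in runs if r[0] <= max_offset_bp]
    if five:
        out.append(min(five, key=lambda r: (r[0], -(r[1] - r[0]))))
    three = [r for r in runs if L - r[1] <= max_offset_bp]
    if three:
        out.append(max(three, key=lambda r: (r[1], r[1] - r[0])))
    return out


def find_gaps(sequence: str, min_run_n: int = 10) -> list[tuple[int, int]]:
    """Maximal runs of >= min_run_n consecutive N (assembly gaps)."""
    return [
        (m.start(), m.end())
        for m in re.finditer("N{%d,}" % min_run_n, sequence.upper())
    ]


# ---------------------------------------------------------------------------
# chromosome records and classification
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeRecord:
    name: str
    length: int
    haplotype: str = ""
    species: str = ""
    gaps: list[tuple[int, int]] = field(default_factory=list)
    telomeres: list[tuple[int, int]] = field(default_factory=list)
    rdna: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.gaps = as_sorted_disjoint(self.gaps)
        for ivs in (self.gaps, self.telomeres, self.rdna):
            for s, e in ivs:
                if not (0 <= s < e <= self.length):
                    raise ValueError(
                        f"{self.name}: interval [{s},{e}) outside [0,{self.length})"
                    )

    @classmethod
    def from_sequence(cls, name: str, sequence: str, min_run_n: int = 10,
                      rdna: list[tuple[int, int]] | None = None,
                      **telomere_kwargs) -> "ChromosomeRecord":
        return cls(
            name=name,
            length=len(sequence),
            gaps=find_gaps(sequence, min_run_n),
            telomeres=detect_telomeres(sequence, **telomere_kwargs),
            rdna=rdna or [],
        )

    def has_telomere(self, terminus: str, tol_bp: int = 10_000) -> bool:
        if terminus == "p":
            return any(s <= tol_bp for s, _ in self.telomeres)
        return any(self.length - e <= tol_bp for _, e in self.telomeres)


def classify_chromosome(chrom: ChromosomeRecord, terminus_tol_bp: int = 10_000) -> str:
    """Status: ``t2t`` (gapless, telomere both ends), ``gapped`` (>= 1 gap,
    takes precedence) or ``missing_telomere``."""
    if chrom.gaps:
        return "gapped"
    if chrom.has_telomere("p", terminus_tol_bp) and chrom.has_telomere("q", terminus_tol_bp):
        return "t2t"
    return "missing_telomere"


def count_issues(chrom: ChromosomeRecord, terminus_tol_bp: int = 10_000):
    """Return ``(n_gaps_total, n_non_rdna_issues)``.

    A gap counts toward non-rDNA issues unless it overlaps an rDNA interval;
    each missing terminus telomere adds one issue.
    """
    n_gaps = len(chrom.gaps)
    non_rdna = sum(
        1
        for gs, ge in chrom.gaps
        if not any(gs < re_ and ge > rs for rs, re_ in chrom.rdna)
    )
    for terminus in ("p", "q"):
        if not chrom.has_telomere(terminus, terminus_tol_bp):
            non_rdna += 1
    return n_gaps, non_rdna


# ---------------------------------------------------------------------------
# contig statistics and summaries
# ---------------------------------------------------------------------------


def contigs_from_gaps(length: int, gaps: list[tuple[int, int]]) -> list[int]:
    """Contig lengths obtained by splitting [0, length) at gap intervals."""
    contigs = []
    pos = 0
    for gs, ge in as_sorted_disjoint(gaps):
        if gs > pos:
            contigs.append(gs - pos)
        pos = ge
    if pos < length:
        contigs.append(length - pos)
    return contigs


def contig_n50(contig_lengths) -> int:
    """Smallest length L such that contigs >= L hold half the total."""
    lengths = sorted(int(x) for x in contig_lengths)
    if not lengths:
        raise ValueError("empty contig list")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for x in reversed(lengths):
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


@dataclass
class AssemblySummary:
    """Per-assembly summary mirroring the standard genome-report columns."""

    assembly: str
    total_gb: float
    contig_n50_mb: float
    n_t2t: int
    n_non_rdna_issues: int
    qv: float | None = None  # consumed as input, never computed here

    def as_row(self) -> dict:
        return dict(
            assembly=self.assembly,
            total_gb=self.total_gb,
            contig_n50_mb=self.contig_n50_mb,
            n_t2t=self.n_t2t,
            n_non_rdna_issues=self.n_non_rdna_issues,
            qv=self.qv,
        )


def summarize_assembly(name: str, chroms: list[ChromosomeRecord],
                       qv: float | None = None,
                       terminus_tol_bp: int = 10_000) -> AssemblySummary:
    total_bp = sum(c.length for c in chroms)
    contigs = [x for c in chroms for x in contigs_from_gaps(c.length, c.gaps)]
    n_t2t = sum(classify_chromosome(c, terminus_tol_bp) == "t2t" for c in chroms)
    issues = sum(count_issues(c, terminus_tol_bp)[1] for c in chroms)
    return AssemblySummary(
        assembly=name,
        total_gb=total_bp / 1e9,
        contig_n50_mb=contig_n50(contigs) / 1e6 if contigs else 0.0,
        n_t2t=n_t2t,
        n_non_rdna_issues=issues,
        qv=qv,
    )


#: printed precision per summary column (decimal places, rounded half-up)
SUMMARY_PRECISION = {
    "total_gb": 2,
    "contig_n50_mb": 2,
    "n_t2t": 1,
    "n_non_rdna_issues": 1,
    "qv": 1,
}


def summarize_assemblies(table: pd.DataFrame) -> pd.Series:
    """Average row over per-assembly summaries, rounded half-up to the
    conventional printed precision per column. Columns entirely missing
    stay missing; non-numeric columns are skipped."""
    out = {}
    for col in table.columns:
        if col == "assembly":
            continue
        vals = pd.to_numeric(table[col], errors="coerce").dropna()
        if vals.empty:
            out[col] = np.nan
            continue
        out[col] = round_half_up(vals.mean(), SUMMARY_PRECISION.get(col, 2))
    return pd.Series(out, name="Average")


def percent_t2t(n_t2t_per_assembly, n_chroms_per_assembly) -> float:
    """Overall T2T percentage with integer arithmetic until the division."""
    total_t2t = int(sum(int(x) for x in n_t2t_per_assembly))
    total = int(sum(int(x) for x in n_chroms_per_assembly))
    if total == 0:
        raise ValueError("no chromosomes")
    return round_half_up(100 * total_t2t / total, 0)


def per_chromosome_table(chroms: list[ChromosomeRecord],
                         terminus_tol_bp: int = 10_000) -> pd.DataFrame:
    rows = []
    for c in chroms:
        n_gaps, issues = count_issues(c, terminus_tol_bp)
        rows.append(dict(
            chrom=c.name, length=c.length, haplotype=c.haplotype,
            status=classify_chromosome(c, terminus_tol_bp),
            n_gaps=n_gaps, n_non_rdna_issues=issues,
        ))
    return pd.DataFrame(rows)


__all__ = [
    "ChromosomeRecord", "AssemblySummary",
    "detect_telomeres", "find_gaps", "classify_chromosome", "count_issues",
    "contigs_from_gaps", "contig_n50", "summarize_assembly",
    "summarize_assemblies", "percent_t2t", "per_chromosome_table",
    "SUMMARY_PRECISION",
]
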