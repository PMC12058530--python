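"""Satellite array architecture: merge annotations into arrays, classify by
genomic context, partition centromeric HOR arrays into mini/normal classes
and compare haplotype pairs.

Annotations and arrays are pandas frames with BED-style half-open intervals:

* annotations: ``chrom, start, end, family[, strand]``
* arrays: ``chrom, start, end, family, n_members, covered_bp[, cls, arm]``

Array classes: ``rdna`` (family rDNA), ``subterminal`` (within the terminal
window of an arm), ``centromeric_hor`` (the largest non-subterminal
alpha-satellite array on the chromosome — a deliberate simplification of
active-array identification, which in real assemblies uses HOR/SF annotation
and methylation dips) and ``interstitial`` (everything else).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import percent_ratio

MINICENTROMERE_THRESHOLD_BP = 700_000

ANNOTATION_COLS = ["chrom", "start", "end", "family"]
ARRAY_COLS = ["chrom", "start", "end", "family", "n_members", "covered_bp"]


def is_alpha_family(family: str) -> bool:
    """Is this family label an alpha-satellite HOR family?"""
    fam = str(family).lower()
    return fam.startswith(("alphasat", "asat", "alpha_sat", "hor_"))


def is_rdna_family(family: str) -> bool:
    return str(family).lower() == "rdna"


def _check_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    for col in ANNOTATION_COLS:
        if col not in annotations.columns:
            raise ValueError(f"annotation table lacks column {col!r}")
    bad = annotations[annotations["start"] >= annotations["end"]]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(
            f"malformed annotation interval {r['chrom']}:{r['start']}-{r['end']} "
            f"({r['family']})"
        )
    return annotations


def merge_to_arrays(annotations: pd.DataFrame, max_gap_bp: int = 10_000,
                    min_array_bp: int = 10_000) -> pd.DataFrame:
    """Merge same-family annotations into arrays.

    Annotations of one family on one chromosome are chained while their gap
    is <= ``max_gap_bp``; resulting arrays shorter than ``min_array_bp`` are
    discarded. ``covered_bp`` is the bp covered by members (spacers between
    tracts do not count), so ``covered_bp <= end - start``.
    """
    if annotations.empty:
        return pd.DataFrame(columns=ARRAY_COLS)
    _check_annotations(annotations)
    rows = []
    for (chrom, family), grp in annotations.groupby(["chrom", "family"], sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_start = cur_end = None
        members: list[tuple[int, int]] = []

        def flush():
            if cur_start is None or cur_end - cur_start < min_array_bp:
                return
            covered = 0
            last = cur_start
            for s, e in members:
                covered += max(0, e - max(s, last))
                last = max(last, e)
            rows.append(dict(chrom=chrom, start=int(cur_start), end=int(cur_end),
                             family=family, n_members=len(members),
                             covered_bp=int(covered)))

        for r in grp.itertuples():
            if cur_start is None:
                cur_start, cur_end, members = r.start, r.end, [(r.start, r.end)]
            elif r.start - cur_end <= max_gap_bp:
                cur_end = max(cur_end, r.end)
                members.append((r.start, r.end))
            else:
                flush()
                cur_start, cur_end, members = r.start, r.end, [(r.start, r.end)]
        flush()
    out = pd.DataFrame(rows, columns=ARRAY_COLS)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def classify_arrays(arrays: pd.DataFrame, chrom_lengths: dict[str, int],
                    end_window_bp: int = 500_000) -> pd.DataFrame:
    """Assign ``cls`` and ``arm`` to every array (see module docstring)."""
    if arrays.empty:
        out = arrays.copy()
        out["cls"] = pd.Series(dtype=str)
        out["arm"] = pd.Series(dtype=str)
        return out
    out = arrays.copy().reset_index(drop=True)
    cls = np.array(["interstitial"] * len(out), dtype=object)
    arm = np.array(["unknown"] * len(out), dtype=object)
    for i, r in out.iterrows():
        L = chrom_lengths[r["chrom"]]
        if not (0 <= r["start"] < r["end"] <= L):
            raise ValueError(
                f"array outside chromosome: {r['chrom']}:{r['start']}-{r['end']}"
            )
        if is_rdna_family(r["family"]):
            cls[i] = "rdna"
        elif r["start"] < end_window_bp:
            cls[i], arm[i] = "subterminal", "p"
        elif r["end"] > L - end_window_bp:
            cls[i], arm[i] = "subterminal", "q"
    # largest non-subterminal alpha-satellite array per chromosome
    for chrom, grp in out.groupby("chrom"):
        cand = [
            i for i in grp.index
            if cls[i] == "interstitial" and is_alpha_family(out.at[i, "family"])
        ]
        if cand:
            largest = max(cand, key=lambda i: out.at[i, "end"] - out.at[i, "start"])
            cls[largest] = "centromeric_hor"
    out["cls"] = cls
    out["arm"] = arm
    return out


def classify_array(array: pd.Series | dict, chrom_length: int,
                   end_window_bp: int = 500_000,
                   chrom_arrays: pd.DataFrame | None = None):
    """Classify a single array; ``chrom_arrays`` supplies the chromosome
    context needed for the largest-alpha-array rule (defaults to the array
    alone)."""
    if chrom_arrays is None:
        chrom_arrays = pd.DataFrame([dict(array)])
    else:
        chrom_arrays = chrom_arrays.copy()
    lengths = {str(r["chrom"]): chrom_length for _, r in chrom_arrays.iterrows()}
    res = classify_arrays(chrom_arrays, lengths, end_window_bp)
    match = res[
        (res["chrom"] == array["chrom"])
        & (res["start"] == array["start"])
        & (res["end"] == array["end"])
    ].iloc[0]
    return match["cls"], match["arm"]


def minicentromere_partition(array_lengths, threshold_bp: int = MINICENTROMERE_THRESHOLD_BP):
    """Split HOR array lengths into (minicentromeres, normal), preserving
    order. Minicentromeres are arrays strictly shorter than the threshold
    (700 kb by convention)."""
    lengths = [int(x) for x in array_lengths]
    if any(x <= 0 for x in lengths):
        raise ValueError("array lengths must be positive")
    mini = [x for x in lengths if x < threshold_bp]
    normal = [x for x in lengths if x >= threshold_bp]
    return mini, normal


@dataclass
class HaplotypePairStats:
    n_pairs: int
    n_fold_exceeding: int
    pct_fold_exceeding: float
    n_div_pairs: int
    n_div_exceeding: int
    pct_div_exceeding: float


def haplotype_pair_stats(pairs, fold_threshold: float = 1.5,
                         div_threshold: float = 0.05) -> HaplotypePairStats:
    """Fractions of haplotype array pairs exceeding a size-fold and a
    sequence-divergence threshold.

    ``pairs`` is an iterable of ``(len_h1, len_h2, divergence)`` where
    divergence may be None/NaN (such pairs are excluded from the divergence
    denominator). The fold ratio is max/min, so it is >= 1 and symmetric in
    the two haplotypes. Percentages are rounded half-up to one decimal
    (7/23 -> 30.4, 9/23 -> 39.1).
    """
    n_pairs = n_fold = n_div_pairs = n_div = 0
    for l1, l2, div in pairs:
        if l1 <= 0 or l2 <= 0:
            raise ValueError("array lengths must be positive")
        n_pairs += 1
        if max(l1, l2) / min(l1, l2) > fold_threshold:
            n_fold += 1
        if div is not None and not (isinstance(div, float) and np.isnan(div)):
            if not 0.0 <= div <= 1.0:
                raise ValueError("divergence fraction must lie in [0, 1]")
            n_div_pairs += 1
            if div > div_threshold:
                n_div += 1
    return HaplotypePairStats(
        n_pairs=n_pairs,
        n_fold_exceeding=n_fold,
        pct_fold_exceeding=percent_ratio(n_fold, n_pairs) if n_pairs else 0.0,
        n_div_pairs=n_div_pairs,
        n_div_exceeding=n_div,
        pct_div_exceeding=percent_ratio(n_div, n_div_pairs) if n_div_pairs else 0.0,
    )


def read_bed_annotations(path) -> pd.DataFrame:
    """Read BED4+ satellite annotations (name column = family)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "family", "score", "strand"][: df.shape[1]]
    df.columns = cols + [f"extra{i}" for i in range(df.shape[1] - len(cols))]
    if "strand" not in df.columns:
        df["strand"] = "unknown"
    return df[["chrom", "start", "end", "family", "strand"]]


def write_bed_arrays(arrays: pd.DataFrame, path) -> None:
    """Arrays as BED6+ with class and arm in extra columns."""
    out = arrays.copy()
    out["score"] = 0
    out["strand"] = "."
    cols = ["chrom", "start", "end", "family", "score", "strand"]
    for extra in ("cls", "arm", "n_members", "covered_bp"):
        if extra in out.columns:
            cols.append(extra)
    out[cols].to_csv(path, sep="\t", header=False, index=False)


__all__ = [
    "MINICENTROMERE_THRESHOLD_BP", "HaplotypePairStats",
    "is_alpha_family", "is_rdna_family",
    "merge_to_arrays", "classify_arrays", "classify_array",
    "minicentromere_partition", "haplotype_pair_stats",
    "read_bed_annotations", "write_bed_arrays",
]
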