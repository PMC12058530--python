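"""CpG methylation smoothing and centromere dip region (CDR) calling.

The kinetochore site of a centromere is marked by a stretch of hypomethylated
CpGs (the CDR) inside the otherwise hypermethylated alpha-satellite HOR
array. The caller here is deliberately simple and fully parameterized:
window means are computed over the array, the baseline is the median of the
defined window means, windows dropping more than ``drop`` below the baseline
are dip windows, and consecutive dip windows merge into CDRs. Because the
baseline is median-relative, an array that is uniformly hypomethylated has no
dip by definition. Merged dips are refined to ``step``-resolution so that the
reported CDR interval tracks the underlying hypomethylated segment rather
than the coarse window grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRACK_COLS = ["chrom", "start", "end", "coverage", "fraction"]


@dataclass
class MethylationTrack:
    """Per-CpG methylation fractions, sorted by (chrom, position).

    ``df`` columns: chrom, start, end (start+1), coverage, fraction in [0,1].
    Positions address the C of a forward-strand CG.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        for col in TRACK_COLS:
            if col not in df.columns:
                raise ValueError(f"methylation track lacks column {col!r}")
        if not df.empty:
            if ((df["fraction"] < 0) | (df["fraction"] > 1)).any():
                raise ValueError("methylation fractions must lie in [0, 1]")
            df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
            dup = df.duplicated(subset=["chrom", "start"])
            if dup.any():
                raise ValueError("duplicate CpG positions in track")
        self.df = df
        self._by_chrom = {c: g for c, g in df.groupby("chrom")} if not df.empty else {}

    def positions_in(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        g = self._by_chrom.get(chrom)
        if g is None:
            return self.df.iloc[0:0]
        i = np.searchsorted(g["start"].to_numpy(), [start, end])
        return g.iloc[i[0]:i[1]]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read_tsv(cls, path) -> "MethylationTrack":
        """Read the 5-column simplified track: chrom start end coverage fraction."""
        df = pd.read_csv(path, sep="\t", header=None, names=TRACK_COLS, comment="#")
        return cls(df)

    @classmethod
    def read_bedmethyl(cls, path) -> "MethylationTrack":
        """Read 9+-column bedMethyl; column 11 (percent modified) -> fraction."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 11:
            raise ValueError("bedMethyl needs >= 11 columns")
        out = pd.DataFrame(dict(
            chrom=df.iloc[:, 0], start=df.iloc[:, 1], end=df.iloc[:, 2],
            coverage=df.iloc[:, 9], fraction=df.iloc[:, 10] / 100.0,
        ))
        return cls(out)

    def to_tsv(self, path) -> None:
        self.df[TRACK_COLS].to_csv(path, sep="\t", header=False, index=False)


def binned_methylation(track: MethylationTrack, region, window_bp: int,
                       step_bp: int) -> pd.DataFrame:
    """Sliding-window mean methylation over ``region = (chrom, start, end)``.

    Windows start every ``step_bp`` and tile the region (the last windows are
    truncated at the region end). Windows without CpGs carry NaN means.
    Columns: chrom, start, end, mean, n.
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("need window_bp >= step_bp > 0")
    chrom, rstart, rend = region
    g = track.positions_in(chrom, rstart, rend)
    pos = g["start"].to_numpy()
    frac = g["fraction"].to_numpy()
    starts = np.arange(rstart, rend, step_bp, dtype=int)
    ends = np.minimum(starts + window_bp, rend)
    i0 = np.searchsorted(pos, starts)
    i1 = np.searchsorted(pos, ends)
    csum = np.concatenate([[0.0], np.cumsum(frac)])
    n = i1 - i0
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, (csum[i1] - csum[i0]) / np.maximum(n, 1), np.nan)
    return pd.DataFrame(dict(chrom=chrom, start=starts, end=ends, mean=mean, n=n))


def _runs_with_gaps(flags: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Index runs of True allowing up to max_gap consecutive False inside."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    runs = []
    run_start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap:
            prev = i
        else:
            runs.append((run_start, prev))
            run_start = prev = i
    runs.append((run_start, prev))
    return runs


def call_cdrs(track: MethylationTrack, array, window_bp: int = 5_000,
              step_bp: int = 1_000, drop: float = 0.20,
              min_len_bp: int = 1_000, merge_gap_windows: int = 2) -> pd.DataFrame:
    """Call hypomethylation dips (CDRs) inside one satellite array.

    ``array`` is ``(chrom, start, end)`` or a mapping with those keys.
    Baseline = median of defined window means over the array; dip windows
    fall below ``baseline - drop``. Dip windows merge across at most
    ``merge_gap_windows`` intervening non-dip windows; merged dips are
    refined at ``step_bp`` resolution and dips shorter than ``min_len_bp``
    are discarded. Returns chrom, start, end, mean_inside, mean_flank.
    """
    if isinstance(array, (tuple, list)):
        chrom, astart, aend = array
    else:
        chrom, astart, aend = array["chrom"], array["start"], array["end"]
    astart, aend = int(astart), int(aend)

    wins = binned_methylation(track, (chrom, astart, aend), window_bp, step_bp)
    defined = wins.dropna(subset=["mean"])
    if defined.empty:
        warnings.warn(f"array {chrom}:{astart}-{aend} has no CpGs; no CDR call")
        return pd.DataFrame(columns=["chrom", "start", "end",
                                     "mean_inside", "mean_flank"])
    baseline = float(defined["mean"].median())
    threshold = baseline - drop
    is_dip = (wins["mean"] < threshold).to_numpy()

    rows = []
    for i0, i1 in _runs_with_gaps(is_dip, merge_gap_windows):
        lo = int(wins.at[i0, "start"])
        hi = int(wins.at[i1, "end"])
        # refine boundaries at step resolution
        fine = binned_methylation(track, (chrom, lo, hi), step_bp, step_bp)
        fine_dip = (fine["mean"] < threshold).to_numpy()
        for j0, j1 in _runs_with_gaps(fine_dip, merge_gap_windows):
            s = int(fine.at[j0, "start"])
            e = int(min(fine.at[j1, "end"], aend))
            if e - s < min_len_bp:
                continue
            inside = track.positions_in(chrom, s, e)["fraction"]
            flank_lo = track.positions_in(chrom, max(astart, s - 5 * window_bp), s)
            flank_hi = track.positions_in(chrom, e, min(aend, e + 5 * window_bp))
            flank = pd.concat([flank_lo, flank_hi])["fraction"]
            if inside.empty or flank.empty:
                continue
            if inside.mean() >= flank.mean():
                continue
            rows.append(dict(chrom=chrom, start=s, end=e,
                             mean_inside=float(inside.mean()),
                             mean_flank=float(flank.mean())))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                      "mean_inside", "mean_flank"])
    # dips are disjoint by construction, but enforce ordering
    return out.sort_values(["start"]).reset_index(drop=True)


def call_cdrs_all(track: MethylationTrack, arrays: pd.DataFrame,
                  **kwargs) -> pd.DataFrame:
    """Call CDRs for every centromeric HOR array in an array table; adds
    ``array_id`` and ``array_length`` columns."""
    frames = []
    cen = arrays[arrays["cls"] == "centromeric_hor"] if "cls" in arrays else arrays
    for aid, (_, arr) in enumerate(cen.iterrows()):
        cdrs = call_cdrs(track, arr, **kwargs)
        cdrs["array_id"] = aid
        cdrs["array_length"] = int(arr["end"] - arr["start"])
        frames.append(cdrs)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "mean_inside",
                                     "mean_flank", "array_id", "array_length"])
    return pd.concat(frames, ignore_index=True)


def cdr_length_vs_array_regression(pairs):
    """OLS of total CDR length on array length -> (slope, intercept, r2).

    ``pairs``: iterable of (array_length_bp, total_cdr_length_bp). The CDR
    length per array is the sum over its dips, which handles multi-dip
    arrays deterministically.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (array_length, cdr_length) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("array lengths have zero variance")
    res = stats.linregress(x, y)
    ss_res = float(np.sum((y - (res.intercept + res.slope * x)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(res.slope), float(res.intercept), r2


__all__ = [
    "MethylationTrack", "TRACK_COLS",
    "binned_methylation", "call_cdrs", "call_cdrs_all",
    "cdr_length_vs_array_regression",
]
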