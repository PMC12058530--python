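"""Subterminal heterochromatic cap decomposition.

Great-ape subterminal caps are megabase-scale blocks of a short AT-rich
satellite (pCht-like) organized into tracts of a few hundred kb interrupted
by spacer segments (segmental-duplication-derived in real genomes) that are
hypomethylated relative to the flanking satellite. This module detects caps
from classified satellite arrays, decomposes them into tracts and spacers
from the annotation gaps (an implementable proxy for sequence-level spacer
identification), and computes tract statistics, spacer modal length,
periodicity and midpoint-centred methylation profiles with a one-sided
hypomethylation-pocket test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import merge_intervals


def detect_caps(arrays: pd.DataFrame, chrom_lengths: dict[str, int],
                end_window_bp: int = 500_000, min_cap_bp: int = 1_000_000,
                merge_gap_bp: int = 200_000) -> pd.DataFrame:
    """Subterminal cap spans per chromosome arm.

    For each arm, subterminal-class arrays are merged across gaps up to
    ``merge_gap_bp`` (spacer scale); the merged block nearest the terminus is
    the cap if its satellite content reaches ``min_cap_bp``. Columns:
    chrom, start, end, arm.
    """
    rows = []
    if arrays.empty or "cls" not in arrays.columns:
        return pd.DataFrame(columns=["chrom", "start", "end", "arm"])
    sub = arrays[arrays["cls"] == "subterminal"]
    for (chrom, arm), grp in sub.groupby(["chrom", "arm"]):
        merged = merge_intervals(
            [(r.start, r.end) for r in grp.itertuples()], max_gap=merge_gap_bp
        )
        if not merged:
            continue
        block = merged[0] if arm == "p" else merged[-1]
        covered = sum(
            min(e, block[1]) - max(s, block[0])
            for s, e in zip(grp["start"], grp["end"])
            if s < block[1] and e > block[0]
        )
        if covered >= min_cap_bp:
            rows.append(dict(chrom=chrom, start=int(block[0]),
                             end=int(block[1]), arm=arm))
    return (pd.DataFrame(rows, columns=["chrom", "start", "end", "arm"])
            .sort_values(["chrom", "start"]).reset_index(drop=True))


def _tracts_in_cap(cap, annotations: pd.DataFrame, join_gap_bp: int = 0):
    """Satellite tract intervals inside the cap (same-family annotations
    merged across gaps <= join_gap_bp so butt-joined monomer records form
    one tract)."""
    chrom, cstart, cend = cap
    ann = annotations[
        (annotations["chrom"] == chrom)
        & (annotations["start"] < cend)
        & (annotations["end"] > cstart)
    ]
    if ann.empty:
        return []
    ivs = [(max(int(r.start), cstart), min(int(r.end), cend)) for r in ann.itertuples()]
    return merge_intervals(ivs, max_gap=join_gap_bp)


def find_spacers(cap, annotations: pd.DataFrame, min_spacer_bp: int = 5_000,
                 max_spacer_bp: int = 200_000, modal_bin_bp: int = 1_000):
    """Spacers = length-filtered unannotated gaps between consecutive tracts.

    ``cap`` is ``(chrom, start, end)`` or a mapping with those keys. Returns
    ``(spacers, modal_length_bp)`` where spacers has columns chrom, start,
    end, midpoint, left_tract, right_tract. The modal length is the most
    common spacer length after flooring to ``modal_bin_bp`` bins, ties broken
    toward the smaller bin; None when there are no spacers.
    """
    if not isinstance(cap, (tuple, list)):
        cap = (cap["chrom"], cap["start"], cap["end"])
    chrom, cstart, cend = cap[0], int(cap[1]), int(cap[2])
    tracts = _tracts_in_cap((chrom, cstart, cend), annotations)
    cols = ["chrom", "start", "end", "midpoint", "left_tract", "right_tract"]
    if len(tracts) < 2:
        return pd.DataFrame(columns=cols), None
    rows = []
    for i, ((_, le), (rs, _)) in enumerate(zip(tracts, tracts[1:])):
        gap = rs - le
        if min_spacer_bp <= gap <= max_spacer_bp:
            rows.append(dict(chrom=chrom, start=le, end=rs,
                             midpoint=(le + rs) // 2,
                             left_tract=i, right_tract=i + 1))
    spacers = pd.DataFrame(rows, columns=cols)
    if spacers.empty:
        return spacers, None
    lengths = (spacers["end"] - spacers["start"]).to_numpy()
    bins = (lengths // modal_bin_bp) * modal_bin_bp
    vals, counts = np.unique(bins, return_counts=True)
    modal = int(vals[counts == counts.max()].min())  # tie -> smaller bin
    return spacers, modal


@dataclass
class CapStructure:
    """A cap decomposed into satellite tracts and spacers."""

    chrom: str
    start: int
    end: int
    arm: str
    tracts: list[tuple[int, int]] = field(default_factory=list)
    spacers: pd.DataFrame = field(default_factory=pd.DataFrame)
    modal_spacer_bp: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def bookkeeping(self) -> dict:
        """Tract + spacer + unannotated-margin bp must equal cap length."""
        tract_bp = sum(e - s for s, e in self.tracts)
        spacer_bp = (
            int((self.spacers["end"] - self.spacers["start"]).sum())
            if not self.spacers.empty else 0
        )
        return dict(tract_bp=tract_bp, spacer_bp=spacer_bp,
                    margin_bp=self.length - tract_bp - spacer_bp)


def build_cap_structure(cap_row, annotations: pd.DataFrame,
                        **spacer_kwargs) -> CapStructure:
    cap = (cap_row["chrom"], int(cap_row["start"]), int(cap_row["end"]))
    tracts = _tracts_in_cap(cap, annotations)
    spacers, modal = find_spacers(cap, annotations, **spacer_kwargs)
    return CapStructure(chrom=cap[0], start=cap[1], end=cap[2],
                        arm=cap_row.get("arm", "unknown"), tracts=tracts,
                        spacers=spacers, modal_spacer_bp=modal)


def tract_stats(cap: CapStructure):
    """(mean tract length, sd, mean spacer-to-spacer spacing).

    Spacing is the distance between consecutive spacer midpoints — the cap's
    periodicity. sd and spacing are NaN when there are fewer than two tracts
    or spacers.
    """
    if not cap.tracts:
        raise ValueError("cap has no tracts")
    lengths = np.array([e - s for s, e in cap.tracts], dtype=float)
    mean_len = float(lengths.mean())
    sd_len = float(lengths.std(ddof=1)) if lengths.size > 1 else float("nan")
    if cap.spacers is not None and len(cap.spacers) > 1:
        mids = cap.spacers["midpoint"].to_numpy(dtype=float)
        spacing = float(np.diff(np.sort(mids)).mean())
    else:
        spacing = float("nan")
    return mean_len, sd_len, spacing


def spacer_methylation_profile(spacers: pd.DataFrame, track,
                               flank_bp: int = 25_000, bin_bp: int = 500):
    """Spacer-midpoint-centred methylation profile and pocket test.

    Profiles are aligned on spacer midpoints over ±``flank_bp``, binned at
    ``bin_bp`` and averaged across spacers. The pocket statistic is
    (mean CpG fraction inside spacers) − (mean fraction in flanking satellite
    within ``flank_bp`` of the midpoint, excluding CpGs inside any spacer),
    with a one-sided rank-sum (Mann-Whitney) test of spacer < flank.

    Returns ``(profile, pocket)``: profile has columns offset, mean, sd, n;
    pocket is a dict with statistic, p_value, n_inside, n_flank.
    """
    if spacers.empty:
        raise ValueError("no spacers given")
    spacer_ivs = {
        chrom: [(int(r.start), int(r.end)) for r in grp.itertuples()]
        for chrom, grp in spacers.groupby("chrom")
    }

    offsets = np.arange(-flank_bp, flank_bp, bin_bp)
    per_spacer_bins = []
    inside_vals, flank_vals = [], []
    for r in spacers.itertuples():
        mid = int(r.midpoint)
        g = track.positions_in(r.chrom, mid - flank_bp, mid + flank_bp)
        if g.empty:
            per_spacer_bins.append(np.full(offsets.size, np.nan))
            continue
        pos = g["start"].to_numpy()
        frac = g["fraction"].to_numpy()
        rel = pos - mid
        bin_idx = (rel + flank_bp) // bin_bp
        means = np.full(offsets.size, np.nan)
        for b in np.unique(bin_idx):
            means[int(b)] = frac[bin_idx == b].mean()
        per_spacer_bins.append(means)
        in_this = (pos >= r.start) & (pos < r.end)
        inside_vals.append(frac[in_this])
        in_any = np.zeros(pos.size, dtype=bool)
        for s, e in spacer_ivs.get(r.chrom, []):
            in_any |= (pos >= s) & (pos < e)
        flank_vals.append(frac[~in_any])

    if not inside_vals or all(v.size == 0 for v in inside_vals):
        raise ValueError("no CpGs in any spacer window")
    mat = np.vstack(per_spacer_bins)
    with np.errstate(invalid="ignore"):
        prof_mean = np.nanmean(mat, axis=0)
        prof_sd = (np.nanstd(mat, axis=0, ddof=1)
                   if mat.shape[0] > 1 else np.full(offsets.size, np.nan))
    n_per_bin = np.sum(~np.isnan(mat), axis=0)
    profile = pd.DataFrame(dict(offset=offsets, mean=prof_mean,
                                sd=prof_sd, n=n_per_bin))

    inside = np.concatenate([v for v in inside_vals if v.size])
    flank = (np.concatenate([v for v in flank_vals if v.size])
             if flank_vals else np.array([]))
    if flank.size == 0:
        raise ValueError("no CpGs in flanking satellite")
    statistic = float(inside.mean() - flank.mean())
    if np.all(inside == inside[0]) and np.all(flank == inside[0]):
        p = 0.5  # fully tied: no evidence in either direction
    else:
        p = float(stats.mannwhitneyu(inside, flank, alternative="less").pvalue)
    pocket = dict(statistic=statistic, p_value=p,
                  n_inside=int(inside.size), n_flank=int(flank.size))
    return profile, pocket


__all__ = [
    "CapStructure",
    "detect_caps", "find_spacers", "build_cap_structure",
    "tract_stats", "spacer_methylation_profile",
]
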