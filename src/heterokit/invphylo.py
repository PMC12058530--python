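"""Inversion phylogenetics: Fitch parsimony on a dated ape tree, recall
against prior callsets, and breakpoint feature-enrichment by permutation.

Interspecific inversions are treated as presence/absence characters over the
leaves of a rooted species tree. Because inversions are derived relative to
the reference state, the root is fixed to "reference" and a character that
can be explained by a single state change is assigned to that branch; any
character needing two or more changes is flagged recurrent. Heterozygous
species are treated as missing by default (only homozygous carriers are
confidently inverted in a diploid assembly comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from ._util import percent_ratio

_INF = float("inf")


@dataclass(frozen=True)
class Branch:
    """An edge of the rooted tree, identified by its child node."""

    branch_id: str
    length: float
    clade: tuple[str, ...]  # leaf labels below the edge


class SpeciesTree:
    """Rooted species tree with branch lengths in millions of years (Ma)."""

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self.tree = tree
        seen = set()
        for i, node in enumerate(tree.preorder_node_iter()):
            label = (
                node.taxon.label if node.taxon is not None else node.label
            )
            if label is None:
                label = f"node{i}"
                node.label = label
            if label in seen:
                raise ValueError(f"duplicate node label: {label}")
            seen.add(label)
            if node.edge.length is not None and node.edge.length < 0:
                raise ValueError("negative branch length")

    @staticmethod
    def _label(node) -> str:
        return node.taxon.label if node.taxon is not None else node.label

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_names(self) -> list[str]:
        return [self._label(lf) for lf in self.tree.leaf_node_iter()]

    def branches(self) -> list[Branch]:
        """All edges below the root, identified by their child node label."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            clade = tuple(self._label(lf) for lf in node.leaf_iter())
            out.append(Branch(self._label(node),
                              float(node.edge.length or 0.0), clade))
        return out

    def total_length(self) -> float:
        return sum(b.length for b in self.branches())


#: Fixture split times (Ma): human-Pan ~6, African apes ~10.75, orangutans
#: ~19, chimp-bonobo ~1.7, Bornean-Sumatran orangutan 0.9.
DEFAULT_APE_NEWICK = (
    "((Bornean_orangutan:0.9,Sumatran_orangutan:0.9)pongo:18.1,"
    "(gorilla:10.75,(human:6.0,(chimpanzee:1.7,bonobo:1.7)pan:4.3)"
    "homo_pan:4.75)homininae:8.25)root;"
)

#: Siamang split is not among the stated divergence dates; 22 Ma is a fixture
#: value for the gibbon/great-ape split chosen once for the simulator.
DEFAULT_APE_NEWICK_WITH_SIAMANG = (
    "(siamang:22.0,((Bornean_orangutan:0.9,Sumatran_orangutan:0.9)pongo:18.1,"
    "(gorilla:10.75,(human:6.0,(chimpanzee:1.7,bonobo:1.7)pan:4.3)"
    "homo_pan:4.75)homininae:8.25)greatapes:3.0)root;"
)


def default_ape_tree(include_siamang: bool = False) -> SpeciesTree:
    """The dated ape species tree used as simulation/analysis default."""
    nwk = DEFAULT_APE_NEWICK_WITH_SIAMANG if include_siamang else DEFAULT_APE_NEWICK
    return SpeciesTree.from_newick(nwk)


# --------------------------------------------------------------------------
# Fitch parsimony with a reference-state root
# --------------------------------------------------------------------------


def genotypes_to_character(row: pd.Series | dict, leaves,
                           het_as_present: bool = False) -> dict[str, int | None]:
    """Collapse per-haplotype genotypes to a species presence character.

    A species is "present" iff both haplotype columns (``{leaf}`` or
    ``{leaf}_hap1/2``) are ``inverted``; heterozygous species are missing
    unless ``het_as_present``.
    """
    char: dict[str, int | None] = {}
    for leaf in leaves:
        cols = [c for c in (f"{leaf}_hap1", f"{leaf}_hap2", leaf) if c in row]
        vals = [row[c] for c in cols]
        if not vals or any(v == "missing" for v in vals):
            char[leaf] = None
        elif all(v == "inverted" for v in vals):
            char[leaf] = 1
        elif any(v == "inverted" for v in vals):
            char[leaf] = 1 if het_as_present else None
        else:
            char[leaf] = 0
    return char


def _sankoff_min_changes(tree: SpeciesTree, states: dict[str, int]) -> int:
    """Minimum number of state changes with the root fixed to state 0.

    Unit-cost Sankoff dynamic programme over the rooted tree; leaves missing
    from ``states`` contribute no cost (pruned).
    """
    cost: dict[int, tuple[float, float]] = {}
    for node in tree.tree.postorder_node_iter():
        label = SpeciesTree._label(node)
        if node.is_leaf():
            s = states.get(label)
            if s is None:
                cost[id(node)] = (0.0, 0.0)
            else:
                cost[id(node)] = (0.0, _INF) if s == 0 else (_INF, 0.0)
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                k0, k1 = cost[id(child)]
                c0 += min(k0, k1 + 1)
                c1 += min(k1, k0 + 1)
            cost[id(node)] = (c0, c1)
    root_cost = cost[id(tree.tree.seed_node)][0]
    return int(root_cost) if root_cost != _INF else 0


def fitch_assign(character: dict[str, int | None], tree: SpeciesTree):
    """Assign a presence/absence character to the tree.

    Returns ``(min_changes, branch_id_or_None, recurrent)``. With exactly one
    change the event is a single gain whose branch is the unique edge whose
    clade (restricted to non-missing leaves) equals the present set; with two
    or more changes the character is recurrent and no branch is assigned.
    """
    defined = {k: v for k, v in character.items() if v is not None}
    if not defined:
        raise ValueError("character is missing for all species")
    if len(defined) < 2:
        raise ValueError("character defined for fewer than 2 species")
    present = {k for k, v in defined.items() if v == 1}
    changes = _sankoff_min_changes(tree, defined)
    if changes == 0:
        return 0, None, False
    if changes >= 2:
        return changes, None, True
    for b in tree.branches():
        visible = {leaf for leaf in b.clade if leaf in defined}
        if visible and visible == present:
            return 1, b.branch_id, False
    # a single loss cannot happen with a reference root and one change
    raise AssertionError("single-change character with no matching branch")


def assign_inversions(genotypes: pd.DataFrame, tree: SpeciesTree,
                      het_as_present: bool = False) -> pd.DataFrame:
    """Fitch-assign every inversion character in a genotype table."""
    leaves = tree.leaf_names()
    rows = []
    for _, row in genotypes.iterrows():
        char = genotypes_to_character(row, leaves, het_as_present)
        if all(v is None for v in char.values()) or sum(
            v is not None for v in char.values()
        ) < 2:
            rows.append(dict(event=row["event"], changes=np.nan,
                             branch="", recurrent=False, assigned=False))
            continue
        changes, branch, recurrent = fitch_assign(char, tree)
        rows.append(dict(event=row["event"], changes=changes,
                         branch=branch or "", recurrent=recurrent,
                         assigned=branch is not None))
    return pd.DataFrame(rows)


def branch_count_regression(counts, lengths):
    """OLS of per-branch event counts on branch lengths -> (slope, r2)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.size < 3:
        raise ValueError("need >= 3 branches")
    if np.allclose(lengths, lengths[0]):
        raise ValueError("branch lengths have zero variance")
    res = stats.linregress(lengths, counts)
    ss_res = float(np.sum((counts - (res.intercept + res.slope * lengths)) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(res.slope), r2


# --------------------------------------------------------------------------
# recall against prior callsets
# --------------------------------------------------------------------------


def _reciprocal_overlap(a, b) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def recall_vs_previous(current: pd.DataFrame, previous: pd.DataFrame,
                       min_reciprocal_overlap: float = 0.5):
    """Fraction of previous calls confirmed by a current call.

    Both frames need ``chrom``, ``start``, ``end``. A previous call is
    confirmed if some current call on the same chromosome overlaps it
    reciprocally by at least the threshold. Returns
    ``(confirmed_count, percent)`` with the percentage rounded half-up to one
    decimal (79/114 -> 69.3).
    """
    if previous.empty:
        raise ValueError("previous callset is empty")
    confirmed = 0
    cur_by_chrom = dict(tuple(current.groupby("chrom"))) if not current.empty else {}
    for _, prev in previous.iterrows():
        cur = cur_by_chrom.get(prev["chrom"])
        if cur is None:
            continue
        p = (prev["start"], prev["end"])
        hit = any(
            _reciprocal_overlap(p, (c.start, c.end)) >= min_reciprocal_overlap
            for c in cur.itertuples()
        )
        confirmed += bool(hit)
    return confirmed, percent_ratio(confirmed, len(previous))


# --------------------------------------------------------------------------
# breakpoint feature enrichment by permutation
# --------------------------------------------------------------------------


def _count_hits(starts, ends, feat_starts, feat_ends, pad):
    """Number of intervals with >= 1 (padded) breakpoint inside a feature."""
    hits = 0
    for s, e in zip(starts, ends):
        hit = False
        for bp in (s, e):
            lo, hi = bp - pad, bp + pad
            if np.any((feat_starts <= hi) & (feat_ends > lo)):
                hit = True
                break
        hits += hit
    return hits


def breakpoint_feature_enrichment(
    inversions: pd.DataFrame,
    features: pd.DataFrame,
    chrom_lengths: dict[str, int],
    gap_intervals: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    pad_bp: int = 10_000,
) -> dict:
    """Permutation test for features (e.g. SDs) at inversion breakpoints.

    The observed statistic is the number of inversions with at least one
    breakpoint within ``pad_bp`` of a feature interval. The null preserves
    each inversion's chromosome and length and replaces its position with a
    uniform draw avoiding assembly gaps. Fold = observed / mean(null);
    one-sided empirical P = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n_inv = len(inversions)
    if features.empty:
        warnings.warn("feature list is empty; fold undefined")
        return dict(observed=0, null_mean=0.0, null_sd=0.0,
                    fold=float("nan"), p_value=1.0, n_perm=n_perm, seed=seed,
                    observed_fraction_pct=0.0 if n_inv else float("nan"))

    feats = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in features.groupby("chrom")
    }
    gaps = {}
    if gap_intervals is not None and not gap_intervals.empty:
        gaps = {
            chrom: list(zip(grp["start"], grp["end"]))
            for chrom, grp in gap_intervals.groupby("chrom")
        }
    empty = (np.array([]), np.array([]))

    observed = 0
    for inv in inversions.itertuples():
        fs, fe = feats.get(inv.chrom, empty)
        observed += _count_hits([inv.start], [inv.end], fs, fe, pad_bp)

    null = np.zeros(n_perm)
    inv_list = list(inversions.itertuples())
    for p in range(n_perm):
        count = 0
        for inv in inv_list:
            L = chrom_lengths[inv.chrom]
            ilen = inv.end - inv.start
            fs, fe = feats.get(inv.chrom, empty)
            chrom_gaps = gaps.get(inv.chrom, [])
            for _try in range(1000):
                s = int(rng.integers(0, max(1, L - ilen)))
                e = s + ilen
                if not any(gs < e and ge > s for gs, ge in chrom_gaps):
                    break
            count += _count_hits([s], [e], fs, fe, pad_bp)
        null[p] = count

    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else float("inf")
    p_value = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    return dict(
        observed=int(observed),
        null_mean=null_mean,
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        fold=float(fold),
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
        observed_fraction_pct=percent_ratio(observed, n_inv) if n_inv else float("nan"),
    )


__all__ = [
    "SpeciesTree", "Branch", "default_ape_tree",
    "DEFAULT_APE_NEWICK", "DEFAULT_APE_NEWICK_WITH_SIAMANG",
    "genotypes_to_character", "fitch_assign", "assign_inversions",
    "branch_count_regression", "recall_vs_previous",
    "breakpoint_feature_enrichment",
]
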