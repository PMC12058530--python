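"""Synthetic diploid ape-like genome generator with full ground truth.

Emulates the architectural features of hominoid chromosome arms at reduced
scale: telomeric ``TTAGGG`` runs, centromeric alpha-satellite higher-order
repeat (HOR) arrays with optionally bimodal length distributions (normal
centromeres versus sub-700-kb "minicentromeres"), subterminal heterochromatic
caps built from a 32-bp AT-rich satellite interrupted by periodic spacers,
rDNA arrays of integer unit counts, assembly gaps (N runs), CpG methylation
tracks carrying centromere dip regions (CDRs) and hypomethylated spacer
pockets, and inversions evolved on a dated species tree.

Every placed feature is recorded in a :class:`TruthTables` bundle so that the
downstream analysis modules can be validated by exact round-trip. All interval
coordinates are 0-based half-open (BED convention); a CpG site is addressed by
the position of the C of the forward-strand CG. One top-level seed fixes all
randomness; each feature class draws from a child generator derived by a fixed
offset, so enabling one feature does not perturb the others.

The generator makes no claim of biological sequence realism (no indel
evolution, no transposable elements, no read simulation): background sequence
is i.i.d. uniform over ACGT, and satellite arrays are exact tandem repeats
with an optional uniform substitution rate.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import child_rng, round_half_up

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed child-seed offsets per feature class
_OFF_BACKGROUND = 11
_OFF_TELOMERE = 23
_OFF_CENTROMERE = 37
_OFF_CAP = 41
_OFF_RDNA = 53
_OFF_GAPS = 61
_OFF_METH = 71
_OFF_INV = 83
_OFF_MOTIFS = 97


def _random_seq(rng: np.random.Generator, n: int, p=None) -> np.ndarray:
    """Random uint8 base array of length n (optionally biased base weights)."""
    if p is None:
        idx = rng.integers(0, 4, size=n)
    else:
        idx = rng.choice(4, size=n, p=p)
    return _ACGT[idx]


def _tile(unit: np.ndarray, length: int) -> np.ndarray:
    reps = int(np.ceil(length / len(unit)))
    return np.tile(unit, reps)[:length]


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class TelomereConfig:
    motif: str = "TTAGGG"           # canonical vertebrate telomere 6-mer
    run_bp: int = 5_000


@dataclass
class CentromereConfig:
    """Alpha-satellite HOR array model.

    The default array-length distribution mirrors the bimodal pattern seen in
    bonobo: a minicentromere component (mean 110 kb, observed range
    ~15-674 kb) holding 27/48 of arrays, and a normal component (mean 3.6 Mb,
    range ~1.6-6.7 Mb) for the rest.
    """

    monomer_bp: int = 171
    monomers_per_unit: int = 12
    distribution: str = "mixture"    # "mixture" | "unimodal"
    mixture_weight: float = 27 / 48  # probability of the small component
    mean_small_bp: float = 110_000.0
    sd_small_bp: float = 100_000.0
    mean_large_bp: float = 3_600_000.0
    sd_large_bp: float = 1_200_000.0
    min_bp: int = 15_000
    max_bp: int = 6_700_000
    substitution_rate: float = 0.0   # per-base; 0 keeps identity tests exact

    @property
    def unit_bp(self) -> int:
        return self.monomer_bp * self.monomers_per_unit


@dataclass
class CapConfig:
    """Subterminal heterochromatic cap: satellite tracts + periodic spacers.

    Defaults follow the gorilla-like architecture: a 32-bp AT-rich satellite
    monomer, tracts of mean ~400 kb (reported range 335-536 kb) interrupted by
    spacers of 34 kb, building a ~6 Mb cap on the p arm.
    """

    p_arm: bool = True
    q_arm: bool = False
    monomer_bp: int = 32
    at_fraction: float = 0.8
    tract_mean_bp: float = 400_000.0
    tract_sd_bp: float = 50_000.0
    spacer_bp: int = 34_000
    spacer_period_bp: int | None = None  # if set, tract = period - spacer
    cap_length_bp: int = 6_000_000
    n_tracts: int | None = None          # if set, overrides cap_length_bp


@dataclass
class RdnaConfig:
    unit_bp: int = 45_000            # human rDNA repeat unit ~45 kb
    copies: int = 20
    n_rdna_chromosomes: int = 1      # rDNA placed on the first k chromosomes


@dataclass
class GapConfig:
    n_gaps: int = 1                  # per haplotype, in background sequence
    gap_bp: int = 10_000
    min_run_n: int = 10


@dataclass
class MethylationConfig:
    background_mean: float = 0.9
    background_sd: float = 0.05
    cdr_mean: float = 0.1
    cdr_slope: float = 0.3           # truth CDR length = slope * array length
    cdr_noise_sd_bp: float = 10_000.0
    cdr_min_bp: int = 15_000
    spacer_pocket_mean: float = 0.1
    coverage_mean: float = 30.0


@dataclass
class InversionConfig:
    rate_per_ma: float = 2.0         # events per branch per Ma
    recurrent_fraction: float = 0.0
    n_events: int | None = None      # fixed event count overrides the rate
    min_len_bp: int = 10_000
    max_len_bp: int = 1_000_000


@dataclass
class SimConfig:
    """Top-level simulation parameters; ``seed`` fixes all randomness."""

    n_chromosomes: int = 3
    chrom_length_bp: int = 16_000_000
    haplotypes: tuple[str, ...] = ("hap1", "hap2")
    telomere: TelomereConfig = field(default_factory=TelomereConfig)
    centromere: CentromereConfig = field(default_factory=CentromereConfig)
    cap: CapConfig = field(default_factory=CapConfig)
    rdna: RdnaConfig = field(default_factory=RdnaConfig)
    gaps: GapConfig = field(default_factory=GapConfig)
    methylation: MethylationConfig = field(default_factory=MethylationConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 0:
            raise ValueError("n_chromosomes must be >= 0")
        if self.chrom_length_bp <= 0:
            raise ValueError("chrom_length_bp must be > 0")
        if not 0.0 <= self.centromere.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must lie in [0, 1]")
        for frac in (
            self.methylation.background_mean,
            self.methylation.cdr_mean,
            self.methylation.spacer_pocket_mean,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("methylation fractions must lie in [0, 1]")
        if len(self.telomere.motif) != 6:
            raise ValueError("telomere motif must be a 6-mer")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        kwargs = {}
        sub = {
            "telomere": TelomereConfig,
            "centromere": CentromereConfig,
            "cap": CapConfig,
            "rdna": RdnaConfig,
            "gaps": GapConfig,
            "methylation": MethylationConfig,
            "inversion": InversionConfig,
        }
        for key, val in d.items():
            if key in sub:
                kwargs[key] = sub[key](**val)
            elif key == "haplotypes":
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class ChromosomeTooShortError(ValueError):
    """Configured features do not fit in the chromosome."""

    def __init__(self, chrom: str, needed: int, available: int):
        self.chrom = chrom
        self.deficit = needed - available
        super().__init__(
            f"chromosome {chrom}: configured features need {needed} bp but "
            f"only {available} bp are available (deficit {self.deficit} bp)"
        )


# --------------------------------------------------------------------------
# truth tables
# --------------------------------------------------------------------------

_IV_COLS = ["chrom", "start", "end"]


@dataclass
class TruthTables:
    """Ground-truth annotations for one simulated diploid assembly.

    All frames carry BED-style half-open intervals plus a ``haplotype``
    column; ``satellites`` is the annotation-level truth (one row per tract /
    array / rDNA block, family in ``family``), ``arrays`` the merged
    array-level truth with class labels.
    """

    chrom_lengths: dict[str, int] = field(default_factory=dict)
    telomeres: pd.DataFrame = field(default_factory=pd.DataFrame)
    gaps: pd.DataFrame = field(default_factory=pd.DataFrame)
    satellites: pd.DataFrame = field(default_factory=pd.DataFrame)
    arrays: pd.DataFrame = field(default_factory=pd.DataFrame)
    spacers: pd.DataFrame = field(default_factory=pd.DataFrame)
    caps: pd.DataFrame = field(default_factory=pd.DataFrame)
    cdrs: pd.DataFrame = field(default_factory=pd.DataFrame)
    rdna: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        for name in ("telomeres", "gaps", "satellites", "arrays",
                     "spacers", "caps", "cdrs"):
            df = getattr(self, name)
            if df.empty:
                continue
            for _, row in df.iterrows():
                length = self.chrom_lengths[row["chrom"]]
                if not (0 <= row["start"] < row["end"] <= length):
                    raise ValueError(
                        f"truth {name} interval outside chromosome: "
                        f"{row['chrom']}:{row['start']}-{row['end']}"
                    )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        bed4 = {
            "telomeres": ("telomere",),
            "gaps": ("gap",),
        }
        for name, (label,) in bed4.items():
            df = getattr(self, name)
            path = outdir / f"truth_{name}.bed"
            out = df[_IV_COLS].copy() if not df.empty else pd.DataFrame(columns=_IV_COLS)
            out["name"] = label
            out.to_csv(path, sep="\t", header=False, index=False)
            written[name] = path
        for name, namecol in (
            ("satellites", "family"),
            ("arrays", "cls"),
            ("spacers", None),
            ("caps", None),
            ("cdrs", None),
        ):
            df = getattr(self, name)
            path = outdir / f"truth_{name}.bed"
            out = df[_IV_COLS].copy() if not df.empty else pd.DataFrame(columns=_IV_COLS)
            out["name"] = df[namecol] if (namecol and not df.empty) else name.rstrip("s")
            out.to_csv(path, sep="\t", header=False, index=False)
            written[name] = path
        path = outdir / "truth_rdna.tsv"
        self.rdna.to_csv(path, sep="\t", index=False)
        written["rdna"] = path
        path = outdir / "chrom_lengths.tsv"
        pd.Series(self.chrom_lengths, name="length").rename_axis("chrom").to_csv(
            path, sep="\t"
        )
        written["chrom_lengths"] = path
        return written


# --------------------------------------------------------------------------
# assembly generation
# --------------------------------------------------------------------------


def _draw_array_length(cfg: CentromereConfig, rng: np.random.Generator) -> tuple[int, str]:
    """Draw one HOR array length (bp) and its truth component label."""

    def lognormal(mean, sd):
        mu = np.log(mean**2 / np.sqrt(sd**2 + mean**2))
        sigma = np.sqrt(np.log(1 + (sd / mean) ** 2))
        return rng.lognormal(mu, sigma)

    if cfg.distribution == "mixture" and rng.random() < cfg.mixture_weight:
        length, comp = lognormal(cfg.mean_small_bp, cfg.sd_small_bp), "small"
    elif cfg.distribution == "mixture":
        length, comp = lognormal(cfg.mean_large_bp, cfg.sd_large_bp), "large"
    else:
        length, comp = lognormal(cfg.mean_large_bp, cfg.sd_large_bp), "unimodal"
    length = int(np.clip(length, cfg.min_bp, cfg.max_bp))
    return length, comp


def _build_cap(cfg: CapConfig, monomer: np.ndarray, rng: np.random.Generator):
    """Return (seq array, tract spans, spacer spans) relative to cap start."""
    tracts: list[tuple[int, int]] = []
    spacers: list[tuple[int, int]] = []
    parts: list[np.ndarray] = []
    pos = 0

    def draw_tract() -> int:
        if cfg.spacer_period_bp is not None:
            return int(cfg.spacer_period_bp) - int(cfg.spacer_bp)
        return int(max(cfg.monomer_bp, rng.normal(cfg.tract_mean_bp, cfg.tract_sd_bp)))

    if cfg.n_tracts is not None:
        # exact tract count: no truncation, cap length is emergent
        for i in range(int(cfg.n_tracts)):
            tract_len = draw_tract()
            parts.append(_tile(monomer, tract_len))
            tracts.append((pos, pos + tract_len))
            pos += tract_len
            if i < int(cfg.n_tracts) - 1:
                parts.append(_random_seq(rng, int(cfg.spacer_bp)))
                spacers.append((pos, pos + int(cfg.spacer_bp)))
                pos += int(cfg.spacer_bp)
        return np.concatenate(parts), tracts, spacers

    while pos < cfg.cap_length_bp:
        tract_len = min(draw_tract(), cfg.cap_length_bp - pos)
        parts.append(_tile(monomer, tract_len))
        tracts.append((pos, pos + tract_len))
        pos += tract_len
        if pos >= cfg.cap_length_bp:
            break
        spacer_len = min(int(cfg.spacer_bp), cfg.cap_length_bp - pos)
        if spacer_len < cfg.spacer_bp:
            # do not end a cap on a truncated spacer; pad with satellite
            parts.append(_tile(monomer, spacer_len))
            s, e = tracts[-1]
            tracts[-1] = (s, e + spacer_len)
            pos += spacer_len
            break
        parts.append(_random_seq(rng, spacer_len))
        spacers.append((pos, pos + spacer_len))
        pos += spacer_len
    return np.concatenate(parts), tracts, spacers


def generate_assembly(config: SimConfig, seed: int | None = None):
    """Build the diploid synthetic assembly.

    Returns ``(sequences, truth)`` where ``sequences`` maps chromosome name
    (``{hap}_chr{i}``) to an upper-case DNA string (gaps as N) and ``truth``
    is the :class:`TruthTables` bundle. Deterministic given (config, seed).
    """
    config.validate()
    seed = config.seed if seed is None else seed

    motif_rng = child_rng(seed, _OFF_MOTIFS)
    at = config.cap.at_fraction / 2.0
    gc = (1.0 - config.cap.at_fraction) / 2.0
    cap_monomer = _random_seq(motif_rng, config.cap.monomer_bp, p=[at, gc, gc, at])
    # guarantee one CpG per cap monomer so tract methylation is defined
    cg_at = int(motif_rng.integers(0, config.cap.monomer_bp - 1))
    cap_monomer[cg_at] = ord("C")
    cap_monomer[cg_at + 1] = ord("G")
    rdna_unit = _random_seq(motif_rng, config.rdna.unit_bp)

    # whole motif copies only, so exact-tandem detection recovers the truth
    # interval exactly (run_bp is rounded down to a multiple of the motif)
    n_copies = max(1, config.telomere.run_bp // 6)
    telo_fwd = np.frombuffer((config.telomere.motif * n_copies).encode(),
                             dtype=np.uint8)
    telo_rev = np.frombuffer(revcomp(config.telomere.motif * n_copies).encode(),
                             dtype=np.uint8)

    sequences: dict[str, str] = {}
    chrom_lengths: dict[str, int] = {}
    telomeres, gaps_rows, sat_rows, array_rows = [], [], [], []
    spacer_rows, cap_rows, rdna_rows = [], [], []

    for h_i, hap in enumerate(config.haplotypes):
        cen_rng = child_rng(seed, _OFF_CENTROMERE + 1000 * h_i)
        cap_rng = child_rng(seed, _OFF_CAP + 1000 * h_i)
        bg_rng = child_rng(seed, _OFF_BACKGROUND + 1000 * h_i)
        gap_rng = child_rng(seed, _OFF_GAPS + 1000 * h_i)

        for c_i in range(config.n_chromosomes):
            chrom = f"{hap}_chr{c_i + 1}"
            L = int(config.chrom_length_bp)

            # --- plan features -------------------------------------------
            array_len, comp = _draw_array_length(config.centromere, cen_rng)
            hor_monomer = _random_seq(cen_rng, config.centromere.monomer_bp)
            hor_unit = _tile(hor_monomer, config.centromere.unit_bp)
            # small per-monomer variation inside the unit keeps the unit,
            # not the monomer, the repeating entity
            n_mut = max(1, config.centromere.unit_bp // 100)
            mut_pos = cen_rng.integers(0, config.centromere.unit_bp, size=n_mut)
            hor_unit = hor_unit.copy()
            hor_unit[mut_pos] = _random_seq(cen_rng, n_mut)
            cen_seq = _tile(hor_unit, array_len)
            if config.centromere.substitution_rate > 0:
                mask = cen_rng.random(array_len) < config.centromere.substitution_rate
                cen_seq = cen_seq.copy()
                cen_seq[mask] = _random_seq(cen_rng, int(mask.sum()))

            features: list[tuple[str, object]] = [("telomere_p", telo_rev)]
            if config.cap.p_arm and config.cap.cap_length_bp > 0:
                cap_seq, ctr, csp = _build_cap(config.cap, cap_monomer, cap_rng)
                features.append(("cap_p", (cap_seq, ctr, csp)))
            features.append(("background", None))
            features.append(("centromere", cen_seq))
            features.append(("background", None))
            has_rdna = (
                c_i < config.rdna.n_rdna_chromosomes and config.rdna.copies > 0
            )
            if has_rdna:
                features.append(("rdna", _tile(rdna_unit,
                                               config.rdna.unit_bp * config.rdna.copies)))
                features.append(("background", None))
            if config.cap.q_arm and config.cap.cap_length_bp > 0:
                cap_seq, ctr, csp = _build_cap(config.cap, cap_monomer, cap_rng)
                features.append(("cap_q", (cap_seq, ctr, csp)))
            features.append(("telomere_q", telo_fwd))

            fixed = 0
            n_bg = 0
            for kind, payload in features:
                if kind == "background":
                    n_bg += 1
                elif kind.startswith("cap"):
                    fixed += len(payload[0])
                else:
                    fixed += len(payload)
            available = L - fixed
            min_bg = 1_000 * n_bg
            if available < min_bg:
                raise ChromosomeTooShortError(chrom, fixed + min_bg, L)
            # random split of background bp across the open slots
            w = bg_rng.dirichlet(np.ones(n_bg)) if n_bg > 1 else np.array([1.0])
            bg_sizes = np.floor(w * (available - min_bg)).astype(int) + 1_000
            bg_sizes[-1] += available - int(bg_sizes.sum())

            # --- lay out sequence and record truth -----------------------
            parts: list[np.ndarray] = []
            pos = 0
            bg_j = 0
            for kind, payload in features:
                if kind == "background":
                    seg = _random_seq(bg_rng, int(bg_sizes[bg_j]))
                    bg_j += 1
                    parts.append(seg)
                    pos += len(seg)
                    continue
                if kind.startswith("telomere"):
                    parts.append(payload)
                    telomeres.append(
                        dict(chrom=chrom, start=pos, end=pos + len(payload),
                             haplotype=hap, terminus="p" if kind.endswith("p") else "q")
                    )
                    pos += len(payload)
                    continue
                if kind.startswith("cap"):
                    cap_seq, ctr, csp = payload
                    arm = "p" if kind.endswith("p") else "q"
                    cap_rows.append(dict(chrom=chrom, start=pos, end=pos + len(cap_seq),
                                         haplotype=hap, arm=arm))
                    for s, e in ctr:
                        sat_rows.append(dict(chrom=chrom, start=pos + s, end=pos + e,
                                             family="pCht", haplotype=hap))
                    for s, e in csp:
                        spacer_rows.append(dict(chrom=chrom, start=pos + s, end=pos + e,
                                                haplotype=hap, arm=arm))
                    array_rows.append(dict(chrom=chrom, start=pos, end=pos + len(cap_seq),
                                           family="pCht", cls="subterminal", arm=arm,
                                           haplotype=hap, component=""))
                    parts.append(cap_seq)
                    pos += len(cap_seq)
                    continue
                if kind == "centromere":
                    sat_rows.append(dict(chrom=chrom, start=pos, end=pos + len(payload),
                                         family="alphasat_HOR", haplotype=hap))
                    array_rows.append(dict(chrom=chrom, start=pos, end=pos + len(payload),
                                           family="alphasat_HOR", cls="centromeric_hor",
                                           arm="unknown", haplotype=hap, component=comp))
                    parts.append(payload)
                    pos += len(payload)
                    continue
                if kind == "rdna":
                    sat_rows.append(dict(chrom=chrom, start=pos, end=pos + len(payload),
                                         family="rDNA", haplotype=hap))
                    array_rows.append(dict(chrom=chrom, start=pos, end=pos + len(payload),
                                           family="rDNA", cls="rdna", arm="unknown",
                                           haplotype=hap, component=""))
                    rdna_rows.append(dict(chrom=chrom, start=pos, end=pos + len(payload),
                                          haplotype=hap, unit_bp=config.rdna.unit_bp,
                                          copies=config.rdna.copies))
                    parts.append(payload)
                    pos += len(payload)
                    continue
                raise AssertionError(kind)

            seq = np.concatenate(parts)
            assert len(seq) == L, (chrom, len(seq), L)
            sequences[chrom] = seq  # uint8 for now; gaps punched below
            chrom_lengths[chrom] = L

        # --- assembly gaps in background sequence ------------------------
        hap_chroms = [f"{hap}_chr{i + 1}" for i in range(config.n_chromosomes)]
        if config.gaps.n_gaps > 0 and hap_chroms:
            feature_df = pd.DataFrame(
                sat_rows + [t for t in telomeres]
            )
            for _ in range(config.gaps.n_gaps):
                chrom = hap_chroms[int(gap_rng.integers(0, len(hap_chroms)))]
                L = chrom_lengths[chrom]
                occupied = feature_df[feature_df["chrom"] == chrom]
                for _try in range(200):
                    start = int(gap_rng.integers(0, L - config.gaps.gap_bp))
                    end = start + config.gaps.gap_bp
                    clash = (
                        (occupied["start"] < end) & (occupied["end"] > start)
                    ).any()
                    clash = clash or any(
                        g["chrom"] == chrom and g["start"] < end and g["end"] > start
                        for g in gaps_rows
                    )
                    if not clash:
                        sequences[chrom][start:end] = ord("N")
                        gaps_rows.append(dict(chrom=chrom, start=start, end=end,
                                              haplotype=hap))
                        break

    sequences = {c: a.tobytes().decode() for c, a in sequences.items()}

    truth = TruthTables(
        chrom_lengths=chrom_lengths,
        telomeres=pd.DataFrame(telomeres),
        gaps=pd.DataFrame(gaps_rows, columns=_IV_COLS + ["haplotype"]),
        satellites=pd.DataFrame(sat_rows),
        arrays=pd.DataFrame(array_rows),
        spacers=pd.DataFrame(spacer_rows, columns=_IV_COLS + ["haplotype", "arm"]),
        caps=pd.DataFrame(cap_rows, columns=_IV_COLS + ["haplotype", "arm"]),
        rdna=pd.DataFrame(rdna_rows,
                          columns=_IV_COLS + ["haplotype", "unit_bp", "copies"]),
    )
    truth.validate()
    return sequences, truth


def write_fasta(sequences: dict[str, str], haplotypes, outdir: str | Path,
                width: int = 60) -> dict[str, Path]:
    """One wrapped FASTA per haplotype (chromosomes prefixed ``{hap}_``)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for hap in haplotypes:
        recs = [
            SeqRecord(Seq(s), id=c, description="")
            for c, s in sequences.items()
            if c.startswith(f"{hap}_")
        ]
        path = outdir / f"{hap}.fasta"
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(recs)
        paths[hap] = path
    return paths


# --------------------------------------------------------------------------
# methylation track generation
# --------------------------------------------------------------------------


def place_truth_cdrs(truth: TruthTables, config: SimConfig,
                     seed: int | None = None) -> pd.DataFrame:
    """Draw one truth CDR per centromeric HOR array.

    CDR length = slope * array_length + Gaussian noise, clipped to
    [cdr_min_bp, 0.9 * array_length], placed uniformly inside the array.
    Stored on ``truth.cdrs`` and returned.
    """
    seed = config.seed if seed is None else seed
    rng = child_rng(seed, _OFF_METH + 7)
    mcfg = config.methylation
    rows = []
    arrays = truth.arrays
    if not arrays.empty:
        cen = arrays[arrays["cls"] == "centromeric_hor"]
        for aid, (_, arr) in enumerate(cen.iterrows()):
            alen = int(arr["end"] - arr["start"])
            clen = mcfg.cdr_slope * alen + rng.normal(0.0, mcfg.cdr_noise_sd_bp)
            clen = int(np.clip(clen, mcfg.cdr_min_bp, 0.9 * alen))
            off = int(rng.integers(0, alen - clen + 1))
            rows.append(dict(chrom=arr["chrom"], start=int(arr["start"]) + off,
                             end=int(arr["start"]) + off + clen,
                             haplotype=arr["haplotype"], array_id=aid,
                             array_length=alen))
    truth.cdrs = pd.DataFrame(
        rows, columns=_IV_COLS + ["haplotype", "array_id", "array_length"]
    )
    return truth.cdrs


def generate_methylation(sequences: dict[str, str], truth: TruthTables,
                         config: SimConfig, seed: int | None = None):
    """Per-CpG methylation track over the generated sequence.

    Fractions are Normal(background) clipped to [0, 1] everywhere except
    inside truth CDRs and truth spacer intervals, where the configured low
    means apply. If ``truth.cdrs`` is empty it is populated first via
    :func:`place_truth_cdrs`. Returns a :class:`heterokit.methdip.MethylationTrack`.
    """
    from .methdip import MethylationTrack

    seed = config.seed if seed is None else seed
    rng = child_rng(seed, _OFF_METH)
    mcfg = config.methylation
    if truth.cdrs.empty and not truth.arrays.empty:
        place_truth_cdrs(truth, config, seed)

    frames = []
    for chrom in sorted(sequences):
        arr = np.frombuffer(sequences[chrom].encode(), dtype=np.uint8)
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        if cg.size == 0:
            warnings.warn(f"no CpG sites on {chrom}; emitting empty track")
            continue
        frac = rng.normal(mcfg.background_mean, mcfg.background_sd, size=cg.size)
        for df, mean in ((truth.cdrs, mcfg.cdr_mean),
                         (truth.spacers, mcfg.spacer_pocket_mean)):
            if df is None or df.empty:
                continue
            for _, iv in df[df["chrom"] == chrom].iterrows():
                m = (cg >= iv["start"]) & (cg < iv["end"])
                frac[m] = rng.normal(mean, mcfg.background_sd, size=int(m.sum()))
        frac = np.clip(frac, 0.0, 1.0)
        cov = np.maximum(1, rng.poisson(mcfg.coverage_mean, size=cg.size))
        frames.append(pd.DataFrame(dict(
            chrom=chrom, start=cg, end=cg + 1, coverage=cov, fraction=frac
        )))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["chrom", "start", "end", "coverage", "fraction"])
    return MethylationTrack(df)


# --------------------------------------------------------------------------
# inversion simulation on a species tree
# --------------------------------------------------------------------------


def simulate_inversions_on_tree(tree, config: SimConfig, seed: int | None = None):
    """Evolve inversion presence/absence characters on a rooted, dated tree.

    Each event is placed on one branch chosen with probability proportional
    to branch length (or on two branches for the configured recurrent
    fraction); a leaf carries the inverted state iff an odd number of event
    branches lie on its root path. Returns ``(genotypes, truth)`` where
    ``genotypes`` has one row per event with a reference interval and one
    inv/ref column per leaf, and ``truth`` records the branch(es) of origin.

    ``tree`` is a :class:`heterokit.invphylo.SpeciesTree` with branch lengths
    in Ma.
    """
    seed = config.seed if seed is None else seed
    rng = child_rng(seed, _OFF_INV)
    icfg = config.inversion

    branches = [b for b in tree.branches() if b.length > 0]
    if not branches:
        raise ValueError("tree has no branches of positive length")
    lengths = np.array([b.length for b in branches])
    total = lengths.sum()
    if total <= 0:
        raise ValueError("zero-length tree")

    if icfg.n_events is not None:
        n_events = int(icfg.n_events)
    else:
        n_events = int(rng.poisson(icfg.rate_per_ma * total))

    leaves = tree.leaf_names()
    chrom_names = [f"chr{i + 1}" for i in range(max(1, config.n_chromosomes))]
    geno_rows, truth_rows = [], []
    for ev in range(n_events):
        i = int(rng.choice(len(branches), p=lengths / total))
        ev_branches = [branches[i]]
        recurrent = rng.random() < icfg.recurrent_fraction
        if recurrent and len(branches) > 1:
            j = i
            while j == i:
                j = int(rng.choice(len(branches), p=lengths / total))
            ev_branches.append(branches[j])
        present: set[str] = set()
        for b in ev_branches:
            present ^= set(b.clade)
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        inv_len = int(rng.integers(icfg.min_len_bp, icfg.max_len_bp))
        inv_len = min(inv_len, config.chrom_length_bp - 1)
        start = int(rng.integers(0, config.chrom_length_bp - inv_len))
        row = dict(event=f"inv{ev}", chrom=chrom, start=start, end=start + inv_len)
        for leaf in leaves:
            row[leaf] = "inverted" if leaf in present else "reference"
        geno_rows.append(row)
        truth_rows.append(dict(
            event=f"inv{ev}",
            branches=",".join(b.branch_id for b in ev_branches),
            recurrent=len(ev_branches) > 1,
        ))
    cols = ["event", "chrom", "start", "end"] + list(leaves)
    genotypes = pd.DataFrame(geno_rows, columns=cols)
    truth_df = pd.DataFrame(truth_rows, columns=["event", "branches", "recurrent"])
    return genotypes, truth_df


def write_config(config: SimConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2))


__all__ = [
    "SimConfig", "TelomereConfig", "CentromereConfig", "CapConfig",
    "RdnaConfig", "GapConfig", "MethylationConfig", "InversionConfig",
    "TruthTables", "ChromosomeTooShortError",
    "generate_assembly", "generate_methylation", "place_truth_cdrs",
    "simulate_inversions_on_tree", "write_fasta", "write_config", "revcomp",
]
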