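"""End-to-end pipeline driver and summary-table reporting.

``run_pipeline`` simulates a diploid genome (or starts from provided inputs),
runs the analysis stages (qc, arrays, cdr, caps, rdna, inversions) and writes
every output file plus a JSON manifest with SHA-256 checksums, so that two
runs with the same config and seed are byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import asmqc, capstruct, invphylo, methdip, rdnanor, satarch, synthio

log = logging.getLogger("heterokit")

CONFIG_SCHEMA_VERSION = 1
ALL_STAGES = ("qc", "arrays", "cdr", "caps", "rdna", "inversions")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 from the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed or lacks its inputs (exit code 3)."""


@dataclass
class PipelineConfig:
    outdir: str = "heterokit_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: synthio.SimConfig = field(default_factory=synthio.SimConfig)
    # analysis parameters (documented defaults of the respective modules)
    telomere_min_run_bp: int = 2_000
    telomere_max_offset_bp: int = 10_000
    gap_min_run_n: int = 10
    merge_max_gap_bp: int = 50_000  # above the spacer scale: caps stay whole
    min_array_bp: int = 10_000
    end_window_bp: int = 500_000
    cdr_window_bp: int = 5_000
    cdr_step_bp: int = 1_000
    cdr_drop: float = 0.20
    rdna_unit_bp: int = 45_000
    n_perm: int = 1_000

    _KNOWN = None  # filled below

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        version = d.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version}")
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in d:
            d["sim"] = synthio.SimConfig.from_dict(d["sim"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
            bad = set(d["stages"]) - set(ALL_STAGES)
            if bad:
                raise ConfigError(f"unknown stages: {sorted(bad)}")
        try:
            return cls(**d)
        except TypeError as err:
            raise ConfigError(str(err)) from err

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as err:
            raise ConfigError(f"cannot read config {path}: {err}") from err
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, analyse and report; returns the manifest dict.

    The manifest lists every output file with its checksum, the stages run,
    the seed and headline statistics per stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    log.info("pipeline start: stages=%s seed=%d outdir=%s",
             ",".join(config.stages), seed, outdir)

    files: dict[str, str] = {}
    stats: dict[str, dict] = {}

    def record(name: str, path: Path):
        files[name] = _sha256(path)

    # --- simulate -----------------------------------------------------------
    sim = config.sim
    sequences, truth = synthio.generate_assembly(sim, seed)
    synthio.place_truth_cdrs(truth, sim, seed)
    track = synthio.generate_methylation(sequences, truth, sim, seed)
    fasta_paths = synthio.write_fasta(sequences, sim.haplotypes, outdir)
    for hap, p in fasta_paths.items():
        record(f"fasta_{hap}", p)
    for name, p in truth.write(outdir / "truth").items():
        record(f"truth_{name}", p)
    meth_path = outdir / "methylation.tsv"
    track.to_tsv(meth_path)
    record("methylation", meth_path)
    log.info("simulated %d chromosomes, seed=%d", len(sequences), seed)

    annotations = truth.satellites
    chrom_lengths = truth.chrom_lengths
    arrays = None

    def need_arrays():
        nonlocal arrays
        if arrays is None:
            merged = satarch.merge_to_arrays(
                annotations, config.merge_max_gap_bp, config.min_array_bp
            )
            arrays = satarch.classify_arrays(
                merged, chrom_lengths, config.end_window_bp
            )
        return arrays

    for stage in config.stages:
        try:
            if stage == "qc":
                records = []
                for chrom, seq in sorted(sequences.items()):
                    rdna_ivs = [
                        (int(r.start), int(r.end))
                        for r in truth.satellites.itertuples()
                        if r.chrom == chrom and satarch.is_rdna_family(r.family)
                    ] if not truth.satellites.empty else []
                    records.append(asmqc.ChromosomeRecord.from_sequence(
                        chrom, seq, min_run_n=config.gap_min_run_n,
                        rdna=rdna_ivs,
                        motif=sim.telomere.motif,
                        min_run_bp=config.telomere_min_run_bp,
                        max_offset_bp=config.telomere_max_offset_bp,
                    ))
                per_chrom = asmqc.per_chromosome_table(records)
                path = outdir / "qc_chromosomes.tsv"
                per_chrom.to_csv(path, sep="\t", index=False)
                record("qc_chromosomes", path)
                summaries = []
                for hap in sim.haplotypes:
                    hap_recs = [r for r in records if r.name.startswith(f"{hap}_")]
                    if hap_recs:
                        summaries.append(
                            asmqc.summarize_assembly(hap, hap_recs).as_row()
                        )
                table = pd.DataFrame(summaries)
                path = outdir / "qc_summary.tsv"
                table1_report(table).to_csv(path, sep="\t", index=False)
                record("qc_summary", path)
                stats["qc"] = dict(
                    n_chromosomes=len(records),
                    n_t2t=int((per_chrom["status"] == "t2t").sum()),
                    pct_t2t=asmqc.percent_t2t(
                        [int((per_chrom["status"] == "t2t").sum())],
                        [len(records)],
                    ),
                )
            elif stage == "arrays":
                arr = need_arrays()
                path = outdir / "arrays.bed"
                satarch.write_bed_arrays(arr, path)
                record("arrays", path)
                cen = arr[arr["cls"] == "centromeric_hor"]
                mini, normal = satarch.minicentromere_partition(
                    (cen["end"] - cen["start"]).tolist()
                ) if not cen.empty else ([], [])
                stats["arrays"] = dict(
                    n_arrays=len(arr), n_centromeric=len(cen),
                    n_mini=len(mini), n_normal=len(normal),
                )
            elif stage == "cdr":
                arr = need_arrays()
                if track.df.empty:
                    raise StageError("stage cdr: methylation track is empty")
                cdrs = methdip.call_cdrs_all(
                    track, arr, window_bp=config.cdr_window_bp,
                    step_bp=config.cdr_step_bp, drop=config.cdr_drop,
                )
                path = outdir / "cdrs.bed"
                cdrs.to_csv(path, sep="\t", index=False)
                record("cdrs", path)
                stats["cdr"] = dict(n_cdrs=len(cdrs))
                if cdrs["array_id"].nunique() >= 3:
                    pairs = [
                        (grp["array_length"].iloc[0],
                         int((grp["end"] - grp["start"]).sum()))
                        for _, grp in cdrs.groupby("array_id")
                    ]
                    if len({p[0] for p in pairs}) > 1:
                        slope, intercept, r2 = (
                            methdip.cdr_length_vs_array_regression(pairs)
                        )
                        stats["cdr"].update(slope=slope, r2=r2)
            elif stage == "caps":
                arr = need_arrays()
                caps = capstruct.detect_caps(
                    arr, chrom_lengths, config.end_window_bp
                )
                path = outdir / "caps.bed"
                caps.to_csv(path, sep="\t", index=False)
                record("caps", path)
                modal_lengths = []
                all_spacers = []
                for _, cap in caps.iterrows():
                    cs = capstruct.build_cap_structure(cap, annotations)
                    if cs.modal_spacer_bp is not None:
                        modal_lengths.append(cs.modal_spacer_bp)
                    if not cs.spacers.empty:
                        all_spacers.append(cs.spacers)
                if all_spacers:
                    spacers = pd.concat(all_spacers, ignore_index=True)
                    path = outdir / "spacers.bed"
                    spacers.to_csv(path, sep="\t", index=False)
                    record("spacers", path)
                    profile, pocket = capstruct.spacer_methylation_profile(
                        spacers, track
                    )
                    path = outdir / "spacer_profile.tsv"
                    profile.to_csv(path, sep="\t", index=False)
                    record("spacer_profile", path)
                    path = outdir / "pocket.json"
                    path.write_text(json.dumps(pocket, indent=2))
                    record("pocket", path)
                    stats["caps"] = dict(
                        n_caps=len(caps), n_spacers=len(spacers),
                        modal_spacer_bp=(min(modal_lengths) if modal_lengths else None),
                        pocket_statistic=pocket["statistic"],
                        pocket_p=pocket["p_value"],
                    )
                else:
                    stats["caps"] = dict(n_caps=len(caps), n_spacers=0)
            elif stage == "rdna":
                arr = need_arrays()
                table = rdnanor.rdna_table(arr, config.rdna_unit_bp)
                if not table.empty:
                    # chromosome names are {hap}_chr{i}
                    table["haplotype"] = [c.split("_")[0] for c in table["chrom"]]
                path = outdir / "rdna.tsv"
                table.to_csv(path, sep="\t", index=False)
                record("rdna", path)
                stats["rdna"] = dict(
                    n_arrays=len(table),
                    diploid_total=rdnanor.total_rdna(table, "diploid"),
                )
            elif stage == "inversions":
                tree = invphylo.default_ape_tree()
                genotypes, inv_truth = synthio.simulate_inversions_on_tree(
                    tree, sim, seed
                )
                path = outdir / "inversion_genotypes.tsv"
                genotypes.to_csv(path, sep="\t", index=False)
                record("inversion_genotypes", path)
                if genotypes.empty:
                    stats["inversions"] = dict(n_events=0)
                else:
                    assign = invphylo.assign_inversions(genotypes, tree)
                    path = outdir / "inversion_assignments.tsv"
                    assign.to_csv(path, sep="\t", index=False)
                    record("inversion_assignments", path)
                    stats["inversions"] = dict(
                        n_events=len(genotypes),
                        n_assigned=int(assign["assigned"].sum()),
                        n_recurrent=int(assign["recurrent"].sum()),
                    )
            else:  # pragma: no cover - guarded by config validation
                raise StageError(f"unknown stage {stage}")
        except StageError:
            raise
        except Exception as err:
            raise StageError(f"stage {stage} failed: {err}") from err
        log.info("stage %s done", stage)

    manifest = dict(
        schema_version=CONFIG_SCHEMA_VERSION,
        seed=seed,
        stages=list(config.stages),
        files=files,
        stats=stats,
    )
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("manifest written: %s (%d files)", path, len(files))
    return manifest


# --------------------------------------------------------------------------
# summary-table reporting
# --------------------------------------------------------------------------


def table1_report(per_assembly: pd.DataFrame) -> pd.DataFrame:
    """Append an Average row to a per-assembly summary table.

    Means are rounded half-up to the printed precision per column (2 dp for
    Gb/Mb columns, 1 dp for counts and QV); columns that are entirely
    missing stay missing.
    """
    if per_assembly.empty:
        raise ValueError("need at least one assembly row")
    avg = asmqc.summarize_assemblies(per_assembly)
    avg_row = {c: avg.get(c) for c in per_assembly.columns if c != "assembly"}
    avg_row["assembly"] = "Average"
    return pd.concat(
        [per_assembly, pd.DataFrame([avg_row])], ignore_index=True
    )


def format_table(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a summary table."""
    return table.to_string(index=False)


__all__ = [
    "PipelineConfig", "ConfigError", "StageError",
    "run_pipeline", "table1_report", "format_table",
    "ALL_STAGES", "CONFIG_SCHEMA_VERSION",
]
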