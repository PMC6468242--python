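"""End-to-end orchestration: simulate -> peakset -> enrichment -> dNSAF -> mass.

A single validated config drives every stage.  Inputs come either from
a ``synthetic`` block (the generator writes a complete data directory)
or from a ``data_dir`` laid out the same way:

    annotation.tsv              gene_id/chrom/tss/strand/biotype
    chrom_sizes.tsv             chrom/size
    peaks/<factor>_<rep>.narrowPeak
    coverage/total_reads.tsv    sample_id/factor/replicate_id/total_reads/path
    coverage/*.bedgraph
    proteomics/counts.tsv, proteomics/shared.tsv
    column/markers.tsv, column/gradient.tsv, column/sample.tsv

Each stage writes its tables under the output directory plus a JSON
summary; ``run_all`` collates the summaries into report.json.  The
report is a pure function of the config (and its seed), so reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import enrichment as enr
from . import hydrodynamics as hydro
from . import peakset as pks
from . import proteomics as prot
from . import synthetic as syn

logger = logging.getLogger("adacomplex")


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "adacomplex_out"
    data_dir: str | None = None  # pre-existing inputs; None -> synthetic block
    synthetic: dict[str, Any] | None = None  # SyntheticConfig overrides
    # peakset stage
    factors: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(pks.DEFAULT_MIN_SUPPORT)
    )  # factor -> min_support
    primary_factor: str = pks.DEFAULT_PRIMARY
    cofactors: list[str] = dataclasses.field(
        default_factory=lambda: list(pks.DEFAULT_COFACTORS)
    )
    # enrichment stage
    pseudocount: float = enr.DEFAULT_PSEUDOCOUNT
    tss_max_dist: int = enr.DEFAULT_TSS_MAX_DIST
    flank: int = enr.DEFAULT_FLANK
    # dNSAF stage
    dnsaf_threshold: float = prot.DEFAULT_DNSAF_THRESHOLD
    sample_runs: list[str] = dataclasses.field(
        default_factory=lambda: ["fraction18", "fraction19"]
    )
    mock_run: str | None = "mock"
    # hydrodynamics stage
    vbar: float = hydro.DEFAULT_VBAR
    density: float = hydro.DEFAULT_DENSITY
    viscosity: float = hydro.DEFAULT_VISCOSITY
    calibration_method: str = "linear"
    void_volume: float = 7.4
    total_volume: float | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.synthetic is not None:
            syn_known = {f.name for f in dataclasses.fields(syn.SyntheticConfig)}
            syn_unknown = set(cfg.synthetic) - syn_known
            if syn_unknown:
                raise ConfigError(f"unknown synthetic keys: {sorted(syn_unknown)}")
        if cfg.data_dir is None and cfg.synthetic is None:
            raise ConfigError("config needs either data_dir or a synthetic block")
        if cfg.data_dir is not None and not Path(cfg.data_dir).is_dir():
            raise ConfigError(f"data_dir does not exist: {cfg.data_dir}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    syn_cfg = syn.SyntheticConfig(**(cfg.synthetic or {}))
    data_dir = out / "data"
    truth = syn.simulate_all(syn_cfg, data_dir)
    n_by_class: dict[str, int] = {}
    for l in truth.loci:
        n_by_class[l.locus_class] = n_by_class.get(l.locus_class, 0) + 1
    return {
        "seed": syn_cfg.seed,
        "data_dir": str(data_dir),
        "planted_loci": n_by_class,
        "planted_members": truth.member_proteins,
        "true_rs_nm": truth.true_rs,
        "true_s": truth.true_s,
    }


def _load_replicate_peaks(data: Path, factor: str) -> list[pks.ReplicatePeakSet]:
    files = sorted((data / "peaks").glob(f"{factor}_*.narrowPeak"))
    if not files:
        raise FileNotFoundError(f"no peak files for factor {factor} under {data}/peaks")
    return [
        pks.ReplicatePeakSet(factor=factor, replicate_id=f.stem.split("_", 1)[1],
                             peaks=pks.read_narrowpeak(f))
        for f in files
    ]


def stage_peakset(cfg: PipelineConfig, data: Path, out: Path) -> dict:
    reproducible = {}
    for factor, min_support in cfg.factors.items():
        reps = _load_replicate_peaks(data, factor)
        reproducible[factor] = pks.reproducible_peaks(reps, min_support)
        logger.info(
            "%s: %d reproducible peaks from %d replicates (min_support=%d)",
            factor, len(reproducible[factor]), len(reps), min_support,
        )
    loci = pks.build_reference_set(
        reproducible, primary=cfg.primary_factor, cofactors=cfg.cofactors
    )
    pks.write_bed(
        [dataclasses.replace(l.interval, name=l.locus_class) for l in loci],
        out / "reference_peaks.bed",
    )
    pks.write_reference_table(loci, out / "reference_support.tsv")
    counts: dict[str, int] = {}
    for l in loci:
        counts[l.locus_class] = counts.get(l.locus_class, 0) + 1
    primary, cof0 = cfg.primary_factor, cfg.cofactors[0]
    non_overlap = 1.0 - pks.overlap_fraction(reproducible[primary], reproducible[cof0])
    return {
        "n_reference_loci": len(loci),
        "loci_per_class": counts,
        f"fraction_{primary}_not_overlapping_{cof0}": round(non_overlap, 4),
    }


def _load_tracks(data: Path) -> tuple[dict[str, list[enr.CoverageTrack]], enr.CoverageTrack]:
    sizes = pd.read_csv(data / "chrom_sizes.tsv", sep="\t")
    chrom_sizes = dict(zip(sizes["chrom"], sizes["size"]))
    totals = pd.read_csv(data / "coverage" / "total_reads.tsv", sep="\t")
    by_factor: dict[str, list[enr.CoverageTrack]] = {}
    input_track = None
    for row in totals.itertuples(index=False):
        track = enr.read_bedgraph(
            data / row.path, chrom_sizes, float(row.total_reads),
            sample_id=row.sample_id, factor=row.factor, replicate_id=row.replicate_id,
        )
        if row.factor == "input":
            input_track = track
        else:
            by_factor.setdefault(row.factor, []).append(track)
    if input_track is None:
        raise FileNotFoundError("no input (total chromatin) track in total_reads.tsv")
    return by_factor, input_track


def stage_enrichment(cfg: PipelineConfig, data: Path, out: Path) -> dict:
    loci = _read_reference(out / "reference_support.tsv")
    by_factor, input_track = _load_tracks(data)
    annotation = enr.read_tss_table(data / "annotation.tsv")
    rows = []
    median_z: dict[str, dict[str, float]] = {}
    for factor, tracks in sorted(by_factor.items()):
        enrichments = enr.locus_enrichments(loci, tracks, input_track, cfg.pseudocount)
        for e in enrichments:
            rows.append(
                {
                    "chrom": e.locus.interval.chrom,
                    "start": e.locus.interval.start,
                    "end": e.locus.interval.end,
                    "class": e.locus.locus_class,
                    "factor": factor,
                    "mean_log2": round(e.mean_log2, 6),
                    "z": round(e.z, 6),
                }
            )
        for cls in (pks.CANONICAL, pks.ADA2B_ONLY):
            zs = [e.z for e in enrichments if e.locus.locus_class == cls]
            if zs:
                median_z.setdefault(cls, {})[factor] = round(float(pd.Series(zs).median()), 4)
    pd.DataFrame(rows).to_csv(out / "locus_enrichment.tsv", sep="\t", index=False)

    # TSS assignment and biotype composition of the primary-only loci
    ada_only = [l for l in loci if l.locus_class == pks.ADA2B_ONLY]
    assigned = []
    assign_rows = []
    for l in ada_only:
        t = enr.nearest_tss(l.interval, annotation, cfg.tss_max_dist)
        assign_rows.append(
            {
                "chrom": l.interval.chrom, "start": l.interval.start,
                "end": l.interval.end,
                "gene_id": t.gene_id if t else ".",
                "biotype": t.biotype if t else ".",
            }
        )
        if t is not None:
            assigned.append(t)
    pd.DataFrame(assign_rows).to_csv(out / "tss_assignment.tsv", sep="\t", index=False)
    unique_tss = sorted({t.gene_id: t for t in assigned}.values(), key=lambda t: t.gene_id)
    summary: dict[str, Any] = {
        "median_z_by_class": median_z,
        "n_ada2b_only_loci": len(ada_only),
        "n_unique_tss_within_1kb": len({t.gene_id for t in assigned}),
    }
    if assigned:
        summary["trna_fraction"] = round(enr.biotype_fraction(assigned, "tRNA"), 4)
        for factor, tracks in sorted(by_factor.items()):
            m = enr.tss_intensity_matrix(tracks, unique_tss, cfg.flank)
            m.to_frame().to_csv(out / f"intensity_{factor}.tsv", sep="\t")
    return summary


def _read_reference(path: Path) -> list[pks.ReferenceLocus]:
    df = pd.read_csv(path, sep="\t")
    factor_cols = [c for c in df.columns if c not in ("chrom", "start", "end", "class")]
    loci = []
    for _, r in df.iterrows():
        loci.append(
            pks.ReferenceLocus(
                interval=pks.GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])),
                support={f: bool(r[f]) for f in factor_cols},
                locus_class=r["class"],
            )
        )
    return loci


def stage_dnsaf(cfg: PipelineConfig, data: Path, out: Path) -> dict:
    shared = data / "proteomics" / "shared.tsv"
    rows = prot.read_spectral_counts(
        data / "proteomics" / "counts.tsv",
        shared if shared.exists() and shared.stat().st_size > 0 else None,
    )
    table = prot.build_dnsaf_table(rows)
    prot.write_dnsaf_table(table, out / "dnsaf.tsv")
    enriched = prot.enriched_proteins(
        table, cfg.sample_runs, cfg.dnsaf_threshold, cfg.mock_run
    )
    matrix = prot.abundance_matrix(table, table.runs, cfg.sample_runs)
    matrix.rename_axis("protein_id").to_csv(out / "abundance_matrix.tsv", sep="\t")
    return {
        "runs": table.runs,
        "threshold": cfg.dnsaf_threshold,
        "enriched_proteins": enriched,
    }


def stage_hydrodynamics(cfg: PipelineConfig, data: Path, out: Path) -> dict:
    markers = hydro.read_marker_table(data / "column" / "markers.tsv")
    gradient = hydro.read_gradient_table(data / "column" / "gradient.tsv")
    sample = pd.read_csv(data / "column" / "sample.tsv", sep="\t")
    calibration = hydro.calibrate_stokes(
        markers, cfg.void_volume, cfg.total_volume, cfg.calibration_method
    )
    results = []
    for r in sample.itertuples(index=False):
        rs = hydro.stokes_radius(float(r.elution_ml), calibration)
        s = hydro.sedimentation_from_gradient(float(r.peak_fraction), gradient)
        est = hydro.svedberg_mass(
            hydro.SvedbergInput(
                stokes_radius=rs, sedimentation=s,
                vbar=cfg.vbar, density=cfg.density, viscosity=cfg.viscosity,
            )
        )
        results.append(
            {
                "name": r.name, "stokes_radius_nm": round(rs, 3),
                "sedimentation_s": round(s, 3), "mass_kda": round(est.mass, 1),
            }
        )
    pd.DataFrame(results).to_csv(out / "mass_estimates.tsv", sep="\t", index=False)
    return {"calibration_method": calibration.method, "estimates": results}


# ---------------------------------------------------------------------------
# Orchestration


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order; return (and write) the collated report."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": _config_echo(cfg)}
    stage = "simulate"
    try:
        if cfg.synthetic is not None:
            report["simulate"] = stage_simulate(cfg, out)
            data = Path(report["simulate"]["data_dir"])
        else:
            data = Path(cfg.data_dir)  # validated in from_dict
        stage = "peakset"
        report["peakset"] = stage_peakset(cfg, data, out)
        stage = "enrichment"
        report["enrichment"] = stage_enrichment(cfg, data, out)
        stage = "dnsaf"
        report["dnsaf"] = stage_dnsaf(cfg, data, out)
        stage = "hydrodynamics"
        report["hydrodynamics"] = stage_hydrodynamics(cfg, data, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def _config_echo(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def demo_config(out_dir: str = "adacomplex_demo", seed: int = 0) -> PipelineConfig:
    """The bundled one-command synthetic demo configuration."""
    return PipelineConfig.from_dict(
        {"out_dir": out_dir, "synthetic": {"seed": seed}}
    )
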