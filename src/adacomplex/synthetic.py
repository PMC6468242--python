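"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the structure of the real study's inputs —
multi-factor, multi-replicate ChIP-seq peak calls with dropout and edge
jitter, Poisson read coverage with planted fold enrichment, MudPIT
spectral-count tables with shared peptide groups and a mock run, and a
gel-filtration marker table — while recording the planted truth so each
stage's recovery can be asserted.

Defaults are chosen as a realistic desk-scale miniature of the study:
a 600 kb two-chromosome genome carries 60 canonical SAGA loci, 20
Ada2b-only loci and 20 unbound control genes on a regular gene grid;
half the Ada2b-only loci sit at tRNA gene TSSs.  Three factors bind with
the study's replicate structure (4x Ada2b, 3x Spt3, 3x Sgf11).  The
proteomics tables plant a four-member complex (Ada2b, Gcn5, Ada3,
Sgf29) at 20x contaminant abundance, and the column tables plant a
complex at Rs = 7.8 nm sedimenting at 7.3 S with its gradient peak in
fraction 19.

Every sub-generator draws from its own seeded stream, so stages can be
regenerated independently and outputs are byte-identical under a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .enrichment import CoverageTrack, TSSRecord, write_bedgraph
from .hydrodynamics import FRACTION_VOLUME_ML
from .peakset import ADA2B_ONLY, CANONICAL, GenomicInterval, write_bed

UNBOUND = "unbound"

# sub-stream indices so each generator has an independent seeded RNG
_STREAM_ANNOTATION = 1
_STREAM_PEAKS = 2
_STREAM_COVERAGE = 3
_STREAM_PROTEOMICS = 4
_STREAM_COLUMN = 5


@dataclasses.dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with desk-scale defaults."""

    seed: int = 0
    chrom_sizes: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"chr2L": 300_000, "chr2R": 300_000}
    )
    # gene / locus layout
    gene_slot: int = 3_000  # bp of genome per gene
    n_genes: int = 200
    trna_fraction: float = 0.30
    n_canonical_loci: int = 60
    n_ada2b_only_loci: int = 20
    n_unbound_controls: int = 20
    ada2b_only_trna_fraction: float = 0.50
    locus_halfwidth: int = 150  # bp; the planted enriched window is TSS +/- this
    # peak simulation
    replicates: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"Ada2b": 4, "Spt3": 3, "Sgf11": 3}
    )
    peak_width_mean: float = 300.0
    peak_width_sd: float = 50.0
    peak_edge_jitter: int = 30  # bp, uniform on each edge
    replicate_dropout: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"Ada2b": 0.03, "Spt3": 0.03, "Sgf11": 0.03}
    )
    # coverage simulation
    background_rate: float = 0.5  # reads per bp per sample
    enrichment_fold: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=lambda: {
            CANONICAL: {"Ada2b": 8.0, "Spt3": 8.0, "Sgf11": 8.0},
            ADA2B_ONLY: {"Ada2b": 12.0, "Spt3": 1.0, "Sgf11": 1.0},
            UNBOUND: {"Ada2b": 1.0, "Spt3": 1.0, "Sgf11": 1.0},
        }
    )
    # proteomics simulation
    complex_members: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"Ada2b": 555, "Gcn5": 813, "Ada3": 507, "Sgf29": 295}
    )
    n_contaminants: int = 36
    member_abundance: float = 20.0  # relative to contaminant abundance 1
    spectra_per_run: int = 2_000
    n_shared_pairs: int = 4
    shared_fraction: float = 0.2  # of a paralog pair's spectra moved to a group
    sample_runs: tuple[str, str] = ("fraction18", "fraction19")
    mock_run: str = "mock"
    # column simulation
    marker_radii: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "thyroglobulin": 8.5,
            "apoferritin": 6.1,
            "aldolase": 4.8,
            "ovalbumin": 2.8,
            "carbonic_anhydrase": 2.1,
        }
    )
    void_volume: float = 7.4  # ml (dextran 2000)
    total_volume: float = 24.0  # ml
    column_intercept: float = 20.5  # ml; true model ve = intercept + slope * Rs
    column_slope: float = -1.5  # ml per nm
    elution_noise_sd: float = 0.05  # ml
    true_rs: float = 7.8  # nm, planted complex
    gradient_slope: float = 0.35  # S per fraction
    gradient_intercept: float = 0.65  # S
    gradient_fractions: tuple[float, ...] = (6.0, 10.0, 14.0, 18.0, 22.0)
    gradient_noise_sd: float = 0.05  # S
    true_peak_fraction: float = 19.0

    @property
    def true_s(self) -> float:
        return self.gradient_intercept + self.gradient_slope * self.true_peak_fraction

    @property
    def factors(self) -> list[str]:
        return list(self.replicates)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclasses.dataclass
class PlantedLocus:
    interval: GenomicInterval
    locus_class: str
    gene_id: str
    biotype: str


@dataclasses.dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery assertions."""

    loci: list[PlantedLocus]
    genes: list[TSSRecord]
    member_proteins: list[str]
    true_abundances: dict[str, float]
    true_rs: float
    true_s: float
    true_peak_fraction: float
    sample_elution_ml: float  # noiseless model elution of the planted complex

    def to_json(self) -> dict:
        return {
            "loci": [
                {
                    "chrom": l.interval.chrom,
                    "start": l.interval.start,
                    "end": l.interval.end,
                    "class": l.locus_class,
                    "gene_id": l.gene_id,
                    "biotype": l.biotype,
                }
                for l in self.loci
            ],
            "genes": [dataclasses.asdict(g) for g in self.genes],
            "member_proteins": self.member_proteins,
            "true_abundances": self.true_abundances,
            "true_rs": self.true_rs,
            "true_s": self.true_s,
            "true_peak_fraction": self.true_peak_fraction,
            "sample_elution_ml": self.sample_elution_ml,
        }


# ---------------------------------------------------------------------------
# Annotation and locus layout


def make_annotation(config: SyntheticConfig) -> list[TSSRecord]:
    """Lay out genes on a regular slot grid with an exact tRNA quota.

    Each gene occupies one ``gene_slot`` window with its TSS at the slot
    centre; strand is random; exactly round(trna_fraction * n_genes)
    genes are tRNA, the rest protein_coding, in seeded random positions.
    """
    rng = config.rng(_STREAM_ANNOTATION)
    slots: list[tuple[str, int]] = []
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        for pos in range(0, size - config.gene_slot + 1, config.gene_slot):
            slots.append((chrom, pos))
    if config.n_genes > len(slots):
        raise ValueError(
            f"genome too small: {config.n_genes} genes need {config.n_genes} "
            f"slots of {config.gene_slot} bp, only {len(slots)} available"
        )
    chosen = sorted(rng.choice(len(slots), size=config.n_genes, replace=False))
    n_trna = round(config.trna_fraction * config.n_genes)
    biotypes = np.array(["protein_coding"] * config.n_genes, dtype=object)
    biotypes[rng.choice(config.n_genes, size=n_trna, replace=False)] = "tRNA"
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = []
    for i, slot_idx in enumerate(chosen):
        chrom, pos = slots[slot_idx]
        tss = pos + config.gene_slot // 2
        genes.append(
            TSSRecord(
                gene_id=f"gene{i:04d}",
                chrom=chrom,
                position=tss,
                strand=str(strands[i]),
                biotype=str(biotypes[i]),
            )
        )
    return genes


def plant_loci(genes: list[TSSRecord], config: SyntheticConfig) -> SyntheticTruth:
    """Assign locus classes to gene TSSs.

    Canonical and unbound loci take protein-coding TSSs; Ada2b-only loci
    take a configured mix of tRNA and protein-coding TSSs (default half
    each, mirroring the observed tRNA bias of ADA-bound sites).
    """
    rng = config.rng(_STREAM_ANNOTATION).spawn(1)[0]
    trna = [g for g in genes if g.biotype == "tRNA"]
    coding = [g for g in genes if g.biotype == "protein_coding"]
    n_ada_trna = round(config.ada2b_only_trna_fraction * config.n_ada2b_only_loci)
    n_ada_coding = config.n_ada2b_only_loci - n_ada_trna
    n_coding_needed = n_ada_coding + config.n_canonical_loci + config.n_unbound_controls
    if n_ada_trna > len(trna) or n_coding_needed > len(coding):
        raise ValueError("not enough genes of the required biotypes to plant loci")
    trna_pick = list(rng.choice(len(trna), size=n_ada_trna, replace=False))
    coding_pick = list(rng.choice(len(coding), size=n_coding_needed, replace=False))
    ada_genes = [trna[i] for i in trna_pick] + [coding[i] for i in coding_pick[:n_ada_coding]]
    canon_genes = [
        coding[i]
        for i in coding_pick[n_ada_coding : n_ada_coding + config.n_canonical_loci]
    ]
    unbound_genes = [
        coding[i] for i in coding_pick[n_ada_coding + config.n_canonical_loci :]
    ]
    loci = []
    for cls, gene_list in (
        (CANONICAL, canon_genes),
        (ADA2B_ONLY, ada_genes),
        (UNBOUND, unbound_genes),
    ):
        for g in gene_list:
            iv = GenomicInterval(
                g.chrom,
                max(0, g.position - config.locus_halfwidth),
                g.position + config.locus_halfwidth,
            )
            loci.append(
                PlantedLocus(interval=iv, locus_class=cls, gene_id=g.gene_id, biotype=g.biotype)
            )
    loci.sort(key=lambda l: (l.interval.chrom, l.interval.start))
    return SyntheticTruth(
        loci=loci,
        genes=genes,
        member_proteins=sorted(config.complex_members),
        true_abundances={
            **{m: config.member_abundance for m in config.complex_members},
            **{f"contam{i:03d}": 1.0 for i in range(config.n_contaminants)},
        },
        true_rs=config.true_rs,
        true_s=config.true_s,
        true_peak_fraction=config.true_peak_fraction,
        sample_elution_ml=config.column_intercept + config.column_slope * config.true_rs,
    )


def write_annotation(genes: list[TSSRecord], out_dir: Path, gene_length: int = 1000) -> None:
    """Write the annotation as both GTF (1-based) and a 5-column TSV."""
    gtf = out_dir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start1, end1 = g.position + 1, g.position + gene_length
            else:
                start1, end1 = max(1, g.position + 1 - gene_length + 1), g.position + 1
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                "\t".join(
                    [g.chrom, "synthetic", "gene", str(start1), str(end1),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )
    with open(out_dir / "annotation.tsv", "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\tbiotype\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.position}\t{g.strand}\t{g.biotype}\n")


# ---------------------------------------------------------------------------
# Peak calls


def _factors_binding(cls: str, config: SyntheticConfig) -> list[str]:
    folds = config.enrichment_fold[cls]
    return [f for f in config.factors if folds.get(f, 1.0) > 1.0]


def simulate_replicate_peaks(
    truth: SyntheticTruth, config: SyntheticConfig
) -> dict[tuple[str, str], list[GenomicInterval]]:
    """Per factor-replicate peak calls with dropout and edge jitter.

    Every replicate of a binding factor observes each planted locus with
    probability 1 - dropout; an observed peak is centred on the locus
    with width ~ Normal(peak_width_mean, peak_width_sd) and each edge
    jittered uniformly by +/- peak_edge_jitter bp.
    """
    rng = config.rng(_STREAM_PEAKS)
    out: dict[tuple[str, str], list[GenomicInterval]] = {}
    for factor in config.factors:
        dropout = config.replicate_dropout[factor]
        for rep in range(1, config.replicates[factor] + 1):
            peaks = []
            for locus in truth.loci:
                if factor not in _factors_binding(locus.locus_class, config):
                    continue
                if rng.random() < dropout:
                    continue
                center = (locus.interval.start + locus.interval.end) // 2
                width = max(50, int(rng.normal(config.peak_width_mean, config.peak_width_sd)))
                start = center - width // 2 + int(
                    rng.integers(-config.peak_edge_jitter, config.peak_edge_jitter + 1)
                )
                end = center + width // 2 + int(
                    rng.integers(-config.peak_edge_jitter, config.peak_edge_jitter + 1)
                )
                start = max(0, start)
                end = max(start + 1, end)
                peaks.append(GenomicInterval(locus.interval.chrom, start, end))
            peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
            out[(factor, f"rep{rep}")] = peaks
    return out


# ---------------------------------------------------------------------------
# Coverage


def simulate_coverage(
    truth: SyntheticTruth, config: SyntheticConfig
) -> list[CoverageTrack]:
    """Poisson per-base coverage for every ChIP replicate plus one input.

    Background rate is uniform; inside a planted locus the rate is
    multiplied by the class/factor enrichment fold.  The input track has
    no planted enrichment.  ``total_reads`` is the realised read sum.
    """
    rng = config.rng(_STREAM_COVERAGE)
    tracks = []
    samples = [("input", "input", "rep1")]
    for factor in config.factors:
        for rep in range(1, config.replicates[factor] + 1):
            samples.append((f"{factor}_rep{rep}", factor, f"rep{rep}"))
    for sample_id, factor, rep in samples:
        bins = {}
        for chrom in sorted(config.chrom_sizes):
            rate = np.full(config.chrom_sizes[chrom], config.background_rate)
            if factor != "input":
                for locus in truth.loci:
                    if locus.interval.chrom != chrom:
                        continue
                    fold = config.enrichment_fold[locus.locus_class].get(factor, 1.0)
                    rate[locus.interval.start : locus.interval.end] *= fold
            bins[chrom] = rng.poisson(rate).astype(float)
        total = float(sum(a.sum() for a in bins.values()))
        tracks.append(
            CoverageTrack(
                sample_id=sample_id, factor=factor, replicate_id=rep,
                bins=bins, total_reads=total, bin_width=1,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Spectral counts


def simulate_spectral_counts(config: SyntheticConfig):
    """Multinomial spectral-count tables for sample and mock runs.

    Spectra are drawn with probability proportional to abundance x
    length.  The mock run draws from contaminants only.  For each of
    ``n_shared_pairs`` contaminant paralog pairs, a fixed fraction of
    the pair's spectra is moved into a shared peptide group.

    Returns (counts_rows, shared_rows) as lists of dicts matching the
    counts/shared TSV schemas.
    """
    rng = config.rng(_STREAM_PROTEOMICS)
    members = sorted(config.complex_members)
    lengths = dict(config.complex_members)
    contams = [f"contam{i:03d}" for i in range(config.n_contaminants)]
    for c in contams:
        lengths[c] = int(rng.integers(200, 1001))
    abundance = {**{m: config.member_abundance for m in members}, **{c: 1.0 for c in contams}}
    pair_ids = rng.choice(config.n_contaminants, size=2 * config.n_shared_pairs, replace=False)
    pairs = [
        (contams[pair_ids[2 * i]], contams[pair_ids[2 * i + 1]])
        for i in range(config.n_shared_pairs)
    ]
    counts_rows, shared_rows = [], []
    run_pools = {r: members + contams for r in config.sample_runs}
    run_pools[config.mock_run] = contams
    for run_id, pool in run_pools.items():
        w = np.array([abundance[p] * lengths[p] for p in pool], dtype=float)
        draws = rng.multinomial(config.spectra_per_run, w / w.sum())
        spc = dict(zip(pool, (int(x) for x in draws)))
        shared_here: dict[str, tuple[str, int]] = {}  # protein -> (group, sSpC)
        for gi, (a, b) in enumerate(pairs):
            if a not in spc or b not in spc:
                continue
            sspc = int(round(config.shared_fraction * (spc[a] + spc[b])))
            if sspc == 0:
                continue
            # remove the shared spectra proportionally from the pair
            take_a = min(spc[a], int(round(sspc * spc[a] / max(1, spc[a] + spc[b]))))
            take_b = min(spc[b], sspc - take_a)
            sspc = take_a + take_b
            if sspc == 0:
                continue
            spc[a] -= take_a
            spc[b] -= take_b
            gid = f"group{gi}"
            shared_here[a] = (gid, sspc)
            shared_here[b] = (gid, sspc)
        for p in pool:
            counts_rows.append(
                {"protein_id": p, "run_id": run_id, "length": lengths[p], "uSpC": spc[p]}
            )
            if p in shared_here:
                gid, sspc = shared_here[p]
                shared_rows.append(
                    {"group_id": gid, "protein_id": p, "run_id": run_id, "sSpC": sspc}
                )
    return counts_rows, shared_rows


# ---------------------------------------------------------------------------
# Gel filtration and gradient


def simulate_gel_filtration(truth: SyntheticTruth, config: SyntheticConfig):
    """Marker, gradient and sample tables from a monotone column model.

    Marker elution volumes follow ve = intercept + slope * Rs plus
    Gaussian noise; gradient marker s values follow the linear fraction
    model; the planted complex elutes at its model volume plus noise and
    peaks in the configured gradient fraction.

    Returns (markers, gradient, sample) as row-dict lists.
    """
    if config.column_slope >= 0:
        raise ValueError("column model must be monotone decreasing (slope < 0)")
    rng = config.rng(_STREAM_COLUMN)
    markers = []
    for name in sorted(config.marker_radii, key=lambda n: -config.marker_radii[n]):
        rs = config.marker_radii[name]
        ve = config.column_intercept + config.column_slope * rs + rng.normal(0, config.elution_noise_sd)
        if ve <= config.void_volume:
            raise ValueError(f"marker {name} would elute in the void volume")
        markers.append({"name": name, "stokes_radius_nm": rs, "elution_ml": round(ve, 4)})
    gradient = [
        {
            "fraction": f,
            "s": round(
                config.gradient_intercept + config.gradient_slope * f
                + rng.normal(0, config.gradient_noise_sd), 4,
            ),
        }
        for f in config.gradient_fractions
    ]
    sample_ve = truth.sample_elution_ml + rng.normal(0, config.elution_noise_sd)
    sample = [
        {
            "name": "ada_complex",
            "elution_ml": round(sample_ve, 4),
            "peak_fraction": config.true_peak_fraction,
        }
    ]
    return markers, gradient, sample


# ---------------------------------------------------------------------------
# Orchestration


def _write_tsv(rows: list[dict], path: Path) -> None:
    if not rows:
        path.write_text("")
        return
    cols = list(rows[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")


def simulate_all(config: SyntheticConfig, out_dir: str | Path) -> SyntheticTruth:
    """Generate every pipeline input under ``out_dir`` plus truth.json."""
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)
    (out / "proteomics").mkdir(exist_ok=True)
    (out / "column").mkdir(exist_ok=True)

    genes = make_annotation(config)
    truth = plant_loci(genes, config)
    write_annotation(genes, out)

    with open(out / "chrom_sizes.tsv", "w") as fh:
        fh.write("chrom\tsize\n")
        for c in sorted(config.chrom_sizes):
            fh.write(f"{c}\t{config.chrom_sizes[c]}\n")

    peaks = simulate_replicate_peaks(truth, config)
    for (factor, rep), ivs in peaks.items():
        write_bed(ivs, out / "peaks" / f"{factor}_{rep}.narrowPeak")

    tracks = simulate_coverage(truth, config)
    with open(out / "coverage" / "total_reads.tsv", "w") as fh:
        fh.write("sample_id\tfactor\treplicate_id\ttotal_reads\tpath\n")
        for t in tracks:
            fname = f"{t.sample_id}.bedgraph"
            write_bedgraph(t, out / "coverage" / fname)
            fh.write(
                f"{t.sample_id}\t{t.factor}\t{t.replicate_id}\t"
                f"{t.total_reads:.0f}\tcoverage/{fname}\n"
            )

    counts_rows, shared_rows = simulate_spectral_counts(config)
    _write_tsv(counts_rows, out / "proteomics" / "counts.tsv")
    _write_tsv(shared_rows, out / "proteomics" / "shared.tsv")

    markers, gradient, sample = simulate_gel_filtration(truth, config)
    _write_tsv(markers, out / "column" / "markers.tsv")
    _write_tsv(gradient, out / "column" / "gradient.tsv")
    _write_tsv(sample, out / "column" / "sample.tsv")

    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth
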