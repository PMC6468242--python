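# Methods

## Reference peak set and locus classification

Coordinates are 0-based half-open (BED/narrowPeak convention)
throughout; GTF input (1-based inclusive) is converted on read. Two
intervals *overlap* when they share at least one base — the weakest
consistent predicate and the common choice in peak-overlap work.
Duplicate identical peaks within a replicate are dropped on read.

Reproducibility is counted per peak: a peak (from any replicate of a
factor) is kept when peaks from at least `min_support` distinct
replicates overlap it, counting its own replicate; each replicate
contributes at most one unit of support. Kept peaks are merged
(union, with bookended intervals joined). Defaults: Ada2b requires
3 of 4 replicates, Spt3 and Sgf11 require 2 of 3; both the factor
names and the thresholds are configuration, so the stage generalises
beyond this factor trio.

Reference loci are the merged union of all factors' reproducible
peaks. A locus is supported by factor *f* when it overlaps any of *f*'s
*reproducible* peaks (not raw peaks — consistent with the filter that
defines the set). Classification over the three configured factors:
primary present with both co-factors absent → `ada2b_only`; all three
present → `canonical`; the remaining six support patterns → `other`.

## Enrichment, Z-scores, TSS assignment

RPM in a window is the binned read-count sum × 10⁶ / total mapped
reads. Locus enrichment is log₂((chip_rpm + c)/(input_rpm + c)) with
pseudocount c = 0.5 RPM (the zero-signal guard; the method is otherwise
undefined at empty loci), averaged over replicates. Z-scores use the
population (divide-by-N) standard deviation over all reference loci of
one factor; an all-equal population is an error, not a NaN.

Nearest-TSS distance is 0 when the TSS lies inside the locus, else the
distance to the nearer locus edge; assignments beyond 1 kb (default)
return none; ties break to the lexicographically smallest gene id so
results are order-independent. Biotype fractions are computed over
unique gene ids.

Intensity matrices average replicate tracks in RPM over TSS ± flank
(default 500 bp) windows. Windows are strand-oriented: column +k is
always k bases downstream of transcription, which for minus-strand
genes means the window is flipped (and shifted by one base so the
mapping is exact). Windows truncated at chromosome edges are
zero-padded and flagged rather than dropped.

## dNSAF

Shared-peptide groups carry a group-level shared count; each group's
spectra are distributed among its members proportionally to their
unique counts, or equally when no member has unique spectra (the only
split that is both neutral and conservation-preserving). Distribution
conserves total spectra exactly: Σ dSpC = Σ uSpC + Σ sSpC per run.
dNSAF divides by protein length and normalises to sum to one per run,
making values comparable across runs of different depth.

Enrichment calling uses the **mean** dNSAF across the chosen runs
(the two complex-containing gel-filtration fractions are averaged)
against the 0.035 threshold; the mock rule excludes any protein whose
mock dNSAF is at least its sample mean. Both the averaging and the
mock comparison are design choices where the upstream description is
loose; they are the most conservative readings that still recover the
planted complex.

## Hydrodynamics

Default calibration fits a least-squares line of Stokes radius against
elution volume over the markers; a Porath-style fit of Rs against
√(−ln K_av) (K_av = (Ve−V0)/(Vt−V0)) is available when the total column
volume is known. Predictions outside the marker elution range warn
about extrapolation. Gradient sedimentation values are a linear fit of
marker s against fraction number. Fractions convert to volumes at
0.5 ml per fraction with the peak at the fraction midpoint.

The Svedberg mass is M = 6πηN_A·Rs·s/(1 − v̄ρ), with Rs in cm, s in
seconds, returned in kDa. Default constants are water at 20 °C
(η = 0.01002 poise, ρ = 0.9982 g/cm³) and v̄ = 0.73 mL/g, a typical
value for globular protein complexes; all are overridable per call.
Optional input uncertainties propagate first-order (the mass is
linear in Rs, s and η, so those relative errors pass through
unchanged; the buoyancy term contributes ρ/(1−v̄ρ) and v̄/(1−v̄ρ)
sensitivities). v̄ρ ≥ 1 (a floating particle) is rejected.

## Synthetic study design

The generator is a desk-scale miniature of the real study, not a tuned
fixture; its defaults are fixed once:

- **Genome / loci:** two 300 kb chromosomes; 200 genes on a 3 kb slot
  grid (exact 30 % tRNA quota); 60 canonical, 20 Ada2b-only and 20
  unbound control loci planted at gene TSSs (±150 bp), with exactly
  half the Ada2b-only loci at tRNA TSSs, mirroring the observed tRNA
  bias of ADA-bound sites. The slot grid keeps loci ≥ 1 kb apart so
  nearest-TSS assignment is unambiguous.
- **Peaks:** width ~ Normal(300, 50) bp, edges jittered ± 30 bp,
  replicate dropout 0.03 per factor — strong, reproducible peaks, the
  regime the reproducibility thresholds presuppose.
- **Coverage:** uniform Poisson background at 0.5 reads/bp per sample
  (~300 k reads/sample); in-locus rates multiplied by the class/factor
  fold — canonical: 8× for all three factors; ada2b_only: 12× for
  Ada2b and 1× for Spt3/Sgf11 (Ada2b enrichment is reported *stronger*
  at Ada2b-only sites than at canonical ones, which is what makes its
  Z-distribution there positively shifted); the input track carries no
  planted signal.
- **Proteomics:** four members (Ada2b, Gcn5, Ada3, Sgf29 at realistic
  lengths) at 20× the abundance of 36 contaminants; 2000 spectra per
  run drawn multinomially ∝ abundance × length; the mock run draws
  from contaminants only; four contaminant paralog pairs share 20 % of
  their spectra through shared groups.
- **Column:** marker radii 8.5/6.1/4.8/2.8/2.1 nm, void volume 7.4 ml;
  true monotone model ve = 20.5 − 1.5·Rs ml with 0.05 ml Gaussian
  noise; the complex planted at Rs = 7.8 nm. Gradient model
  s = 0.65 + 0.35·fraction with 0.05 S noise, so the planted peak in
  fraction 19 corresponds to 7.3 S.

Each sub-generator draws from its own seeded stream, so outputs are
byte-identical under a fixed seed and stages can be regenerated
independently.

What the synthetic data does **not** emulate: read-level artefacts
(mappability, GC and fragment-length biases, duplicates), irregular
gene density, peak-shape asymmetry, spectral-count overdispersion
beyond multinomial sampling, and column non-linearity. Passing the
recovery tests therefore shows the *bookkeeping and statistics* are
correct under the stated model, not that the pipeline is robust to
every artefact of real data.

## Pipeline

`run_all` executes simulate (optional) → peakset → enrichment → dNSAF
→ hydrodynamics from one validated config (unknown keys rejected
before anything runs). Every stage writes its tables plus a JSON
summary; the collated `report.json` echoes the config and seed for
provenance, and report numbers are taken from the stage outputs
themselves, so the report cannot drift from what is on disk. A stage
failure aborts with the stage named in the error.

Problem sizes throughout (600 kb genome, 80 bound loci, 2000
spectra/run) were chosen as the smallest study at which all planted
effects are comfortably resolvable; the full-data analysis of the
deposited ChIP-seq (GEO GSE98865) and MudPIT (PXD011770) datasets is
an external, optional reproduction: its published counts (1650
canonical sites, 2382 unique Sgf11 sites, 267 Ada2b-only peaks, 189
TSSs, 42 % Ada2b/Spt3 non-overlap, 50 % tRNA) depend on aligner and
peak-caller versions and are not asserted by the test suite.

## Known limitations

- Reproducibility counting is peak-centric, not IDR; no blacklist
  filtering.
- bedGraph only for coverage (no BigWig I/O); 1 bp bins by default
  (configurable coarser bins trade resolution for speed/memory).
- The exact solvent constants and Rs-fitting method used for the
  published 239 ± 20 kDa figure live in supplementary material not
  reproduced here; the defaults documented above land inside the
  published band but are this package's own choices.
- Protein inference, FDR filtering and peptide-level modelling are out
  of scope; spectral-count tables are taken as given.
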