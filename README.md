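# secmx

Assembly-state analysis of multiplexed SEC co-fractionation proteomics.

In SEC co-fractionation mass spectrometry, native protein assemblies are
separated by size-exclusion chromatography into ~55 fractions before
digestion and quantification; with isobaric (TMT) labels, several fractions
share one LC-MS/MS run and each reporter channel maps back to one fraction
of one condition and replicate.  A protein that participates in several
assemblies elutes as several peaks — `secmx` treats **each elution peak as
an assembly state**, aligns states between two biological conditions, maps
phosphopeptide elution peaks onto them, and quantifies differential state
abundance and phosphorylation.  It is aimed at proteomics groups running
two-condition SEC-TMT (global and/or phospho-enriched) experiments, and at
method developers who need a fully simulated test bed with planted ground
truth.

## What it computes

Given peptide-level reporter tables, a TMT design, an MW calibration
standard and monomer masses, the pipeline:

1. filters to proteotypic, non-decoy peptides and normalizes reporters to
   their precursor (MS1) intensity;
2. corrects mix-level batch effects from the fractions shared by adjacent
   mixes (factor = mean over shared fractions of the median peptide ratio),
   normalizes conditions by their nonzero-median ratio, union-averages
   replicates, and smooths profiles with a zero-phase [¼, ½, ¼] filter;
3. detects elution peaks (prominence ≥ 5% of the profile maximum, apex
   separation ≥ 3 fractions, apex intensity ≥ 1000) and classifies each
   apex as *monomeric* or *complexed* against a log-linear MW calibration
   with a 1.5× monomer-mass boundary;
4. aligns peaks across conditions by enumerating missing-augmented
   *alignment paths* scored `1 / (var + 1)`, where missing samples
   contribute `threshold²` (default 3 fractions) to the variance, and
   greedily selects the best non-redundant paths — a partition of all peaks
   into assembly states;
5. maps phosphopeptide peaks to the nearest global state within 3
   fractions (the annotation adopts the global apex; many peptides may
   share one state);
6. computes per-state `log2(B/A)` peak-height fold changes, per-peptide
   phospho fold changes, and the 3×3 response-group grid (A–I) crossing
   both at a ±2-fold cutoff.

A synthetic-data module generates complete experiments — Gaussian assembly
states, TMT mixing schemes with or without overlapping fractions, batch
factors, log-normal noise, detection-floor censoring, missingness, phospho
subsets — with ground truth sufficient to score apex recovery, fold-change
error, classification and phospho mapping.

## Worked example

```python
from secmx import GeneratorConfig, score_recovery, simulate_experiment
from secmx.pipeline import run_pipeline

sim = simulate_experiment(GeneratorConfig(seed=3, n_proteins=100, noise_sigma=0.1))
res = run_pipeline(sim.records, sim.design, sim.standard, sim.monomer_masses)
```

Running `python examples/05_full_pipeline_differentials.py` (exactly the
code above plus printing) gives:

```
assembly states: 187 (187 mutual)
  monomeric 100, complexed 87
phospho annotations: 122 (122 mapped)
states beyond the 2-fold cutoff: 38
  P00001~s1: log2(HCT116/HEK293) = -1.06
  P00003~s1: log2(HCT116/HEK293) = +1.58
  P00005~s1: log2(HCT116/HEK293) = -1.32
response-group counts (peak level):
B    10
C     1
D     1
E    36
F     7
H     4
I     2
recovery vs planted truth: apex recall 1.000, fold-change RMSE 0.058 log2 units,
classification accuracy 1.000
```

187 assembly states were detected and aligned in both conditions; 100
elute at their monomer position, 87 earlier (complexed).  38 states change
more than 2-fold between the cell lines.  Of the phospho/global pairs, 36
sit in group E (unchanged in both) while 10 sit in group B (phosphorylation
up in HCT116 on an unchanged assembly state) — the pattern the response
grid is designed to isolate.  Against the planted truth, every state apex
was recovered within ±1 fraction and fold changes to 0.06 log2 units RMSE
at 10% multiplicative noise.

The other scripts in `examples/` walk through each capability separately
(simulation, batch correction, calibration + peak calling, path alignment).
A thin CLI mirrors the stages (`secmx simulate|preprocess|calibrate|peaks|
align|quantify|report|run`); stages communicate only via TSV files, so runs
are restartable and inspectable.

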