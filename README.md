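# regdriver

An integrative regulatory-genomics analysis pipeline, exercisable end-to-end on
synthetic cohorts with planted ground truth. It covers:

- **Genomic intervals** (`regdriver.intervals`) — 0-based half-open interval
  engine with BED3/BED6 I/O, merging, intersection, promoter windows
  (TSS ± flank), and point-in-peak assignment.
- **Driver prioritization** (`regdriver.drivers`) — candidate amplified driver
  genes from linked copy-number / expression / essentiality tables:
  amplification-frequency filter (default ≥ 5 % of samples), per-gene
  CN–expression Pearson correlation (losses excluded by default), BH-FDR
  selection, essentiality ranking (lower score = rank 1), and a Fisher's-exact
  2×2 clinical association helper.
- **TF co-occupancy** (`regdriver.cooccupancy`) — common/unique classification
  of two peak sets with per-set co-occupied fractions, plus the differential
  peak filter (p < 1e-4 and fold change > 4, both strict).
- **Target signatures** (`regdriver.signatures`) — joint direct-target
  derivation from paired knockdown DE tables (FDR < 0.1, direction-concordant
  intersection) plus promoter co-binding by both factors (TSS ± 5 kb);
  (weighted) z-score-sum signature scoring and Pearson score correlation. A
  30-gene AR-signaling panel ships as packaged data.
- **Germline risk** (`regdriver.germline`) — LD proxy expansion (r² ≥ 0.5,
  inclusive, from dosages or precomputed LD tables), permutation
  fold-enrichment of risk SNPs in A-only/B-only/common binding regions, eQTL
  eGene mapping, PWM log-odds allele-affinity deltas (both strands, SNP-covering
  placements), exact binomial allelic-imbalance tests, and qPCR standard-curve
  quantification.
- **Survival** (`regdriver.survival`) — Kaplan–Meier, multi-group log-rank, and
  single-covariate Cox PH (Breslow/Efron ties, Newton–Raphson) implemented
  directly, with stratification schemes: median split, CN split, joint-high,
  genotype-within-expression-stratum, Gleason subgroups, and deep-loss
  exclusion.
- **Synthetic cohorts** (`regdriver.simulate`) — seeded generators for every
  input above with planted truth: CN–expression effect sizes, co-occupancy
  fractions, joint targets, LD blocks, SNP-in-peak enrichment, allelic ratios,
  motif-completing risk alleles, and proportional-hazards survival times.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the property- and simulation-based acceptance
criteria (oracle equivalence, planted-truth recovery, statistical calibration,
determinism); the other files are per-module unit and property tests.

## CLI

Every stage is a subcommand; `run-all` chains them in dependency order
(simulate → drivers → cooccupancy → signatures → germline → survival) and
writes per-stage TSVs, a log with in/out counts per filter, and a
`manifest.json` with a sha256 checksum for every output. Reruns with the same
config are byte-identical.

```sh
regdriver run-all --seed 7 --outdir out/
regdriver run-all --config config.yaml --stages simulate,cooccupancy
regdriver simulate --seed 7 --outdir out/
```

Example `config.yaml` (defaults shown; `sim` takes any
`regdriver.simulate.SimConfig` field):

```yaml
seed: 7
outdir: regdriver_out
freq_min: 0.05      # amplification-frequency threshold
fdr_corr: 0.05      # BH-FDR for CN-expression correlation
fdr_de: 0.1         # DE-gene FDR cutoff
promoter_flank: 5000
r2_min: 0.5         # LD proxy threshold (inclusive)
p_max: 1.0e-4       # differential-peak p cutoff (strict)
fc_min: 4.0         # differential-peak fold-change cutoff (strict)
n_perm: 1000        # enrichment permutations
sim:
  n_samples: 200
  cooccupancy_fraction: 0.5
```

Analysis stages read the simulated inputs from `<outdir>/simulate/` by
default; set paths under `inputs:` (e.g. `inputs: {peaks_a: my_a.bed}`) to run
on your own files.

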