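# mirshift

Linking large-scale miRNA upregulation to mRNA repression in
pressure-overload heart failure.

In the failing heart (TAC, transverse aortic constriction), more
transcripts go down than up while miRNAs rise on a large scale.
`mirshift` is the analysis pipeline for testing whether the second
observation explains the first, plus the downstream functional readouts
used to confirm individual targets.  It is written for computational
biologists who want each stage as a tested, reusable library function —
and for anyone who wants to validate such a pipeline against planted
ground truth before trusting it on real libraries.

The stages:

1. **Differential expression** (`mirshift.diffexpr`) — total-count
   normalization, FPKM, reference-miRNA normalization, equal-variance
   Student's t, and hard cut-off calling (mRNA: FPKM > 2, fold > 2.0,
   p < 0.05; miRNA: mean count > 100, fold > 1.70, p < 0.05).
2. **Seed-match scanning** (`mirshift.seedscan`) — canonical 8mer /
   7mer-m8 / 7mer-A1 / 6mer sites: a site is the reverse complement of
   miRNA seed positions 2–8 (or 2–7), optionally followed by an A
   opposite position 1; strongest-type precedence and greedy
   non-overlap per miRNA.
3. **Cumulative fold-change shift** (`mirshift.association`) — genes
   stratified by site count for the upregulated miRNAs; each stratum's
   log2FC distribution compared with the zero-site background by a
   two-sample Kolmogorov–Smirnov test,
   D = sup_x |F̂₁(x) − F̂₂(x)|, with median shifts per stratum.
4. **Site prioritization** (`mirshift.clip`) — Ago2 CLIP peak overlap
   (half-open intervals, ≥ 1 nt), seed-region conservation class
   (mean score > 0.6), deterministic ranking, and validation-enrichment
   tables.
5. **Functional readouts** (`mirshift.readouts`) — percent spliced in,
   PSI = 100·inclusion/(inclusion+exclusion), and calcium line-scan
   transient metrics: amplitude ΔF/F0, full duration at half-maximum
   (FDHM), and release synchrony as the coefficient of variation of
   per-position half-rise times.
6. **Synthetic data** (`mirshift.synthetic`) — generators for every
   input with planted ground truth: negative-binomial miRNA counts,
   rejection-sampled UTRs whose site counts are exact, per-site log2
   repression, Ago2 peaks, conservation tracks, and double-exponential
   calcium transients.

See `docs/methods.md` for the models, conventions, and their rationale.

## Worked example

Simulate a study-shaped dataset (quadruplicate miRNA and duplicate mRNA
libraries, 35% of miRNAs planted up around 2.5-fold, −0.2 log2 repression
per seed site) and run every stage:

```python
from mirshift import pipeline

cfg = pipeline.PipelineConfig(seed=1)
params = pipeline.SimulationParams()
truth = pipeline.simulate_inputs(params, cfg, base_dir="demo")
print(f"planted: {len(truth.planted_sites)} sites, "
      f"{len(truth.mirna_up_ids)} up-miRNAs")

summary = pipeline.run_pipeline(cfg, base_dir="demo")
print(f"miRNA DE: {summary['n_mirna_up']} up / {summary['n_mirna_down']} down")
print(f"mRNA DE:  {summary['n_mrna_up']} up / {summary['n_mrna_down']} down")
print(f"targeted: {100*summary['targeted_fraction']:.1f}% of genes "
      f"({100*summary['multi_fraction']:.1f}% with >=2 sites)")
for s in summary["strata"]:
    print(f"  sites {s['stratum']:>3}: n={s['n']:<3} D={s['ks_d']:.3f} "
          f"p={s['p_value']:.2e} median shift {s['median_shift']:+.3f}")
print(f"Ago2-overlapped sites: {summary['n_sites_ago2']}/{summary['n_sites']}")
```

Output:

```
planted: 949 sites, 52 up-miRNAs
miRNA DE: 49 up / 0 down
mRNA DE:  1 up / 2 down
targeted: 74.0% of genes (48.0% with >=2 sites)
  sites   1: n=104 D=0.337 p=1.53e-05 median shift -0.273
  sites 2-4: n=176 D=0.713 p=2.58e-29 median shift -0.745
  sites >=5: n=16  D=0.971 p=8.74e-12 median shift -1.134
Ago2-overlapped sites: 471/666
```

Reading it: the DE caller recovers 49 of the 52 planted up-miRNAs with no
false down calls; the repression signal strengthens monotonically with
site count — the KS distance D from the zero-site background grows from
0.34 to 0.97 and the median log2 fold-change shift from −0.27 to −1.13 as
genes carry more sites; and 471 of 666 predicted sites fall under a
simulated Ago2 peak (the generator covered 70% of true sites).  At
duplicate mRNA libraries and a 2-fold cut-off, few individual genes reach
significance (1 up / 2 down) even though the distribution-level shift is
unambiguous — which is exactly why the analysis is distributional.

The same stages are available as CLI subcommands
(`mirshift simulate | de-mirna | de-mrna | scan | associate | prioritize |
run-all | transients | psi`); `run-all` writes TSV tables and a
`summary.json` into the configured output directory.

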