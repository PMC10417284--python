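# cfmethsim

Simulation and analysis of **library-preparation bias in cell-free DNA
(cfDNA) methylome sequencing**.

cfDNA fragments carry the CpG methylation signature of their tissue of
origin, which can be recovered from bulk methylation sequencing by
deconvolution against a reference atlas. The measurement is distorted by
double-stranded library preparation (dsLP): jagged fragment ends (5′
single-stranded overhangs) are blunted by end repair, and the fill-in
reaction incorporates **unmethylated** cytosines, overwriting the biological
methylation state across the overhang region. Single-stranded preparation
(ssLP) needs no end repair and avoids the artifact. Urinary cfDNA is far
more jagged than plasma cfDNA, so the artifact is strongest there.

`cfmethsim` provides:

* a mechanistic **fragment simulator** (tissue mixtures, Bernoulli CpG
  methylation from a reference atlas, jagged ends, ssLP/dsLP preparation,
  enzymatic conversion with error, pUC19/lambda spike-ins) with full
  seed-level reproducibility and matched-seed library comparisons;
* the **analysis stack**: per-site methylation counts with read trimming
  and mate-overlap deduplication, global CpG and CHH methylation,
  within-read **M-bias** profiles with flatness/shape statistics, spike-in
  **conversion QC**, and the jagged-end index

  **JI-U = (M1 − M2) / M1 × 100**,

  where M1 is the mean CpG methylation in the first 30 bp of read 1 and M2
  in the 30 bp at the fragment's 3′ end read by the start of read 2;
* two **tissue-of-origin deconvolution** algorithms: site-based bounded
  least squares (0 ≤ x ≤ 1, Σx ≤ 1, solved by SLSQP) whose slack is the
  *undetermined* fraction, and fragment-level U/X/M classification with
  non-negative least squares over marker blocks;
* paired/unpaired t-tests with Bonferroni correction, a scenario runner for
  the fluid × library grid, and a `cfmethsim` command-line interface.

## Worked example

```python
import numpy as np
from cfmethsim import (
    SimConfig, JagSpec, make_toy_atlas, simulate_sample,
    extract_site_counts, global_methylation, jagged_index_u,
    sample_beta_from_counts, deconvolve_site,
)

site_atlas, block_atlas = make_toy_atlas(3, 10, high_beta=0.9, low_beta=0.1, seed=1)
mix = {"tissueA": 0.6, "tissueB": 0.3, "tissueC": 0.1}

for library in ("ssLP", "dsLP"):
    cfg = SimConfig(mixture=mix, n_fragments=20_000, library=library,
                    jag_prob=0.8, jag_length=JagSpec(mean=25.0), seed=1)
    ds = simulate_sample(cfg, site_atlas)          # urine-like jaggedness
    counts = extract_site_counts(ds.fragments)
    res = deconvolve_site(sample_beta_from_counts(counts, site_atlas), site_atlas)
    ji = jagged_index_u(ds.fragments)
    print(library, round(global_methylation(counts), 4),
          round(ji.ji_u, 1), {t: round(v, 3) for t, v in res.proportions.items()},
          round(res.undetermined, 3))
```

prints

```
ssLP 0.6281 -1.7 {'tissueA': 0.601, 'tissueB': 0.291, 'tissueC': 0.102} 0.006
dsLP 0.5633 43.4 {'tissueA': 0.54, 'tissueB': 0.261, 'tissueC': 0.09} 0.109
```

Both runs share the same latent fragments (same seed). The single-stranded
library recovers the simulated (0.6, 0.3, 0.1) mixture with an undetermined
fraction near zero and a JI-U near zero — jaggedness is invisible without
end repair. The end-repaired library shows depressed global methylation, a
large JI-U (the fill-in signal the index is built on), and an undetermined
fraction of ~11% absorbing the non-biological methylation patterns, while
the individual tissue proportions shrink roughly proportionally.

The same workflow is available from the shell:

```bash
cfmethsim run --out results/grid --replicates 3 --n-fragments 12000 --seed 0 --plots
cfmethsim simulate --config sim.yaml --atlas atlas.tsv --out sample.pat.tsv.gz
cfmethsim profile --pat sample.pat.tsv.gz --out-prefix sample --trim-r2 5
cfmethsim jagged --pat sample.pat.tsv.gz
```

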