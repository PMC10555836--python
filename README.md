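# optopattern

Spatial analysis of optogenetically induced gene expression around a
localized source.

When a morphogen such as SHH is switched on by light in a defined region of
a cell layer or organoid, the question is always the same: did the induction
reshape gene expression *around* the source, and over what length scale?
`optopattern` implements the computational stack for answering it:

* **Radial gene-set enrichment** in barcoded-spot spatial transcriptomics
  data: spots are partitioned into concentric annuli around the stimulated
  center, gene-set counts are normalized to annulus totals and to the mean
  over annuli, and significance is assessed against two permutation nulls —
  1,000 random centers and 1,000 random gene sets.
* **Distance-to-source statistics** in segmented single-molecule FISH data:
  cells positive for a transcript (≥ 5 molecules by default) are matched to
  the nearest source-positive cell and the per-gene distance distributions
  are summarized boxplot-style.
* **Expression QC and module scoring**: UMI / mitochondrial filtering,
  log-normalization, and per-cell module scores against expression-matched
  control genes, with curated dorsoventral neural-tube marker modules
  (floor plate → p3 / pMN / p0-2 / dp1-6 → roof plate) bundled.
* **An LED stimulation bytecode DSL**: decode/encode/simulate the 1 Hz
  four-instruction illumination programs (ON/OFF up to 127 s, REPEAT, HALT)
  and derive duty cycles and cumulative light doses.
* **A synthetic-data generator** producing spot lattices and segmented-cell
  tables with the statistical structure above (heterogeneous capture,
  exponential induction kernel, source poles and ring genes), so the whole
  pipeline is testable without any external download.

## The statistic at the core

For annulus $c_k$ (defined by breakpoints $r_1 < \dots < r_K$ around a
center, default 500, 775, 1050, 1325, 1600, 1825 with an open outer bin),
the gene-set fraction is

$$f_k = \frac{\sum_{g \in S}\sum_{s \in c_k} x_{gs}}{\sum_{g}\sum_{s \in c_k} x_{gs}},
\qquad \tilde f_k = \frac{f_k}{\mathrm{mean}_j f_j},$$

so $\tilde f_k$ averages to 1 and is insensitive to smooth capture-efficiency
variation. The one-sided exact permutation p-value for annulus $k$ is
$p_k = (1 + \#\{\tilde f_k^{null} \ge \tilde f_k\})/(N+1)$ with $N$ resampled
centers or gene sets (the plain exceedance fraction
$\#\{\tilde f_k^{null} > \tilde f_k\}/N$ is available via
`tie_policy="strict"` / `--paper-literal-p`).

## Worked example

```python
from optopattern import (DEFAULT_BREAKPOINTS, SyntheticConfig,
                         dual_permutation_test, generate_spot_dataset)

cfg = SyntheticConfig(rng_seed=1)          # 30x30 lattice, 3-fold induction
data = generate_spot_dataset(cfg)
profile, res_c, res_g = dual_permutation_test(
    data, cfg.induced_set, tuple(data.coords.mean(axis=0)),
    DEFAULT_BREAKPOINTS, n_permutations=1000, seed=1)
```

Output of `python examples/radial_enrichment.py`:

```
annulus   score   p(center)  p(geneset)
c1        1.697      0.0160     0.0010
c2        1.067      0.2997     0.1029
c3        0.912      0.7932     0.9700
...
c7        0.774      0.9760     0.9990
```

The innermost annulus carries 1.7× its expected share of induced-set
transcripts, and no random center (p = 0.016) or random gene set
(p = 0.001) reproduces it — the enrichment is tied to both the stimulated
location and the induced genes. The other scripts in `examples/` walk
through the stimulation DSL, the generators, source distances and module
scores the same way.

A thin CLI mirrors the library
(`optopattern {stim,simulate,enrich,distance,score,demo}`), e.g.

```bash
optopattern demo --seed 1 --out demo_run/
optopattern enrich --data demo_run/data.h5 --geneset shh_set \
    --center 1450,1450 --nperm 1000 --seed 1 --out report.json
```

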