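# alnseg

Bayesian change-point segmentation and classification of encoded
pairwise and three-way nucleotide alignments.

## The problem

Non-coding sequence — 3′ UTRs in particular — harbours short functional
elements (polyadenylation signals, miRNA seed matches, AU/CU/CA-rich
protein-binding elements) that leave only subtle footprints in sequence
composition and in conservation between closely related species.
Neither conservation nor GC content alone resolves them.  `alnseg`
encodes an alignment so that conservation, GC content and
transition/transversion structure are carried *jointly* in a single
symbol stream, then segments that stream with a Bayesian multiple
change-point model whose segments fall into K latent *segment classes*.
The number of segments and the number of distinguishable classes serve
as proxies for the functional complexity of the region analysed.

It is aimed at comparative genomicists working with alignments of
closely related species (the motivating system is *D. melanogaster* /
*D. simulans* / *D. yakuba* 3′ UTRs) who want class calls in BED form,
per-class FASTA for downstream motif discovery, and annotation
enrichment statistics.

## Model

An encoded sequence `x_1..x_n` over an alphabet of size A (8 symbols for
a pairwise alignment, 32 for a three-way alignment, 2 for binary
GC/conservation encodings) is cut by change-points into segments.  Each
segment `i`, assigned to class `c` with counts `n_i = (n_i1..n_iA)`, is
multinomial with parameter `θ_i ~ Dirichlet(α_c)`; `θ_i` is integrated
out, giving the Dirichlet-multinomial marginal

    P(segment i | c) = Γ(S_c)/Γ(S_c+N_i) · Π_a Γ(α_ca+n_ia)/Γ(α_ca),
    S_c = Σ_a α_ca.

Priors: each eligible inter-position boundary is present independently
with probability ρ (default 0.01); class labels are categorical with
weights `π ~ Dirichlet(1,...,1)`; each `α_ca ~ Gamma(1, 10)`.  Block
boundaries between concatenated alignment blocks (e.g. successive
3′ UTRs) are *fixed* change-points, present in every segmentation.  A
varying-dimensional MCMC sampler (collapsed birth/death/shift boundary
moves, exact Gibbs label and weight updates, random-walk Metropolis on
log α) simulates the posterior over segmentations.

Model dimension K is chosen two ways:

* **Procedure 1** — `DICV = −2·mean(logL) + 2·var(logL)` over the
  sampled log-likelihood; take the first local minimum of the K→DICV
  curve (ties and sub-noise dips resolve toward smaller K; models
  containing empty classes are stepped down).
* **Procedure 2** — the largest K for which every class is *stable*:
  its posterior conservation and GC series vary little and its mixture
  proportion is not negligible.

Segments are called per class as runs of ≥ 8 positions with posterior
class probability ≥ 0.5, exported as BED6, and tested for annotation
enrichment with an exact multinomial goodness-of-fit test (expected
counts proportional to class coverage; Bonferroni correction).

## Worked example

Segment a planted three-class sequence and recover its structure:

```python
import numpy as np
from alnseg import SegmentationModel, simulate as sim
from alnseg.selection import fit_k_range, dicv_curve, select_procedure1, select_by_stability

F = np.array([  # three pair8 symbol-frequency vectors, well separated
    [0.725, 0.010, 0.019, 0.010, 0.010, 0.145, 0.010, 0.039],
    [0.145, 0.010, 0.019, 0.010, 0.010, 0.725, 0.010, 0.039],
    [0.300, 0.060, 0.090, 0.060, 0.060, 0.250, 0.060, 0.120],
])
F = F / F.sum(axis=1, keepdims=True)
seq, truth = sim.multiclass(F, boundary_rate=0.01, length=30_000, seed=11)

traces = fit_k_range(seq, range(1, 6), seed=4, iterations=1200)
print(dicv_curve(traces).round(0))
print("Procedure 1:", select_procedure1(traces))
print("Procedure 2:", select_by_stability(traces))
print(traces[3].summary())
```

prints:

```
1    72810.0
2    72194.0
3    70276.0
4    70688.0
5    70601.0
Name: DICV, dtype: float64
Procedure 1: 3
Procedure 2: 3
Change-point segmentation results
================================================================
scheme: pair8       length:      30000  fixed boundaries: 0
classes (K): 3      iterations: 1200     burn-in: 600
seed: 1892783322   rho: 0.01
----------------------------------------------------------------
posterior mean change-points k: 302.56
posterior mean segment length L: 98.92
mean log-likelihood: -34838.75   DICV: 70276.07
----------------------------------------------------------------
   class     MP  conservation     GC  Ts/Tv
0      0 0.3638        0.8975 0.2152 1.4990
1      1 0.2985        0.5425 0.4984 0.8808
2      2 0.3377        0.9010 0.8084 1.3205
```

Both procedures recover the three planted classes; the class summary
table reproduces the planted conservation (0.899, 0.899, 0.550), GC
(0.211, 0.810, 0.490) and roughly equal mixture proportions to within
sampling error, and the posterior change-point count (303) matches the
281 planted boundaries plus prior-level extras.  The same workflow is
available from the shell:

```sh
alnseg simulate control --length 100000 --seed 1 --out ctrl.txt
alnseg segment --encoded ctrl.txt --scheme pair8 --k-min 1 --k-max 5 \
       --iterations 2000 --seed 1 --outdir traces/
alnseg select --traces traces/ --encoded ctrl.txt --scheme pair8 --out selection.yaml
```

For real data, `alnseg encode` reads MAF or aligned FASTA (optionally
sliced by BED/GFF3 intervals), `alnseg call` writes BED6 segment calls,
and `alnseg enrich` tests annotation enrichment.

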