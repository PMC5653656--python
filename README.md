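# cistrans

Classification of **cis- vs trans-acting regulatory divergence** from
allele-specific count data in F0 parents and their F1 hybrids.

When two inbred strains differ in transcription-factor occupancy, chromatin
state or gene expression at a locus, the change can be driven by *cis*-acting
variation (linked to the affected allele — in an F1 hybrid the two alleles
still differ, recapitulating the parental ratio) or by *trans*-acting
variation (the shared nuclear environment — the parents differ but the two F1
alleles, sitting in the same nucleus, do not). `cistrans` takes replicate
read counts at SNVs — per strain in the F0s, per allele in the F1s — and
assigns each site one of four classes (**conserved**, **cis**, **trans**,
**cis–trans**), then builds the downstream analyses on top: inheritance modes
of total occupancy, mechanisms at lineage-specific sites, distance decay of
cis-effect coordination, and cross-layer integration with chromatin marks and
gene expression. A synthetic-data generator provides ground truth for every
stage, so the whole pipeline is testable without external data.

Intended users: regulatory genomicists analyzing allele-specific ChIP-seq /
RNA-seq from reciprocal crosses, and methodologists who want a transparent,
fully simulated testbed for hybrid-based cis/trans inference.

## Model

For each site with F0 replicates *i* and F1 replicates *j*:

```
x_i ~ Po(mu_i),   mu_i ~ Ga(r, p_mu/(1-p_mu))      # strain A parent  -> NB
y_i ~ Po(nu_i),   nu_i ~ Ga(r, p_nu/(1-p_nu))      # strain B parent  -> NB
z_j ~ Bi(n_j, p_j),  p_j ~ Be(alpha, beta)         # F1 allele A      -> beta-binomial
```

with NB size `r` the reciprocal of a site-level dispersion estimated from the
F0 replicates. Writing `m = alpha/(alpha+beta)` for the F1 allelic mean, the
four hypotheses are constrained maximum-likelihood fits:

| class     | F0 constraint      | F1 constraint                                              | k |
|-----------|--------------------|------------------------------------------------------------|---|
| conserved | `p_mu = p_nu`      | `m = 1/2`                                                  | 2 |
| cis       | free               | `m = odds(p_mu) / (odds(p_mu) + odds(p_nu))`               | 3 |
| trans     | free               | `m = 1/2`                                                  | 3 |
| cis–trans | free               | free                                                       | 4 |

The winner minimizes `BIC = k ln N − 2 ln L̂` (N = replicate observations,
24 in the reference design); `ΔBIC` to the runner-up is the call confidence.
The same NB machinery drives the inheritance models (F1 total vs each
parent), the 2:1 test at lineage-specific sites (`2 y_j` vs the bound
parent), and the preprocessing follows the standard recipe: median-of-ratios
size factors, minimum-depth filters, 250 bp SNV thinning, per-peak
aggregation of histone-mark SNVs.

## Worked example

```bash
python examples/04_distance_decay.py
```

```
bin mid-distance (kb) vs Spearman rho:
     0.9 kb  rho = +0.941 (n = 216)
     1.9 kb  rho = +0.951 (n = 127)
     2.9 kb  rho = +0.950 (n = 60)
     ...
log-distance slope -0.1175 (90% CI -0.1908 .. -0.0443)
elbow of fitted curve: 12.6 kb
```

The script plants anchor sites whose allelic shift propagates to neighbors
attenuated by `exp(−d / 10 kb)`. The per-bin Spearman ρ of allelic
proportions decays with distance; the negative log-distance slope (CI
excluding zero) detects the decay and the elbow of the fitted curve — the
point of maximal perpendicular distance to the 1–50 kb chord — estimates the
genomic span of a shared cis effect (here ≈ 13 kb for a 10 kb truth). The
other examples cover classification (`01`), inheritance (`02`),
lineage-specific sites (`03`) and cross-layer integration (`05`).

There is also a thin CLI:

```bash
cistrans simulate --out sim/ --seed 17
cistrans run-all --counts sim/sites.tsv --seed 17 --out results/
```

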