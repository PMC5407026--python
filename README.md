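# allelicburst

Allele-specific transcriptional bursting kinetics from single-cell RNA-seq.

In diploid cells, transcription of each allele proceeds in bursts: the
promoter toggles between an OFF and an ON state with activation rate
`k_on` and deactivation rate `k_off`, and transcribes at rate `s` while ON
(all rates per mRNA lifetime; the decay rate is normalised to 1). The
stationary transcript count of one allele follows a Poisson-Beta mixture,

```
Y ~ Poisson(phi_c * s * p),     p ~ Beta(k_on, k_off),
```

with `phi_c` a per-cell size factor that modulates burst size. **Burst
frequency** is `k_on`; **burst size** is `s / k_off`. Given allele-specific
read counts at one heterozygous locus per gene across cells, `allelicburst`
estimates `(k_on, k_off, s)` separately per allele, corrected for the
technical noise of single-cell protocols, and asks whether the two alleles
of a gene burst with different kinetics, show mean allelic imbalance, or
fire non-independently (coordinated / repulsed bursting). It is aimed at
anyone studying *cis*-regulatory control of expression stochasticity with
allele-resolved scRNA-seq, and at method developers who need a fully
simulatable benchmark of the whole inference chain.

## What it does

1. **Classification.** An empirical-Bayes EM assigns each cell to one of
   four states per gene (neither allele observed, A only, B only, both),
   modelling stray reads on a silent allele via the per-base sequencing
   error `epsilon` and the allelic ratio of doubly-expressed cells via a
   symmetric Beta prior. Genes are then labelled silent, monoallelic, or
   biallelic; kinetics are attempted only for *biallelic bursty* genes
   (each allele expressed in 5–95% of assignable cells).
2. **Technical noise.** Spike-ins of known concentration identify the
   observation model `Q ~ Z * Poisson(alpha * Y^beta)` with dropout
   `Z ~ Bernoulli(expit(kappa + tau * log Y))`: Poisson log-linear
   regression for `(alpha, beta)` on non-zero counts, multi-start
   Nelder-Mead for `(kappa, tau)` on the zero-decomposing likelihood.
3. **Kinetics.** *Histogram repiling* deconvolves the observed count
   histogram: each observed level maps back to `Y = (Q/alpha)^(1/beta)`
   and is reweighted by the inverse detection probability. Cell-size
   normalised factorial moments `m1, m2, m3` of the repiled histogram then
   invert in closed form to `(k_on, k_off, s)`; degenerate regimes
   (near-constitutive, near-silent) are flagged non-estimable rather than
   truncated. Standard errors come from a paired-cell bootstrap.
4. **Testing.** A pooled-resampling bootstrap tests equality of allelic
   burst frequency and burst size; an exact binomial test measures mean
   allelic imbalance; a chi-square on the classification table tests
   independence of the two alleles' ON states, with a coordinated /
   repulsed direction call; each test family is Benjamini-Hochberg
   corrected across genes.

A bundled simulator generates data from exactly this generative hierarchy
(with ground truth attached), so every stage is testable without any
external dataset.

## Worked example

Simulate 200 cells, ten genes whose alleles share kinetics
(`k_on = k_off = 0.2`, `s = 50`) and two genes whose A allele bursts five
times more frequently (`k_on = 1.0`), with realistic dropout and
amplification noise estimated from simulated spike-ins:

```python
import numpy as np
from allelicburst import (
    KineticParams, run_scale, simulate_dataset, simulate_spike_ins,
)
from allelicburst.simulate import MOUSE_LIKE_NOISE

diff = KineticParams(k_on=1.0, k_off=0.2, s=50.0)
base = KineticParams(k_on=0.2, k_off=0.2, s=50.0)
sim = simulate_dataset(
    kinetics_a=[base] * 10 + [diff] * 2,
    kinetics_b=[base] * 12,
    n_cells=200, sigma_size=0.1, noise=MOUSE_LIKE_NOISE, seed=7,
)
spikes = simulate_spike_ins(
    MOUSE_LIKE_NOISE, np.array([2, 5, 10, 30, 100, 300, 1000, 3000.0]),
    n_cells=200, seed=8,
)
spikes.cells = sim.cells

results = run_scale(sim.counts(), spikes=spikes, cell_sizes=sim.phi,
                    n_boot=1000, random_state=1)
print(results[["gene", "category", "burst_frequency_A", "burst_frequency_B",
               "q_diff_frequency", "q_diff_size"]].round(3).to_string(index=False))
```

Output:

```
  gene         category  burst_frequency_A  burst_frequency_B  q_diff_frequency  q_diff_size
 gene0 biallelic_bursty              0.299              0.236             0.797        0.621
 gene1 biallelic_bursty              0.272              0.231             0.797        0.954
 gene2 biallelic_bursty              0.492              0.363             0.740        0.352
 gene3 biallelic_bursty              0.311              0.298             0.904        0.954
 gene4 biallelic_bursty              0.223              0.248             0.797        0.954
 gene5 biallelic_bursty              0.243              0.218             0.797        0.954
 gene6 biallelic_bursty              0.438              0.323             0.740        0.954
 gene7 biallelic_bursty              0.373              0.257             0.585        0.954
 gene8 biallelic_bursty              0.180              0.377             0.220        0.132
 gene9 biallelic_bursty              0.233              0.268             0.797        0.954
gene10 biallelic_bursty              2.516              0.257             0.012        0.352
gene11 biallelic_bursty              0.866              0.277             0.012        0.954
```

All twelve genes are classified biallelic bursty. The two genes simulated
with a five-fold allelic difference in activation rate — and only those —
are flagged by the differential burst-frequency test after FDR control
(`q_diff_frequency = 0.012`), while their burst-size test stays null, as
it should: the alternative changed `k_on`, not `s/k_off`. The estimated
burst frequencies for the null genes scatter around the true 0.2–0.3 after
noise correction.

The same pipeline is available from the shell:

```sh
allelicburst --allele-a A.tsv --allele-b B.tsv --spikeins spikes.tsv \
             --seed 1 --out-prefix out
```

which writes `out_results.tsv` (per-gene categories, kinetics, p/q values,
direction calls), `out_noise.tsv`, `out_eta.tsv` and `out_phi.tsv`.

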