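# chipbit2

A Bayesian ChIP-seq peak caller that detects **strong and weak protein
binding sites** at promoters, enhancers, or genome-wide, by jointly
modeling read intensities from a sample (immunoprecipitated) profile and
its matched input (control) profile. For peaks at promoters it
simultaneously predicts the target gene.

## Who this is for

ChIP-seq analysts who need more than the strong, sharp peaks that
count-threshold callers report. Weakly bound sites — partner transcription
factors, many histone marks — sit only modestly above the amplified
background DNA and are easily discarded, yet they carry real regulatory
signal. Pooling strong and weak sites in **one global bound component**
while comparing each window against **its own local input level** is what
lets the weak sites surface.

## The model

Candidate regions (promoter intervals, enhancer intervals, or genome-wide
runs of read-bearing windows, each holding ≥ 2 sample reads) are tiled
with fixed-length windows. Window *w* of region *n* carries a
depth-normalized sample intensity *s*, an input intensity *r*, and a
signed distance *d* to the governing feature. Its binding status
*b* ∈ {0, 1} has the posterior

    P(b | s, d)  ∝  P(s | b) · P(d | b) · P(b)

with the signal mixture

    s | b=1  ~  N(μ₁, σ₁²)        (global bound component)
    s | b=0  ~  N(r,  σ₀²)        (background, centred on the window's input)

and, in promoter mode, the distance mixture

    d | b=1  ~  Exp(λ) on |d|     (binding decays toward the TSS)
    d | b=0  ~  U(−d_P/2, d_P/2)  (background uniform over the promoter)

In enhancer mode both distance components are uniform over the enhancer
interval, so the distance term cancels; genome-wide there is none. P(b)
is a fixed uniform prior. μ₁, σ₁², λ are estimated by hard-assignment EM
(5% relative-change stopping rule); σ₀² is fixed in advance from the
input profile, scaled by (1 + L_in/L_s) to account for counting noise in
both profiles. Consecutive windows with posterior above 0.9 are merged
into one peak, scored by the run's maximum posterior, and written as BED6.

Full details, parameter defaults, and design rationale: `docs/methods.md`.

## Worked example

The package bundles a simulator that writes a matched sample/input SAM
pair with planted peaks and full truth labels:

```python
from chipbit2.synthetic_data import SimConfig, simulate

config = SimConfig(genome=[("chr1", 2_000_000)], n_strong=40, n_weak=40,
                   sample_depth=200_000, input_depth=200_000, seed=11)
paths, truth = simulate(config, "demo")
```

Calling peaks genome-wide with 200 bp windows:

```console
$ chipbit2 wg --sample demo/sample.sam --input demo/input.sam \
      --out demo/peaks.bed -w 200
INFO chipbit2.pipeline: 10000 windows
INFO chipbit2.pipeline: EM iter 1: mu1=3550 sigma1_sq=9.121e+06 lambda=0.001 n_bound=325 max_rel_change=4.058
INFO chipbit2.pipeline: EM iter 2: mu1=4360 sigma1_sq=9.104e+06 lambda=0.001 n_bound=266 max_rel_change=0.2281
INFO chipbit2.pipeline: EM iter 3: mu1=4576 sigma1_sq=8.9e+06 lambda=0.001 n_bound=241 max_rel_change=0.04946
INFO chipbit2.pipeline: 88 peaks above posterior 0.90
88 peaks written to demo/peaks.bed (mode=wg, 1 candidate regions, EM converged in 3 iterations)

$ head -5 demo/peaks.bed
# chrom	start	end	name	score	strand
chr1	55600	56000	peak_1	1000	.
chr1	165000	165400	peak_2	1000	.
chr1	170400	170800	peak_3	1000	.
chr1	178200	178400	peak_4	997	.
```

The EM trace shows the bound-component mean μ₁ settling (intensities are
reads per 10 million, so μ₁ ≈ 4576 means ≈ 92 reads in a 200 bp window
against a ≈ 20-read background) and the relative parameter change dropping
below the 5% stopping rule in three iterations. The BED score column is
`round(1000 × posterior)`. Scoring these 88 calls against the simulator's
truth gives precision 0.886, recall 0.975, F1 0.929, with 95% of the
weak (2.5×) peaks recovered.

Promoter mode additionally needs a TSS annotation (`--tss demo/tss.tsv`,
tab-separated chrom/position/strand/gene; a GFF can be converted with
e.g. `awk '$3=="gene"' in.gff | awk -v OFS='\t' '{print $1, ($7=="+")?$4-1:$5-1, $7, $9}'`)
and writes the predicted target gene in the BED name column.

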