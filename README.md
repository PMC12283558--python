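# tradis-essentia

Gene-essentiality analysis for saturated transposon-insertion
(TraDIS/Tn-seq) libraries, plus the comparative layers that usually
follow such a screen.  Written for microbial genomicists who have a
mapped insertion-site table (or junction-tagged reads) and want
per-gene essentiality calls, essential-domain detection, cross-species
agreement over orthologs, and functional/phyletic profiles — all as a
Python library with a thin `tradis-essentia` command line.

## The statistic at the core

For each gene *g* the **insertion index** is

&nbsp;&nbsp;&nbsp;&nbsp;ii&#8342; = (unique insertion sites in *g*) / (length of *g* in bp).

In a saturated library (~1 unique insertion per 12 bp of tolerant
sequence) the distribution of ii is bimodal.  The near-zero mode
(essential genes) is fitted with an exponential distribution on the
section ii ≤ 0.006 and the right mode (non-essential genes) with a
gamma distribution on ii ≥ 0.03 — by conditional maximum likelihood,
since that section is left-truncated.  Each gene is scored by

&nbsp;&nbsp;&nbsp;&nbsp;llr(ii) = log₂[ f_exp(ii; λ) / f_gamma(ii; k, θ) ]

and called **essential** if llr > log₂(12) (the essential mode is ≥ 12
times more likely), **non-essential** if llr < −log₂(12), **unclear**
otherwise.  A 300 bp window sliding every 150 bp then re-inspects
non-essential and unclear genes: an insertion-free window flags a
candidate essential domain and promotes the gene.

Downstream, orthologs between species are 1:1 bidirectional best hits
(E-value ≤ 1e-5, query and subject coverage ≥ 70%, proteins with
within-proteome paralogs excluded), joined with per-species calls into
agreement tables; COG labels are counted per letter; and phyletic
presence/absence matrices are clustered by complete linkage on
Euclidean distances.  A synthetic-data generator emits every input the
pipeline consumes together with a ground-truth manifest, so the whole
chain is validated by recovery tests.  See `docs/methods.md` for the
full model description and `examples/` for one narrative script per
capability.

## Worked example

`examples/01_simulate_and_call.py` simulates a 650 kb genome with 500
genes (10% essential, insertion-free) and calls essentiality:

```
genome: 650,000 bp, 500 genes, 49,369 unique insertion sites (~1 per 13 bp)
fitted modes: exponential rate 4.93e+04, gamma shape 4.24, scale 0.0194 (generator truth: shape 5.0, scale 0.0167)
calls: {'essential': 52, 'non_essential': 448, 'unclear': 0} (2 promoted by the domain scan)
agreement with ground truth: 499/500 genes (99.8%)
```

The fitted gamma describes the non-essential insertion-index mode; the
huge exponential rate reflects an essential mode sitting at zero.  52
genes tolerated (almost) no insertions — the 50 planted essential
genes plus 2 genes carrying an insertion-free core that the sliding
window promoted — and 499 of 500 calls match the generator's truth.

The same analysis from the shell:

```sh
tradis-essentia simulate --out bundle --seed 42 --n-genes 500 --genome-length 650000
tradis-essentia call --gff bundle/annotation.gff3 --sites bundle/sites.tsv --out calls.tsv
tradis-essentia domains --gff bundle/annotation.gff3 --sites bundle/sites.tsv \
    --calls calls.tsv --out domain_report.tsv
```

or end to end from a YAML config with `tradis-essentia run --config run.yaml`.

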