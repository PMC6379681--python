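# topocleave

Single-nucleotide mapping of type II topoisomerase (DNA gyrase) cleavage
sites on a bacterial chromosome from strand-aware fragment-end profiles,
plus the downstream motif and enrichment analyses, and a simulator that
makes the whole pipeline testable without any external data.

The enzyme cuts both DNA strands leaving a 4-bp 5'-overhang. A
poison-trapped, strand-separated sequencing library therefore produces a
distinctive signature at each cleavage site: two "walls" of fragment
3'-ends at positions *i* and *i + 5*, flanking a 4-bp coverage gap. This
package detects those paired walls genome-wide and characterises the
sites.

## Modules

| module | what it does |
|---|---|
| `topocleave.ends_profiles` | SAM/FASTA input; per-position, per-orientation 3'/5'-end counts; WIG/bedGraph/TSV track output |
| `topocleave.gcs_caller` | quartet library scaling, mock smoothing + division, count-ratio (Audic–Claverie-type) significance test, paired-wall site calling, replicate merging |
| `topocleave.motif_kit` | 130-bp site window extraction, PPM/PWM/GC-track construction, bias masking, strand-max scanning, GC-periodicity estimation |
| `topocleave.region_stats` | binomial interval enrichment, genome-bin scan with exact binomial envelope, Fisher 2×2, exact conditional Poisson test, TU-compartment association, sign test on strength ratios |
| `topocleave.topo_sim` | synthetic genomes with planted (optionally motif-carrying) sites, full four-sample quartets with wall-pinned signal fragments and an ori–ter copy-number gradient, ground-truth tables |
| `topocleave.cli` | `topocleave` command with `profile / call / motif / scan / stats / simulate` subcommands; every run writes a manifest |

Each site call carries walls (*i*, *i + 5*), the canonical position
p0 = *i* + 1 (first base of the overhang), a strength (mean wall height
in normalized units) and per-wall p-values.

## CLI quick start

```sh
# simulate three replicate quartets with 6 planted sites
topocleave simulate --out run/sim --seed 4 --genome-length 30000 \
    --n-sites 6 --n-fragments 30000 --signal-fraction 0.5 --replicates 3

# call sites (each --quartet lists the four SAMs of one replicate:
# treated_ip,treated_mock,untreated_ip,untreated_mock)
topocleave call --fasta run/sim/genome.fasta --out run/calls \
    --quartet run/sim/rep0_treated_ip.sam,run/sim/rep0_treated_mock.sam,run/sim/rep0_untreated_ip.sam,run/sim/rep0_untreated_mock.sam \
    --quartet run/sim/rep1_treated_ip.sam,run/sim/rep1_treated_mock.sam,run/sim/rep1_untreated_ip.sam,run/sim/rep1_untreated_mock.sam \
    --quartet run/sim/rep2_treated_ip.sam,run/sim/rep2_treated_mock.sam,run/sim/rep2_untreated_ip.sam,run/sim/rep2_untreated_mock.sam

# build the combined motif and scan sequences with it
topocleave motif --fasta run/sim/genome.fasta --calls sim=run/calls/gcs.tsv --out run/motif
topocleave scan --ppm run/motif/ppm.tsv --fasta run/sim/genome.fasta --out run/scan.tsv

# enrichment statistics
topocleave stats --calls run/calls/gcs.tsv --genome-length 30000 --out run/stats
```

Key thresholds are exposed as flags with their analysis defaults:
significance level 0.0025, mock smoothing window 200 kb, top-732 sites
per condition for the combined motif, 130-bp window at offsets −63..66
with bias masking at offsets 0..3, 10 genome bins with a
0.0005/0.9995 binomial envelope.

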