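# deltadepth

Detect large mutagenesis-induced deletions (and duplications) by comparing
depth-of-coverage between wild-type and mutant whole-genome sequencing
samples.

Radiation mutagenesis (X-ray, gamma) routinely knocks out genes through
deletions of hundreds of kilobases to tens of megabases — far beyond the
reach of short-read structural-variant callers tuned for sub-kilobase
events, yet trivially visible as a drop in aligned read depth. In polyploid
crops such deletions are heritable (homoeologous copies buffer the loss), so
locating them quickly against a reference genome is the fastest route from a
mutant phenotype to a PCR marker for breeding. `deltadepth` implements the
windowed depth-comparison scan for that setting, a simulation framework that
measures its sensitivity and specificity, and a co-dominant three-primer
marker designer for genotyping progeny across a called deletion.

## Method

For each sample the per-base depth (from `samtools depth`) is averaged in
sliding windows (width *w*, step *s*; genome scans default to 3 Mbp / 1 Mbp)
and divided by the sample's genome-wide mean, so the genome average is 1.
The per-window difference

&nbsp;&nbsp;&nbsp;&nbsp;∆depth*ᵢ* = wt*ᵢ* − mut*ᵢ*

is ≈ +1 over a homozygous deletion in the mutant and ≈ 0 elsewhere.
Detection thresholds q95 and q99 are the 95th/99th nearest-rank percentiles
of an empirical null built by drawing window values from the two samples
independently and uniformly at random (4,000 unpaired draws) and recording
their differences; because the draw is cross-positional, shared structure
(repeat content, GC) widens the null and makes the thresholds conservative
for the position-matched ∆depth. Runs of consecutive windows above the
threshold merge into region calls; a simulated deletion counts as detected
when calls cover ≥ 80% of its span.

## Worked example

Simulate a wild-type/mutant pair with known deletions, then scan it:

```
$ deltadepth simulate --seed 5 --coverage 5 --n-chroms 1 \
    --chrom-length 30000000 --classes 50000,100000,150000 --outdir demo
simulated 1 chromosome(s), 3 deletion(s) -> demo

$ cat demo/truth.bed
chr1    10263799    10363799    100000
chr1    13474955    13524955    50000
chr1    15455203    15605203    150000

$ deltadepth scan --wt demo/wt.depth.tsv --mut demo/mut.depth.tsv \
    --lengths demo/lengths.tsv --w 50000 --s 5000 \
    --criterion q99 --reps 4000 --seed 7 --outdir demo/scan
4 call(s), 0 artifact(s) -> demo/scan

$ cat demo/scan/calls.bed
chr1    10245000    10380000    deletion       1.04
chr1    13460000    13545000    deletion       0.9579
chr1    15435000    15620000    deletion       1.077
chr1    21600000    21655000    duplication    -0.1346
```

Each implanted deletion is recovered as a call whose footprint covers it to
within one window and whose peak ∆depth ≈ 1 — the normalized signature of a
homozygous deletion (mutant depth ≈ 0 against wild-type ≈ genome mean).
The fourth call is a borderline lower-tail excursion flagged as a candidate
duplication (peak −0.13, just past the 1st-percentile line) — the kind of
marginal call the q99/q95 distinction and the depth tracks exist to
adjudicate. `demo/scan/thresholds.yaml` records the resampled thresholds
for the run, and `deltadepth plot` renders the depth and ∆depth tracks with
the q95/q99 lines.

Benchmark the detector itself (sensitivity/specificity over seeded
replicates):

```
$ deltadepth evaluate --replicates 20 --seed 1 --out eval.json
```

which reports, per criterion, mean ± SD sensitivity and specificity,
detection rate per deletion-length class, and the length distribution of
false positives.

Design a genotyping marker across a called deletion:

```
$ deltadepth marker --deletion chr3B:700000000-767800000 \
    --wt-target 712 --mut-target 414 --out marker.json
WT band [712], mutant band [414]
```

Wild-type homozygotes show the 712 bp in→post band, mutant homozygotes the
414 bp pre→post junction band, heterozygotes both.

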