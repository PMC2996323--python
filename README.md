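# gerppy

Evolutionary constraint detection from deep multiple sequence
alignments: per-position **rejected substitutions (RS)** scores by
maximum-likelihood rescaling of a neutral phylogenetic tree, followed
by **constrained element** prediction with exact dynamic-programming
p-values and shuffle-based false-positive control.

## The problem

Sequence under purifying selection accumulates fewer substitutions
than neutral DNA. Given a multiple alignment of a reference genome to
many other species and a neutral tree `T` whose branch lengths are
expected substitutions per neutral site, each alignment column can be
scored for a substitution *deficit*, and runs of high-scoring columns
can be aggregated into discrete constrained elements — candidate
functional sequence. This package is for comparative genomicists who
want both a per-base conservation track and ranked, p-valued element
calls from a MAF alignment.

## The method

**Position scores.** For a column with nucleotides `c_1..c_k` (gapped
species projected out of the tree; columns with fewer than 3 ungapped
species are not scored), the neutral rate is `n = Σ branch lengths`
of the projected tree, and a single rescaling factor `r` applied to
every branch is fit by maximum likelihood,

    L(r) = Pr(c_1, …, c_k | T_r),      r̂ = argmax L(r),  r ∈ [0, 3],

with the likelihood computed by Felsenstein's pruning recursion under
the HKY85 substitution model (rate matrix normalised to one expected
substitution per unit branch length). The score is

    RS = n − r̂·n = n (1 − r̂)  ∈  [−2n, +n],

positive for a substitution deficit (constraint), negative for a
surplus.

**Elements.** The null model of a region is the empirical
distribution `P(x)` of its own discretized RS scores (long runs of
shallow positions excluded, clearly constrained intervals removed by
a preliminary pass, a uniform prior added). A candidate element of
length `L` and summed score `S` gets the exact p-value
`Pr(Σ_{i=1..L} x_i ≥ S)` with `x_i ~ P` i.i.d., computed by iterated
convolution. Candidates start and end at boundaries of maximal runs
of non-negative scores; predictions are selected greedily in order of
increasing p-value, discarding overlaps, and selection stops when the
expected fraction of false predictions — estimated by rerunning the
full machinery on column-shuffled tracks — exceeds the chosen cutoff
(default 5% of predictions).

## Worked example

Simulate a 2 kb alignment on the default 16-leaf tree (total branch
length 5.8 substitutions/site) with two planted constrained blocks,
then score it and call elements:

```bash
gerppy simulate --columns 2000 --blocks 500:100:0.1,1200:60:0.2 --seed 4 \
    --out-maf sim.maf --out-tree sim.nwk
gerppy score sim.maf --tree sim.nwk --reference sp01 -o sim.rates
gerppy elems sim.rates -o elements.bed --fpr-report elements.fpr --seed 2
```

which prints

```
[gerppy] simulated 2000 columns -> sim.maf
[gerppy] scored 2000 of 2000 positions -> sim.rates
[gerppy] 2 elements, 162 bases (expected false: 0.00 elements) -> elements.bed
```

`sim.rates` has one `neutral_rate<TAB>rs_score` line per reference
position (zeros where fewer than 3 species aligned):

```
5.800000	3.295997
5.606667	3.598720
5.800000	-2.455883
```

and `elements.bed` contains the recovered elements (BED6 plus a
p-value column). Both planted blocks — `[500, 600)` at r = 0.1 and
`[1200, 1260)` at r = 0.2 — are found with near-exact boundaries:

```
chr1	500	601	elem_1	516.1	.	2.2e-150
chr1	1199	1260	elem_2	282.1	.	9.6e-69
```

The score column is the summed RS over the element (e.g. 516.1 ≈ 101
positions × 5.8 × (1 − 0.1)); the p-value is the probability of an
equally long, equally high-scoring segment under the region's null.
Every command writes a `*.config.json` sidecar recording the full
parameter set of the run.

The same pipeline is available as a library
(`simulate_alignment` / `score_alignment` / `detect_elements`), which
is the more convenient surface for simulation studies.

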