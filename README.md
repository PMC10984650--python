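# bgskit

Quantitative-genetic background selection: genome-wide B′ diversity-
reduction maps, composite-likelihood inference of the distribution of
fitness effects (DFE) and mutation rate, deleterious substitution-rate
prediction, and a built-in Wright–Fisher validation engine.

## The problem

Purifying selection against recurrent deleterious mutations in conserved
regions (coding sequence, conserved non-coding elements) perturbs linked
neutral variation, creating megabase-scale troughs in diversity along
chromosomes ("background selection").  Fitting a linked-selection model
to windowed diversity yields estimates of the deleterious mutation rate
and the strength of selection per annotation class.  Classic background-
selection (BGS) theory assumes deleterious mutations never fix, which
breaks down for weakly selected sites (2Ns ≲ 1) and biases inference
when annotations include weakly constrained sequence.

`bgskit` implements the Santiago–Caballero (SC16) quantitative-genetic
alternative: each conserved segment contributes additive fitness
variance V_A whose cumulative, autocorrelated effect on a linked neutral
site at recombination fraction r is V_A·Q², with
Q = 1/(κ + r(1−κ)).  The equilibrium V_A is coupled to the deleterious
substitution rate R through

    N_f = N·exp(−V_A·Q²/2),   R = 2·N_f·U·s / expm1(4·N_f·s),
    V_A = (U − 2R)·s,

solved jointly per segment (U = 2μL is the segment's diploid mutation
rate; s the heterozygous cost; R the per-lineage substitution rate with
neutral limit U/2).  Classic BGS is the R = 0 special case.  The package
is aimed at population geneticists who want to fit these models to
windowed diversity (their own count tables, BED annotations and
recombination maps) or to study the theory itself.

## Worked example

Solve the joint equilibrium for one 50 kb conserved segment
(`python examples/01_segment_equilibrium.py`):

```
         s      2Ns   B=Nf/N  R/neutral        V_A
   1.0e-06      0.0   1.0000     0.9980  1.999e-12
   3.2e-06      0.0   1.0000     0.9937  1.996e-11
   1.0e-05      0.0   0.9999     0.9801  1.987e-10
   3.2e-05      0.1   0.9993     0.9381  1.956e-09
   1.0e-04      0.2   0.9938     0.8144  1.856e-08
   3.2e-04      0.6   0.9632     0.5116  1.545e-07
   1.0e-03      2.0   0.9048     0.0997  9.003e-07
   3.2e-03      6.3   0.9175     0.0001  3.162e-06
   1.0e-02     20.0   0.9604     0.0000  1.000e-05
```

The reduction factor B = N_f/N is U-shaped in s with its minimum near
2Ns ≈ 1: nearly neutral mutations fix (R/neutral → 1) and contribute
little standing fitness variance, strongly deleterious ones never fix
and reach the classic mutation–selection-balance variance V_A = U·s.

The other examples build reduction maps (`02`), generate a synthetic
genome and re-estimate its parameters by composite likelihood (`03` —
the fit recovers π₀, μ and the mean selection coefficient to a few
percent under the binomial sampling model), validate the theory against
the Wright–Fisher simulator (`04`), and predict substitution rates and
implied divergence per feature class (`05`).

A thin CLI mirrors the pipeline stages for file-based workflows:

```
bgskit synth --seed 3 --out demo/          # synthetic genome in standard formats
bgskit bmap --features conserved:demo/segments.bed \
            --recmap demo/recmap.tsv --N 10000 --out demo/bmap
bgskit fit  --windows demo/windows.tsv --bmap demo/bmap \
            --starts 10 --seed 1 --loco --out demo/fit
bgskit predict-sub --fit demo/fit/fit.json --segments demo/segments.tsv \
            --mu 1.5e-8 --t-mya 6:12 --out demo/sub
```

Inputs are generic formats: BED feature tracks, HapMap-style
recombination maps, tab-separated per-site allele counts or per-window
pairwise-difference counts.  See `docs/methods.md` for the model,
estimation details, the simulators, and known limitations.

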