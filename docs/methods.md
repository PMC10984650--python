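# Methods

## Model

`bgskit` models background selection — the reduction of linked neutral
diversity caused by purifying selection against recurrent deleterious
mutations — in the quantitative-genetic framework of Santiago &
Caballero (SC16) rather than the classic mutation–selection-balance
(McVicker-style) framework.  The central object is the additive genetic
fitness variance `V_A` contributed by each conserved segment.  Heritable
fitness variance inflates the variance of stochastic allele-frequency
change at linked neutral sites; because the perturbation a neutral
lineage receives from its fitness background is autocorrelated across
generations until the background decays, the cumulative effect is
`V_A * Q^2`, with `Q = 1/(kappa + r(1-kappa))` the summed geometric
autocorrelation for a site at recombination fraction `r` from the
segment and per-generation background decay rate `kappa`.  The
fitness-effective population size at position `x` is

    B(x) = N_f(x)/N = exp( -1/2 * sum_g V_A,g * Q_g^2(s, r_{x,g}) )

summed over conserved segments `g`.

For each segment the equilibrium `V_A` is tied to the deleterious
substitution rate.  With diploid segment mutation rate `U = 2*mu*L`,
heterozygous cost `s` (homozygous `2s`, multiplicative across sites):

    N_f = N * exp(-V_A * Q^2 / 2)
    R   = 2*N_f*U*s / expm1(4*N_f*s)        (per-lineage substitutions/gen)
    V_A = (U - 2R) * s

`R` is Kimura's fixation probability under the fitness-effective size
times the `N*U` new mutations per generation; its neutral limit is
`U/2 = mu*L` (one genome copy's rate), which makes `V_A >= 0` hold for
every deleterious mutation — the printed rate convention in the source
theory elides this ploidy factor, and all package outputs report
substitution rates as fractions of the neutral rate, which is invariant
to the convention.  The system is solved per segment by damped
fixed-point iteration on `N_f` (the substituted right-hand side is
monotone, so the root is unique), with a guaranteed bracketed
root-finding fallback on `log N_f`; tolerance 1e-10 relative, 500
iterations max.

When `R` underflows (`2Ns >~ 20`), `V_A = U*s` exactly and the exponent
reduces to the classic background-selection term
`mu*L*s/(s + r(1-s))^2`: classic B is the strong-selection special case,
and the package computes both map families with the same machinery
(classic simply substitutes `V_A = U*s`), which makes
`B_classic <= B'` pointwise by construction.

### Within-segment decay

For a segment's own equilibrium the inflation factor is
`Q^2 = 2/[(1-Z)(2-(2-M)Z)]` with retention

    Z = 1 - s - M - 1/(2N)

where `M` is the segment's internal map length in Morgans.  The three
decay terms are selection, internal recombination, and pair coalescence:
the autocorrelation a lineage accumulates with its fitness background
cannot outlive the coalescent time scale, so the sum is truncated at
rate `1/(2N)` per generation.  The coalescent term is negligible
whenever `2Ns >> 1` and is required for the exact neutral limit
(`N_f -> N` as `s -> 0` for every `M`, including `M = 0`); its
weak-selection limit reproduces the neutral drift genic variance
`V_A -> 2NUs^2 = 4*N*mu*L*s^2`.  Forward simulation (below) confirms the
resulting predictions in the weak (`2Ns <= 0.2`) and strong
(`2Ns >= 20`) domains; in the nearly neutral band (`2Ns ~ 1-4`) the
standard model still under-predicts `B` by ~10-20%, a residual that our
calibration runs show grows with the interference strength rather than
matching any constant decay term — the same nearly-neutral
standard-model error reported for this model class, and the reason the
local-rescaling variant exists.

### Local rescaling

Selective interference means a segment experiences a local
fitness-effective size `B(x)*N` rather than `N`.  `local_rescale`
re-solves every segment with `N` replaced by `Bhat(x_g)*N` (the fitted
reduction averaged over a configurable window, default 1 kb, around the
segment midpoint) and rebuilds the map; `solve_rescaled_equilibrium`
does the single-segment self-consistent version (iterating
`B_{k+1} = N_f(B_k N)/(B_k N)` to a fixed point).  Rescaling leaves
strongly selected cells unchanged and mainly deepens/shallows the "U"
of `B(s)` around `2Ns ~ 1`; in the Wright-Fisher validation it is what
closes the nearly-neutral gap.  Because the rescaling input is itself a
fitted map, a refit on rescaled maps partially reuses the data; the CLI
logs this caveat and only one outer round is performed by default.

## Reduction maps

Maps are computed on a fixed step grid (default 10 kb, left edges) over
log10-spaced grids of selection coefficients (`1e-8..1e-2` by default,
`..1e-1` in the strong preset) and per-bp mutation rates
(`1e-11..1e-7`).  The flanking `Q` uses `kappa = s_j` (the classic
decay), so the solved `V_A` carries all corrections and the classic
equivalence at strong selection is exact; a position's recombination
fraction to a segment is the Haldane transform of the map distance to
the segment midpoint.  Segments longer than 1e-3 Morgans are split first
so the single-`r` approximation stays accurate.  Segments on other
chromosomes contribute through `r = 0.5` exactly (the unlinked
fitness-variance effect is real in this model class and is not
dropped); within a chromosome, per-segment contributions below a 1e-10
floor are truncated for speed (set `floor=0` for exact log-additivity).
Per-feature-class tensors are stored separately so inference can mix
classes; log B is stored in 32-bit floats.

## Composite-likelihood inference

Per-site biallelic allele counts are summarized into windows (default
1 Mb): a site with `n` observed chromosomes and `a` alternate copies
adds `a*(n-a)` differing and `n*(n-1)/2` total pairwise comparisons.
The observation model is `Y_b ~ Binomial(n_b, pi0 * Bbar(b; mu, W))`
with `W` an (n_s x K) matrix of per-class DFE simplices.  Mixing uses
the grid trick: `log B` is nearly proportional to the per-cell mutation
rate (the exponent carries `V_A ~ 2mL`), so the tensors are
interpolated **linearly in m** at `w_{j,k} = mu*W_{j,k}` — exact at the
grid nodes, within 1e-3 of a from-scratch map elsewhere on the toys we
checked, and decaying linearly to `log B = 0` below the smallest grid
column.  (Interpolating linearly in `log10 m` instead errs by tens of
percent mid-decade.)

The likelihood is maximized with a bounded derivative-free quadratic
trust-region method (scipy's COBYQA, the BOBYQA family), multi-started
from a seeded RNG with Dirichlet(1) DFE columns and log-uniform rate
draws, plus a longer polish run from the best start.  Direction-set
optimizers (Powell) stall far from the optimum on this surface.  `pi0`
is profiled out analytically by default — its binomial score is
monotone, so the profile optimum is unique and removes the dominant
likelihood ridge — which roughly halves the evaluations needed; joint
optimization is available (`profile_pi0=False`).  `mu` bounds default to
`[1e-10, 8e-8]` and a boundary-pinned estimate is flagged.

Model assessment: in-sample and leave-one-chromosome-out R^2 on
window-level `pi = Y/n` against `pi0*Bbar`, windows equally weighted
(config flag for count weighting); block-jackknife standard errors over
10 Mb blocks with the `(g-1)/g` scaling; predicted per-class
substitution-rate fractions `sum_j W_jk * mean_g R(s_j)/(U_g/2)` and the
implied divergence `d = fraction * mu * t/g` (defaults `mu = 1.5e-8`,
28-year generations, 6-12 Myr).

The explainable-variance ceiling `r2_coal` models per-window residual
variance as the Tajima/Wakeley variance of `pi` for `n` haplotypes:
a mutational term `(n+1)/(3(n-1)) * pi/sites` plus a genealogical term
`2(n^2+n+3)/(9n(n-1)) * pi^2 / K_b`, where `K_b` is the number of
quasi-independent genealogy blocks per window (window span divided by a
configurable span, default 10 kb).  In the large-`n`, single-block limit
this recovers the `~2/9 * pi^2` noise floor per genealogy.

## Ground-truth engines

**Wright-Fisher simulator.**  Discrete generations, `N` diploids, a
selected region of `L` bp with per-bp deleterious rate `mu`, cost `s`
per heterozygous copy and `2s` homozygous (multiplicative, truncated at
zero), Poisson crossovers at `r_bp` per bp, and interleaved neutral
reporter sites used to measure linked diversity.  Mutations live in
per-haplotype position-sorted lists (selected and neutral separately, so
the fitness pass only walks selected lists); parents are drawn by
rejection sampling against the maximum fitness; allele counts are
reconciled every few generations (a fixed mutation multiplies every
fitness by the same constant, so deferred removal is exact), at which
point equilibrium statistics are sampled: diversity at the neutral
reporters, selected fixations, and the genic variance
`sum_l 2 p_l (1-p_l) s^2`.  Defaults: 10N burn-in, 10N sampling,
`B_obs` = reporter diversity over `4*N*mu_neutral*L` (or over a paired
neutral control run).  The reporter density is capped at `2e-8`/bp so
measurement cost stays flat across deleterious-rate cells.  The
validation table compares `B_obs`, `R_obs`, `VA_obs` to the solved
equilibrium, its self-rescaled variant, and classic B, with 95%
replicate CIs; the fitness-variance flux identity `V_A = (U-2R)s` is
scored as a z-statistic with the fixation-count noise propagated.

**Synthetic genome.**  Chromosomes (default 5 x 20 Mb) with ~7%
conserved sequence in exponential segments (mean 1.5 kb) placed on a
piecewise-constant lognormal recombination map around 1 cM/Mb; truth
`pi0 = 1e-3`, `mu = 1.5e-8`, point-mass DFE, `N = 10,000`, 100 sampled
haplotypes, 80% accessibility, megabase windows.  Window counts are
drawn `Y_b ~ Binomial(n_b, pi0*Bbar_true(b))`; an optional unit-mean
Gamma multiplier on `p_b` (shape `nu`; 450 gives ~5% per-window noise,
the `2/(9 K)` genealogical floor at ~100 independent blocks per Mb)
emulates genealogical variance.  The layout seed is separate from the
noise seed so layouts can be held fixed across noise realizations.

What the generator does and does not emulate: it produces exactly the
windowed observation model the likelihood assumes, so recovery tests
validate the maps, mixing, and optimizer — under binomial-only sampling
the fit returns the truth to a few percent.  It does not produce
linkage disequilibrium, genealogical correlation between windows, SFS
distortion, or model misspecification; with the Gamma noise mode on,
the mu-DFE likelihood ridge flattens and `mu` is identified only to
roughly +/-40% at this scale (consistent with the noise-sensitivity of
linked-selection mutation-rate estimates generally).  One consequence:
a classic-BGS fit to weak-selection truth from this generator shows the
failure as a ~5x deflated mutation rate at near-truth mean `s` (the
classic and joint maps share the same spatial kernel at matched `s`, so
the shared `mu` absorbs the variance ratio); the mean-`s` inflation seen
with forward-simulated data — where the weak-selection truth carries no
resolvable spatial signal — is outside this generator's reach.

## Numerical choices and defaults

- All `exp(x)-1` via `expm1`; map exponents kept in log space;
  `exp` overflow in the fixation rate returns 0, never NaN.
- Coordinates 0-based half-open (BED) internally; strand ignored.
- Recombination fractions via Haldane's map function, capped at 0.5.
- Desk-scale validation conditions: N=500, L=50 kb, r_bp=1e-8,
  mu in {1e-8, 1e-7}, 2Ns in {0.2, 2, 20}, 100 replicates;
  chosen so the full validation runs in minutes on one core while the
  per-cell CI half-width stays below ~5% of B.
- Per-site observed allele counts (not panel size) keep diversity
  unbiased under missing genotypes; sites with fewer than two observed
  chromosomes are skipped and counted.
- Windows with no comparisons or no accessible map positions are
  flagged and excluded from likelihoods and R^2.

## Known limitations

- The nearly neutral band `2Ns ~ 1-4` is under-predicted by the
  standard model (interference); use the locally rescaled maps there,
  with the double-dipping caveat above.
- Additive fitness only (no dominance, no epistasis), no back mutation
  at substituted sites, equilibrium demography inside the solver.
- The DFE is a discrete simplex on the grid; continuous families and
  SFS-based inference are out of scope.
- Composite likelihood ignores between-window dependence; jackknife
  SEs, not likelihood curvature, are the uncertainty estimates.
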