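# Methods

## Model and assumptions

The unit of analysis is a single bacterial cell expressing an inducible
catabolic enzyme (LacZ) under a repressor-controlled promoter.  Growth
rate is the fitness proxy: `W = W₀(1 + B − C)` with benefit
`B = a·y·x/(k+x)` (Michaelis–Menten in the lactose dose `x`) and cost
`C = b·y/(h−y)` (divergent as expression approaches the cellular resource
ceiling `h`).  Cells with `y > h` are treated as non-growing (`W = 0`),
and `W` is floored at zero just below the ceiling, where the cost pole
would otherwise produce negative growth — the serial-dilution simulator
needs non-negative rates.  The optimum `y_opt = h − √(b·h·(k+x)/(a·x))`
is clamped to `[0, h]`: at low doses the closed form goes negative, and
since fitness is then monotone decreasing in `y`, the biological optimum
is zero expression.

Expression is modeled at steady state only.  Each copy `i` contributes a
Hill response to an effective dose `x·zᵢ·z₀`, where `ln zᵢ ~ N(0, η_in)`
independently per copy and `ln z₀ ~ N(0, η_ex)` shared across the cell.
All noise amplitudes and the dose-fluctuation amplitude Δx are standard
deviations of **natural** logarithms; this convention reproduces the
reference coefficient-of-variation band (CV 0.26 at η=0.1, 0.72 at η=0.5,
measured at x = x₀) which a base-10 convention does not.  Noise is
redrawn per cell and per cell cycle with no temporal autocorrelation.
Induction is treated as monostable (true for lactose, not for synthetic
gratuitous inducers, which are out of scope); transient dynamics and
bistability are not modeled.

Genotypes are lists of per-copy maximal expressions `y_max`: singleton
`[1.0]`, dosage-sharing duplicate `[0.5, 0.5]`, expression-doubling
duplicate `[1.0, 1.0]`.  Averaging two independent intrinsic draws halves
the intrinsic variance exactly; extrinsic noise is untouched.  In the
linear (small-noise) regime the total variance reduction upon
dosage-sharing duplication is half the intrinsic variance share,
`0.5·η_in²/(η_in² + η_ex²)` — 25% at equal amplitudes, measured 25–30%
across η = 0.1–1 once Hill nonlinearity is included.

## Selection coefficients

A trial pairs two genotypes in *distinct cells*: they share the
environmental dose but draw intrinsic **and** extrinsic noise
independently.  `S = W_chal/W_ref − 1` per trial; `⟨S⟩` is the mean of
per-trial ratios (the ratio-of-means is available for diagnostics, and at
these parameter values the two differ by ~1e-5).  Because the two cells'
fitnesses are independent random variables, `⟨S⟩` carries a small Jensen
term `E[W]·E[1/W] − 1 > 0` even for identically distributed genotypes;
it is ≤ ~1e-5 at the noise levels used, an order of magnitude below the
intrinsic-noise buffering gain (~8e-4), and is the reason the
"extrinsic-only" comparison is *nearly* rather than exactly neutral.
Skewness is the uncorrected Fisher–Pearson g₁.  "Moderate" noise means
η_in = η_ex = 0.3, "high" means η_in = η_ex = 1.

The effectively-neutral map over expression level and genome size
rescales the ceiling (`h = 0.36·G`, `G` in Mbp) and the effective
population size (`⟨N⟩ = 3·10⁹/G^1.44`), switches the benefit off, and
evaluates the doubling duplication at a saturating dose (100·x₀), where
realized expression equals `y_max` and input noise is inert; the map
flags `|⟨N⟩·⟨S⟩| < 1`.  The dose choice is ours — the comparison is
drawn in terms of expression itself, and saturation is the cleanest way
to pin expression at `y`.

## Information transfer

The dose→expression channel is scored by the mutual information between
`ln x` and `y`, in bits, from a plug-in 2-D histogram.  Marginal bins are
equal-count (quantile) with 32 bins per axis.  The binning was calibrated
on an additive-Gaussian reference channel with known information
`0.5·log₂(1 + σ_s²/σ_n²)`: at n = 10⁴–10⁵ the 32-bin quantile estimator
is accurate to within ~0.03 bits, while equal-width binning at the same
size underestimates by ~0.1 bit or more (the response saturates, piling
mass into edge bins).  Quantile bins are also invariant to monotone
transforms of either marginal, which suits a sigmoidal readout.  No
bias correction is applied; the estimator's residual bias at the
operating sizes is documented by the oracle tests.  Two estimates are
compared by mapping each to an equivalent correlation
`r = √(1 − 2^(−2I))`, Fisher-transforming, and z-testing the difference
at the common sample size.

## Synthetic inputs

Fluctuating lactose: `ln(x/x_median) ~ N(0, Δx)`, default Δx = 1;
Δx = 0 is a constant environment.

Promoter-mutant activities: the target distribution is known only through
summaries — unimodal with mode at the wild-type activity, support
bounded a little above it, sample skewness ≈ −0.68, and ~10% of mass in
the half-expression band [0.4, 0.6].  The generator is a two-component
mixture: a scaled Beta bulk on (0, 1.3] with its mode pinned at 1, plus
a narrow Gaussian cluster at 0.5 (SD 0.05).  The Beta concentration and
the cluster weight are solved from the analytic mixture moments so the
skewness and band-mass targets are met exactly at the population level;
infeasible target combinations raise a configuration error.  Setting
`frac_half_expression=None` drops the cluster (used for symmetric
overrides).  The generator emulates only these printed summaries — it is
a synthetic stand-in, not a re-fit of any mutant-library data — so
agreement of downstream results with it demonstrates internal
consistency of the framework, not properties of real promoter libraries.
Mutations affect only mean expression, never the noise amplitudes, and
carry no epistasis.

## Serial-dilution evolution simulator

Carrying capacity N = 10⁵ cells, dilution factor D = 100, one passage per
day, dose redrawn each passage and shared by all cells; no mutations.
Within a passage, growth proceeds in synchronous generation steps: every
cell draws its own expression and hence `W`, grows in volume by
`2^(W·τ)` over a step of τ = 1 doubling time, and the population is
rebinned into unit cells between steps (stochastic rounding).  When the
next full step would overshoot the capacity, the final fractional step
length is solved by bisection so total volume lands on N exactly (W not
redrawn within the fraction), bounding a passage at log₂(D) ≈ 6.64
generations; growth is also capped at 24 h.  Dilution samples the next
N/D founders binomially with probability proportional to end-of-passage
genotype volumes: the deterministic volume ratio dominates, and the
binomial noise is what generates replicate scatter and drift (variance
`f(1−f)/(N/D)` per passage).

The analytic prediction is logistic competition
`f(t) = 1/(1 + (1/f₀ − 1)·2^(−⟨S⟩t))` with `⟨S⟩` measured independently
at the same conditions.  The comparison reports the maximum residual of
the replicate mean and the fraction of checkpoints at which the curve
lies inside the mean ± 2 SD replicate envelope.  With three replicates
the per-checkpoint SD estimate is noisy, so a correct model still
occasionally loses single checkpoints; the strict all-points flag is
reported but the calibrated expectation is near-universal (≥90%)
coverage.

## Population genetics

All closed forms are Haldane-style: competition `r = r₀·2^{S·t}`,
`f = r/(1+r)`; punctual beneficial mutant `P_fix = 2S`,
`t_fix = log₂(⟨N⟩²)/S`, half-invasion at `t_fix/2`; neutral
`P_fix = 1/⟨N⟩`, `t_fix = 2⟨N⟩`; recurrent supply `r = μ_b·2^{S·t}/S`
(valid μ_b·N > 1; for scarce supply a punctual mutant delayed by
`T = log₂(D)/(μ_b·N)`); duplications use the effective coefficient
`S′ = S − μ_d` and fix only if `S > μ_d`.  Successive fixations stack as
`t_fix(m) + Σ t_half(i)`.

The time-dependent duplicate frequency uses a two-class per-generation
recurrence: the duplicate class grows by `(1+S)`, fractions μ_d and μ_c
convert between classes, and frequencies renormalize.  Its fixed point is
exactly `μ_c/(μ_c+μ_d)` at S = 0 and matches the first-order deleterious
balance `μ_c/(μ_c+μ_d−S)` to O(S·(μ_d+f)); with both rates zero it is
pure competition at per-generation factor `(1+S)` (identically
`2^{log₂(1+S)·t}`).  A consequence of explicit back-conversion: under
positive selection with a *high* deletion rate the system plateaus at
`1 − f ≈ (1+S)·μ_d/S` rather than fixing — fixation in the usual sense
requires `S ≫ μ_d`.

## Problem sizes and numerical choices

Monte Carlo sizes: 10⁴ trials for distribution-level summaries, 10⁵ for
means quoted to two figures (MC standard errors ~3e-5 on ⟨S⟩), 2·10³ per
grid cell for landscapes and maps.  The simulator's reference run is
3 replicates × 151 passages (~1000 generations) at N = 10⁵, a few
seconds of CPU; sweep-shape claims (gain monotone in η_in, anti-monotone
in η_ex and Δx, peaked at intermediate dose) are established on the
analytic side from ⟨S⟩ at n = 10⁵ per condition, with the simulator
checked against the envelope at the reference conditions.  Hill-curve
fitting is trust-region least squares on 40 log-spaced doses spanning
x₀/30–30·x₀ with free amplitude, exponent, and midpoint, initialized at
the deterministic values.  The EC50-deviation test samples candidate
EC50s log-uniformly on [0.01, 1] mM and measures Euclidean distance to
the optimal curve on 50 log-spaced doses in [0.001, 10] mM.  All
stochastic entry points take an explicit seeded generator; experiment
runners write manifests (config + seed + version) beside their outputs.

## Known limitations

The cost model ignores the permease (LacY), which would sharpen the
benefit side; expression noise is dose-independent in amplitude;
competing cells never share extrinsic state (no common micro-environment
beyond the dose); the promoter-activity generator reproduces summary
statistics, not the underlying mutational spectrum; and the simulator's
synchronous-generation scheme approximates asynchronous division —
adequate at |S| ≲ 10⁻² where per-generation growth differences are
first-order, untested far beyond that.
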