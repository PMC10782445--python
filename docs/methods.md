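# Methods

## Model

The package estimates the reduction free energy ΔG of a redox cofactor in a
protein from paired energy evaluations of MD snapshots. Each snapshot drawn
from the equilibrium ensemble of one redox state is re-evaluated with the
other state's Hamiltonian; because the switch is instantaneous, the energy
difference is the statistical work of the switching process and the Crooks
fluctuation relation

p(W | forward) / p̃(−W | backward) = exp[β(W − ΔG)]

holds exactly, however far the instantaneous switch drives the system from
equilibrium. Reduction (electron appears) is the forward protocol, oxidation
the backward protocol; oxidized-ensemble frames yield forward work
W = ε_red − ε_ox and reduced-ensemble frames backward work W = ε_ox − ε_red,
never cross-assigned.

Assumptions inherited from the data-generation stage and *not* checked by
this package: the two ensembles are adequately sampled and overlap; the
energies are protein-only contributions (whole-system differences drown the
signal in solvent fluctuations); molecular-mechanics energies carry no
electronic/polarization terms, so absolute potentials are uncalibrated and
only shifts δE between systems sharing the same cofactor are meaningful.

## Estimators

**Crooks–Bayes (CB).** Under the Crooks relation, the probability that a
work value belongs to the forward rather than the backward sample is
logistic in β(W − Δg), which gives the likelihood

L(Δg) = ∏_fwd f(β(W_i − Δg) + M) · ∏_bwd f(β(W_j + Δg) − M),
f(x) = 1/(1+e^(−x)), M = ln(n_fwd/n_bwd).

With a flat prior, L is the posterior density. The point estimate is the
posterior mean (optimal under squared error) and the reported uncertainty is
the posterior SD. Whether that SD or a resampling quantity is the "right"
error is a genuinely open choice; we implement and label the posterior SD.
It is conservative relative to the BAR asymptotic error (it lacks the
−1/n_F − 1/n_R correction), which is what makes it trustworthy at small μ.

Numerics: the log-likelihood is accumulated as −logaddexp(0, −x) in chunks
(work values of hundreds of kJ/mol would overflow any direct exponential);
the grid is uniform with 4001 points, centered on the BAR root, spanning
±max(10 k_BT, 5 × pooled work SD); if more than 1e-4 of the posterior mass
falls in the outer 2% of the grid, the span doubles (up to 8 times) before
erroring. Normalization and moments use the trapezoid rule; normalization is
enforced to 1e-6.

**BAR.** The maximum of the same likelihood, i.e. the root of

Σ_fwd f(−β(W_i − Δg) − M) = Σ_bwd f(−β(W_j + Δg) + M),

which is the standard Bennett/maximum-likelihood balance condition; the
residual is monotone in Δg, so the root is bracketed starting from the two
one-sided Jarzynski estimates, expanding geometrically (never beyond
50 k_BT outside the data range) and refined by Brent's method to 1e-12.
Because BAR maximizes the CB likelihood, the posterior mode and the BAR root
coincide for any sample sizes — a cross-check the tests exercise. The BAR
standard error is the asymptotic ML variance
(1/β²)·([Σ f(x)f(−x)]⁻¹ − 1/n_F − 1/n_R), clamped at zero in the degenerate
small-sample corner where the subtraction goes negative.

**Histogram crossing.** ΔG = W* where the forward and negated-backward work
densities cross. Shared uniform bins (Freedman–Diaconis default) over the
union support; crossings located by linear interpolation of the density
difference between adjacent bin centers. Real data can produce several
crossings; the one inside the overlap region closest to the BAR estimate is
reported, with no standard error (the construction has no natural one).
Disjoint histograms and identical samples raise distinct errors pointing the
user to CB/BAR.

**One-sided estimators.** Jarzynski ΔG = −β⁻¹ ln⟨e^(−βW)⟩ via log-sum-exp
(identical to Zwanzig FEP for instantaneous switches; applied to backward
work it estimates −ΔG of the forward process, and the caller flips the
sign), and the linear-response Gaussian approximation ΔG = ⟨W⟩ − βσ²/2 with
the unbiased sample variance. Neither carries a default error bar.

**Convergence diagnostics.** The CB estimate is recomputed on growing
*prefix* subsets (first μ values per direction, preserving trajectory
order — reproducible without extra randomness and matching how data
accumulates in a simulation campaign); the posterior SD is expected to
shrink like μ^(−1/2).

## Units and constants

Energies in kJ/mol, potentials in mV, temperatures in kelvin (default
298 K). k_B = 0.008314462618 kJ mol⁻¹ K⁻¹ and F = 96485.3 C mol⁻¹
(= 96.4853 kJ mol⁻¹ V⁻¹), fixed. ΔG = −nFE with n = 1 electron throughout
the defaults.

## Synthetic data

`generate_crooks_gaussian` draws forward work from N(ΔG + βσ²/2, σ²) and
backward work from N(−ΔG + βσ²/2, σ²): the unique Gaussian pair satisfying
the Crooks relation with free-energy difference ΔG, hence an analytic ground
truth. σ = 0 is the quasistatic limit (every work value equals ±ΔG). The
defaults elsewhere in the tests (n = 2000–4000 per direction, σ of a few
kJ/mol at 298 K) mirror the scale of a realistic MD campaign of a few
thousand switching events per system. `generate_energy_table` embeds those
works into snapshot-energy pairs with a baseline energy ~N(0, 100² kJ/mol)
— potential-energy fluctuations two orders of magnitude above the redox
signal, as in real proteins — split evenly over replicates.

`generate_crooks_mixture` provides a non-Gaussian stress generator that is
*exactly* Crooks-consistent: tilting a Gaussian component N(m, s²) by
e^(−β(W−ΔG)) yields the shifted component N(m − βs², s²) with an
exponentially tilted weight, and ΔG follows in closed form from weight
normalization. (An importance-weighting approximation was considered and
rejected since the exact conjugate is available.)

Synthetic titrations place 25 points (default) uniformly over midpoint
± 150 mV — the span of a typical thin-layer electrochemistry sweep — with
Gaussian response noise (default studies use SD 0.02, a 2% normalized
absorbance error) clipped to [−0.1, 1.1].

What a green test on this generator establishes: the estimators correctly
invert work distributions that satisfy the Crooks relation. What it does not
establish: robustness to non-equilibrium sampling artifacts, inter-replicate
drift, autocorrelation, or force-field error — none of which the generator
emulates.

## Nernst fitting

The reduced fraction is 1/(1 + exp(nF(E_app − E)/RT)), decreasing in the
applied potential (reduction favored at low potential). The fit floats the
midpoint plus an amplitude and baseline (initialized at 1 and 0; normalized
experimental ΔA rarely spans exactly [0, 1]), fixes n = 1 (a free-n variant
exists behind a flag), and uses scipy's `curve_fit`; the midpoint SE comes
from the fit covariance. Curves that never leave one plateau (response range
< 0.3) are rejected as ill-conditioned rather than returning an arbitrary
midpoint.

## Shifts and benchmarking

δE = E_mut − E_ref with errors combined in quadrature. Benchmark
correlations (Pearson) exclude the reference's identically-zero row and are
reported both over all mutants and over single mutants only (double mutants
identified by label); with a systematic offset between prediction and
experiment plausible in either sign convention, the mean signed offset over
single mutants is printed both ways rather than asserting one.

## Known limitations

- No reweighting/trimming of work values: all samples are used as given.
- No multi-state (MBAR-style) generalization; exactly two states.
- The histogram-crossing estimate depends on binning and is provided for
  comparison, not recommended for reporting.
- Absolute potentials are exposed but flagged uncalibrated; only shifts
  should be compared with experiment.
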