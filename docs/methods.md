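# Methods

## The model

Grain micronutrient concentration observed at projected locations
$s_1,\dots,s_n$ (km) is modelled with a spatial linear mixed model

$$ y(s) = x(s)^{\mathsf T}\beta + u(s) + \varepsilon, $$

where $x(s)$ collects the fixed effects (intercept, a centred easting
trend, and any retained covariates), $u$ is a zero-mean Gaussian random
field with covariance $\sigma^2\rho(h)$, and $\varepsilon$ is iid
$N(0,\tau^2)$ — the *nugget*, interpreted as fine-scale spatial variation
plus (small) measurement error. The correlation function is the Matérn
family in the convention

$$ \rho(h) = \frac{1}{2^{\kappa-1}\Gamma(\kappa)}
   \left(\frac{h}{\phi}\right)^{\kappa} K_\kappa\!\left(\frac{h}{\phi}\right), $$

with distance parameter $\phi$ (km) and smoothness $\kappa$; $\kappa=1/2$
is the exponential model. The implied variogram is
$\gamma(h)=\tau^2+\sigma^2(1-\rho(h))$, with sill $\tau^2+\sigma^2$.
Distances are planar Euclidean on projected kilometres; there is no
geodesic or anisotropic option.

## Estimation

The fixed effects are profiled out by generalised least squares at every
candidate covariance and the overall variance scale is profiled in closed
form, so the numerical search runs over only
$(\log\nu,\log\phi)$ with $\nu=\tau^2/\sigma^2$ the noise-to-signal ratio.
Writing $C=\sigma^2 A$ with $A=\nu I + R(\phi,\kappa)$, the profile MLE of
the scale is $r^{\mathsf T}A^{-1}r/n$ (ML) or $/(n-p)$ (REML). This
two-parameter profiling is the approach of the classical geostatistical
likelihood software lineage; it is faster and substantially more robust
than a raw three-parameter search over $(\tau^2,\sigma^2,\phi)$, and the
reported parameter set is identical.

The search uses Nelder–Mead on the log scale with a widened initial
simplex and (by default) three restarts; the best restart wins, so the
reported log-likelihood is non-decreasing in the number of starts.
Reported REML values follow the canonical error-contrast definition
(including the $-\tfrac12\log|X^{\mathsf T}X|$-relative constant), so they
equal the multivariate-normal log-density of any orthonormal contrast
$Ky$, $KX=0$ — this identity is what the oracle tests assert to $10^{-8}$.

The smoothness $\kappa$ is never optimised continuously: it is profiled
over a discrete grid (default $\{0.25, 0.5, 1.0, 1.5, 2.0, 2.5\}$,
user-overridable) on the null model, and the winning value is reused for
all subsequent models on the same data.

Numerical safeguards: Cholesky factorisation with escalating diagonal
jitter ($10^{-10}$–$10^{-6}$ of the mean diagonal) absorbs near-duplicate
close-pair locations; $\log\nu$ is clipped to $\pm13.8$ (pure-signal to
pure-nugget); $\phi$ is bounded between half the smallest non-zero
distance and twice the domain diameter; Bessel underflow at extreme
$h/\phi$ returns correlation 0. For the grid smoothness values
$\kappa\in\{0.5,1,1.5,2,2.5\}$ the correlation uses closed forms or the
dedicated $K_0/K_1$ routines, which agree with the generic
$K_\kappa$ formula to $10^{-12}$ and are several times faster.

## Covariate selection

Candidates arrive in an a-priori expert ranking (soil and environmental
groups are selected separately, producing separate models). Starting from
the null model (intercept + centred easting trend, fitted by ML), each
candidate in rank order is added to the working model and tested by a
1-df likelihood-ratio test ($L = 2(\ell_1-\ell_0)$, clipped at zero
against optimiser noise). A predictor with $p>0.05$ is dropped; otherwise
it is provisionally retained and stays in the working model. After the
pass, each p-value is compared with its alpha-investing threshold:
wealth starts at $W_0=\alpha(1-\alpha)$, the spend at test $j$ is
$\alpha_j = W_{j-1}/(1+j-r_j)$ with $r_j$ the index of the last rejection,
rejection pays back $\alpha$, and acceptance charges
$\alpha_j/(1-\alpha_j)$. Provisionally retained predictors whose p-value
also clears the threshold are definitively retained, and the final model
is refitted by REML. The wealth-update constants are configurable; the
defaults follow a standard published alpha-investing scheme, and the FDR
guarantee is verified empirically (500 global-null datasets) rather than
assumed.

Two deliberate readings where the procedure's description is ambiguous:
the selection runs as a single forward pass (a provisionally retained
predictor that later fails the wealth threshold is *not* removed before
subsequent tests), and wealth is spent on every test, including those
already dropped at the 0.05 screen.

## Prediction and cross-validation

The E-BLUP at a target $s_0$ with covariates $x_0$ is the universal
kriging (external drift) predictor
$\hat y(s_0)=x_0^{\mathsf T}\hat\beta + c^{\mathsf T}C^{-1}(y-X\hat\beta)$
with $c_i=\sigma^2\rho(\lVert s_i-s_0\rVert)$, and prediction error
variance $c_{00}-c^{\mathsf T}C^{-1}c + d^{\mathsf T}(X^{\mathsf T}C^{-1}X)^{-1}d$,
$d=x_0-X^{\mathsf T}C^{-1}c$. By default the prediction target is the
full process (signal + nugget): $c_{00}=\tau^2+\sigma^2$, the nugget being
read as genuine fine-scale variation, and a target coinciding with a
datum honours it (exact interpolation when $\tau^2=0$). A switch selects
signal-only prediction ($c_{00}=\sigma^2$); the choice only shifts the
variance surface by (at most) $\tau^2$ and does not affect the predictor
at unobserved sites.

Leave-one-out cross-validation holds the covariance parameters at the
full-data REML fit (re-estimating them per fold is prohibitively slow and
changes nothing material at these sizes — a documented limitation) but
re-estimates $\beta$ by GLS within every fold. The standardised squared
prediction errors $(y_i-\hat y_{-i})^2/\mathrm{pev}_{-i}$ are
$\chi^2_1$ under a correctly specified model: mean 1, median 0.4549. The
reference interval for the sample median uses continuity-corrected
normal rank bounds around $n/2$ mapped through the $\chi^2_1$ quantile
function (exact binomial ranks behind a flag); at $n=1600$ it evaluates
to $[0.40, 0.51]$.

## Dietary threshold and risk communication

If maize supplies a share $s$ of daily energy (either given directly or
derived as intake × energy density / ADER), it should supply the same
share of the zinc estimated average requirement, which pins the required
grain concentration at $s\cdot\mathrm{EAR}/\mathrm{intake}$ (intake in
kg/day). Defaults: EAR 10.3 mg/day, intake 342.8 g/day, energy density
3.79 kcal/g, share 61.9% → 18.6 mg/kg. The ADER default (2099 kcal) is
*derived* from those figures, not an independent datum. Below-threshold
probabilities are $\Phi((t-\hat y)/\sqrt{\mathrm{pev}})$ under normal
prediction errors, and are labelled with an IPCC-style calibrated-language
scale in lower-closed bins
$\{<0.01, 0.01\text{–}0.10, 0.10\text{–}0.33, 0.33\text{–}0.66,
0.66\text{–}0.90, 0.90\text{–}0.99, \ge 0.99\}$; only the central
"about as likely as not" label is anchored in the risk-communication
literature this scale follows, the rest are configurable.

## The synthetic survey generator

The generator emulates the study conditions so that every stage is
testable against a known truth. Coverage designs are k-means centroids of
a 50× oversampled uniform draw (space-filling, reproducible), plus ~10%
close pairs offset within 1 km (the offset is a free design parameter:
no value is documented for the original survey). Soil covariates are
log-normal with medians and log-SDs at the scale of labile micronutrient
fractions; pH and the sorption partition coefficient are symmetric;
cross-correlation is imposed by a Gaussian copula on the latent scale.
Environmental covariates are smooth surfaces built from long-range
Matérn fields (distance parameter five times the response's) optionally
mixed with a deterministic south–north gradient: climate covariates in a
long narrow country are dominated by latitude and elevation, so modelling
them as stationary patches alone would make them statistically
indistinguishable from the response's own random field. Temperature
carries the strongest gradient share (0.8); positive quantities
(precipitation, slope) use a log-scale field.

The response adds fixed effects (easting trend 0.019; pH 0.40; log
exchangeable Zn 0.6; temperature 0.65 per degree, sized so that adding it
removes a visible share of the spatially correlated variance, as in the
survey emulated; intercept set for a marginal mean near 21.5 mg/kg) to a
Matérn field ($\sigma^2=3.3$, $\phi=21$ km, $\kappa=1$) and nugget
($\tau^2=5$) — the fitted random-effects scale of the survey the package
emulates. The component values are prioritised over the survey's marginal
SD (≈4.5 mg/kg): with fitted-scale covariate effects the implied marginal
SD is ≈3.1, and no attempt is made to force the difference into the fixed
effects. The full-size default is 1600 sites over a 180 × 620 km domain;
the calibration and recovery studies use a quarter-area domain at the
same sampling density for n=400, while the demo keeps the full-length
domain so the temperature gradient stays identifiable.

What the generator does **not** emulate: cropland masking and access
constraints of a real sampling frame, non-Gaussian response errors,
covariate measurement error, anisotropy, and non-stationarity of the
random-effect variances. Passing tests therefore demonstrate internal
correctness and calibration of the *methods*, not properties of any real
survey.

## Problem sizes and known limitations

- Simulation studies run at desk scale: cross-validation calibration
  pools ten n=400 surveys; false-discovery control uses 500 datasets at
  n=200 with nine noise predictors; parameter recovery refits twenty
  n=400 surveys over the smoothness grid {0.5, 1.0, 2.0}.
- $\sigma^2$ and $\phi$ lie on the well-known flat Matérn likelihood
  ridge (only $\sigma^2/\phi^{2\kappa}$ is well identified under infill
  asymptotics). ML and REML therefore agree closely on $\tau^2$ and on
  the variogram over the sampled distance range, while $\sigma^2$ and
  $\phi$ individually can differ by ~10% between the two, and occasional
  replicates run to the $\phi$ search bound. Tests compare what is
  identifiable.
- Smoothness is weakly identified at n=400: profiled $\hat\kappa$ piles
  onto the ends of the grid, and the generating $\kappa=1$ becomes the
  modal selection only around n≥1000 (the original survey had n=1600).
  This was confirmed with a brute-force likelihood grid independent of
  the package's optimiser; the recovery study reports the full selection
  counts rather than hiding the effect.
- The variance-explained decomposition follows the definition
  r2_adj = [(τ²₀+σ²₀) − (τ²₁+σ²₁)]/(τ²₀+σ²₀) and
  r2_adj_c = (σ²₀−σ²₁)/σ²₀ against the null model verbatim. Applied to
  published variance-component sets, the correlated-variance proportions
  reproduce exactly; the corresponding total-variance proportions printed
  alongside such tables do not always follow from this definition, and no
  attempt is made to match them.
- Grid I/O is CSV throughout; there is no raster/GeoTIFF writer and no
  geographic-projection handling — coordinates are assumed already
  projected to km.
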