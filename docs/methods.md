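# Methods

## Distributional model

Counts are modelled as gamma mixtures of (quasi-)Poisson distributions.
Biological replicates share an expected abundance whose true value varies
with squared coefficient of variation $\psi_g$ (a gamma distribution);
sequencing adds technical noise with variance $\sigma_g^2 \mu$.  Together,

$$\mathrm{var}(y_{gi}) = \sigma_g^2 \mu_{gi} + \psi_g \mu_{gi}^2
 = \sigma_g^2 (\mu_{gi} + \phi_g \mu_{gi}^2), \qquad \phi_g = \psi_g/\sigma_g^2 .$$

With $\sigma_g^2 = 1$ the counts are exactly negative binomial with
dispersion $\phi_g$; $\sqrt{\psi_g}$ is the biological coefficient of
variation (BCV).  Observation weights $w_{gi}$ divide the quasi-dispersion
($w_{gi}/\sigma_g^2$ can be read as a conceptual number of technical
replicates behind observation $y_{gi}$).

All internal GLM arithmetic is on the natural-log scale (offsets are log
effective library sizes); fold changes are converted to log2 only in
reported tables.

### Continuous counts

Fractional counts arise from probabilistic read assignment and from
divided counts.  The NB probability mass function is generalized by
replacing its binomial coefficient with
$\Gamma(y + 1/\phi)\,/\,(\Gamma(1/\phi)\,\Gamma(y+1))$, giving a smooth
positive function of real $y \ge 0$ that coincides with the NB pmf at
integers.  The matching unit deviance is

$$d(y,\mu,\phi) = 2\Big[y \log\tfrac{y}{\mu}
  - (y + \tfrac1\phi)\log\tfrac{1+\phi y}{1+\phi\mu}\Big],$$

with Poisson limit $2[y\log(y/\mu) - (y-\mu)]$ at $\phi=0$ and
$(2/\phi)\log(1+\phi\mu)$ at $y=0$.

**Numerics.** Writing $a = 1/\phi$, the deviance equals
$2[g(y,\mu) - g(y+a,\mu+a)]$ with $g(x,x_0) = x\log(x/x_0) - (x - x_0)$.
For $|y-\mu| < 0.05\,\mu$ both terms nearly cancel, so the difference is
evaluated directly as the series
$2\sum_{k\ge2} (-1)^k (y-\mu)^k\,[\mu^{1-k} - (\mu+a)^{1-k}]/(k(k-1))$,
with the bracket computed through `expm1`/`log1p`; truncation at $k=14$
leaves relative error below $10^{-12}$ in that regime.  Elsewhere $g$
itself uses a series for small relative deviations.  This achieves the
10-significant-digit accuracy needed because downstream quasi-dispersions
are ratios of sums of these quantities.

## GLM fitting

One-way layouts (any design whose distinct rows number exactly the
coefficients) decompose into independent intercept problems solved by
plain Fisher scoring per group; with equal offsets the fitted mean is the
group mean exactly.  General designs use Fisher scoring with Levenberg
damping: the expected information $X^T W X$ (working weights
$w\mu/(1+\phi\mu)$) gets $\lambda$ times its diagonal added; a step is
accepted only if the deviance does not increase, otherwise $\lambda$ is
multiplied by 10 and the step retried ($\lambda/10$ on acceptance).  The
deviance path is therefore non-increasing by construction, and
convergence is declared on a deviance change below
`tol * (deviance + 1)` — deviance-based rather than coefficient-based,
since the acceptance rule already tracks deviance.  We use the exact
expected information (with damping) rather than a simplified
approximation plus line search; the damping plays the same
convergence-guarding role.

Starting values come from a linear regression of
$\log((y + 1/8)/\mathrm{ELS})$ on the design.  Linear predictors are
clamped so fitted means stay within $[10^{-10}, 10^{10}] \times$ ELS;
all-zero rows are flagged and given zero fitted values with a $-\infty$
coefficient sentinel.

Reported log-fold-changes come from a second fit on prior-augmented
counts: sample $i$ receives $\mathrm{prior}_i = c\,\mathrm{ELS}_i/
\overline{\mathrm{ELS}}$ (default $c = 0.125$) and offsets become
$\log(\mathrm{ELS}_i + 2\,\mathrm{prior}_i)$.  Tests and fitted values use
the unaugmented fit.

## NB-dispersion estimation

The Cox–Reid adjusted profile likelihood at fixed $\phi$ is the continuous
NB log-likelihood at the genewise fit minus
$\tfrac12 \log\det(X^T W X)$, removing the bias that mean estimation
induces in dispersion estimation (the GLM analogue of REML).  The
determinant is computed from an eigendecomposition with eigenvalues
floored at $10^{-300}$, so degenerate information (all-zero genes)
contributes only its non-degenerate part; the floor is $\phi$-independent
and cannot move an argmax.

APLs are evaluated on a 21-point grid, equally spaced on the log2 scale
over BCV 0.005–2 ($\phi$ from $2.5\times10^{-5}$ to 4, covering bulk and
single-cell regimes), then once more on a refinement grid re-centred on
the common maximizer (factor $2^{\pm 6}$).  Maximization interpolates each
gene's grid values with a not-a-knot cubic spline on $\log\phi$ — chosen
because it reproduces cubic (hence locally quadratic likelihood) shapes
exactly — and takes the best of the interior stationary points and grid
endpoints, with numerically stable quadratic root formulas for
nearly-degenerate cubic segments.

- **Common**: maximizes the equally weighted APL mean over genes.
- **Trended**: genes are ordered by average abundance (log2 CPM from an
  intercept-only NB fit on prior-augmented counts) and the per-grid-point
  APLs smoothed by a symmetric moving average spanning
  $\min(\max(0.25,\,10/G),\,1)$ of the genes (edge windows shrink); the
  trend maximizes the smoothed curve, so equal abundances get equal
  trend values.
- **Tagwise**: maximizes $\mathrm{APL}_g + G_0\,\mathrm{APL}^{\text{local}}_g$
  where the local shared APL is the smoothed value at the gene's abundance
  rank and $G_0 = d_{\text{prior}}/(n-p)$.  The prior df, when not given,
  comes from the spread of genewise deviance dispersions about the trend
  using the same F-distribution moment fit as the quasi-dispersion EB
  (infinite when there is no excess spread).  $d_{\text{prior}} = \infty$
  returns the trend exactly; 0 returns the genewise maximizers.

## Bias-adjusted quasi-likelihood

Classical QL treats the residual deviance as $\sigma^2 \chi^2_{n-p}$,
which under-estimates $\sigma^2$ badly when counts are small.  Instead,
for every observation the exact mean $e$ and variance $v$ of its unit
deviance under (continuous-)NB$(\hat\mu, \phi)$ are computed and matched
by a scaled chi-square with scale $s = v/(2e)$ and fractional df
$k = 2e^2/v$.  Moments are probability-weighted sums over the integers up
to cumulative mass $1-10^{-12}$ (capped at $10^6$ terms, and de-duplicated
over repeated $(\mu,\phi)$ pairs); when $\mu(1+\phi\mu) > 10^4$ the gamma
mixing-distribution limit is used instead —
$e = 2a(\log a - \psi(a))$, $v = 4a^2(\psi'(a) - 1/a)$ with $a = 1/\phi$,
which is $(1, 2)$ (the $\chi^2_1$ limit) at $\phi = 0$ — continuous with
the exact branch to better than $10^{-3}$ relative.

Per gene, observations with fitted mean exactly zero contribute nothing;
the remaining $n_g$ observations contribute adjusted deviances $w\,d/s$
and df $w\,k$.  Residual df are allocated proportionally,
$\mathrm{df}_g = (\sum w k) \times (n_g - p)/n_g$, and the raw
quasi-dispersion is $s^2_g = (\sum w\,d/s)\,/\,\mathrm{df}_g$.  In the
large-count Poisson limit ($s \to 1$, $k \to 1$) this is exactly the
classical residual deviance over $n-p$, and on pure-Poisson data the
estimator is unbiased at every count size (the benchmark in
`examples/poisson_benchmark.py`).  The proportional allocation was chosen
over per-observation leverage weighting; it is validated behaviourally by
the unbiasedness benchmark and the classical-limit identity rather than
by source equivalence with any other implementation.

### Empirical Bayes squeezing

On $z = \log s^2$ the df-dependent mean offset of a log chi-square,
$\psi(\mathrm{df}/2) - \log(\mathrm{df}/2)$, is removed; the remainder is
smoothed on abundance by a df-weighted local linear regression (tricube
kernel, window 0.3 of genes; written in-package because no installed
smoother accepts per-point weights plus a kernel).  The prior df $d_0$
solves $\mathrm{var}(\text{detrended } z) -
\overline{\psi'(\mathrm{df}/2)} = \psi'(d_0/2)$ via a Newton trigamma
inverse; non-positive excess gives $d_0 = \infty$.  Genes with df below
0.05 are excluded from hyperparameter estimation (their log-s² moments
are numerically unstable) but still squeezed.  The posterior is the
df-weighted average $(d_0 s_0^2 + \mathrm{df}\,s^2)/(d_0 + \mathrm{df})$
on posterior df $d_0 + \mathrm{df}$.

In the QL pipeline the NB-dispersion defaults to a single constant:
the common APL maximizer over the 5% most abundant genes (falling back to
all genes for small panels).  This keeps the trend in biological variation
global while the quasi-dispersions absorb gene-specific variability, and
it avoids genewise NB-dispersion estimation entirely for large datasets.

## Testing

Null models for a contrast matrix $C$ ($p \times r$, full column rank)
span the coefficient directions orthogonal to $C$ (QR-based completion,
numerically stable and reparameterization-invariant).  The LRT refers
$\mathrm{LR} = D_0 - D_1 \ge 0$ to $\chi^2_r$; the quasi-F test refers
$(\mathrm{LR}/r)/s^2_{\text{post}}$ to $F(r,\,d_0 + \mathrm{df})$
(chi-square when $d_0 = \infty$; NA for genes with zero adjusted df).
Single-df tails use the equivalent $2\,P(T_{d} > \sqrt{F})$ form so the
threshold test reduces to them exactly.

The threshold (TREAT-style) test constrains the contrast at the two
boundary nulls $\pm\tau$ (natural-log scale) by refitting with the
contrast direction moved into the offset, takes signed square roots of
the two deviance differences scaled by the posterior quasi-dispersion,
and sums their upper $t$ tails:
$p = P(T > z_{\text{near}}) + P(T > z_{\text{far}})$ with
$z_{\text{near}} = \mathrm{sign}(|\hat\beta|-\tau)\sqrt{\mathrm{LR}_{\text{near}}/s^2}$.
At $\tau = 0$ this is exactly the ordinary two-sided test; at
$|\hat\beta| = \tau$ the near-boundary LR vanishes and $p \ge 0.5$
exactly.  These deviance-based roots were preferred over Wald roots
precisely because they make both reductions identities rather than
approximations (the averaged-boundary form matches the stated behaviour
of the expectation-based threshold p-value but is not guaranteed
source-identical to any published implementation).

BH adjustment excludes NA p-values from the denominator; ranking and
sign calls are stable in gene order.

## Normalization and filtering

TMM compares each sample to a reference (the sample whose 75th-percentile
normalized count is closest to the mean, ties to the lowest index).  Genes
zero in either library are dropped; log-ratios M and abundances A are
doubly trimmed (30% and 5% per tail, nearest-rank boundaries, boundary
ties kept) and the factor is the inverse-approximate-binomial-variance
weighted mean of surviving M.  TMMwsp additionally pairs singleton genes
(positive in exactly one library) largest-with-largest across libraries
into synthetic shared genes before the same trimming; ties break by gene
index, unpaired singletons are dropped, and a sample with no usable genes
gets factor 1 with a warning.  Factors are rescaled to geometric mean 1.

`filter_by_expr` keeps genes reaching CPM $\ge$
`min_count / median(ELS) * 1e6` in at least (smallest group size) samples
— adjusted to `large_n + (k - large_n) * min_prop` for groups beyond 10 —
and total count at least `min_total_count`, with a $10^{-14}$ tolerance
guarding exact boundaries.

External offset matrices are recentred by a single additive constant onto
the mean log library size (`scale_offset`), preserving all offset
differences exactly.

## Applications

- **Differential exon usage**: exon-level QL fit; exon contrast
  coefficients $\beta_e$ with precisions $1/\mathrm{SE}_e^2$ from the
  observed information times the posterior quasi-dispersion; gene value
  is the precision-weighted mean; exon statistic
  $t_e = (\beta_e - \bar\beta_g)/\mathrm{SE}_e \cdot \sqrt{m/(m-1)}$,
  where the $\sqrt{m/(m-1)}$ factor approximately compensates the
  correlation between an exon and the gene average (no closed form is
  available; the factor is validated by null uniformity of the gene-level
  p-values).  Gene p-values: mean $t_e^2$ on an $(m-1,\,\text{mean
  posterior df})$ F reference, and Simes over exon p-values.  Single-exon
  genes are dropped and counted.
- **Methylation**: `model_matrix_meth` expands an $n \times p$ sample
  design to $2n \times (n+p)$ with per-sample coverage indicators plus
  group log-ratio terms on methylated rows; Me/Un columns of a sample
  share its total library size.
- **Divided counts**: per-transcript pooled quasi-Poisson statistic over
  resamples, moderated towards 1 with 3 pseudo-df (mild shrinkage,
  configurable) and floored at 1; divided library sizes are the column
  sums of the divided counts, i.e. raw sizes scaled down by the
  count-weighted mean overdispersion.
- **z-scores**: mid-p NB tail probabilities computed in the smaller tail
  in log space (`ndtri_exp`), linear interpolation of neighbouring
  integers' mid-p values for fractional counts.
- **MDS**: pairwise distances are root-mean-square of the top-|log2-CPM|
  differences; classical principal coordinates with per-dimension
  variance-explained fractions.

## Synthetic data

Generators draw a gamma abundance (CV² $= \psi$) and then a scaled Poisson
technical layer ($\sigma^2 \times$ Poisson$(\lambda/\sigma^2)$), matching
the quadratic variance exactly and producing fractional counts when
$\sigma^2 \ne 1$; $\sigma^2 = 1$ gives exact NB draws.  Defaults emulate a
small bulk RNA-seq experiment: library size $10^6$, baseline abundances
log-uniform over log2-CPM $[-2, 10]$, BCV 0.1–0.32, 3 replicates per
group; the Poisson benchmark uses 100 samples and 10,000 genes with means
log-uniform on $[2^{-5}, 2^7]$ (the mean distribution is a package choice;
only its range is prescribed by the benchmark's design).  What the
generators do not emulate: outlier samples, GC/length biases,
sample-specific trends, correlated genes, or zero inflation beyond NB —
so passing tests demonstrate correctness of the estimators under the
stated model, not robustness to those artefacts.

Problem sizes in the test-suite simulations (up to 10,000 genes × 100
samples for the benchmark; 2,000 genes × 20 replicates elsewhere) were
chosen so Monte-Carlo error is comfortably below the tolerances being
asserted.

## Known limitations

- Robust (outlier-protected) tagwise dispersion and robust QL
  hyperparameter estimation are not implemented; the standard fits assume
  no hypervariable outliers.
- Other engines implementing this bias adjustment do not document their
  exact fractional-df allocation; ours is validated behaviourally (see
  above), so per-gene values can differ from other implementations even
  where ensemble behaviour matches.
- `glm_treat` requires a single-df contrast; multi-df threshold tests are
  out of scope.
- Readers handle plain-text formats only (TSV, MatrixMarket, Bismark
  coverage); BAM/FASTQ/HDF5 inputs are out of scope.
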