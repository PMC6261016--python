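# Methods

This note documents the models `mdirt` implements, the estimation and
numerical choices behind them, what the synthetic cohorts do and do not
emulate, and the package's known limitations.

## Response model and mixture structure

Conditions are binary indicators. Within latent class $c$, condition $i$
follows a logistic item response curve
$P(x_i{=}1 \mid \theta, c) = \operatorname{logit}^{-1}\!\big(a(\theta - \beta_{ic})\big)$,
and conditions are locally independent given $(\theta, c)$. The latent
complexity is normal within class, $\theta \mid c \sim N(\mu_c, \sigma_c)$,
and class membership is categorical with proportions $\pi_c$. The
discrimination $a$ is a fixed constant, 1.7 by default — the classical
value that makes the logistic curve approximate the normal ogive — so the
mixture stage is a mixture *Rasch* model: within a class, a patient's total
condition count is sufficient for $\theta$.

Identifiability conventions:

- difficulties are sum-zero within each class ($\sum_i \beta_{ic} = 0$);
  class location and scale live in $(\mu_c, \sigma_c)$;
- classes are reported in order of descending $\pi_c$ (ties broken by
  $\mu_c$), which fixes label switching;
- $\sigma_c$ has a floor of 0.05 to prevent degenerate collapse.

## Estimation

The marginal likelihood integrates $\theta$ on standardized Gauss–Hermite
nodes $z_q$ (21 by default; weights normalized to sum to one), with
$\theta_{qc} = \mu_c + \sigma_c z_q$. Estimation is EM:

- **E-step** — exact posteriors over (class, node) for each patient.
- **M-step** — exact. $\pi_c$ updates in closed form. For the rest,
  the linear predictor $a(\mu_c + \sigma_c z_q - \beta_{ic})$ is *linear*
  in $(\mu_c, \sigma_c, \beta_{ic})$, so maximizing the expected
  complete-data log-likelihood within a class is a weighted logistic
  regression on a fixed $(Q \times I)$-row design. It is solved by damped
  Newton iterations with step halving, warm-started from the previous
  iteration. Because the node set is symmetric, the sign of $\sigma_c$ is
  unidentified; a negative estimate is reflected.

With both steps exact, the quadrature marginal log-likelihood is
non-decreasing across iterations; the test-suite asserts this trace
property on every fit. Convergence is declared when the absolute
log-likelihood change falls below `tol` (1e-6 by default) or after
`max_iter` (500) iterations; non-convergence flags the model rather than
raising.

Mixture likelihoods are multimodal, so fits use multistart (10 random
starts by default): each start perturbs logit-prevalence difficulty
profiles by class, runs a short EM burst (50 iterations), and the best
start is polished to convergence. Everything is a pure function of
(data, config, seed).

**Missing data.** Missing indicator cells contribute nothing to a person's
likelihood (ignorable missingness). They can only enter through directly
supplied matrices — indicator construction from encounters never produces
missingness (absence of a code is a 0).

## Fit index and class selection

$\mathrm{BIC} = -2\log L + k\ln n$ with
$k = C(I-1) + (C-1) + 2C$: sum-zero difficulties, mixing proportions, and a
per-class trait mean and sd. Different software counts mixture-IRT
parameters differently, so `compute_fit` also accepts an explicit $k$ for
reproducing externally printed fit rows; BIC comparisons within one
convention are the meaningful ones. `select_classes` fits a range of class
counts and takes the BIC minimum, with an override parameter because the
statistically optimal solution is not always the clinically interpretable
one (a redundant extra class is a common reason to step down by one).

## Within-subgroup scaling diagnostics

After modal assignment, each subgroup is screened separately:

- **Prevalence skew** — conditions with prevalence strictly below 5% or
  strictly above 95% within the subgroup are dropped before scaling
  (high-prevalence ones are reported for descriptive use).
- **Loevinger's H** — for items $i$ (more prevalent) and $j$:
  $H_{ij} = 1 - F_{ij}/E_{ij}$ with $F_{ij}$ the observed count of the
  Guttman error cell ($x_i{=}0 \wedge x_j{=}1$) and
  $E_{ij} = n\,\hat P(x_i{=}0)\hat P(x_j{=}1)$ its expectation under
  marginal independence; item and scale coefficients aggregate the sums.
  Pairs with $E_{ij}=0$ are flagged undefined and excluded from
  aggregates. The conventional $H \ge 0.3$ bound marks an acceptable scale.
- **Monotonicity** — restscore trace lines: patients are grouped by their
  count of the *other* conditions, adjacent groups merged to at least 50
  patients, and any significant decrease of the item proportion between a
  lower and higher restscore group (one-sided pooled two-proportion z-test,
  $\alpha = 0.05$) flags a violation. Significance testing is used because
  visual trace inspection does not automate; $\alpha$, the group-size
  floor, and an optional group-count cap are configurable.
- **Item selection** — monotonicity violators are removed first (worst
  first, recomputing), then items with $H_i$ below `H_min` (lowest first,
  recomputing). Fewer than two survivors raises an error advising
  descriptive-only treatment of that subgroup.
- **Person fit** — Guttman errors are counted under the subgroup's
  descending-prevalence item ordering (ties broken alphabetically, a rule
  the rarity-ordering idea itself does not pin down); patients with more
  than one error (default) are excluded as ill-fitting. Counting raw
  errors, rather than a normed person-fit coefficient, matches the worked
  hypertension/heart-failure style of reasoning the rule encodes; a normed
  variant would be a straightforward extension.

## Subgroup calibration

On the Mokken-selected items and fit-retained patients, both a 1PL and a
2PL model are calibrated by single-class MML-EM:

- **1PL** — slope fixed at 1.7, sum-zero difficulties, $(\mu,\sigma)$
  estimated; $k = (I-1)+2$.
- **2PL** — per-item slopes and difficulties; $\sigma$ is fixed at 1 to
  identify the slopes, and $\mu$ is recovered from the sum-zero constraint.
  The M-step factorizes into independent two-parameter logistic regressions
  per item. Slopes are kept in $[0.2, 5]$ (boundary-pinned slopes are
  flagged); $k = (I-1)+I+2$. A common-slope constrained variant is
  available and agrees with the 1PL maximum to numerical tolerance, since
  the two parameterizations describe the same family.

These are the standard resolutions of the latent-scale indeterminacy: the
1PL pins the slope and frees the scale, the 2PL pins the scale and frees
the slopes. Model choice defaults to BIC; because "the slopes are similar
enough for the simpler model" is a legitimate informal criterion with no
canonical threshold, the comparison record also reports the slope max/min
ratio and the likelihood-ratio statistic rather than hard-coding a rule.
Item characteristic curve profiles evaluate each item's curve on a $\theta$
grid; an item's location (the 0.5 crossing) equals its difficulty, which is
what makes cross-subgroup location comparisons meaningful.

## Characterization

Categorical covariates are dichotomized most-populated-category versus
rest (unknowns fold into the rest; a modal tie requires an explicit
mapping). For each binary covariate the saturated one-covariate
class-membership model is fitted, whose model-based margins equal the
class-conditional sample proportions — the display convention of
"probability of the characteristic within the class" — with Wald intervals
on the logit scale, $\mathrm{se} = 1/\sqrt{n_k p(1-p)}$, back-transformed.
Classes separated on a covariate ($p \in \{0,1\}$) are flagged with a
$[0,1]$ interval. Covariates are profiled one at a time (marginal
profiles, matching the tabular presentation this stage reproduces); a
jointly adjusted multinomial model is out of scope.

All pairwise class contrasts use a Scheffé correction: the contrast
z-statistic is compared with $\sqrt{\chi^2_{K-1,1-\alpha}}$, the
large-sample Scheffé bound that protects the entire contrast family among
$K$ classes simultaneously. Classes are then lettered compact-letter-display
style: letters are maximal cliques of the non-significance graph, so
classes sharing a letter are pairwise indistinguishable after correction.

## Synthetic cohorts

The generator draws from exactly the model the estimator assumes — class,
then normal trait, then Bernoulli indicators — plus class-conditional
Bernoulli covariates. Preset scenarios:

- `single_class` — one class, 10 conditions, difficulties evenly spread on
  $[-2, 2]$, $n = 2{,}000$;
- `two_class_easy` — two equal classes whose difficulty vectors differ by
  3 logits on every condition, $n = 4{,}000$: the easy-recovery regime used
  to validate assignment and selection;
- `paper_like` — six themed classes (substance use, complex mental health,
  complex diabetes, liver disease, cancer+cardiac, cancer+mental health)
  over 29 conditions. Class-conditional prevalences are solved by
  quadrature root-finding so the *marginal* prevalence profile lands on a
  published high-risk cohort's values (hypertension 72%, chronic pain 77%,
  drug abuse 20%, ...); mixing proportions follow the published subgroup
  sizes, and covariate probabilities echo the published class profiles
  (e.g. married 19% in the substance-use class). Default $n = 10{,}000$;
- `guttman_perfect` — deterministic threshold responses
  $x_i = \mathbf{1}[\theta \ge \beta_i]$, which produce zero Guttman errors
  for every patient under prevalence ordering.

What the generator does **not** emulate: real EHR coding error and
under-capture, correlated residuals between related diagnoses (local
dependence), covariates that causally drive class membership rather than
merely differing by class, longitudinal encounter dynamics, and the
upstream construction of a high-risk cohort from a hospitalization risk
score. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness of
the scientific conclusions to their violation. The class-conditional
Bernoulli covariate scheme is a testing-harness choice, not a claim about
any real population.

## Problem sizes and numerical choices

The test-suite and acceptance battery run at deliberately reduced sizes,
chosen so the full statistical battery stays cheap while keeping every
recovery margin wide: difficulty recovery uses 20 replicates of
$n = 2{,}000$; assignment accuracy one cohort of $n = 4{,}000$;
class-count selection 20 replicates each at $n = 1{,}000$–$1{,}500$ with 3
EM starts, 150-iteration cap, and tolerance $10^{-4}$ (BIC gaps at these
sizes are orders of magnitude larger than the likelihood resolution).
Observed margins are comfortable: difficulty RMSE ~0.04 against the 0.15
bound, assignment accuracy ~0.98 against 0.9, selection hit rates 20/20 in
calibration runs against the 16/20 bound.

Other numerical details: quadrature uses probabilists' Hermite nodes with
normalized weights; Bernoulli log-probabilities go through `log_expit` so
$|a(\theta-\beta)|$ up to ~700 is safe; posterior ties in modal assignment
break to the lowest class index (logged); the monotonicity z-test uses the
pooled-proportion standard error; per-stage pipeline seeds are derived from
the global seed by hashing the stage name, so stages can be rerun in
isolation without breaking whole-run reproducibility.

## Limitations

- Dichotomous indicators only; no polytomous items, no 3PL guessing
  parameter, no covariate-dependent mixing, and no standard errors for
  mixture parameters (a bootstrap would be the natural add-on).
- ICD-9 prefix matching only; no ICD-10/SNOMED mapping or terminology
  services, and the shipped condition dictionary is an illustrative
  synthetic example, not a validated instrument.
- Mokken diagnostics cover monotone homogeneity; double monotonicity and
  invariant item ordering are not checked, and item selection targets a
  single scale per subgroup (no multi-scale partitioning).
- Whether a single code occurrence in any setting should suffice for every
  condition is data-dependent; `min_occurrences` and setting/date filters
  are exposed rather than fixed.
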