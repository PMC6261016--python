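# mdirt — mixture-distribution IRT phenotyping of comorbidity profiles

`mdirt` discovers latent subgroups among medically complex patients from
binary diagnosis indicators, and quantifies each condition's — and each
patient's — position on a latent *medical complexity* continuum.  It is
aimed at health-services and biostatistics researchers who have
patients × conditions indicator data (typically built from ICD-9 encounter
codes) and want interpretable comorbidity phenotypes rather than a flat
risk score.

## The model

The core is a mixture-distribution item response model.  For patient $p$
with latent complexity $\theta$ in latent class $c$, the probability of the
condition vector $x = (x_1,\dots,x_I)$ is

$$p(x \mid \theta, c) \;=\; \prod_{i=1}^{I}
\frac{\exp\!\big[x_i\, a(\theta-\beta_{ic})\big]}{1+\exp\!\big[a(\theta-\beta_{ic})\big]},$$

with class-specific condition locations ("difficulties") $\beta_{ic}$, a
discrimination constant $a = 1.7$ (the Rasch convention), class mixing
proportions $\pi_c$, and $\theta \mid c \sim N(\mu_c, \sigma_c)$.  A person
whose complexity equals a condition's location has probability exactly 0.5
of carrying it.  Estimation is marginal-maximum-likelihood EM with
Gauss–Hermite quadrature; the number of classes is chosen by BIC
($-2\log L + k\ln n$, lower is better) with a manual override for
interpretability.  Patients are assigned to their highest-posterior class.

Around that core the package implements the full analysis pipeline:

- **cohort_io** — encounter CSVs, ICD-9 code-pattern dictionaries
  (`"303.*"` families), indicator matrices with missingness, round-trip I/O;
- **preprocess** — cohort filters (near-total missingness, zero-condition
  patients, random subsampling) and the <5% / >95% prevalence screen;
- **synthetic** — cohort generators with known ground truth, including a
  29-condition six-class scenario whose marginal prevalences follow a
  published high-risk cohort profile;
- **mixture** — mixture-Rasch EM, BIC class selection, modal assignment;
- **mokken** — within-subgroup Loevinger's $H$, restscore monotonicity
  checks, scale item selection, and Guttman-error person fit (patients with
  more than one error are excluded as ill-fitting);
- **subgroup** — 1PL/2PL calibration per subgroup with item characteristic
  curves;
- **characterize** — per-class covariate predicted probabilities with 95%
  CIs and Scheffé-corrected equivalence letters;
- **pipeline / cli** — end-to-end orchestration with a reproducibility
  manifest, and a `mdirt` command-line tool.

## Worked example

```python
import numpy as np
from mdirt import preset_scenario, generate_cohort, fit_mixture, select_classes

spec = preset_scenario("two_class_easy")        # 2 classes, 10 conditions, n=4000
matrix, truth = generate_cohort(spec)

selection = select_classes(matrix, range(1, 5), seed=7, n_starts=3,
                           max_iter=150, tol=1e-4)
print(selection.table[["minus2LL", "k", "BIC"]].round(1))
print("chosen C =", selection.chosen)

model, fit, estimates = fit_mixture(matrix, selection.chosen, seed=3)
modal = np.array([e.modal_class for e in estimates])
acc = max(np.mean(modal == truth.classes), np.mean((3 - modal) == truth.classes))
print("assignment accuracy:", round(acc, 3))
```

prints

```
           minus2LL   k      BIC
n_classes
1           55041.3  11  55132.5
2           35201.7  23  35392.4
3           35183.4  35  35473.7
4           35163.7  47  35553.5
chosen C = 2
assignment accuracy: 0.982
```

(The three- and four-class fits hit the iteration cap, which the selection
table records via their `converged` flags; their BIC values are already far
above the two-class model's.)

The fit table mirrors the usual class-selection ladder: the two-class model
drops the deviance by ~20,000 over one class, while three and four classes
buy almost no likelihood and are penalized by BIC; modal assignment then
recovers 98% of the true class labels.  The same flow runs from the shell:

```bash
mdirt run --scenario two_class_easy --out run1 --seed 7
```

which writes the matrix, fit table, assignments, per-subgroup Mokken and
IRT artifacts, characterization tables and a `manifest.json` that makes the
run reproducible bit-for-bit.

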