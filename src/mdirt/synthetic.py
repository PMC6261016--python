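"""Synthetic cohorts with known latent structure.

Generates patients from the same generative model the estimator assumes:
class ~ Categorical(pi), theta ~ Normal(mu_c, sigma_c), and each condition
indicator Bernoulli(logistic(a*(theta - beta_ic))).  Because the ground
truth (class labels, traits, the spec itself) is returned alongside the
matrix, every downstream stage — filtering, mixture estimation, Mokken
scaling, person fit, subgroup calibration, characterization — can be tested
for recovery without any external data.

Difficulties can be supplied directly on the logit scale or derived from
target class-conditional prevalences (solved by quadrature + root finding),
which is how the ``paper_like`` preset pins its marginal prevalence profile
to a published comorbidity table.  A ``threshold`` response mode replaces
the Bernoulli draw with the deterministic rule x_i = 1[theta >= beta_ic],
producing perfect Guttman patterns (zero Guttman errors for every patient
under prevalence ordering).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .cohort_io import ConditionDefinition, DiagnosisMatrix, EncounterTable
from .mixture import DEFAULT_DISCRIMINATION, _gh_nodes

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "generate_covariates",
    "generate_encounters",
    "preset_scenario",
    "difficulty_for_prevalence",
    "PRESET_NAMES",
]


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``difficulties`` is (n_classes, n_conditions) on the logit scale;
    ``covariate_probs`` maps covariate name -> per-class Bernoulli
    probability vector.  ``response`` is "bernoulli" (stochastic, the model
    proper) or "threshold" (deterministic Guttman-perfect responses).
    """

    n_patients: int
    n_conditions: int
    n_classes: int
    mixing: list[float]
    difficulties: list[list[float]]
    trait_means: list[float]
    trait_sds: list[float]
    discrimination: float = DEFAULT_DISCRIMINATION
    covariate_probs: dict[str, list[float]] = field(default_factory=dict)
    condition_names: list[str] | None = None
    response: str = "bernoulli"
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.mixing, dtype=float)
        if len(pi) != self.n_classes or (pi <= 0).any() or not np.isclose(pi.sum(), 1.0):
            raise ValueError("mixing must be a positive simplex of length n_classes")
        beta = np.asarray(self.difficulties, dtype=float)
        if beta.shape != (self.n_classes, self.n_conditions):
            raise ValueError("difficulties must be n_classes x n_conditions")
        if len(self.trait_means) != self.n_classes or len(self.trait_sds) != self.n_classes:
            raise ValueError("trait parameter lengths must equal n_classes")
        if (np.asarray(self.trait_sds, dtype=float) <= 0).any():
            raise ValueError("trait_sds must be positive")
        if self.discrimination <= 0:
            raise ValueError("discrimination must be positive")
        if self.response not in ("bernoulli", "threshold"):
            raise ValueError("response must be 'bernoulli' or 'threshold'")
        for name, probs in self.covariate_probs.items():
            p = np.asarray(probs, dtype=float)
            if len(p) != self.n_classes or (p < 0).any() or (p > 1).any():
                raise ValueError(f"covariate {name!r} probabilities invalid")
        if self.condition_names is None:
            width = len(str(self.n_conditions - 1))
            self.condition_names = [f"cond_{i:0{width}d}" for i in range(self.n_conditions)]
        if len(self.condition_names) != self.n_conditions:
            raise ValueError("condition_names length mismatch")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSpec":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class GroundTruth:
    """True class (1-based) and trait per patient, plus the generating spec."""

    classes: np.ndarray
    thetas: np.ndarray
    spec: CohortSpec

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=int)
        self.thetas = np.asarray(self.thetas, dtype=float)
        if len(self.classes) != self.spec.n_patients or len(self.thetas) != self.spec.n_patients:
            raise ValueError("ground-truth lengths must equal n_patients")
        if self.classes.min() < 1 or self.classes.max() > self.spec.n_classes:
            raise ValueError("classes must lie in 1..n_classes")

    def to_frame(self) -> pd.DataFrame:
        width = len(str(self.spec.n_patients - 1)) if self.spec.n_patients else 1
        ids = [f"P{i:0{width}d}" for i in range(self.spec.n_patients)]
        return pd.DataFrame(
            {"patient_id": ids, "true_class": self.classes, "true_theta": self.thetas}
        )


def difficulty_for_prevalence(
    p: float, mu: float = 0.0, sigma: float = 1.0, a: float = DEFAULT_DISCRIMINATION
) -> float:
    """Solve E_theta[logistic(a*(theta - beta))] = p for beta by quadrature."""
    if not (0 < p < 1):
        raise ValueError("target prevalence must be in (0, 1)")
    z, w = _gh_nodes(61)
    theta = mu + sigma * z

    def gap(beta: float) -> float:
        return float(w @ expit(a * (theta - beta))) - p

    lo, hi = mu - 50.0, mu + 50.0
    return brentq(gap, lo, hi, xtol=1e-10)


def generate_cohort(spec: CohortSpec) -> tuple[DiagnosisMatrix, GroundTruth]:
    """Draw a cohort from the spec; pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    pi = np.asarray(spec.mixing, dtype=float)
    beta = np.asarray(spec.difficulties, dtype=float)
    mu = np.asarray(spec.trait_means, dtype=float)
    sd = np.asarray(spec.trait_sds, dtype=float)
    n = spec.n_patients
    classes = rng.choice(spec.n_classes, size=n, p=pi)  # 0-based draw
    thetas = rng.normal(mu[classes], sd[classes])
    eta = spec.discrimination * (thetas[:, None] - beta[classes])
    if spec.response == "bernoulli":
        X = (rng.random((n, spec.n_conditions)) < expit(eta)).astype(float)
    else:
        X = (thetas[:, None] >= beta[classes]).astype(float)
    width = len(str(n - 1)) if n else 1
    ids = [f"P{i:0{width}d}" for i in range(n)]
    matrix = DiagnosisMatrix(pd.DataFrame(X, index=ids, columns=spec.condition_names))
    truth = GroundTruth(classes=classes + 1, thetas=thetas, spec=spec)
    return matrix, truth


def generate_covariates(truth: GroundTruth, spec: CohortSpec | None = None) -> pd.DataFrame:
    """Class-conditional Bernoulli binary covariates aligned to the cohort."""
    spec = spec or truth.spec
    if not spec.covariate_probs:
        raise ValueError("spec has no covariate_probs")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    out = truth.to_frame()[["patient_id"]].copy()
    cls0 = truth.classes - 1
    for name, probs in spec.covariate_probs.items():
        p = np.asarray(probs, dtype=float)[cls0]
        out[name] = (rng.random(len(cls0)) < p).astype(int)
    return out


def generate_encounters(
    matrix: DiagnosisMatrix, dictionary: Sequence[ConditionDefinition], seed: int = 0
) -> EncounterTable:
    """Emit encounter rows realizing every positive cell (inverse of
    indicator building): each positive cell yields >= 1 encounter with a code
    sampled from that condition's patterns, so
    ``build_indicator_matrix(generate_encounters(M), dictionary)`` recovers
    M on observed cells at min_occurrences=1."""
    by_name = {d.name: d for d in dictionary}
    missing = [c for c in matrix.condition_names if c not in by_name]
    if missing:
        raise ValueError(f"conditions without dictionary entries: {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    vals = matrix.values
    for p, pid in enumerate(matrix.patient_ids):
        for c, cname in enumerate(matrix.condition_names):
            if vals[p, c] == 1.0:
                patterns = by_name[cname].code_patterns
                n_enc = 1 + rng.poisson(0.5)
                for _ in range(n_enc):
                    pat = patterns[rng.integers(len(patterns))]
                    code = pat.rstrip("*").rstrip(".")
                    rows.append((pid, code, "outpatient"))
    records = pd.DataFrame(rows, columns=["patient_id", "icd9", "setting"])
    return EncounterTable(records=records)


# ---------------------------------------------------------------------------
# Preset scenarios
# ---------------------------------------------------------------------------

#: Marginal prevalences of the 29 modelled conditions, echoing a published
#: high-risk cohort profile (hypertension 72%, chronic pain 77%, ...).
_PAPER_LIKE_PREVALENCE = {
    "depression": 0.40,
    "anxiety": 0.19,
    "ptsd": 0.22,
    "bipolar": 0.07,
    "psychosis": 0.09,
    "drug_abuse": 0.20,
    "alcohol_abuse": 0.18,
    "nicotine_abuse": 0.29,
    "hypertension": 0.72,
    "coronary_artery_disease": 0.29,
    "congestive_heart_failure": 0.21,
    "cardiac_arrhythmias": 0.24,
    "chronic_pulmonary_disease": 0.33,
    "cerebrovascular_disease": 0.13,
    "peripheral_vascular_disease": 0.17,
    "clotting_disorders": 0.06,
    "diabetes": 0.43,
    "electrolyte_disorders": 0.15,
    "thyroid_disorders": 0.11,
    "chronic_renal_failure": 0.17,
    "acute_renal_failure": 0.10,
    "polyneuropathy": 0.12,
    "liver_disease": 0.13,
    "chronic_hepatitis": 0.10,
    "chronic_arthritis": 0.47,
    "chronic_pain": 0.77,
    "weight_loss": 0.07,
    "anemia": 0.20,
    "malignant_neoplasm": 0.22,
}

#: Class themes for the six "paper_like" subpopulations: these conditions get a
#: prevalence boost within the class, compensated in the remaining classes so
#: the marginal profile stays on target.
_PAPER_LIKE_THEMES = {
    "substance_use": ["drug_abuse", "alcohol_abuse", "nicotine_abuse", "chronic_hepatitis"],
    "complex_mental_health": ["depression", "anxiety", "ptsd", "bipolar", "psychosis"],
    "complex_diabetes": ["diabetes", "chronic_renal_failure", "polyneuropathy"],
    "liver_disease": ["liver_disease", "chronic_hepatitis"],
    "cancer_cardiac": [
        "malignant_neoplasm",
        "coronary_artery_disease",
        "congestive_heart_failure",
        "cardiac_arrhythmias",
    ],
    "cancer_mental_health": ["malignant_neoplasm", "depression"],
}

#: Mixing proportions matching the relative sizes of the six subgroups.
_PAPER_LIKE_MIXING = [0.137, 0.214, 0.346, 0.085, 0.126, 0.092]

PRESET_NAMES = ("two_class_easy", "paper_like", "single_class", "guttman_perfect")


def _paper_like_spec(seed: int) -> CohortSpec:
    names = list(_PAPER_LIKE_PREVALENCE)
    pi = np.asarray(_PAPER_LIKE_MIXING, dtype=float)
    pi = pi / pi.sum()
    C = len(pi)
    boost = 0.25
    p_target = np.array([_PAPER_LIKE_PREVALENCE[n] for n in names])
    p_class = np.tile(p_target, (C, 1))
    for c, theme in enumerate(_PAPER_LIKE_THEMES.values()):
        for cond in theme:
            i = names.index(cond)
            p_boosted = min(0.95, p_target[i] + boost)
            p_rest = (p_target[i] - pi[c] * p_boosted) / (1 - pi[c])
            if p_rest < 0.02:
                p_rest = 0.02
                p_boosted = (p_target[i] - (1 - pi[c]) * p_rest) / pi[c]
            p_class[c, i] = p_boosted
            for c2 in range(C):
                if c2 != c and np.isclose(p_class[c2, i], p_target[i]):
                    p_class[c2, i] = p_rest
    a = DEFAULT_DISCRIMINATION
    beta = np.array(
        [[difficulty_for_prevalence(p_class[c, i], 0.0, 1.0, a) for i in range(len(names))] for c in range(C)]
    )
    covs = {
        # class-conditional covariate probabilities in the order of the themes
        "married": [0.19, 0.37, 0.42, 0.30, 0.47, 0.38],
        "male": [0.92, 0.84, 0.97, 0.96, 0.98, 0.93],
        "age65plus": [0.20, 0.41, 0.73, 0.39, 0.85, 0.62],
        "unemployed": [0.22, 0.06, 0.01, 0.07, 0.004, 0.04],
        "ed3plus": [0.46, 0.42, 0.39, 0.41, 0.38, 0.36],
        "inpatient1plus": [0.68, 0.54, 0.64, 0.64, 0.65, 0.57],
    }
    return CohortSpec(
        n_patients=10_000,
        n_conditions=len(names),
        n_classes=C,
        mixing=pi.tolist(),
        difficulties=beta.tolist(),
        trait_means=[0.0] * C,
        trait_sds=[1.0] * C,
        discrimination=a,
        covariate_probs=covs,
        condition_names=names,
        seed=seed,
    )


def preset_scenario(name: str, *, seed: int | None = None, n_patients: int | None = None) -> CohortSpec:
    """Named, fully specified scenarios with pinned default seeds.

    - ``single_class``: one class, 10 conditions, evenly spread difficulties.
    - ``two_class_easy``: two equal classes whose difficulty vectors are
      separated by 3 logits on every condition — easy recovery territory.
    - ``paper_like``: six themed classes over 29 conditions whose marginal
      prevalences follow a published high-risk cohort profile.
    - ``guttman_perfect``: deterministic threshold responses; every patient
      is Guttman-consistent under prevalence ordering.
    """
    if name == "single_class":
        beta = np.linspace(-2.0, 2.0, 10)
        spec = CohortSpec(
            n_patients=2_000,
            n_conditions=10,
            n_classes=1,
            mixing=[1.0],
            difficulties=[(beta - beta.mean()).tolist()],
            trait_means=[0.0],
            trait_sds=[1.0],
            covariate_probs={"covariate_a": [0.3]},
            seed=101 if seed is None else seed,
        )
    elif name == "two_class_easy":
        b1 = np.array([-1.5] * 5 + [1.5] * 5)
        spec = CohortSpec(
            n_patients=4_000,
            n_conditions=10,
            n_classes=2,
            mixing=[0.5, 0.5],
            difficulties=[b1.tolist(), (-b1).tolist()],
            trait_means=[0.0, 0.0],
            trait_sds=[1.0, 1.0],
            covariate_probs={"covariate_a": [0.2, 0.5], "covariate_b": [0.7, 0.3]},
            seed=202 if seed is None else seed,
        )
    elif name == "paper_like":
        spec = _paper_like_spec(303 if seed is None else seed)
    elif name == "guttman_perfect":
        beta = np.linspace(-1.5, 1.5, 8)
        spec = CohortSpec(
            n_patients=500,
            n_conditions=8,
            n_classes=1,
            mixing=[1.0],
            difficulties=[(beta - beta.mean()).tolist()],
            trait_means=[0.0],
            trait_sds=[1.0],
            response="threshold",
            seed=404 if seed is None else seed,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; valid names: {PRESET_NAMES}")
    if n_patients is not None:
        spec.n_patients = n_patients
    return spec
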