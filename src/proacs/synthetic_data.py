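"""Synthetic PRO-CTCAE-style item response generator with known ground truth.

The generator emulates the structure of a cross-sectional PRO-CTCAE
administration: each patient carries a latent symptomatic-AE burden factor
f ~ N(0,1) and a latent profile class; each symptom term j has a latent
severity s_ij = mu_{c_i, j} + lambda_j * f_i + e_ij with residual variance
1 - lambda_j^2, so the marginal latent variance is 1 within a single class.
A term's attribute responses share s_ij plus small independent attribute
noise and are binned by attribute-specific ordered thresholds into the 0-4
ordinal response scale.  Administration masks (missing by design) are
Bernoulli per (patient, term), and a continuous external criterion is
generated as criterion_loading * f + noise, scaled to unit variance.

Because all parameters are known, every downstream stage (composite
scoring, correlations, dimensionality, factor models, reliability, latent
profiles) can be tested against closed-form population targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .scoring import ATTRIBUTES, TermDefinition


@dataclass(frozen=True)
class ClassSpec:
    """One latent profile class: mixing proportion and per-term mean shifts
    of the latent severity, in latent (probit) units."""

    proportion: float
    mean_shifts: tuple[float, ...]


@dataclass
class GeneratorConfig:
    n_patients: int
    terms: list[TermDefinition]
    loadings: np.ndarray  # per-term standardized loading in (0, 1)
    class_spec: list[ClassSpec] = field(default_factory=lambda: [ClassSpec(1.0, ())])
    attribute_thresholds: dict[str, np.ndarray] = field(default_factory=dict)
    admin_rates: np.ndarray | None = None  # per-term missing-by-design probability
    term_offsets: np.ndarray | None = None  # per-term prevalence offset (latent units)
    criterion_loading: float = 0.90
    attribute_noise_var: float = 0.1
    seed: int = 0

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.admin_rates is None:
            self.admin_rates = np.zeros(len(self.terms))
        self.admin_rates = np.asarray(self.admin_rates, dtype=float)
        if self.term_offsets is None:
            self.term_offsets = np.zeros(len(self.terms))
        self.term_offsets = np.asarray(self.term_offsets, dtype=float)
        if not self.attribute_thresholds:
            self.attribute_thresholds = default_thresholds()
        self.attribute_thresholds = {
            a: np.asarray(t, dtype=float) for a, t in self.attribute_thresholds.items()
        }
        # pad zero-length class shifts to the term count
        self.class_spec = [
            ClassSpec(c.proportion, tuple(c.mean_shifts) or (0.0,) * len(self.terms))
            for c in self.class_spec
        ]

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if not self.terms:
            raise ConfigurationError("at least one term required")
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("term_ids must be unique")
        p = len(self.terms)
        if self.loadings.shape != (p,):
            raise ConfigurationError("loadings must have one entry per term")
        if np.any(self.loadings < 0) or np.any(self.loadings >= 1):
            raise ConfigurationError("loadings must lie in [0, 1)")
        if self.admin_rates.shape != (p,):
            raise ConfigurationError("admin_rates must have one entry per term")
        if self.term_offsets.shape != (p,):
            raise ConfigurationError("term_offsets must have one entry per term")
        if np.any(self.admin_rates < 0) or np.any(self.admin_rates >= 1):
            raise ConfigurationError("admin_rates must lie in [0, 1)")
        total = sum(c.proportion for c in self.class_spec)
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(f"mixing proportions sum to {total}, not 1")
        for c in self.class_spec:
            if not (0 < c.proportion <= 1):
                raise ConfigurationError("mixing proportions must lie in (0, 1]")
            if len(c.mean_shifts) != p:
                raise ConfigurationError("class mean shifts must have one entry per term")
        for a in ATTRIBUTES:
            t = self.attribute_thresholds.get(a)
            if t is None or t.shape != (4,):
                raise ConfigurationError(f"attribute {a!r}: need an ordered 4-vector of thresholds")
            if np.any(np.diff(t) <= 0):
                raise ConfigurationError(f"attribute {a!r}: thresholds must be strictly increasing")
        if not (0 <= self.criterion_loading < 1):
            raise ConfigurationError("criterion_loading must lie in [0, 1)")
        if self.attribute_noise_var < 0:
            raise ConfigurationError("attribute_noise_var must be nonnegative")


@dataclass
class TruthRecord:
    """Ground truth stored alongside a generated dataset."""

    factor: pd.Series  # latent burden f_i
    classes: pd.Series  # latent class index c_i
    config: GeneratorConfig

    def to_json_dict(self) -> dict:
        cfg = self.config
        return {
            "n_patients": cfg.n_patients,
            "terms": [{"term_id": t.term_id, "attributes": list(t.attributes)} for t in cfg.terms],
            "loadings": cfg.loadings.tolist(),
            "class_proportions": [c.proportion for c in cfg.class_spec],
            "class_mean_shifts": [list(c.mean_shifts) for c in cfg.class_spec],
            "admin_rates": cfg.admin_rates.tolist(),
            "term_offsets": cfg.term_offsets.tolist(),
            "criterion_loading": cfg.criterion_loading,
            "attribute_noise_var": cfg.attribute_noise_var,
            "seed": cfg.seed,
            "factor": self.factor.tolist(),
            "classes": self.classes.tolist(),
        }


@dataclass
class SyntheticDataset:
    items: pd.DataFrame  # wide: <term>__<attribute>, NaN for masked terms
    criterion: pd.Series  # continuous external criterion, unit variance
    truth: TruthRecord


@dataclass
class TargetSummary:
    """Closed-form population values implied by a generator configuration."""

    loadings_std: np.ndarray
    omega: float
    class_proportions: np.ndarray
    criterion_correlation: float


def default_thresholds() -> dict[str, np.ndarray]:
    """Default ordinal cutpoints on the unit-variance attribute latent.

    Frequency tends to be endorsed before severity, and severity before
    interference, so the cutpoints shift upward across attributes.  With a
    standard-normal latent these give roughly 55/45/35% nonzero response
    rates for frequency/severity/interference, in the range seen for
    commonly endorsed symptom terms in treated cancer cohorts.
    """
    return {
        "frequency": np.array([-0.15, 0.60, 1.35, 2.10]),
        "severity": np.array([0.10, 0.90, 1.70, 2.45]),
        "interference": np.array([0.40, 1.15, 1.90, 2.60]),
    }


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one dataset from the configured generative model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, len(config.terms)

    pi = np.array([c.proportion for c in config.class_spec])
    shifts = np.array([c.mean_shifts for c in config.class_spec])  # K x p
    classes = rng.choice(len(pi), size=n, p=pi)
    factor = rng.standard_normal(n)
    lam = config.loadings
    eps = rng.standard_normal((n, p)) * np.sqrt(1.0 - lam**2)
    # s_ij: per-term prevalence offset + class shift + common factor + residual
    latent = config.term_offsets[None, :] + shifts[classes] + factor[:, None] * lam[None, :] + eps

    sd_attr = np.sqrt(1.0 + config.attribute_noise_var)
    columns: dict[str, np.ndarray] = {}
    for j, term in enumerate(config.terms):
        for a in term.attributes:
            noise = rng.standard_normal(n) * np.sqrt(config.attribute_noise_var)
            # normalize so the attribute latent is unit-variance within one class
            z = (latent[:, j] + noise) / sd_attr
            resp = np.searchsorted(config.attribute_thresholds[a], z, side="right")
            columns[f"{term.term_id}__{a}"] = resp.astype(float)

    items = pd.DataFrame(columns, index=pd.RangeIndex(n, name="patient"))

    mask = rng.random((n, p)) < config.admin_rates[None, :]
    for j, term in enumerate(config.terms):
        rows = mask[:, j]
        if rows.any():
            items.loc[rows, [f"{term.term_id}__{a}" for a in term.attributes]] = np.nan

    cl = config.criterion_loading
    criterion = cl * factor + np.sqrt(1.0 - cl**2) * rng.standard_normal(n)
    criterion = pd.Series(criterion, index=items.index, name="criterion")

    truth = TruthRecord(
        factor=pd.Series(factor, index=items.index, name="factor"),
        classes=pd.Series(classes, index=items.index, name="class"),
        config=config,
    )
    return SyntheticDataset(items=items, criterion=criterion, truth=truth)


def population_targets(config: GeneratorConfig) -> TargetSummary:
    """Closed-form targets for recovery tests.

    omega is McDonald's omega of the per-term latent indicators:
    (sum lambda)^2 / ((sum lambda)^2 + sum(1 - lambda^2)).
    """
    config.validate()
    lam = config.loadings
    s = lam.sum()
    omega = 0.0 if s == 0 else s**2 / (s**2 + np.sum(1.0 - lam**2))
    return TargetSummary(
        loadings_std=lam.copy(),
        omega=float(omega),
        class_proportions=np.array([c.proportion for c in config.class_spec]),
        criterion_correlation=float(config.criterion_loading),
    )


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------

_LUNG8 = [
    # (term, attributes, standardized loading)
    ("fatigue", ("severity", "interference"), 0.870),
    ("general_pain", ("frequency", "severity", "interference"), 0.741),
    ("decreased_appetite", ("severity", "interference"), 0.645),
    ("shortness_of_breath", ("severity", "interference"), 0.643),
    ("nausea", ("frequency", "severity"), 0.624),
    ("sad", ("frequency", "severity", "interference"), 0.600),
    ("constipation", ("severity",), 0.558),
    ("cough", ("severity", "interference"), 0.466),
]

_BREAST16 = [
    ("fatigue", ("severity", "interference"), 0.844),
    ("concentration", ("severity", "interference"), 0.827),
    ("memory", ("severity", "interference"), 0.806),
    ("general_pain", ("frequency", "severity", "interference"), 0.766),
    ("joint_pain", ("frequency", "severity", "interference"), 0.739),
    ("dizziness", ("severity", "interference"), 0.682),
    ("nausea", ("frequency", "severity"), 0.636),
    ("shortness_of_breath", ("severity", "interference"), 0.609),
    ("taste_changes", ("severity",), 0.586),
    ("heart_palpitations", ("frequency", "severity"), 0.582),
    ("insomnia", ("severity", "interference"), 0.577),
    ("swelling", ("frequency", "severity", "interference"), 0.560),
    ("numbness_tingling", ("severity", "interference"), 0.531),
    ("hair_loss", ("interference",), 0.476),
    ("constipation", ("severity",), 0.446),
    ("diarrhea", ("frequency",), 0.315),
]

_HEADNECK17 = [
    ("difficulty_swallowing", ("severity",), 0.877),
    ("dry_mouth", ("severity",), 0.812),
    ("taste_changes", ("severity",), 0.812),
    ("decreased_appetite", ("severity", "interference"), 0.796),
    ("mouth_throat_sore", ("severity", "interference"), 0.741),
    ("general_pain", ("frequency", "severity", "interference"), 0.736),
    ("hoarseness", ("severity",), 0.721),
    ("fatigue", ("severity", "interference"), 0.702),
    ("radiation_skin_reaction", ("severity",), 0.696),
    ("cheilosis", ("severity",), 0.670),
    ("cough", ("severity", "interference"), 0.665),
    ("nausea", ("frequency", "severity"), 0.611),
    ("anxious", ("frequency", "severity", "interference"), 0.535),
    ("constipation", ("severity",), 0.531),
    ("sad", ("frequency", "severity", "interference"), 0.517),
    ("insomnia", ("severity", "interference"), 0.512),
    ("vomiting", ("frequency", "severity"), 0.506),
]

# per-cohort missing-by-design ranges (min, max) observed in multi-phase
# PRO-CTCAE administration schedules
_ADMIN_RANGES = {"lung8": (0.03, 0.07), "breast16": (0.11, 0.37), "headneck17": (0.03, 0.32)}

_PRESETS = {"lung8": _LUNG8, "breast16": _BREAST16, "headneck17": _HEADNECK17}

#: four latent profile classes for the lung cohort: a large low-burden class,
#: a small high-burden class, and two classes with equal total burden that
#: trade one predominant symptom (shortness of breath vs decreased appetite,
#: both severity+interference terms with near-identical loadings, so the
#: expected ACS of the two classes matches by construction while their
#: profiles differ by 2.2 latent SD on the traded terms).
_LUNG8_CLASSES = [
    # proportions ~ 113/17/24/29 of 183
    ClassSpec(0.62, (-0.6, -0.6, -0.6, -0.6, -0.6, -0.6, -0.6, -0.6)),
    ClassSpec(0.09, (1.8, 1.8, 1.8, 1.8, 1.8, 1.8, 1.8, 1.8)),
    # terms: fatigue, pain, appetite, sob, nausea, sad, constipation, cough
    ClassSpec(0.13, (1.0, 0.2, 0.2, 2.4, 0.2, 0.2, 0.2, 0.4)),
    ClassSpec(0.16, (1.0, 0.2, 2.4, 0.2, 0.2, 0.2, 0.2, 0.4)),
]


def wellsep_lpa_config(n_patients: int = 500, seed: int = 0) -> GeneratorConfig:
    """Well-separated four-class configuration for latent-profile recovery.

    Uses the lung8 term set with attribute thresholds spread to cover the
    shifted latent range, so every class's composite distribution stays in
    the interior of the 0-3 scale (approximately unimodal, away from floor
    and ceiling pileups).  Classes: low burden, high burden, and two classes
    of equal total burden trading predominant symptoms -- one elevated on
    shortness of breath + cough, the other on decreased appetite + fatigue.
    All four traded terms are severity+interference terms with identical
    threshold sets, so the two trading classes have identical expected ACS
    by construction while their mean profiles differ by 2.4 latent SD on
    the traded terms.
    """
    spec = _PRESETS["lung8"]
    terms = [TermDefinition(t, attrs) for t, attrs, _ in spec]
    # mild within-class loadings: latent profile models assume local
    # independence given class, so in the well-separated regime the class
    # structure -- not a within-class common factor -- carries the
    # between-term correlation
    loadings = np.full(len(terms), 0.3)
    base = (0.0,) * 8
    # terms: fatigue, pain, appetite, sob, nausea, sad, constipation, cough
    sob_cough = (0.0, 0.0, 0.0, 2.4, 0.0, 0.0, 0.0, 2.4)
    app_fatigue = (2.4, 0.0, 2.4, 0.0, 0.0, 0.0, 0.0, 0.0)
    high = (2.4,) * 8
    wide = {
        "frequency": np.array([-0.9, 0.7, 2.3, 3.9]),
        "severity": np.array([-0.8, 0.8, 2.4, 4.0]),
        "interference": np.array([-0.7, 0.9, 2.5, 4.1]),
    }
    return GeneratorConfig(
        n_patients=n_patients,
        terms=terms,
        loadings=loadings,
        class_spec=[
            ClassSpec(0.35, base),
            ClassSpec(0.15, high),
            ClassSpec(0.25, sob_cough),
            ClassSpec(0.25, app_fatigue),
        ],
        attribute_thresholds=wide,
        criterion_loading=0.90,
        seed=seed,
    )


def preset_config(
    name: str,
    n_patients: int | None = None,
    with_classes: bool = False,
    with_missingness: bool = False,
    seed: int = 0,
) -> GeneratorConfig:
    """Build a GeneratorConfig for one of the named cohort presets.

    ``lung8`` (8 terms, default n=183), ``breast16`` (16 terms, n=260) and
    ``headneck17`` (17 terms, n=146) use term sets and standardized
    loadings representative of treated lung, breast, and head/neck cancer
    cohorts.  ``with_classes`` adds the four-profile latent class structure
    (lung8 only); ``with_missingness`` turns on per-term missing-by-design
    masks spanning the cohort's administration-rate range.
    """
    if name not in _PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    spec = _PRESETS[name]
    defaults_n = {"lung8": 183, "breast16": 260, "headneck17": 146}
    terms = [TermDefinition(t, attrs) for t, attrs, _ in spec]
    loadings = np.array([lam for _, _, lam in spec])
    p = len(terms)
    if with_missingness:
        lo, hi = _ADMIN_RANGES[name]
        admin = np.linspace(lo, hi, p)
    else:
        admin = np.zeros(p)
    if with_classes:
        if name != "lung8":
            raise ConfigurationError("latent profile classes are defined for the lung8 preset")
        classes = list(_LUNG8_CLASSES)
    else:
        classes = [ClassSpec(1.0, (0.0,) * p)]
    # prevalence gradient: more salient (higher-loading) terms are also the
    # more commonly endorsed ones, as in treated cancer cohorts
    offsets = np.round(1.2 * (loadings - loadings.mean()), 3)
    return GeneratorConfig(
        n_patients=n_patients or defaults_n[name],
        terms=terms,
        loadings=loadings,
        class_spec=classes,
        admin_rates=admin,
        term_offsets=offsets,
        seed=seed,
    )
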