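"""Synthetic lesion cohorts with the dependence structure reader studies assume.

The generator emulates the data-generating situation of a two-reader
breast-ultrasound CAD study:

* pathology truth ~ Bernoulli(prevalence);
* each lesion carries a latent *severity* (standard normal within class,
  malignant lesions shifted up by ``class_separation`` SD);
* the four per-plane CAD calls are exchangeably correlated binaries,
  realized by thresholding an equicorrelated Gaussian vector whose shared
  factor is the lesion's (class-standardized) severity — so the
  class-conditional marginal positive rate is *exact* at any correlation,
  and CAD calls are positively dependent on reader scores;
* each reader observes severity plus reader-specific Gaussian noise and
  bins it with four fixed thresholds into the ordinal BI-RADS categories
  {3, 4A, 4B, 4C, 5} (an ordered-probit reader model: experience is a
  noise parameter, not a free 2x5 table).

All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq
from scipy.special import roots_hermitenorm

from .core_model import BiradsCategory

__all__ = [
    "ReaderProfile",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "fused_positive_rate",
    "calibrate_to_fused_targets",
    "recover_plane_parameters",
    "reader_profile_from_operating_point",
    "default_config",
    "config_from_file",
    "config_to_dict",
]

PLANE_COLUMNS = (
    "plane_call_long",
    "plane_call_trans",
    "plane_call_obl_a",
    "plane_call_obl_b",
)

#: Fused operating point of the 2-of-4 rule the defaults are calibrated to.
DEFAULT_FUSED_SENSITIVITY = 0.875
DEFAULT_FUSED_SPECIFICITY = 0.814
#: Default inter-plane latent correlation. No empirical estimate exists for
#: this quantity; 0.3 is a placeholder expressing "same lesion, different
#: probe angle" dependence and should be treated as such.
DEFAULT_PLANE_RHO = 0.3
DEFAULT_PREVALENCE = 0.391


@dataclass(frozen=True)
class ReaderProfile:
    """Ordered-probit reader: noisy severity thresholded into 5 categories.

    ``thresholds`` are the four strictly increasing cutpoints on the
    observed (severity + noise) scale separating categories 3 | 4A | 4B |
    4C | 5; the second cutpoint is therefore the reader's operating point
    for the "category 4B or higher" dichotomization.
    """

    name: str
    noise_sd: float
    thresholds: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        t = tuple(float(x) for x in self.thresholds)
        object.__setattr__(self, "thresholds", t)
        if len(t) != 4 or any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be 4 strictly increasing values")


@dataclass(frozen=True)
class SimulationConfig:
    n_lesions: int
    prevalence: float
    plane_sens: float
    plane_fpr: float
    plane_rho: float
    reader_profiles: tuple[ReaderProfile, ...]
    seed: int
    #: Mean severity gap (in SD units) between malignant and benign lesions.
    class_separation: float = 2.0

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        for name in ("prevalence", "plane_sens", "plane_fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.plane_rho < 1.0:
            raise ValueError("plane_rho must lie in [0, 1)")
        object.__setattr__(self, "reader_profiles", tuple(self.reader_profiles))

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SyntheticCohort:
    """Simulated lesions in the pipeline CSV schema.

    ``frame`` columns: lesion_id, pathology ('malignant'/'benign'), the
    four plane-call columns ('M'/'B'), and one ``<reader>_without``
    BI-RADS label column per reader profile.
    """

    config: SimulationConfig
    frame: pd.DataFrame = field(repr=False)

    @property
    def n_lesions(self) -> int:
        return len(self.frame)

    @property
    def n_malignant(self) -> int:
        return int((self.frame["pathology"] == "malignant").sum())

    def positive_plane_counts(self) -> np.ndarray:
        return (self.frame[list(PLANE_COLUMNS)] == "M").sum(axis=1).to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fused-rate arithmetic and calibration
# ---------------------------------------------------------------------------

def fused_positive_rate(
    p: float, k: int, n_planes: int = 4, rho: float = 0.0
) -> float:
    """Probability that >= k of ``n_planes`` exchangeable calls are positive.

    Each call has marginal positive probability ``p``; ``rho`` is the
    equicorrelation of the latent Gaussian vector behind the calls.  At
    rho = 0 this is the binomial tail sum_{j>=k} C(n,j) p^j (1-p)^(n-j);
    for rho > 0 the tail is integrated over the shared latent factor by
    Gauss-Hermite quadrature.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if not 1 <= k <= n_planes:
        raise ValueError("k must lie in [1, n_planes]")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if rho == 0.0:
        return float(stats.binom.sf(k - 1, n_planes, p))
    if p in (0.0, 1.0):
        return p
    z_cut = stats.norm.ppf(1.0 - p)
    nodes, weights = roots_hermitenorm(80)
    q = stats.norm.cdf((np.sqrt(rho) * nodes - z_cut) / np.sqrt(1.0 - rho))
    tail = stats.binom.sf(k - 1, n_planes, q)
    return float(np.dot(weights, tail) / np.sqrt(2.0 * np.pi))


def calibrate_to_fused_targets(
    target_sens: float,
    target_spec: float,
    k: int,
    n_planes: int = 4,
    rho: float = 0.0,
) -> tuple[float, float]:
    """Per-plane (sensitivity, false-positive rate) hitting fused targets.

    Inverts the k-of-n fused rate by monotone root finding, separately for
    the malignant arm (fused rate = ``target_sens``) and the benign arm
    (fused rate = ``1 - target_spec``); the round-trip residual is below
    1e-9.  ``rho = 0`` inverts the plain binomial tail.
    """
    for name, v in (("target_sens", target_sens), ("target_spec", target_spec)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1)")

    def invert(target: float) -> float:
        f = lambda p: fused_positive_rate(p, k, n_planes, rho) - target
        return float(brentq(f, 1e-12, 1.0 - 1e-12, xtol=1e-14, rtol=8.9e-16))

    return invert(target_sens), invert(1.0 - target_spec)


def reader_profile_from_operating_point(
    name: str,
    sensitivity: float,
    specificity: float,
    class_separation: float,
    lower_spacing: float = 0.9,
    upper_spacings: tuple[float, float] = (0.8, 1.6),
) -> ReaderProfile:
    """Reader profile whose expected dichotomized operating point is given.

    Under the ordered-probit reader model the observed score is
    N(0, s^2) for benign and N(d, s^2) for malignant lesions, with
    s^2 = 1 + noise_sd^2 and d the class separation.  Probit inversion of
    the target (sensitivity, specificity) yields the total scale
    s = d / (z_spec - z_(1-sens)) and the 4B cutpoint c2 = z_spec * s; the
    remaining cutpoints are spaced at ``lower_spacing`` and
    ``upper_spacings`` observed-scale SDs around c2.  Requires s >= 1,
    i.e. the requested operating point cannot beat a noise-free reader.
    """
    z_spec = stats.norm.ppf(specificity)
    z_miss = stats.norm.ppf(1.0 - sensitivity)
    if z_spec <= z_miss:
        raise ValueError("operating point must be above chance")
    s = class_separation / (z_spec - z_miss)
    if s < 1.0:
        raise ValueError(
            "operating point unattainable: implied score scale below the "
            "severity scale (increase class_separation or relax the target)"
        )
    noise_sd = float(np.sqrt(s * s - 1.0))
    c2 = z_spec * s
    thresholds = (
        c2 - lower_spacing * s,
        c2,
        c2 + upper_spacings[0] * s,
        c2 + upper_spacings[0] * s + upper_spacings[1] * s,
    )
    return ReaderProfile(name=name, noise_sd=noise_sd, thresholds=thresholds)


def default_config(n_lesions: int = 512, seed: int = 20180931) -> SimulationConfig:
    """Packaged default: a 512-lesion cohort matching the study conditions.

    Prevalence 39.1%; per-plane rates calibrated so the 2-of-4 fused rule
    attains sensitivity 87.5% / specificity 81.4% at the default
    inter-plane correlation; an experienced reader (noise SD 0.3)
    targeting 76.0%/92.9% and a novice targeting 60.0%/84.9% without CAD.
    """
    sigma_exp = 0.3
    s_exp = float(np.sqrt(1.0 + sigma_exp**2))
    z_spec_e = stats.norm.ppf(290 / 312)
    z_miss_e = stats.norm.ppf(1.0 - 0.76)
    d = float(s_exp * (z_spec_e - z_miss_e))
    experienced = reader_profile_from_operating_point(
        "experienced", 0.76, 290 / 312, d
    )
    novice = reader_profile_from_operating_point("novice", 0.60, 265 / 312, d)
    plane_sens, plane_fpr = calibrate_to_fused_targets(
        DEFAULT_FUSED_SENSITIVITY,
        DEFAULT_FUSED_SPECIFICITY,
        k=2,
        rho=DEFAULT_PLANE_RHO,
    )
    return SimulationConfig(
        n_lesions=n_lesions,
        prevalence=DEFAULT_PREVALENCE,
        plane_sens=plane_sens,
        plane_fpr=plane_fpr,
        plane_rho=DEFAULT_PLANE_RHO,
        reader_profiles=(novice, experienced),
        seed=seed,
        class_separation=d,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a cohort; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_lesions
    malignant = rng.random(n) < config.prevalence

    # latent severity: standard normal within class, malignant shifted up
    shared = rng.standard_normal(n)
    severity = shared + config.class_separation * malignant

    # equicorrelated plane latents; the shared factor is the within-class
    # standardized severity, which ties CAD calls to reader scores
    rho = config.plane_rho
    noise = rng.standard_normal((n, 4))
    z = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * noise
    p_class = np.where(malignant, config.plane_sens, config.plane_fpr)
    with np.errstate(divide="ignore"):
        cut = stats.norm.ppf(1.0 - p_class)  # +/- inf at p = 0 or 1
    plane_positive = z >= cut[:, None]

    data: dict[str, object] = {
        "lesion_id": [f"L{i:05d}" for i in range(n)],
        "pathology": np.where(malignant, "malignant", "benign"),
    }
    for j, col in enumerate(PLANE_COLUMNS):
        data[col] = np.where(plane_positive[:, j], "M", "B")

    labels = np.array([BiradsCategory(r).label for r in range(5)])
    for profile in config.reader_profiles:
        observed = severity + profile.noise_sd * rng.standard_normal(n)
        ranks = np.searchsorted(np.asarray(profile.thresholds), observed)
        data[f"{profile.name}_without"] = labels[ranks]

    frame = pd.DataFrame(data)
    return SyntheticCohort(config=config, frame=frame)


def recover_plane_parameters(cohort: SyntheticCohort) -> tuple[float, float]:
    """Empirical class-conditional per-plane positive rates.

    Pools the four exchangeable planes within each pathology class; returns
    (plane_sens_hat, plane_fpr_hat).
    """
    calls = (cohort.frame[list(PLANE_COLUMNS)] == "M").to_numpy()
    malignant = (cohort.frame["pathology"] == "malignant").to_numpy()
    if malignant.all() or not malignant.any():
        raise ValueError("both pathology classes must be present")
    return float(calls[malignant].mean()), float(calls[~malignant].mean())


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "n_lesions": config.n_lesions,
        "prevalence": config.prevalence,
        "plane_sens": config.plane_sens,
        "plane_fpr": config.plane_fpr,
        "plane_rho": config.plane_rho,
        "class_separation": config.class_separation,
        "seed": config.seed,
        "reader_profiles": [
            {
                "name": p.name,
                "noise_sd": p.noise_sd,
                "thresholds": list(p.thresholds),
            }
            for p in config.reader_profiles
        ],
    }


def config_from_file(path, seed: Optional[int] = None) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML/JSON key-value file.

    Keys omitted from the file fall back to the packaged default config;
    ``seed`` (if given) overrides any seed in the file.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    base = config_to_dict(default_config())
    unknown = set(raw) - set(base)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    base.update(raw)
    if seed is not None:
        base["seed"] = seed
    profiles = tuple(
        ReaderProfile(
            name=p["name"],
            noise_sd=float(p["noise_sd"]),
            thresholds=tuple(p["thresholds"]),
        )
        for p in base.pop("reader_profiles")
    )
    return SimulationConfig(reader_profiles=profiles, **base)
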