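"""Synthetic two-wave cohort generator.

Generates wide per-participant tables with the statistical structure the
latent change score analysis assumes: three latent cognitive domains (verbal
memory, working memory, processing speed) each measured by several tests, five
hippocampal MRI biomarkers treated as manifest variables, cross-wave
level/change structure, and cognition-dependent (missing-at-random) attrition
between waves.

The structural model per biomarker is an 8-variable Gaussian system
{biomarker level, biomarker change, 3 cognitive levels, 3 cognitive changes}
expressed in baseline-SD units: levels have unit variance, change SDs and
level-change covariances are derived in closed form from the calibrated
cross-wave stability r and the wave-3/wave-2 SD ratio k::

    cov(level, change) = r*k - 1,      var(change) = k^2 + 1 - 2*r*k

so that corr(w2, w3) = r and var(w3)/var(w2) = k^2 exactly.  The five
biomarkers are drawn conditionally independent given the cognitive block, with
conditional coefficients chosen so each biomarker's 8x8 structural block
matches its calibrated cross-correlations exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from . import calibration as calib

__all__ = [
    "BiomarkerCalibration",
    "IndicatorCalibration",
    "GeneratorConfig",
    "default_calibration",
    "generate_cohort",
    "apply_attrition",
    "write_cohort_csv",
    "read_cohort_csv",
    "measurement_columns",
]

STRUCT_KINDS = ("level_level", "cog_level_bio_change", "bio_level_cog_change", "change_change")


@dataclass
class BiomarkerCalibration:
    """Calibration of one manifest biomarker (native units)."""

    name: str
    mean_w2: float
    sd_w2: float
    sd_w3: float
    stability: float
    change_mean_sd: float  # standardized mean change, baseline-SD units
    #: kind -> domain -> standardized structural correlation with cognition
    paths: dict = field(default_factory=dict)
    unit: str = ""
    source: str = ""

    @property
    def sd_ratio(self) -> float:
        return self.sd_w3 / self.sd_w2

    @property
    def level_change_cov(self) -> float:
        """cov(level, change) in baseline-SD units, implied by stability."""
        return self.stability * self.sd_ratio - 1.0

    @property
    def change_var(self) -> float:
        k = self.sd_ratio
        return k * k + 1.0 - 2.0 * self.stability * k

    @property
    def change_sd(self) -> float:
        return float(np.sqrt(self.change_var))

    def path(self, kind: str, domain: str) -> float:
        return float(self.paths[kind][domain])


@dataclass
class IndicatorCalibration:
    """Calibration of one cognitive test (native units)."""

    name: str
    domain: str
    mean_w2: float
    sd_w2: float
    sd_w3: float
    stability: float
    sign: float = 1.0  # -1 if larger raw values mean worse performance


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator.

    Structural variables are generated in standardized (baseline-SD) units and
    mapped to native units through the calibrated wave-2 SDs; cognitive latent
    levels have unit variance and zero mean at wave 2.
    """

    n_wave2: int = calib.N_WAVE2
    n_wave3: int = calib.N_WAVE3
    biomarkers: dict = field(default_factory=dict)
    indicators: dict = field(default_factory=dict)
    domains: tuple = calib.DOMAINS
    #: 3x3 latent level correlations, nested dict domain -> domain
    domain_level_corr: dict = field(default_factory=dict)
    #: own-domain level -> change correlation
    domain_level_change_corr: dict = field(default_factory=dict)
    #: latent change SD in baseline-SD units, per domain
    domain_change_sd: dict = field(default_factory=dict)
    domain_change_mean_sd: dict = field(default_factory=dict)
    #: change-change correlation between different domains
    cross_domain_change_corr: float = 0.30
    #: level(d1) -> change(d2 != d1) correlation
    cross_domain_level_change_corr: float = 0.0
    attrition_slope: float = 0.5
    sex_female_prop: float = calib.FEMALE_PROP
    #: additive shift (in each measure's baseline SDs) applied to females
    sex_shift_sd: float = 0.0
    age_w2_mean_days: float = calib.AGE_W2_MEAN_YEARS * calib.DAYS_PER_YEAR
    age_w2_sd_days: float = calib.AGE_W2_SD_YEARS * calib.DAYS_PER_YEAR
    wave_gap_days: float = calib.WAVE_GAP_YEARS * calib.DAYS_PER_YEAR
    wave_gap_jitter_days: float = 30.0
    test_scan_gap_days: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in calib.TEST_SCAN_GAP_DAYS.items()}
    )
    mmse_trait_mean: float = 28.5
    mmse_trait_sd: float = 2.1
    mmse_wave_noise_sd: float = 0.8
    mmse_cognition_corr: float = 0.6
    #: force exact measurement (zero indicator residuals); testing aid
    zero_measurement_noise: bool = False
    metadata: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ #
    # structural moments

    def structural_order(self, biomarker: str) -> list:
        return (
            ["bio_level", "bio_change"]
            + [f"{d}_level" for d in self.domains]
            + [f"{d}_change" for d in self.domains]
        )

    def cognitive_correlation(self) -> np.ndarray:
        """6x6 correlation of {3 levels, 3 changes} (unit-diagonal)."""
        d = list(self.domains)
        k = len(d)
        R = np.eye(2 * k)
        for i in range(k):
            for j in range(i + 1, k):
                r = float(self.domain_level_corr[d[i]][d[j]])
                R[i, j] = R[j, i] = r
                rc = self.cross_domain_change_corr
                R[k + i, k + j] = R[k + j, k + i] = rc
        for i in range(k):
            for j in range(k):
                if i == j:
                    r = float(self.domain_level_change_corr[d[i]])
                else:
                    r = self.cross_domain_level_change_corr
                R[i, k + j] = R[k + j, i] = r
        return R

    def structural_correlation(self, biomarker: str) -> np.ndarray:
        """8x8 unit-diagonal correlation among the structural variables."""
        bio = self.biomarkers[biomarker]
        d = list(self.domains)
        k = len(d)
        n = 2 + 2 * k
        R = np.eye(n)
        R[0, 1] = R[1, 0] = bio.level_change_cov / bio.change_sd
        R[2:, 2:] = self.cognitive_correlation()
        for j, dom in enumerate(d):
            R[0, 2 + j] = R[2 + j, 0] = bio.path("level_level", dom)
            R[0, 2 + k + j] = R[2 + k + j, 0] = bio.path("bio_level_cog_change", dom)
            R[1, 2 + j] = R[2 + j, 1] = bio.path("cog_level_bio_change", dom)
            R[1, 2 + k + j] = R[2 + k + j, 1] = bio.path("change_change", dom)
        return R

    def structural_sds(self, biomarker: str) -> np.ndarray:
        bio = self.biomarkers[biomarker]
        return np.array(
            [1.0, bio.change_sd]
            + [1.0] * len(self.domains)
            + [float(self.domain_change_sd[d]) for d in self.domains]
        )

    def structural_covariance(self, biomarker: str) -> np.ndarray:
        D = self.structural_sds(biomarker)
        return self.structural_correlation(biomarker) * np.outer(D, D)

    def structural_means(self, biomarker: str) -> np.ndarray:
        bio = self.biomarkers[biomarker]
        return np.array(
            [0.0, bio.change_mean_sd]
            + [0.0] * len(self.domains)
            + [float(self.domain_change_mean_sd[d]) for d in self.domains]
        )

    # ------------------------------------------------------------------ #
    # measurement model

    def latent_w3_var(self, domain: str) -> float:
        s = float(self.domain_change_sd[domain])
        c = float(self.domain_level_change_corr[domain]) * s
        return 1.0 + s * s + 2.0 * c

    def latent_stability(self, domain: str) -> float:
        s = float(self.domain_change_sd[domain])
        c = float(self.domain_level_change_corr[domain]) * s
        return (1.0 + c) / np.sqrt(self.latent_w3_var(domain))

    def reliability(self, indicator: str) -> float:
        if self.zero_measurement_noise:
            return 1.0
        ind = self.indicators[indicator]
        rel = ind.stability / self.latent_stability(ind.domain)
        return float(np.clip(rel, 0.05, 0.98))

    def loading(self, indicator: str, oriented: bool = False) -> float:
        """Native-units loading per baseline-SD of the latent level."""
        ind = self.indicators[indicator]
        lam = np.sqrt(self.reliability(indicator)) * ind.sd_w2
        sign = 1.0 if oriented else ind.sign
        return float(sign * lam)

    def intercept(self, indicator: str, oriented: bool = False) -> float:
        ind = self.indicators[indicator]
        return float(ind.mean_w2 if not oriented or ind.sign > 0 else -ind.mean_w2)

    def residual_sd(self, indicator: str, wave: int) -> float:
        if self.zero_measurement_noise:
            return 0.0
        ind = self.indicators[indicator]
        lam2 = self.loading(indicator) ** 2
        if wave == 2:
            var = ind.sd_w2**2 - lam2
        else:
            var = ind.sd_w3**2 - lam2 * self.latent_w3_var(ind.domain)
            var = max(var, 0.02 * ind.sd_w3**2)
        return float(np.sqrt(max(var, 0.0)))

    # ------------------------------------------------------------------ #

    def validate(self) -> None:
        """Check invariants; raise ``ValueError`` naming the offence."""
        if not (0 < self.n_wave3 <= self.n_wave2):
            raise ValueError(
                f"need 0 < n_wave3 <= n_wave2, got {self.n_wave3}, {self.n_wave2}"
            )
        for name, ind in self.indicators.items():
            if ind.sd_w2 <= 0 or ind.sd_w3 <= 0:
                raise ValueError(f"indicator {name}: SDs must be positive")
            if not np.isfinite(self.loading(name)):
                raise ValueError(f"indicator {name}: non-finite loading")
        for name, bio in self.biomarkers.items():
            if bio.sd_w2 <= 0 or bio.sd_w3 <= 0:
                raise ValueError(f"biomarker {name}: SDs must be positive")
            R = self.structural_correlation(name)
            if not np.allclose(R, R.T, atol=1e-12):
                raise ValueError(f"biomarker {name}: structural matrix not symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-12):
                raise ValueError(f"biomarker {name}: structural matrix diagonal != 1")
            w = np.linalg.eigvalsh(R)
            if w[0] <= 1e-10:
                raise ValueError(
                    f"biomarker {name}: structural correlation matrix not positive "
                    f"definite (smallest eigenvalue {w[0]:.3e})"
                )

    # ------------------------------------------------------------------ #
    # population observed moments (for shared-math consistency checks)

    def observed_order(self, biomarker: str) -> list:
        inds = [i for d in self.domains for i in calib.DOMAIN_INDICATORS.get(d, ()) if i in self.indicators]
        return (
            [f"{biomarker}_w2", f"{biomarker}_w3"]
            + [f"{i}_w2" for i in inds]
            + [f"{i}_w3" for i in inds]
        )

    def population_moments(self, biomarker: str, oriented: bool = True):
        """Population mean vector and covariance of the 20 observed variables.

        ``oriented=True`` gives the moments after downstream score orientation
        (reaction time flipped so higher = better).
        """
        bio = self.biomarkers[biomarker]
        names = self.observed_order(biomarker)
        inds = [n[:-3] for n in names[2:] if n.endswith("_w2")]
        k = len(self.domains)
        nlat = 2 + 2 * k
        p = len(names)
        Lam = np.zeros((p, nlat))
        tau = np.zeros(p)
        resid = np.zeros(p)
        # biomarker rows, native units
        Lam[0, 0] = bio.sd_w2
        Lam[1, 0] = bio.sd_w2
        Lam[1, 1] = bio.sd_w2
        tau[0] = tau[1] = bio.mean_w2
        dom_ix = {d: j for j, d in enumerate(self.domains)}
        for r, ind_name in enumerate(inds):
            ind = self.indicators[ind_name]
            j = dom_ix[ind.domain]
            lam = self.loading(ind_name, oriented=oriented)
            t = self.intercept(ind_name, oriented=oriented)
            r2, r3 = 2 + r, 2 + len(inds) + r
            Lam[r2, 2 + j] = lam
            Lam[r3, 2 + j] = lam
            Lam[r3, 2 + k + j] = lam
            tau[r2] = tau[r3] = t
            resid[r2] = self.residual_sd(ind_name, 2) ** 2
            resid[r3] = self.residual_sd(ind_name, 3) ** 2
        Psi = self.structural_covariance(biomarker)
        alpha = self.structural_means(biomarker)
        mu = tau + Lam @ alpha
        Sigma = Lam @ Psi @ Lam.T + np.diag(resid)
        return names, mu, Sigma

    # ------------------------------------------------------------------ #
    # (de)serialization

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["biomarkers"] = {
            k: BiomarkerCalibration(**v) for k, v in d.get("biomarkers", {}).items()
        }
        d["indicators"] = {
            k: IndicatorCalibration(**v) for k, v in d.get("indicators", {}).items()
        }
        d["domains"] = tuple(d.get("domains", calib.DOMAINS))
        return cls(**d)


def default_calibration() -> GeneratorConfig:
    """Generator configuration transcribed from the source study's tables.

    Wave-2 means/SDs and sample sizes come from the printed descriptives;
    cross-wave stabilities from the bold diagonal of the printed correlation
    matrix; standardized mean changes from the longitudinal-change results
    text; and the biomarker-cognition structural correlations from the printed
    standardized path table (one column per biomarker, kept separate).
    """
    biomarkers = {}
    for name in calib.BIOMARKERS:
        m2, s2, _m3, s3 = calib.BIOMARKER_DESCRIPTIVES[name]
        biomarkers[name] = BiomarkerCalibration(
            name=name,
            mean_w2=m2,
            sd_w2=s2,
            sd_w3=s3,
            stability=calib.BIOMARKER_STABILITY[name],
            change_mean_sd=calib.STANDARDIZED_CHANGE[name],
            paths={k: dict(v) for k, v in calib.STRUCTURAL_PATHS[name].items()},
            source="descriptives + stability diagonal + standardized path table",
        )
    indicators = {}
    for name, (m2, s2, _m3, s3) in calib.COGNITIVE_DESCRIPTIVES.items():
        domain = next(d for d, ids in calib.DOMAIN_INDICATORS.items() if name in ids)
        indicators[name] = IndicatorCalibration(
            name=name,
            domain=domain,
            mean_w2=m2,
            sd_w2=s2,
            sd_w3=s3,
            stability=calib.COGNITIVE_STABILITY[name],
            sign=calib.COGNITIVE_SIGN[name],
        )
    level_corr = {
        "verbal_memory": {"working_memory": 0.58, "speed": 0.49},
        "working_memory": {"verbal_memory": 0.58, "speed": 0.70},
        "speed": {"verbal_memory": 0.49, "working_memory": 0.70},
    }
    cfg = GeneratorConfig(
        biomarkers=biomarkers,
        indicators=indicators,
        domain_level_corr=level_corr,
        domain_level_change_corr=dict(calib.DOMAIN_LEVEL_CHANGE_CORR),
        domain_change_sd={d: 0.5 for d in calib.DOMAINS},
        domain_change_mean_sd={d: calib.STANDARDIZED_CHANGE[d] for d in calib.DOMAINS},
        metadata={"sources": dict(calib.SOURCES)},
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------- #
# table layout helpers

AGE_COLUMNS = ("age_days_test_w2", "age_days_scan_w2", "age_days_test_w3", "age_days_scan_w3")


def measurement_columns(config: GeneratorConfig, wave: int | None = None) -> list:
    """Biomarker + cognitive measurement columns (optionally one wave)."""
    waves = (2, 3) if wave is None else (wave,)
    cols = []
    for w in waves:
        cols += [f"{b}_w{w}" for b in config.biomarkers]
        cols += [f"{i}_w{w}" for i in config.indicators]
    return cols


def wave3_columns(config: GeneratorConfig) -> list:
    return measurement_columns(config, wave=3) + ["mmse_w3", "age_days_test_w3", "age_days_scan_w3"]


# ---------------------------------------------------------------------- #
# generation


def _conditional_biomarker_draw(config, biomarker, C, mu_c, Sigma_c, rng):
    """Draw (level, change) for one biomarker given the cognitive block C.

    Gaussian conditioning reproduces the configured 8x8 joint exactly while
    keeping biomarkers conditionally independent of each other given
    cognition.
    """
    Sigma = config.structural_covariance(biomarker)
    mu = config.structural_means(biomarker)
    Sbb, Sbc, Scc = Sigma[:2, :2], Sigma[:2, 2:], Sigma[2:, 2:]
    A = Sbc @ np.linalg.inv(Scc)
    cond = Sbb - A @ Sbc.T
    w = np.linalg.eigvalsh(cond)
    if w[0] <= -1e-10:
        raise ValueError(
            f"biomarker {biomarker}: conditional covariance not positive "
            f"semi-definite (smallest eigenvalue {w[0]:.3e})"
        )
    cond = cond + 1e-14 * np.eye(2)
    L = np.linalg.cholesky(cond)
    n = C.shape[0]
    E = rng.standard_normal((n, 2))
    return mu[:2] + (C - mu_c) @ A.T + E @ L.T


def generate_cohort(config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Generate a complete (pre-attrition) cohort table.

    Returns a DataFrame indexed by participant id with demographics, MMSE, and
    all biomarker/cognitive columns at both waves; byte-identical for a fixed
    seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_wave2
    k = len(config.domains)

    sex = (rng.random(n) < config.sex_female_prop).astype(int)
    age_t2 = rng.normal(config.age_w2_mean_days, config.age_w2_sd_days, n)
    gap = config.wave_gap_days + rng.normal(0.0, config.wave_gap_jitter_days, n)
    gap = np.maximum(gap, 180.0)
    age_t3 = age_t2 + gap
    g2m, g2s = config.test_scan_gap_days["w2"]
    g3m, g3s = config.test_scan_gap_days["w3"]
    age_s2 = age_t2 + rng.normal(g2m, g2s, n)
    age_s3 = age_t3 + rng.normal(g3m, g3s, n)

    # cognitive structural block: 3 levels then 3 changes, baseline-SD units
    Rc = np.eye(2 * k)
    Rc[:, :] = config.cognitive_correlation()
    Dc = np.concatenate(
        [np.ones(k), [float(config.domain_change_sd[d]) for d in config.domains]]
    )
    Sigma_c = Rc * np.outer(Dc, Dc)
    mu_c = np.concatenate(
        [np.zeros(k), [float(config.domain_change_mean_sd[d]) for d in config.domains]]
    )
    C = mu_c + rng.standard_normal((n, 2 * k)) @ np.linalg.cholesky(Sigma_c).T

    data = {
        "sex": sex,
        "age_days_test_w2": age_t2,
        "age_days_scan_w2": age_s2,
        "age_days_test_w3": age_t3,
        "age_days_scan_w3": age_s3,
    }

    shift = config.sex_shift_sd * sex  # in baseline-SD units of each measure

    for name, bio in config.biomarkers.items():
        B = _conditional_biomarker_draw(config, name, C, mu_c, Sigma_c, rng)
        lvl, chg = B[:, 0] + shift, B[:, 1]
        w2 = bio.mean_w2 + bio.sd_w2 * lvl
        w3 = bio.mean_w2 + bio.sd_w2 * (lvl + chg)
        if name == "fa":
            w2, w3 = np.clip(w2, 0.0, 1.0), np.clip(w3, 0.0, 1.0)
        if name in ("volume", "pct_icv", "md", "t1"):
            w2, w3 = np.maximum(w2, 0.0), np.maximum(w3, 0.0)
        data[f"{name}_w2"] = w2
        data[f"{name}_w3"] = w3

    dom_ix = {d: j for j, d in enumerate(config.domains)}
    for name, ind in config.indicators.items():
        j = dom_ix[ind.domain]
        lat2 = C[:, j] + shift
        lat3 = lat2 + C[:, k + j]
        lam, tau = config.loading(name), config.intercept(name)
        e2 = rng.standard_normal(n) * config.residual_sd(name, 2)
        e3 = rng.standard_normal(n) * config.residual_sd(name, 3)
        data[f"{name}_w2"] = tau + lam * lat2 + e2
        data[f"{name}_w3"] = tau + lam * lat3 + e3

    # MMSE: a per-person trait correlated with general cognitive level,
    # observed with small wave noise, rounded and right-censored at 30
    g = C[:, :k].mean(axis=1)
    g = (g - 0.0) / np.sqrt(Sigma_c[:k, :k].mean())
    rho = config.mmse_cognition_corr
    trait = config.mmse_trait_mean + config.mmse_trait_sd * (
        rho * g + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    )
    for w in (2, 3):
        score = trait + rng.standard_normal(n) * config.mmse_wave_noise_sd
        data[f"mmse_w{w}"] = np.clip(np.round(score), 0, 30)

    df = pd.DataFrame(data, index=pd.RangeIndex(1, n + 1, name="pid"))
    order = (
        ["sex", *AGE_COLUMNS, "mmse_w2", "mmse_w3"]
        + measurement_columns(config, wave=2)
        + measurement_columns(config, wave=3)
    )
    return df[order]


# ---------------------------------------------------------------------- #
# attrition


def baseline_cognitive_composite(table: pd.DataFrame, config: GeneratorConfig) -> pd.Series:
    """Observed standardized mean of the oriented, z-scored wave-2 tests."""
    z = []
    for name, ind in config.indicators.items():
        col = table[f"{name}_w2"] * ind.sign
        z.append((col - col.mean()) / col.std(ddof=0))
    comp = pd.concat(z, axis=1).mean(axis=1)
    return (comp - comp.mean()) / comp.std(ddof=0)


def apply_attrition(table: pd.DataFrame, config: GeneratorConfig, seed: int) -> pd.DataFrame:
    """Blank wave-3 columns for non-returners.

    Retention probability is logistic in the *observed* baseline cognitive
    composite (slope ``config.attrition_slope``); the intercept is solved so
    the expected number of returners equals ``config.n_wave3``.  Missingness
    therefore depends only on observed wave-2 data (missing at random), and
    wave-2 values are never altered.
    """
    rng = np.random.default_rng(seed)
    g = baseline_cognitive_composite(table, config).to_numpy()
    target = config.n_wave3 / len(table)
    b = config.attrition_slope

    def expected(a):
        return expit(a + b * g).mean() - target

    a = brentq(expected, -20.0, 20.0)
    p = expit(a + b * g)
    keep = rng.random(len(table)) < p
    out = table.copy()
    out.loc[~keep, wave3_columns(config)] = np.nan
    out.attrs["attrition"] = {
        "intercept": float(a),
        "slope": float(b),
        "n_retained": int(keep.sum()),
        "target_retention": float(target),
    }
    return out


# ---------------------------------------------------------------------- #
# generating parameters on a model spec's scale


def generating_parameters(config: GeneratorConfig, spec) -> np.ndarray:
    """Pack the generator's population parameters as a theta vector for ``spec``.

    The model identifies each cognitive factor by fixing its marker loading to
    1, so the model's latent scale is the generator's baseline-SD scale
    multiplied by the marker's native-unit loading; all structural moments are
    rescaled accordingly.  Used for shared-math consistency checks and as the
    truth in recovery studies.
    """
    bio = config.biomarkers[spec.biomarker]
    markers = {d: spec.indicators[d][0] for d in spec.domains}
    # restrict the generator's structural block to the model's latents
    # (marginalization of a jointly Gaussian system keeps the sub-moments)
    order = config.structural_order(spec.biomarker)
    keep = [order.index(name) for name in spec.latents]
    scale = np.array(
        [bio.sd_w2, bio.sd_w2]
        + [config.loading(markers[d], oriented=True) for d in spec.domains]
        + [config.loading(markers[d], oriented=True) for d in spec.domains]
    )
    Psi_full = config.structural_covariance(spec.biomarker)
    Psi = Psi_full[np.ix_(keep, keep)] * np.outer(scale, scale)
    alpha = config.structural_means(spec.biomarker)[keep] * scale
    alpha[0] = bio.mean_w2
    loadings, intercepts, resid = {}, {}, {}
    for d in spec.domains:
        lam_m = config.loading(markers[d], oriented=True)
        for ind in spec.indicators[d]:
            loadings[ind] = config.loading(ind, oriented=True) / lam_m
            intercepts[ind] = config.intercept(ind, oriented=True)
            resid[(ind, 2)] = config.residual_sd(ind, 2) ** 2
            resid[(ind, 3)] = config.residual_sd(ind, 3) ** 2
    return spec.pack(loadings, intercepts, resid, alpha, Psi)


# ---------------------------------------------------------------------- #
# I/O


def write_cohort_csv(table: pd.DataFrame, path, config: GeneratorConfig | None = None, seed=None):
    """Write the cohort as CSV (empty field = missing) plus a YAML sidecar."""
    path = str(path)
    table.to_csv(path, index=True, na_rep="")
    if config is not None:
        sidecar = path[:-4] + ".config.yaml" if path.endswith(".csv") else path + ".config.yaml"
        payload = {"seed": seed, "generator": config.to_dict()}
        with open(sidecar, "w") as fh:
            yaml.safe_dump(payload, fh, default_flow_style=False, sort_keys=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="pid")
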