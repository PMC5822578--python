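"""Latent change score model specification and implied moments.

One model couples a single manifest hippocampal biomarker (two waves) to
latent cognitive domains, each measured by the same indicators at both waves
under strong measurement invariance (equal loadings and intercepts across
waves).  Wave-3 constructs are decomposed through fixed unit paths as

    level_w3 = level_w2 + change

with zero disturbance, so the latent change variable is exactly the
difference of the two occasions.  The biomarker enters as two manifest
columns: its wave-2 column *is* its level and its wave-3 column is exactly
level + change (no residual).

Free parameters: non-marker loadings, indicator intercepts (one per
indicator, shared across waves), per-wave indicator residual variances (log
scale), the biomarker level mean, all change means (cognitive level means are
fixed at 0; intercepts carry location), and the full symmetric covariance of
the structural variables, parameterized by a log-Cholesky factor so any
parameter vector maps to an admissible (positive definite) covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import calibration as calib

__all__ = [
    "ModelSpec",
    "MomentStructure",
    "build_model_spec",
    "implied_moments",
    "degrees_of_freedom",
    "DEFAULT_INDICATOR_MAP",
]

DEFAULT_INDICATOR_MAP = {
    ind: dom for dom, inds in calib.DOMAIN_INDICATORS.items() for ind in inds
}

#: alternative roster with memory and span subtests entered separately
#: (immediate/delayed recall; forward/backward span), 12 indicators per wave
ROSTER12_MAP = {
    "logical_memory_immediate": "verbal_memory",
    "logical_memory_delayed": "verbal_memory",
    "verbal_pairs_immediate": "verbal_memory",
    "verbal_pairs_delayed": "verbal_memory",
    "spatial_span_forward": "working_memory",
    "spatial_span_backward": "working_memory",
    "digit_backward": "working_memory",
    "letter_number": "working_memory",
    "digit_symbol": "speed",
    "symbol_search": "speed",
    "choice_rt": "speed",
    "inspection_time": "speed",
}


@dataclass
class MomentStructure:
    """Model-implied mean vector and covariance matrix."""

    mu: np.ndarray
    Sigma: np.ndarray


@dataclass
class ModelSpec:
    """Structural description of one latent change score model.

    Parameters are packed into a flat ``theta`` vector in blocks:
    free loadings, intercepts, log residual variances (wave 2 then wave 3),
    structural means (biomarker level, biomarker change, one change mean per
    domain), and the log-Cholesky factor of the structural covariance
    (diagonal entries on the log scale, row-major lower triangle).
    """

    biomarker: str
    domains: tuple
    indicators: dict  # domain -> ordered tuple of indicator names

    # derived layout (filled in __post_init__)
    observed: tuple = field(default=(), init=False)
    latents: tuple = field(default=(), init=False)
    indicator_list: tuple = field(default=(), init=False)

    def __post_init__(self):
        seen = {}
        for dom in self.domains:
            for ind in self.indicators[dom]:
                if ind in seen:
                    raise ValueError(
                        f"indicator {ind!r} assigned to both {seen[ind]!r} and {dom!r}"
                    )
                seen[ind] = dom
        self.indicator_list = tuple(ind for d in self.domains for ind in self.indicators[d])
        self.observed = (
            (f"{self.biomarker}_w2", f"{self.biomarker}_w3")
            + tuple(f"{i}_w2" for i in self.indicator_list)
            + tuple(f"{i}_w3" for i in self.indicator_list)
        )
        self.latents = (
            ("bio_level", "bio_change")
            + tuple(f"{d}_level" for d in self.domains)
            + tuple(f"{d}_change" for d in self.domains)
        )
        self._dom_ix = {d: j for j, d in enumerate(self.domains)}
        self._ind_dom = {ind: d for d in self.domains for ind in self.indicators[d]}
        self._markers = {d: self.indicators[d][0] for d in self.domains}
        self._free_loadings = tuple(
            ind
            for d in self.domains
            for ind in self.indicators[d]
            if ind != self._markers[d]
        )

    # ------------------------------------------------------------------ #
    # layout

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_latent(self) -> int:
        return len(self.latents)

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_list)

    @property
    def n_free(self) -> int:
        k = self.n_latent
        return (
            len(self._free_loadings)
            + self.n_indicators  # intercepts
            + 2 * self.n_indicators  # residual variances per wave
            + 2
            + len(self.domains)  # structural means
            + k * (k + 1) // 2  # structural covariance (log-Cholesky)
        )

    @property
    def parameter_names(self) -> list:
        names = [f"loading[{i}]" for i in self._free_loadings]
        names += [f"intercept[{i}]" for i in self.indicator_list]
        names += [f"log_resid[{i}_w{w}]" for w in (2, 3) for i in self.indicator_list]
        names += ["mean[bio_level]", "mean[bio_change]"]
        names += [f"mean[{d}_change]" for d in self.domains]
        for i in range(self.n_latent):
            for j in range(i + 1):
                tag = "log_chol" if i == j else "chol"
                names.append(f"{tag}[{self.latents[i]},{self.latents[j]}]")
        return names

    def _blocks(self):
        nl, ni, nd = len(self._free_loadings), self.n_indicators, len(self.domains)
        k = self.n_latent
        sizes = [nl, ni, 2 * ni, 2 + nd, k * (k + 1) // 2]
        offs = np.cumsum([0] + sizes)
        return offs

    # ------------------------------------------------------------------ #
    # pack / unpack

    def pack(self, loadings: dict, intercepts: dict, resid_var: dict, alpha: np.ndarray, Psi: np.ndarray) -> np.ndarray:
        """Pack named parameter values into a theta vector.

        ``loadings``/``intercepts`` map indicator name -> value;
        ``resid_var`` maps (indicator, wave) -> variance; ``alpha`` is the
        structural mean vector (cognitive level entries ignored, fixed 0);
        ``Psi`` the structural covariance.
        """
        theta = np.empty(self.n_free)
        offs = self._blocks()
        theta[offs[0] : offs[1]] = [loadings[i] for i in self._free_loadings]
        theta[offs[1] : offs[2]] = [intercepts[i] for i in self.indicator_list]
        lv = [resid_var[(i, w)] for w in (2, 3) for i in self.indicator_list]
        theta[offs[2] : offs[3]] = np.log(np.maximum(lv, 1e-12))
        k = self.n_latent
        nd = len(self.domains)
        means = [alpha[0], alpha[1]] + [alpha[2 + nd + j] for j in range(nd)]
        theta[offs[3] : offs[4]] = means
        L = np.linalg.cholesky(Psi)
        vals = []
        for i in range(k):
            for j in range(i + 1):
                vals.append(np.log(L[i, i]) if i == j else L[i, j])
        theta[offs[4] :] = vals
        return theta

    def unpack(self, theta: np.ndarray):
        """theta -> (loadings vector over all indicators, tau, resid_var (ni,2), alpha, Psi)."""
        theta = np.asarray(theta, dtype=float)
        offs = self._blocks()
        free = dict(zip(self._free_loadings, theta[offs[0] : offs[1]]))
        lam = np.array(
            [1.0 if i in self._markers.values() else free[i] for i in self.indicator_list]
        )
        tau = theta[offs[1] : offs[2]].copy()
        rv = np.exp(theta[offs[2] : offs[3]]).reshape(2, self.n_indicators)
        k, nd = self.n_latent, len(self.domains)
        m = theta[offs[3] : offs[4]]
        alpha = np.zeros(k)
        alpha[0], alpha[1] = m[0], m[1]
        alpha[2 + nd :] = m[2:]
        L = np.zeros((k, k))
        vals = iter(theta[offs[4] :])
        for i in range(k):
            for j in range(i + 1):
                v = next(vals)
                L[i, j] = np.exp(v) if i == j else v
        Psi = L @ L.T
        return lam, tau, rv, alpha, Psi

    # ------------------------------------------------------------------ #
    # implied moments

    def effect_matrix(self, lam: np.ndarray) -> np.ndarray:
        """Total-effect matrix of the structural variables on the observed."""
        p, k, nd = self.n_observed, self.n_latent, len(self.domains)
        ni = self.n_indicators
        Lam = np.zeros((p, k))
        Lam[0, 0] = 1.0
        Lam[1, 0] = Lam[1, 1] = 1.0
        for r, ind in enumerate(self.indicator_list):
            d = self._dom_ix[self._ind_dom[ind]]
            Lam[2 + r, 2 + d] = lam[r]
            Lam[2 + ni + r, 2 + d] = lam[r]
            Lam[2 + ni + r, 2 + nd + d] = lam[r]
        return Lam

    def implied_moments(self, theta: np.ndarray) -> MomentStructure:
        lam, tau, rv, alpha, Psi = self.unpack(theta)
        ni = self.n_indicators
        Lam = self.effect_matrix(lam)
        tau_full = np.zeros(self.n_observed)
        tau_full[2 : 2 + ni] = tau
        tau_full[2 + ni :] = tau
        mu = tau_full + Lam @ alpha
        resid = np.zeros(self.n_observed)
        resid[2 : 2 + ni] = rv[0]
        resid[2 + ni :] = rv[1]
        Sigma = Lam @ Psi @ Lam.T + np.diag(resid)
        Sigma = 0.5 * (Sigma + Sigma.T)
        return MomentStructure(mu=mu, Sigma=Sigma)

    def degrees_of_freedom(self) -> int:
        p = self.n_observed
        return p * (p + 1) // 2 + p - self.n_free

    # ------------------------------------------------------------------ #

    def structural_index(self, name: str) -> int:
        return self.latents.index(name)

    def to_text(self) -> str:
        """Human-readable roster and fixed/free pattern."""
        lines = [
            f"latent change score model: biomarker = {self.biomarker}",
            f"observed variables ({self.n_observed}): " + ", ".join(self.observed),
            f"structural variables ({self.n_latent}): " + ", ".join(self.latents),
            "fixed: wave-3 construct = level + change (unit paths, zero disturbance);",
            "       biomarker manifest at both waves (zero residual);",
            "       marker loading per domain = 1; cognitive level means = 0;",
            "       loadings and intercepts invariant across waves",
        ]
        for d in self.domains:
            marker = self._markers[d]
            lines.append(
                f"domain {d}: marker {marker} (loading fixed 1), free: "
                + ", ".join(i for i in self.indicators[d] if i != marker)
            )
        lines.append(f"free parameters: {self.n_free}; degrees of freedom: {self.degrees_of_freedom()}")
        return "\n".join(lines)


def build_model_spec(biomarker: str, indicator_map: dict | None = None) -> ModelSpec:
    """Build the canonical three-domain spec for one hippocampal biomarker.

    ``indicator_map`` maps indicator name -> domain; the default is the
    9-test roster (verbal memory: logical memory, verbal paired associates;
    working memory: spatial span, digit span backward, letter-number
    sequencing; speed: digit-symbol, symbol search, choice reaction time,
    inspection time).
    """
    if biomarker not in calib.BIOMARKERS:
        raise ValueError(f"unknown biomarker {biomarker!r}; expected one of {calib.BIOMARKERS}")
    imap = dict(DEFAULT_INDICATOR_MAP) if indicator_map is None else dict(indicator_map)
    domains = tuple(dict.fromkeys(imap.values()))
    indicators = {d: tuple(i for i, dd in imap.items() if dd == d) for d in domains}
    return ModelSpec(biomarker=biomarker, domains=domains, indicators=indicators)


def implied_moments(spec: ModelSpec, theta: np.ndarray) -> MomentStructure:
    return spec.implied_moments(theta)


def degrees_of_freedom(spec: ModelSpec) -> int:
    return spec.degrees_of_freedom()
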