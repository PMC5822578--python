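"""Result surfaces: fit indices, typed structural correlations with FDR,
standardized mean-change tests, cross-wave stabilities, and the MMSE
sensitivity filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fiml import FittedModel, ReferenceFit, standardize

__all__ = [
    "FitIndices",
    "fit_indices",
    "extract_structural_correlations",
    "fdr_adjust",
    "mean_change_summary",
    "cross_wave_stability",
    "mmse_exclusion_filter",
]

#: Table row order of the structural-correlation surface
KIND_ORDER = ("level_level", "cog_level_bio_change", "bio_level_cog_change", "change_change")
DOMAIN_ORDER = ("working_memory", "verbal_memory", "speed")


@dataclass
class FitIndices:
    """Chi-square and derived absolute/incremental fit indices."""

    chi2: float
    df: int
    p: float
    rmsea: float
    cfi: float
    tli: float
    tli_clamped: float
    n: int
    rmsea_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "rmsea": self.rmsea,
            "cfi": self.cfi,
            "tli": self.tli,
            "tli_clamped": self.tli_clamped,
            "n": self.n,
        }


def fit_indices(
    chi2_or_model,
    df_model: int | ReferenceFit = None,
    n: int | ReferenceFit = None,
    chi2_baseline: float | None = None,
    df_baseline: int | None = None,
    baseline: ReferenceFit | None = None,
    saturated: ReferenceFit | None = None,
) -> FitIndices:
    """Compute chi-square, RMSEA, CFI and TLI.

    Two call forms: ``fit_indices(fitted, saturated=..., baseline=..., n=...)``
    derives the chi-squares from log-likelihoods; or pass precomputed scalars
    ``fit_indices(chi2, df, n, chi2_baseline, df_baseline)`` (the latter two
    optional — without them only RMSEA is meaningful and CFI/TLI are NaN).

    RMSEA = sqrt(max(chi2 - df, 0) / (df * n)); it is 0 whenever chi2 <= df.
    """
    if isinstance(chi2_or_model, FittedModel):
        fitted = chi2_or_model
        if saturated is None:
            raise ValueError("saturated fit required")
        chi2 = max(0.0, 2.0 * (saturated.loglik - fitted.loglik))
        dfm = fitted.spec.degrees_of_freedom()
        nn = fitted.n_used if n is None else int(n)
        if baseline is not None:
            chi2_b = max(0.0, 2.0 * (saturated.loglik - baseline.loglik))
            p = fitted.spec.n_observed
            df_b = p * (p + 1) // 2 + p - baseline.n_params
        else:
            chi2_b, df_b = np.nan, 0
    else:
        chi2 = max(0.0, float(chi2_or_model))
        dfm = int(df_model)
        nn = int(n)
        chi2_b = np.nan if chi2_baseline is None else float(chi2_baseline)
        df_b = 0 if df_baseline is None else int(df_baseline)

    rmsea_defined = dfm > 0
    if rmsea_defined:
        rmsea = float(np.sqrt(max(chi2 - dfm, 0.0) / (dfm * nn)))
        p_val = float(stats.chi2.sf(chi2, dfm))
    else:
        rmsea, p_val = 0.0, np.nan

    if np.isfinite(chi2_b) and df_b > 0 and dfm > 0:
        num = max(chi2 - dfm, 0.0)
        den = max(chi2_b - df_b, chi2 - dfm, 0.0)
        cfi = 1.0 - (num / den if den > 0 else 0.0)
        ratio_b = chi2_b / df_b
        tli = (ratio_b - chi2 / dfm) / (ratio_b - 1.0) if ratio_b != 1.0 else np.nan
    else:
        cfi, tli = np.nan, np.nan
    tli_clamped = float(np.clip(tli, 0.0, 1.0)) if np.isfinite(tli) else np.nan
    return FitIndices(
        chi2=float(chi2),
        df=dfm,
        p=p_val,
        rmsea=rmsea,
        cfi=float(cfi) if np.isfinite(cfi) else np.nan,
        tli=float(tli) if np.isfinite(tli) else np.nan,
        tli_clamped=tli_clamped,
        n=nn,
        rmsea_defined=rmsea_defined,
    )


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1, mapped back to the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def extract_structural_correlations(fitted: FittedModel, alpha: float = 0.05) -> pd.DataFrame:
    """The 12 biomarker-cognition standardized structural correlations.

    Four kinds (level-level, cognitive level predicting biomarker change,
    biomarker level predicting cognitive change, change-change) by three
    domains, with delta-method SEs, Wald p-values and per-model BH-FDR
    adjustment over this 12-test family.
    """
    std = standardize(fitted)
    spec = fitted.spec
    idx = {(r.var1, r.var2): r for r in std.itertuples()}

    def lookup(a, b):
        return idx.get((a, b)) or idx[(b, a)]

    doms = [d for d in DOMAIN_ORDER if d in spec.domains]
    doms += [d for d in spec.domains if d not in doms]
    rows = []
    for kind in KIND_ORDER:
        for dom in doms:
            if kind == "level_level":
                r = lookup("bio_level", f"{dom}_level")
            elif kind == "cog_level_bio_change":
                r = lookup(f"{dom}_level", "bio_change")
            elif kind == "bio_level_cog_change":
                r = lookup("bio_level", f"{dom}_change")
            else:
                r = lookup("bio_change", f"{dom}_change")
            rows.append(
                {
                    "biomarker": spec.biomarker,
                    "kind": kind,
                    "domain": dom,
                    "estimate": r.estimate,
                    "se": r.se,
                    "p": r.p,
                }
            )
    out = pd.DataFrame(rows)
    pvals = out["p"].to_numpy()
    if np.all(np.isfinite(pvals)):
        out["p_fdr"] = fdr_adjust(pvals)
        out["survives_fdr"] = out["p_fdr"] < alpha
    else:
        out["p_fdr"] = np.nan
        out["survives_fdr"] = False
    return out


def mean_change_summary(fitted: FittedModel) -> pd.DataFrame:
    """Mean change per structural change variable, native and baseline-SD units.

    z is the Wald statistic of the native-units change mean; the SD-units
    value divides by the model-implied SD of the corresponding baseline
    level.
    """
    spec = fitted.spec
    std = standardize(fitted)
    names = fitted.param_names
    rows = []
    change_vars = ["bio_change"] + [f"{d}_change" for d in spec.domains]
    alpha = fitted.structural_means()
    for ch in change_vars:
        pname = "mean[bio_change]" if ch == "bio_change" else f"mean[{ch}]"
        j = names.index(pname)
        est = alpha[spec.structural_index(ch)]
        se = fitted.se[j]
        z = est / se if se > 0 else np.nan
        srow = std[(std.kind == "std_change_mean") & (std.var1 == ch)].iloc[0]
        label = spec.biomarker if ch == "bio_change" else ch[: -len("_change")]
        rows.append(
            {
                "variable": label,
                "change_native": est,
                "change_sd_units": srow.estimate,
                "se_sd_units": srow.se,
                "z": z,
                "p": 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def cross_wave_stability(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Complete-pairs Pearson r between wave-2 and wave-3 of each variable."""
    bases = sorted(
        {c[:-3] for c in table.columns if c.endswith("_w2") and f"{c[:-3]}_w3" in table.columns}
    )
    rows = []
    for b in bases:
        x = table[f"{b}_w2"].to_numpy(dtype=float)
        y = table[f"{b}_w3"].to_numpy(dtype=float)
        m = np.isfinite(x) & np.isfinite(y)
        n = int(m.sum())
        if n < min_pairs or np.std(x[m]) == 0 or np.std(y[m]) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x[m], y[m])[0, 1])
        rows.append({"variable": b, "r": r, "n_pairs": n, "defined": n >= min_pairs})
    return pd.DataFrame(rows).set_index("variable")


def mmse_exclusion_filter(table: pd.DataFrame, cutoff: int = 24):
    """Drop participants scoring below the MMSE cutoff at any wave.

    Returns (filtered table, number removed); a missing MMSE never triggers
    removal.
    """
    cols = [c for c in table.columns if c.startswith("mmse_w")]
    if not cols:
        raise ValueError("no MMSE columns present")
    below = pd.concat([table[c] < cutoff for c in cols], axis=1).any(axis=1)
    return table.loc[~below].copy(), int(below.sum())
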