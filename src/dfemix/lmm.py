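"""Linear mixed-model test for a directional effect of mutation number.

Growth rate is regressed on the number of carried mutations (total or of a
specific type) with mating type and introgressed-region markers as fixed
factors and MA line, haplotype and assay plate as random factors.  The
count term is tested by a likelihood-ratio test between nested ML fits
(ML, not REML, since the models differ in a fixed effect), with the
statistic referred to a chi-square with 1 degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = ["fit_growth_lmm", "lrt_count", "lrt_table", "lrt_from_logliks"]

LOGLIK_TOL = 1e-8


def lrt_from_logliks(loglik_full: float, loglik_reduced: float) -> tuple[float, float]:
    """Chi-square statistic and p-value (df = 1) for nested ML fits.

    The statistic 2*(logL_full - logL_reduced) is clipped at zero (a warning
    is emitted upstream when the deficit exceeds the convergence tolerance);
    identical log likelihoods give statistic 0 and p = 1.
    """
    stat = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


@dataclass
class LmmFit:
    """Thin wrapper around a converged ML mixed-model fit."""

    loglik: float
    fixed_effects: pd.Series
    variance_components: dict
    converged: bool
    result: object


def _build_vc(data: pd.DataFrame, random_factors) -> dict:
    """Variance-component formulas for random factors with >= 2 levels.

    Single-level factors (e.g. the MA-line factor in a within-cross
    analysis) are dropped with a warning.
    """
    vc = {}
    for factor in random_factors:
        if factor not in data.columns:
            raise KeyError(f"random factor {factor!r} missing from data")
        if data[factor].nunique() < 2:
            warnings.warn(
                f"random factor {factor!r} has a single level and is dropped"
            )
            continue
        vc[factor] = f"0 + C({factor})"
    return vc


def fit_growth_lmm(
    data: pd.DataFrame,
    include_count: bool = True,
    count_col: str = "n_mutations",
    response: str = "growth_rate",
    fixed_factors: tuple[str, ...] = (),
    random_factors: tuple[str, ...] = ("line", "haplotype", "plate"),
) -> LmmFit:
    """ML fit of the growth-rate mixed model, with or without the count term."""
    terms = [count_col] if include_count else []
    terms += [f"C({f})" for f in fixed_factors]
    formula = f"{response} ~ " + (" + ".join(terms) if terms else "1")
    vc = _build_vc(data, random_factors)
    groups = np.ones(len(data))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            formula, data, groups=groups, vc_formula=vc, re_formula="0"
        )
        res = None
        for method in ("lbfgs", "bfgs", "cg"):
            cand = model.fit(reml=False, method=method, maxiter=500)
            if res is None or (
                np.isfinite(cand.llf) and cand.llf > res.llf + LOGLIK_TOL
            ):
                res = cand
            if bool(res.converged) and np.isfinite(res.llf):
                break
    converged = bool(res.converged) and np.isfinite(res.llf)
    vcomp = dict(zip(vc.keys(), np.atleast_1d(res.vcomp))) if vc else {}
    return LmmFit(
        loglik=float(res.llf),
        fixed_effects=res.fe_params,
        variance_components=vcomp,
        converged=converged,
        result=res,
    )


def lrt_count(
    data: pd.DataFrame,
    count_col: str = "n_mutations",
    response: str = "growth_rate",
    fixed_factors: tuple[str, ...] = (),
    random_factors: tuple[str, ...] = ("line", "haplotype", "plate"),
) -> dict:
    """Likelihood-ratio test of the mutation-count fixed effect (df = 1).

    Returns the chi-square statistic (clipped at zero up to the convergence
    tolerance), the p-value, the count coefficient, and both fits.
    """
    kwargs = dict(
        count_col=count_col,
        response=response,
        fixed_factors=fixed_factors,
        random_factors=random_factors,
    )
    full = fit_growth_lmm(data, include_count=True, **kwargs)
    reduced = fit_growth_lmm(data, include_count=False, **kwargs)
    if not (full.converged and reduced.converged):
        warnings.warn("mixed-model fit did not converge; LRT is unreliable")
    raw = 2.0 * (full.loglik - reduced.loglik)
    if raw < -LOGLIK_TOL * max(1.0, abs(full.loglik)):
        warnings.warn(f"negative LRT statistic {raw:.3g} clipped to 0")
    stat, p = lrt_from_logliks(full.loglik, reduced.loglik)
    return {
        "statistic": float(stat),
        "p_value": p,
        "df": 1,
        "coefficient": float(full.fixed_effects.get(count_col, np.nan)),
        "full": full,
        "reduced": reduced,
        "converged": full.converged and reduced.converged,
    }


def lrt_table(
    data: pd.DataFrame,
    count_cols: tuple[str, ...] = ("n_mutations",),
    cross_col: str | None = "cross",
    **kwargs,
) -> pd.DataFrame:
    """Per-cross and combined LRTs, one row per (cross, count type)."""
    rows = []
    groups: list[tuple[str, pd.DataFrame]] = []
    if cross_col is not None and cross_col in data.columns:
        groups += [(str(c), g) for c, g in data.groupby(cross_col)]
    groups.append(("combined", data))
    for name, grp in groups:
        for col in count_cols:
            res = lrt_count(grp, count_col=col, **kwargs)
            rows.append(
                {
                    "cross": name,
                    "count_type": col,
                    "chi_square": res["statistic"],
                    "p_value": res["p_value"],
                    "coefficient": res["coefficient"],
                    "converged": res["converged"],
                }
            )
    return pd.DataFrame(rows)
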