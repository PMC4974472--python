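"""Mixed-effects models for the four biodiversity measures.

Fixed effects follow the study design (protection status, land use and
their interaction, management group, size/age class, use intensity, plus
elevation / slope / agricultural-suitability confounders); random
intercepts for study and for spatial block within study absorb
between-study methodological differences and local spatial structure.

Families: within-sample richness is modelled as Poisson with a log link
(an observation-level random intercept is added when the Pearson
dispersion exceeds 1.5); total abundance and rarefied richness as Gaussian
on ln(x+1); endemicity as Gaussian on the community-weighted mean log10
range size, whose contrasts are negated for reporting (endemicity is its
reciprocal, so inference is identical up to sign). All fits maximize the
full likelihood (ML, not REML) so that likelihood-ratio tests between
nested fixed structures are valid; model simplification is backward
elimination on those tests, dropping the weakest term until every
remaining droppable term has P < 0.05 while never violating marginality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from paeffect._laplace import PoissonLaplaceGLMM
from paeffect.constants import (
    INTENSITIES,
    LAND_USES,
    MANAGEMENT_GROUPS,
    MEASURES,
    SIZE_AGE_CLASSES,
    TROPIC_LATITUDE,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "Contrast",
    "fit_mixed_model",
    "likelihood_ratio_test",
    "backward_eliminate",
    "percent_difference",
    "contrast_from_vector",
    "fit_measure_suite",
    "prepare_analysis_table",
]

CONFOUNDERS = ("elevation", "slope", "ag_suitability")

# Response -> (analysis column, family, transform applied to the raw column)
_RESPONSE_MAP = {
    "richness": ("richness", "poisson", None),
    "abundance": ("log_abundance", "gaussian", "log1p"),
    "rarefied_richness": ("log_rarefied", "gaussian", "log1p"),
    "endemicity": ("cwm_log10_range", "gaussian", None),
}


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    ``fixed`` lists terms by column name, with ``a:b`` for interactions;
    marginality is enforced structurally (an interaction protects its main
    effects from elimination). ``keep`` holds terms of scientific interest
    that backward elimination must never test (the headline protection
    term). ``random`` may contain "study", "block" (nested in study) and
    "obs" (observation-level intercept for overdispersion).
    """

    response: str
    family: str | None = None  # None -> family implied by the response
    fixed: list[str] = field(default_factory=lambda: ["protected"])
    random: list[str] = field(default_factory=lambda: ["study", "block"])
    keep: set[str] = field(default_factory=lambda: {"protected"})

    def __post_init__(self) -> None:
        if self.response not in _RESPONSE_MAP:
            raise ValueError(f"unknown response {self.response!r}")
        if self.family is None:
            self.family = _RESPONSE_MAP[self.response][1]
        if self.family not in ("poisson", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        bad = set(self.random) - {"study", "block", "obs"}
        if bad:
            raise ValueError(f"unknown random terms {sorted(bad)}")
        for t in self.fixed:
            for f in t.split(":"):
                if not f.isidentifier():
                    raise ValueError(f"malformed term {t!r}")


@dataclass
class FitResult:
    """Fixed-effect estimates and variance components from one ML fit."""

    params: pd.Series
    se: pd.Series
    cov_params: pd.DataFrame
    var_components: dict[str, float]
    loglik: float
    converged: bool
    singular: bool
    n_obs: int
    n_studies: int
    family: str
    response: str
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...]
    term_columns: dict[str, list[str]]
    df_fixed: int
    dispersion: float | None = None
    factor_levels: dict[str, list[str]] | None = None

    def coef(self, name: str) -> tuple[float, float]:
        if name not in self.params.index:
            raise KeyError(f"coefficient {name!r} not in model")
        return float(self.params[name]), float(self.se[name])


@dataclass(frozen=True)
class LRTResult:
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class Contrast:
    label: str
    percent_difference: float
    ci_low: float
    ci_high: float
    estimate: float  # link-scale effect
    se: float


# ---------------------------------------------------------------------------
# analysis table preparation


def prepare_analysis_table(measures: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Join site measures with classified sites and add model columns.

    Adds transformed responses, z-scored confounders, the latitudinal zone
    (tropical iff |latitude| <= 23.43665 degrees) and categorical columns
    with explicit reference levels (unprotected; primary vegetation;
    minimal intensity).
    """
    df = sites.merge(measures, on="site_id", how="left")
    df["protected"] = df["protected"].astype(int)
    with np.errstate(invalid="ignore"):
        df["log_abundance"] = np.log1p(df["abundance"])
        df["log_rarefied"] = np.log1p(df["rarefied_richness"])
    for c in CONFOUNDERS:
        sd = df[c].std(ddof=0)
        df[c + "_z"] = (df[c] - df[c].mean()) / (sd if sd > 0 else 1.0)
    df["latitudinal_zone"] = pd.Categorical(
        np.where(df["latitude"].abs() <= TROPIC_LATITUDE, "tropical", "temperate"),
        categories=["tropical", "temperate"],
    )
    df["land_use"] = pd.Categorical(df["land_use"], categories=list(LAND_USES))
    df["use_intensity"] = pd.Categorical(df["use_intensity"], categories=list(INTENSITIES))
    df["management_group"] = pd.Categorical(
        df["management_group"], categories=list(MANAGEMENT_GROUPS)
    )
    df["size_age_class"] = pd.Categorical(
        df["size_age_class"], categories=list(SIZE_AGE_CLASSES)
    )
    return df


def _model_frame(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, str]:
    ycol = _RESPONSE_MAP[spec.response][0]
    cols = {ycol, "study_id", "block_id"}
    for t in spec.fixed:
        cols.update(t.split(":"))
    missing = cols - set(data.columns)
    if missing:
        raise ValueError(f"analysis table lacks columns {sorted(missing)}")
    frame = data[sorted(cols)].copy()
    n0 = len(frame)
    frame = frame.dropna()
    # Categorical columns may carry unused levels after subsetting.
    for c in frame.columns:
        if isinstance(frame[c].dtype, pd.CategoricalDtype):
            frame[c] = frame[c].cat.remove_unused_categories()
    if len(frame) < n0:
        logger.info(
            "%s model: dropped %d rows with undefined response/covariates",
            spec.response,
            n0 - len(frame),
        )
    if frame["study_id"].nunique() < 1 or len(frame) <= len(spec.fixed) + 1:
        raise ValueError(f"too few rows to fit the {spec.response} model")
    return frame.reset_index(drop=True), ycol


def _design(frame: pd.DataFrame, fixed: list[str]):
    formula = "1" if not fixed else "1 + " + " + ".join(fixed)
    dm = patsy.dmatrix(formula, frame, return_type="dataframe")
    di = dm.design_info
    term_columns = {
        term.name(): list(dm.columns[slc]) for term, slc in di.term_slices.items()
    }
    return dm, term_columns


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one mixed model by maximum likelihood.

    Gaussian responses use a linear mixed model with profiled residual
    variance; Poisson responses use the in-package Laplace-approximated
    marginal likelihood. Rows with undefined response or covariates are
    dropped (logged). With a single study the study intercept is confounded
    with the fixed intercept and the fit degrades gracefully to the model
    without it (ordinary least squares in the no-random-term limit).
    """
    frame, ycol = _model_frame(data, spec)
    return _fit_frame(frame, ycol, spec)


def _fit_frame(
    frame: pd.DataFrame, ycol: str, spec: ModelSpec, robust: bool = False
) -> FitResult:
    dm, term_columns = _design(frame, spec.fixed)
    y = frame[ycol].to_numpy(dtype=float)
    n_studies = frame["study_id"].nunique()
    if spec.family == "poisson":
        res = _fit_poisson(frame, y, dm, spec)
    else:
        res = _fit_gaussian(frame, y, dm, spec, n_studies, robust=robust)
    params = pd.Series(res["beta"], index=dm.columns)
    se = pd.Series(res["se"], index=dm.columns)
    cov = pd.DataFrame(res["cov_beta"], index=dm.columns, columns=dm.columns)
    factor_levels = {
        c: list(frame[c].cat.categories)
        for c in frame.columns
        if isinstance(frame[c].dtype, pd.CategoricalDtype)
    }
    return FitResult(
        params=params,
        se=se,
        cov_params=cov,
        var_components=res["sigma2"],
        loglik=res["loglik"],
        converged=res["converged"],
        singular=res["singular"],
        n_obs=len(frame),
        n_studies=n_studies,
        family=spec.family,
        response=spec.response,
        fixed_terms=tuple(spec.fixed),
        random_terms=tuple(spec.random),
        term_columns=term_columns,
        df_fixed=dm.shape[1],
        dispersion=res.get("dispersion"),
        factor_levels=factor_levels,
    )


def _factor_codes(frame: pd.DataFrame, spec: ModelSpec) -> dict[str, np.ndarray]:
    factors: dict[str, np.ndarray] = {}
    if "study" in spec.random and frame["study_id"].nunique() > 1:
        factors["study"] = pd.factorize(frame["study_id"])[0]
    if "block" in spec.random:
        block_key = frame["study_id"].astype(str) + "/" + frame["block_id"].astype(str)
        if block_key.nunique() > frame["study_id"].nunique():
            factors["block"] = pd.factorize(block_key)[0]
    if "obs" in spec.random:
        factors["obs"] = np.arange(len(frame))
    return factors


def _fit_poisson(frame, y, dm, spec) -> dict:
    factors = _factor_codes(frame, spec)
    if not factors:
        factors = {"study": np.zeros(len(frame), dtype=int)}
    model = PoissonLaplaceGLMM(y, dm.to_numpy(), factors)
    res = model.fit()
    mu = res["mu"]
    p = dm.shape[1]
    res["dispersion"] = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12)) / max(len(y) - p, 1))
    res["sigma2"] = {f"sigma2_{k}": v for k, v in res["sigma2"].items()}
    return res


def _fit_gaussian(frame, y, dm, spec, n_studies, robust: bool = False) -> dict:
    import statsmodels.api as sm

    X = dm.to_numpy()
    use_study = "study" in spec.random and n_studies > 1
    block_key = frame["study_id"].astype(str) + "/" + frame["block_id"].astype(str)
    use_block = "block" in spec.random and block_key.nunique() > n_studies
    if not use_study and not use_block:
        ols = sm.OLS(y, X).fit()
        cov = np.asarray(ols.cov_params())
        # ML residual variance and the matching ML log-likelihood.
        sigma2 = float(np.sum(ols.resid**2) / len(y))
        return {
            "beta": np.asarray(ols.params),
            "se": np.asarray(ols.bse),
            "cov_beta": cov,
            "sigma2": {"sigma2_study": 0.0, "sigma2_block": 0.0, "sigma2_resid": sigma2},
            "loglik": float(ols.llf),
            "converged": True,
            "singular": True,
        }
    groups = frame["study_id"] if use_study else block_key
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if use_study and use_block:
            df = frame.copy()
            df["_y"] = y
            for j, c in enumerate(dm.columns):
                df[f"_x{j}"] = dm.iloc[:, j].to_numpy()
            fixed_rhs = " + ".join(f"_x{j}" for j in range(1, dm.shape[1]))
            formula = "_y ~ " + (fixed_rhs if fixed_rhs else "1")
            model = sm.MixedLM.from_formula(
                formula,
                groups="study_id",
                re_formula="1",
                vc_formula={"block": "0 + C(block_id)"},
                data=df,
            )
        else:
            model = sm.MixedLM(y, X, groups=np.asarray(groups))
        # Optimizers differ in robustness near boundary (singular) optima;
        # try a short cascade and keep the best converged likelihood.
        res = None
        for meth in ("lbfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=False, method=meth, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            key = (lambda f: (f.llf,)) if robust else (
                lambda f: (bool(f.converged), f.llf)
            )
            if res is None or key(cand) > key(res):
                res = cand
            if res.converged and not robust:
                break
        if res is None:
            raise RuntimeError("all linear mixed-model optimizers failed")
    singular = any("singular" in str(w.message).lower() for w in caught)
    converged = bool(res.converged)
    k = dm.shape[1]
    beta = np.asarray(res.fe_params)[:k]
    cov = np.asarray(res.cov_params())[:k, :k]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    sigma2 = {
        "sigma2_study": float(res.cov_re.iloc[0, 0]) if use_study else 0.0,
        "sigma2_block": float(res.vcomp[0]) if (use_study and use_block) else (
            float(res.cov_re.iloc[0, 0]) if (use_block and not use_study) else 0.0
        ),
        "sigma2_resid": float(res.scale),
    }
    singular = singular or min(sigma2.values()) < 1e-8
    return {
        "beta": beta,
        "se": se,
        "cov_beta": cov,
        "sigma2": sigma2,
        "loglik": float(res.llf),
        "converged": converged,
        "singular": singular,
    }


# ---------------------------------------------------------------------------
# inference


def likelihood_ratio_test(
    full: FitResult,
    reduced: FitResult,
    tol: float = 0.05,
    *,
    require_convergence: bool = True,
) -> LRTResult:
    """Chi-square LRT of nested ML fits: ``chi2 = 2 (l_full - l_reduced)``."""
    if require_convergence and (not full.converged or not reduced.converged):
        raise ValueError("refusing LRT on a non-converged fit")
    if not set(reduced.fixed_terms) <= set(full.fixed_terms):
        raise ValueError("reduced fixed terms must be a subset of the full terms")
    if (reduced.family, reduced.response, reduced.n_obs, reduced.random_terms) != (
        full.family,
        full.response,
        full.n_obs,
        full.random_terms,
    ):
        raise ValueError("LRT requires identical family, response, data and random structure")
    df = full.df_fixed - reduced.df_fixed
    if df <= 0:
        raise ValueError("full model must have more fixed-effect parameters")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < -tol:
        raise ValueError(
            f"negative LRT statistic ({chi2:.3g}): the full fit is worse; refit needed"
        )
    chi2 = max(chi2, 0.0)
    return LRTResult(chi_square=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def _droppable(terms: list[str], keep: set[str]) -> list[str]:
    """Terms eligible for elimination under marginality."""
    out = []
    for t in terms:
        fs = set(t.split(":"))
        if t in keep:
            continue
        if any(fs < set(o.split(":")) for o in terms if o != t):
            continue  # a higher-order interaction contains this term
        out.append(t)
    return out


def backward_eliminate(
    data: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05
) -> tuple[ModelSpec, FitResult, list[dict]]:
    """Backward elimination on likelihood-ratio tests.

    Repeatedly tests every currently droppable fixed term (interactions
    before the main effects they protect; ``spec.keep`` terms never
    tested), drops the term with the highest P when that P >= alpha, and
    stops when every droppable term has P < alpha. Returns the final spec,
    its fit, and the full trace of tests.
    """
    frame, ycol = _model_frame(data, spec)
    current = spec
    fit = _fit_frame(frame, ycol, current)
    trace: list[dict] = []
    step = 0
    while True:
        cand = _droppable(list(current.fixed), current.keep)
        if not cand:
            break
        tests = []
        for t in cand:
            red_spec = replace(current, fixed=[x for x in current.fixed if x != t])
            red_fit = _fit_frame(frame, ycol, red_spec)
            try:
                lrt = likelihood_ratio_test(fit, red_fit)
            except ValueError:
                # Refit signal: re-optimize both fits with the full optimizer
                # cascade before giving up.
                fit = _fit_frame(frame, ycol, current, robust=True)
                red_fit = _fit_frame(frame, ycol, red_spec, robust=True)
                lrt = likelihood_ratio_test(fit, red_fit, require_convergence=False)
            tests.append((t, red_spec, red_fit, lrt))
            trace.append(
                {
                    "step": step,
                    "term": t,
                    "chi_square": lrt.chi_square,
                    "df": lrt.df,
                    "p_value": lrt.p_value,
                    "dropped": False,
                }
            )
        worst = max(tests, key=lambda x: x[3].p_value)
        if worst[3].p_value >= alpha:
            current, fit = worst[1], worst[2]
            for rec in trace:
                if rec["step"] == step and rec["term"] == worst[0]:
                    rec["dropped"] = True
            step += 1
            continue
        break
    return current, fit, trace


def percent_difference(fit: FitResult, name: str, *, negate: bool = False) -> Contrast:
    """Back-transform one log-link coefficient to a percentage difference.

    ``percent = 100 (exp(b) - 1)`` with the Wald 95% interval
    ``100 (exp(b +- 1.96 se) - 1)``. ``negate`` flips the sign of the
    coefficient first (used for endemicity, modelled on the CWM log range
    whose reciprocal is reported).
    """
    b, s = fit.coef(name)
    if negate:
        b = -b
    return _contrast(name, b, s)


def contrast_from_vector(fit: FitResult, weights: dict[str, float], label: str,
                         *, negate: bool = False) -> Contrast:
    """Percentage difference for a linear combination of coefficients."""
    c = np.zeros(len(fit.params))
    idx = {n: i for i, n in enumerate(fit.params.index)}
    for name, w in weights.items():
        if name not in idx:
            raise KeyError(f"coefficient {name!r} not in model")
        c[idx[name]] = w
    b = float(c @ fit.params.to_numpy())
    s = float(np.sqrt(c @ fit.cov_params.to_numpy() @ c))
    if negate:
        b = -b
    return _contrast(label, b, s)


def _contrast(label: str, b: float, s: float) -> Contrast:
    z = 1.959963984540054
    return Contrast(
        label=label,
        percent_difference=100.0 * (np.exp(b) - 1.0),
        ci_low=100.0 * (np.exp(b - z * s) - 1.0),
        ci_high=100.0 * (np.exp(b + z * s) - 1.0),
        estimate=b,
        se=s,
    )


# ---------------------------------------------------------------------------
# the model suite


def _maybe_add_olre(data: pd.DataFrame, spec: ModelSpec, fit: FitResult,
                    olre: str) -> tuple[ModelSpec, FitResult]:
    if (
        spec.family == "poisson"
        and olre == "auto"
        and fit.dispersion is not None
        and fit.dispersion > 1.5
        and "obs" not in spec.random
    ):
        logger.info(
            "%s: Pearson dispersion %.2f > 1.5; adding observation-level intercept",
            spec.response,
            fit.dispersion,
        )
        spec = replace(spec, random=[*spec.random, "obs"])
        fit = fit_mixed_model(data, spec)
    return spec, fit


def _term_of_interest_lrt(data, spec, fit, term) -> LRTResult | None:
    reduced_fixed = [t for t in spec.fixed if t != term]
    red = replace(spec, fixed=reduced_fixed)
    frame, ycol = _model_frame(data, spec)
    red_fit = _fit_frame(frame, ycol, red)
    try:
        return likelihood_ratio_test(fit, red_fit)
    except ValueError:
        try:
            full_fit = _fit_frame(frame, ycol, spec, robust=True)
            red_fit = _fit_frame(frame, ycol, red, robust=True)
            return likelihood_ratio_test(full_fit, red_fit, require_convergence=False)
        except ValueError as exc:
            logger.warning("LRT for %s failed: %s", term, exc)
            return None


def _protection_contrasts(fit: FitResult, response: str) -> list[Contrast]:
    negate = response == "endemicity"
    return [percent_difference(fit, "protected", negate=negate)]


def _per_land_use_contrasts(fit: FitResult, response: str) -> list[Contrast]:
    """Protection effect within each land use from the interaction model.

    The effect within the reference land use is the protection main effect;
    within any other level it adds the interaction coefficient, with the
    full covariance carried through.
    """
    negate = response == "endemicity"
    levels = (fit.factor_levels or {}).get("land_use", list(LAND_USES))
    inter_cols = fit.term_columns.get("protected:land_use", [])
    out = []
    for lu in levels:
        weights = {"protected": 1.0}
        col = next((c for c in inter_cols if f"[{lu}]" in c or f"[T.{lu}]" in c), None)
        if lu != levels[0] and col is None:
            continue  # inestimable cell: level absent on one side
        if col is not None:
            weights[col] = 1.0
        try:
            out.append(contrast_from_vector(fit, weights, f"protected@{lu}", negate=negate))
        except KeyError:
            continue
    return out


def _management_contrasts(fit: FitResult, response: str) -> list[Contrast]:
    negate = response == "endemicity"
    out = []
    for c in fit.term_columns.get("management_group", []):
        level = c.split("[T.")[-1].rstrip("]")
        out.append(
            contrast_from_vector(fit, {c: 1.0}, f"management@{level}", negate=negate)
        )
    return out


def _size_age_contrasts(fit: FitResult, response: str) -> list[Contrast]:
    negate = response == "endemicity"
    return [
        contrast_from_vector(
            fit, {c: 1.0}, "size_age@" + c.split("[T.")[-1].rstrip("]"), negate=negate
        )
        for c in fit.term_columns.get("size_age_class", [])
    ]


def _defined(data: pd.DataFrame, response: str) -> bool:
    ycol = _RESPONSE_MAP[response][0]
    if ycol not in data.columns:
        return False
    ok = data[ycol].notna()
    return bool(ok.sum() >= 20 and data.loc[ok, "study_id"].nunique() >= 2)


def fit_measure_suite(
    all_sites: pd.DataFrame,
    matched_sites: pd.DataFrame | None = None,
    *,
    olre: str = "auto",
    alpha: float = 0.05,
    include_interaction: bool = True,
    include_management: bool = True,
    include_size_age: bool = True,
) -> dict:
    """Run the analysis model set for every defined biodiversity measure.

    For each measure with enough defined data this fits, on the all-sites
    table: the headline protection model, the four-level management-group
    model, and the protection x land-use interaction model; and on the
    matched-sites table: the protection re-run and the size/age-class
    model. Confounders enter every model and are subject to backward
    elimination; the terms of scientific interest are never eliminated.
    Measures with no defined data (e.g. abundance in an occurrence-only
    world) are absent from the result.
    """
    conf = [c + "_z" for c in CONFOUNDERS]
    bundle: dict[str, dict] = {}
    for response in MEASURES:
        if not _defined(all_sites, response):
            logger.info("measure %s undefined in the all-sites data; skipped", response)
            continue
        entry: dict[str, dict] = {}

        spec = ModelSpec(
            response=response, fixed=["protected", *conf], keep={"protected"}
        )
        final_spec, fit, trace = backward_eliminate(all_sites, spec, alpha=alpha)
        final_spec, fit = _maybe_add_olre(all_sites, final_spec, fit, olre)
        entry["protection"] = {
            "fit": fit,
            "trace": trace,
            "lrt": _term_of_interest_lrt(all_sites, final_spec, fit, "protected"),
            "contrasts": _protection_contrasts(fit, response),
        }

        if include_management:
            spec = ModelSpec(
                response=response,
                fixed=["management_group", *conf],
                keep={"management_group"},
            )
            final_spec, fit, trace = backward_eliminate(all_sites, spec, alpha=alpha)
            final_spec, fit = _maybe_add_olre(all_sites, final_spec, fit, olre)
            entry["management"] = {
                "fit": fit,
                "trace": trace,
                "lrt": _term_of_interest_lrt(
                    all_sites, final_spec, fit, "management_group"
                ),
                "contrasts": _management_contrasts(fit, response),
            }

        if include_interaction:
            spec = ModelSpec(
                response=response,
                fixed=["protected", "land_use", "protected:land_use", *conf],
                keep={"protected", "land_use", "protected:land_use"},
            )
            final_spec, fit, trace = backward_eliminate(all_sites, spec, alpha=alpha)
            final_spec, fit = _maybe_add_olre(all_sites, final_spec, fit, olre)
            entry["protection_land_use"] = {
                "fit": fit,
                "trace": trace,
                "lrt": _term_of_interest_lrt(
                    all_sites, final_spec, fit, "protected:land_use"
                ),
                "contrasts": _per_land_use_contrasts(fit, response),
            }

        if matched_sites is not None and _defined(matched_sites, response):
            spec = ModelSpec(
                response=response, fixed=["protected", *conf], keep={"protected"}
            )
            final_spec, fit, trace = backward_eliminate(matched_sites, spec, alpha=alpha)
            final_spec, fit = _maybe_add_olre(matched_sites, final_spec, fit, olre)
            entry["protection_matched"] = {
                "fit": fit,
                "trace": trace,
                "lrt": _term_of_interest_lrt(matched_sites, final_spec, fit, "protected"),
                "contrasts": _protection_contrasts(fit, response),
            }

            if include_size_age:
                usable = matched_sites[
                    matched_sites["size_age_class"].notna()
                ]
                if usable["size_age_class"].nunique() >= 2 and _defined(usable, response):
                    spec = ModelSpec(
                        response=response,
                        fixed=["size_age_class", *conf],
                        keep={"size_age_class"},
                    )
                    final_spec, fit, trace = backward_eliminate(usable, spec, alpha=alpha)
                    final_spec, fit = _maybe_add_olre(usable, final_spec, fit, olre)
                    entry["size_age"] = {
                        "fit": fit,
                        "trace": trace,
                        "lrt": _term_of_interest_lrt(
                            usable, final_spec, fit, "size_age_class"
                        ),
                        "contrasts": _size_age_contrasts(fit, response),
                    }

        bundle[response] = entry
    return bundle
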