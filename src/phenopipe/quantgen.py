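"""Quantitative genetics on longitudinal phenotype tables: variance
components, genotype BLUEs and time-resolved broad-sense heritability.

The design model for one trait at one time point is

    Y = mu + C + G + Exp + Basin + x + y + TablePosition
        + x_within + y_within + G:Exp + Exp:(Basin + x + y + TablePosition
        + x_within + y_within) + Exp:Basin:G + Exp:G:(x_within + y_within)
        + error,

with the intercept and the check-genotype factor ``C`` fixed and every
other term an independent random effect (variance times identity on its
levels).  Check genotypes sharpen the design-effect estimates but are
excluded from genotype-level outputs.  For single-experiment tables all
terms involving ``Exp`` are dropped.

Variance components are estimated by REML (Fisher scoring with an EM
fallback).  Genotype means are best linear unbiased estimators (BLUEs) from
the same model with genotype as a fixed effect.  Broad-sense heritability
uses the classical ANOVA route: a fixed-effects linear model with genotype
entered after the main design factors gives mean squares MS(G) and MS(E),
from which

    sigma2_G = (MS(G) - MS(E)) / r_bar   (truncated at 0),
    sigma2_E = MS(E),
    H2 = sigma2_G / (sigma2_G + sigma2_E),

with ``r_bar`` the effective (harmonic-mean) replicate number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "REQUIRED_COLUMNS",
    "VarianceComponents",
    "HeritabilityEstimate",
    "default_random_terms",
    "validate_table",
    "fit_variance_components",
    "compute_blues",
    "estimate_heritability",
    "heritability_timecourse",
    "timecourse_frame",
]

REQUIRED_COLUMNS = [
    "genotype",
    "is_check",
    "experiment",
    "basin",
    "x",
    "y",
    "tile",
    "x_within",
    "y_within",
    "time_h",
    "trait",
    "value",
]

#: main effects and interactions of the design model (colon = interaction)
FULL_RANDOM_TERMS = [
    "genotype",
    "experiment",
    "basin",
    "x",
    "y",
    "tile",
    "x_within",
    "y_within",
    "genotype:experiment",
    "experiment:basin",
    "experiment:x",
    "experiment:y",
    "experiment:tile",
    "experiment:x_within",
    "experiment:y_within",
    "experiment:basin:genotype",
    "experiment:genotype:x_within",
    "experiment:genotype:y_within",
]


def validate_table(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    dup = df.duplicated(subset=["experiment", "tile", "x_within", "y_within", "time_h", "trait"])
    # duplicated plants at one time/trait break the one-value-per-plant contract
    if dup.any():
        raise ValueError("phenotype table has duplicate plant x time x trait rows")


def default_random_terms(df: pd.DataFrame) -> list[str]:
    """The design model's random terms, pruned for single-experiment tables."""
    terms = list(FULL_RANDOM_TERMS)
    if df["experiment"].nunique() < 2:
        terms = [t for t in terms if "experiment" not in t.split(":")]
    return terms


def _select(df: pd.DataFrame, trait: str | None, time_h: float | None) -> pd.DataFrame:
    out = df
    if trait is not None:
        out = out[out["trait"] == trait]
    if time_h is not None:
        out = out[np.isclose(out["time_h"].to_numpy(dtype=float), time_h)]
    if out.empty:
        raise ValueError(f"no rows for trait={trait!r} at time={time_h!r}")
    return out.reset_index(drop=True)


def _term_design(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    """0/1 incidence matrix for a (possibly crossed) factor term."""
    cols = term.split(":")
    labels = df[cols[0]].astype(str)
    for c in cols[1:]:
        labels = labels + "|" + df[c].astype(str)
    codes, levels = pd.factorize(labels, sort=True)
    Z = np.zeros((len(df), len(levels)))
    Z[np.arange(len(df)), codes] = 1.0
    return Z, list(levels)


def _check_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Fixed design for intercept + check factor.

    The check factor has one level per check genotype and a single
    reference level pooling everything else, so with no checks it reduces
    to the intercept alone.
    """
    n = len(df)
    X = [np.ones(n)]
    names = ["intercept"]
    checks = sorted(df.loc[df["is_check"].astype(bool), "genotype"].astype(str).unique())
    for g in checks:
        X.append(((df["genotype"].astype(str) == g) & df["is_check"].astype(bool)).to_numpy(float))
        names.append(f"check[{g}]")
    return np.column_stack(X), names


@dataclass
class VarianceComponents:
    """REML variance-component estimates for the design model."""

    components: dict[str, float]
    standard_errors: dict[str, float]
    loglik: float
    n_iter: int
    converged: bool
    n_obs: int
    dropped_terms: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> float:
        return self.components[term]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": k, "variance": v, "se": self.standard_errors.get(k, np.nan)}
            for k, v in self.components.items()
        ]
        return pd.DataFrame(rows)


class _RemlProblem:
    """REML for a mixed model with independent random terms.

    Scoring/EM work on the variance scale; the model is small enough
    (hundreds to ~2000 observations) that the n x n covariance matrix is
    handled directly.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Zs: dict[str, np.ndarray]):
        self.y = y
        self.X = X
        self.names = list(Zs) + ["residual"]
        n = len(y)
        self.Gs = [Z @ Z.T for Z in Zs.values()] + [np.eye(n)]
        self.n = n
        self.p = np.linalg.matrix_rank(X)

    def _P_and_logdet(self, sigma2: np.ndarray):
        V = sum(s * G for s, G in zip(sigma2, self.Gs))
        c, low = cho_factor(V, lower=True)
        logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv_X = cho_solve((c, low), self.X)
        XtVinvX = self.X.T @ Vinv_X
        sign, logdet_XVX = np.linalg.slogdet(XtVinvX)
        Vinv = cho_solve((c, low), np.eye(self.n))
        P = Vinv - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T)
        return P, logdet_V, logdet_XVX

    def loglik(self, sigma2: np.ndarray) -> float:
        P, ldV, ldX = self._P_and_logdet(sigma2)
        return float(-0.5 * (ldV + ldX + self.y @ P @ self.y))

    def fit(self, max_iter: int = 500, tol: float = 1e-8):
        k = len(self.Gs)
        vy = float(np.var(self.y))
        if vy == 0:
            vy = 1.0
        floor = 1e-10 * vy
        sigma2 = np.full(k, vy / k)
        ll = self.loglik(sigma2)
        n_iter = 0
        converged = False
        info = np.eye(k)
        for n_iter in range(1, max_iter + 1):
            P, _, _ = self._P_and_logdet(sigma2)
            Py = P @ self.y
            PG = [P @ G for G in self.Gs]
            score = np.array(
                [-0.5 * (np.trace(PG_j) - self.y @ PG_j @ Py) for PG_j in PG]
            )
            info = np.array(
                [[0.5 * np.sum(PG[j] * PG[l].T) for l in range(k)] for j in range(k)]
            )
            # active set: components pinned at the zero boundary whose score
            # still points outward are held fixed this iteration, which
            # stops the scoring step from thrashing against the constraint
            free = ~((sigma2 <= 2 * floor) & (score < 0))
            if not free.any():
                converged = True
                break
            step = np.zeros(k)
            sub = info[np.ix_(free, free)] + 1e-12 * np.eye(int(free.sum()))
            try:
                step[free] = np.linalg.solve(sub, score[free])
            except np.linalg.LinAlgError:
                step[free] = score[free] / np.maximum(np.diag(sub), 1e-12)
            # step-halving line search keeps the ascent monotone
            ll_new, proposal = -np.inf, sigma2
            for _ in range(20):
                cand = np.maximum(sigma2 + step, floor)
                try:
                    ll_cand = self.loglik(cand)
                except np.linalg.LinAlgError:
                    ll_cand = -np.inf
                if np.isfinite(ll_cand) and ll_cand >= ll - 1e-12:
                    ll_new, proposal = ll_cand, cand
                    break
                step *= 0.5
            if not np.isfinite(ll_new):
                # EM fallback: slower but guaranteed-ascent update
                q = np.array([np.trace(G) for G in self.Gs])
                em = sigma2 + (sigma2**2 / q) * np.array(
                    [self.y @ PG_j @ Py - np.trace(PG_j) for PG_j in PG]
                )
                proposal = np.maximum(em, floor)
                ll_new = self.loglik(proposal)
            delta = abs(ll_new - ll) / (abs(ll) + 1.0)
            sigma2, ll = proposal, ll_new
            if delta < tol:
                converged = True
                break
        se = np.full(k, np.nan)
        try:
            se = np.sqrt(np.maximum(np.diag(np.linalg.inv(info)), 0.0))
        except np.linalg.LinAlgError:
            pass
        sigma2 = np.where(sigma2 <= 2 * floor, 0.0, sigma2)  # truncate at zero, flagged by exact 0
        return sigma2, se, ll, n_iter, converged


def fit_variance_components(
    table: pd.DataFrame,
    trait: str | None = None,
    time_h: float | None = None,
    random_terms: list[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> VarianceComponents:
    """REML variance components for one trait at one time point.

    Terms whose factor has fewer than 2 levels in the data are dropped with
    a warning (they are unidentifiable); for single-experiment tables every
    term involving experiment is dropped silently, as the design model
    prescribes.
    """
    validate_table(table)
    df = _select(table, trait, time_h)
    if random_terms is None:
        random_terms = default_random_terms(df)
    dropped: list[str] = []
    Zs: dict[str, np.ndarray] = {}
    for term in random_terms:
        Z, levels = _term_design(df, term)
        if len(levels) < 2:
            dropped.append(term)
            warnings.warn(f"dropping unidentifiable random term {term!r} (single level)")
            continue
        Zs[term] = Z
    X, _ = _check_design(df)
    y = df["value"].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("phenotype values must be finite")
    prob = _RemlProblem(y, X, Zs)
    sigma2, se, ll, n_iter, converged = prob.fit(max_iter=max_iter, tol=tol)
    if not converged:
        raise RuntimeError(
            f"REML did not converge in {n_iter} iterations "
            f"(last estimates: {dict(zip(prob.names, sigma2))})"
        )
    return VarianceComponents(
        components=dict(zip(prob.names, map(float, sigma2))),
        standard_errors=dict(zip(prob.names, map(float, se))),
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        n_obs=len(df),
        dropped_terms=dropped,
    )


def compute_blues(
    table: pd.DataFrame,
    trait: str | None = None,
    time_h: float | None = None,
    components: VarianceComponents | None = None,
    include_checks: bool = False,
) -> pd.Series:
    """Genotype means as best linear unbiased estimators (BLUEs).

    Refits the design model with genotype as a fixed effect (cell-means
    coding) and every genotype-free design term random, then solves the
    generalized least squares problem under the implied covariance.  Random
    terms involving genotype are omitted once genotype is fixed.  Check
    genotypes participate in the fit but are excluded from the output
    unless ``include_checks``.
    """
    validate_table(table)
    df = _select(table, trait, time_h)
    terms = [t for t in default_random_terms(df) if "genotype" not in t.split(":")]
    if components is not None:
        variances = {t: components.components[t] for t in terms if t in components.components}
        resid = components.components.get("residual", None)
    else:
        variances, resid = None, None

    y = df["value"].to_numpy(dtype=float)
    Zg, genotypes = _term_design(df, "genotype")
    Zs: dict[str, np.ndarray] = {}
    for term in terms:
        Z, levels = _term_design(df, term)
        if len(levels) >= 2:
            Zs[term] = Z

    if variances is None or resid is None:
        prob = _RemlProblem(y, Zg, Zs)
        sigma2, _, _, _, converged = prob.fit()
        if not converged:
            raise RuntimeError("REML for the BLUE model did not converge")
        variances = dict(zip(list(Zs), sigma2[:-1]))
        resid = float(sigma2[-1])

    n = len(df)
    V = resid * np.eye(n)
    for term, Z in Zs.items():
        V += variances.get(term, 0.0) * (Z @ Z.T)
    c, low = cho_factor(V, lower=True)
    VinvZg = cho_solve((c, low), Zg)
    beta = np.linalg.solve(Zg.T @ VinvZg, VinvZg.T @ y)
    out = pd.Series(beta, index=pd.Index(genotypes, name="genotype"), name="blue")
    if not include_checks:
        checks = set(df.loc[df["is_check"].astype(bool), "genotype"].astype(str))
        out = out[~out.index.isin(checks)]
    return out


# ---------------------------------------------------------------------------
# ANOVA heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    """Broad-sense (plot-level) heritability at one trait x time point."""

    trait: str
    time_h: float
    MS_G: float
    MS_E: float
    df_G: float
    df_E: float
    r_bar: float
    sigma2_G: float
    sigma2_E: float
    H2: float
    ci95: tuple[float, float]
    n_genotypes: int
    is_day: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.H2 <= 1.0:
            raise ValueError("H2 must lie in [0, 1]")


def _knapp_ci(
    F: float, df_G: float, df_E: float, r_bar: float, alpha: float = 0.05
) -> tuple[float, float]:
    """F-pivot (Knapp-type) confidence bounds mapped to plot-level H2.

    Under the balanced one-way model ``F / (1 + r_bar * sigma2_G / sigma2_E)``
    follows an F(df_G, df_E) distribution; inverting the pivot at the two
    quantiles and mapping ``lambda = r_bar * sigma2_G / sigma2_E`` through
    ``H2 = lambda / (lambda + r_bar)`` gives the interval.
    """
    lo_q = stats.f.ppf(1 - alpha / 2, df_G, df_E)
    hi_q = stats.f.ppf(alpha / 2, df_G, df_E)
    lam_lo = F / lo_q - 1.0
    lam_hi = F / hi_q - 1.0
    lo = float(np.clip(lam_lo / (lam_lo + r_bar), 0.0, 1.0)) if lam_lo + r_bar > 0 else 0.0
    hi = float(np.clip(lam_hi / (lam_hi + r_bar), 0.0, 1.0)) if lam_hi + r_bar > 0 else 1.0
    return (lo, hi)


def _sequential_anova(df: pd.DataFrame) -> tuple[float, float, float, float]:
    """Sequential (type I) ANOVA with genotype entered last.

    Fixed effects: basin nested within experiment, within-image row and
    column, then genotype.  Returns (MS_G, MS_E, df_G, df_E).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    work = df.copy()
    work["eb"] = work["experiment"].astype(str) + ":" + work["basin"].astype(str)
    terms = []
    for col in ("eb", "x_within", "y_within"):
        if work[col].nunique() > 1:
            terms.append(f"C({col})")
    terms.append("C(genotype)")
    model = ols("value ~ " + " + ".join(terms), data=work).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm warns on perfect fits
        tab = sm.stats.anova_lm(model, typ=1)
    ms_g = float(tab.loc["C(genotype)", "sum_sq"] / tab.loc["C(genotype)", "df"])
    df_g = float(tab.loc["C(genotype)", "df"])
    df_e = float(tab.loc["Residual", "df"])
    if df_e < 1:
        raise ValueError("no residual degrees of freedom for the ANOVA model")
    ms_e = float(tab.loc["Residual", "sum_sq"] / df_e)
    return ms_g, ms_e, df_g, df_e


def estimate_heritability(
    table: pd.DataFrame,
    trait: str | None = None,
    time_h: float | None = None,
    genotypes: list[str] | None = None,
    alpha: float = 0.05,
    ci_method: str = "knapp",
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> HeritabilityEstimate:
    """ANOVA-based broad-sense heritability for one trait x time point.

    Check genotypes are excluded, as is any genotype outside an optional
    ``genotypes`` subset.  ``r_bar`` is the harmonic mean of per-genotype
    replicate counts.  The default confidence interval inverts the F pivot
    (Knapp-type); ``ci_method="bootstrap"`` resamples replicates within
    genotype instead.
    """
    validate_table(table)
    df = _select(table, trait, time_h)
    df = df[~df["is_check"].astype(bool)]
    if genotypes is not None:
        df = df[df["genotype"].isin(genotypes)]
    if df["genotype"].nunique() < 2:
        raise ValueError("heritability needs at least 2 genotypes")
    counts = df.groupby("genotype")["value"].size()
    if counts.max() < 2:
        raise ValueError("heritability needs replicated genotypes")

    ms_g, ms_e, df_g, df_e = _sequential_anova(df)
    r_bar = float(len(counts) / np.sum(1.0 / counts.to_numpy()))
    sigma2_g = max(0.0, (ms_g - ms_e) / r_bar)
    h2 = sigma2_g / (sigma2_g + ms_e) if (sigma2_g + ms_e) > 0 else 0.0

    if ci_method == "knapp":
        ci = _knapp_ci(ms_g / ms_e, df_g, df_e, r_bar, alpha)
    elif ci_method == "bootstrap":
        rng = rng or np.random.default_rng(0)
        reps = []
        grouped = [g.reset_index(drop=True) for _, g in df.groupby("genotype")]
        for _ in range(n_boot):
            boot = pd.concat(
                [g.iloc[rng.integers(0, len(g), len(g))] for g in grouped],
                ignore_index=True,
            )
            try:
                bg, be, _, _ = _sequential_anova(boot)
            except ValueError:
                continue
            s2 = max(0.0, (bg - be) / r_bar)
            reps.append(s2 / (s2 + be) if s2 + be > 0 else 0.0)
        ci = (
            float(np.quantile(reps, alpha / 2)),
            float(np.quantile(reps, 1 - alpha / 2)),
        )
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return HeritabilityEstimate(
        trait=str(df["trait"].iloc[0]),
        time_h=float(df["time_h"].iloc[0]),
        MS_G=ms_g,
        MS_E=ms_e,
        df_G=df_g,
        df_E=df_e,
        r_bar=r_bar,
        sigma2_G=sigma2_g,
        sigma2_E=ms_e,
        H2=float(h2),
        ci95=ci,
        n_genotypes=int(len(counts)),
    )


def heritability_timecourse(
    table: pd.DataFrame,
    trait: str,
    genotypes: list[str] | None = None,
    schedule=None,
    **kwargs,
) -> list[HeritabilityEstimate]:
    """Heritability at every time point of one trait, on a fixed genotype set.

    When ``genotypes`` is None the subset common to all time points is
    used, so estimates are comparable along the time course.  A
    :class:`~phenopipe.layout.MeasurementSchedule` annotates each estimate
    as day or night.
    """
    validate_table(table)
    df = table[(table["trait"] == trait) & (~table["is_check"].astype(bool))]
    if df.empty:
        raise ValueError(f"no rows for trait {trait!r}")
    times = sorted(df["time_h"].unique())
    if genotypes is None:
        sets = [set(df.loc[df["time_h"] == t, "genotype"]) for t in times]
        genotypes = sorted(set.intersection(*sets))
    if not genotypes:
        raise ValueError("empty common genotype subset across time points")
    out = []
    for t in times:
        est = estimate_heritability(table, trait=trait, time_h=t, genotypes=genotypes, **kwargs)
        if schedule is not None:
            est.is_day = schedule.is_day(t)
        out.append(est)
    return out


def timecourse_frame(estimates: list[HeritabilityEstimate]) -> pd.DataFrame:
    """Heritability time course as a flat CSV-ready table."""
    return pd.DataFrame(
        [
            {
                "trait": e.trait,
                "time_h": e.time_h,
                "is_day": e.is_day,
                "H2": e.H2,
                "lo95": e.ci95[0],
                "hi95": e.ci95[1],
                "MS_G": e.MS_G,
                "MS_E": e.MS_E,
                "r_bar": e.r_bar,
            }
            for e in estimates
        ]
    )
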