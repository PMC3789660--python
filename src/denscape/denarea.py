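"""Den-area-scale analysis: matched-case-control discrete-choice models.

Each used site (den) is matched with m available sites into a choice set;
the probability that alternative j of set s is the used one follows a
conditional logit,

    P(j | s) = exp(x_sj' beta) / sum_k exp(x_sk' beta),

with no intercept (it cancels within a set).  The pipeline covers:

* z-score standardization of continuous covariates (with the literal
  divide-by-mean-times-sd variant available as a flag for sensitivity
  checks);
* variance-inflation-factor screening for multicollinearity;
* maximum-likelihood fitting by Newton's method with analytic gradient and
  Hessian (the log-likelihood is concave), SEs from the inverse observed
  information;
* AICc ranking of a candidate model set, Akaike weights, and model averaging
  of the confidence set (ΔAICc ≤ 4) with unconditional SEs and odds ratios;
* quasi-complete-separation detection (the reason substrate is summarized
  descriptively rather than fitted);
* k-fold cross-validation prediction error (the proportion of held-out sets
  whose used site is not the top-ranked alternative).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTINUOUS_COVARIATES = ("rodent_burrows", "visibility", "shrub_count")


class ChoiceDataError(ValueError):
    pass


class SeparationError(RuntimeError):
    """Raised when (quasi-)complete separation makes the MLE unbounded."""


# ---------------------------------------------------------------------------
# Choice-set plumbing
# ---------------------------------------------------------------------------

@dataclass
class ChoiceSet:
    """One used row plus its matched available rows (a view over tidy data)."""

    set_id: object
    rows: pd.DataFrame

    @property
    def n_available(self) -> int:
        return len(self.rows) - 1


def split_choice_sets(df: pd.DataFrame) -> list[ChoiceSet]:
    """Group a tidy choice table into validated ChoiceSets."""
    sets = []
    for sid, grp in df.groupby("set_id", sort=True):
        n_used = int(grp["used"].sum())
        if n_used != 1:
            raise ChoiceDataError(f"choice set {sid!r} has {n_used} used rows (expected 1)")
        if len(grp) < 2:
            raise ChoiceDataError(f"choice set {sid!r} has no available rows")
        sets.append(ChoiceSet(sid, grp))
    if not sets:
        raise ChoiceDataError("no choice sets in input")
    return sets


# ---------------------------------------------------------------------------
# Covariate preparation
# ---------------------------------------------------------------------------

def standardize(col, literal: bool = False):
    """Standardize a covariate column; returns (standardized, mean, sd).

    Default is the conventional z-score (x - mean)/sd.  ``literal=True``
    applies x/(mean*sd) instead, preserved as a sensitivity variant of the
    divide-by-mean-and-sd phrasing sometimes used for this transform.
    """
    x = np.asarray(col, dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ChoiceDataError("constant column cannot be standardized")
    z = x / (mean * sd) if literal else (x - mean) / sd
    return z, mean, sd


def standardize_covariates(
    df: pd.DataFrame, columns=CONTINUOUS_COVARIATES, literal: bool = False
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Standardize the named columns; returns (new frame, {col: (mean, sd)})."""
    out = df.copy()
    scale = {}
    for c in columns:
        out[c], mean, sd = standardize(df[c], literal=literal)
        scale[c] = (mean, sd)
    return out, scale


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1 - R²_j) regressing column j
    on the remaining columns (with intercept).  Perfect collinearity is
    reported as ``inf`` rather than raised."""
    X = np.asarray(design, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ChoiceDataError("VIF needs at least 2 columns")
    if n <= k:
        raise ChoiceDataError(f"VIF needs more rows ({n}) than columns ({k})")
    vifs = []
    for j in range(k):
        y = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            vifs.append(np.inf)
            continue
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        vifs.append(np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2))
    return pd.Series(vifs, index=list(design.columns), name="vif")


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Ordered terms of a conditional-logit model.

    Main effects are covariate names; interactions are ``"a:b"``.  An
    interaction's main effects must be listed in the spec (interaction-only
    models are not part of the candidate designs used here).
    """

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        for t in self.terms:
            for part in t.split(":"):
                if part not in CONTINUOUS_COVARIATES:
                    raise ChoiceDataError(f"unknown covariate {part!r} in term {t!r}")
            if ":" in t and not all(p in self.terms for p in t.split(":")):
                raise ChoiceDataError(f"interaction {t!r} requires its main effects in the model")

    @property
    def name(self) -> str:
        return " + ".join(t.replace(":", " x ") for t in self.terms)

    @property
    def k(self) -> int:
        return len(self.terms)


def candidate_models() -> list[ModelSpec]:
    """The ten-model candidate set of mains and paired interactions over
    burrow count, visibility and shrub count."""
    b, v, s = "rodent_burrows", "visibility", "shrub_count"
    return [
        ModelSpec((b, v)),
        ModelSpec((b, s, v)),
        ModelSpec((b, v, f"{b}:{v}")),
        ModelSpec((b,)),
        ModelSpec((b, s)),
        ModelSpec((b, s, f"{b}:{s}")),
        ModelSpec((s, v, f"{s}:{v}")),
        ModelSpec((s, v)),
        ModelSpec((v,)),
        ModelSpec((s,)),
    ]


def build_design(df: pd.DataFrame, terms) -> np.ndarray:
    cols = []
    for t in terms:
        vals = np.ones(len(df))
        for part in t.split(":"):
            vals = vals * df[part].to_numpy(dtype=float)
        cols.append(vals)
    return np.column_stack(cols)


class _GroupedDesign:
    """Stacked design matrix with segment boundaries, one segment per set."""

    def __init__(self, df: pd.DataFrame, terms):
        sets = split_choice_sets(df)
        Xs, used, starts, seg = [], [], [], []
        pos = 0
        for i, cs in enumerate(sets):
            X = build_design(cs.rows, terms)
            Xs.append(X)
            starts.append(pos)
            used.append(pos + int(np.flatnonzero(cs.rows["used"].to_numpy())[0]))
            seg.extend([i] * len(X))
            pos += len(X)
        self.X = np.vstack(Xs)
        self.starts = np.asarray(starts)
        self.used = np.asarray(used)
        self.seg = np.asarray(seg)
        self.n_sets = len(sets)




# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------

def condlogit_loglik(beta, df: pd.DataFrame, terms) -> float:
    """Conditional-logit log-likelihood over matched choice sets:
    sum_s [x_used' beta - log sum_j exp(x_sj' beta)]."""
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ChoiceDataError("non-finite beta")
    return _loglik(beta, _GroupedDesign(df, terms))


def _set_probs(beta, gd: "_GroupedDesign"):
    """Per-row choice probabilities and per-set log-normalizers."""
    eta = gd.X @ beta
    m = np.maximum.reduceat(eta, gd.starts)
    e = np.exp(eta - m[gd.seg])
    sums = np.add.reduceat(e, gd.starts)
    return eta, e / sums[gd.seg], m + np.log(sums)

def _loglik(beta, gd: "_GroupedDesign") -> float:
    eta, _, lognorm = _set_probs(beta, gd)
    return float(eta[gd.used].sum() - lognorm.sum())


def _score_hessian(beta, gd: "_GroupedDesign"):
    """Gradient and Hessian of the log-likelihood (analytic):
    g = sum_s (x_used - mu_s),  H = -sum_s (sum_j p_j x_j x_j' - mu_s mu_s')."""
    _, p, _ = _set_probs(beta, gd)
    W = gd.X * p[:, None]
    mu = np.add.reduceat(W, gd.starts, axis=0)  # n_sets x k
    g = gd.X[gd.used].sum(axis=0) - mu.sum(axis=0)
    H = -(W.T @ gd.X) + mu.T @ mu
    return g, H


@dataclass
class ModelFit:
    spec: ModelSpec
    beta: dict[str, float]
    se: dict[str, float]
    loglik: float
    k: int
    n_sets: int
    converged: bool
    aicc: float = math.nan
    delta_aicc: float = math.nan
    weight: float = math.nan
    message: str = ""


def fit_condlogit(
    spec: ModelSpec,
    df: pd.DataFrame,
    max_iter: int = 500,
    gtol: float = 1e-8,
    raise_on_separation: bool = True,
) -> ModelFit:
    """Maximize the conditional-logit likelihood by damped Newton from a
    zero start.  The log-likelihood is concave, so Newton with step-halving
    converges whenever the MLE exists; runaway coefficients (no finite
    maximum) are reported as separation.  With
    ``raise_on_separation=False`` a separated fit is returned with the last
    (capped) coefficients and ``converged=False`` instead of raising — the
    coefficient *direction* is still informative, e.g. for ranking
    alternatives in cross-validation."""
    gd = _GroupedDesign(df, spec.terms)
    beta = np.zeros(spec.k)
    ll = _loglik(beta, gd)
    converged = False
    message = ""
    for _ in range(max_iter):
        g, H = _score_hessian(beta, gd)
        if np.linalg.norm(g, ord=np.inf) < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            if raise_on_separation:
                raise SeparationError(
                    f"singular information matrix for model {spec.name!r}; the data likely "
                    "exhibit (quasi-)complete separation — run detect_separation on its terms"
                ) from None
            message = "separation suspected: singular information matrix"
            break
        # step-halving line search on the concave log-likelihood
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new = _loglik(cand, gd)
            if ll_new >= ll:
                break
            t /= 2.0
        beta, ll = cand, ll_new
        if np.linalg.norm(beta, ord=np.inf) > 35.0:
            if raise_on_separation:
                raise SeparationError(
                    f"diverging coefficients while fitting {spec.name!r}; the data likely "
                    "exhibit (quasi-)complete separation — run detect_separation on its terms"
                )
            message = "separation suspected: diverging coefficients (capped)"
            break
    else:
        message = f"no convergence in {max_iter} Newton iterations (||g||={np.linalg.norm(g):.3g})"

    # Complete separation: the likelihood supremum (0) is approached at a
    # finite beta once per-set probabilities saturate, so the gradient
    # vanishes without the coefficients diverging.  Flag it via the
    # log-likelihood itself.
    if converged and ll > -1e-6:
        if raise_on_separation:
            raise SeparationError(
                f"model {spec.name!r} perfectly predicts every used row "
                "(complete separation; the likelihood has no interior maximum) — "
                "run detect_separation on its terms"
            )
        converged = False
        message = "separation suspected: perfect prediction of all used rows"

    _, H = _score_hessian(beta, gd)
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(spec.k, np.nan)
        message = message or "singular observed information at the optimum"
    return ModelFit(
        spec=spec,
        beta=dict(zip(spec.terms, beta.tolist())),
        se=dict(zip(spec.terms, se.tolist())),
        loglik=ll,
        k=spec.k,
        n_sets=gd.n_sets,
        converged=converged,
        message=message,
    )


# ---------------------------------------------------------------------------
# Information-theoretic model comparison
# ---------------------------------------------------------------------------

def compute_aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2K + 2K(K+1)/(n - K - 1)."""
    if n <= k + 1:
        raise ChoiceDataError(f"AICc undefined: n={n} <= K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> tuple[np.ndarray, np.ndarray]:
    """(ΔAICc, Akaike weights) for a model set.

    Δ_i = AICc_i - min AICc;  w_i = exp(-Δ_i/2) / sum_j exp(-Δ_j/2).
    Invariant to adding a constant to every AICc.
    """
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ChoiceDataError("AICc values must be a non-empty finite list")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return delta, w


def fit_model_set(
    specs, df: pd.DataFrame, k_offset: int = 0
) -> list[ModelFit]:
    """Fit every candidate model and rank by AICc (sample size = number of
    choice sets; ``k_offset`` adds a constant to every model's parameter
    count, for comparison with software that counts an extra parameter)."""
    fits = [fit_condlogit(s, df) for s in specs]
    n = fits[0].n_sets
    for f in fits:
        f.k = f.spec.k + k_offset
        f.aicc = compute_aicc(f.loglik, f.k, n)
    delta, w = akaike_weights([f.aicc for f in fits])
    for f, d, wi in zip(fits, delta, w):
        f.delta_aicc = float(d)
        f.weight = float(wi)
    return sorted(fits, key=lambda f: f.aicc)


def model_table(fits) -> pd.DataFrame:
    """AICc ranking table: model, K, loglik, AICc, ΔAICc, w."""
    return pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "K": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "AICc": [f.aicc for f in fits],
            "delta_AICc": [f.delta_aicc for f in fits],
            "weight": [f.weight for f in fits],
        }
    )


def average_models(
    fits, delta_threshold: float = 4.0, zero_substitution: bool = False, z: float = 1.96
) -> pd.DataFrame:
    """Model-averaged coefficients over the confidence set (ΔAICc ≤ threshold).

    Weights are renormalized within the confidence set.  By default each
    term is averaged over the models that contain it (natural averaging,
    with the weights renormalized again over those models);
    ``zero_substitution=True`` instead averages over all confidence-set
    models with beta = 0, SE = 0 where the term is absent.  The
    unconditional SE incorporates between-model variance:

        Un.SE = sum_i w_i * sqrt(SE_i² + (beta_i - beta_bar)²)

    Odds ratios are exp(weighted beta) with Wald CIs
    exp(weighted beta ± z · Un.SE).
    """
    conf = [f for f in fits if f.delta_aicc <= delta_threshold]
    if not conf:
        raise ChoiceDataError(f"no models within ΔAICc <= {delta_threshold}")
    w_all = np.array([f.weight for f in conf])
    w_all = w_all / w_all.sum()
    terms: list[str] = []
    for f in conf:
        for t in f.spec.terms:
            if t not in terms:
                terms.append(t)
    rows = []
    for t in terms:
        if zero_substitution:
            betas = np.array([f.beta.get(t, 0.0) for f in conf])
            ses = np.array([f.se.get(t, 0.0) for f in conf])
            w = w_all
        else:
            has = [i for i, f in enumerate(conf) if t in f.beta]
            betas = np.array([conf[i].beta[t] for i in has])
            ses = np.array([conf[i].se[t] for i in has])
            w = w_all[has] / w_all[has].sum()
        beta_bar = float(w @ betas)
        un_se = float(w @ np.sqrt(ses**2 + (betas - beta_bar) ** 2))
        rows.append(
            {
                "term": t,
                "wt_beta": beta_bar,
                "un_se": un_se,
                "odds_ratio": math.exp(beta_bar),
                "lo": math.exp(beta_bar - z * un_se),
                "hi": math.exp(beta_bar + z * un_se),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Separation detection
# ---------------------------------------------------------------------------

@dataclass
class SeparationReport:
    term: str
    flag: str  # "none" | "quasi" | "complete"
    sensitivity: float
    specificity: float
    rule: str

    @property
    def separated(self) -> bool:
        return self.flag != "none"


def detect_separation(
    df: pd.DataFrame, term: str, quasi_threshold: float = 0.9
) -> SeparationReport:
    """Flag terms whose values (almost) perfectly distinguish used rows.

    For a categorical term, every non-trivial subset of levels is tried as a
    used-row predictor; for a continuous term, every threshold (both
    directions).  A rule with sensitivity = specificity = 1 is complete
    separation; both ≥ ``quasi_threshold`` is quasi-complete.
    """
    used = df["used"].to_numpy(dtype=bool)
    if used.sum() == 0 or (~used).sum() == 0:
        raise ChoiceDataError("need both used and available rows")
    col = df[term]
    best = (0.0, 0.0, "")
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.astype(str).unique())
        vals = col.astype(str).to_numpy()
        for r in range(1, len(levels)):
            for subset in itertools.combinations(levels, r):
                pred = np.isin(vals, subset)
                best = _better(best, pred, used, f"{term} in {set(subset)}")
    else:
        x = col.to_numpy(dtype=float)
        cuts = np.unique(x)
        mids = (cuts[:-1] + cuts[1:]) / 2.0 if len(cuts) > 1 else []
        for t in mids:
            best = _better(best, x > t, used, f"{term} > {t:g}")
            best = _better(best, x < t, used, f"{term} < {t:g}")
    sens, spec, rule = best
    if sens == 1.0 and spec == 1.0:
        flag = "complete"
    elif sens >= quasi_threshold and spec >= quasi_threshold:
        flag = "quasi"
    else:
        flag = "none"
    return SeparationReport(term=term, flag=flag, sensitivity=sens, specificity=spec, rule=rule)


def _better(best, pred, used, rule):
    sens = float(pred[used].mean())
    spec = float((~pred[~used]).mean())
    return (sens, spec, rule) if min(sens, spec) > min(best[0], best[1]) else best


# ---------------------------------------------------------------------------
# Cross-validation and descriptive summaries
# ---------------------------------------------------------------------------

def kfold_cv(spec: ModelSpec, df: pd.DataFrame, k: int, seed: int = 0) -> float:
    """K-fold cross-validation prediction error (delta).

    Choice sets are shuffled into k folds; the model is fit on k-1 folds and
    in each held-out set the predicted choice is the alternative with
    maximal x'beta-hat.  Delta is the proportion of held-out sets whose used
    row is not top-ranked.  ``k = n_sets`` gives leave-one-out.
    """
    ids = df["set_id"].unique()
    n = len(ids)
    if not (2 <= k <= n):
        raise ChoiceDataError(f"k must be in [2, {n}], got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    folds = np.array_split(perm, k)
    if any(len(f) == 0 for f in folds):
        raise ChoiceDataError("a fold has no choice sets")
    wrong = 0
    for fold in folds:
        mask = df["set_id"].isin(fold)
        # capped coefficients preserve the ranking direction, so separated
        # training folds still yield predictions
        fit = fit_condlogit(spec, df[~mask], raise_on_separation=False)
        beta = np.array([fit.beta[t] for t in spec.terms])
        for cs in split_choice_sets(df[mask]):
            X = build_design(cs.rows, spec.terms)
            pred = int(np.argmax(X @ beta))
            used = int(np.flatnonzero(cs.rows["used"].to_numpy())[0])
            wrong += pred != used
    return wrong / n


def substrate_proportions(df: pd.DataFrame, column: str = "substrate") -> pd.DataFrame:
    """Within-group (used vs available) substrate category proportions."""
    out = []
    for label, grp in (("used", df[df["used"] == 1]), ("available", df[df["used"] == 0])):
        if len(grp) == 0:
            raise ChoiceDataError(f"no {label} records")
        props = grp[column].value_counts(normalize=True)
        for cat, p in props.items():
            out.append({"group": label, "category": cat, "proportion": float(p)})
    return pd.DataFrame(out)
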