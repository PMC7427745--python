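"""Asthma-control labelling and the multivariate classification model.

The outcome label combines symptom-control items (four guideline questions
over the past four weeks) with an exercise bronchoprovocation test: a child
is *uncontrolled* when three or more symptom items are positive OR the
maximal post-exercise FEV1 fall exceeds 12%; asthmatic children not meeting
either clause are *controlled*, and non-asthmatic controls are labelled
separately and excluded from model fitting.

Candidate home-monitoring features are screened for pairwise collinearity
(|r| > 0.8), then entered into a binary logistic regression by stepwise
forward likelihood-ratio selection (entry p < 0.10, removal p > 0.20) run
on each of the m imputed data sets; the majority-vote feature set is
refitted per imputation and pooled with Rubin's rules. Model fit is
summarised by the Nagelkerke pseudo R-squared and per-feature odds ratios;
classification against the clinical label yields sensitivity, specificity
and predictive values.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imputation import ImputedSet, pool

UNCONTROLLED, CONTROLLED, NON_ASTHMATIC = "uncontrolled", "controlled", "non_asthmatic"


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class GinaSymptoms:
    """Four symptom-control items over the past 4 weeks."""

    daytime_symptoms: bool       # > 2 episodes weekly
    reliever_use: bool           # > 2 uses weekly
    nocturnal_symptoms: bool
    activity_limitation: bool

    @property
    def count(self) -> int:
        return sum((self.daytime_symptoms, self.reliever_use,
                    self.nocturnal_symptoms, self.activity_limitation))


@dataclass(frozen=True)
class BPTResult:
    """Exercise bronchoprovocation outcome: maximal FEV1 fall, % (positive = fall)."""

    max_fev1_fall_pct: float

    def __post_init__(self):
        if not -20.0 <= self.max_fev1_fall_pct <= 100.0:
            raise ModelError("FEV1 fall out of admissible range")


@dataclass(frozen=True)
class ControlLabel:
    label: str
    basis: str  # GINA | BPT | both | n/a


def label_control(gina: GinaSymptoms, bpt: BPTResult) -> ControlLabel:
    """Uncontrolled iff >= 3 symptom items OR FEV1 fall > 12% (strict)."""
    by_gina = gina.count >= 3
    by_bpt = bpt.max_fev1_fall_pct > 12.0
    if by_gina and by_bpt:
        return ControlLabel(UNCONTROLLED, "both")
    if by_gina:
        return ControlLabel(UNCONTROLLED, "GINA")
    if by_bpt:
        return ControlLabel(UNCONTROLLED, "BPT")
    return ControlLabel(CONTROLLED, "n/a")


# ---------------------------------------------------------------------------
# Logistic machinery
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    features: list[str]
    coefficients: np.ndarray     # slopes, aligned with features
    intercept: float | None
    covariance: np.ndarray | None = None  # (1+k) x (1+k), intercept first
    nagelkerke: float | None = None
    selection_trace: list = field(default_factory=list)
    firth: bool = False

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        if self.intercept is None:
            raise ModelError("model has no intercept; supply one for scoring")
        return self.intercept + X[self.features].to_numpy(dtype=float) @ self.coefficients

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "coefficients": list(map(float, self.coefficients)),
            "intercept": self.intercept,
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "nagelkerke": self.nagelkerke,
            "firth": self.firth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LogisticModel":
        with open(path) as fh:
            d = json.load(fh)
        cov = None if d.get("covariance") is None else np.asarray(d["covariance"])
        return cls(d["features"], np.asarray(d["coefficients"], dtype=float),
                   d.get("intercept"), cov, d.get("nagelkerke"),
                   firth=d.get("firth", False))


def _loglik(y, p):
    eps = 1e-12
    return float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def _fit_mle(X: np.ndarray, y: np.ndarray):
    """Plain logistic MLE (Newton); raises on separation/non-convergence."""
    import warnings

    import statsmodels.api as sm

    model = sm.Logit(y, X)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=200, method="newton")
    if not res.mle_retvals.get("converged", False):
        raise ModelError("logistic fit did not converge")
    diag = np.diag(res.cov_params())
    if not np.all(np.isfinite(diag)) or np.any(diag < 0) or np.any(np.sqrt(
            np.maximum(diag, 0.0)) > 1e3):
        raise ModelError("quasi-separation: unstable estimates")
    return np.asarray(res.params), np.asarray(res.cov_params()), float(res.llf)


def _fit_firth(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalised logistic regression (Jeffreys-prior score correction)."""
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XtW = X.T * w
        info = XtW @ X + 1e-10 * np.eye(k)
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = p * (1 - p)
    info = (X.T * w) @ X + 1e-10 * np.eye(k)
    cov = np.linalg.inv(info)
    ll = _loglik(y, p) + 0.5 * np.linalg.slogdet(info)[1]
    return beta, cov, ll


def fit_logistic(X: pd.DataFrame, y: np.ndarray, features: list[str]
                 ) -> LogisticModel:
    """Fit intercept + features; falls back to Firth under separation."""
    design = np.column_stack([np.ones(len(X))] +
                             [X[f].to_numpy(dtype=float) for f in features])
    y = np.asarray(y, dtype=float)
    firth = False
    try:
        params, cov, _ = _fit_mle(design, y)
    except Exception:
        params, cov, _ = _fit_firth(design, y)
        firth = True
    model = LogisticModel(list(features), params[1:], float(params[0]), cov, firth=firth)
    model.nagelkerke = nagelkerke_r2(model, X, y)
    return model


def nagelkerke_r2(model: LogisticModel, X: pd.DataFrame, y: np.ndarray) -> float:
    """Cox-Snell pseudo R-squared rescaled by its attainable maximum."""
    y = np.asarray(y, dtype=float)
    n = y.size
    p1 = 1.0 / (1.0 + np.exp(-model.linear_predictor(X)))
    ll1 = _loglik(y, p1)
    p0 = np.full(n, y.mean())
    ll0 = _loglik(y, p0)
    cox_snell = 1.0 - np.exp((ll0 - ll1) * 2.0 / n)
    max_cs = 1.0 - np.exp(ll0 * 2.0 / n)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Collinearity and stepwise selection
# ---------------------------------------------------------------------------

def collinearity_screen(X: pd.DataFrame, threshold: float = 0.8
                        ) -> list[tuple[str, str]]:
    """Feature pairs with |Pearson r| strictly greater than the threshold."""
    corr = X.corr().abs()
    flagged = []
    for a, b in itertools.combinations(X.columns, 2):
        if corr.loc[a, b] > threshold:
            flagged.append((a, b))
    return flagged


def _lr_pvalue(ll_full: float, ll_reduced: float, df: int = 1) -> float:
    lr = max(2.0 * (ll_full - ll_reduced), 0.0)
    return float(stats.chi2.sf(lr, df))


def _stepwise_single(X: pd.DataFrame, y: np.ndarray, candidates: list[str],
                     flagged: list[tuple[str, str]], entry: float,
                     removal: float, trace: list) -> list[str]:
    """Forward likelihood-ratio selection with backward removal checks."""

    def loglik_for(feats: list[str]) -> float:
        # The likelihood-ratio tests need the *unpenalised* log-likelihood
        # for every candidate model, including those fitted by the Firth
        # fallback, or p-values across models are not comparable.
        design = np.column_stack([np.ones(len(X))] +
                                 [X[f].to_numpy(dtype=float) for f in feats])
        try:
            _, _, ll = _fit_mle(design, y)
        except Exception:
            beta, _, _ = _fit_firth(design, y)
            with np.errstate(over="ignore"):
                p = 1.0 / (1.0 + np.exp(-(design @ beta)))
            ll = _loglik(y, p)
        return ll

    conflicts = {}
    for a, b in flagged:
        conflicts.setdefault(a, set()).add(b)
        conflicts.setdefault(b, set()).add(a)

    selected: list[str] = []
    ll_current = loglik_for(selected)
    while True:
        barred = set().union(*(conflicts.get(f, set()) for f in selected)) \
            if selected else set()
        best, best_p, best_ll = None, 1.0, None
        for f in candidates:
            if f in selected or f in barred:
                continue
            ll_new = loglik_for(selected + [f])
            p = _lr_pvalue(ll_new, ll_current)
            if p < best_p:
                best, best_p, best_ll = f, p, ll_new
        if best is None or best_p >= entry:
            break
        selected.append(best)
        ll_current = best_ll
        trace.append(("add", best, best_p))
        # backward pass
        removed = True
        while removed and len(selected) > 1:
            removed = False
            for f in list(selected):
                rest = [g for g in selected if g != f]
                ll_rest = loglik_for(rest)
                p = _lr_pvalue(ll_current, ll_rest)
                if p > removal:
                    selected.remove(f)
                    ll_current = ll_rest
                    trace.append(("remove", f, p))
                    removed = True
                    break
    return selected


def stepwise_logistic(imputed: ImputedSet, labels: np.ndarray,
                      candidates: list[str] | None = None,
                      entry: float = 0.10, removal: float = 0.20,
                      collinearity_threshold: float = 0.8) -> LogisticModel:
    """Stepwise forward-LR logistic model across multiply-imputed data.

    Selection runs separately on each completed data set; features chosen
    in a majority of them form the final set, which is refitted per
    imputation and pooled with Rubin's rules. Among majority sets of equal
    vote the pooled Nagelkerke R-squared (mean across imputations) decides,
    with fewer terms breaking ties. ``labels`` must be binary
    (1 = uncontrolled, 0 = controlled).
    """
    y = np.asarray(labels, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ModelError("labels must be binary 0/1")
    first = imputed.datasets[0]
    candidates = list(candidates if candidates is not None else first.columns)

    trace: list = []
    votes: dict[frozenset, int] = {}
    per_dataset_sets = []
    for ds in imputed.datasets:
        flagged = collinearity_screen(ds[candidates], collinearity_threshold)
        sel = _stepwise_single(ds, y, candidates, flagged, entry, removal, trace)
        per_dataset_sets.append(sel)
        votes[frozenset(sel)] = votes.get(frozenset(sel), 0) + 1

    counts: dict[str, int] = {}
    for sel in per_dataset_sets:
        for f in sel:
            counts[f] = counts.get(f, 0) + 1
    majority = [f for f in candidates if counts.get(f, 0) > imputed.m / 2.0]
    if not majority:
        # no feature selected in a majority of imputations: intercept-only
        model = LogisticModel([], np.array([]), float(np.log(y.mean() / (1 - y.mean())))
                              if 0 < y.mean() < 1 else 0.0)
        model.nagelkerke = 0.0
        model.selection_trace = trace
        return model

    fits = [fit_logistic(ds, y, majority) for ds in imputed.datasets]
    params = np.array([[f.intercept] + list(f.coefficients) for f in fits])
    variances = np.array([np.diag(f.covariance) for f in fits])
    pooled = pool(params, variances)
    cov = np.diag(pooled.total_variance)
    model = LogisticModel(majority, pooled.estimate[1:], float(pooled.estimate[0]), cov,
                          firth=any(f.firth for f in fits))
    model.nagelkerke = float(np.mean([f.nagelkerke for f in fits]))
    model.selection_trace = trace
    return model


# ---------------------------------------------------------------------------
# Odds ratios, scoring, classification
# ---------------------------------------------------------------------------

def odds_ratios(model: LogisticModel, z: float = 1.96) -> pd.DataFrame:
    """Per-feature odds ratio, 95% CI, and the inverse odds ratio.

    The inverse (exp(-beta)) expresses the effect per unit *decrease* of
    the covariate, the natural reading for negatively coded features such
    as wake-up time.
    """
    if model.covariance is not None:
        se = np.sqrt(np.diag(model.covariance))[1:len(model.features) + 1]
    else:
        se = np.full(len(model.features), np.nan)
    beta = model.coefficients
    return pd.DataFrame({
        "coefficient": beta,
        "se": se,
        "odds_ratio": np.exp(beta),
        "ci_low": np.exp(beta - z * se),
        "ci_high": np.exp(beta + z * se),
        "inverse_odds_ratio": np.exp(-beta),
    }, index=model.features)


def score(model: LogisticModel, features: pd.DataFrame, threshold: float = 0.5,
          intercept: float | None = None) -> pd.DataFrame:
    """Predicted probability of uncontrolled asthma and the class call.

    The class is uncontrolled iff p strictly exceeds the threshold. A
    published slope-only model needs ``intercept`` supplied here.
    """
    if intercept is not None:
        model = LogisticModel(model.features, model.coefficients, float(intercept))
    eta = model.linear_predictor(features)
    p = 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame({"probability": p,
                         "predicted": np.where(p > threshold, UNCONTROLLED, CONTROLLED)},
                        index=features.index)


@dataclass
class ClassificationMetrics:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ModelError("confusion-matrix cells must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else np.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else np.nan

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        return {name: round(100.0 * getattr(self, name), decimals)
                for name in ("sensitivity", "specificity", "ppv", "npv")}


def classification_metrics(true_labels, predicted_labels,
                           positive: str = UNCONTROLLED) -> ClassificationMetrics:
    t = np.asarray(true_labels) == positive
    p = np.asarray(predicted_labels) == positive
    return ClassificationMetrics(
        tp=int(np.sum(t & p)), fn=int(np.sum(t & ~p)),
        fp=int(np.sum(~t & p)), tn=int(np.sum(~t & ~p)))


# ---------------------------------------------------------------------------
# Univariate group comparisons (reporting plumbing)
# ---------------------------------------------------------------------------

def univariate_report(features: pd.DataFrame, groups: pd.Series,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Three-group comparison per parameter with a normality/variance gate.

    Shapiro-Wilk (per group) and Levene tests route each parameter either
    to one-way ANOVA with Tukey HSD post-hocs or to Kruskal-Wallis with
    Games-Howell post-hocs. Returns one row per parameter with the routed
    test, its p-value, and significant post-hoc pairs.
    """
    import pingouin as pg
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rows = []
    for col in features.columns:
        data = pd.DataFrame({"value": features[col], "group": groups}).dropna()
        present = [g for g, d in data.groupby("group", observed=True) if len(d) >= 3]
        data = data[data["group"].isin(present)]
        if len(present) < 2:
            rows.append({"parameter": col, "test": "insufficient", "p_value": np.nan,
                         "significant_pairs": ""})
            continue
        samples = [d["value"].to_numpy() for _, d in data.groupby("group", observed=True)]
        normal = all(len(s) < 3 or stats.shapiro(s).pvalue > alpha for s in samples)
        homogeneous = stats.levene(*samples).pvalue > alpha if len(samples) > 1 else True
        if normal and homogeneous:
            p = float(stats.f_oneway(*samples).pvalue)
            tk = pairwise_tukeyhsd(data["value"], data["group"], alpha=alpha)
            pairs = [f"{g1}|{g2}" for (g1, g2), rej in
                     zip(itertools.combinations(tk.groupsunique, 2), tk.reject) if rej]
            test = "anova"
        else:
            p = float(stats.kruskal(*samples).pvalue)
            gh = pg.pairwise_gameshowell(data=data, dv="value", between="group")
            pairs = [f"{r.A}|{r.B}" for r in gh.itertuples() if r.pval < alpha]
            test = "kruskal-wallis"
        rows.append({"parameter": col, "test": test, "p_value": p,
                     "significant_pairs": ";".join(pairs)})
    return pd.DataFrame(rows).set_index("parameter")
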