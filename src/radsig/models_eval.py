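"""Final model fitting and evaluation.

Multivariable logistic regression (maximum likelihood, statsmodels) for
the binary response endpoint and Cox regression (maximum partial
likelihood, Efron ties, lifelines) for the survival endpoint.
Discrimination is the area under the ROC curve (Mann-Whitney statistic,
ties counted 1/2) or Harrell's concordance index, both with
bias-corrected-and-accelerated (BCa) bootstrap 95% confidence intervals
over 400 resamples. Cutoffs: Youden index on training scores (binary);
maximally selected rank statistics — the standardized two-sample
log-rank statistic maximised over admissible score splits — for risk
stratification (survival). Calibration: Hosmer-Lemeshow for predicted
probabilities and the Greenwood-Nam-d'Agostino (GND) test for predicted
survival at a landmark time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FittedModel", "EvaluationReport", "fit_logistic", "fit_cox",
    "auc", "auc_estimate", "concordance", "concordance_estimate",
    "youden_cutoff", "confusion", "maxstat_cutoff", "kaplan_meier",
    "logrank_2sample", "km_logrank", "hosmer_lemeshow", "gnd_test",
]


# ------------------------------------------------------------- models

@dataclass
class FittedModel:
    kind: str                       # "logistic" | "cox"
    coefficients: dict[str, float]  # logistic includes "intercept"
    feature_names: list[str]
    training_meta: dict = field(default_factory=dict)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_names].to_numpy(dtype=float)
        beta = np.array([self.coefficients[f] for f in self.feature_names])
        lp = X @ beta
        if self.kind == "logistic":
            lp = lp + self.coefficients["intercept"]
        return lp

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        if self.kind != "logistic":
            raise ValueError("probabilities are defined for logistic models")
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(table)))

    def predict_survival(self, table: pd.DataFrame, t_star: float) -> np.ndarray:
        """S(t*|x) from the stored Breslow baseline cumulative hazard."""
        if self.kind != "cox":
            raise ValueError("survival predictions need a Cox model")
        base = self.training_meta["baseline_cumhaz"]
        h0 = float(np.interp(t_star, base["time"], base["cumhaz"]))
        return np.exp(-h0 * np.exp(self.linear_predictor(table)))


def fit_logistic(table: pd.DataFrame, labels: np.ndarray,
                 tol: float = 1e-8) -> FittedModel:
    labels = np.asarray(labels)
    X = sm.add_constant(table.to_numpy(dtype=float), has_constant="add")
    try:
        res = sm.Logit(labels, X).fit(disp=0, method="newton", tol=tol,
                                      maxiter=200)
    except Exception as exc:
        raise RuntimeError(
            f"logistic fit failed for covariates {list(table.columns)}: {exc}"
        ) from exc
    params = np.asarray(res.params)
    if not res.mle_retvals.get("converged", True) or np.abs(params).max() > 1e3:
        worst = table.columns[int(np.argmax(np.abs(params[1:])))]
        raise RuntimeError(f"logistic fit did not converge (separation?); "
                           f"largest coefficient on {worst!r}")
    coeffs = {"intercept": float(params[0])}
    coeffs.update({f: float(b) for f, b in zip(table.columns, params[1:])})
    return FittedModel("logistic", coeffs, list(table.columns),
                       {"n": len(labels), "llf": float(res.llf)})


def fit_cox(table: pd.DataFrame, times: np.ndarray, events: np.ndarray
            ) -> FittedModel:
    df = table.copy()
    df["time"] = np.asarray(times, float)
    df["event"] = np.asarray(events, int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise RuntimeError(
            f"Cox fit failed for covariates {list(table.columns)}: {exc}"
        ) from exc
    coeffs = {f: float(b) for f, b in cph.params_.items()}
    base = cph.baseline_cumulative_hazard_
    meta = {"n": len(df), "n_events": int(df["event"].sum()),
            "baseline_cumhaz": {"time": base.index.to_numpy(dtype=float),
                                "cumhaz": base.iloc[:, 0].to_numpy(dtype=float)}}
    return FittedModel("cox", coeffs, list(table.columns), meta)


# ----------------------------------------------------- discrimination

def auc_estimate(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC, ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def concordance_estimate(scores: np.ndarray, times: np.ndarray,
                         events: np.ndarray) -> float:
    """Harrell's C: higher score = worse outcome (earlier event)."""
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int).astype(bool)
    comparable = (e[:, None] & ((t[:, None] < t[None, :])
                                | ((t[:, None] == t[None, :]) & ~e[None, :])))
    np.fill_diagonal(comparable, False)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no usable pairs for concordance")
    conc = comparable & (s[:, None] > s[None, :])
    ties = comparable & (s[:, None] == s[None, :])
    return float((conc.sum() + 0.5 * ties.sum()) / n_pairs)


def _bca_interval(estimate: float, boots: np.ndarray, jack: np.ndarray,
                  alpha: float = 0.05, accelerated: bool = True
                  ) -> tuple[float, float]:
    boots = boots[np.isfinite(boots)]
    if len(boots) == 0:
        return float("nan"), float("nan")
    prop = ((boots < estimate).sum() + 0.5 * (boots == estimate).sum()) / len(boots)
    prop = min(max(prop, 1.0 / (len(boots) + 1)), len(boots) / (len(boots) + 1.0))
    z0 = stats.norm.ppf(prop)
    if accelerated and len(jack) > 2:
        d = jack.mean() - jack
        denom = (d ** 2).sum() ** 1.5
        a = (d ** 3).sum() / (6 * denom) if denom > 0 else 0.0
    else:
        a = 0.0
    out = []
    for q in (alpha / 2, 1 - alpha / 2):
        z = stats.norm.ppf(q)
        adj = z0 + (z0 + z) / (1 - a * (z0 + z))
        out.append(float(np.quantile(boots, stats.norm.cdf(adj))))
    return out[0], out[1]


def _bootstrap_metric(stat_fn, n: int, valid_fn, n_boot: int, seed: int):
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            if valid_fn(idx):
                break
            redraws += 1
        boots[b] = stat_fn(idx)
    if redraws:
        logger.info("redrew %d degenerate bootstrap resamples", redraws)
    return boots


@dataclass
class MetricResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int


def auc(scores: np.ndarray, labels: np.ndarray, n_boot: int = 400,
        seed: int = 0, accelerated: bool = True) -> MetricResult:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    est = auc_estimate(scores, labels)
    n = len(labels)
    boots = _bootstrap_metric(
        lambda idx: auc_estimate(scores[idx], labels[idx]), n,
        lambda idx: len(np.unique(labels[idx])) == 2, n_boot, seed)
    jack = np.array([auc_estimate(np.delete(scores, i), np.delete(labels, i))
                     for i in range(n)
                     if len(np.unique(np.delete(labels, i))) == 2])
    lo, hi = _bca_interval(est, boots, jack, accelerated=accelerated)
    return MetricResult(est, lo, hi, n_boot)


def concordance(scores: np.ndarray, times: np.ndarray, events: np.ndarray,
                n_boot: int = 400, seed: int = 0, accelerated: bool = True
                ) -> MetricResult:
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    est = concordance_estimate(scores, times, events)
    n = len(times)

    def stat(idx):
        try:
            return concordance_estimate(scores[idx], times[idx], events[idx])
        except ValueError:
            return float("nan")

    boots = _bootstrap_metric(stat, n, lambda idx: events[idx].sum() > 0,
                              n_boot, seed)
    jack = []
    for i in range(n):
        keep = np.arange(n) != i
        try:
            jack.append(concordance_estimate(scores[keep], times[keep],
                                             events[keep]))
        except ValueError:
            pass
    lo, hi = _bca_interval(est, boots, np.asarray(jack),
                           accelerated=accelerated)
    return MetricResult(est, lo, hi, n_boot)


# ------------------------------------------------------------ cutoffs

def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximising sensitivity + specificity - 1 over midpoints
    of adjacent observed scores (ties resolved toward the lower one)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0])
    cands = (uniq[:-1] + uniq[1:]) / 2
    n1 = labels.sum()
    n0 = len(labels) - n1
    best_t, best_j = cands[0], -np.inf
    for t in cands:
        sens = ((scores >= t) & (labels == 1)).sum() / n1
        spec = ((scores < t) & (labels == 0)).sum() / n0
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def confusion(scores: np.ndarray, labels: np.ndarray, threshold: float
              ) -> dict[str, int]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    return {"tp": int((pred & (labels == 1)).sum()),
            "fp": int((pred & (labels == 0)).sum()),
            "fn": int((~pred & (labels == 1)).sum()),
            "tn": int((~pred & (labels == 0)).sum())}


# --------------------------------------------------- survival metrics

def kaplan_meier(times: np.ndarray, events: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(event times, survival, Greenwood variance) — right-continuous."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq = np.unique(t[e == 1])
    surv, var_terms = [], []
    s = 1.0
    gw = 0.0
    n = len(t)
    for u in uniq:
        at_risk = (t >= u).sum()
        d = ((t == u) & (e == 1)).sum()
        s *= 1 - d / at_risk
        if at_risk > d:
            gw += d / (at_risk * (at_risk - d))
        surv.append(s)
        var_terms.append(s ** 2 * gw)
    return uniq, np.asarray(surv), np.asarray(var_terms)


def km_at(times: np.ndarray, events: np.ndarray, t_star: float
          ) -> tuple[float, float]:
    """(KM survival, Greenwood variance) at time t_star."""
    uniq, surv, var = kaplan_meier(times, events)
    idx = np.searchsorted(uniq, t_star, side="right") - 1
    if idx < 0:
        return 1.0, 0.0
    return float(surv[idx]), float(var[idx])


def logrank_2sample(times: np.ndarray, events: np.ndarray,
                    groups: np.ndarray) -> tuple[float, float, float, float]:
    """Two-sample log-rank: (chi2, p, O1 - E1, variance)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups).astype(int)
    uniq = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in uniq:
        at_risk = times >= u
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == u) & (events == 1)).sum()
        d1 = ((times == u) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0, float(o_minus_e), 0.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1)), float(o_minus_e), float(var)


def maxstat_cutoff(scores: np.ndarray, times: np.ndarray, events: np.ndarray,
                   min_prop: float = 0.1) -> float:
    """Maximally selected rank statistic: the score split maximising the
    absolute standardized log-rank statistic, both groups >= min_prop*n."""
    scores = np.asarray(scores, float)
    n = len(scores)
    uniq = np.unique(scores)
    cands = (uniq[:-1] + uniq[1:]) / 2
    admissible = [t for t in cands
                  if min((scores >= t).sum(), (scores < t).sum()) >= min_prop * n]
    if not admissible:
        raise ValueError("no admissible cutpoint under the group-size "
                         "constraint")
    best_t, best_z = admissible[0], -np.inf
    for t in admissible:
        grp = (scores >= t).astype(int)
        _, _, ome, var = logrank_2sample(times, events, grp)
        z = abs(ome) / np.sqrt(var) if var > 0 else 0.0
        if z > best_z + 1e-12:
            best_z, best_t = z, t
    return float(best_t)


def km_logrank(groups: np.ndarray, times: np.ndarray, events: np.ndarray):
    """Per-group KM curves plus the two-sample log-rank chi2 and p."""
    groups = np.asarray(groups).astype(int)
    if len(np.unique(groups)) != 2:
        raise ValueError("risk stratification needs exactly 2 non-empty groups")
    curves = {}
    for g in np.unique(groups):
        sel = groups == g
        t, s, v = kaplan_meier(times[sel], events[sel])
        curves[int(g)] = pd.DataFrame({"time": t, "survival": s,
                                       "greenwood_var": v})
    chi2, p, ome, var = logrank_2sample(times, events, groups)
    return curves, chi2, p


# ---------------------------------------------------------- calibration

def hosmer_lemeshow(pred_probs: np.ndarray, labels: np.ndarray, g: int = 10
                    ) -> tuple[float, float, int]:
    """Hosmer-Lemeshow chi2, p, and the effective group count.

    Groups are equal-frequency deciles of predicted probability;
    duplicate quantile edges collapse groups (df adjusts, minimum 1).
    """
    p = np.asarray(pred_probs, float)
    y = np.asarray(labels)
    if len(p) < 2 * g:
        raise ValueError(f"need at least {2 * g} subjects for {g} groups")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, g + 1)[1:-1]))
    grp = np.searchsorted(edges, p, side="right")
    chi2 = 0.0
    g_eff = 0
    for gi in np.unique(grp):
        sel = grp == gi
        n_g = sel.sum()
        obs = y[sel].sum()
        exp = p[sel].sum()
        denom = exp * (1 - exp / n_g)
        if denom <= 0:
            continue
        chi2 += (obs - exp) ** 2 / denom
        g_eff += 1
    df = max(g_eff - 2, 1)
    return float(chi2), float(stats.chi2.sf(chi2, df)), g_eff


def gnd_test(pred_surv: np.ndarray, times: np.ndarray, events: np.ndarray,
             t_star: float, g: int = 10) -> tuple[float, float, int]:
    """Greenwood-Nam-d'Agostino calibration test at landmark t_star.

    Subjects are grouped by predicted survival quantiles; per group the
    observed KM survival at t_star is compared with the mean predicted
    survival, standardized by the Greenwood variance. Groups without
    events before t_star (zero variance) are dropped with df adjusted.
    """
    ps = np.asarray(pred_surv, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if t_star > times.max():
        raise ValueError("t_star beyond observed follow-up")
    edges = np.unique(np.quantile(ps, np.linspace(0, 1, g + 1)[1:-1]))
    grp = np.searchsorted(edges, ps, side="right")
    chi2 = 0.0
    contributing = 0
    for gi in np.unique(grp):
        sel = grp == gi
        if sel.sum() == 0:
            continue
        km, var = km_at(times[sel], events[sel], t_star)
        if var <= 0:
            logger.info("GND: group %d has zero Greenwood variance; dropped", gi)
            continue
        chi2 += (km - ps[sel].mean()) ** 2 / var
        contributing += 1
    if contributing == 0:
        return 0.0, 1.0, 0
    return float(chi2), float(stats.chi2.sf(chi2, contributing)), contributing


# --------------------------------------------------------------- report

@dataclass
class EvaluationReport:
    endpoint: str
    metric: MetricResult
    cutoff: float | None = None
    confusion: dict[str, int] | None = None
    group_sizes: tuple[int, int] | None = None
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    calibration_stat: float | None = None
    calibration_p: float | None = None

    def to_dict(self) -> dict:
        out = {"endpoint": self.endpoint,
               "estimate": self.metric.estimate,
               "ci_low": self.metric.ci_low, "ci_high": self.metric.ci_high}
        for key in ("cutoff", "confusion", "group_sizes", "logrank_chi2",
                    "logrank_p", "calibration_stat", "calibration_p"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out


def evaluate_binary(model: FittedModel, table: pd.DataFrame,
                    labels: np.ndarray, threshold: float | None = None,
                    n_boot: int = 400, seed: int = 0) -> EvaluationReport:
    """Discrimination + cutoff transfer + HL calibration on one dataset."""
    probs = model.predict_proba(table)
    metric = auc(probs, labels, n_boot=n_boot, seed=seed)
    if threshold is None:
        threshold = youden_cutoff(probs, labels)
    conf = confusion(probs, labels, threshold)
    try:
        hl_stat, hl_p, _ = hosmer_lemeshow(probs, labels)
    except ValueError:
        hl_stat = hl_p = None
    return EvaluationReport("binary-response", metric, cutoff=float(threshold),
                            confusion=conf, calibration_stat=hl_stat,
                            calibration_p=hl_p)


def evaluate_survival(model: FittedModel, table: pd.DataFrame,
                      times: np.ndarray, events: np.ndarray,
                      threshold: float | None = None, t_star: float = 24.0,
                      n_boot: int = 400, seed: int = 0) -> EvaluationReport:
    """Concordance + risk stratification + GND calibration on one dataset."""
    risk = model.linear_predictor(table)
    metric = concordance(risk, times, events, n_boot=n_boot, seed=seed)
    if threshold is None:
        threshold = maxstat_cutoff(risk, times, events)
    groups = (risk >= threshold).astype(int)
    if len(np.unique(groups)) == 2:
        _, chi2, p = km_logrank(groups, times, events)
        sizes = (int((groups == 0).sum()), int((groups == 1).sum()))
    else:
        chi2 = p = None
        sizes = (int((groups == 0).sum()), int((groups == 1).sum()))
    gnd_stat = gnd_p = None
    if model.kind == "cox" and t_star <= times.max():
        ps = model.predict_survival(table, t_star)
        gnd_stat, gnd_p, _ = gnd_test(ps, times, events, t_star)
    return EvaluationReport("survival", metric, cutoff=float(threshold),
                            group_sizes=sizes, logrank_chi2=chi2, logrank_p=p,
                            calibration_stat=gnd_stat, calibration_p=gnd_p)
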