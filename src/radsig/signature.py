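"""Signature discovery: repeated stratified CV, four selectors, occurrence rule.

The training cohort is split into 33 repetitions of stratified 3-fold
cross-validation (99 runs). In every run the features are Yeo-Johnson
transformed and z-scored on the internal training part (parameters
frozen and applied to the internal validation part), and four selectors
each nominate at most five features: mutual-information maximisation
(MIM), minimal-redundancy-maximum-relevance (MRMR, difference
criterion), an elastic net (mixing 0.5, penalty weight by internal
5-fold CV), and univariable regression (smallest Wald p).

A feature becomes a candidate when it occurs in at least 50% of the 99
runs for at least 3 of the 4 selectors; candidates are ranked by the
sum of their four per-method occurrence fractions (cumulative
occurrence) and greedily pruned so no two signature members have
|Spearman rho| > 0.5 on the full training data. Signatures from two
modalities can be pooled and re-pruned the same way, and clinical
covariates with a significant univariable association (Wald p < 0.05)
are appended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._fastglm import uni_cox_wald, uni_logistic_wald
from .outcomes import BINARY, OutcomeData

logger = logging.getLogger(__name__)

SELECTOR_METHODS = ("MIM", "MRMR", "elastic-net", "univariate")


# ------------------------------------------------------------- CV scheme

@dataclass
class CVScheme:
    """(repetition, fold) -> train/validation row indices."""
    assignments: list[tuple[int, int, np.ndarray, np.ndarray]]
    reps: int
    folds: int
    seed: int

    @property
    def n_runs(self) -> int:
        return len(self.assignments)


def make_cv_scheme(outcomes: OutcomeData, endpoint_kind: str, reps: int = 33,
                   folds: int = 3, seed: int = 0) -> CVScheme:
    """Stratified by label (binary) or event indicator (survival)."""
    strata = (outcomes.labels if endpoint_kind == BINARY
              else outcomes.events)
    strata = np.asarray(strata)
    counts = np.bincount(strata)
    if counts.min() < folds:
        raise ValueError(
            f"stratification infeasible: smallest class has {counts.min()} "
            f"subjects for {folds} folds")
    rng = np.random.default_rng(seed)
    assignments = []
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for fold, (tr, va) in enumerate(skf.split(np.zeros(len(strata)), strata)):
            assignments.append((rep, fold, tr, va))
    return CVScheme(assignments, reps, folds, seed)


# ------------------------------------------------------ transformations

def yeo_johnson(x: np.ndarray, lam: float) -> np.ndarray:
    """The Yeo-Johnson power transform at a given lambda."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lam) > 1e-12:
        out[pos] = ((x[pos] + 1) ** lam - 1) / lam
    else:
        out[pos] = np.log1p(x[pos])
    if abs(lam - 2) > 1e-12:
        out[~pos] = -(((1 - x[~pos]) ** (2 - lam)) - 1) / (2 - lam)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out


def yeo_johnson_mle(x: np.ndarray, bounds: tuple[float, float] = (-5.0, 5.0)
                    ) -> float:
    """Maximum-likelihood lambda (profile log-likelihood, bounded search)."""
    x = np.asarray(x, dtype=float)
    const = float((np.sign(x) * np.log1p(np.abs(x))).sum())
    n = x.size

    def neg_llf(lam: float) -> float:
        xt = yeo_johnson(x, lam)
        var = xt.var(ddof=0)
        if var <= 0 or not np.isfinite(var):
            return np.inf
        return 0.5 * n * np.log(var) - (lam - 1) * const

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(neg_llf, bounds=bounds, method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


@dataclass
class TransformParams:
    """Per-feature Yeo-Johnson lambda + post-transform z-scaling."""
    lambdas: dict[str, float | None]
    means: dict[str, float]
    sds: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)


def fit_yeo_johnson(table: pd.DataFrame) -> TransformParams:
    lambdas: dict[str, float | None] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    flags: dict[str, str] = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            lambdas[col] = None
            means[col], sds[col] = float(x[0]), 1.0
            flags[col] = "constant_identity"
            continue
        try:
            lam = yeo_johnson_mle(x)
            xt = yeo_johnson(x, lam)
        except Exception:
            xt, lam = x, None
            flags[col] = "yj_failed_identity"
        lambdas[col] = None if lam is None else float(lam)
        sd = float(np.std(xt, ddof=0))
        means[col] = float(np.mean(xt))
        sds[col] = sd if sd > 0 else 1.0
        if sd == 0:
            flags[col] = "constant_after_transform"
    return TransformParams(lambdas, means, sds, flags)


def apply_transform(params: TransformParams, table: pd.DataFrame
                    ) -> pd.DataFrame:
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        lam = params.lambdas[col]
        xt = x if lam is None else yeo_johnson(x, lam)
        out[col] = (xt - params.means[col]) / params.sds[col]
    return pd.DataFrame(out, index=table.index)


# ----------------------------------------------------------- selectors

def _bin_columns(X: np.ndarray, n_bins: int = 4) -> np.ndarray:
    xb = np.empty(X.shape, dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(X.shape[1]):
        edges = np.quantile(X[:, j], qs)
        xb[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return xb


def _mi_discrete(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / len(a)
    pa = joint.sum(1, keepdims=True)
    pb = joint.sum(0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def _endpoint_vector(outcomes: OutcomeData, endpoint_kind: str) -> np.ndarray:
    return (outcomes.labels if endpoint_kind == BINARY
            else outcomes.events).astype(np.int64)


def _select_mim(Xb, y_disc, names, k):
    rel = [_mi_discrete(Xb[:, j], y_disc) for j in range(Xb.shape[1])]
    order = sorted(range(len(names)), key=lambda j: (-rel[j], names[j]))
    return [names[j] for j in order[:k]]


def _select_mrmr(Xb, y_disc, names, k):
    p = Xb.shape[1]
    rel = np.array([_mi_discrete(Xb[:, j], y_disc) for j in range(p)])
    selected: list[int] = []
    red_sum = np.zeros(p)
    remaining = set(range(p))
    while len(selected) < min(k, p):
        if selected:
            crit = {j: rel[j] - red_sum[j] / len(selected) for j in remaining}
        else:
            crit = {j: rel[j] for j in remaining}
        best = min(remaining, key=lambda j: (-crit[j], names[j]))
        selected.append(best)
        remaining.discard(best)
        for j in remaining:
            red_sum[j] += _mi_discrete(Xb[:, j], Xb[:, best])
    return [names[j] for j in selected]


def _select_univariate(X, outcomes, endpoint_kind, names, k):
    pvals = []
    for j in range(X.shape[1]):
        if endpoint_kind == BINARY:
            _, pv = uni_logistic_wald(X[:, j], outcomes.labels)
        else:
            _, pv = uni_cox_wald(X[:, j], outcomes.times, outcomes.events)
        pvals.append(pv)
    order = sorted(range(len(names)), key=lambda j: (pvals[j], names[j]))
    return [names[j] for j in order[:k]]


def _enet_logistic(X, y, names, k, seed, l1_ratio=0.5, n_lambdas=12,
                   internal_folds=5):
    n = len(y)
    yc = y - y.mean()
    lam_max = np.abs(X.T @ yc).max() / (n * l1_ratio)
    lam_max = max(lam_max, 1e-6)
    lams = np.geomspace(lam_max, lam_max * 0.01, n_lambdas)
    cs = 1.0 / (n * lams)
    min_class = np.bincount(y).min()
    cv = min(internal_folds, min_class)
    scores = np.zeros(n_lambdas)
    if cv >= 2:
        skf = StratifiedKFold(cv, shuffle=True, random_state=seed % (2**31 - 1))
        for tr, te in skf.split(X, y):
            clf = LogisticRegression(l1_ratio=l1_ratio, solver="saga",
                                     warm_start=True, max_iter=300, tol=1e-3,
                                     random_state=seed % (2**31 - 1))
            for i, c in enumerate(cs):
                clf.C = c
                clf.fit(X[tr], y[tr])
                eta = X[te] @ clf.coef_.ravel() + clf.intercept_[0]
                # mean negative log-likelihood on the held-out part
                scores[i] += float(np.mean(np.logaddexp(0.0, eta))
                                   - np.mean(y[te] * eta))
        best = int(np.argmin(scores))
    else:
        best = n_lambdas // 2
    clf = LogisticRegression(l1_ratio=l1_ratio, solver="saga", C=cs[best],
                             max_iter=1000, tol=1e-4,
                             random_state=seed % (2**31 - 1))
    clf.fit(X, y)
    coefs = clf.coef_.ravel()
    nz = np.flatnonzero(coefs)
    order = sorted(nz, key=lambda j: (-abs(coefs[j]), names[j]))
    return [names[j] for j in order[:k]]


def _enet_cox(X, times, events, names, k, seed, l1_ratio=0.5, n_lambdas=12,
              internal_folds=5):
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(events.astype(bool), times)
    base = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=n_lambdas,
                                  alpha_min_ratio=0.01)
    base.fit(X, y)
    alphas = base.alphas_
    min_class = min(events.sum(), len(events) - events.sum())
    cv = int(min(internal_folds, max(min_class, 0)))
    best = len(alphas) // 2
    if cv >= 2:
        from lifelines.utils import concordance_index
        skf = StratifiedKFold(cv, shuffle=True, random_state=seed % (2**31 - 1))
        scores = np.zeros(len(alphas))
        for tr, te in skf.split(X, events):
            if events[tr].sum() == 0 or events[te].sum() == 0:
                continue
            m = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas,
                                       fit_baseline_model=False)
            m.fit(X[tr], y[tr])
            for i, a in enumerate(m.alphas_):
                risk = m.predict(X[te], alpha=a)
                try:
                    scores[i] += concordance_index(times[te], -risk, events[te])
                except ZeroDivisionError:
                    pass
        best = int(np.argmax(scores))
    coefs = base.coef_[:, min(best, base.coef_.shape[1] - 1)]
    nz = np.flatnonzero(coefs)
    order = sorted(nz, key=lambda j: (-abs(coefs[j]), names[j]))
    return [names[j] for j in order[:k]]


def run_selectors(train_table: pd.DataFrame, outcomes: OutcomeData,
                  endpoint_kind: str, k: int = 5, seed: int = 0
                  ) -> dict[str, list[str]]:
    """Each selector's ordered list of at most ``k`` feature names."""
    names = list(train_table.columns)
    X = train_table.to_numpy(dtype=float)
    y_disc = _endpoint_vector(outcomes, endpoint_kind)
    Xb = _bin_columns(X)
    out = {}
    out["MIM"] = _select_mim(Xb, y_disc, names, k)
    out["MRMR"] = _select_mrmr(Xb, y_disc, names, k)
    try:
        if endpoint_kind == BINARY:
            out["elastic-net"] = _enet_logistic(X, outcomes.labels, names, k, seed)
        else:
            out["elastic-net"] = _enet_cox(X, outcomes.times, outcomes.events,
                                           names, k, seed)
    except Exception as exc:
        logger.warning("elastic-net selector failed: %s", exc)
        out["elastic-net"] = []
    out["univariate"] = _select_univariate(X, outcomes, endpoint_kind, names, k)
    return out


# -------------------------------------------------------------- CV loop

@dataclass
class CVRunRecord:
    rep: int
    fold: int
    selected: dict[str, list[str]]
    performance: dict[str, float] = field(default_factory=dict)


def _fit_eval_binary(Xtr, ytr, Xva, yva) -> float:
    from .models_eval import auc_estimate
    clf = LogisticRegression(C=np.inf, max_iter=500)
    clf.fit(Xtr, ytr)
    return auc_estimate(clf.decision_function(Xva), yva)


def _fit_eval_cox(Xtr, ttr, etr, Xva, tva, eva) -> float:
    from lifelines import CoxPHFitter
    from .models_eval import concordance_estimate
    df = pd.DataFrame(Xtr, columns=[f"f{i}" for i in range(Xtr.shape[1])])
    df["time"], df["event"] = ttr, etr
    cph = CoxPHFitter(penalizer=1e-4)
    cph.fit(df, "time", "event")
    risk = Xva @ cph.params_.to_numpy()
    return concordance_estimate(risk, tva, eva)


def run_cv(table: pd.DataFrame, outcomes: OutcomeData, endpoint_kind: str,
           scheme: CVScheme, k: int = 5, evaluate: bool = False
           ) -> list[CVRunRecord]:
    """Execute every (repetition, fold) run of the discovery CV.

    With ``evaluate=True`` each selector's chosen features are used to
    fit an internal model whose validation-part AUC (binary) or
    concordance (survival) is recorded.
    """
    records = []
    for rep, fold, tr, va in scheme.assignments:
        train_tab = table.iloc[tr]
        valid_tab = table.iloc[va]
        out_tr = outcomes.subset(tr)
        out_va = outcomes.subset(va)
        params = fit_yeo_johnson(train_tab)
        ztr = apply_transform(params, train_tab)
        zva = apply_transform(params, valid_tab)
        run_seed = scheme.seed * 10007 + rep * 101 + fold
        selected = run_selectors(ztr, out_tr, endpoint_kind, k, seed=run_seed)
        rec = CVRunRecord(rep, fold, selected)
        if evaluate:
            for method, feats in selected.items():
                if not feats:
                    rec.performance[method] = float("nan")
                    continue
                Xtr = ztr[feats].to_numpy()
                Xva = zva[feats].to_numpy()
                try:
                    if endpoint_kind == BINARY:
                        rec.performance[method] = _fit_eval_binary(
                            Xtr, out_tr.labels, Xva, out_va.labels)
                    else:
                        rec.performance[method] = _fit_eval_cox(
                            Xtr, out_tr.times, out_tr.events,
                            Xva, out_va.times, out_va.events)
                except Exception as exc:
                    logger.warning("run (%d,%d) %s evaluation failed: %s",
                                   rep, fold, method, exc)
                    rec.performance[method] = float("nan")
        records.append(rec)
    return records


# ------------------------------------------------------ occurrence rule

def aggregate_occurrence(records: list[CVRunRecord],
                         methods: tuple[str, ...] = SELECTOR_METHODS,
                         min_occurrence: float = 0.5,
                         min_methods: int = 3
                         ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Occurrence table (feature x method), cumulative occurrence, candidates.

    occurrence(f, m) = fraction of the n runs whose method-m list
    contains f (the denominator is always the full run count, even if a
    selector returned an empty list in some runs). Candidates need
    occurrence >= 50% in at least 3 of the 4 methods; cumulative
    occurrence is the sum of the four fractions.
    """
    n_runs = len(records)
    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        for method in methods:
            for feat in rec.selected.get(method, []):
                counts.setdefault(feat, {m: 0 for m in methods})[method] += 1
    if not counts:
        empty = pd.DataFrame(columns=list(methods))
        return empty, pd.Series(dtype=float), []
    occ = pd.DataFrame.from_dict(counts, orient="index").fillna(0) / n_runs
    occ = occ[list(methods)]
    cumulative = occ.sum(axis=1).rename("cumulative_occurrence")
    qualifies = (occ >= min_occurrence).sum(axis=1) >= min_methods
    candidates = sorted(occ.index[qualifies],
                        key=lambda f: (-cumulative[f], f))
    return occ, cumulative, candidates


@dataclass
class Signature:
    features: list[str]
    clinical: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def members(self) -> list[str]:
        return self.features + self.clinical

    @property
    def is_empty(self) -> bool:
        return not self.members


def prune_correlated(candidates: list[str], cumulative: pd.Series,
                     train_table: pd.DataFrame, rho_max: float = 0.5
                     ) -> Signature:
    """Greedy de-correlation: accept by descending cumulative occurrence,
    reject anything with |Spearman rho| > rho_max to an accepted member."""
    ranked = sorted(candidates, key=lambda f: (-cumulative.get(f, 0.0), f))
    accepted: list[str] = []
    for feat in ranked:
        ok = True
        for kept in accepted:
            rho = sstats.spearmanr(train_table[feat], train_table[kept]).statistic
            if abs(rho) > rho_max:
                ok = False
                break
        if ok:
            accepted.append(feat)
    prov = {"candidates": list(ranked),
            "cumulative_occurrence": {f: float(cumulative.get(f, 0.0))
                                      for f in ranked}}
    if not accepted:
        logger.info("no feature selected")
    return Signature(accepted, provenance=prov)


def join_signatures(sig_a: Signature, sig_b: Signature,
                    train_table: pd.DataFrame, rho_max: float = 0.5
                    ) -> Signature:
    """Pool two signatures and re-prune with carried-over occurrences."""
    cum = {}
    for sig in (sig_a, sig_b):
        cum.update(sig.provenance.get("cumulative_occurrence", {}))
    members = list(dict.fromkeys(sig_a.features + sig_b.features))
    cumulative = pd.Series({f: cum.get(f, 0.0) for f in members})
    return prune_correlated(members, cumulative, train_table, rho_max)


def add_clinical(sig: Signature, clinical: pd.DataFrame | None,
                 outcomes: OutcomeData, endpoint_kind: str,
                 alpha: float = 0.05) -> Signature:
    """Append clinical covariates with univariable Wald p < alpha."""
    if clinical is None or clinical.empty:
        return sig
    encoded = pd.get_dummies(clinical, drop_first=True, dtype=float)
    pvals = {}
    for col in encoded.columns:
        x = encoded[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        if endpoint_kind == BINARY:
            coef, pv = uni_logistic_wald(x, outcomes.labels)
            if abs(coef) > 40:
                logger.warning("separation for clinical covariate %s; skipped",
                               col)
                continue
        else:
            coef, pv = uni_cox_wald(x, outcomes.times, outcomes.events)
        pvals[col] = pv
    added = sorted([c for c, p in pvals.items() if p < alpha])
    return Signature(sig.features, clinical=added,
                     provenance={**sig.provenance, "clinical_p": pvals})


def discover_signature(table: pd.DataFrame, outcomes: OutcomeData,
                       endpoint_kind: str, reps: int = 33, folds: int = 3,
                       seed: int = 0, k: int = 5,
                       clinical: pd.DataFrame | None = None,
                       evaluate: bool = False):
    """End-to-end discovery on a representative feature table.

    Returns (signature, records, occurrence table).
    """
    scheme = make_cv_scheme(outcomes, endpoint_kind, reps, folds, seed)
    records = run_cv(table, outcomes, endpoint_kind, scheme, k, evaluate)
    occ, cumulative, candidates = aggregate_occurrence(records)
    sig = prune_correlated(candidates, cumulative, table)
    sig.provenance["occurrence"] = {m: occ[m].to_dict() for m in occ.columns} \
        if not occ.empty else {}
    sig.provenance["n_runs"] = len(records)
    if clinical is not None:
        sig = add_clinical(sig, clinical, outcomes, endpoint_kind)
    return sig, records, occ
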