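"""Balanced presence/pseudo-absence GLM ensemble.

The habitat model is a binomial GLM (logit link) of cell presence on the
eight standardized candidate covariates.  Terms are chosen by a
backward-forward stepwise search that minimizes AIC starting from the
full model.  The whole procedure is replicated 100 times — replicate r
pairs the fixed presence cells with pseudo-absence set r and a fresh
stratified 70/30 train/test split — and each replicate's predictive
power is scored by the rank-based (Mann-Whitney) AUC on its held-out
30%.  Models with mean AUC >= 0.7 are flagged usable.  Competing models
within Delta-AIC <= 2 of the best are tabulated with Akaike weights
w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .env import CANONICAL_VARIABLES, EnvStack, canonical_name
from .occurrence import PresenceSet, PseudoAbsenceDesign

__all__ = [
    "FittedModel",
    "ReplicateResult",
    "EnsembleSummary",
    "fit_glm_binomial",
    "stepwise_aic",
    "akaike_weights",
    "competing_models",
    "auc",
    "run_replicates",
]

AUC_USABLE_THRESHOLD = 0.7
COMPETING_DELTA_AIC = 2.0


def _spec_key(terms) -> tuple[str, ...]:
    return tuple(sorted(canonical_name(t) for t in terms))


@dataclass
class FittedModel:
    """A fitted binomial GLM on standardized covariates.

    ``coefficients`` maps "intercept" and each retained term to its ML
    estimate; ``aic = -2 log L + 2 (number of coefficients)``.
    """

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool = True

    def predict(self, X: pd.DataFrame | np.ndarray, terms=None) -> np.ndarray:
        """Occupancy probability for rows of covariates.

        ``X`` is either a DataFrame with the model terms as columns or an
        array whose columns follow ``terms`` (default: the model's own
        term order).
        """
        if isinstance(X, pd.DataFrame):
            mat = X[list(self.terms)].to_numpy(float)
        else:
            order = list(self.terms if terms is None else terms)
            mat = np.asarray(X, float)[:, [order.index(t) for t in self.terms]]
        beta = np.array([self.coefficients[t] for t in self.terms])
        eta = self.coefficients["intercept"] + mat @ beta
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))


def fit_glm_binomial(design: pd.DataFrame, response) -> FittedModel:
    """Maximum-likelihood logistic fit of presence on the design columns.

    The intercept is added internally; ``design`` holds one column per
    term (possibly none, for the intercept-only model).  Complete
    separation or IRLS non-convergence is reported through the
    ``converged`` flag rather than raised, so callers can drop and count
    the replicate.
    """
    y = np.asarray(response, float)
    if design.isna().to_numpy().any():
        raise ValueError("missing covariate values in design matrix")
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all() or uniq.size < 2:
        raise ValueError("response must contain both presences and absences")

    terms = _spec_key(design.columns)
    X = sm.add_constant(design[list(terms)].to_numpy(float), has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            # complete separation drives the likelihood to its supremum of
            # 0 and the coefficients to infinity; flag both symptoms
            converged = (
                bool(res.converged)
                and np.all(np.abs(res.params) < 1e3)
                and res.llf < -1e-6
            )
        except Exception:
            res = None
            converged = False
    if res is None:
        nan = float("nan")
        return FittedModel(terms, {}, nan, float("inf"), int(y.size), False)

    names = ["intercept", *terms]
    coefs = dict(zip(names, map(float, res.params)))
    return FittedModel(
        terms=terms,
        coefficients=coefs,
        log_likelihood=float(res.llf),
        aic=float(res.aic),
        n_obs=int(y.size),
        converged=converged,
    )


@dataclass
class StepwisePath:
    """Every candidate model evaluated during the search."""

    steps: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    def record(self, terms: tuple[str, ...], aic: float) -> None:
        self.steps.append((terms, aic))

    def unique_specs(self) -> list[tuple[str, ...]]:
        seen: dict[tuple[str, ...], None] = {}
        for t, _ in self.steps:
            seen.setdefault(t, None)
        return list(seen)


def stepwise_aic(
    full_terms,
    design: pd.DataFrame,
    response,
) -> tuple[FittedModel, StepwisePath]:
    """Backward-forward stepwise AIC selection from the full model.

    At each iteration every single-term deletion from, and addition to,
    the current model is scored; the move that most decreases AIC is
    taken, stopping when no move improves it.  Exact AIC ties are broken
    toward the smaller model, then lexicographic term order.  Returns the
    best refitted model and the search path.
    """
    full = _spec_key(full_terms)
    cache: dict[tuple[str, ...], FittedModel] = {}
    path = StepwisePath()

    def fit(terms: tuple[str, ...]) -> FittedModel:
        if terms not in cache:
            cache[terms] = fit_glm_binomial(design[list(terms)], response)
            path.record(terms, cache[terms].aic)
        return cache[terms]

    current = fit(full)
    while True:
        moves: list[tuple[float, int, tuple[str, ...]]] = []
        for t in current.terms:  # deletions
            cand = tuple(x for x in current.terms if x != t)
            moves.append((fit(cand).aic, len(cand), cand))
        for t in full:  # additions
            if t not in current.terms:
                cand = _spec_key((*current.terms, t))
                moves.append((fit(cand).aic, len(cand), cand))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best_aic, _, best_terms = moves[0]
        if best_aic < current.aic:
            current = cache[best_terms]
        else:
            break
    return current, path


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights exp(-Delta_i/2) normalized over the model set."""
    aics = np.asarray(aics, float)
    if aics.size == 0:
        raise ValueError("no AIC values")
    delta = aics - np.min(aics)
    rel = np.exp(-delta / 2.0)
    return rel / rel.sum()


def competing_models(
    path: StepwisePath,
    design: pd.DataFrame,
    response,
    delta_max: float = COMPETING_DELTA_AIC,
) -> pd.DataFrame:
    """Competing-model table: every spec visited by the search, refitted
    on the same data, restricted to Delta-AIC <= ``delta_max`` of the
    best, sorted best-first, with Akaike weights over the retained set.

    Columns: ``model`` (signed term list like ``+CHLA -SST``), ``terms``,
    ``n_terms``, ``aic``, ``delta_aic``, ``akaike_weight``.
    """
    fits = []
    for terms in path.unique_specs():
        fm = fit_glm_binomial(design[list(terms)], response)
        if fm.converged and np.isfinite(fm.aic):
            fits.append(fm)
    if not fits:
        raise ValueError("no fittable models on the search path")
    best = min(f.aic for f in fits)
    keep = [f for f in fits if f.aic - best <= delta_max]
    keep.sort(key=lambda f: (f.aic, len(f.terms), f.terms))
    w = akaike_weights([f.aic for f in keep])
    rows = []
    for f, wi in zip(keep, w):
        signed = " ".join(
            f"{'+' if f.coefficients[t] >= 0 else '-'}{t}" for t in f.terms
        )
        rows.append({
            "model": signed or "(intercept only)",
            "terms": f.terms,
            "n_terms": len(f.terms),
            "aic": f.aic,
            "delta_aic": f.aic - best,
            "akaike_weight": float(wi),
        })
    return pd.DataFrame(rows)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties score 1/2."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


@dataclass
class ReplicateResult:
    replicate_index: int
    pseudo_absence_set_index: int
    train_cells: np.ndarray
    test_cells: np.ndarray
    best_model: FittedModel
    auc: float


@dataclass
class EnsembleSummary:
    n_replicates: int
    n_converged: int
    mean_auc: float
    se_auc: float
    usable: bool
    term_selection_counts: dict[str, int]
    term_sign_positive_counts: dict[str, int]

    def selection_frequency(self, term: str) -> float:
        return self.term_selection_counts.get(canonical_name(term), 0) / max(
            self.n_converged, 1
        )


def _stratified_split(rng, n: int, train_frac: float) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.permutation(n)
    n_train = int(round(train_frac * n))
    return idx[:n_train], idx[n_train:]


def run_replicates(
    presences: PresenceSet,
    design: PseudoAbsenceDesign,
    stack: EnvStack,
    n_rep: int = 100,
    seed: int = 0,
    terms=CANONICAL_VARIABLES,
    train_frac: float = 0.7,
    shuffle_labels: bool = False,
) -> tuple[list[ReplicateResult], EnsembleSummary]:
    """Fit the balanced replicate ensemble.

    Replicate r pairs all presence cells with pseudo-absence set r,
    splits each class 70/30 into train/test, runs stepwise AIC selection
    on the training portion and scores the selected model's AUC on the
    test portion.  Non-converged replicates are excluded from the summary
    but counted.  ``shuffle_labels=True`` permutes the presence/absence
    labels within each replicate (null calibration).

    Returns the per-replicate results and an :class:`EnsembleSummary`
    with the mean test AUC, its standard error sd/sqrt(n), the usable
    flag (mean AUC >= 0.7) and term-selection tallies.
    """
    if design.n_sets < n_rep:
        raise ValueError(f"{design.n_sets} pseudo-absence sets < {n_rep} replicates")
    terms = _spec_key(terms)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    pres = presences.cells

    results: list[ReplicateResult] = []
    for r in range(n_rep):
        absent = design.sets[r]
        tr_p, te_p = _stratified_split(rng, pres.size, train_frac)
        tr_a, te_a = _stratified_split(rng, absent.size, train_frac)
        train_cells = np.concatenate([pres[tr_p], absent[tr_a]])
        test_cells = np.concatenate([pres[te_p], absent[te_a]])
        y_train = np.concatenate([np.ones(tr_p.size), np.zeros(tr_a.size)])
        y_test = np.concatenate([np.ones(te_p.size), np.zeros(te_a.size)])
        if shuffle_labels:
            y_train = rng.permutation(y_train)
            y_test = rng.permutation(y_test)

        X_train = pd.DataFrame(
            stack.design_matrix(train_cells, terms), columns=list(terms)
        )
        X_test = pd.DataFrame(
            stack.design_matrix(test_cells, terms), columns=list(terms)
        )
        best, _ = stepwise_aic(terms, X_train, y_train)
        if not best.converged:
            results.append(ReplicateResult(r, r, train_cells, test_cells,
                                           best, float("nan")))
            continue
        scores = best.predict(X_test)
        results.append(
            ReplicateResult(r, r, train_cells, test_cells, best,
                            auc(scores, y_test))
        )

    ok = [res for res in results if res.best_model.converged]
    aucs = np.array([res.auc for res in ok])
    sel: dict[str, int] = {t: 0 for t in terms}
    pos: dict[str, int] = {t: 0 for t in terms}
    for res in ok:
        for t in res.best_model.terms:
            sel[t] += 1
            if res.best_model.coefficients[t] > 0:
                pos[t] += 1
    mean_auc = float(aucs.mean()) if aucs.size else float("nan")
    se_auc = (
        float(aucs.std(ddof=1) / np.sqrt(aucs.size)) if aucs.size >= 2 else float("nan")
    )
    summary = EnsembleSummary(
        n_replicates=n_rep,
        n_converged=len(ok),
        mean_auc=mean_auc,
        se_auc=se_auc,
        usable=bool(aucs.size and mean_auc >= AUC_USABLE_THRESHOLD),
        term_selection_counts=sel,
        term_sign_positive_counts=pos,
    )
    return results, summary


def replicate_table(results: list[ReplicateResult]) -> pd.DataFrame:
    """Flat per-replicate table (replicate, selected terms, coefficients,
    AIC, AUC) for CSV export."""
    rows = []
    for res in results:
        fm = res.best_model
        rows.append({
            "replicate": res.replicate_index,
            "pseudo_absence_set": res.pseudo_absence_set_index,
            "converged": fm.converged,
            "terms": " ".join(fm.terms),
            "coefficients": ";".join(
                f"{k}={v:.6g}" for k, v in sorted(fm.coefficients.items())
            ),
            "aic": fm.aic,
            "auc": res.auc,
        })
    return pd.DataFrame(rows)
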