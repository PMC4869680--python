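"""Predictive validity, model comparison, specificity, filter search.

Predictive validity of a scoring method is the evidence for a model in
which CS+ and CS− scores are drawn from distributions with different
means. It is computed from a regression in which the vector of event
types (CS+ = 1, CS− = 0) is the dependent variable and the score
vector is a regressor, complemented by subject-specific intercepts —
equivalent to a repeated-measures ANOVA. The residual sum of squares
is converted to a negative log likelihood

    NLL = n * log(RSS / n)

where n is the number of observations; smaller NLL means higher
evidence. No parameter-count penalty is applied because the predictive
regression has the same dimension for every scoring method compared.
An absolute NLL difference above 3 is treated as decisive (the
probability of the null given the data is < e^-3 ≈ .05). The t
statistic of the score coefficient in this regression is algebraically
identical to the paired t across subjects and is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .basis import fit_rf, gamma_rf, derivative_rf, BasisSet
from .exceptions import InsufficientDataError, InvalidSpecError, ValidationError
from .hp_series import FilterSpec, HeartPeriodSeries, bandpass, epoch_trials

__all__ = [
    "ModelEvidence",
    "ComparisonVerdict",
    "predictive_validity",
    "compare",
    "permutation_specificity",
    "optimize_filters",
    "DECISIVE_DELTA",
    "DEFAULT_HP_GRID",
    "DEFAULT_LP_GRID",
]

#: |ΔNLL| above which a model comparison is decisive
DECISIVE_DELTA = 3.0

#: numerical floor on the residual sum of squares
RSS_FLOOR = 1e-300

#: default cutoff grids for the filter search (Hz)
DEFAULT_HP_GRID = (0.01, 0.015, 0.02, 0.03, 0.05, 0.1)
DEFAULT_LP_GRID = (0.25, 0.5, 1.0)


@dataclass(frozen=True)
class ModelEvidence:
    method: str
    nll: float
    t_stat: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ComparisonVerdict:
    method_a: str
    method_b: str
    delta_nll: float

    @property
    def decisive(self) -> bool:
        return abs(self.delta_nll) > DECISIVE_DELTA


def predictive_validity(scores: pd.DataFrame, method: str = "") -> ModelEvidence:
    """Evidence that a method's scores separate CS+ from CS−.

    ``scores`` must hold one row per subject × condition with columns
    ``subject``, ``condition`` (cs_plus/cs_minus) and ``score``.
    """
    pivot = scores.pivot_table(index="subject", columns="condition", values="score")
    if not {"cs_plus", "cs_minus"}.issubset(pivot.columns) or pivot.isna().any().any():
        raise ValidationError("every subject needs exactly one CS+ and one CS− score")
    n_subj = len(pivot)
    if n_subj < 3:
        raise InsufficientDataError(f"need >= 3 subjects, got {n_subj}")

    s = np.concatenate([pivot["cs_plus"].to_numpy(), pivot["cs_minus"].to_numpy()])
    y = np.concatenate([np.ones(n_subj), np.zeros(n_subj)])
    dummies = np.vstack([np.eye(n_subj)] * 2)
    X = np.column_stack([s, dummies])

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = max(float(resid @ resid), RSS_FLOOR)
    n = y.size
    nll = n * np.log(rss / n)

    dof = n - rank
    sigma2 = rss / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[0, 0]))
    t = float(beta[0] / se) if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return ModelEvidence(method=method, nll=float(nll), t_stat=t, p_value=p, n=n)


def compare(e1: ModelEvidence, e2: ModelEvidence) -> ComparisonVerdict:
    """ΔNLL verdict between two methods fit on the same observations."""
    if e1.n != e2.n:
        raise ValidationError(f"evidence computed on different n ({e1.n} vs {e2.n})")
    return ComparisonVerdict(method_a=e1.method, method_b=e2.method,
                             delta_nll=e1.nll - e2.nll)


def _shuffle(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.permutation(labels)


@dataclass(frozen=True)
class PermutationResult:
    t_stat: float
    p_value: float
    mean_scores: pd.DataFrame  # subject, condition, score (averaged over perms)


def permutation_specificity(
    labels_per_subject: Sequence[np.ndarray],
    score_fn: Callable[[int, np.ndarray], tuple[float, float]],
    n_perm: int = 1000,
    seed: int | None = None,
    permuter: Callable[[np.ndarray, np.random.Generator], np.ndarray] = _shuffle,
) -> PermutationResult:
    """Specificity check by within-subject trial-label permutation.

    For each permutation, the retained-trial condition labels are
    shuffled within subject (preserving per-condition counts), pseudo
    CS+/CS− scores are recomputed with ``score_fn(subject_index,
    labels)``, and scores are averaged over permutations before a
    paired t test across subjects. With truly exchangeable labels the
    test should be null.

    ``permuter`` defaults to a uniform shuffle; passing an identity
    function reproduces the unpermuted statistic.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    for labels in labels_per_subject:
        vals, counts = np.unique(labels, return_counts=True)
        if len(vals) < 2 or counts.min() < 2:
            raise InsufficientDataError("need >= 2 trials per pseudo-condition after permutation")
    rng = np.random.default_rng(seed)
    n_subj = len(labels_per_subject)
    acc = np.zeros((n_subj, 2))
    for _ in range(n_perm):
        for i, labels in enumerate(labels_per_subject):
            s_plus, s_minus = score_fn(i, permuter(labels, rng))
            acc[i, 0] += s_plus
            acc[i, 1] += s_minus
    acc /= n_perm
    res = stats.ttest_rel(acc[:, 0], acc[:, 1])
    mean_scores = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subj), 2),
            "condition": ["cs_plus", "cs_minus"] * n_subj,
            "score": acc.ravel(),
        }
    )
    return PermutationResult(t_stat=float(res.statistic), p_value=float(res.pvalue),
                             mean_scores=mean_scores)


# ---------------------------------------------------------------------------
# filter optimisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterSearchResult:
    best_spec: FilterSpec
    best_evidence: ModelEvidence
    surface: pd.DataFrame  # hp_cutoff, lp_cutoff, nll, indistinguishable


def optimize_filters(
    sessions: Sequence[tuple[HeartPeriodSeries, pd.DataFrame]],
    hp_grid: Sequence[float] = DEFAULT_HP_GRID,
    lp_grid: Sequence[float] = DEFAULT_LP_GRID,
    model_id: str = "G2",
    refit_rf: bool = True,
    base_bset: BasisSet | None = None,
) -> FilterSearchResult:
    """Grid-search band-pass cutoffs by predictive validity.

    For every (hp, lp) pair the unfiltered per-subject series are
    refiltered, the canonical RF is refit on the grand-mean CS+ minus
    CS− difference wave (unless ``refit_rf`` is off), designs are
    rebuilt and re-estimated, and the NLL of the predictive regression
    is recorded. Settings whose NLL lies within +3 of the minimum are
    marked statistically indistinguishable from the winner.
    """
    if len(hp_grid) < 1 or len(lp_grid) < 1:
        raise ValidationError("empty cutoff grid")
    fs = sessions[0][0].fs
    nyq = fs / 2.0
    if min(hp_grid) <= 0 or max(lp_grid) >= nyq:
        raise InvalidSpecError("cutoff grid outside (0, Nyquist)")

    rows = []
    best: tuple[float, FilterSpec, ModelEvidence] | None = None
    for hp in hp_grid:
        for lp in lp_grid:
            spec = FilterSpec(hp_cutoff=hp, lp_cutoff=lp)
            filtered = [(bandpass(s, spec, allow_refilter=True), tr) for s, tr in sessions]
            ev = _evidence_for_filtered(filtered, spec, model_id, refit_rf, base_bset)
            rows.append({"hp_cutoff": hp, "lp_cutoff": lp, "nll": ev.nll})
            if best is None or ev.nll < best[0]:
                best = (ev.nll, spec, ev)
    assert best is not None
    surface = pd.DataFrame(rows)
    surface["indistinguishable"] = surface["nll"] <= best[0] + DECISIVE_DELTA
    return FilterSearchResult(best_spec=best[1], best_evidence=best[2], surface=surface)


def _evidence_for_filtered(
    filtered: Sequence[tuple[HeartPeriodSeries, pd.DataFrame]],
    spec: FilterSpec,
    model_id: str,
    refit_rf: bool,
    base_bset: BasisSet | None,
) -> ModelEvidence:
    fs = filtered[0][0].fs
    if refit_rf:
        diffs = []
        for series, trials in filtered:
            epochs = epoch_trials(series, trials)
            diffs.append(
                glm.condition_mean_epoch(epochs, "cs_plus")
                - glm.condition_mean_epoch(epochs, "cs_minus")
            )
        fit = fit_rf(np.mean(diffs, axis=0), fs=fs)
        canonical = gamma_rf(fit.params, fs=fs)
        funcs = (canonical,) if model_id == "G1" else (canonical, derivative_rf(canonical))
        bset = BasisSet(functions=funcs, model_id=model_id)
    else:
        if base_bset is None:
            raise ValidationError("refit_rf=False requires base_bset")
        bset = base_bset

    records = []
    for subj, (series, trials) in enumerate(filtered):
        design = glm.build_design(trials, bset, len(series), fs, t0=series.t0,
                                  filter_spec=spec)
        est = glm.estimate(design, series, model_id=model_id, subject_id=str(subj))
        for cond, score in glm.score_model_based(est, bset).items():
            records.append({"subject": subj, "condition": cond, "score": score})
    return predictive_validity(pd.DataFrame.from_records(records), method=model_id)
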