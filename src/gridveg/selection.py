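"""Stability assessment: repeated cross-validated stepwise selection and a
shadow-feature (Boruta-style) importance procedure.

Both methods ask the same question from different angles: when the available
years are subsampled or the model is refit under randomness, how often does a
feature come out on top?  Stepwise selection tallies, over repeated k-fold
partitions of the years, how often each feature has the largest absolute
Pearson correlation with the response on a training set.  The shadow-feature
procedure appends an independently shuffled copy of every feature to the
design matrix, fits a random-forest regression, and counts a *hit* whenever a
real feature's importance exceeds the best shadow importance; binomial tests
on the hit counts confirm or reject features, and the whole run is repeated
to estimate how often each feature is confirmed.

Importances are out-of-bag permutation importances normalized per feature to
a z-score over trees (mean increase in OOB squared error divided by its
standard error), the classic regression-forest convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)


@dataclass
class SelectionFrequency:
    feature_id: str
    times_selected_best: int
    total_folds: int

    @property
    def selection_pct(self) -> float:
        return 100.0 * self.times_selected_best / self.total_folds


def stepwise_cv_selection(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    k: int = 3,
    reps: int = 100,
    seed: int | np.random.Generator | None = 0,
) -> list[SelectionFrequency]:
    """Repeated k-fold stepwise forward selection (first step only).

    For each repetition the years are partitioned into ``k`` folds by a
    seeded shuffle; on each training set the feature with the maximum
    absolute Pearson correlation with ``y`` is recorded as *best*.
    Frequencies are tallied over ``reps * k`` fold fits.  Constant features
    on a training fold are skipped for that fold; ties in |r| break by
    catalog order.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, F = X.shape
    if n < k:
        raise ValueError("fewer years than folds")
    if len(feature_ids) != F:
        raise ValueError("feature_ids length mismatch")
    rng = np.random.default_rng(seed)
    counts = np.zeros(F, dtype=int)
    total = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fold in folds:
            train = np.setdiff1d(perm, fold)
            Xt, yt = X[train], y[train]
            if np.std(yt) == 0:
                continue
            sx = Xt.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = ((Xt - Xt.mean(0)) * (yt - yt.mean())[:, None]).mean(0) / (sx * yt.std())
            r = np.where(sx > 0, np.abs(r), -np.inf)
            counts[int(np.argmax(r))] += 1
            total += 1
    out = [SelectionFrequency(fid, int(c), total) for fid, c in zip(feature_ids, counts)]
    out.sort(key=lambda s: (-s.times_selected_best, s.feature_id))
    return out


# ---------------------------------------------------------------------------
# Shadow-feature importance (Boruta-style), written from scratch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings for the importance source.

    Defaults follow standard regression-forest practice: 500 trees,
    ceil(F/3) candidate features per split, minimum node size 5, permutation
    importance computed out-of-bag.  ``min_node_size`` uses the classic
    regression-forest semantic: nodes with at most that many cases become
    terminal, but children of a split may be any size (mapped to
    ``min_samples_split = min_node_size + 1`` with unconstrained leaves;
    constraining leaf sizes instead makes the trees far shallower at small n
    and visibly blurs the importance ranking of correlated features).
    """

    n_trees: int = 500
    max_features: str | float = "third"     # "third" -> ceil(F/3)
    min_node_size: int = 5
    random_state: int | None = None


@dataclass
class BorutaRunResult:
    feature_ids: list[str]
    decisions: dict[str, str]               # confirmed | rejected | tentative
    importance: dict[str, float]            # mean z over iterations (kept features)
    hits: dict[str, int]
    n_iterations: int


@dataclass
class BorutaOutcome:
    feature_id: str
    mean_importance: float                  # over confirming repetitions (NaN if never)
    confirmed_pct: float
    decisions: list[str] = field(default_factory=list)


def _oob_permutation_z(
    rf: RandomForestRegressor, X: np.ndarray, y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-feature OOB permutation importance z-scores.

    For each tree: baseline OOB squared error, then the error after permuting
    each column on the OOB rows; the importance of a feature in a tree is the
    error increase.  Per feature, z = mean over trees / (sd / sqrt(n_trees)).
    All permuted variants of a tree's OOB matrix are stacked into one predict
    call to keep the per-tree overhead constant.
    """
    n, F = X.shape
    imps = np.full((len(rf.estimators_), F), np.nan)
    for t, (tree, states) in enumerate(zip(rf.estimators_, rf.estimators_samples_)):
        oob = np.setdiff1d(np.arange(n), states)
        if oob.size < 2:
            continue
        Xo = X[oob]
        k = oob.size
        stacked = np.repeat(Xo[None, :, :], F + 1, axis=0)
        for j in range(F):
            stacked[j + 1, :, j] = rng.permutation(Xo[:, j])
        preds = tree.predict(stacked.reshape(-1, F)).reshape(F + 1, k)
        err = ((preds - y[oob][None, :]) ** 2).mean(axis=1)
        imps[t] = err[1:] - err[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(imps, axis=0)
        sd = np.nanstd(imps, axis=0, ddof=1)
        n_used = np.sum(np.isfinite(imps), axis=0)
        z = np.where(sd > 0, mean / (sd / np.sqrt(np.maximum(n_used, 1))), 0.0)
    return z


def boruta_run(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    max_runs: int = 500,
    alpha: float = 0.05,
    rf_config: RFConfig = RFConfig(),
    seed: int | np.random.Generator | None = 0,
) -> BorutaRunResult:
    """One shadow-feature selection run.

    Each iteration appends an independently shuffled shadow copy of every
    kept feature, fits the forest, and counts a hit for each undecided
    feature whose importance exceeds the maximum shadow importance.  After
    each iteration, one-sided binomial tests of the hit count against
    Binomial(iterations, 0.5) at level ``alpha`` confirm (upper tail) or
    reject (lower tail) features; rejected features leave the design matrix,
    confirmed ones keep competing.  Stops when all features are decided or
    after ``max_runs`` iterations; undecided features are tentative.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, F = X.shape
    if n < 5:
        raise ValueError("need at least 5 observations")
    if F < 1:
        raise ValueError("need at least one feature")
    if n <= rf_config.min_node_size:
        raise ValueError("fewer observations than the tree node-size minimum")
    rng = np.random.default_rng(seed)
    status = np.array(["tentative"] * F, dtype=object)
    hits = np.zeros(F, dtype=int)
    imp_sum = np.zeros(F)
    imp_n = np.zeros(F, dtype=int)
    it = 0
    while it < max_runs and np.any(status == "tentative"):
        it += 1
        kept = np.flatnonzero(status != "rejected")
        Xk = X[:, kept]
        shadows = Xk[rng.permuted(np.tile(np.arange(n), (kept.size, 1)), axis=1).T,
                     np.arange(kept.size)]
        design = np.hstack([Xk, shadows])
        mf = (int(np.ceil(design.shape[1] / 3))
              if rf_config.max_features == "third" else rf_config.max_features)
        rf = RandomForestRegressor(
            n_estimators=rf_config.n_trees,
            max_features=mf,
            min_samples_split=rf_config.min_node_size + 1,
            min_samples_leaf=1,
            bootstrap=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(design, y)
        z = _oob_permutation_z(rf, design, y, rng)
        z_real, z_shadow = z[: kept.size], z[kept.size:]
        shadow_max = z_shadow.max() if z_shadow.size else 0.0
        imp_sum[kept] += z_real
        imp_n[kept] += 1
        undecided = status == "tentative"
        hit_now = np.zeros(F, dtype=bool)
        hit_now[kept] = z_real > shadow_max
        hits[undecided & hit_now] += 1
        # binomial decisions on undecided features
        for j in np.flatnonzero(undecided):
            p_hi = sps.binom.sf(hits[j] - 1, it, 0.5)   # P(X >= hits)
            p_lo = sps.binom.cdf(hits[j], it, 0.5)      # P(X <= hits)
            if p_hi < alpha:
                status[j] = "confirmed"
            elif p_lo < alpha:
                status[j] = "rejected"
    importance = {
        fid: (imp_sum[j] / imp_n[j] if imp_n[j] else np.nan)
        for j, fid in enumerate(feature_ids)
    }
    return BorutaRunResult(
        feature_ids=list(feature_ids),
        decisions={fid: str(status[j]) for j, fid in enumerate(feature_ids)},
        importance=importance,
        hits={fid: int(hits[j]) for j, fid in enumerate(feature_ids)},
        n_iterations=it,
    )


def boruta_repeat(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    reps: int = 500,
    seed: int | None = 0,
    **run_kwargs,
) -> list[BorutaOutcome]:
    """Repeat :func:`boruta_run` with derived seeds; summarize per feature.

    ``confirmed_pct`` is the percentage of repetitions in which the feature
    was confirmed (tentative counts as not confirmed); ``mean_importance``
    averages the run importance over confirming repetitions only.  Sorted by
    mean importance descending (unconfirmed features last).
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(reps)
    n_conf = np.zeros(len(feature_ids), dtype=int)
    imp_sum = np.zeros(len(feature_ids))
    decisions: list[list[str]] = [[] for _ in feature_ids]
    for rep in range(reps):
        res = boruta_run(X, y, feature_ids,
                         seed=np.random.default_rng(child_seeds[rep]), **run_kwargs)
        for j, fid in enumerate(feature_ids):
            dec = res.decisions[fid]
            decisions[j].append(dec)
            if dec == "confirmed":
                n_conf[j] += 1
                imp_sum[j] += res.importance[fid]
    out = []
    for j, fid in enumerate(feature_ids):
        mean_imp = imp_sum[j] / n_conf[j] if n_conf[j] else np.nan
        out.append(BorutaOutcome(
            feature_id=fid,
            mean_importance=float(mean_imp),
            confirmed_pct=100.0 * n_conf[j] / reps,
            decisions=decisions[j],
        ))
    out.sort(key=lambda o: (-(o.mean_importance if np.isfinite(o.mean_importance) else -np.inf),
                            o.feature_id))
    return out
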