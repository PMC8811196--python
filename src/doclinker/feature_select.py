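"""Consensus selection of DOC-associated taxa.

Three independent routes flag OTUs whose abundance tracks dissolved
organic carbon, and only taxa identified by all three are reported:

* **Random forest** — a random-forest regressor of DOC on OTU
  abundances is refit on random 80% subsamples over 50 iterations;
  per-OTU impurity importances are averaged across iterations and
  divided by the maximum so the top taxon scores exactly 1.
* **Neural network** — a feed-forward net with one hidden layer
  (15 sigmoid nodes by default, linear output) regresses DOC on
  abundances; hyperparameters (hidden size, learning rate, L2
  coefficient) come from a randomized search scored by test-set MSE,
  and training stops once test MSE fails to improve over ten epochs.
  A *signed* per-OTU importance is derived by the connection-weight
  product (sum over hidden nodes of input→hidden × hidden→output
  weights) and normalized by the maximum absolute value, so it lies in
  [−1, 1] with positive meaning higher abundance ↔ higher DOC.
* **Indicator species analysis** — samples are split into high- and
  low-DOC cohorts; each OTU's IndVal statistic combines specificity
  (A, how concentrated its mean abundance is in one cohort) and
  fidelity (B, in what fraction of that cohort's samples it occurs):
  IndVal_g = sqrt(A_g × B_g), reported for the best cohort, with a
  label-permutation p-value.

``ConsensusSelector`` runs all three on the same OTU universe and
intersects the selections.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import ParameterSampler, train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "make_group_labels",
    "rf_importance",
    "nn_importance",
    "indval",
    "consensus_select",
    "RandomForestImportance",
    "NeuralNetworkImportance",
    "IndicatorSpecies",
    "ConsensusSelector",
]


def make_group_labels(doc, quantiles: tuple[float, float] = (0.5, 0.5)) -> np.ndarray:
    """Assign each sample to the ``low`` or ``high`` DOC cohort.

    With the default median split, the bottom ceil(n/2) samples by DOC
    are ``low`` and the top floor(n/2) are ``high`` (125 samples give
    the 63 low / 62 high extreme-cohort design). Non-default quantiles
    (q_low, q_high) keep only samples at or below / above the
    respective DOC quantiles; in-between samples get the label
    ``excluded``.
    """
    doc = np.asarray(doc, dtype=float)
    n = len(doc)
    order = np.argsort(doc, kind="mergesort")
    labels = np.full(n, "excluded", dtype=object)
    q_low, q_high = quantiles
    if not (0 < q_low <= 1) or not (0 < q_high <= 1):
        raise ValueError("cohort quantiles must be in (0, 1]")
    if q_low == 0.5 and q_high == 0.5:
        n_low = int(np.ceil(n / 2))
        labels[order[:n_low]] = "low"
        labels[order[n_low:]] = "high"
    else:
        n_low = int(np.floor(n * q_low))
        n_high = int(np.floor(n * (1 - q_high))) if q_high != 0.5 else n - n_low
        labels[order[:n_low]] = "low"
        if n_high > 0:
            labels[order[-n_high:]] = "high"
    return labels


class RandomForestImportance(BaseEstimator):
    """Subsample-averaged random-forest feature ranking.

    Fits ``n_iter`` forests, each on a random ``frac`` fraction of the
    samples drawn without replacement, averages the impurity-based
    importances and rescales by the maximum so the top feature scores 1.

    Attributes
    ----------
    importances_ : ndarray of shape (n_features,)
        Max-normalized mean importances in [0, 1].
    """

    def __init__(
        self,
        n_iter: int = 50,
        frac: float = 0.8,
        n_estimators: int = 100,
        random_state: int | None = 0,
    ):
        self.n_iter = n_iter
        self.frac = frac
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        if not (0 < self.frac <= 1):
            raise ValueError(f"frac must be in (0, 1], got {self.frac}")
        X, y = check_X_y(X, y)
        if X.shape[0] < 10:
            raise ValueError("need at least 10 samples")
        rng = np.random.default_rng(self.random_state)
        n_sub = max(2, int(round(self.frac * X.shape[0])))
        total = np.zeros(X.shape[1])
        for _ in range(self.n_iter):
            idx = rng.choice(X.shape[0], size=n_sub, replace=False)
            forest = RandomForestRegressor(
                n_estimators=self.n_estimators,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(X[idx], y[idx])
            total += forest.feature_importances_
        mean_imp = total / self.n_iter
        top = mean_imp.max()
        self.importances_ = mean_imp / top if top > 0 else mean_imp
        return self


class NeuralNetworkImportance(BaseEstimator):
    """Signed feature importance from a shallow feed-forward regressor.

    Features are standardized, a holdout test split is made, and
    ``n_search`` hyperparameter draws (hidden layer size, learning
    rate, L2 regularization) are each trained with early stopping
    (training halts when validation MSE fails to improve over
    ``patience`` epochs); the configuration with the lowest test-set
    MSE wins and is refit ``n_ensemble`` times on the full data from
    different initializations. Signed importances are the
    connection-weight products w_in @ w_out averaged over the refits
    (restart averaging cancels the initialization noise of irrelevant
    features, whose weight products carry random signs), normalized
    into [−1, 1]; positive means higher abundance associated with
    higher DOC. The permutation
    alternative (magnitude from permutation importance, sign from the
    feature–response Spearman correlation) is available with
    ``method="permutation"``.

    Attributes
    ----------
    importances_ : ndarray of shape (n_features,)
        Signed, max-|.|-normalized importances.
    best_params_ : dict
        Winning hyperparameter draw.
    """

    def __init__(
        self,
        hidden_layer_size: int = 15,
        n_search: int = 10,
        n_ensemble: int = 5,
        patience: int = 10,
        test_size: float = 0.25,
        max_iter: int = 400,
        method: str = "connection_weight",
        random_state: int | None = 0,
    ):
        self.hidden_layer_size = hidden_layer_size
        self.n_search = n_search
        self.n_ensemble = n_ensemble
        self.patience = patience
        self.test_size = test_size
        self.max_iter = max_iter
        self.method = method
        self.random_state = random_state

    def _candidate_grid(self, n_samples: int) -> dict:
        h = self.hidden_layer_size
        if n_samples < h:
            warnings.warn(
                f"fewer samples ({n_samples}) than hidden nodes ({h}); reducing layer size",
                UserWarning,
                stacklevel=2,
            )
            h = max(2, n_samples // 2)
        sizes = sorted({max(2, h - 5), h, h + 5, h + 10})
        return {
            "hidden_layer_sizes": [(s,) for s in sizes],
            "learning_rate_init": [1e-3, 3e-3, 1e-2, 3e-2],
            "alpha": [1e-5, 1e-4, 1e-3, 1e-2, 1e-1],
        }

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        rng = np.random.default_rng(self.random_state)
        scaler = StandardScaler()
        Xs = scaler.fit_transform(X)
        ys_mean, ys_std = y.mean(), y.std() or 1.0
        ys = (y - ys_mean) / ys_std
        X_tr, X_te, y_tr, y_te = train_test_split(
            Xs, ys, test_size=self.test_size, random_state=int(rng.integers(2**31 - 1))
        )
        grid = self._candidate_grid(X.shape[0])
        sampler = ParameterSampler(
            grid, n_iter=self.n_search, random_state=int(rng.integers(2**31 - 1))
        )
        def _make(params, seed):
            return MLPRegressor(
                activation="logistic",
                solver="adam",
                early_stopping=True,
                n_iter_no_change=self.patience,
                validation_fraction=0.15,
                max_iter=self.max_iter,
                random_state=seed,
                **params,
            )

        best_mse, best_model, best_params = np.inf, None, None
        for params in sampler:
            model = _make(params, int(rng.integers(2**31 - 1)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence chatter
                model.fit(X_tr, y_tr)
            mse = float(np.mean((model.predict(X_te) - y_te) ** 2))
            if mse < best_mse:
                best_mse, best_model, best_params = mse, model, params
        self.best_params_ = best_params
        self.best_test_mse_ = best_mse
        self.model_ = best_model
        if self.method == "connection_weight":
            # restart-averaged refits of the winning configuration
            imp = np.zeros(X.shape[1])
            for _ in range(max(1, self.n_ensemble)):
                model = _make(best_params, int(rng.integers(2**31 - 1)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(Xs, ys)
                imp += model.coefs_[0] @ model.coefs_[1].ravel()
            imp /= max(1, self.n_ensemble)
        elif self.method == "permutation":
            from sklearn.inspection import permutation_importance

            perm = permutation_importance(
                best_model, X_te, y_te, n_repeats=10,
                random_state=int(rng.integers(2**31 - 1)),
            )
            signs = np.array([
                np.sign(np.corrcoef(rankdata(Xs[:, j]), rankdata(ys))[0, 1]) or 1.0
                for j in range(X.shape[1])
            ])
            imp = perm.importances_mean.clip(min=0) * signs
        else:
            raise ValueError(f"unknown importance method {self.method!r}")
        top = np.abs(imp).max()
        self.importances_ = imp / top if top > 0 else imp
        return self


def _indval_stats(
    x: np.ndarray, is_high: np.ndarray, sqrt_form: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IndVal over all OTU columns for one labeling.

    Returns (stat per OTU maximized over groups, argmax group code with
    1 = high). OTUs absent everywhere get stat 0.
    """
    mean_h = x[is_high].mean(axis=0)
    mean_l = x[~is_high].mean(axis=0)
    denom = mean_h + mean_l
    with np.errstate(invalid="ignore", divide="ignore"):
        a_h = np.where(denom > 0, mean_h / denom, 0.0)
        a_l = np.where(denom > 0, mean_l / denom, 0.0)
    b_h = (x[is_high] > 0).mean(axis=0)
    b_l = (x[~is_high] > 0).mean(axis=0)
    iv_h, iv_l = a_h * b_h, a_l * b_l
    if sqrt_form:
        iv_h, iv_l = np.sqrt(iv_h), np.sqrt(iv_l)
    stat = np.maximum(iv_h, iv_l)
    group = (iv_h >= iv_l).astype(int)
    return stat, group


def indval(
    counts,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    sqrt_form: bool = True,
    exact: bool = False,
) -> pd.DataFrame:
    """Indicator species analysis with a permutation null.

    For each OTU and cohort g: specificity A_g = mean abundance in g /
    (sum of group mean abundances); fidelity B_g = fraction of g's
    samples where the OTU is present (count > 0). The group-equalized
    statistic is sqrt(A_g × B_g) (``sqrt_form=False`` gives the classic
    A × B product). The reported stat is the maximum over the two
    cohorts and the p-value is
    (1 + #{label permutations with stat >= observed}) / (1 + n_perm).
    With ``exact=True`` all distinct labelings preserving group sizes
    are enumerated and p is the exact proportion.

    Returns a DataFrame indexed like the OTU columns with columns
    ``stat``, ``p``, ``group``.
    """
    if isinstance(counts, pd.DataFrame):
        otu_ids = list(counts.columns)
        x = counts.to_numpy(dtype=float)
    else:
        x = np.asarray(counts, dtype=float)
        otu_ids = list(range(x.shape[1]))
    labels = np.asarray(list(groups))
    keep = labels != "excluded"
    x, labels = x[keep], labels[keep]
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    is_high = labels == "high" if "high" in uniq else labels == uniq[1]
    if is_high.sum() < 2 or (~is_high).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    stat_obs, grp = _indval_stats(x, is_high, sqrt_form)
    if exact:
        n = len(is_high)
        k = int(is_high.sum())
        count = np.zeros_like(stat_obs)
        total = 0
        for combo in itertools.combinations(range(n), k):
            perm = np.zeros(n, dtype=bool)
            perm[list(combo)] = True
            s, _ = _indval_stats(x, perm, sqrt_form)
            count += s >= stat_obs - 1e-12
            total += 1
        p = count / total
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        count = np.zeros_like(stat_obs)
        for _ in range(n_perm):
            s, _ = _indval_stats(x, rng.permutation(is_high), sqrt_form)
            count += s >= stat_obs - 1e-12
        p = (1 + count) / (1 + n_perm)
    return pd.DataFrame(
        {
            "stat": stat_obs,
            "p": p,
            "group": np.where(grp == 1, "high", "low"),
        },
        index=otu_ids,
    )


class IndicatorSpecies(BaseEstimator):
    """Estimator wrapper for :func:`indval`.

    ``fit(X, groups)`` stores ``stats_``, ``pvalues_`` and ``groups_``
    arrays aligned with the feature columns.
    """

    def __init__(
        self,
        n_perm: int = 999,
        sqrt_form: bool = True,
        random_state: int | None = 0,
    ):
        self.n_perm = n_perm
        self.sqrt_form = sqrt_form
        self.random_state = random_state

    def fit(self, X, groups):
        res = indval(
            X, groups, n_perm=self.n_perm, seed=self.random_state, sqrt_form=self.sqrt_form
        )
        self.stats_ = res["stat"].to_numpy()
        self.pvalues_ = res["p"].to_numpy()
        self.groups_ = res["group"].to_numpy()
        self.result_ = res
        return self


def _mean_nonzero_cutoff(values: np.ndarray) -> float:
    nz = values[values > 0]
    return float(nz.mean()) if len(nz) else np.inf


@dataclass(frozen=True)
class ConsensusResult:
    scores: pd.DataFrame
    selected: list


def consensus_select(
    scores: pd.DataFrame,
    rf_cutoff: float | None = None,
    nn_cutoff: float | None = None,
    alpha: float = 0.05,
) -> ConsensusResult:
    """Intersect the three per-method selections.

    ``scores`` must have columns ``rf_importance``, ``nn_importance``,
    ``indval_stat``, ``indval_p``, ``indval_group``. When a cutoff is
    None the default rule "importance above the mean of the nonzero
    (absolute) importances" is applied; explicit cutoffs must lie in
    [0, 1]. IS selection is ``indval_p < alpha``. Returns the score
    table augmented with per-method membership and the consensus flag,
    plus the selected OTU list.
    """
    for cut, name in ((rf_cutoff, "rf_cutoff"), (nn_cutoff, "nn_cutoff")):
        if cut is not None and not (0 <= cut <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {cut}")
    rf = scores["rf_importance"].to_numpy(dtype=float)
    nn = np.abs(scores["nn_importance"].to_numpy(dtype=float))
    rf_cut = _mean_nonzero_cutoff(rf) if rf_cutoff is None else rf_cutoff
    nn_cut = _mean_nonzero_cutoff(nn) if nn_cutoff is None else nn_cutoff
    out = scores.copy()
    out["rf_selected"] = rf >= rf_cut
    out["nn_selected"] = nn >= nn_cut
    out["is_selected"] = scores["indval_p"].to_numpy() < alpha
    out["consensus"] = out["rf_selected"] & out["nn_selected"] & out["is_selected"]
    out["selected_by"] = [
        "+".join(
            m
            for m, flag in (("RF", r), ("NN", n_), ("IS", i))
            if flag
        )
        for r, n_, i in zip(out["rf_selected"], out["nn_selected"], out["is_selected"])
    ]
    return ConsensusResult(scores=out, selected=list(out.index[out["consensus"]]))


class ConsensusSelector(BaseEstimator):
    """Three-method consensus selection of DOC-associated taxa.

    ``fit(X, y)`` takes a rarefied samples x OTUs table and the
    per-sample DOC vector; cohorts for indicator species analysis are
    derived from ``y`` by the configured quantile split. After fitting,
    ``scores_`` holds the Table-shaped per-OTU score frame
    (rf_importance, nn_importance, indval stat/p/group, per-method
    membership, consensus flag) and ``selected_`` the consensus OTU
    ids; ``get_support()`` gives the boolean mask.
    """

    def __init__(
        self,
        rf_n_iter: int = 50,
        rf_frac: float = 0.8,
        rf_n_estimators: int = 100,
        nn_hidden: int = 15,
        nn_search: int = 10,
        n_perm: int = 999,
        rf_cutoff: float | None = None,
        nn_cutoff: float | None = None,
        alpha: float = 0.05,
        cohort_quantiles: tuple[float, float] = (0.5, 0.5),
        sqrt_form: bool = True,
        random_state: int | None = 0,
    ):
        self.rf_n_iter = rf_n_iter
        self.rf_frac = rf_frac
        self.rf_n_estimators = rf_n_estimators
        self.nn_hidden = nn_hidden
        self.nn_search = nn_search
        self.n_perm = n_perm
        self.rf_cutoff = rf_cutoff
        self.nn_cutoff = nn_cutoff
        self.alpha = alpha
        self.cohort_quantiles = cohort_quantiles
        self.sqrt_form = sqrt_form
        self.random_state = random_state

    def fit(self, X, y):
        otu_ids = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.shape(X)[1]))
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.random_state)
        seeds = rng.integers(2**31 - 1, size=3)

        rf = RandomForestImportance(
            n_iter=self.rf_n_iter,
            frac=self.rf_frac,
            n_estimators=self.rf_n_estimators,
            random_state=int(seeds[0]),
        ).fit(Xa, y)
        nn = NeuralNetworkImportance(
            hidden_layer_size=self.nn_hidden,
            n_search=self.nn_search,
            random_state=int(seeds[1]),
        ).fit(Xa, y)
        groups = make_group_labels(y, self.cohort_quantiles)
        iv = indval(
            pd.DataFrame(Xa, columns=otu_ids),
            groups,
            n_perm=self.n_perm,
            seed=int(seeds[2]),
            sqrt_form=self.sqrt_form,
        )
        scores = pd.DataFrame(
            {
                "rf_importance": rf.importances_,
                "nn_importance": nn.importances_,
                "indval_stat": iv["stat"].to_numpy(),
                "indval_p": iv["p"].to_numpy(),
                "indval_group": iv["group"].to_numpy(),
            },
            index=otu_ids,
        )
        result = consensus_select(
            scores, rf_cutoff=self.rf_cutoff, nn_cutoff=self.nn_cutoff, alpha=self.alpha
        )
        self.scores_ = result.scores
        self.selected_ = result.selected
        self.group_labels_ = groups
        self.support_ = self.scores_["consensus"].to_numpy()
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]


def rf_importance(X, y, n_iter: int = 50, frac: float = 0.8, seed: int = 0) -> np.ndarray:
    """Functional wrapper over :class:`RandomForestImportance`."""
    return RandomForestImportance(n_iter=n_iter, frac=frac, random_state=seed).fit(X, y).importances_


def nn_importance(X, y, n_search: int = 10, seed: int = 0, **kwargs) -> np.ndarray:
    """Functional wrapper over :class:`NeuralNetworkImportance`."""
    return (
        NeuralNetworkImportance(n_search=n_search, random_state=seed, **kwargs)
        .fit(X, y)
        .importances_
    )
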