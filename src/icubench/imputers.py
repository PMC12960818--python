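"""Imputation methods behind a single fit/impute contract.

Implemented in-package:

* ``mean`` / ``median`` — per stay-variable central value of the observed
  hours, with a train-cohort fallback for fully missing stay-variables.
* ``locf`` — last observation carried forward; a leading gap is backfilled
  from the first observed value by default.
* ``linear`` — straight-line interpolation between the nearest observed
  anchors on the hour grid; edge gaps extend the nearest anchor.
* ``mice`` / ``missforest`` — chained-equations imputation on the flattened
  (one row per stay, variables x hours columns) representation: columns are
  visited in order of increasing missingness and each is regressed on all
  others, iterating to tolerance.  ``mice`` uses a ridge-regularised linear
  regressor; ``missforest`` a random forest.

Deep-learning imputers plug in through :func:`register_deep_adapter`; the
adapter enforces the same contract (observed cells untouched, output
complete) around any external model exposing fit/impute on
(stays x hours x variables) tensors.

The contract: ``fit`` receives a training cohort (by protocol, one with a
30% MCAR mask applied, in standardized space); ``impute`` receives a masked
cohort and returns it with every missing cell filled and every observed
cell untouched.
"""

from __future__ import annotations

import numpy as np

from .cohort import N_VARIABLES, VARIABLES, Cohort

__all__ = [
    "BaseImputer",
    "CentralImputer",
    "LOCFImputer",
    "LinearInterpolationImputer",
    "ChainedImputer",
    "DeepAdapter",
    "ContractViolation",
    "register_imputer",
    "register_deep_adapter",
    "get_imputer",
    "available_imputers",
    "check_contract",
]


class ContractViolation(RuntimeError):
    """An imputer broke the fit/impute contract."""


class BaseImputer:
    """Fit/impute interface shared by every imputation method."""

    name: str = "base"

    def fit(self, cohort: Cohort) -> "BaseImputer":
        return self

    def impute(self, cohort: Cohort) -> Cohort:  # pragma: no cover - abstract
        raise NotImplementedError

    # helpers ---------------------------------------------------------------

    @staticmethod
    def _finalize(original: Cohort, filled_values: np.ndarray) -> Cohort:
        """Re-assert the contract: observed cells copied back verbatim,
        output complete."""
        obs = original.observed()
        out_values = np.where(obs, original.values, filled_values)
        if np.isnan(out_values).any():
            raise ContractViolation("imputer output still contains missing cells")
        return Cohort(out_values, np.zeros_like(obs), original.stay_ids.copy())


class CentralImputer(BaseImputer):
    """Per stay-variable mean or median imputation."""

    def __init__(self, statistic: str = "mean"):
        if statistic not in ("mean", "median"):
            raise ValueError("statistic must be 'mean' or 'median'")
        self.statistic = statistic
        self.name = statistic
        self._fallback: dict[str, float] | None = None

    def fit(self, cohort: Cohort) -> "CentralImputer":
        stat = np.nanmean if self.statistic == "mean" else np.nanmedian
        self._fallback = {}
        for j, v in enumerate(VARIABLES):
            col = cohort.values[:, :, j]
            if np.isnan(col).all():
                continue
            self._fallback[v] = float(stat(col))
        return self

    def impute(self, cohort: Cohort) -> Cohort:
        stat = np.nanmean if self.statistic == "mean" else np.nanmedian
        filled = cohort.values.copy()
        for i in range(cohort.n_stays):
            for j, v in enumerate(VARIABLES):
                series = filled[i, :, j]
                miss = np.isnan(series)
                if not miss.any():
                    continue
                if miss.all():
                    if self._fallback is None or v not in self._fallback:
                        raise ValueError(
                            f"stay {cohort.stay_ids[i]} variable {v} is fully missing "
                            "and no training fallback is available (call fit first)"
                        )
                    fill = self._fallback[v]
                else:
                    fill = float(stat(series))
                series[miss] = fill
        return self._finalize(cohort, filled)


class LOCFImputer(BaseImputer):
    """Last observation carried forward."""

    name = "locf"

    def __init__(self, leading_policy: str = "backfill"):
        if leading_policy not in ("backfill", "central"):
            raise ValueError("leading_policy must be 'backfill' or 'central'")
        self.leading_policy = leading_policy
        self._central = CentralImputer("mean")

    def fit(self, cohort: Cohort) -> "LOCFImputer":
        self._central.fit(cohort)
        return self

    def impute(self, cohort: Cohort) -> Cohort:
        filled = cohort.values.copy()
        for i in range(cohort.n_stays):
            for j, v in enumerate(VARIABLES):
                series = filled[i, :, j]
                obs_idx = np.flatnonzero(~np.isnan(series))
                if obs_idx.size == 0:
                    fb = self._central._fallback
                    if fb is None or v not in fb:
                        raise ValueError(
                            f"stay {cohort.stay_ids[i]} variable {v} is fully missing "
                            "and no training fallback is available (call fit first)"
                        )
                    series[:] = fb[v]
                    continue
                last = np.nan
                if self.leading_policy == "backfill":
                    last = series[obs_idx[0]]
                elif self._central._fallback and v in self._central._fallback:
                    last = self._central._fallback[v]
                for t in range(series.size):
                    if np.isnan(series[t]):
                        series[t] = last
                    else:
                        last = series[t]
        return self._finalize(cohort, filled)


class LinearInterpolationImputer(BaseImputer):
    """Straight-line interpolation between nearest observed anchors.

    Edge gaps (no anchor on one side) take the nearest anchor's value
    (constant extension) under the default policy.
    """

    name = "linear"

    def __init__(self, edge_policy: str = "nearest"):
        if edge_policy != "nearest":
            raise ValueError("only the 'nearest' edge policy is implemented")
        self.edge_policy = edge_policy
        self._central = CentralImputer("mean")

    def fit(self, cohort: Cohort) -> "LinearInterpolationImputer":
        self._central.fit(cohort)
        return self

    def impute(self, cohort: Cohort) -> Cohort:
        filled = cohort.values.copy()
        hours = np.arange(cohort.n_hours, dtype=float)
        for i in range(cohort.n_stays):
            for j, v in enumerate(VARIABLES):
                series = filled[i, :, j]
                obs = ~np.isnan(series)
                if not obs.any():
                    fb = self._central._fallback
                    if fb is None or v not in fb:
                        raise ValueError(
                            f"stay {cohort.stay_ids[i]} variable {v} is fully missing "
                            "and no training fallback is available (call fit first)"
                        )
                    series[:] = fb[v]
                    continue
                if obs.all():
                    continue
                # np.interp: linear between anchors, constant beyond the ends
                series[~obs] = np.interp(hours[~obs], hours[obs], series[obs])
        return self._finalize(cohort, filled)


class ChainedImputer(BaseImputer):
    """Chained-equations imputation on the flattened per-stay table.

    Each stay becomes one row of ``n_hours * 4`` columns.  Fitting: missing
    entries start at their column means; columns are then visited in order
    of increasing training missingness, each regressed on all other columns
    over the rows where it is observed, and its missing entries overwritten
    with predictions; sweeps repeat until the mean absolute change of
    imputed entries drops below ``tol`` or ``max_iter`` is reached.  The
    entire per-sweep sequence of fitted column regressors is kept and
    replayed in order at impute time — replaying only final-sweep models
    lets the chained feedback loop amplify when large correlated blocks are
    jointly missing — which makes imputation deterministic given the fitted
    state.

    ``regressor='linear'`` uses an evidence-tuned Bayesian ridge by default
    (the flat design is strongly collinear; pass ``ridge_alpha`` for a
    fixed penalty); ``'forest'`` a random forest.
    """

    def __init__(
        self,
        regressor: str = "linear",
        max_iter: int | None = None,
        tol: float = 1e-3,
        seed: int = 0,
        ridge_alpha: float | None = None,
        n_estimators: int = 10,
        max_features: float | str = 0.2,
        max_depth: int | None = 12,
    ):
        if regressor not in ("linear", "forest"):
            raise ValueError("regressor must be 'linear' or 'forest'")
        self.regressor = regressor
        self.name = "mice" if regressor == "linear" else "missforest"
        # the forest variant converges in very few sweeps and dominates cost
        self.max_iter = max_iter if max_iter is not None else (5 if regressor == "linear" else 2)
        self.tol = tol
        self.seed = seed
        self.ridge_alpha = ridge_alpha
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.max_depth = max_depth
        self._col_means: np.ndarray | None = None
        self._order: np.ndarray | None = None
        self._sequence: list[tuple[int, object]] = []
        self._predictors: np.ndarray | None = None

    def _new_model(self):
        if self.regressor == "linear":
            # the flat design is strongly collinear; an evidence-tuned
            # Bayesian ridge adapts the penalty to the data, while an
            # explicit ridge_alpha pins it
            if self.ridge_alpha is None:
                from sklearn.linear_model import BayesianRidge

                return BayesianRidge()
            from sklearn.linear_model import Ridge

            return Ridge(alpha=self.ridge_alpha)
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            random_state=self.seed,
            n_jobs=1,
        )

    @staticmethod
    def _flatten(cohort: Cohort) -> np.ndarray:
        return cohort.values.reshape(cohort.n_stays, -1).copy()

    def fit(self, cohort: Cohort) -> "ChainedImputer":
        X = self._flatten(cohort)
        obs = ~np.isnan(X)
        n_cols = X.shape[1]
        with np.errstate(invalid="ignore"):
            means = np.nanmean(X, axis=0)
        degenerate = ~np.isfinite(means)
        means[degenerate] = 0.0  # all-missing columns: mean-fill at zero (standardized space)
        self._col_means = means
        self._predictors = ~degenerate
        missing_per_col = (~obs).sum(axis=0)
        self._order = np.argsort(missing_per_col, kind="stable")

        X_filled = np.where(obs, X, means)
        self._sequence = []
        prev_imputed = X_filled[~obs].copy()
        for _ in range(max(self.max_iter, 1)):
            for c in self._order:
                if degenerate[c]:
                    continue
                other = self._predictors.copy()
                other[c] = False
                rows = obs[:, c]
                if rows.sum() < 2:
                    continue
                model = self._new_model()
                model.fit(X_filled[rows][:, other], X_filled[rows, c])
                self._sequence.append((int(c), model))
                fill_rows = ~rows
                if fill_rows.any():
                    X_filled[fill_rows, c] = model.predict(X_filled[fill_rows][:, other])
            if (~obs).any():
                cur = X_filled[~obs]
                delta = float(np.mean(np.abs(cur - prev_imputed)))
                prev_imputed = cur.copy()
                if delta < self.tol:
                    break
            else:
                break
        return self

    def impute(self, cohort: Cohort) -> Cohort:
        if self._col_means is None:
            raise ValueError("ChainedImputer must be fitted before imputing")
        X = self._flatten(cohort)
        obs = ~np.isnan(X)
        X_filled = np.where(obs, X, self._col_means)
        if (~obs).any():
            # replay the exact training sweep sequence
            for c, model in self._sequence:
                fill_rows = ~obs[:, c]
                if not fill_rows.any():
                    continue
                other = self._predictors.copy()
                other[c] = False
                X_filled[fill_rows, c] = model.predict(X_filled[fill_rows][:, other])
        filled = X_filled.reshape(cohort.values.shape)
        return self._finalize(cohort, filled)


class DeepAdapter(BaseImputer):
    """Contract-enforcing wrapper around an external tensor imputer.

    The handle must expose ``fit(X)`` and ``impute(X)`` (or ``predict``)
    where ``X`` is a float array of shape (stays, hours, variables) with
    NaN marking missing entries — the convention of time-series imputation
    libraries such as PyPOTS.  Both the native-missing and artificial-mask
    cells arrive as NaN; how the model weights them internally is its own
    convention.  The adapter re-checks the contract on every output.
    """

    def __init__(self, name: str, handle):
        self.name = name
        self.handle = handle

    def fit(self, cohort: Cohort) -> "DeepAdapter":
        if hasattr(self.handle, "fit"):
            self.handle.fit(cohort.values.copy())
        return self

    def impute(self, cohort: Cohort) -> Cohort:
        call = getattr(self.handle, "impute", None) or getattr(self.handle, "predict", None)
        if call is None:
            raise ContractViolation(f"adapter handle {self.name!r} has no impute/predict")
        filled = np.asarray(call(cohort.values.copy()), dtype=float)
        if filled.shape != cohort.values.shape:
            raise ContractViolation(
                f"adapter {self.name!r} returned shape {filled.shape}, "
                f"expected {cohort.values.shape}"
            )
        obs = cohort.observed()
        if not np.allclose(filled[obs], cohort.values[obs], equal_nan=False):
            raise ContractViolation(f"adapter {self.name!r} altered observed cells")
        if np.isnan(filled).any():
            raise ContractViolation(f"adapter {self.name!r} left missing cells unfilled")
        return self._finalize(cohort, filled)


def check_contract(imputer: BaseImputer, cohort: Cohort) -> Cohort:
    """Run ``impute`` and verify the contract explicitly.

    Returns the imputed cohort; raises :class:`ContractViolation` on any
    breach.  Useful for vetting externally registered imputers.
    """
    out = imputer.impute(cohort)
    if out.values.shape != cohort.values.shape:
        raise ContractViolation("output shape differs from input")
    if np.isnan(out.values).any():
        raise ContractViolation("output contains missing cells")
    obs = cohort.observed()
    if not np.array_equal(out.values[obs], cohort.values[obs]):
        raise ContractViolation("observed cells were altered")
    return out


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_BUILTINS = {
    "mean": lambda **kw: CentralImputer("mean"),
    "median": lambda **kw: CentralImputer("median"),
    "locf": lambda **kw: LOCFImputer(**kw),
    "linear": lambda **kw: LinearInterpolationImputer(**kw),
    "mice": lambda **kw: ChainedImputer(regressor="linear", **kw),
    "missforest": lambda **kw: ChainedImputer(regressor="forest", **kw),
}

_REGISTRY: dict[str, object] = dict(_BUILTINS)

# Deep models available through the optional PyPOTS dependency; named here
# so the error message can point at the extra.
_PYPOTS_MODELS = ("saits", "brits", "usgan", "gpvae")


def register_imputer(name: str, factory) -> None:
    """Register a factory (callable returning a BaseImputer) under a name."""
    _REGISTRY[name] = factory


def register_deep_adapter(name: str, handle) -> DeepAdapter:
    """Wrap an external tensor imputer in the contract and register it."""
    adapter = DeepAdapter(name, handle)
    _REGISTRY[name] = lambda **kw: adapter
    return adapter


def available_imputers() -> list[str]:
    return sorted(_REGISTRY)


def get_imputer(name: str, **params) -> BaseImputer:
    if name in _REGISTRY:
        return _REGISTRY[name](**params)
    if name in _PYPOTS_MODELS:
        try:
            import pypots  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                f"imputer {name!r} needs the optional PyPOTS dependency; "
                "install the 'deep' extra (pip install icubench[deep]) and "
                "register the model via register_deep_adapter"
            ) from exc
        raise KeyError(
            f"PyPOTS is installed but {name!r} is not registered; wrap the model "
            "with register_deep_adapter"
        )
    raise KeyError(f"unknown imputer {name!r}; available: {available_imputers()}")
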