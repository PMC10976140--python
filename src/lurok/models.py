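"""Land-use-regression model families under a common fit/predict contract.

Three families are supported:

* **PLS** — partial least squares on centered-and-scaled covariates with a
  small fixed number of scores (default 3), the dimension-reduction route.
* **RF** — a random forest with the reference hyperparameters mtry=50
  (clamped to the number of variables), ntree=500, node size 5, plus an
  out-of-bag permutation importance ("IncMSE-style").
* **SLR** — supervised forward stepwise linear regression: start from the
  single best sign-plausible predictor, add the predictor with the largest
  R² gain each round while every selected coefficient keeps its expected
  sign, stop when the gain drops below a threshold (default 0.1), then
  remove variables worst-first until all variance inflation factors are at
  most 3.

Every fitted model records its training column order and predicts from any
covariate frame containing those columns, regardless of storage order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)


@dataclass
class PLSSpec:
    n_scores: int = 3

    def __post_init__(self):
        if self.n_scores < 1:
            raise ValueError("n_scores must be >= 1")


@dataclass
class RFSpec:
    mtry: int = 50
    ntree: int = 500
    node_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")


@dataclass
class SLRSpec:
    r2_gain_threshold: float = 0.1
    vif_threshold: float = 3.0
    enforce_sign: bool = True

    def __post_init__(self):
        if self.r2_gain_threshold <= 0 or self.vif_threshold <= 0:
            raise ValueError("thresholds must be positive")


def _as_frame(X) -> pd.DataFrame:
    """Accept a plain frame or a (data, meta) covariate tuple."""
    if isinstance(X, tuple):
        X = X[0]
    if not isinstance(X, pd.DataFrame):
        raise TypeError("covariates must be a pandas DataFrame")
    if X.isna().any().any():
        raise ValueError("covariate matrix has missing cells")
    if X.columns.duplicated().any():
        raise ValueError("covariate column names must be unique")
    return X


class LURModel:
    """Abstract fit/predict contract shared by the three families."""

    family: str
    columns: list[str]

    def _align(self, X) -> np.ndarray:
        X = _as_frame(X)
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"missing covariate column(s): {missing}")
        return X[self.columns].to_numpy(dtype=float)

    def predict(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class PLSModel(LURModel):
    family = "PLS"

    def __init__(self, columns, pls: PLSRegression, center, scale, score_flip):
        self.columns = list(columns)
        self._pls = pls
        self._center = center
        self._scale = scale
        self._score_flip = score_flip  # +-1 per score; diagnostics only

    def predict(self, X) -> np.ndarray:
        return self._pls.predict(self._align(X)).ravel()

    def scores(self, X) -> np.ndarray:
        """Score matrix (units × n_scores), sign-fixed so the first score
        correlates non-negatively with the training response."""
        t = self._pls.transform(self._align(X))
        return t * self._score_flip


def fit_pls(X, y, spec: PLSSpec | None = None) -> PLSModel:
    """Fit a PLS regression of concentrations on covariates.

    Covariates are centered and scaled internally; zero-variance columns are
    dropped with a warning. Constant responses are rejected.
    """
    spec = spec or PLSSpec()
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant; PLS undefined")
    sd = X.std(axis=0, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance column(s): {dead}")
        X = X.drop(columns=dead)
    n, p = X.shape
    if not 1 <= spec.n_scores < min(n, p + 1):
        raise ValueError(
            f"n_scores={spec.n_scores} must satisfy 1 <= n_scores < min(n_units, n_variables+1)"
        )
    if n < spec.n_scores + 2:
        raise ValueError("need at least n_scores + 2 units")
    pls = PLSRegression(n_components=spec.n_scores, scale=True)
    pls.fit(X.to_numpy(dtype=float), y)
    t = pls.x_scores_
    yc = y - y.mean()
    flip = np.ones(spec.n_scores)
    corr0 = float(t[:, 0] @ yc)
    if corr0 < 0:
        flip[0] = -1.0
    return PLSModel(X.columns, pls, pls._x_mean, pls._x_std, flip)


def pls_score_correlations(model: PLSModel, X) -> pd.Series:
    """Pearson correlation of each covariate with the first PLS score.

    Zero-variance columns get correlation 0 (flagged via a warning). Used as
    the interpretability diagnostic for PLS models: the first score explains
    most covariate variation, so these correlations show which geographic
    variables drive it.
    """
    Xf = _as_frame(X)[model.columns]
    t1 = model.scores(Xf)[:, 0]
    out = {}
    t1c = t1 - t1.mean()
    denom_t = np.sqrt((t1c**2).sum())
    for c in model.columns:
        v = Xf[c].to_numpy(dtype=float)
        vc = v - v.mean()
        denom_v = np.sqrt((vc**2).sum())
        if denom_v == 0 or denom_t == 0:
            warnings.warn(f"zero-variance column {c!r}: correlation set to 0")
            out[c] = 0.0
        else:
            out[c] = float(vc @ t1c / (denom_v * denom_t))
    return pd.Series(out, name="corr_with_first_score")


# ---------------------------------------------------------------------------
# random forest


_mtry_warned: set[tuple[int, int]] = set()


class RFModel(LURModel):
    family = "RF"

    def __init__(self, columns, forest: RandomForestRegressor, y_train):
        self.columns = list(columns)
        self.forest = forest
        self._y_train = np.asarray(y_train, dtype=float)

    def predict(self, X) -> np.ndarray:
        return self.forest.predict(self._align(X))


def fit_rf(X, y, spec: RFSpec | None = None) -> RFModel:
    """Fit a random forest with the reference hyperparameters.

    mtry (features tried per split) is clamped to the number of variables
    with a logged warning when it exceeds it, keeping the reference setting
    usable at any scale.
    """
    spec = spec or RFSpec()
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if len(y) < spec.node_size + 1:
        raise ValueError("need at least node_size + 1 units")
    mtry = spec.mtry
    if mtry > X.shape[1]:
        if (spec.mtry, X.shape[1]) not in _mtry_warned:
            _mtry_warned.add((spec.mtry, X.shape[1]))
            logger.warning(
                "mtry=%d exceeds n_variables=%d; clamping", mtry, X.shape[1]
            )
        mtry = X.shape[1]
    forest = RandomForestRegressor(
        n_estimators=spec.ntree,
        max_features=mtry,
        min_samples_leaf=spec.node_size,
        oob_score=len(y) >= 10,
        bootstrap=True,
        random_state=spec.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n OOB coverage warnings
        forest.fit(X.to_numpy(dtype=float), y)
    return RFModel(X.columns, forest, y)


def _oob_indices_per_tree(forest: RandomForestRegressor, n: int) -> list[np.ndarray]:
    """Out-of-bag sample indices for each tree, reconstructed by replaying
    the bootstrap draw from each tree's seed (verified against
    ``oob_prediction_`` in the test suite)."""
    out = []
    for tree in forest.estimators_:
        rs = np.random.RandomState(tree.random_state)
        sampled = rs.randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        out.append(np.nonzero(mask)[0])
    return out


def rf_importance(model: RFModel, X, y=None, top_k: int | None = None) -> pd.DataFrame:
    """IncMSE-style permutation importance, ranked.

    For each tree, the MSE on its out-of-bag samples is compared with the
    MSE after permuting one covariate among those samples; the importance of
    the covariate is the mean increase across trees, with its standard error
    reported. ``top_k`` (default all; the reference diagnostic uses 10)
    truncates the ranked table.
    """
    Xa = model._align(X)
    y = model._y_train if y is None else np.asarray(y, dtype=float)
    n, p = Xa.shape
    oob = _oob_indices_per_tree(model.forest, n)
    rng = np.random.default_rng(model.forest.random_state)
    increases = np.full((len(model.forest.estimators_), p), np.nan)
    for t_i, (tree, idx) in enumerate(zip(model.forest.estimators_, oob)):
        if len(idx) < 2:
            continue
        base = np.mean((tree.predict(Xa[idx]) - y[idx]) ** 2)
        for j in range(p):
            Xp = Xa[idx].copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            increases[t_i, j] = np.mean((tree.predict(Xp) - y[idx]) ** 2) - base
    mean_inc = np.nanmean(increases, axis=0)
    n_trees = np.sum(~np.isnan(increases[:, 0]))
    sd_inc = np.nanstd(increases, axis=0, ddof=1) / max(np.sqrt(n_trees), 1.0)
    out = (
        pd.DataFrame(
            {"variable": model.columns, "inc_mse": mean_inc, "se": sd_inc}
        )
        .sort_values("inc_mse", ascending=False, ignore_index=True)
    )
    return out.head(top_k) if top_k is not None else out


# ---------------------------------------------------------------------------
# supervised stepwise linear regression


def _ols(Xa: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS with intercept; returns (coefficients incl. intercept first, R²)."""
    A = np.column_stack([np.ones(len(y)), Xa])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return coef, r2


def compute_vif(X, variables: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per variable: VIF_j = 1/(1−R²_j) from
    regressing variable j on the other variables (with intercept).
    A single variable has VIF 1; exact collinearity gives +inf."""
    X = _as_frame(X)
    variables = list(variables) if variables is not None else list(X.columns)
    out = {}
    for v in variables:
        others = [c for c in variables if c != v]
        if not others:
            out[v] = 1.0
            continue
        _, r2 = _ols(X[others].to_numpy(dtype=float), X[v].to_numpy(dtype=float))
        r2 = min(r2, 1.0)
        out[v] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def _signs_ok(
    coef: np.ndarray, variables: list[str], expected: dict[str, str]
) -> bool:
    """coef excludes the intercept; a variable with sign '0' is unconstrained."""
    for b, v in zip(coef, variables):
        s = expected.get(v, "0")
        if s == "+" and b <= 0:
            return False
        if s == "-" and b >= 0:
            return False
    return True


class SLRModel(LURModel):
    family = "SLR"

    def __init__(self, columns, coef, intercept, trace, vifs):
        self.columns = list(columns)  # selected variables, selection order
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)
        self.trace = trace  # list of dicts: round, variable, r2, decision
        self.vifs = vifs

    @property
    def selected_variables(self) -> list[str]:
        return self.columns

    def predict(self, X) -> np.ndarray:
        return self.intercept + self._align(X) @ self.coef


def fit_slr(X, y, spec: SLRSpec | None = None, expected_sign: dict[str, str] | None = None) -> SLRModel:
    """Supervised forward stepwise regression with sign and VIF screening.

    ``expected_sign`` maps variable names to '+', '-' or '0' (unconstrained);
    it may also be supplied via a covariate meta frame with an
    ``expected_sign`` column when ``X`` is a (data, meta) tuple.

    Round 0 picks the single variable with the highest R² whose coefficient
    matches its expected sign; each later round adds the variable giving the
    largest R² gain among candidates that keep every selected coefficient
    sign-plausible, stopping when the best gain falls below
    ``r2_gain_threshold``. Variables are then removed worst-first (refitting
    after each removal) until all VIFs are at most ``vif_threshold``.
    """
    spec = spec or SLRSpec()
    if isinstance(X, tuple) and expected_sign is None:
        meta = X[1]
        expected_sign = meta["expected_sign"].to_dict()
    X = _as_frame(X)
    expected = dict(expected_sign or {})
    if not spec.enforce_sign:
        expected = {}
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 units")

    selected: list[str] = []
    trace: list[dict] = []
    current_r2 = 0.0
    round_no = 0
    while True:
        best = None
        for v in X.columns:
            if v in selected:
                continue
            cand = selected + [v]
            coef, r2 = _ols(X[cand].to_numpy(dtype=float), y)
            plausible = _signs_ok(coef[1:], cand, expected)
            trace.append(
                {
                    "round": round_no,
                    "variable": v,
                    "r2": r2,
                    "sign_ok": plausible,
                    "decision": "candidate",
                }
            )
            if plausible and (best is None or r2 > best[1]):
                best = (v, r2)
        if best is None:
            if round_no == 0:
                signs = {v: expected.get(v, "0") for v in X.columns}
                raise ValueError(
                    "no sign-plausible starting variable; candidate expected "
                    f"signs: {signs}"
                )
            break
        gain = best[1] - current_r2
        if round_no > 0 and gain < spec.r2_gain_threshold:
            trace.append(
                {
                    "round": round_no,
                    "variable": best[0],
                    "r2": best[1],
                    "sign_ok": True,
                    "decision": f"stop (gain {gain:.4f} < {spec.r2_gain_threshold})",
                }
            )
            break
        selected.append(best[0])
        current_r2 = best[1]
        trace.append(
            {
                "round": round_no,
                "variable": best[0],
                "r2": best[1],
                "sign_ok": True,
                "decision": "selected",
            }
        )
        round_no += 1
        if len(selected) == X.shape[1]:
            break

    # iterative worst-first VIF pruning with refit
    while len(selected) > 1:
        vifs = compute_vif(X, selected)
        worst = vifs.idxmax()
        if vifs[worst] <= spec.vif_threshold:
            break
        selected.remove(worst)
        trace.append(
            {
                "round": round_no,
                "variable": worst,
                "r2": np.nan,
                "sign_ok": True,
                "decision": f"removed (VIF {vifs[worst]:.2f} > {spec.vif_threshold})",
            }
        )
    coef, r2 = _ols(X[selected].to_numpy(dtype=float), y)
    vifs = compute_vif(X, selected)
    return SLRModel(selected, coef[1:], coef[0], trace, vifs)


# ---------------------------------------------------------------------------
# dispatch


FAMILIES = {"PLS", "RF", "SLR"}


def fit_lur(family: str, X, y, spec=None, expected_sign=None) -> LURModel:
    """Fit any family under the uniform contract used by validation and
    exposure assessment."""
    fam = family.upper()
    if fam == "PLS":
        return fit_pls(X, y, spec)
    if fam == "RF":
        return fit_rf(X, y, spec)
    if fam == "SLR":
        return fit_slr(X, y, spec, expected_sign=expected_sign)
    raise ValueError(f"unknown model family {family!r}; expected one of {sorted(FAMILIES)}")
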