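"""Stepwise linear discriminant analysis (SWLDA).

Classical stepwise regression of a 0/1 class code on epoch features: a
forward step adds the excluded feature with the smallest partial-F p-value if
it is below ``p_in``; a backward step removes the included feature with the
largest p-value if it exceeds ``p_out``; the loop repeats to a fixed point or
until ``max_features`` are in the model.  Final weights are the ordinary
least-squares coefficients of the selected features (plus intercept), and an
epoch's score is the fitted value — higher means more target-like.

``p_in <= p_out`` prevents entry/removal cycling; an iteration cap guards the
loop regardless and raises if hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_RIDGE_TOL = 1e-10  # relative variance below which a candidate is unusable


@dataclass(frozen=True)
class SWLDAConfig:
    """Stepwise thresholds: enter below ``p_in``, remove above ``p_out``."""

    p_in: float = 0.1
    p_out: float = 0.15
    max_features: int = 60

    def __post_init__(self) -> None:
        if not (0 < self.p_in <= self.p_out < 1):
            raise ValueError("need 0 < p_in <= p_out < 1")
        if self.max_features < 1:
            raise ValueError("max_features must be positive")


@dataclass(frozen=True)
class SWLDAModel:
    """Selected feature indices, their weights, and the intercept."""

    selected: tuple[int, ...]
    weights: np.ndarray
    intercept: float
    n_features_in: int
    n_epochs: int
    config: SWLDAConfig = field(default_factory=SWLDAConfig)

    def to_dict(self) -> dict:
        return {
            "selected": [int(i) for i in self.selected],
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "n_features_in": int(self.n_features_in),
            "n_epochs": int(self.n_epochs),
            "config": {"p_in": self.config.p_in, "p_out": self.config.p_out,
                       "max_features": self.config.max_features},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SWLDAModel":
        return cls(selected=tuple(d["selected"]),
                   weights=np.asarray(d["weights"], dtype=float),
                   intercept=float(d["intercept"]),
                   n_features_in=int(d["n_features_in"]),
                   n_epochs=int(d["n_epochs"]),
                   config=SWLDAConfig(**d["config"]))


def _ols(A: np.ndarray, y: np.ndarray):
    """OLS fit; returns (beta, rss, df_resid, p-values per column)."""
    n, k = A.shape
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    df = n - rank
    if df <= 0:
        return beta, rss, 0, np.ones(k)
    sigma2 = rss / df
    cov = np.linalg.pinv(A.T @ A) * sigma2
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta + 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(tval), df=df)
    return beta, rss, df, pvals


def _rebuild_state(X: np.ndarray, y: np.ndarray, selected: list[int]):
    """Orthonormal basis of [1, X_sel], residual, RSS, residualized candidates."""
    n = X.shape[0]
    A = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
    Q, _ = np.linalg.qr(A)
    r = y - Q @ (Q.T @ y)
    Xr = X - Q @ (Q.T @ X)
    for j in selected:
        Xr[:, j] = 0.0
    return Q, r, float(r @ r), Xr


def swlda_fit(X: np.ndarray, y: np.ndarray,
              config: SWLDAConfig | None = None) -> SWLDAModel:
    """Fit SWLDA on an (epochs x features) matrix and 0/1 (or boolean) labels.

    If no feature passes ``p_in`` at the first step the model is empty and
    every score equals the intercept (the label mean); this is logged.
    Zero-variance features and features collinear with the current model are
    skipped.  Epoch order does not affect the result.
    """
    config = config or SWLDAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("labels must align with epochs")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels are constant; need both classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 epochs per class")

    col_scale = (X ** 2).sum(axis=0) + 1e-300
    selected: list[int] = []
    Q, r, rss, Xr = _rebuild_state(X, y, selected)
    col_ss = (Xr ** 2).sum(axis=0)

    max_iter = 20 * config.max_features + 50
    for _ in range(max_iter):
        changed = False

        # Forward: add the best candidate if its partial-F p-value < p_in.
        if len(selected) < config.max_features:
            df_new = n - (len(selected) + 2)  # after adding one more column
            if df_new >= 1:
                usable = col_ss > _RIDGE_TOL * col_scale
                with np.errstate(divide="ignore", invalid="ignore"):
                    c = r @ Xr
                    ss_add = np.where(usable, c * c / np.where(usable, col_ss, 1.0), 0.0)
                    rss_new = np.maximum(rss - ss_add, 0.0)
                    F = ss_add / np.where(rss_new > 0, rss_new / df_new, np.inf)
                F = np.where((rss_new <= 1e-12 * max(rss, 1e-300)) & usable,
                             np.inf, F)
                pvals = np.where(usable, stats.f.sf(F, 1, df_new), np.inf)
                j = int(np.argmin(pvals))  # ties -> lowest index
                if pvals[j] < config.p_in:
                    qn = Xr[:, j] / np.sqrt(col_ss[j])
                    Q = np.column_stack([Q, qn])
                    r = r - qn * (qn @ r)
                    rss = float(r @ r)
                    Xr = Xr - np.outer(qn, qn @ Xr)
                    Xr[:, j] = 0.0
                    col_ss = (Xr ** 2).sum(axis=0)
                    selected.append(j)
                    changed = True

        # Backward: drop the worst included feature if its p-value > p_out.
        if selected:
            A = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
            _, _, df, pvals = _ols(A, y)
            feat_p = pvals[1:]  # skip intercept
            worst = int(np.argmax(feat_p))
            if df >= 1 and feat_p[worst] > config.p_out:
                removed = selected.pop(worst)
                logger.debug("backward step removed feature %d (p=%.3g)",
                             removed, feat_p[worst])
                Q, r, rss, Xr = _rebuild_state(X, y, selected)
                col_ss = (Xr ** 2).sum(axis=0)
                changed = True

        if not changed:
            break
    else:
        raise RuntimeError("stepwise selection did not converge "
                           f"within {max_iter} iterations")

    if not selected:
        logger.warning("no feature passed p_in=%.3g; returning empty model",
                       config.p_in)
        return SWLDAModel(selected=(), weights=np.empty(0),
                          intercept=float(y.mean()), n_features_in=p,
                          n_epochs=n, config=config)

    A = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
    beta, _, _, _ = _ols(A, y)
    return SWLDAModel(selected=tuple(selected),
                      weights=np.asarray(beta[1:], dtype=float),
                      intercept=float(beta[0]), n_features_in=p,
                      n_epochs=n, config=config)


def swlda_score(model: SWLDAModel, features: np.ndarray) -> np.ndarray | float:
    """Linear score ``intercept + w . x`` for one vector or a feature matrix."""
    features = np.asarray(features, dtype=float)
    single = features.ndim == 1
    mat = features[None, :] if single else features
    if mat.shape[1] != model.n_features_in:
        raise ValueError(
            f"feature length {mat.shape[1]} != trained {model.n_features_in}")
    if model.selected:
        scores = model.intercept + mat[:, list(model.selected)] @ model.weights
    else:
        scores = np.full(mat.shape[0], model.intercept)
    return float(scores[0]) if single else scores


def stepwise_fixed_point_violations(X: np.ndarray, y: np.ndarray,
                                    model: SWLDAModel) -> dict:
    """Check the stepwise fixed point by direct regressions (diagnostic).

    Returns counts of excluded features whose entry p-value is below ``p_in``
    and of included features whose p-value exceeds ``p_out``; both are zero
    for a converged model (up to collinear candidates, which cannot enter).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    sel = list(model.selected)
    base = np.column_stack([np.ones(n)] + [X[:, j] for j in sel])
    enterable = 0
    if len(sel) < model.config.max_features:
        for j in range(p):
            if j in sel:
                continue
            A = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(A) <= np.linalg.matrix_rank(base):
                continue
            _, _, df, pv = _ols(A, y)
            if df >= 1 and pv[-1] < model.config.p_in:
                enterable += 1
    removable = 0
    if sel:
        _, _, df, pv = _ols(base, y)
        if df >= 1:
            removable = int((pv[1:] > model.config.p_out).sum())
    return {"enterable": enterable, "removable": removable}
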