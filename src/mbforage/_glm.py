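"""Internal ridge-stabilized logistic fitting shared by the choice models.

A tiny L2 penalty (default 1e-4, never on the intercept) keeps fits finite
under quasi-separation without materially biasing large-n estimates.  The
model-comparison metric throughout is percent deviance explained,
100 * (1 - dev_model / dev_null), against the bias-only null refit on the
same rows.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression

_EPS = 1e-12
#: |coefficient| beyond which we flag the fit as (near-)separated.
SEPARATION_LIMIT = 30.0


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def null_deviance(y: np.ndarray) -> float:
    p = np.full_like(y, np.mean(y), dtype=float)
    return bernoulli_deviance(y, p)


def fit_logistic(X, y, l2: float = 1e-4) -> dict:
    """Penalized-MLE logistic fit; returns coefs, bias, deviances and quality.

    ``X`` of shape (n, k) with k possibly 0 (bias-only null model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if n == 0:
        raise ValueError("no observations")
    uniq = np.unique(y)
    if len(uniq) < 2:
        raise ValueError("responses are all identical; logistic fit undefined")
    dev_null = null_deviance(y)
    if X.shape[1] == 0:
        pbar = float(np.mean(y))
        return {
            "coef": np.zeros(0),
            "bias": float(np.log(pbar / (1 - pbar))),
            "deviance": dev_null,
            "null_deviance": dev_null,
            "pct_deviance_explained": 0.0,
            "separation_flag": False,
        }
    model = LogisticRegression(C=1.0 / l2, solver="lbfgs", max_iter=2000, tol=1e-8)
    model.fit(X, y)
    p = model.predict_proba(X)[:, 1]
    dev = bernoulli_deviance(y, p)
    coef = model.coef_.ravel()
    return {
        "coef": coef,
        "bias": float(model.intercept_[0]),
        "deviance": dev,
        "null_deviance": dev_null,
        "pct_deviance_explained": float(100.0 * (1.0 - dev / dev_null)),
        "separation_flag": bool(np.any(np.abs(coef) > SEPARATION_LIMIT)),
    }
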