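"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: dummy-variable OLS
with an explicitly assembled design matrix and a hand-rolled clustered
sandwich, and a plain-Python run-length scan for visit construction.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def dummy_ols_cluster(
    df: pd.DataFrame,
    outcome: str,
    regressors: list[str],
    fe_dims: list,
    cluster: str,
):
    """Full dummy-variable OLS with CR1 clustered sandwich.

    Builds intercept + dummies (first level dropped per FE dimension) + the
    regressors, solves by least squares, and computes
    V = c (X'X)^-1 (sum_g s_g s_g') (X'X)^-1 with c = G/(G-1)*(N-1)/(N-K).
    Returns (params, se) for the regressors only.
    """
    n = len(df)
    blocks = [np.ones((n, 1))]
    for dim in fe_dims:
        if isinstance(dim, tuple):
            key = df[list(dim)].astype(str).agg("_".join, axis=1)
        else:
            key = df[dim]
        d = pd.get_dummies(key, drop_first=True, dtype=float)
        blocks.append(d.to_numpy())
    Xr = df[regressors].to_numpy(dtype=float)
    X = np.hstack(blocks + [Xr])
    y = df[outcome].to_numpy(dtype=float)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    ncol = X.shape[1]
    # the dummy design is rank-deficient when the FE level graph is
    # disconnected (one redundant intercept per extra component); the CR1
    # degrees of freedom count the rank, not the column count
    K = np.linalg.matrix_rank(X)
    codes, _ = pd.factorize(df[cluster])
    G = codes.max() + 1
    S = np.zeros((G, ncol))
    Xe = X * e[:, None]
    for j in range(ncol):
        S[:, j] = np.bincount(codes, weights=Xe[:, j], minlength=G)
    bread = np.linalg.pinv(X.T @ X)
    c = (G / (G - 1.0)) * ((n - 1.0) / (n - K))
    V = c * bread @ (S.T @ S) @ bread
    k = len(regressors)
    params = pd.Series(beta[-k:], index=regressors)
    se = pd.Series(np.sqrt(np.diag(V)[-k:]), index=regressors)
    return params, se


def scan_monthly_hours(hours: list[pd.Timestamp], k: int) -> dict[str, int]:
    """Brute-force qualifying-hour count per month under a k-epoch rule.

    Walks the sorted at-hospital hour list, accumulating runs of consecutive
    hours (splitting whenever the month changes) and summing the lengths of
    runs of length >= k.
    """
    out: dict[str, int] = {}
    run: list[pd.Timestamp] = []

    def flush():
        if len(run) >= k:
            m = run[0].strftime("%Y-%m")
            out[m] = out.get(m, 0) + len(run)

    for t in sorted(hours):
        if run and (t - run[-1] == pd.Timedelta(hours=1)) and t.month == run[-1].month and t.year == run[-1].year:
            run.append(t)
        else:
            flush()
            run = [t]
    flush()
    return out


def scan_monthly_days(hours: list[pd.Timestamp], k: int) -> dict[str, int]:
    """Distinct days touched by qualifying runs, per month (brute force)."""
    days: dict[str, set] = {}
    run: list[pd.Timestamp] = []

    def flush():
        if len(run) >= k:
            m = run[0].strftime("%Y-%m")
            days.setdefault(m, set()).update(t.date() for t in run)

    for t in sorted(hours):
        if run and (t - run[-1] == pd.Timedelta(hours=1)) and t.month == run[-1].month and t.year == run[-1].year:
            run.append(t)
        else:
            flush()
            run = [t]
    flush()
    return {m: len(s) for m, s in days.items()}
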