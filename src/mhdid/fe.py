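"""High-dimensional fixed-effects least squares with cluster-robust inference.

Fixed effects are absorbed by the within transformation: alternating
projections (Gauss-Seidel sweeps) repeatedly subtract cell means for each FE
dimension until every cell mean is numerically zero. This scales to hundreds
of thousands of users where explicit dummy matrices would not; a
dummy-variable OLS oracle in the test suite guards correctness.

Inference is the cluster-robust sandwich

    V = c * (X'X)^-1 (sum_g X_g' e_g e_g' X_g) (X'X)^-1,
    c = G/(G-1) * (N-1)/(N-K),

with the CR1 small-sample factor, where K counts the regressors plus the
absorbed fixed-effect levels (levels minus connected-component adjustments in
the two-way case, so K matches what explicit dummy-variable OLS would use).
Confidence intervals use normal critical values: with cluster counts in the
thousands the difference from t is immaterial.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.stats
import yaml

from .config import CohortWindow
from .errors import ConvergenceError, EstimationError
from .panel import event_time_dummies

FEDim = str | tuple[str, ...]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression.

    ``fe_dims`` entries are panel column names or tuples of column names; a
    tuple denotes the interaction of the named categoricals (e.g.
    ``("month_idx", "used")`` for month-by-subgroup fixed effects).
    """

    outcome: str
    regressors: tuple[str, ...]
    fe_dims: tuple[FEDim, ...]
    cluster: str = "user_id"
    demean_tol: float = 1e-8
    max_sweeps: int = 100
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.regressors)) != len(self.regressors):
            raise EstimationError("duplicate regressor names in spec")
        if not self.fe_dims:
            raise EstimationError("at least one fixed-effect dimension is required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regressors"] = list(self.regressors)
        d["fe_dims"] = [list(f) if isinstance(f, tuple) else f for f in self.fe_dims]
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d) -> "ModelSpec":
        d = dict(d)
        d["regressors"] = tuple(d["regressors"])
        d["fe_dims"] = tuple(tuple(f) if isinstance(f, list) else f for f in d["fe_dims"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, source) -> "ModelSpec":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls.from_dict(data)


@dataclass
class FitResult:
    """Coefficients, cluster-robust covariance and diagnostics of one fit."""

    params: pd.Series
    se: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    n_clusters: int
    r2: float
    r2_within: float
    sweeps: int
    final_delta: float
    df_absorbed: int
    label: str = ""

    @property
    def ci_low(self) -> pd.Series:
        return self.params - 1.96 * self.se

    @property
    def ci_high(self) -> pd.Series:
        return self.params + 1.96 * self.se

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2.0 * scipy.stats.norm.sf(np.abs(z)), index=self.params.index)

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient table: term, estimate, se, ci, p."""
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.se.to_numpy(),
                "ci_low": self.ci_low.to_numpy(),
                "ci_high": self.ci_high.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )

    def to_json(self, path=None) -> str:
        payload = {
            "label": self.label,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "r2": self.r2,
            "r2_within": self.r2_within,
            "sweeps": self.sweeps,
            "final_delta": self.final_delta,
            "df_absorbed": self.df_absorbed,
            "terms": self.to_frame().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def wald(self, terms: Sequence[str]) -> tuple[float, int, float]:
        """Wald statistic, df and p-value for H0: the named terms are all 0."""
        terms = list(terms)
        if not terms:
            raise EstimationError("no terms given for Wald test")
        b = self.params.loc[terms].to_numpy()
        V = self.vcov.loc[terms, terms].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        df = len(terms)
        return stat, df, float(scipy.stats.chi2.sf(stat, df))

    def summary(self) -> str:
        lines = [
            f"{self.label or 'fit'}: n_obs={self.n_obs}, n_clusters={self.n_clusters}, "
            f"R2={self.r2:.3f} (within {self.r2_within:.3f})",
            f"{'term':<18}{'estimate':>12}{'se':>10}{'ci_low':>10}{'ci_high':>10}{'p':>10}",
        ]
        for t in self.params.index:
            lines.append(
                f"{t:<18}{self.params[t]:>12.4f}{self.se[t]:>10.4f}"
                f"{self.ci_low[t]:>10.4f}{self.ci_high[t]:>10.4f}{self.pvalues[t]:>10.2g}"
            )
        return "\n".join(lines)


def _factorize_dim(panel: pd.DataFrame, dim: FEDim) -> np.ndarray:
    if isinstance(dim, tuple):
        codes = None
        for col in dim:
            c, uniq = pd.factorize(panel[col], sort=True)
            codes = c if codes is None else codes * len(uniq) + c
        codes, _ = pd.factorize(codes, sort=True)
        return codes.astype(np.int64)
    codes, _ = pd.factorize(panel[dim], sort=True)
    return codes.astype(np.int64)


def demean(
    panel: pd.DataFrame,
    columns: Sequence[str],
    fe_dims: Sequence[FEDim],
    tol: float = 1e-8,
    max_sweeps: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Within-transform *columns* with respect to the fixed-effect dimensions.

    Alternating projections: each sweep subtracts current cell means for every
    FE dimension in turn; convergence is declared when the largest absolute
    cell mean across all dimensions and columns falls below *tol*. A single
    dimension converges in one sweep (exact group demeaning).

    Returns the transformed columns and a diagnostics dict with ``sweeps``,
    ``final_delta`` and per-dimension level counts.
    """
    if not fe_dims:
        raise EstimationError("at least one fixed-effect dimension is required")
    X = np.ascontiguousarray(panel[list(columns)].to_numpy(dtype=np.float64))
    dims = []
    for dim in fe_dims:
        codes = _factorize_dim(panel, dim)
        counts = np.bincount(codes).astype(np.float64)
        dims.append((codes, counts))

    sweeps_used = 0
    delta = np.inf
    for sweep in range(1, max_sweeps + 1):
        for codes, counts in dims:
            for j in range(X.shape[1]):
                means = np.bincount(codes, weights=X[:, j]) / counts
                X[:, j] -= means[codes]
        delta = 0.0
        for codes, counts in dims:
            for j in range(X.shape[1]):
                means = np.bincount(codes, weights=X[:, j]) / counts
                m = float(np.max(np.abs(means)))
                if m > delta:
                    delta = m
        sweeps_used = sweep
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"demeaning did not converge in {max_sweeps} sweeps (last delta {delta:.3e})",
            sweeps=max_sweeps,
            max_delta=delta,
        )

    out = pd.DataFrame(X, columns=list(columns), index=panel.index)
    diag = {
        "sweeps": sweeps_used,
        "final_delta": delta,
        "levels": [int(c.size) for _, c in dims],
    }
    return out, diag


def _absorbed_df(panel: pd.DataFrame, fe_dims: Sequence[FEDim]) -> int:
    """Degrees of freedom absorbed by the FE dimensions.

    One dimension absorbs its level count; two dimensions absorb
    L1 + L2 - (number of connected components of the bipartite level graph);
    further dimensions add L_i - 1 each (the standard approximation).
    """
    dims = [_factorize_dim(panel, d) for d in fe_dims]
    levels = [int(d.max()) + 1 for d in dims]
    if len(dims) == 1:
        return levels[0]
    g = scipy.sparse.coo_matrix(
        (np.ones(len(dims[0])), (dims[0], dims[1])), shape=(levels[0], levels[1])
    )
    n_comp, _ = scipy.sparse.csgraph.connected_components(
        scipy.sparse.block_array([[None, g], [g.T, None]]), directed=False
    )
    df = levels[0] + levels[1] - n_comp
    for lv in levels[2:]:
        df += lv - 1
    return df


def fit(spec: ModelSpec, panel: pd.DataFrame) -> FitResult:
    """Estimate *spec* on *panel* by demeaned OLS with clustered sandwich SEs.

    Raises ``EstimationError`` on rank deficiency (naming the offending
    columns), on regressors fully absorbed by the fixed effects, or when
    fewer than two clusters are present.
    """
    cols = [spec.outcome, *spec.regressors]
    cluster_codes = _factorize_dim(panel, spec.cluster)
    n_clusters = int(cluster_codes.max()) + 1
    if n_clusters < 2:
        raise EstimationError("clustered inference needs at least 2 clusters")

    dm, diag = demean(panel, cols, spec.fe_dims, tol=spec.demean_tol, max_sweeps=spec.max_sweeps)
    y = dm[spec.outcome].to_numpy()
    X = dm[list(spec.regressors)].to_numpy()
    n, k = X.shape

    raw_norms = np.linalg.norm(panel[list(spec.regressors)].to_numpy(dtype=float), axis=0)
    dm_norms = np.linalg.norm(X, axis=0)
    absorbed = [
        spec.regressors[j]
        for j in range(k)
        if dm_norms[j] <= 1e-10 * max(1.0, raw_norms[j])
    ]
    if absorbed:
        raise EstimationError(
            f"regressors collinear with the fixed effects (absorbed to zero): {absorbed}"
        )

    # rank check via pivoted QR, naming the offending columns
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag_R = np.abs(np.diag(R))
    rank_tol = diag_R[0] * max(n, k) * np.finfo(float).eps if diag_R[0] > 0 else 0.0
    deficient = diag_R <= rank_tol
    if deficient.any():
        offending = [spec.regressors[piv[j]] for j in np.flatnonzero(deficient)]
        raise EstimationError(f"design matrix is rank deficient; offending columns: {offending}")

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    e = y - X @ beta

    # cluster scores S[g, j] = sum_{i in g} X_ij e_i
    S = np.empty((n_clusters, k))
    Xe = X * e[:, None]
    for j in range(k):
        S[:, j] = np.bincount(cluster_codes, weights=Xe[:, j], minlength=n_clusters)
    bread = np.linalg.inv(XtX)
    df_absorbed = _absorbed_df(panel, spec.fe_dims)
    k_eff = k + df_absorbed
    if n - k_eff <= 0:
        raise EstimationError("no residual degrees of freedom after absorbing fixed effects")
    c = (n_clusters / (n_clusters - 1.0)) * ((n - 1.0) / (n - k_eff))
    V = c * bread @ (S.T @ S) @ bread
    V = 0.5 * (V + V.T)

    ssr = float(e @ e)
    sst_within = float(y @ y)
    y_raw = panel[spec.outcome].to_numpy(dtype=float)
    sst_total = float(np.sum((y_raw - y_raw.mean()) ** 2))
    idx = pd.Index(spec.regressors, name="term")
    return FitResult(
        params=pd.Series(beta, index=idx),
        se=pd.Series(np.sqrt(np.diag(V)), index=idx),
        vcov=pd.DataFrame(V, index=idx, columns=idx),
        n_obs=n,
        n_clusters=n_clusters,
        r2=1.0 - ssr / sst_total if sst_total > 0 else np.nan,
        r2_within=1.0 - ssr / sst_within if sst_within > 0 else np.nan,
        sweeps=diag["sweeps"],
        final_delta=diag["final_delta"],
        df_absorbed=df_absorbed,
        label=spec.label,
    )


def ddd_terms(panel: pd.DataFrame, window: CohortWindow) -> pd.DataFrame:
    """Triple-interaction columns 1[event_time = r] * used for the DDD design.

    Requires both the used and the never-used subgroup to be nonempty (the
    never-used adopters are the within-cohort baseline the third difference
    needs). Returns the interaction columns named ``<event col>_x_used``.
    """
    used = panel["used"].to_numpy()
    if used.all() or not used.any():
        missing = "never-used" if used.all() else "used"
        raise EstimationError(f"DDD requires both subgroups; the {missing} subgroup is empty")
    ev = event_time_dummies(panel, window)
    out = pd.DataFrame(index=panel.index)
    for col in ev.columns:
        out[f"{col}_x_used"] = ev[col].to_numpy() * used
    out.attrs["event_terms"] = {
        f"{c}_x_used": r for c, r in ev.attrs["event_terms"].items()
    }
    return out
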