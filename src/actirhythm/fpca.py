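"""Functional PCA of 24-hour activity curves in a periodic Fourier basis.

A participant's rest-activity rhythm is summarised as 288 five-minute epoch
means over the 24-h day.  Each profile is smoothed by ordinary least squares
onto an orthonormal Fourier basis (constant + J sine/cosine harmonic pairs);
because the basis is orthonormal in L2[0, 24), PCA on the coefficient vectors
*is* functional PCA: the eigenvectors are eigenfunction coefficients, the
eigenvalues are the variances of the corresponding per-participant scores.

The model/results split follows the statsmodels convention:
``FunctionalPCA(coefficients, basis).fit(n_components=4)`` returns an
:class:`FPCAResults` carrying the mean curve, eigenfunctions, component
variances, scores, variance-explained fractions, scree diagnostics and
median-split group mean curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericalError

#: number of 5-minute epochs in one day
N_EPOCHS = 288

#: epoch width in hours (5 minutes)
EPOCH_HOURS = 24.0 / N_EPOCHS


def epoch_midpoints(period: float = 24.0, n_epochs: int = N_EPOCHS) -> np.ndarray:
    """Midpoint times (hours) of the 5-min epoch grid: t_j = (j + 0.5) * dt."""
    dt = period / n_epochs
    return (np.arange(n_epochs) + 0.5) * dt


@dataclass(frozen=True)
class FourierBasis:
    """Orthonormal Fourier basis on [0, T): 1/sqrt(T), sqrt(2/T) sin/cos pairs.

    Parameters
    ----------
    period : float
        Period T in hours (24 for a diurnal rhythm).
    n_harmonics : int
        Number J of sine/cosine harmonic pairs; the basis has K = 2J + 1
        functions.  The default of 9 harmonics resolves features down to
        roughly 24/9 ~ 2.7 h while smoothing epoch-level noise.
    """

    period: float = 24.0
    n_harmonics: int = 9

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ConfigurationError("basis period must be positive")
        if self.n_harmonics < 0:
            raise ConfigurationError("n_harmonics must be nonnegative")

    @property
    def n_basis(self) -> int:
        return 2 * self.n_harmonics + 1

    def design(self, t: np.ndarray) -> np.ndarray:
        """Evaluate all K basis functions at times ``t`` -> (len(t), K)."""
        t = np.asarray(t, dtype=float)
        T = self.period
        cols = [np.full_like(t, 1.0 / np.sqrt(T))]
        amp = np.sqrt(2.0 / T)
        for m in range(1, self.n_harmonics + 1):
            w = 2.0 * np.pi * m * t / T
            cols.append(amp * np.sin(w))
            cols.append(amp * np.cos(w))
        return np.column_stack(cols)

    def gram(self, n_points: int = N_EPOCHS) -> np.ndarray:
        """Quadrature Gram matrix on the epoch-midpoint grid (dt weight)."""
        t = epoch_midpoints(self.period, n_points)
        phi = self.design(t)
        return phi.T @ phi * (self.period / n_points)


@dataclass
class CurveFit:
    """One smoothed 24-h activity curve in basis-coefficient form."""

    participant_id: int
    stratum: str
    coefficients: np.ndarray
    fit_rmse: float


def fit_curve(
    epoch_means: np.ndarray,
    basis: FourierBasis,
    participant_id: int = 0,
    stratum: str = "overall",
) -> CurveFit:
    """Least-squares Fourier fit of one complete 288-epoch profile.

    Raises
    ------
    ValueError
        If the profile contains missing epochs (exclusions must be applied
        upstream) or the basis is larger than the grid.
    """
    y = np.asarray(epoch_means, dtype=float)
    if y.shape != (N_EPOCHS,):
        raise ValueError(f"expected a profile of {N_EPOCHS} epoch means, got shape {y.shape}")
    if np.isnan(y).any():
        raise ValueError(
            "profile has missing epochs; apply the exclusion cascade "
            "(prep.apply_exclusions) before curve fitting"
        )
    if basis.n_basis > N_EPOCHS:
        raise ConfigurationError("basis larger than the epoch grid (K > 288)")
    phi = basis.design(epoch_midpoints(basis.period))
    c, *_ = np.linalg.lstsq(phi, y, rcond=None)
    resid = y - phi @ c
    return CurveFit(participant_id, stratum, c, float(np.sqrt(np.mean(resid**2))))


def fit_curves(
    profiles: pd.DataFrame, basis: FourierBasis, stratum: str = "overall"
) -> pd.DataFrame:
    """Fit all rows of a wide (participants x 288) profile table at once.

    Returns a DataFrame of coefficient vectors indexed by participant id,
    with a ``fit_rmse`` column appended.
    """
    y = profiles.to_numpy(dtype=float)
    if y.shape[1] != N_EPOCHS:
        raise ValueError(f"profile table must have {N_EPOCHS} columns")
    bad = np.isnan(y).any(axis=1)
    if bad.any():
        ids = list(profiles.index[bad][:5])
        raise ValueError(
            f"{bad.sum()} profiles have missing epochs (e.g. {ids}); "
            "apply the exclusion cascade first"
        )
    phi = basis.design(epoch_midpoints(basis.period))
    coef, *_ = np.linalg.lstsq(phi, y.T, rcond=None)
    resid = y.T - phi @ coef
    rmse = np.sqrt(np.mean(resid**2, axis=0))
    out = pd.DataFrame(coef.T, index=profiles.index,
                       columns=[f"c{k}" for k in range(basis.n_basis)])
    out["fit_rmse"] = rmse
    out.attrs["stratum"] = stratum
    return out


def _coef_matrix(coefficients: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, pd.Index]:
    if isinstance(coefficients, pd.DataFrame):
        cols = [c for c in coefficients.columns if c != "fit_rmse"]
        return coefficients[cols].to_numpy(dtype=float), coefficients.index
    arr = np.asarray(coefficients, dtype=float)
    return arr, pd.RangeIndex(arr.shape[0])


class FunctionalPCA:
    """Functional PCA model for Fourier-coefficient curve representations.

    Parameters
    ----------
    coefficients : DataFrame or (n, K) array
        One row per participant; the output of :func:`fit_curves` (a possible
        ``fit_rmse`` column is ignored).
    basis : FourierBasis
        The basis the coefficients are expressed in.
    weights : array, optional
        Positive per-participant analytic weights (e.g. survey weights).
        ``None`` gives the unweighted decomposition; equal weights reproduce
        it exactly.
    """

    def __init__(
        self,
        coefficients: pd.DataFrame | np.ndarray,
        basis: FourierBasis,
        weights: np.ndarray | None = None,
    ):
        self.coef, self.ids = _coef_matrix(coefficients)
        if self.coef.shape[1] != basis.n_basis:
            raise ValueError(
                f"coefficient dimension {self.coef.shape[1]} does not match "
                f"basis size {basis.n_basis}"
            )
        self.basis = basis
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != (self.coef.shape[0],):
                raise ValueError("weights must be one per participant")
            if (weights <= 0).any():
                raise ValueError("weights must be positive")
        self.weights = weights

    def fit(self, n_components: int = 4) -> "FPCAResults":
        """Eigendecompose the (weighted) coefficient covariance.

        The covariance uses divisor n - 1 (unweighted) or the analytic-weight
        analogue sum(w) - sum(w^2)/sum(w).  Eigenfunction signs follow a fixed
        convention: the coefficient of largest absolute value is positive.
        """
        n, K = self.coef.shape
        if n < 2:
            raise NumericalError("functional PCA needs at least 2 curves")
        if not 1 <= n_components <= K:
            raise ConfigurationError(f"n_components must be in [1, {K}]")
        w = self.weights
        if w is None:
            mu = self.coef.mean(axis=0)
            C = self.coef - mu
            S = C.T @ C / (n - 1)
        else:
            sw = w.sum()
            mu = w @ self.coef / sw
            C = self.coef - mu
            denom = sw - (w**2).sum() / sw
            S = (C * w[:, None]).T @ C / denom
        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals)[::-1]
        evals = np.maximum(evals[order], 0.0)
        evecs = evecs[:, order]
        # deterministic sign: largest-|coefficient| entry of each eigenvector > 0
        for m in range(K):
            j = int(np.argmax(np.abs(evecs[:, m])))
            if evecs[j, m] < 0:
                evecs[:, m] = -evecs[:, m]
        return FPCAResults(self, mu, evals, evecs, n_components)


@dataclass
class FPCAResults:
    """Fitted functional PCA: mean curve, eigenfunctions, variances, scores."""

    model: FunctionalPCA
    mean_coefficients: np.ndarray
    eigenvalues: np.ndarray          # all K, non-increasing
    eigenvectors: np.ndarray         # K x K, columns sign-fixed
    n_components: int
    _scores: pd.DataFrame | None = field(default=None, repr=False)

    # -- basic quantities -------------------------------------------------
    @property
    def basis(self) -> FourierBasis:
        return self.model.basis

    @property
    def component_variances(self) -> np.ndarray:
        """Variances lambda_m of the retained components."""
        return self.eigenvalues[: self.n_components]

    @property
    def total_variance(self) -> float:
        """Trace of the coefficient covariance (total functional variance)."""
        return float(self.eigenvalues.sum())

    @property
    def eigen_coefficients(self) -> np.ndarray:
        """K x M matrix of retained eigenfunction coefficients."""
        return self.eigenvectors[:, : self.n_components]

    @property
    def variance_fractions(self) -> np.ndarray:
        """lambda_m / total variance for the retained components."""
        return self.component_variances / self.total_variance

    # -- curves on the grid ----------------------------------------------
    def mean_curve(self, t: np.ndarray | None = None) -> np.ndarray:
        if t is None:
            t = epoch_midpoints(self.basis.period)
        return self.basis.design(t) @ self.mean_coefficients

    def eigenfunctions(self, t: np.ndarray | None = None) -> np.ndarray:
        """Retained eigenfunctions tabulated at ``t`` -> (M, len(t))."""
        if t is None:
            t = epoch_midpoints(self.basis.period)
        return (self.basis.design(t) @ self.eigen_coefficients).T

    # -- scores -----------------------------------------------------------
    def scores(
        self, coefficients: pd.DataFrame | np.ndarray | None = None
    ) -> pd.DataFrame:
        """Per-participant component scores s_im = (c_i - mu)' b_m.

        Raw scores carry the curve's units; ``std_score_*`` columns divide by
        sqrt(lambda_m) so one unit is one score standard deviation.
        """
        if coefficients is None:
            coef, ids = self.model.coef, self.model.ids
        else:
            coef, ids = _coef_matrix(coefficients)
        if coef.shape[1] != self.basis.n_basis:
            raise ValueError("coefficient basis does not match the fitted model")
        s = (coef - self.mean_coefficients) @ self.eigen_coefficients
        lam = self.component_variances
        cols = {f"score_{m + 1}": s[:, m] for m in range(self.n_components)}
        for m in range(self.n_components):
            sd = np.sqrt(lam[m]) if lam[m] > 0 else np.nan
            cols[f"std_score_{m + 1}"] = s[:, m] / sd
        out = pd.DataFrame(cols, index=pd.Index(ids, name="participant_id"))
        if coefficients is None:
            self._scores = out
        return out

    # -- diagnostics ------------------------------------------------------
    def variance_explained(self) -> pd.DataFrame:
        """Percent of total variance per retained component, with cumulative."""
        pct = 100.0 * self.variance_fractions
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "variance": self.component_variances,
                "pct_variance": pct,
                "cum_pct_variance": np.cumsum(pct),
            }
        )

    def scree(self) -> tuple[np.ndarray, int]:
        """Full eigenvalue sequence and an elbow suggestion.

        The suggestion is the position of the largest drop in successive
        eigenvalue ratios lambda_m / lambda_{m+1}, restricted to eigenvalues
        above numerical noise.  It is a diagnostic only; pipelines keep their
        configured component count.
        """
        lam = self.eigenvalues
        tiny = max(lam[0], 1.0) * 1e-12
        usable = lam > tiny
        k = int(usable.sum())
        if k < 2:
            return lam, 1
        ratios = lam[: k - 1] / lam[1:k]
        return lam, int(np.argmax(ratios)) + 1

    def group_mean_curves(
        self, component: int, coefficients: pd.DataFrame | np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Mean smoothed curves for the high and low halves of one score.

        Splits at the sample median of the component's scores; ties at the
        median fall in the low group.  Returns (high, low) on the epoch grid.
        """
        if not 1 <= component <= self.n_components:
            raise ValueError(f"component must be in [1, {self.n_components}]")
        if coefficients is None:
            coef = self.model.coef
        else:
            coef, _ = _coef_matrix(coefficients)
        if coef.shape[0] < 2:
            raise ValueError("median split needs at least 2 curves")
        s = (coef - self.mean_coefficients) @ self.eigen_coefficients[:, component - 1]
        med = np.median(s)
        high = s > med
        phi = self.basis.design(epoch_midpoints(self.basis.period))
        if not high.any():          # all scores tied at the median
            mean_all = phi @ coef.mean(axis=0)
            return mean_all, mean_all
        return phi @ coef[high].mean(axis=0), phi @ coef[~high].mean(axis=0)

    def summary(self) -> str:
        lam, suggested = self.scree()
        lines = [
            "Functional PCA of 24-h activity curves",
            "=" * 46,
            f"curves: {self.model.coef.shape[0]}   basis: Fourier, "
            f"{self.basis.n_harmonics} harmonics (K={self.basis.n_basis})",
            f"weights: {'analytic' if self.model.weights is not None else 'none'}",
            f"retained components: {self.n_components} (scree suggests {suggested})",
            "",
            f"{'comp':>4} {'variance':>12} {'% var':>8} {'cum %':>8}",
        ]
        cum = 0.0
        for m in range(self.n_components):
            pct = 100.0 * self.eigenvalues[m] / self.total_variance
            cum += pct
            lines.append(f"{m + 1:>4} {self.eigenvalues[m]:>12.5g} {pct:>8.2f} {cum:>8.2f}")
        lines.append(f"total functional variance: {self.total_variance:.6g}")
        return "\n".join(lines)
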