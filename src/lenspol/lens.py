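"""Group-specific opinion lenses and the subjective distance they induce.

A *lens* is a group's subjective re-representation of the opinion space. Its
basis vectors are the principal axes of the in-group opinion covariance
:math:`\\Sigma`, each scaled by the square root of its eigenvalue
(:math:`\\sqrt{\\lambda_k}\\,v_k`). Mapping opinions into lens coordinates and
taking Euclidean distance there yields the Mahalanobis distance

.. math::

    d(x_i, x_j \\mid L)^2 = (x_i - x_j)^\\top \\Sigma^{-1} (x_i - x_j),

so a homogeneous (low-variance) group perceives a given objective difference
as large, and in one dimension the perceived distance is simply
:math:`|\\Delta| / \\sigma` — the difference normalized by the in-group
standard deviation.

Degenerate (rank-deficient) covariances are handled by a ridge
:math:`\\Sigma + \\epsilon\\,(\\mathrm{tr}\\,\\Sigma / m)\\,I`; a perfectly
unanimous group then perceives very large but finite distances (if
:math:`\\mathrm{tr}\\,\\Sigma = 0` the ridge scale falls back to
:math:`\\epsilon I`).

:class:`LensModel` is the scikit-learn-style estimator (``fit`` on in-group
opinions, ``transform`` into lens coordinates); :func:`build_lens`,
:func:`build_lens_set` and :func:`subjective_distance` are the functional
surface over it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .opinion_model import NONPARTISAN_LABEL, OpinionWave

logger = logging.getLogger(__name__)

__all__ = [
    "Lens",
    "LensModel",
    "LensSet",
    "build_lens",
    "build_lens_set",
    "subjective_distance",
    "weighted_group_covariance",
]

_SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class Lens:
    """A fitted lens: scaled principal-axis basis and its induced metric.

    ``basis`` columns are sqrt(eigenvalue) * eigenvector of the *raw*
    covariance (eigenvalues nonincreasing); ``metric`` is the inverse of the
    ridge-regularized covariance, so
    ``metric @ (basis @ basis.T + regularization_applied * I) == I``.
    """

    group_label: str
    fitted_on_wave: str
    basis: np.ndarray
    metric: np.ndarray
    eigenvalues: np.ndarray
    regularization_applied: float = 0.0

    @property
    def m(self) -> int:
        return self.metric.shape[0]

    def whitener(self) -> np.ndarray:
        """Matrix ``A`` with ``A @ A.T == metric``; Euclidean distance of
        ``x @ A`` equals the subjective distance."""
        return np.linalg.cholesky(self.metric)

    def to_dict(self) -> dict:
        return {
            "group_label": self.group_label,
            "fitted_on_wave": self.fitted_on_wave,
            "basis": self.basis.tolist(),
            "metric": self.metric.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "regularization_applied": float(self.regularization_applied),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Lens":
        return cls(
            group_label=d["group_label"],
            fitted_on_wave=d["fitted_on_wave"],
            basis=np.asarray(d["basis"], dtype=float),
            metric=np.asarray(d["metric"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            regularization_applied=float(d["regularization_applied"]),
        )


def weighted_group_covariance(
    wave: OpinionWave, group_label: str, min_members: int = 2
) -> np.ndarray:
    """Weighted unbiased covariance of one group's opinions.

    Weights are normalized to sum to the in-group count ``n_g`` (frequency
    weight convention) and the denominator is ``n_g - 1``, so the estimator
    is invariant to rescaling all weights and reduces to the ordinary
    unbiased sample covariance under equal weights. For the nonpartisan
    label ``"None"`` the in-group is the entire sample.
    """
    if group_label == NONPARTISAN_LABEL:
        mask = np.ones(wave.n, dtype=bool)
    else:
        mask = wave.group_mask(group_label)
    n_g = int(mask.sum())
    if n_g < min_members:
        raise ValueError(
            f"group {group_label!r} has {n_g} member(s) in wave "
            f"{wave.wave_label!r}; at least {min_members} required for a covariance"
        )
    x = wave.opinions[mask]
    w = wave.weights[mask]
    w = w * (n_g / w.sum())
    mu = (w[:, None] * x).sum(axis=0) / n_g
    xc = x - mu
    cov = (w[:, None] * xc).T @ xc / (n_g - 1)
    return (cov + cov.T) / 2.0


def build_lens(
    covariance: np.ndarray,
    group_label: str,
    ridge_epsilon: float = 1e-6,
    fitted_on_wave: str = "",
) -> Lens:
    """Eigendecompose an in-group covariance into a :class:`Lens`.

    The metric is the inverse of ``covariance + reg * I`` with
    ``reg = ridge_epsilon * mean(diag)`` (or ``ridge_epsilon`` itself for an
    all-zero covariance); the basis columns are the raw covariance's
    eigenvectors scaled by the square roots of their eigenvalues, sorted by
    nonincreasing eigenvalue.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    asym = np.max(np.abs(cov - cov.T)) if cov.size else 0.0
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"covariance not symmetric (max asymmetry {asym:.3g})")
    cov = (cov + cov.T) / 2.0
    m = cov.shape[0]
    if ridge_epsilon < 0:
        raise ValueError("ridge_epsilon must be nonnegative")
    trace = float(np.trace(cov))
    scale = trace / m if trace > 0 else 1.0
    reg = float(ridge_epsilon) * scale

    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -_SYMMETRY_TOL * max(1.0, abs(evals).max()):
        raise ValueError("covariance is not positive semidefinite")
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]  # nonincreasing
    evals, evecs = evals[order], evecs[:, order]

    reg_evals = evals + reg
    if reg_evals.min() <= 0.0:
        raise ValueError(
            f"singular lens for group {group_label!r}: zero variance along "
            "a principal axis and no ridge regularization"
        )
    basis = evecs * np.sqrt(evals)[None, :]
    metric = (evecs / reg_evals[None, :]) @ evecs.T
    metric = (metric + metric.T) / 2.0
    return Lens(
        group_label=group_label,
        fitted_on_wave=fitted_on_wave,
        basis=basis,
        metric=metric,
        eigenvalues=evals,
        regularization_applied=reg,
    )


def subjective_distance(x_i, x_j, lens: Lens) -> float:
    """Distance between two opinion vectors as perceived through ``lens``.

    ``sqrt((x_i - x_j)^T metric (x_i - x_j))``; symmetric in its two vector
    arguments, zero iff they coincide (positive-definite metric), but
    generally different across lenses.
    """
    xi = np.asarray(x_i, dtype=float).ravel()
    xj = np.asarray(x_j, dtype=float).ravel()
    if xi.shape[0] != lens.m or xj.shape[0] != lens.m:
        raise ValueError(
            f"dimension mismatch: vectors of length {xi.shape[0]}/{xj.shape[0]} "
            f"vs lens of dimension {lens.m}"
        )
    delta = xi - xj
    return float(np.sqrt(delta @ lens.metric @ delta))


class LensModel(TransformerMixin, BaseEstimator):
    """Fit a group lens to in-group opinions, scikit-learn style.

    Parameters
    ----------
    ridge_epsilon : float, default 1e-6
        Relative ridge added to the covariance before inversion.
    group_label : str, default "None"
        Identity label attached to the fitted lens.

    Attributes
    ----------
    covariance_ : ndarray of shape (m, m)
        Weighted unbiased in-group covariance.
    lens_ : Lens
        The fitted lens value object.
    basis_, metric_, eigenvalues_ : ndarray
        Convenience views of ``lens_``.
    """

    def __init__(self, ridge_epsilon: float = 1e-6, group_label: str = NONPARTISAN_LABEL):
        self.ridge_epsilon = ridge_epsilon
        self.group_label = group_label

    def fit(self, X, y=None, sample_weight=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, m = X.shape
        if n < 2:
            raise ValueError("at least two samples are required to fit a lens")
        if sample_weight is None:
            sample_weight = np.ones(n)
        wave = OpinionWave(
            wave_label="<fit>",
            opinions=X,
            identities=[self.group_label] * n,
            weights=np.asarray(sample_weight, dtype=float),
            item_names=[f"x{j}" for j in range(m)],
        )
        self.covariance_ = weighted_group_covariance(wave, self.group_label)
        self.lens_ = build_lens(self.covariance_, self.group_label, self.ridge_epsilon)
        self.basis_ = self.lens_.basis
        self.metric_ = self.lens_.metric
        self.eigenvalues_ = self.lens_.eigenvalues
        self.n_features_in_ = m
        return self

    def transform(self, X):
        """Map opinions into subjective (lens) coordinates ``x' = L^{-1} x``.

        Euclidean distances between transformed points equal the subjective
        distances between the originals.
        """
        check_is_fitted(self, "lens_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("dimension mismatch in transform")
        return X @ self.lens_.whitener()

    def pairwise_distance(self, X, Y=None):
        """Subjective distances between rows of ``X`` and rows of ``Y``."""
        check_is_fitted(self, "lens_")
        from scipy.spatial.distance import cdist

        A = self.lens_.whitener()
        X = np.atleast_2d(np.asarray(X, dtype=float)) @ A
        Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float)) @ A
        return cdist(X, Y)


@dataclass
class LensSet:
    """All lenses of one wave: mapping group label -> :class:`Lens`.

    Always contains the ``"None"`` (nonpartisan/population) lens. Groups that
    were too small to carry their own covariance fall back to the population
    lens; ``fallbacks`` records them. Lookups of labels absent from the set
    (e.g. a group present only in a later wave) also fall back to the
    population lens.
    """

    fitted_on_wave: str
    lenses: dict[str, Lens]
    fallbacks: list[str] = field(default_factory=list)

    def lens_for(self, group_label: str) -> Lens:
        lens = self.lenses.get(group_label)
        if lens is None:
            logger.info(
                "group %r has no lens fitted on wave %r; using the population lens",
                group_label,
                self.fitted_on_wave,
            )
            return self.lenses[NONPARTISAN_LABEL]
        return lens

    def groups(self) -> list[str]:
        return list(self.lenses)

    @property
    def m(self) -> int:
        return self.lenses[NONPARTISAN_LABEL].m

    def __eq__(self, other) -> bool:
        if not isinstance(other, LensSet):
            return NotImplemented
        if self.fitted_on_wave != other.fitted_on_wave:
            return False
        if set(self.lenses) != set(other.lenses):
            return False
        return all(
            np.array_equal(self.lenses[g].metric, other.lenses[g].metric)
            for g in self.lenses
        )

    def to_dict(self) -> dict:
        return {
            "fitted_on_wave": self.fitted_on_wave,
            "fallbacks": list(self.fallbacks),
            "lenses": {g: lens.to_dict() for g, lens in self.lenses.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LensSet":
        return cls(
            fitted_on_wave=d["fitted_on_wave"],
            lenses={g: Lens.from_dict(ld) for g, ld in d["lenses"].items()},
            fallbacks=list(d.get("fallbacks", [])),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LensSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_lens_set(
    wave: OpinionWave, ridge_epsilon: float = 1e-6, min_group_size: int = 3
) -> LensSet:
    """Fit one lens per identity group of ``wave`` (plus the population lens).

    The ``"None"`` lens is fitted on the full sample — the nonpartisan
    convention that unaffiliated respondents treat everyone as in-group.
    Groups with fewer than ``min_group_size`` members receive the population
    lens instead (recorded in ``fallbacks`` and logged).
    """
    pop_cov = weighted_group_covariance(wave, NONPARTISAN_LABEL)
    pop_lens = build_lens(pop_cov, NONPARTISAN_LABEL, ridge_epsilon, wave.wave_label)
    lenses = {NONPARTISAN_LABEL: pop_lens}
    fallbacks: list[str] = []
    for g in wave.groups():
        if g == NONPARTISAN_LABEL:
            continue
        n_g = int(wave.group_mask(g).sum())
        if n_g < min_group_size:
            logger.info(
                "group %r has %d member(s) (< %d) in wave %r; falling back to "
                "the population lens",
                g, n_g, min_group_size, wave.wave_label,
            )
            lenses[g] = Lens(
                group_label=g,
                fitted_on_wave=wave.wave_label,
                basis=pop_lens.basis,
                metric=pop_lens.metric,
                eigenvalues=pop_lens.eigenvalues,
                regularization_applied=pop_lens.regularization_applied,
            )
            fallbacks.append(g)
            continue
        cov = weighted_group_covariance(wave, g, min_members=min_group_size)
        lenses[g] = build_lens(cov, g, ridge_epsilon, wave.wave_label)
    return LensSet(fitted_on_wave=wave.wave_label, lenses=lenses, fallbacks=fallbacks)
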