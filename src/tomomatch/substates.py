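"""Conformer assignment from paired template-matching scores.

Running two templates of the same complex in different conformations — for
the 80S ribosome, the rotated and unrotated ratcheting states of the small
subunit — over the same tomogram yields two scores per particle. The ratio

    x_i = cc_i_rot / cc_i_unrot

is modeled as a two-component Gaussian mixture

    p(x) = pi_rot N(x | mu_rot, sigma_rot^2)
           + (1 - pi_rot) N(x | mu_unrot, sigma_unrot^2)

fitted by expectation-maximization; each particle is assigned the state with
the larger posterior. By convention the component with the larger mean is the
"rotated" state (the rotated template scores relatively higher there).

The EM is implemented in closed form for the 1D two-component case so the
log-likelihood path of every iteration is available (it is non-decreasing by
construction). ``ScoreRatioGMM`` is a scikit-learn-style estimator
(get_params/set_params, fit/predict/predict_proba, trailing-underscore fitted
attributes) and composes with sklearn model selection; :func:`fit_gmm` is the
functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DegenerateFitError, DomainError

__all__ = [
    "ScoreRatioSet",
    "GMMFit",
    "ScoreRatioGMM",
    "score_ratio",
    "fit_gmm",
    "assign_states",
    "pair_particle_lists",
]

_SIGMA_COLLAPSE = 1e-8


def score_ratio(cc_rot, cc_unrot):
    """Elementwise score ratio x = cc_rot / cc_unrot (cc_unrot must be > 0)."""
    rot = np.asarray(cc_rot, dtype=float)
    unrot = np.asarray(cc_unrot, dtype=float)
    if np.any(unrot <= 0):
        raise DomainError("cc_unrot must be > 0 for a meaningful ratio")
    out = rot / unrot
    return float(out) if out.ndim == 0 else out


@dataclass
class ScoreRatioSet:
    """Paired scores and their ratios for a set of particles."""

    x: np.ndarray
    particle_ids: np.ndarray | None = None
    cc_rot: np.ndarray | None = None
    cc_unrot: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).ravel()
        if not np.all(np.isfinite(self.x)) or np.any(self.x <= 0):
            raise DomainError("ratios must be finite and > 0")
        if self.particle_ids is None:
            self.particle_ids = np.arange(len(self.x))
        else:
            self.particle_ids = np.asarray(self.particle_ids)

    @classmethod
    def from_scores(cls, cc_rot, cc_unrot, particle_ids=None):
        rot = np.asarray(cc_rot, dtype=float)
        unrot = np.asarray(cc_unrot, dtype=float)
        return cls(score_ratio(rot, unrot), particle_ids, rot, unrot)

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class GMMFit:
    """Fitted two-component mixture over score ratios."""

    pi_rot: float
    mu_rot: float
    sigma_rot: float
    mu_unrot: float
    sigma_unrot: float
    responsibilities: np.ndarray  # posterior of "rotated" per particle
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool

    def __post_init__(self):
        if not 0 <= self.pi_rot <= 1:
            raise DomainError("pi_rot outside [0, 1]")
        if self.sigma_rot <= 0 or self.sigma_unrot <= 0:
            raise DomainError("component sigmas must be > 0")


def _log_gauss(x, mu, sigma):
    return -0.5 * np.log(2 * np.pi * sigma**2) - (x - mu) ** 2 / (2 * sigma**2)


class ScoreRatioGMM(BaseEstimator):
    """Two-component 1D Gaussian mixture fitted by EM.

    Parameters
    ----------
    tol : float
        Relative log-likelihood change for convergence.
    max_iter : int
        Iteration cap per EM run.
    n_restarts : int
        Random restarts around the deterministic percentile initialization
        (means at the 25th/75th percentiles, equal weights, pooled std); the
        best log-likelihood wins. ``random_state`` only seeds the restarts.
    larger_mean_label : str
        Name given to the component with the larger mean ("rotated").

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, sigmas_ : component parameters, index 0 = larger-mean
        ("rotated") component.
    responsibilities_ : posterior of the rotated component per sample.
    loglik_, loglik_path_, n_iter_, converged_ : EM diagnostics.
    """

    def __init__(
        self,
        tol: float = 1e-6,
        max_iter: int = 500,
        n_restarts: int = 5,
        random_state: int = 0,
        larger_mean_label: str = "rotated",
        other_label: str = "unrotated",
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.larger_mean_label = larger_mean_label
        self.other_label = other_label

    # -- EM core ----------------------------------------------------------

    def _em_run(self, x, pi, mu, sigma):
        """Run EM from one starting point; returns (params, loglik_path)."""
        n = len(x)
        path = []
        prev = -np.inf
        converged = False
        for it in range(self.max_iter):
            # E-step: posteriors under current parameters
            log_p = np.stack(
                [
                    np.log(max(pi[0], 1e-300)) + _log_gauss(x, mu[0], sigma[0]),
                    np.log(max(pi[1], 1e-300)) + _log_gauss(x, mu[1], sigma[1]),
                ]
            )
            m = log_p.max(axis=0)
            log_norm = m + np.log(np.exp(log_p - m).sum(axis=0))
            loglik = float(log_norm.sum())
            path.append(loglik)
            resp = np.exp(log_p - log_norm)

            if it > 0 and abs(loglik - prev) <= self.tol * abs(prev):
                converged = True
                break
            prev = loglik

            # M-step: closed-form updates
            nk = resp.sum(axis=1)
            if np.any(nk < 1e-12):
                raise DegenerateFitError(
                    "a component lost all responsibility; the ratios may be "
                    "unimodal — consider a single-population model"
                )
            pi = nk / n
            mu = (resp * x).sum(axis=1) / nk
            var = (resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk
            sigma = np.sqrt(var)
            if np.any(sigma < _SIGMA_COLLAPSE):
                raise DegenerateFitError(
                    "component variance collapsed (< 1e-8); the data may "
                    "contain duplicated values or too few particles"
                )
        return (pi, mu, sigma, resp), np.array(path), converged, len(path)

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if len(x) < 4:
            raise DomainError("need at least 4 ratios to fit the mixture")
        if not np.all(np.isfinite(x)):
            raise DomainError("ratios must be finite")
        if np.ptp(x) < _SIGMA_COLLAPSE:
            raise DegenerateFitError("all ratios identical: fit degenerate")

        q25, q75 = np.percentile(x, [25, 75])
        pooled = float(x.std())
        starts = [(np.array([0.5, 0.5]), np.array([q75, q25]),
                   np.array([pooled, pooled]))]
        rng = np.random.default_rng(self.random_state)
        for _ in range(max(self.n_restarts - 1, 0)):
            jitter = rng.normal(scale=0.5 * pooled, size=2)
            starts.append(
                (np.array([0.5, 0.5]),
                 np.array([q75, q25]) + jitter,
                 np.array([pooled, pooled]))
            )

        best = None
        first_err: DegenerateFitError | None = None
        for pi0, mu0, s0 in starts:
            try:
                params, path, conv, n_it = self._em_run(x, pi0, mu0, s0)
            except DegenerateFitError as exc:
                first_err = first_err or exc
                continue
            if best is None or path[-1] > best[1][-1]:
                best = (params, path, conv, n_it)
        if best is None:
            raise first_err or DegenerateFitError("all EM restarts degenerated")

        (pi, mu, sigma, resp), path, conv, n_it = best
        # index 0 = larger-mean component ("rotated")
        order = np.argsort(-mu)
        self.weights_ = pi[order]
        self.means_ = mu[order]
        self.sigmas_ = sigma[order]
        self.responsibilities_ = resp[order][0]
        self.loglik_ = float(path[-1])
        self.loglik_path_ = path
        self.converged_ = conv
        self.n_iter_ = n_it
        return self

    # -- inference --------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) posteriors; column 0 = rotated (larger-mean) component."""
        x = np.asarray(X, dtype=float).ravel()
        log_p = np.stack(
            [
                np.log(self.weights_[k]) + _log_gauss(
                    x, self.means_[k], self.sigmas_[k])
                for k in (0, 1)
            ]
        )
        m = log_p.max(axis=0)
        log_norm = m + np.log(np.exp(log_p - m).sum(axis=0))
        return np.exp(log_p - log_norm).T

    def predict(self, X) -> np.ndarray:
        """0 for the rotated (larger-mean) component, 1 for the other."""
        return (self.predict_proba(X)[:, 0] < 0.5).astype(int)

    def score(self, X, y=None) -> float:
        """Mean per-sample log-likelihood."""
        x = np.asarray(X, dtype=float).ravel()
        log_p = np.stack(
            [
                np.log(self.weights_[k]) + _log_gauss(
                    x, self.means_[k], self.sigmas_[k])
                for k in (0, 1)
            ]
        )
        m = log_p.max(axis=0)
        return float((m + np.log(np.exp(log_p - m).sum(axis=0))).mean())

    def to_fit(self) -> GMMFit:
        return GMMFit(
            pi_rot=float(self.weights_[0]),
            mu_rot=float(self.means_[0]),
            sigma_rot=float(self.sigmas_[0]),
            mu_unrot=float(self.means_[1]),
            sigma_unrot=float(self.sigmas_[1]),
            responsibilities=self.responsibilities_,
            loglik=self.loglik_,
            loglik_path=self.loglik_path_,
            n_iter=self.n_iter_,
            converged=self.converged_,
        )


def fit_gmm(
    x: ScoreRatioSet | np.ndarray,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
) -> GMMFit:
    """Fit the two-component mixture to score ratios (see ScoreRatioGMM)."""
    data = x.x if isinstance(x, ScoreRatioSet) else np.asarray(x, dtype=float)
    est = ScoreRatioGMM(
        tol=tol, max_iter=max_iter, n_restarts=n_restarts, random_state=seed
    ).fit(data)
    return est.to_fit()


def pair_particle_lists(
    rot_list, unrot_list, max_dist: float, score_column: str = "zscore"
) -> ScoreRatioSet:
    """Pair peaks from two template-matching runs of the same tomogram.

    Each particle from the rotated-template run is matched to the nearest
    particle of the unrotated-template run within ``max_dist`` voxels
    (one-to-one, greedy by distance — typically half a template diameter);
    the score ratio is taken over ``score_column``.
    """
    if not max_dist > 0:
        raise DomainError("max_dist must be > 0")
    a, b = rot_list.entries, unrot_list.entries
    for df, name in ((a, "rotated"), (b, "unrotated")):
        if score_column not in df.columns:
            raise DomainError(
                f"{name} particle list lacks the {score_column!r} column"
            )
    if len(a) == 0 or len(b) == 0:
        raise DomainError("empty particle list; nothing to pair")
    pa = a[["x", "y", "z"]].to_numpy(float)
    pb = b[["x", "y", "z"]].to_numpy(float)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    pairs = np.argwhere(d <= max_dist)
    order = np.lexsort((pairs[:, 1], pairs[:, 0], d[tuple(pairs.T)]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for i, j in pairs[order]:
        if i in used_a or j in used_b:
            continue
        used_a.add(int(i))
        used_b.add(int(j))
        rows.append((int(i), float(a[score_column].iloc[i]),
                     float(b[score_column].iloc[j])))
    if not rows:
        raise DomainError(f"no peak pairs within {max_dist} voxels")
    ids, cc_rot, cc_unrot = map(np.asarray, zip(*rows))
    return ScoreRatioSet.from_scores(cc_rot, cc_unrot, particle_ids=ids)


def assign_states(fit: GMMFit, x) -> pd.DataFrame:
    """Assign each ratio to a state by its larger posterior.

    Returns a DataFrame with columns x, label ("rotated"/"unrotated", or
    "unassigned" at exact posterior ties of 0.5) and posterior_rotated.
    """
    data = x.x if isinstance(x, ScoreRatioSet) else np.asarray(x, dtype=float)
    data = data.ravel()
    lp_rot = np.log(max(fit.pi_rot, 1e-300)) + _log_gauss(
        data, fit.mu_rot, fit.sigma_rot
    )
    lp_unrot = np.log(max(1 - fit.pi_rot, 1e-300)) + _log_gauss(
        data, fit.mu_unrot, fit.sigma_unrot
    )
    m = np.maximum(lp_rot, lp_unrot)
    post_rot = np.exp(lp_rot - m) / (
        np.exp(lp_rot - m) + np.exp(lp_unrot - m)
    )
    label = np.where(post_rot > 0.5, "rotated", "unrotated")
    label = np.where(np.isclose(post_rot, 0.5, atol=1e-12), "unassigned",
                     label)
    return pd.DataFrame(
        {"x": data, "label": label, "posterior_rotated": post_rot}
    )
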