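"""Signature extraction by non-negative matrix factorization with restarts.

The catalog transpose V (96 x N counts) is factorized as V ~ W H with
W >= 0 the 96 x K signature profiles and H >= 0 the K x N exposures
(attributed mutation counts).  The objective is the generalized
Kullback-Leibler divergence, the natural fit for Poisson-like count data;
a Frobenius option is kept behind a flag.  Multiple random restarts guard
against local minima, and a simple rank-selection scan reports per-K
reconstruction error and restart stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF

from ._classes import CLASS_LABELS
from .catalog import MutationCatalog

_EPS = np.finfo(float).eps


@dataclass
class SignatureSet:
    """96 x K column-stochastic signature profiles with provisional names."""

    profiles: np.ndarray
    signature_ids: list[str]
    class_labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape[0] != len(self.class_labels):
            raise ValueError("profiles must have one row per substitution class")
        if (self.profiles < 0).any():
            raise ValueError("profiles must be non-negative")
        colsums = self.profiles.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("each signature profile must sum to 1")

    @property
    def rank(self) -> int:
        return self.profiles.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles, index=list(self.class_labels), columns=self.signature_ids
        )


@dataclass
class ExposureMatrix:
    """K x N attributed mutation counts plus per-sample fractions."""

    activities: np.ndarray
    signature_ids: list[str]
    sample_ids: list[str]
    relative: np.ndarray = field(init=False)
    zero_samples: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        if (self.activities < -1e-12).any():
            raise ValueError("activities must be non-negative")
        self.activities = np.clip(self.activities, 0.0, None)
        totals = self.activities.sum(axis=0)
        rel = np.zeros_like(self.activities)
        nz = totals > 0
        rel[:, nz] = self.activities[:, nz] / totals[nz]
        self.relative = rel
        self.zero_samples = [s for s, ok in zip(self.sample_ids, nz) if not ok]

    def to_frame(self, relative: bool = False) -> pd.DataFrame:
        data = self.relative if relative else self.activities
        return pd.DataFrame(data, index=self.signature_ids, columns=self.sample_ids)


@dataclass
class FactorizationResult:
    signatures: SignatureSet
    exposures: ExposureMatrix
    rank: int
    reconstruction_error: float
    restarts_used: int
    seed: int
    objective: str = "kl"


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) = sum v log(v/vhat) - v + vhat."""
    V = np.asarray(V, dtype=float)
    WH = np.asarray(WH, dtype=float)
    mask = V > 0
    d = WH.sum() - V.sum()
    d += float(np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))))
    return float(d)


def _objective(V, W, H, objective):
    if objective == "kl":
        return kl_divergence(V, W @ H)
    return 0.5 * float(np.linalg.norm(V - W @ H) ** 2)


def _run_single(V, rank, max_iter, tol, rng, objective):
    """One NMF fit from a strictly positive random-uniform start."""
    scale = np.sqrt(V.mean() / rank)
    W0 = rng.uniform(_EPS, 1.0, size=(V.shape[0], rank)) * scale
    H0 = rng.uniform(_EPS, 1.0, size=(rank, V.shape[1])) * scale
    beta = "kullback-leibler" if objective == "kl" else "frobenius"
    model = NMF(
        n_components=rank,
        init="custom",
        solver="mu",
        beta_loss=beta,
        max_iter=max_iter,
        tol=tol,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Maximum number of iterations")
        W = model.fit_transform(V, W=W0, H=H0)
    return W, model.components_


def refit_exposures(
    V: np.ndarray, W: np.ndarray, n_iter: int = 500, tol: float = 1e-8
) -> np.ndarray:
    """Refit H >= 0 for fixed column-stochastic W by KL multiplicative updates.

    With W column-stochastic this converges to exposures whose column sums
    equal each sample's mutation count exactly, so activities read as
    attributed counts.
    """
    rng_free = np.full((W.shape[1], V.shape[1]), V.mean() / W.shape[1] + _EPS)
    H = rng_free
    Wt = W.T
    wcol = W.sum(axis=0)[:, None]  # ~1 for stochastic W, kept for generality
    prev = None
    for _ in range(n_iter):
        WH = np.maximum(W @ H, _EPS)
        H = H * (Wt @ (V / WH)) / np.maximum(wcol, _EPS)
        if prev is not None and np.abs(H - prev).max() < tol * (1 + H.max()):
            break
        prev = H.copy()
    return H


def factorize(
    catalog: MutationCatalog,
    rank: int,
    n_restarts: int = 20,
    max_iter: int = 2000,
    seed: int = 0,
    tol: float = 1e-6,
    objective: str = "kl",
) -> FactorizationResult:
    """Extract ``rank`` signatures from a catalog, best of ``n_restarts``.

    The best restart is the one with the lowest objective value (ties go to
    the lowest restart index).  W is column-normalized with the scale
    absorbed into H, then H is refit with W fixed so that activities sum to
    each sample's mutation count.  Signatures are ordered by descending
    total activity and named "S1"..."SK".
    """
    V = catalog.counts.T.astype(float)
    if V.sum() == 0:
        raise ValueError("all-zero catalog cannot be factorized")
    if rank < 1 or rank >= min(V.shape):
        raise ValueError(f"rank must be in [1, {min(V.shape) - 1}], got {rank}")
    if objective not in ("kl", "frobenius"):
        raise ValueError("objective must be 'kl' or 'frobenius'")

    streams = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        W, H = _run_single(V, rank, max_iter, tol, rng, objective)
        err = _objective(V, W, H, objective)
        if best is None or err < best[0] - 1e-12:
            best = (err, W, H)
    err, W, H = best

    # normalize W columns, absorb scale into H, then refit H on fixed W
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    W = W / colsum
    H = refit_exposures(V, W)
    err = _objective(V, W, H, objective)

    order = np.argsort(-H.sum(axis=1), kind="stable")
    W, H = W[:, order], H[order]
    names = [f"S{i + 1}" for i in range(rank)]
    sigs = SignatureSet(profiles=W, signature_ids=names)
    expo = ExposureMatrix(
        activities=H, signature_ids=names, sample_ids=list(catalog.sample_ids)
    )
    return FactorizationResult(
        signatures=sigs,
        exposures=expo,
        rank=rank,
        reconstruction_error=err,
        restarts_used=n_restarts,
        seed=seed,
        objective=objective,
    )


def _matched_mean_cosine(A: np.ndarray, B: np.ndarray) -> float:
    """Mean cosine between columns of A and B after Hungarian matching."""
    An = A / np.maximum(np.linalg.norm(A, axis=0), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0), _EPS)
    C = An.T @ Bn
    ri, ci = linear_sum_assignment(-C)
    return float(C[ri, ci].mean())


def select_rank(
    catalog: MutationCatalog,
    k_min: int,
    k_max: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    stability_floor: float = 0.9,
    improvement_ratio: float = 0.05,
    objective: str = "kl",
):
    """Scan ranks and report reconstruction error plus restart stability.

    Stability at K is the mean matched cosine between each restart's
    profiles and the best restart's.  The chosen K is the smallest K with
    stability >= ``stability_floor`` whose relative error improvement going
    to K+1 drops below ``improvement_ratio``; if none qualifies, the most
    stable K is returned.  Returns ``(chosen_k, diagnostics_frame)``.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    V = catalog.counts.T.astype(float)
    if k_max >= min(V.shape):
        raise ValueError(f"k_max must be < {min(V.shape)}")

    rows = []
    for k in range(k_min, k_max + 1):
        streams = np.random.SeedSequence((seed, k)).spawn(n_restarts)
        sols = []
        for ss in streams:
            rng = np.random.default_rng(ss)
            W, H = _run_single(V, k, max_iter, 1e-6, rng, objective)
            sols.append((_objective(V, W, H, objective), W))
        best_i = int(np.argmin([s[0] for s in sols]))
        Wbest = sols[best_i][1]
        others = [s[1] for i, s in enumerate(sols) if i != best_i]
        stability = (
            1.0
            if not others
            else float(np.mean([_matched_mean_cosine(Wbest, W) for W in others]))
        )
        rows.append({"rank": k, "error": sols[best_i][0], "stability": stability})

    diag = pd.DataFrame(rows).set_index("rank")
    chosen = None
    for k in range(k_min, k_max + 1):
        if diag.loc[k, "stability"] < stability_floor:
            continue
        if k == k_max:
            chosen = k
            break
        err_k, err_next = diag.loc[k, "error"], diag.loc[k + 1, "error"]
        if err_k <= 0 or (err_k - err_next) / err_k < improvement_ratio:
            chosen = k
            break
    if chosen is None:
        chosen = int(diag["stability"].idxmax())
    return chosen, diag


def relative_exposures(exposures: ExposureMatrix) -> np.ndarray:
    """Per-sample exposure fractions (column-stochastic where total > 0).

    Zero-total samples keep an all-zero column; their ids are listed in
    ``exposures.zero_samples``.
    """
    return exposures.relative
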