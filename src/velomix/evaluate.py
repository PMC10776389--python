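"""Evaluation metrics and input perturbations.

Per-gene MSE of fitted abundances, per-cell velocity consistency (mean
Pearson correlation with KNN-neighbor velocities), a finite-difference
velocity sign heuristic for datasets with a known cell ordering, recovery
correlations against simulated ground truth (Spearman for latent time — an
order statistic — and Pearson for velocity), and the three count
perturbations used to stress uncertainty estimates: library downsampling,
binomial thinning of unspliced counts, and multiplicative lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import pearsonr, spearmanr

from .data import VelocityDataset
from .simulate import GroundTruth

__all__ = [
    "EvalReport",
    "mse_per_gene",
    "velocity_consistency",
    "finite_difference_truth",
    "sign_accuracy",
    "random_sign_baseline",
    "recovery_correlations",
    "perturb_counts",
]

SIGN_ZERO_TOL = 1e-3  # |v| below this (scaled units) counts as zero velocity


@dataclass
class EvalReport:
    mse_u: np.ndarray
    mse_s: np.ndarray
    consistency: np.ndarray
    sign_accuracy: np.ndarray | None = None
    time_corr: np.ndarray | None = None
    velocity_corr: np.ndarray | None = None

    def to_frame(self, gene_ids) -> pd.DataFrame:
        cols = {"mse_u": self.mse_u, "mse_s": self.mse_s}
        if self.sign_accuracy is not None:
            cols["sign_accuracy"] = self.sign_accuracy
        if self.time_corr is not None:
            cols["time_corr"] = self.time_corr
        if self.velocity_corr is not None:
            cols["velocity_corr"] = self.velocity_corr
        return pd.DataFrame(cols, index=[str(g) for g in gene_ids])


def mse_per_gene(
    fitted_u: np.ndarray, fitted_s: np.ndarray, ds: VelocityDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared error between fitted and observed scaled abundances."""
    mse_u = ((fitted_u - ds.unspliced_scaled) ** 2).mean(axis=0)
    mse_s = ((fitted_s - ds.spliced_scaled) ** 2).mean(axis=0)
    return mse_u, mse_s


def velocity_consistency(velocities: np.ndarray, ds: VelocityDataset) -> np.ndarray:
    """Mean Pearson correlation of each cell's velocity vector with the
    velocity vectors of its KNN neighbors; cells whose velocity has zero
    variance are reported as NaN."""
    if ds.neighbor_graph is None:
        raise ValueError("dataset lacks a neighbor graph")
    v = velocities - velocities.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(v, axis=1)
    graph = ds.neighbor_graph.tocsr()
    out = np.full(ds.n_cells, np.nan)
    for i in range(ds.n_cells):
        nbrs = graph.indices[graph.indptr[i]:graph.indptr[i + 1]]
        nbrs = nbrs[nbrs != i]
        if norms[i] == 0 or nbrs.size == 0:
            continue
        ok = norms[nbrs] > 0
        if not ok.any():
            continue
        nbrs = nbrs[ok]
        out[i] = float(np.mean((v[nbrs] @ v[i]) / (norms[nbrs] * norms[i])))
    return out


def finite_difference_truth(
    spliced_smooth: np.ndarray, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Heuristic ground-truth velocity from an ordered cell position label.

    Per position, the per-gene median smoothed spliced abundance is taken;
    consecutive differences give a velocity proportionality and its sign in
    {-1, 0, +1}.  Returns (ordered positions, v_hat, signs); v_hat has one
    row per position transition.
    """
    uniq = np.unique(positions)
    if uniq.size < 2:
        raise ValueError("need at least two distinct positions")
    med = np.stack(
        [np.median(spliced_smooth[positions == p], axis=0) for p in uniq]
    )
    v_hat = np.diff(med, axis=0)
    signs = np.zeros_like(v_hat, dtype=int)
    signs[v_hat > SIGN_ZERO_TOL] = 1
    signs[v_hat < -SIGN_ZERO_TOL] = -1
    return uniq, v_hat, signs


def sign_accuracy(
    velocities: np.ndarray, positions: np.ndarray, truth_signs: np.ndarray
) -> np.ndarray:
    """Fraction of position transitions whose estimated velocity sign matches
    the finite-difference truth; estimates are aggregated per position by the
    median, the same aggregation as the truth."""
    uniq = np.unique(positions)
    med_v = np.stack([np.median(velocities[positions == p], axis=0) for p in uniq])
    est = med_v[:-1]  # sign at transition i: estimate at position i
    est_signs = np.zeros_like(est, dtype=int)
    est_signs[est > SIGN_ZERO_TOL] = 1
    est_signs[est < -SIGN_ZERO_TOL] = -1
    return (est_signs == truth_signs).mean(axis=0)


def random_sign_baseline(
    truth_signs: np.ndarray, seed: int = 0, n_draws: int = 1000
) -> float:
    """Expected sign accuracy of a uniform random {-1, 0, +1} predictor."""
    rng = np.random.default_rng(seed)
    draws = rng.integers(-1, 2, size=(n_draws,) + truth_signs.shape)
    return float((draws == truth_signs[None]).mean())


def recovery_correlations(
    gt: GroundTruth,
    latent_time: np.ndarray,
    velocity_mean: np.ndarray,
    gene_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene Spearman(inferred latent time, true time) and Pearson
    (inferred velocity, true velocity) across cells; constant columns NaN."""
    g = latent_time.shape[1]
    idx = np.arange(g) if gene_indices is None else np.asarray(gene_indices)
    time_corr = np.full(g, np.nan)
    vel_corr = np.full(g, np.nan)
    for j in range(g):
        t_true = gt.time[:, idx[j]]
        v_true = gt.velocity_true[:, idx[j]]
        if np.ptp(latent_time[:, j]) > 0 and np.ptp(t_true) > 0:
            time_corr[j] = spearmanr(latent_time[:, j], t_true).statistic
        if np.std(velocity_mean[:, j]) > 0 and np.std(v_true) > 0:
            vel_corr[j] = pearsonr(velocity_mean[:, j], v_true).statistic
    return time_corr, vel_corr


def perturb_counts(
    ds: VelocityDataset,
    kind: str,
    strength: float,
    seed: int = 0,
) -> VelocityDataset:
    """In-silico input perturbations.

    downsample: keep each cell at ``strength`` (in (0, 1]) of its library,
    per layer, via multinomial subsampling of rounded counts.
    thin_unspliced: binomial thinning, each unspliced count kept with
    probability 1 - strength.
    multiplicative: multiply normalized (smoothed) abundances entrywise by
    exp(Normal(0, strength)).
    """
    rng = np.random.default_rng(seed)
    out = ds.copy()
    if kind == "downsample":
        if not 0 < strength <= 1:
            raise ValueError("downsample strength must be in (0, 1]")
        if strength == 1.0:
            return out
        out.unspliced_raw = sp.csr_matrix(_downsample(ds.unspliced_raw, strength, rng))
        out.spliced_raw = sp.csr_matrix(_downsample(ds.spliced_raw, strength, rng))
        return out
    if kind == "thin_unspliced":
        if not 0 <= strength <= 1:
            raise ValueError("thinning probability must be in [0, 1]")
        u = np.round(ds.unspliced_raw.toarray()).astype(np.int64)
        out.unspliced_raw = sp.csr_matrix(rng.binomial(u, 1.0 - strength).astype(float))
        return out
    if kind == "multiplicative":
        if strength < 0:
            raise ValueError("multiplicative noise scale must be >= 0")
        for layer in ("unspliced_smooth", "spliced_smooth"):
            x = getattr(ds, layer)
            if x is None:
                raise ValueError("multiplicative perturbation needs normalized layers")
            setattr(out, layer, x * np.exp(rng.normal(0.0, strength, size=x.shape)))
        return out
    raise ValueError(f"unknown perturbation kind {kind!r}")


def _downsample(mat: sp.spmatrix, fraction: float, rng) -> np.ndarray:
    x = np.round(np.asarray(mat.todense())).astype(np.int64)
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        total = int(x[i].sum())
        if total == 0:
            continue
        target = int(round(fraction * total))
        if target == 0:
            continue
        out[i] = rng.multivariate_hypergeometric(x[i], target)
    return out.astype(float)
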