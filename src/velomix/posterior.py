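"""Posterior-predictive quantities from a fitted velocity model.

Velocity samples are functionals of the variational posterior: draw z from
q(z | u, s), form the state-probability-weighted velocity
sum_k E[pi_k | z] (beta * u_k - gamma * s_k) per gene, and repeat L times.
From the resulting L x N x G array come the posterior mean velocity, fitted
abundances, gene-wise latent times, per-cell intrinsic uncertainty (variance
of the cosine similarity between samples and their mean), the velocity-driven
cell-cell transition matrix, the extrinsic uncertainty (the same variance
computed on predicted future states T S), and the velocity coherence score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._ad import no_grad
from .data import VelocityDataset, get_logger
from .model import VelocityModel

__all__ = [
    "VelocityPosterior",
    "TransitionMatrix",
    "posterior_predictive",
    "sample_velocity",
    "latent_time",
    "intrinsic_uncertainty",
    "transition_matrix",
    "extrinsic_uncertainty",
    "velocity_coherence",
]

log = get_logger("analyze")


@dataclass
class VelocityPosterior:
    samples: np.ndarray  # (L, N, G)
    mean: np.ndarray  # (N, G)
    fitted_u: np.ndarray
    fitted_s: np.ndarray
    latent_time: np.ndarray
    state_probs: np.ndarray  # (N, G, 4)
    L: int


@dataclass
class TransitionMatrix:
    probs: sp.csr_matrix  # row-stochastic, support within the KNN graph
    kernel_scale: float


def _check_trained(model: VelocityModel):
    if not model.training_trace:
        raise ValueError("model has not been trained (empty training trace)")


def _scaled_inputs(ds: VelocityDataset) -> tuple[np.ndarray, np.ndarray]:
    if ds.unspliced_scaled is None or ds.spliced_scaled is None:
        raise ValueError("dataset lacks scaled layers; run preprocessing first")
    return ds.unspliced_scaled, ds.spliced_scaled


def sample_velocity(
    model: VelocityModel,
    ds: VelocityDataset,
    L: int | None = None,
    seed: int | None = None,
) -> VelocityPosterior:
    """Draw L posterior velocity samples and posterior-mean summaries."""
    _check_trained(model)
    L = model.config.n_posterior_samples if L is None else L
    if L < 2:
        raise ValueError("need L >= 2 posterior samples")
    seed = model.seed if seed is None else seed
    u, s = _scaled_inputs(ds)
    rng = np.random.default_rng(seed)
    with no_grad():
        zmu, zsc = model.encode(u, s)
    zmu, zsc = zmu.data, zsc.data
    n, g = u.shape
    samples = np.empty((L, n, g))
    fitted_u = np.zeros((n, g))
    fitted_s = np.zeros((n, g))
    times = np.zeros((n, g))
    probs = np.zeros((n, g, 4))
    for l in range(L):
        z = zmu + zsc * rng.standard_normal(zmu.shape)
        dec = model.decode_full(z)
        pi = dec["pi"]
        samples[l] = (pi * dec["velocities"]).sum(axis=-1)
        fitted_u += (pi * dec["u_means"]).sum(axis=-1) / L
        fitted_s += (pi * dec["s_means"]).sum(axis=-1) / L
        times += (pi * dec["times"]).sum(axis=-1) / L
        probs += pi / L
    return VelocityPosterior(
        samples=samples,
        mean=samples.mean(axis=0),
        fitted_u=fitted_u,
        fitted_s=fitted_s,
        latent_time=times,
        state_probs=probs,
        L=L,
    )


def posterior_predictive(
    model: VelocityModel, ds: VelocityDataset, L: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior-predictive mean abundances (fitted u, fitted s): Monte-Carlo
    average over q(z) of the state-probability-weighted mixture means."""
    vp = sample_velocity(model, ds, L=L, seed=seed)
    return vp.fitted_u, vp.fitted_s


def latent_time(
    model: VelocityModel, ds: VelocityDataset, L: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Gene-wise latent time: E_z[ sum_k E[pi_k] t^(k) ] with the steady
    states carried at their phase-boundary times (t_switch and t_max)."""
    vp = sample_velocity(model, ds, L=L, seed=seed)
    return vp.latent_time


def intrinsic_uncertainty(vp: VelocityPosterior) -> np.ndarray:
    """Per-cell variance (over samples, denominator L-1) of the cosine
    similarity between each velocity sample and the posterior mean vector."""
    return _cosine_variance(vp.samples, vp.mean)


def _cosine_variance(samples: np.ndarray, mean: np.ndarray) -> np.ndarray:
    L = samples.shape[0]
    mean_norm = np.linalg.norm(mean, axis=-1)
    samp_norm = np.linalg.norm(samples, axis=-1)  # (L, N)
    bad = (mean_norm == 0) | (samp_norm == 0).any(axis=0)
    if bad.any():
        warnings.warn(f"{bad.sum()} cells with zero-norm vectors: uncertainty set to NaN")
    denom = np.where(bad, 1.0, samp_norm * mean_norm[None, :])
    cos = np.einsum("lng,ng->ln", samples, mean) / denom
    var = cos.var(axis=0, ddof=1)
    var[bad] = np.nan
    return var


def transition_matrix(
    velocities: np.ndarray,
    ds: VelocityDataset,
    kernel_scale: float | None = None,
) -> TransitionMatrix:
    """Velocity-driven transition probabilities on the KNN graph.

    For each directed edge (i, j) the score is the cosine similarity between
    the expression displacement s_j - s_i (smoothed, unscaled spliced) and the
    velocity of cell i; row probabilities are an exponential kernel over the
    scores, self-transitions excluded.
    """
    if ds.neighbor_graph is None:
        raise ValueError("dataset lacks a neighbor graph")
    scale = 10.0 if kernel_scale is None else kernel_scale
    S = ds.spliced_smooth
    graph = ds.neighbor_graph.tocsr()
    n = graph.shape[0]
    indptr = graph.indptr
    indices = graph.indices
    rows, cols, vals = [], [], []
    for i in range(n):
        nbrs = indices[indptr[i]:indptr[i + 1]]
        nbrs = nbrs[nbrs != i]
        if nbrs.size == 0:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
            continue
        delta = S[nbrs] - S[i]
        vi = velocities[i]
        dn = np.linalg.norm(delta, axis=1)
        vn = np.linalg.norm(vi)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = (delta @ vi) / (dn * vn)
        cos = np.nan_to_num(cos, nan=0.0)
        w = np.exp(scale * (cos - cos.max()))
        w /= w.sum()
        rows.extend([i] * nbrs.size)
        cols.extend(nbrs)
        vals.extend(w)
    probs = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return TransitionMatrix(probs=probs, kernel_scale=scale)


def extrinsic_uncertainty(
    model: VelocityModel,
    ds: VelocityDataset,
    L: int | None = None,
    seed: int | None = None,
    vp: VelocityPosterior | None = None,
    recompute_transitions: bool = True,
    kernel_scale: float | None = None,
) -> np.ndarray:
    """Variance of the cosine similarity of predicted future cell states.

    Per velocity draw, the transition matrix is (re)built and the future
    state T S computed; the intrinsic-uncertainty variance formula is then
    applied to the future-state vectors of each cell.
    """
    _check_trained(model)
    if vp is None:
        vp = sample_velocity(model, ds, L=L, seed=seed)
    scale = model.config.kernel_scale if kernel_scale is None else kernel_scale
    S = ds.spliced_smooth
    futures = np.empty_like(vp.samples)
    tm = None
    for l in range(vp.L):
        if tm is None or recompute_transitions:
            tm = transition_matrix(vp.samples[l], ds, scale)
        futures[l] = tm.probs @ S
    return _cosine_variance(futures, futures.mean(axis=0))


def velocity_coherence(
    vp: VelocityPosterior,
    tm: TransitionMatrix,
    ds: VelocityDataset,
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Per-(cell, gene) coherence: elementwise product of the empirical
    displacement T s_n - s_n and the posterior-mean velocity; aggregated as
    means per cell type and gene when labels are present."""
    S = ds.spliced_smooth
    delta = tm.probs @ S - S
    coherence = delta * vp.mean
    if ds.cell_type is None:
        return coherence, None
    df = pd.DataFrame(coherence, columns=[str(g) for g in ds.gene_ids])
    df["cell_type"] = ds.cell_type.astype(str)
    agg = df.groupby("cell_type", observed=True).mean()
    return coherence, agg
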