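"""Variational model of splicing kinetics.

A VAE over per-cell unspliced/spliced abundance profiles (min-max scaled to
[0, 1]).  Each cell has a d-dimensional latent representation z with a
standard-normal prior; per cell and gene a 4-state probability vector pi
(induction, induction steady state, repression, repression steady state) has
a symmetric Dirichlet(0.25) prior.  The approximate posterior factorizes as
q(z | u, s) q(pi | z): a diagonal-Gaussian encoder and a Dirichlet whose
concentrations are produced from z.  Decoder networks map z to per-gene phase
times; gene-level free parameters hold the kinetic rates, switch time and
likelihood scales.  The likelihood of each abundance is a 4-component normal
mixture weighted by E[pi], with means from the closed-form kinetics and a
deflated variance (factor c4 = 0.1) for the silent repression steady state.

Training minimizes the negative ELBO plus a switch-location penalty that pulls
the repression initial state (alpha/beta, alpha/gamma) toward the observed
upper corner of each gene's phase portrait, weighted by lambda = 0.2.
Optimization is minibatch Adam with decoupled weight decay on a hand-rolled
numpy autodiff tape — deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln as _gl

from ._ad import Adam, Tensor, gamma_sample
from .data import RunConfig, VelocityDataset, get_logger
from .kinetics import KineticParams, induction_uv, induction_uv_td, repression_uv

__all__ = ["VelocityModel", "initialize", "fit", "switch_anchor"]

log = get_logger("fit")

_EPS = 1e-4
_LOG2PI = float(np.log(2 * np.pi))


def _inv_softplus(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return np.where(y > 30, y, np.log(np.expm1(np.maximum(y, 1e-8))))


def switch_anchor(u_scaled: np.ndarray, s_scaled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Data-derived anchor (u*, s*) for the switch penalty: per gene, the
    median unspliced and spliced abundance over cells above the 99th
    percentile of unspliced abundance."""
    cut = np.quantile(u_scaled, 0.99, axis=0)
    n, g = u_scaled.shape
    u_star = np.empty(g)
    s_star = np.empty(g)
    for j in range(g):
        m = u_scaled[:, j] >= cut[j]
        u_star[j] = np.median(u_scaled[m, j])
        s_star[j] = np.median(s_scaled[m, j])
    return u_star, s_star


class VelocityModel:
    """Encoder/decoder networks plus gene-level kinetic parameters.

    Also the fitted-model container: after :func:`fit`, ``training_trace``
    holds per-epoch objective values and ``kinetic_params()`` exports the
    fitted rates.
    """

    def __init__(
        self,
        n_genes: int,
        config: RunConfig | None = None,
        variant: str = "constant",
        seed: int | None = None,
    ):
        self.config = config or RunConfig()
        self.n_genes = n_genes
        self.variant = variant
        self.seed = self.config.seed if seed is None else seed
        self.training_trace: list[float] = []
        self.eval_trace: list[float] = []  # fixed-batch, common-random-number objective
        self.u_star: np.ndarray | None = None
        self.s_star: np.ndarray | None = None
        self._rng = np.random.default_rng(self.seed)
        self._build_params()

    # -- parameters -----------------------------------------------------------
    def _linear_init(self, fan_in: int, fan_out: int):
        bound = 1.0 / np.sqrt(fan_in)
        w = self._rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = self._rng.uniform(-bound, bound, size=(fan_out,))
        return Tensor(w, requires_grad=True), Tensor(b, requires_grad=True)

    def _build_params(self):
        g, d, h = self.n_genes, self.config.n_latent, self.config.n_hidden
        p: dict[str, Tensor] = {}
        p["W_enc"], p["b_enc"] = self._linear_init(2 * g, h)
        p["W_zmu"], p["b_zmu"] = self._linear_init(h, d)
        p["W_zsc"], p["b_zsc"] = self._linear_init(h, d)
        p["W_pi"], p["b_pi"] = self._linear_init(d, h)
        for k in range(1, 5):
            p[f"W_pi{k}"], p[f"b_pi{k}"] = self._linear_init(h, g)
        p["W_tind"], p["b_tind"] = self._linear_init(d, h)
        p["W_ind"], p["b_ind"] = self._linear_init(h, g)
        p["W_trep"], p["b_trep"] = self._linear_init(d, h)
        p["W_rep"], p["b_rep"] = self._linear_init(h, g)
        # gene-level free parameters (positivity by softplus downstream)
        # beta starts at 1; gamma starts slower (0.3) so that spliced
        # dynamics stay unsaturated over the time horizon at initialization —
        # with both rates at 1 every component sits at a phase-portrait
        # corner and the gradient with respect to latent times vanishes
        p["alpha_free"] = Tensor(_inv_softplus(np.ones(g)), requires_grad=True)
        p["beta_free"] = Tensor(_inv_softplus(np.ones(g)), requires_grad=True)
        p["gamma_free"] = Tensor(_inv_softplus(np.full(g, 0.3)), requires_grad=True)
        p["tswitch_free"] = Tensor(np.zeros(g), requires_grad=True)  # sigmoid -> t_max/2
        p["sigma_u_free"] = Tensor(_inv_softplus(np.full(g, 0.1)), requires_grad=True)
        p["sigma_s_free"] = Tensor(_inv_softplus(np.full(g, 0.1)), requires_grad=True)
        if self.variant == "time_dependent":
            p["alpha0_free"] = Tensor(_inv_softplus(np.ones(g)), requires_grad=True)
            p["lambda_free"] = Tensor(_inv_softplus(np.ones(g)), requires_grad=True)
        self.params = p

    # -- pieces of the generative model ---------------------------------------
    def _rates(self):
        p = self.params
        alpha = p["alpha_free"].softplus()
        beta = p["beta_free"].softplus()
        gamma = p["gamma_free"].softplus()
        t_s = self.config.t_max * p["tswitch_free"].sigmoid()
        return alpha, beta, gamma, t_s

    def encode(self, u: np.ndarray, s: np.ndarray):
        """Posterior parameters of q(z | u, s): mean and scale, (n, d) each."""
        u = np.atleast_2d(u)
        s = np.atleast_2d(s)
        if u.shape[1] != self.n_genes or s.shape[1] != self.n_genes:
            raise ValueError(
                f"expected {self.n_genes} genes, got u:{u.shape[1]} s:{s.shape[1]}"
            )
        x = Tensor(np.concatenate([u, s], axis=1))
        h = (x @ self.params["W_enc"] + self.params["b_enc"]).relu()
        zmu = h @ self.params["W_zmu"] + self.params["b_zmu"]
        zsc = (h @ self.params["W_zsc"] + self.params["b_zsc"]).softplus() + _EPS
        return zmu, zsc

    def _dirichlet_conc(self, z: Tensor) -> list[Tensor]:
        h = (z @ self.params["W_pi"] + self.params["b_pi"]).relu()
        return [
            (h @ self.params[f"W_pi{k}"] + self.params[f"b_pi{k}"]).softplus() + _EPS
            for k in range(1, 5)
        ]

    def decode_times(self, z: Tensor):
        """Per-gene induction and repression phase times from z.

        t_ind = rho_ind * t_switch lies in (0, t_switch); t_rep =
        t_switch + rho_rep * (t_max - t_switch) lies in (t_switch, t_max).
        """
        if not isinstance(z, Tensor):
            z = Tensor(np.atleast_2d(z))
        p = self.params
        h1 = (z @ p["W_tind"] + p["b_tind"]).relu()
        rho_ind = (h1 @ p["W_ind"] + p["b_ind"]).sigmoid()
        h2 = (z @ p["W_trep"] + p["b_trep"]).relu()
        rho_rep = (h2 @ p["W_rep"] + p["b_rep"]).sigmoid()
        _, _, _, t_s = self._rates()
        t_ind = rho_ind * t_s
        t_rep = (self.config.t_max - t_s) * rho_rep + t_s
        return t_ind, t_rep

    def _state_means(self, t_ind: Tensor, t_rep: Tensor):
        """Mean (u, s) for the four states; each entry is (batch, genes)."""
        alpha, beta, gamma, t_s = self._rates()
        if self.variant == "time_dependent":
            alpha1 = alpha
            alpha0 = self.params["alpha0_free"].softplus()
            lam = self.params["lambda_free"].softplus()
            u1, s1 = induction_uv_td(alpha0, alpha1, lam, beta, gamma, t_ind)
            u2, s2 = alpha1 / beta, alpha1 / gamma
            u3, s3 = repression_uv(beta, gamma, u2, s2, t_rep - t_s)
        else:
            u1, s1 = induction_uv(alpha, beta, gamma, t_ind)
            u2, s2 = alpha / beta, alpha / gamma
            u3, s3 = repression_uv(beta, gamma, u2, s2, t_rep - t_s)
        zero = Tensor(np.zeros(1))
        return (u1, u2, u3, zero), (s1, s2, s3, zero)

    def _component_logliks(self, x: np.ndarray, means, sigma: Tensor) -> list[Tensor]:
        """Per-state normal log-densities log N(x; mean_k, (c_k sigma)^2)."""
        c4 = self.config.c4_scale
        logns = []
        for k, m in enumerate(means):
            ck = c4 if k == 3 else 1.0
            scale = sigma * ck
            diff = Tensor(x) - m
            logns.append(
                -0.5 * _LOG2PI - scale.log() - 0.5 * (diff * diff) / (scale * scale)
            )
        return logns

    def _mixture_loglik(self, x: np.ndarray, means, sigma: Tensor, pis):
        """log sum_k pi_k Normal(x; mean_k, (c_k sigma)^2), stabilized by the
        (detached) max component log-density."""
        logns = self._component_logliks(x, means, sigma)
        shift = np.maximum.reduce([ln.data * np.ones_like(x) for ln in logns])
        total = None
        for pi_k, ln in zip(pis, logns):
            term = pi_k * (ln - Tensor(shift)).exp()
            total = term if total is None else total + term
        return (total + 1e-300).log() + Tensor(shift)

    def _expected_loglik(self, x: np.ndarray, means, sigma: Tensor, pis):
        """sum_k E[pi_k] log N_k: the reconstruction term with the state
        assignment marginalized in expectation.  Under the sparse
        Dirichlet(0.25) posterior family, sampled state weights concentrate
        near the simplex corners, and the expected log-mixture approaches
        this expected complete-data form; it penalizes diffuse state
        probabilities far more strongly than the plug-in log-mixture and is
        what training uses (evaluation uses the plug-in mixture)."""
        logns = self._component_logliks(x, means, sigma)
        total = None
        for pi_k, ln in zip(pis, logns):
            term = pi_k * ln
            total = term if total is None else total + term
        return total

    # -- objective -------------------------------------------------------------
    def _objective(self, u: np.ndarray, s: np.ndarray, eps: np.ndarray,
                   penalty: bool = True, kl_weight: float = 1.0,
                   pi_rng: np.random.Generator | None = None) -> Tensor:
        """Per-cell averaged negative ELBO plus the scaled switch penalty."""
        cfg = self.config
        zmu, zsc = self.encode(u, s)
        z = zmu + zsc * Tensor(eps)
        kl_z = (0.5 * (zsc * zsc + zmu * zmu - 1.0) - zsc.log()).sum(axis=1)

        conc = self._dirichlet_conc(z)
        csum = conc[0] + conc[1] + conc[2] + conc[3]
        c0 = cfg.dirichlet_conc
        # KL( Dir(conc) || Dir(c0 * 1) ), closed form
        kl_pi = csum.gammaln() - Tensor(np.float64(_gl(4 * c0)))
        digsum = csum.digamma()
        for ck in conc:
            kl_pi = kl_pi - ck.gammaln() + Tensor(np.float64(_gl(c0)))
            kl_pi = kl_pi + (ck - c0) * (ck.digamma() - digsum)
        kl_pi = kl_pi.sum(axis=1)

        if pi_rng is not None:
            # reparameterized Dirichlet draw: near-one-hot state weights at
            # small concentration, the stochastic assignment that lets states
            # disentangle during training
            ys = [gamma_sample(ck, pi_rng) for ck in conc]
            ysum = ys[0] + ys[1] + ys[2] + ys[3]
            pis = [yk / ysum for yk in ys]
        else:
            pis = [ck / csum for ck in conc]
        t_ind, t_rep = self.decode_times(z)
        u_means, s_means = self._state_means(t_ind, t_rep)
        sigma_u = self.params["sigma_u_free"].softplus() + _EPS
        sigma_s = self.params["sigma_s_free"].softplus() + _EPS
        ll = self._mixture_loglik(u, u_means, sigma_u, pis)
        ll = ll + self._mixture_loglik(s, s_means, sigma_s, pis)
        recon = -1.0 * ll.sum(axis=1)

        loss = (recon + kl_weight * (kl_z + kl_pi)).mean()
        if penalty:
            # the penalty joins the per-cell-mean objective at full weight:
            # a strong anchor that fixes the phase-portrait corner early so
            # improving the fit requires moving per-cell latent times
            loss = loss + cfg.switch_penalty_weight * self.switch_penalty()
        return loss

    def switch_penalty(self) -> Tensor:
        """Sum over genes of the squared distance between the repression
        initial state (alpha/beta, alpha/gamma) and the anchor (u*, s*)."""
        if self.u_star is None:
            raise ValueError("switch anchor not set; call initialize()/fit() first")
        alpha, beta, gamma, _ = self._rates()
        du = alpha / beta - Tensor(self.u_star)
        dsv = alpha / gamma - Tensor(self.s_star)
        return (du * du + dsv * dsv).sum()

    def log_likelihood(self, u: np.ndarray, s: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Per-gene mixture log-likelihood summed over the given cells."""
        z = Tensor(np.atleast_2d(z))
        conc = self._dirichlet_conc(z)
        csum = conc[0] + conc[1] + conc[2] + conc[3]
        pis = [ck / csum for ck in conc]
        t_ind, t_rep = self.decode_times(z)
        u_means, s_means = self._state_means(t_ind, t_rep)
        sigma_u = self.params["sigma_u_free"].softplus() + _EPS
        sigma_s = self.params["sigma_s_free"].softplus() + _EPS
        ll = self._mixture_loglik(np.atleast_2d(u), u_means, sigma_u, pis)
        ll = ll + self._mixture_loglik(np.atleast_2d(s), s_means, sigma_s, pis)
        out = ll.data.sum(axis=0)
        if not np.all(np.isfinite(out)):
            bad = np.flatnonzero(~np.isfinite(out))
            raise FloatingPointError(f"non-finite log-likelihood for genes {bad[:10]}")
        return out

    def elbo(self, u: np.ndarray, s: np.ndarray, seed: int = 0) -> float:
        """Single-sample negative-ELBO estimate (per-cell mean, no penalty)."""
        rng = np.random.default_rng(seed)
        u, s = np.atleast_2d(u), np.atleast_2d(s)
        eps = rng.standard_normal((u.shape[0], self.config.n_latent))
        return float(self._objective(u, s, eps, penalty=False, pi_rng=rng).data)

    def decode_full(self, z: np.ndarray) -> dict:
        """Inference-mode decode of a latent batch: state probabilities
        E[pi | z] (n, G, 4), phase times, per-state means and velocities."""
        from ._ad import no_grad

        with no_grad():
            zt = Tensor(np.atleast_2d(z))
            conc = self._dirichlet_conc(zt)
            csum = conc[0] + conc[1] + conc[2] + conc[3]
            pi = np.stack([(ck / csum).data for ck in conc], axis=-1)
            t_ind, t_rep = self.decode_times(zt)
            u_means, s_means = self._state_means(t_ind, t_rep)
            alpha, beta, gamma, t_s = (t.data for t in self._rates())
            n = zt.data.shape[0]
            um = np.stack(
                [np.broadcast_to(m.data, (n, self.n_genes)) for m in u_means], axis=-1
            )
            sm = np.stack(
                [np.broadcast_to(m.data, (n, self.n_genes)) for m in s_means], axis=-1
            )
        vel = beta[None, :, None] * um - gamma[None, :, None] * sm
        times = np.stack(
            [
                t_ind.data,
                np.broadcast_to(t_s, (n, self.n_genes)),
                t_rep.data,
                np.full((n, self.n_genes), self.config.t_max),
            ],
            axis=-1,
        )
        return {
            "pi": pi,
            "t_ind": t_ind.data,
            "t_rep": t_rep.data,
            "u_means": um,
            "s_means": sm,
            "velocities": vel,
            "times": times,
        }

    # -- export ----------------------------------------------------------------
    def kinetic_params(self) -> KineticParams:
        alpha, beta, gamma, t_s = (t.data.copy() for t in self._rates())
        kw = dict(
            alpha=alpha, beta=beta, gamma=gamma,
            t_switch=np.minimum(t_s, self.config.t_max * (1 - 1e-9)),
            sigma_u=np.log1p(np.exp(self.params["sigma_u_free"].data)) + _EPS,
            sigma_s=np.log1p(np.exp(self.params["sigma_s_free"].data)) + _EPS,
            t_max=self.config.t_max,
        )
        if self.variant == "time_dependent":
            kw.update(
                variant="time_dependent",
                alpha0=np.log1p(np.exp(self.params["alpha0_free"].data)),
                alpha1=alpha,
                lambda_alpha=np.log1p(np.exp(self.params["lambda_free"].data)),
            )
        return KineticParams(**kw)

    def save(self, path):
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez_compressed(
            path,
            __meta__=np.array(
                [self.variant, str(self.seed), str(self.n_genes)], dtype="U32"
            ),
            __trace__=np.array(self.training_trace),
            __eval_trace__=np.array(self.eval_trace),
            __anchor_u__=self.u_star if self.u_star is not None else np.array([]),
            __anchor_s__=self.s_star if self.s_star is not None else np.array([]),
            **arrays,
        )

    @classmethod
    def load(cls, path, config: RunConfig | None = None) -> "VelocityModel":
        data = np.load(path, allow_pickle=False)
        variant, seed, n_genes = data["__meta__"]
        model = cls(int(n_genes), config, variant=str(variant), seed=int(seed))
        for k in model.params:
            model.params[k].data = data[k]
        model.training_trace = list(data["__trace__"])
        if "__eval_trace__" in data:
            model.eval_trace = list(data["__eval_trace__"])
        if data["__anchor_u__"].size:
            model.u_star = data["__anchor_u__"]
            model.s_star = data["__anchor_s__"]
        return model


# ---------------------------------------------------------------------------
# initialization and training
# ---------------------------------------------------------------------------

def initialize(
    ds: VelocityDataset,
    config: RunConfig | None = None,
    variant: str = "constant",
) -> VelocityModel:
    """Untrained model with data-driven transcription-rate initialization:
    alpha starts at the per-gene median unspliced abundance of cells above the
    99th unspliced percentile; splicing/degradation rates and the switch time
    start at a constant shared by all genes (1.0, 1.0, t_max/2)."""
    cfg = config or RunConfig()
    if ds.unspliced_scaled is None:
        raise ValueError("dataset must be preprocessed (scaled layers) before initialize")
    model = VelocityModel(ds.n_genes, cfg, variant=variant)
    u_star, s_star = switch_anchor(ds.unspliced_scaled, ds.spliced_scaled)
    model.u_star, model.s_star = u_star, s_star
    alpha0 = np.maximum(u_star, 1e-2)
    model.params["alpha_free"].data = _inv_softplus(alpha0)
    if variant == "time_dependent":
        # nested start: alpha0 = alpha1 reproduces the constant-rate model
        model.params["alpha0_free"].data = _inv_softplus(alpha0)
    return model


def fit(
    ds: VelocityDataset,
    config: RunConfig | None = None,
    variant: str = "constant",
    model: VelocityModel | None = None,
) -> VelocityModel:
    """Train by minibatch Adam with decoupled weight decay; records the
    per-epoch mean objective and stops early on a plateau."""
    cfg = config or RunConfig()
    if model is None:
        model = initialize(ds, cfg, variant)
    u, s = ds.unspliced_scaled, ds.spliced_scaled
    n = u.shape[0]
    opt = Adam(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    # fixed evaluation batch with common random numbers: an objective trace
    # that reflects parameter progress rather than Monte-Carlo noise
    eval_rng = np.random.default_rng(cfg.seed + 1)
    eval_idx = eval_rng.permutation(n)[: min(n, 2 * cfg.batch_size)]
    eval_eps = eval_rng.standard_normal((len(eval_idx), cfg.n_latent))
    best = np.inf
    since_best = 0
    for epoch in range(cfg.max_epochs):
        # KL warm-up guards against posterior collapse early in training;
        # once the final objective is in place the step size is decayed,
        # which suppresses late-training oscillation of the reconstruction
        kl_weight = min(1.0, (epoch + 1) / max(1, cfg.kl_warmup_epochs))
        opt.lr = cfg.learning_rate * (cfg.lr_decay if kl_weight >= 1.0 else 1.0)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            eps = rng.standard_normal((len(idx), cfg.n_latent))
            loss = model._objective(u[idx], s[idx], eps,
                                    kl_weight=kl_weight, pi_rng=rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"objective diverged at epoch {epoch}; last finite trace: "
                    f"{model.training_trace[-3:]}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_loss = float(np.mean(losses))
        model.training_trace.append(epoch_loss)
        from ._ad import no_grad

        with no_grad():
            model.eval_trace.append(float(model._objective(
                u[eval_idx], s[eval_idx], eval_eps,
                pi_rng=np.random.default_rng(cfg.seed + 2),
            ).data))
        if epoch_loss < best - 1e-5:
            best = epoch_loss
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                log.info("early stop at epoch %d (objective %.4f)", epoch, epoch_loss)
                break
    log.info("training finished after %d epochs (objective %.4f)",
             len(model.training_trace), model.training_trace[-1])
    return model
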