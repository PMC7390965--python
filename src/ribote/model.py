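"""Hierarchical Bayesian model for differential translation efficiency.

Level 1 is a generalized linear mixed model on the paired count data of
one gene g across libraries j:

* RNA-seq:   y_gj ~ Poisson(lambda_gj)
* ribo-seq:  y_gj ~ ZIP(pi, lambda_gj)   (zero-inflated Poisson)

with   lambda_gj = s_j * mu_g * rho_g(t_j) * delta_g^{I_gj} * exp(eta_{t_j, r_j})

where s_j is the known size factor from housekeeping normalization
(the abundance offset), mu_g the baseline abundance, rho_g(t) the RNA
fold change at time t (1 at baseline), eta_{t,r} a pairing random
effect shared by the RPF and RNA libraries of one biological sample,
and I_gj = 1 only for ribo-seq libraries at the contrast time point, so
delta_g is the gene's translation-efficiency fold change between the
baseline and contrast times.

Level 2 places a spike-and-slab mixture on delta_g: with probability p0
the gene has no TE change and delta_g = 1 exactly (point mass); with
probability 1 - p0, delta_g ~ Gamma(a, b), which supports both up- and
down-regulation.  Remaining priors are diffuse: log mu_g and log rho_g
Gaussian, pi and p0 Beta(1, 1), sigma_pair half-normal.

Inference is Metropolis-within-Gibbs: random-walk moves for the
continuous parameters, a joint (z_g, delta_g) move that proposes from
the spike-and-slab prior (whose Metropolis-Hastings ratio reduces to a
likelihood ratio), a refinement random walk on log delta_g for genes
currently in the slab, a conjugate Beta update for p0, and a logit
random walk for pi.  Gene selection uses the direct posterior
probability rule: q_g = P(z_g = 1 and delta_g outside [1/theta, theta]
| data), and the declared set is the largest q-descending prefix whose
mean (1 - q) stays below the FDR level alpha.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .counts import CountMatrix

__all__ = [
    "ModelSpec",
    "LatentState",
    "PosteriorDraws",
    "zip_logpmf",
    "joint_loglik",
    "fit_mcmc",
    "posterior_change_prob",
    "bayesian_fdr_select",
    "summarize",
    "convergence_diagnostics",
]


# ---------------------------------------------------------------------------
# Likelihood primitives
# ---------------------------------------------------------------------------

def zip_logpmf(y, lam, pi):
    """Log pmf of the zero-inflated Poisson, computed stably in log space.

    log[ pi * 1{y=0} + (1 - pi) * Poisson(y; lam) ].  With pi = 0 this
    is the plain Poisson log pmf; lam = 0 is handled as the limit
    (all mass at zero).
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer) and np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integers")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    if np.any(lam < 0):
        raise ValueError("lam must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lam = np.log(lam)
        pois = np.where(
            (lam == 0) & (y == 0), 0.0, y * log_lam - lam - gammaln(y + 1)
        )
        pois = np.where((lam == 0) & (y > 0), -np.inf, pois)
        log_pi = np.log(pi)
        log1m = np.log1p(-pi)
        out = np.where(
            y == 0, np.logaddexp(log_pi, log1m + pois), log1m + pois
        )
        # pi == 1: all mass at zero
        out = np.where((pi == 1.0) & (y == 0), 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def _poisson_logpmf(y, log_lam, gammaln_y):
    return y * log_lam - np.exp(log_lam) - gammaln_y


def _zip_logpmf_from_log_lam(y, log_lam, gammaln_y, log_pi, log1m_pi):
    pois = _poisson_logpmf(y, log_lam, gammaln_y)
    if np.isneginf(log_pi):  # pi == 0
        return pois
    return np.where(y == 0, np.logaddexp(log_pi, log1m_pi + pois), log1m_pi + pois)


# ---------------------------------------------------------------------------
# Model specification and latent state
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Hyperparameters, priors and MCMC controls.

    ``theta`` is the fold-change threshold of the decision interval (a
    gene is a discovery when its TE moved at least theta-fold in either
    direction); ``alpha_fdr`` the Bayesian FDR level.  ``gamma_shape``
    and ``gamma_rate`` parameterize the slab; ``fix_pi`` / ``fix_p0`` /
    ``fix_sigma_pair`` clamp a global instead of sampling it
    (``fix_sigma_pair=0`` switches the pairing effect off).
    """

    theta: float = 2.0
    alpha_fdr: float = 0.05
    gamma_shape: float = 2.0
    gamma_rate: float = 2.0
    mu_prior_sd: float = 10.0
    rho_prior_sd: float = 5.0
    sigma_pair_scale: float = 1.0
    fix_pi: float | None = None
    fix_p0: float | None = None
    fix_sigma_pair: float | None = None
    contrast_time: int | None = None
    n_chains: int = 2
    n_iter: int = 6000
    n_burnin: int = 1000
    thin: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.theta <= 1:
            raise ValueError("theta must exceed 1")
        if not (0 < self.alpha_fdr < 1):
            raise ValueError("alpha_fdr must lie in (0, 1)")
        for name in ("gamma_shape", "gamma_rate", "mu_prior_sd", "rho_prior_sd",
                     "sigma_pair_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_chains < 1 or self.n_iter <= self.n_burnin or self.thin < 1:
            raise ValueError("invalid MCMC controls")

    def replace(self, **kw) -> "ModelSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class LatentState:
    """One configuration of all latent variables.

    ``log_rho`` has one column per non-baseline time point (ordered);
    ``eta`` one entry per (time, replicate) biological sample.  The
    spike-and-slab constraint delta_g = 1 <=> z_g = 0 is enforced.
    """

    log_mu: np.ndarray
    log_rho: np.ndarray           # (G, T-1)
    z: np.ndarray                 # (G,) in {0, 1}
    delta: np.ndarray             # (G,), == 1 where z == 0
    eta: np.ndarray               # (S,)
    pi: float
    p0: float
    sigma_pair: float

    def validate(self) -> None:
        if not np.all(self.delta[self.z == 0] == 1.0):
            raise ValueError("delta must equal 1 exactly where z == 0")
        if not (0 <= self.pi <= 1 and 0 <= self.p0 <= 1):
            raise ValueError("pi and p0 must lie in [0, 1]")


class _ModelData:
    """Count matrix unpacked into arrays + column groupings for the sampler."""

    def __init__(self, cm: CountMatrix, spec: ModelSpec):
        if cm.size_factors is None:
            raise ValueError("size factors missing; run reference_normalize first")
        if (cm.counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero genes present; run drop_all_zero_genes first")
        self.gene_ids = list(cm.counts.index)
        self.lib_ids = list(cm.counts.columns)
        self.y = cm.counts.to_numpy(dtype=np.int64)
        self.gammaln_y = gammaln(self.y + 1)
        self.log_s = np.log(cm.size_factors.reindex(self.lib_ids).to_numpy(float))
        meta = cm.samples.loc[self.lib_ids]
        self.times = sorted(meta["time"].unique())
        if len(self.times) < 2:
            raise ValueError("need at least two time points")
        self.baseline = self.times[0]
        self.contrast = spec.contrast_time if spec.contrast_time is not None else self.times[-1]
        if self.contrast == self.baseline or self.contrast not in self.times:
            raise ValueError(f"invalid contrast time {self.contrast}")
        self.later_times = [t for t in self.times if t != self.baseline]
        t_of = meta["time"].to_numpy()
        a_of = meta["assay"].to_numpy()
        self.is_rpf = a_of == "rpf"
        self.rpf_cols = np.flatnonzero(self.is_rpf)
        self.rna_cols = np.flatnonzero(~self.is_rpf)
        # column index per non-baseline time (both assays)
        self.cols_by_time = {
            t: np.flatnonzero(t_of == t) for t in self.later_times
        }
        self.delta_cols = np.flatnonzero(self.is_rpf & (t_of == self.contrast))
        # biological samples: unique (time, replicate)
        pairs = list(zip(meta["time"], meta["replicate"]))
        self.sample_keys = sorted(set(pairs))
        key_to_idx = {k: i for i, k in enumerate(self.sample_keys)}
        self.sample_of_col = np.array([key_to_idx[p] for p in pairs])
        self.cols_by_sample = [
            np.flatnonzero(self.sample_of_col == s) for s in range(len(self.sample_keys))
        ]
        # rho column index per library column (-1 at baseline)
        rho_idx = {t: i for i, t in enumerate(self.later_times)}
        self.rho_col_of_lib = np.array([rho_idx.get(t, -1) for t in t_of])
        self.n_genes = self.y.shape[0]
        self.n_libs = self.y.shape[1]
        # prior location: log of the gene's mean normalized count
        norm = self.y / np.exp(self.log_s)[None, :]
        self.mu_anchor = np.log(norm.mean(axis=1) + 0.5)

    def log_lambda(self, state: LatentState) -> np.ndarray:
        ll = self.log_s[None, :] + state.log_mu[:, None]
        ll = ll + state.eta[self.sample_of_col][None, :]
        has_rho = self.rho_col_of_lib >= 0
        ll[:, has_rho] += state.log_rho[:, self.rho_col_of_lib[has_rho]]
        ll[:, self.delta_cols] += np.log(state.delta)[:, None]
        return ll


def joint_loglik(state: LatentState, cm: CountMatrix, spec: ModelSpec | None = None) -> float:
    """Total data log-likelihood: Poisson for RNA columns, ZIP for RPF columns.

    rho and delta equal 1 at the baseline time; delta enters only the
    ribo-seq libraries at the contrast time.
    """
    spec = spec or ModelSpec()
    data = _ModelData(cm, spec)
    state.validate()
    if state.log_mu.shape[0] != data.n_genes or state.log_rho.shape != (
        data.n_genes, len(data.later_times)
    ):
        raise ValueError("state dimensions do not match the count matrix")
    log_lam = data.log_lambda(state)
    with np.errstate(divide="ignore"):
        log_pi, log1m = np.log(state.pi), np.log1p(-state.pi)
    total = _poisson_logpmf(
        data.y[:, data.rna_cols], log_lam[:, data.rna_cols],
        data.gammaln_y[:, data.rna_cols],
    ).sum()
    total += _zip_logpmf_from_log_lam(
        data.y[:, data.rpf_cols], log_lam[:, data.rpf_cols],
        data.gammaln_y[:, data.rpf_cols], log_pi, log1m,
    ).sum()
    return float(total)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (chains, draws[, ...])."""

    gene_ids: list[str]
    delta: np.ndarray             # (C, K, G)
    z: np.ndarray                 # (C, K, G)
    log_mu: np.ndarray            # (C, K, G)
    log_rho: np.ndarray           # (C, K, G, T-1)
    eta: np.ndarray               # (C, K, S)
    pi: np.ndarray                # (C, K)
    p0: np.ndarray                # (C, K)
    sigma_pair: np.ndarray        # (C, K)
    acceptance: dict[str, float]
    later_times: list
    contrast_time: object
    spec: ModelSpec

    @property
    def n_chains(self) -> int:
        return self.delta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.delta.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])


class _Chain:
    def __init__(self, data: _ModelData, spec: ModelSpec, rng: np.random.Generator):
        self.d = data
        self.spec = spec
        self.rng = rng
        G, T1 = data.n_genes, len(data.later_times)
        norm = data.y / np.exp(data.log_s)[None, :]
        # data-informed starting point; priors centred the same way for mu
        self.log_mu = data.mu_anchor.copy()
        self.log_rho = np.zeros((G, T1))
        for i, t in enumerate(data.later_times):
            cols_t = np.intersect1d(data.cols_by_time[t], data.rna_cols)
            base = np.intersect1d(
                np.flatnonzero(data.rho_col_of_lib < 0), data.rna_cols
            )
            self.log_rho[:, i] = np.log(
                (norm[:, cols_t].mean(axis=1) + 0.5)
                / (norm[:, base].mean(axis=1) + 0.5)
            )
        self.z = np.zeros(G, dtype=np.int8)
        self.delta = np.ones(G)
        self.eta = np.zeros(len(data.sample_keys))
        self.pi = spec.fix_pi if spec.fix_pi is not None else 0.1
        self.p0 = spec.fix_p0 if spec.fix_p0 is not None else 0.9
        self.sigma_pair = (
            spec.fix_sigma_pair
            if spec.fix_sigma_pair is not None
            else 0.5 * spec.sigma_pair_scale
        )
        self.log_lam = self.d.log_lambda(self.state())
        # eta is informed by every count of its sample, so its posterior
        # scale shrinks with depth: start the walk near 1/sqrt(sample total)
        sample_tot = max(
            float(np.mean([data.y[:, c].sum() for c in data.cols_by_sample])), 1.0
        )
        self.steps = {
            "mu": 0.1, "rho": 0.1, "delta": 0.3,
            "eta": max(2.0 / np.sqrt(sample_tot), 1e-4), "pi": 0.5,
        }
        self.acc = {k: [0, 0] for k in
                    ("mu", "rho", "delta_mix", "delta_rw", "eta", "pi")}

    def state(self) -> LatentState:
        return LatentState(
            self.log_mu, self.log_rho, self.z, self.delta, self.eta,
            float(self.pi), float(self.p0), float(self.sigma_pair),
        )

    # per-gene log-likelihood over a column subset
    def _gene_ll(self, cols: np.ndarray, log_lam_sub: np.ndarray) -> np.ndarray:
        y = self.d.y[:, cols]
        gl = self.d.gammaln_y[:, cols]
        rpf = self.d.is_rpf[cols]
        out = np.zeros(self.d.n_genes)
        if (~rpf).any():
            out += _poisson_logpmf(
                y[:, ~rpf], log_lam_sub[:, ~rpf], gl[:, ~rpf]
            ).sum(axis=1)
        if rpf.any():
            with np.errstate(divide="ignore"):
                lp, l1m = np.log(self.pi), np.log1p(-self.pi)
            out += _zip_logpmf_from_log_lam(
                y[:, rpf], log_lam_sub[:, rpf], gl[:, rpf], lp, l1m
            ).sum(axis=1)
        return out

    def _metropolis_rows(self, cols, shift, log_prior_ratio, tag):
        """Per-gene accept/reject of a row-wise additive shift on log_lam."""
        cur = self.log_lam[:, cols]
        ll_old = self._gene_ll(cols, cur)
        ll_new = self._gene_ll(cols, cur + shift[:, None])
        logr = ll_new - ll_old + log_prior_ratio
        accept = np.log(self.rng.random(self.d.n_genes)) < logr
        self.log_lam[np.ix_(accept, cols)] += shift[accept, None]
        self.acc[tag][0] += int(accept.sum())
        self.acc[tag][1] += accept.size
        return accept

    def move_mu(self):
        step = self.steps["mu"]
        dmu = step * self.rng.standard_normal(self.d.n_genes)
        prop = self.log_mu + dmu
        sd = self.spec.mu_prior_sd
        lpr = ((self.log_mu - self.d.mu_anchor) ** 2
               - (prop - self.d.mu_anchor) ** 2) / (2 * sd**2)
        accept = self._metropolis_rows(np.arange(self.d.n_libs), dmu, lpr, "mu")
        self.log_mu[accept] = prop[accept]

    def move_rho(self):
        step = self.steps["rho"]
        sd = self.spec.rho_prior_sd
        for i, t in enumerate(self.d.later_times):
            cols = self.d.cols_by_time[t]
            dr = step * self.rng.standard_normal(self.d.n_genes)
            prop = self.log_rho[:, i] + dr
            lpr = (self.log_rho[:, i] ** 2 - prop**2) / (2 * sd**2)
            accept = self._metropolis_rows(cols, dr, lpr, "rho")
            self.log_rho[accept, i] = prop[accept]

    def move_delta_mixture(self):
        """Joint (z, delta) proposal from the spike-and-slab prior.

        Because the proposal equals the conditional prior, the MH ratio
        is the likelihood ratio on the ribo-seq contrast columns only.
        """
        G = self.d.n_genes
        z_new = (self.rng.random(G) >= self.p0).astype(np.int8)
        delta_new = np.where(
            z_new == 1,
            self.rng.gamma(self.spec.gamma_shape, 1.0 / self.spec.gamma_rate, size=G),
            1.0,
        )
        delta_new = np.maximum(delta_new, 1e-300)
        shift = np.log(delta_new) - np.log(self.delta)
        cols = self.d.delta_cols
        accept = self._metropolis_rows(cols, shift, 0.0, "delta_mix")
        self.z[accept] = z_new[accept]
        self.delta[accept] = delta_new[accept]

    def move_delta_rw(self):
        """Random-walk refinement of delta for genes currently in the slab."""
        in_slab = self.z == 1
        if not in_slab.any():
            return
        G = self.d.n_genes
        step = self.steps["delta"]
        dlog = np.where(in_slab, step * self.rng.standard_normal(G), 0.0)
        prop = self.delta * np.exp(dlog)
        a, b = self.spec.gamma_shape, self.spec.gamma_rate
        # Gamma prior ratio + log-scale proposal Jacobian
        lpr = np.where(
            in_slab,
            (a - 1) * dlog - b * (prop - self.delta) + dlog,
            -np.inf,  # spike genes do not move in this step
        )
        accept = self._metropolis_rows(self.d.delta_cols, dlog, lpr, "delta_rw")
        accept &= in_slab
        self.delta[accept] = prop[accept]
        self.acc["delta_rw"][1] -= int((~in_slab).sum())

    def move_eta(self):
        if self.spec.fix_sigma_pair == 0.0:
            return
        step = self.steps["eta"]
        for s, cols in enumerate(self.d.cols_by_sample):
            de = step * self.rng.standard_normal()
            prop = self.eta[s] + de
            cur = self.log_lam[:, cols]
            ll_old = self._gene_ll(cols, cur).sum()
            ll_new = self._gene_ll(cols, cur + de).sum()
            sig = max(self.sigma_pair, 1e-12)
            lpr = (self.eta[s] ** 2 - prop**2) / (2 * sig**2)
            if np.log(self.rng.random()) < ll_new - ll_old + lpr:
                self.eta[s] = prop
                self.log_lam[:, cols] += de
                self.acc["eta"][0] += 1
            self.acc["eta"][1] += 1

    def move_sigma_pair(self):
        if self.spec.fix_sigma_pair is not None:
            return
        prop = self.sigma_pair * np.exp(0.3 * self.rng.standard_normal())
        scale = self.spec.sigma_pair_scale

        def logpost(sig):
            # N(eta; 0, sig) x half-normal(sig; scale), log scale + Jacobian
            return (
                -len(self.eta) * np.log(sig)
                - (self.eta**2).sum() / (2 * sig**2)
                - sig**2 / (2 * scale**2)
                + np.log(sig)
            )

        if np.log(self.rng.random()) < logpost(prop) - logpost(self.sigma_pair):
            self.sigma_pair = prop

    def move_pi(self):
        if self.spec.fix_pi is not None:
            return
        cols = self.d.rpf_cols
        logit = np.log(self.pi) - np.log1p(-self.pi)
        prop_logit = logit + self.steps["pi"] * self.rng.standard_normal()
        prop = 1.0 / (1.0 + np.exp(-prop_logit))
        y = self.d.y[:, cols]
        gl = self.d.gammaln_y[:, cols]
        lam = self.log_lam[:, cols]

        def ll(pi):
            with np.errstate(divide="ignore"):
                lp, l1m = np.log(pi), np.log1p(-pi)
            return _zip_logpmf_from_log_lam(y, lam, gl, lp, l1m).sum()

        # Beta(1,1) prior; logit-scale walk needs the Jacobian pi(1-pi)
        logr = (
            ll(prop) - ll(self.pi)
            + np.log(prop) + np.log1p(-prop)
            - np.log(self.pi) - np.log1p(-self.pi)
        )
        if np.log(self.rng.random()) < logr:
            self.pi = float(prop)
            self.acc["pi"][0] += 1
        self.acc["pi"][1] += 1

    def move_p0(self):
        if self.spec.fix_p0 is not None:
            return
        n1 = int(self.z.sum())
        n0 = self.d.n_genes - n1
        self.p0 = float(self.rng.beta(1 + n0, 1 + n1))

    def iterate(self):
        self.move_mu()
        self.move_rho()
        self.move_delta_mixture()
        self.move_delta_rw()
        self.move_eta()
        self.move_sigma_pair()
        self.move_pi()
        self.move_p0()

    def adapt(self):
        """Scale random-walk steps towards ~30% acceptance (burn-in only)."""
        for tag, key in (("mu", "mu"), ("rho", "rho"), ("delta_rw", "delta"),
                         ("eta", "eta"), ("pi", "pi")):
            acc, tot = self.acc[tag]
            if tot > 0:
                rate = acc / tot
                self.steps[key] *= float(np.exp(np.clip(2.0 * (rate - 0.3), -1.0, 1.0)))
        for k in self.acc:
            self.acc[k] = [0, 0]


def fit_mcmc(cm: CountMatrix, spec: ModelSpec) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler; reproducible given spec.seed."""
    spec.validate()
    data = _ModelData(cm, spec)
    kept = (spec.n_iter - spec.n_burnin) // spec.thin
    C, G, T1, S = spec.n_chains, data.n_genes, len(data.later_times), len(data.sample_keys)
    out = {
        "delta": np.empty((C, kept, G)),
        "z": np.empty((C, kept, G), dtype=np.int8),
        "log_mu": np.empty((C, kept, G)),
        "log_rho": np.empty((C, kept, G, T1)),
        "eta": np.empty((C, kept, S)),
        "pi": np.empty((C, kept)),
        "p0": np.empty((C, kept)),
        "sigma_pair": np.empty((C, kept)),
    }
    acc_totals: dict[str, list[int]] = {}
    seeds = np.random.SeedSequence(spec.seed).spawn(C)
    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        chain = _Chain(data, spec, rng)
        k = 0
        for it in range(spec.n_iter):
            chain.iterate()
            if it < spec.n_burnin:
                if (it + 1) % 50 == 0:
                    chain.adapt()
                if it + 1 == spec.n_burnin:
                    for key in chain.acc:
                        chain.acc[key] = [0, 0]
            elif (it - spec.n_burnin) % spec.thin == spec.thin - 1 and k < kept:
                out["delta"][c, k] = chain.delta
                out["z"][c, k] = chain.z
                out["log_mu"][c, k] = chain.log_mu
                out["log_rho"][c, k] = chain.log_rho
                out["eta"][c, k] = chain.eta
                out["pi"][c, k] = chain.pi
                out["p0"][c, k] = chain.p0
                out["sigma_pair"][c, k] = chain.sigma_pair
                k += 1
        for tag, (a, t) in chain.acc.items():
            tot = acc_totals.setdefault(tag, [0, 0])
            tot[0] += a
            tot[1] += t
    acceptance = {
        tag: (a / t if t else float("nan")) for tag, (a, t) in acc_totals.items()
    }
    return PosteriorDraws(
        gene_ids=data.gene_ids,
        acceptance=acceptance,
        later_times=list(data.later_times),
        contrast_time=data.contrast,
        spec=spec,
        **out,
    )


# ---------------------------------------------------------------------------
# Posterior summaries, FDR selection, diagnostics
# ---------------------------------------------------------------------------

def posterior_change_prob(draws: PosteriorDraws, theta: float | None = None) -> pd.Series:
    """q_g = P(z_g = 1 and delta_g moved at least theta-fold | data)."""
    theta = draws.spec.theta if theta is None else theta
    if theta <= 1:
        raise ValueError("theta must exceed 1")
    delta = draws.flat("delta")
    z = draws.flat("z")
    hit = (z == 1) & ((delta >= theta) | (delta <= 1.0 / theta))
    return pd.Series(hit.mean(axis=0), index=draws.gene_ids, name="q")


def bayesian_fdr_select(q, alpha: float):
    """Direct posterior probability FDR control.

    Sorts genes by q descending (stable, so ties keep input order) and
    selects the largest prefix whose mean posterior error probability
    (1 - q) is at most alpha.  Returns (selected boolean array aligned
    with the input, achieved FDR estimate over the selected set).
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    order = np.argsort(-q, kind="stable")
    prefix_err = np.cumsum(1.0 - q[order]) / np.arange(1, len(q) + 1)
    ok = np.flatnonzero(prefix_err <= alpha)
    selected = np.zeros(len(q), dtype=bool)
    if len(ok) == 0:
        return selected, 0.0
    k = int(ok[-1]) + 1
    selected[order[:k]] = True
    return selected, float(prefix_err[k - 1])


def summarize(
    draws: PosteriorDraws,
    theta: float | None = None,
    alpha: float | None = None,
    fold_changes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene posterior table: delta mean, 95% credible interval, q, FDR call.

    ``fold_changes`` (from :func:`ribote.counts.fold_change_table`) is
    merged in when given, producing the scatter-ready table of naive
    log2 fold changes next to the model's calls.
    """
    theta = draws.spec.theta if theta is None else theta
    alpha = draws.spec.alpha_fdr if alpha is None else alpha
    delta = draws.flat("delta")
    q = posterior_change_prob(draws, theta)
    selected, achieved = bayesian_fdr_select(q.to_numpy(), alpha)
    rho_contrast = np.exp(draws.flat("log_rho")[..., -1])
    table = pd.DataFrame(
        {
            "delta_mean": delta.mean(axis=0),
            "delta_lo": np.quantile(delta, 0.025, axis=0),
            "delta_hi": np.quantile(delta, 0.975, axis=0),
            "q": q.to_numpy(),
            "called": selected,
            "rho_mean": rho_contrast.mean(axis=0),
        },
        index=pd.Index(draws.gene_ids, name="gene_id"),
    )
    table.attrs["achieved_fdr"] = achieved
    table.attrs["theta"] = theta
    table.attrs["alpha"] = alpha
    if fold_changes is not None:
        table = table.join(fold_changes, how="left")
    return table


def convergence_diagnostics(
    draws: PosteriorDraws, n_gene_params: int = 20, rhat_limit: float = 1.1
) -> pd.DataFrame:
    """Split-R-hat and effective sample size for globals + sampled gene deltas.

    Requires >= 2 chains.  Parameters with R-hat above ``rhat_limit``
    (or undefined R-hat from degenerate chains) are flagged.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    params: dict[str, np.ndarray] = {
        "pi": draws.pi, "p0": draws.p0, "sigma_pair": draws.sigma_pair,
    }
    G = len(draws.gene_ids)
    pick = np.linspace(0, G - 1, min(n_gene_params, G)).astype(int)
    for g in pick:
        params[f"delta[{draws.gene_ids[g]}]"] = draws.delta[:, :, g]
    rows = []
    for name, arr in params.items():
        if np.allclose(arr.var(), 0.0):
            rhat, ess = float("nan"), float("nan")
        else:
            rhat = float(az.rhat(arr.astype(float)))
            ess = float(az.ess(arr.astype(float)))
        flagged = not (rhat == rhat) or rhat > rhat_limit  # NaN -> flagged
        rows.append((name, rhat, ess, flagged))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "flagged"])
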