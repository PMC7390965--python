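"""Dense-grid posterior for a one-gene model; validates the MCMC sampler.

For a single gene with two time points, fixed globals (pi, p0 given,
pairing effect off) and known size factors, the posterior of the
TE fold change delta can be computed by brute-force numerical
integration over a (log mu, log rho, delta) grid:

    P(z = 0 | y)           ∝ p0      * ∫∫ L(y | mu, rho, delta=1) dP(mu, rho)
    p(delta | z = 1, y)    ∝ (1-p0)  * Gamma(delta; a, b)
                                     * ∫∫ L(y | mu, rho, delta) dP(mu, rho)

This integration path shares no code with the Metropolis-within-Gibbs
sampler, so agreement between the two (total variation distance on a
shared delta discretization) is a genuine cross-check of the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import gamma as gamma_dist

from .counts import CountMatrix
from .model import ModelSpec, PosteriorDraws, _ModelData, _zip_logpmf_from_log_lam, _poisson_logpmf


@dataclass
class OneGenePosterior:
    """Spike mass at delta = 1 plus a discretized slab density."""

    delta_grid: np.ndarray        # slab evaluation points
    spike_mass: float             # P(z = 0 | y)
    slab_mass: np.ndarray         # probability per grid cell; sums to 1 - spike
    bin_edges: np.ndarray         # cell boundaries for binning MCMC draws

    def tv_distance(self, draws: PosteriorDraws, gene: int = 0, coarsen: int = 4) -> float:
        """Total variation vs MCMC draws on the shared (spike + bins) partition.

        Consecutive grid cells are merged ``coarsen`` at a time so the
        comparison grid is fine enough to resolve the slab's shape but
        coarse enough that per-cell Monte-Carlo noise does not swamp a
        genuine discrepancy.
        """
        edges = np.append(self.bin_edges[::coarsen], self.bin_edges[-1])
        edges = np.unique(edges)
        quad_bins = np.add.reduceat(
            self.slab_mass, np.arange(0, len(self.slab_mass), coarsen)
        )
        delta = draws.flat("delta")[:, gene]
        z = draws.flat("z")[:, gene]
        mc_spike = float((z == 0).mean())
        slab_draws = delta[z == 1]
        mc_bins = (
            np.histogram(slab_draws, bins=edges)[0] / len(delta)
            if len(slab_draws)
            else np.zeros(len(quad_bins))
        )
        # draws outside the grid span count fully towards the distance
        mc_outside = (len(slab_draws) - mc_bins.sum() * len(delta)) / len(delta)
        return 0.5 * (
            abs(mc_spike - self.spike_mass)
            + np.abs(mc_bins - quad_bins).sum()
            + abs(mc_outside)
        )


def one_gene_posterior_quadrature(
    cm: CountMatrix,
    spec: ModelSpec,
    n_mu: int = 161,
    n_rho: int = 161,
    n_delta: int = 241,
    span_sd: float = 8.0,
    delta_range: tuple[float, float] = (0.02, 50.0),
) -> OneGenePosterior:
    """Posterior of delta for a one-gene count matrix by grid integration.

    Requires exactly one gene, two time points, fixed pi and p0 and no
    pairing effect in ``spec`` (this is the regime in which the
    quadrature is exact up to grid resolution).
    """
    if spec.fix_pi is None or spec.fix_p0 is None or spec.fix_sigma_pair != 0.0:
        raise ValueError("quadrature requires fix_pi, fix_p0 and fix_sigma_pair=0")
    data = _ModelData(cm, spec)
    if data.n_genes != 1:
        raise ValueError("quadrature is defined for a single gene")
    if len(data.later_times) != 1:
        raise ValueError("quadrature is defined for two time points")
    y = data.y[0]
    gl = data.gammaln_y[0]
    pi, p0 = spec.fix_pi, spec.fix_p0
    with np.errstate(divide="ignore"):
        log_pi, log1m_pi = np.log(pi), np.log1p(-pi)

    # grids: mu around its data anchor, rho around 0 (prior means), both
    # wide enough that the posterior mass is interior
    anchor = data.mu_anchor[0]
    mu_grid = np.linspace(anchor - span_sd, anchor + span_sd, n_mu)
    rho_grid = np.linspace(-span_sd, span_sd, n_rho)
    log_delta_grid = np.linspace(np.log(delta_range[0]), np.log(delta_range[1]), n_delta)
    delta_grid = np.exp(log_delta_grid)

    # log prior weights (trapezoid cell widths absorbed; normalization
    # cancels in the posterior)
    lw_mu = -((mu_grid - anchor) ** 2) / (2 * spec.mu_prior_sd**2)
    lw_rho = -(rho_grid**2) / (2 * spec.rho_prior_sd**2)

    def col_ll(col: int, log_lam: np.ndarray) -> np.ndarray:
        if data.is_rpf[col]:
            return _zip_logpmf_from_log_lam(y[col], log_lam, gl[col], log_pi, log1m_pi)
        return _poisson_logpmf(y[col], log_lam, gl[col])

    # 2D base log-likelihood over (mu, rho) for every column except the
    # delta-bearing ones; delta columns are added per grid value below
    MU = mu_grid[:, None]
    RHO = rho_grid[None, :]
    base = lw_mu[:, None] + lw_rho[None, :]
    delta_base = []  # per delta column: log lambda without the delta term
    for j in range(data.n_libs):
        rho_term = RHO if data.rho_col_of_lib[j] >= 0 else 0.0
        log_lam = data.log_s[j] + MU + rho_term
        if j in data.delta_cols:
            delta_base.append((j, log_lam))
        else:
            base = base + col_ll(j, log_lam)

    def integrated_ll(log_delta: float) -> float:
        total = base
        for j, log_lam in delta_base:
            total = total + col_ll(j, log_lam + log_delta)
        return float(logsumexp(total))

    log_w_spike = np.log(p0) + integrated_ll(0.0)
    # trapezoid weights on the log-delta grid (slab density in delta is
    # transformed to log-delta: extra + log_delta Jacobian term)
    cell = np.gradient(log_delta_grid)
    a, b = spec.gamma_shape, spec.gamma_rate
    log_slab_prior = gamma_dist.logpdf(delta_grid, a, scale=1.0 / b) + log_delta_grid
    log_w_slab = np.array(
        [
            np.log1p(-p0) + log_slab_prior[k] + np.log(cell[k]) + integrated_ll(log_delta_grid[k])
            for k in range(n_delta)
        ]
    )
    norm = logsumexp(np.append(log_w_slab, log_w_spike))
    spike_mass = float(np.exp(log_w_spike - norm))
    slab_mass = np.exp(log_w_slab - norm)

    # geometric cell edges around the delta grid points
    edges = np.empty(n_delta + 1)
    edges[1:-1] = np.sqrt(delta_grid[:-1] * delta_grid[1:])
    edges[0] = delta_grid[0] ** 2 / edges[1]
    edges[-1] = delta_grid[-1] ** 2 / edges[-2]
    return OneGenePosterior(delta_grid, spike_mass, slab_mass, edges)
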