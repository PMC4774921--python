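import numpy as np
import pytest

from forceshare.model import CostWeights, FingerProfile, normalization_constants


@pytest.fixture
def mean_pair():
    """Finger pair at the published group means (weak little, strong index)."""
    return (
        FingerProfile("left_little", 0.0238, 12.71),
        FingerProfile("right_index", 0.0162, 23.29),
    )


@pytest.fixture
def mean_consts(mean_pair):
    return normalization_constants([mean_pair])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def grid_posterior_medians(data, consts, n_grid=400):
    """Independent oracle: marginal posterior medians of (w, z) by quadrature.

    The per-participant variances integrate out analytically under the
    1/sigma2 prior, leaving log pi(w,z | y) = sum_m [lgamma(N_m/2)
    - (N_m/2) log(RSS_m/2)] on a uniform (w, z) grid.
    """
    from scipy.special import gammaln

    grid = (np.arange(n_grid) + 0.5) / n_grid
    W, Z = np.meshgrid(grid, grid, indexing="ij")
    nu_t = W / consts.b_nu
    lam_t = (1 - W) * Z / consts.b_lam
    mu_t = (1 - W) * (1 - Z) / consts.b_mu
    logpost = np.zeros_like(W)
    for m in range(data.n_participants):
        a_i = nu_t * data.k2_i[m] + lam_t + mu_t * data.invmvc2_i[m]
        a_j = nu_t * data.k2_j[m] + lam_t + mu_t * data.invmvc2_j[m]
        c = a_j / (a_i + a_j)
        rss = data.sum_y2[m] - 2 * c * data.sum_y[m] + data.n_obs[m] * c**2
        logpost += gammaln(data.n_obs[m] / 2) - (data.n_obs[m] / 2) * np.log(rss / 2)
    post = np.exp(logpost - logpost.max())
    post /= post.sum()

    def marginal_median(axis):
        cdf = np.cumsum(post.sum(axis=axis))
        return grid[np.searchsorted(cdf, 0.5)]

    return marginal_median(1), marginal_median(0)
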