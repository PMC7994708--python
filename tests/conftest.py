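import numpy as np
import pytest

import symptomnet as sn


@pytest.fixture(scope="session")
def study_panel():
    """Study-shaped synthetic fixture: 100 subjects x 3 waves x 11 symptoms."""
    return sn.generate_panel(sn.study_config(seed=11))


@pytest.fixture(scope="session")
def stationary_config():
    """Generator matching the pooled-GVAR assumptions (constant wave means)."""
    return dict(between_sd=0.0, wave_means=np.zeros((3, 11)))


def random_pd_correlation(p, rng, df=None):
    """Wishart-based random positive-definite correlation matrix."""
    df = df or max(p + 5, 3 * p)
    A = rng.standard_normal((df, p))
    S = A.T @ A / df
    d = np.sqrt(np.diag(S))
    C = S / np.outer(d, d)
    C = (C + C.T) / 2
    np.fill_diagonal(C, 1.0)
    return C


def nodewise_pcor_oracle(C):
    """Partial correlations via per-node regressions on all other nodes.

    beta_j = C_{-j,-j}^{-1} C_{-j,j};  w_ij = sign(b_ij) sqrt(b_ij b_ji).
    Independent of the precision-matrix route it checks.
    """
    p = C.shape[0]
    betas = np.zeros((p, p))
    r2 = np.zeros(p)
    for j in range(p):
        idx = [k for k in range(p) if k != j]
        beta = np.linalg.solve(C[np.ix_(idx, idx)], C[idx, j])
        betas[j, idx] = beta
        r2[j] = C[j, idx] @ beta
    W = np.sign(betas) * np.sqrt(np.abs(betas * betas.T))
    np.fill_diagonal(W, 0.0)
    return W, r2
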