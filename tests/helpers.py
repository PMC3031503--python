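"""Shared builders for test datasets (synthetic, constructed in-process)."""

import numpy as np

from motifreg.data import LabeledMatrix, RegulatoryDataset


def ids(prefix, count):
    return tuple(f"{prefix}{i + 1}" for i in range(count))


def labeled(values, row_prefix="r", col_prefix="c"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return LabeledMatrix(values, ids(row_prefix, values.shape[0]),
                         ids(col_prefix, values.shape[1]))


def dataset_from_arrays(G, M, T):
    G, M, T = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (G, M, T))
    n, p = G.shape
    m, t = M.shape[1], T.shape[0]
    return RegulatoryDataset(
        G=LabeledMatrix(G, ids("g", n), ids("e", p)),
        M=LabeledMatrix(M, ids("g", n), ids("mo", m)),
        T=LabeledMatrix(T, ids("tf", t), ids("e", p)),
    )


def random_dataset(rng, n=6, p=5, m=3, t=2, rank_deficient=False):
    M = rng.standard_normal((n, m))
    T = rng.standard_normal((t, p))
    if rank_deficient:
        if m > 1:
            M[:, -1] = M[:, 0]
        if t > 1:
            T[-1] = T[0]
    G = rng.standard_normal((n, p))
    return dataset_from_arrays(G, M, T)


def consistency_dataset(seed, n=2000, p=50, m=2, t=2, noise_sd=0.5):
    """Generative-model draw with Bernoulli motifs, Gaussian TF expression
    and a single true coefficient a_11 = 1."""
    rng = np.random.default_rng(seed)
    M = rng.binomial(1, 0.5, size=(n, m)).astype(float)
    T = rng.standard_normal((t, p))
    A = np.zeros((m, t))
    A[0, 0] = 1.0
    G = M @ A @ T + rng.standard_normal((n, p)) * noise_sd
    return dataset_from_arrays(G, M, T), A


def vectorized_design(D):
    """Design matrix of the vectorized regression: vec(G) = (T' kron M) vec(A)."""
    return np.kron(D.T.values.T, D.M.values)
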