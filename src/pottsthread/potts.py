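"""Potts (pairwise maximum-entropy) model over aligned sequences.

The statistical energy of a sequence ``S`` is

    H(S) = sum_{i<j} J_ij(S_i, S_j) + sum_i h_i(S_i),

with sequence probability P(S) = exp(-H(S)) / Z, so lower energy means more
probable.  The partition function Z is never computed: for a kinase-scale
model (L = 259 columns, q = 21 states) the sum over q**L sequences is
intractable, and nothing downstream needs it — threading scores and all
selectivity statistics depend only on energy differences.

Couplings are stored as a full (L, L, q, q) array with the symmetry
J[i, j, a, b] == J[j, i, b, a] and a zero diagonal; each unordered pair is
counted once in the energy.  The canonical parameterization is the zero-sum
gauge, in which couplings sum to zero over either state index, making
per-pair coupling magnitudes comparable — the property the threading score
relies on.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from pottsthread.alignment import Alignment, PROTEIN_ALPHABET

logger = logging.getLogger(__name__)

ZERO_SUM = "zero_sum"

_MODEL_MAGIC = "pottsthread-model"
_MODEL_VERSION = 1


@dataclass
class PottsModel:
    """Fields ``h`` (L, q) and couplings ``J`` (L, L, q, q); see module docstring.

    ``offset`` is a gauge bookkeeping constant added to every sequence energy so
    that gauge transformations preserve absolute energies, not just differences.
    """

    h: np.ndarray
    J: np.ndarray
    gauge: str = "raw"
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.h = np.ascontiguousarray(self.h, dtype=np.float64)
        self.J = np.ascontiguousarray(self.J, dtype=np.float64)
        if self.h.ndim != 2:
            raise ValueError("h must be (L, q)")
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError(f"J must be (L, L, q, q) = {(L, L, q, q)}, got {self.J.shape}")
        if not np.allclose(self.J, self.J.transpose(1, 0, 3, 2), atol=1e-8):
            raise ValueError("J must satisfy J[i,j,a,b] == J[j,i,b,a]")
        if np.abs(self.J[np.arange(L), np.arange(L)]).max(initial=0.0) > 1e-12:
            raise ValueError("J must have a zero diagonal (no self-couplings)")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("model parameters must be finite")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def energies(self, seqs: np.ndarray) -> np.ndarray:
        """Vectorized H(S) for a (n, L) array of encoded sequences."""
        seqs = _check_seqs(seqs, self.L, self.q)
        n, L = seqs.shape
        rows = np.take_along_axis(
            self.h[None, :, :], seqs[:, :, None], axis=2
        )[:, :, 0]
        e = rows.sum(axis=1)
        # pair term: sum over i<j of J[i, j, S_i, S_j]
        iu, ju = np.triu_indices(L, k=1)
        e = e + self.J[iu, ju, seqs[:, iu], seqs[:, ju]].sum(axis=1)
        return e + self.offset


def _check_seqs(seqs: np.ndarray, L: int, q: int) -> np.ndarray:
    seqs = np.asarray(seqs, dtype=np.int64)
    if seqs.ndim == 1:
        seqs = seqs[None, :]
    if seqs.shape[1] != L:
        raise ValueError(f"sequence length {seqs.shape[1]} != model L = {L}")
    bad = (seqs < 0) | (seqs >= q)
    if bad.any():
        n_idx, i_idx = np.argwhere(bad)[0]
        raise ValueError(
            f"symbol {seqs[n_idx, i_idx]} at column {i_idx} outside [0, {q})"
        )
    return seqs


def potts_energy(model: PottsModel, seq: np.ndarray) -> float:
    """Statistical energy H(S) of one encoded sequence (each pair counted once)."""
    seq = np.asarray(seq, dtype=np.int64)
    if seq.ndim != 1:
        raise ValueError("seq must be 1-D; use model.energies for batches")
    return float(model.energies(seq)[0])


def zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Return the equivalent model in the zero-sum gauge.

    Per-pair row/column means of J are moved into the fields and a scalar
    offset, so every sequence keeps its exact energy (to rounding) while
    the couplings sum to zero over either state index.
    """
    J = model.J
    mu_i = J.mean(axis=3)            # (L, L, q): mean over the state of j
    mu_j = J.mean(axis=2)            # (L, L, q): mean over the state of i
    mu = J.mean(axis=(2, 3))         # (L, L)
    Jz = J - mu_i[:, :, :, None] - mu_j[:, :, None, :] + mu[:, :, None, None]
    L = model.L
    off_diag = ~np.eye(L, dtype=bool)
    # each position absorbs its own row means over all partner positions
    h = model.h + np.where(off_diag[:, :, None], mu_i, 0.0).sum(axis=1)
    iu, ju = np.triu_indices(L, k=1)
    offset = model.offset - mu[iu, ju].sum()
    Jz[np.arange(L), np.arange(L)] = 0.0
    return PottsModel(h=h, J=Jz, gauge=ZERO_SUM, offset=offset)


def _conditional_energies(h: np.ndarray, J: np.ndarray, seqs: np.ndarray, i: int) -> np.ndarray:
    """(n, q) energies of each state at site i given the rest of each sequence."""
    Ji = J[i].transpose(0, 2, 1)                    # (L, q_partner, q_self)
    L = h.shape[0]
    sel = Ji[np.arange(L)[None, :], seqs, :]        # (n, L, q_self)
    return h[i][None, :] + sel.sum(axis=1)          # diagonal of J is zero


def sample_sequences(
    model: PottsModel,
    n: int,
    burn_in: int = 200,
    thin: int = 0,
    seed: int = 0,
    alphabet: str | None = None,
) -> Alignment:
    """Draw n sequences from P(S) = exp(-H)/Z by Gibbs sampling.

    n independent chains are run in parallel, each initialized uniformly at
    random and advanced ``burn_in + thin`` full-site sweeps; the final state of
    each chain is returned.  Reproducible for a fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if burn_in < 0 or thin < 0:
        raise ValueError("burn_in and thin must be non-negative")
    rng = np.random.default_rng(seed)
    L, q = model.L, model.q
    seqs = rng.integers(0, q, size=(n, L))
    for _ in range(burn_in + thin):
        for i in range(L):
            e = _conditional_energies(model.h, model.J, seqs, i)
            logp = -e - logsumexp(-e, axis=1, keepdims=True)
            cdf = np.cumsum(np.exp(logp), axis=1)
            u = rng.random(n)
            seqs[:, i] = np.minimum((cdf < u[:, None]).sum(axis=1), q - 1)
    if alphabet is None:
        alphabet = PROTEIN_ALPHABET if q == 21 else PROTEIN_ALPHABET[:q]
    ids = [f"sample_{k:06d}" for k in range(n)]
    return Alignment(seqs, ids, alphabet)


def _pack(h: np.ndarray, Jt: np.ndarray) -> np.ndarray:
    return np.concatenate([h.ravel(), Jt.ravel()])


def _unpack(x: np.ndarray, L: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    nh = L * q
    h = x[:nh].reshape(L, q)
    Jt = x[nh:].reshape(-1, q, q)
    return h, Jt


def _full_J(Jt: np.ndarray, L: int, q: int) -> np.ndarray:
    J = np.zeros((L, L, q, q))
    iu, ju = np.triu_indices(L, k=1)
    J[iu, ju] = Jt
    J[ju, iu] = Jt.transpose(0, 2, 1)
    return J


def fit_pseudolikelihood(
    aln: Alignment,
    l2_field: float = 0.01,
    l2_coupling: float = 0.005,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> PottsModel:
    """Fit a Potts model by L2-regularized pseudolikelihood maximization.

    Maximizes the sum over sites of the conditional log-likelihood
    log P(S_i | S_{\\i}) with penalties ``l2_field * sum(h**2)`` and
    ``l2_coupling * sum(J**2)``, via L-BFGS.  Deterministic given inputs.
    The returned model is in zero-sum gauge.

    Degenerate alignments (all sequences identical, or a column with a single
    observed state) trigger a warning and a heavy-regularization fallback that
    drives the affected couplings toward zero rather than crashing.

    Intended for desk-scale recovery experiments (L of order tens); it makes
    no attempt to reproduce any particular published kinome model.
    """
    if l2_field <= 0 or l2_coupling <= 0:
        raise ValueError("regularization weights must be positive")
    seqs = aln.seqs
    n, L = seqs.shape
    q = aln.q
    degenerate = False
    if np.unique(seqs, axis=0).shape[0] < 2:
        degenerate = True
        warnings.warn(
            "alignment has < 2 distinct sequences; couplings are not "
            "identifiable — falling back to heavy regularization",
            stacklevel=2,
        )
    single_state_cols = [i for i in range(L) if np.unique(seqs[:, i]).size < 2]
    if single_state_cols:
        degenerate = True
        warnings.warn(
            f"column(s) {single_state_cols} carry a single observed state; "
            "falling back to heavy regularization",
            stacklevel=2,
        )
    if degenerate:
        l2_field = max(l2_field, 1.0)
        l2_coupling = max(l2_coupling, 10.0)

    onehot = np.zeros((n, L, q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], seqs] = 1.0
    iu, ju = np.triu_indices(L, k=1)

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        h, Jt = _unpack(x, L, q)
        J = _full_J(Jt, L, q)
        nll = 0.0
        gh = np.zeros_like(h)
        gJ = np.zeros((L, L, q, q))
        for i in range(L):
            e = _conditional_energies(h, J, seqs, i)
            lz = logsumexp(-e, axis=1)
            nll += float((e[np.arange(n), seqs[:, i]] + lz).sum())
            p = np.exp(-e - lz[:, None])
            d = onehot[:, i, :] - p                     # (n, q)
            gh[i] = d.sum(axis=0)
            gJ[i] = np.einsum("na,njb->jab", d, onehot)
            gJ[i, i] = 0.0
        gJt = gJ[iu, ju] + gJ[ju, iu].transpose(0, 2, 1)
        nll /= n
        gh /= n
        gJt /= n
        nll += l2_field * float((h**2).sum()) + l2_coupling * float((Jt**2).sum())
        gh += 2.0 * l2_field * h
        gJt += 2.0 * l2_coupling * Jt
        return nll, _pack(gh, gJt)

    x0 = np.zeros(L * q + (L * (L - 1) // 2) * q * q)
    res = minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    if not res.success:
        logger.warning("pseudolikelihood optimizer stopped early: %s", res.message)
    h, Jt = _unpack(res.x, L, q)
    return zero_sum_gauge(PottsModel(h=h, J=_full_J(Jt, L, q), gauge="raw"))


def save_model(model: PottsModel, path) -> None:
    """Serialize a model: flat text container plus a JSON metadata sidecar.

    Layout of the flat file (one float per line): h row-major (L*q values),
    then J for i<j row-major (L*(L-1)/2 * q*q values).  The sidecar
    ``<path>.json`` records L, q, gauge label and energy offset.
    """
    L, q = model.L, model.q
    iu, ju = np.triu_indices(L, k=1)
    flat = np.concatenate([model.h.ravel(), model.J[iu, ju].ravel()])
    np.savetxt(path, flat, fmt="%.17g", header=f"{_MODEL_MAGIC} v{_MODEL_VERSION}")
    meta = {
        "format": _MODEL_MAGIC,
        "version": _MODEL_VERSION,
        "L": L,
        "q": q,
        "gauge": model.gauge,
        "offset": model.offset,
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path) -> PottsModel:
    """Inverse of :func:`save_model`."""
    with open(f"{path}.json") as fh:
        meta = json.load(fh)
    if meta.get("format") != _MODEL_MAGIC:
        raise ValueError(f"{path}.json is not a model sidecar")
    L, q = meta["L"], meta["q"]
    flat = np.loadtxt(path)
    nh = L * q
    h = flat[:nh].reshape(L, q)
    Jt = flat[nh:].reshape(-1, q, q)
    if Jt.shape[0] != L * (L - 1) // 2:
        raise ValueError("model file length inconsistent with sidecar L, q")
    return PottsModel(h=h, J=_full_J(Jt, L, q), gauge=meta["gauge"], offset=meta["offset"])
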