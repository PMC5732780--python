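"""Synthetic data with the statistical structure the model assumes.

Planted instances: a rank-r factor pair (U_true, V_true) defines interaction
probabilities sigmoid(U_true V_true^T); the binary matrix Y is sampled from
them.  Because sigmoid of a symmetric zero-mean logit has expectation 1/2
regardless of its scale, sparse regimes are reached through an intercept:
the last factor column is a constant pair (1, b), and b is solved by
bisection so the expected density matches the target.  Similarity matrices
are built from cosine proximity of the planted factor rows (mapped affinely
to [0, 1], optional additive noise, re-symmetrized, unit diagonal), so the
neighborhood-regularization assumption -- similar entities have similar
latent vectors -- holds by construction.

Sequence families for the alignment kernel are generated separately: one
random ancestor, each descendant mutated per-position with a fixed
substitution probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .exceptions import InputError
from .kernels import NUCLEOTIDE, PROTEIN, SequenceRecord, SimilarityMatrix
from .model import InteractionMatrix

#: logit scale of the random (signal) part of planted factors; chosen so a
#: planted instance carries strong low-rank signal (logit sd ~ 3)
DEFAULT_SIGNAL_SCALE = 3.0

_ALPHABETS = {NUCLEOTIDE: "ACGT", PROTEIN: "ACDEFGHIKLMNPQRSTVWY"}


@dataclass
class PlantedInstance:
    """A synthetic ground-truth world for the factorization model.

    ``Y`` is the training interaction matrix (masked positives removed);
    ``Y_full`` keeps the pre-mask sample and ``probabilities`` the planted
    sigmoid(U_true V_true^T).
    """

    U_true: np.ndarray
    V_true: np.ndarray
    Y: InteractionMatrix
    Y_full: np.ndarray
    probabilities: np.ndarray
    S_l: SimilarityMatrix
    S_p: SimilarityMatrix
    mask: list[tuple[int, int]]
    seed: int


def _cosine_similarity_01(F: np.ndarray, noise: float, rng) -> np.ndarray:
    """Row-cosine similarity mapped to [0,1], plus noise, symmetrized,
    clipped, unit diagonal."""
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    G = F / norms
    S = (1.0 + G @ G.T) / 2.0
    if noise > 0:
        S = S + rng.normal(0.0, noise, size=S.shape)
    S = (S + S.T) / 2.0
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def _solve_intercept(logits_random: np.ndarray, density_target: float) -> float:
    """Bisection for the intercept b with mean(sigmoid(logits + b)) =
    density_target; the mean is strictly increasing in b."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if expit(logits_random + mid).mean() < density_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate_planted_instance(
    m: int = 100,
    n: int = 30,
    r: int = 5,
    density_target: float = 0.15,
    sim_noise: float = 0.05,
    mask_fraction: float = 0.0,
    seed: int = 0,
    signal_scale: float = DEFAULT_SIGNAL_SCALE,
) -> PlantedInstance:
    """Sample a reproducible planted low-rank instance.

    The first r-1 factor columns are Normal(0, signal_scale/sqrt(r)); the
    last column is the (1, b) intercept pair calibrated by bisection so the
    expected interaction density matches ``density_target``.
    ``mask_fraction`` of the sampled positives are removed from the training
    matrix and listed in ``mask`` (for held-out evaluation).
    """
    if m < 2 or n < 2:
        raise InputError("need m >= 2 and n >= 2")
    if not (1 <= r < min(m, n)):
        raise InputError(f"rank r={r} must satisfy 1 <= r < min(m, n)={min(m, n)}")
    if not (0 < density_target < 1):
        raise InputError("density_target must lie in (0, 1)")
    if sim_noise < 0:
        raise InputError("sim_noise must be nonnegative")
    if not (0 <= mask_fraction < 1):
        raise InputError("mask_fraction must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    sd = signal_scale / np.sqrt(r)
    Zu = rng.normal(0.0, sd, size=(m, r - 1)) if r > 1 else np.zeros((m, 0))
    Zv = rng.normal(0.0, sd, size=(n, r - 1)) if r > 1 else np.zeros((n, 0))
    logits_random = Zu @ Zv.T
    b = _solve_intercept(logits_random, density_target)
    U_true = np.hstack([Zu, np.ones((m, 1))])
    V_true = np.hstack([Zv, np.full((n, 1), b)])

    probabilities = expit(U_true @ V_true.T)
    Y_full = (rng.random((m, n)) < probabilities).astype(float)

    lnc_ids = [f"lnc{i:04d}" for i in range(m)]
    prot_ids = [f"prot{j:03d}" for j in range(n)]
    S_l = SimilarityMatrix(lnc_ids, _cosine_similarity_01(U_true, sim_noise, rng))
    S_p = SimilarityMatrix(prot_ids, _cosine_similarity_01(V_true, sim_noise, rng))

    positives = np.argwhere(Y_full == 1)
    mask: list[tuple[int, int]] = []
    Y_train = Y_full.copy()
    if mask_fraction > 0 and len(positives) > 0:
        n_mask = int(round(mask_fraction * len(positives)))
        chosen = rng.choice(len(positives), size=n_mask, replace=False)
        for idx in sorted(chosen):
            i, j = positives[idx]
            mask.append((int(i), int(j)))
            Y_train[i, j] = 0.0

    Y = InteractionMatrix(lncrna_ids=lnc_ids, protein_ids=prot_ids, Y=Y_train)
    return PlantedInstance(
        U_true=U_true,
        V_true=V_true,
        Y=Y,
        Y_full=Y_full,
        probabilities=probabilities,
        S_l=S_l,
        S_p=S_p,
        mask=mask,
        seed=seed,
    )


def generate_sequence_family(
    n_seqs: int,
    length: int,
    mutation_rate: float,
    alphabet: str = NUCLEOTIDE,
    seed: int = 0,
) -> list[SequenceRecord]:
    """A mutant family: one uniform-random ancestor, each record derived by
    independent per-position substitution with probability
    ``mutation_rate`` (substitutions always change the residue).  Expected
    pairwise similarity decreases monotonically in the rate."""
    if n_seqs < 2:
        raise InputError("need at least 2 sequences")
    if length < 10:
        raise InputError("length must be >= 10")
    if not (0 <= mutation_rate <= 1):
        raise InputError("mutation_rate must lie in [0, 1]")
    if alphabet not in _ALPHABETS:
        raise InputError(f"unknown alphabet {alphabet!r}")

    letters = np.array(list(_ALPHABETS[alphabet]))
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(letters, size=length)
    records = []
    for s in range(n_seqs):
        seq = ancestor.copy()
        hits = rng.random(length) < mutation_rate
        for pos in np.flatnonzero(hits):
            options = letters[letters != seq[pos]]
            seq[pos] = rng.choice(options)
        records.append(
            SequenceRecord(id=f"seq{s:03d}", sequence="".join(seq), alphabet=alphabet)
        )
    return records
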