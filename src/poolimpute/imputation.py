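"""Li-Stephens haplotype-copying HMM imputation from genotype-probability
priors, one study sample at a time.

Each study genotype is modeled as an unordered pair of template haplotypes
drawn from a small reference panel (here the 16 homozygous founders of the
cross). Along the chromosome each of the two copied haplotypes switches
template with probability ``r = 1 - exp(-4 Ne d / k)`` over a genetic
distance of ``d`` Morgans (k templates, effective population size Ne); on a
switch the new template is uniform over all k. Each copied allele is read
with error probability ``lam`` per marker (the mutation parameter), and the
observation at a marker is the decoded prior simplex, so fully decoded
markers anchor the path while undecided (0.5, 0, 0.5) markers are free.

Posterior genotype probabilities come from the forward-backward state
marginals combined with the per-state conditional of the true genotype
given the local observation, ``P(g | state, obs) ∝ obs_g P(g | a1, a2)``.
With fully homozygous priors (p1 = 0) this keeps the heterozygote
probability exactly zero, as expected for inbred lines; a raw projection
onto the template-pair dosage is available as an alternative
(``projection="template"``). The recursion is carried
on ordered-pair k x k matrices for vectorization; with the exchangeable
initial distribution (uniform over unordered pairs) this is exactly the
unordered-pair chain with k(k+1)/2 states, at identical genotype
posteriors. Per-marker rescaling keeps the recursion finite for any number
of markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: smallest inter-marker distance (Morgans); keeps the chain irreducible
MIN_DISTANCE_MORGANS = 1e-8


class ImputationError(ValueError):
    pass


@dataclass
class ReferencePanel:
    """K phased haplotypes x M markers over alleles {0, 1}."""

    haplotypes: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 1:
            raise ImputationError("panel must be a K x M matrix with K >= 1")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ImputationError("panel alleles must be 0 or 1")
        if not self.labels:
            self.labels = [f"hap{i}" for i in range(self.haplotypes.shape[0])]

    @property
    def k(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class HMMParams:
    """Copying-model parameters.

    ne
        Effective population size scaling the switch rate; default 16, the
        size of the founder panel.
    lam
        Per-allele copying error (mutation) probability per marker.
    projection
        How state marginals become genotype posteriors: ``"conditional"``
        (default) weights each state by the true-genotype conditional given
        the observation and the mutation channel, so a zero-heterozygote
        prior yields a zero-heterozygote posterior; ``"template"`` projects
        raw state mass onto the template-pair dosage.
    haploid
        Use single-haplotype states (one copied template, duplicated into a
        homozygous genotype) instead of template pairs; only meaningful for
        fully inbred samples.
    """

    ne: float = 16.0
    lam: float = 1e-3
    projection: str = "conditional"
    haploid: bool = False

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ImputationError("ne must be positive")
        if not 0.0 <= self.lam < 0.5:
            raise ImputationError("lam must lie in [0, 0.5)")
        if self.projection not in ("conditional", "template"):
            raise ImputationError("projection must be 'conditional' or 'template'")


def switch_probability(d: float | np.ndarray, ne: float, k: int) -> np.ndarray:
    """Per-copy template switch probability over ``d`` Morgans.

    ``r = 1 - exp(-4 Ne d / k)``; on a switch the new template is uniform
    over all k haplotypes (so the copy may land back on the same one).
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ImputationError("genetic distance must be non-negative")
    return -np.expm1(-4.0 * ne * d / k)


def allele_copy_table(lam: float) -> np.ndarray:
    """``T[a1, a2, g]`` = P(true dosage g | template alleles a1, a2).

    Each template allele is copied with independent flip probability lam;
    the dosage is the sum of the two copied alleles.
    """
    flip = np.array([[1.0 - lam, lam], [lam, 1.0 - lam]])  # flip[a, c]
    T = np.zeros((2, 2, 3))
    for a1 in (0, 1):
        for a2 in (0, 1):
            for c1 in (0, 1):
                for c2 in (0, 1):
                    T[a1, a2, c1 + c2] += flip[a1, c1] * flip[a2, c2]
    return T


def emission_probability(
    obs: np.ndarray, state_alleles: tuple[int, int], lam: float
) -> float:
    """P(observed simplex | template pair) = sum_g obs_g P(g | a1, a2)."""
    T = allele_copy_table(lam)
    a1, a2 = state_alleles
    return float(np.dot(np.asarray(obs, dtype=float), T[a1, a2]))


def _pair_distances(cm: np.ndarray) -> np.ndarray:
    """cM positions -> M-1 inter-marker distances in Morgans, floored."""
    d = np.diff(np.asarray(cm, dtype=float)) / 100.0
    if (d < 0).any():
        raise ImputationError("genetic positions must be non-decreasing")
    return np.maximum(d, MIN_DISTANCE_MORGANS)


def _transition_matrix(r: float, k: int) -> np.ndarray:
    """Single-copy transition: stay w.p. 1-r, else uniform over k."""
    return (1.0 - r) * np.eye(k) + (r / k) * np.ones((k, k))


def forward_backward(
    sample_obs: np.ndarray,
    panel: ReferencePanel,
    distances: np.ndarray,
    params: HMMParams,
) -> np.ndarray:
    """Posterior genotype simplexes for one sample (M x 3).

    ``sample_obs`` is the M x 3 prior simplex sequence; ``distances`` the
    M-1 inter-marker distances in Morgans.
    """
    obs = np.asarray(sample_obs, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ImputationError("sample observations must be M x 3 simplexes")
    if obs.shape[0] != panel.n_markers:
        raise ImputationError(
            f"marker mismatch: {obs.shape[0]} observations vs "
            f"{panel.n_markers} panel markers"
        )
    return impute_population(obs[None, :, :], panel, distances, params)[0]


def impute_population(
    decoded: np.ndarray,
    panel: ReferencePanel,
    distances: np.ndarray,
    params: HMMParams = HMMParams(),
    chunk_size: int = 128,
) -> np.ndarray:
    """Impute every sample independently; (N, M, 3) posterior simplexes.

    Samples are processed in chunks purely for vectorization; results do
    not depend on chunking or evaluation order.
    """
    decoded = np.asarray(decoded, dtype=float)
    if decoded.ndim != 3 or decoded.shape[2] != 3:
        raise ImputationError("decoded matrix must be N x M x 3")
    N, M, _ = decoded.shape
    if M != panel.n_markers:
        raise ImputationError("marker mismatch between decoded matrix and panel")
    if N == 0:
        return np.zeros((0, M, 3))
    distances = np.asarray(distances, dtype=float)
    if distances.shape != (max(M - 1, 0),):
        raise ImputationError(f"need {M - 1} inter-marker distances")

    k = panel.k
    r = switch_probability(distances, params.ne, k)
    A = [_transition_matrix(float(ri), k) for ri in r]
    T = allele_copy_table(params.lam)
    hap = panel.haplotypes
    if params.haploid:
        # single-copy chain: state = one template, genotype = doubled allele
        pair_T = T[hap, hap]  # (k, M, 3)
        pi = np.full(k, 1.0 / k)
    else:
        # per-marker k x k emission factor tables over template pairs
        pair_T = T[hap[:, None, :], hap[None, :, :]]  # (k, k, M, 3)
        # exchangeable initial distribution: uniform over unordered pairs
        n_unordered = k * (k + 1) // 2
        pi = np.full((k, k), 0.5 / n_unordered)
        np.fill_diagonal(pi, 1.0 / n_unordered)

    out = np.empty((N, M, 3))
    for lo in range(0, N, chunk_size):
        sl = slice(lo, min(lo + chunk_size, N))
        out[sl] = _fb_chunk(decoded[sl], pair_T, pi, A, params)
    return out


def _genotype_weights(obs_m: np.ndarray, pair_T_m: np.ndarray, projection: str):
    """Per-state emission and genotype attribution for one marker.

    Returns ``(E, W)`` with ``E[s, ...]`` the emission probability per
    state and ``W[s, ..., g]`` the genotype distribution each unit of state
    mass contributes: the conditional ``P(g | state, obs)`` by default, or
    the one-hot template dosage under ``projection="template"``.
    """
    joint = obs_m[:, None, None, :] * pair_T_m[None] if pair_T_m.ndim == 3 \
        else obs_m[:, None, :] * pair_T_m[None]
    E = joint.sum(axis=-1)
    if projection == "template":
        dosage = pair_T_m.argmax(axis=-1)  # valid only at lam < 0.5
        W = np.broadcast_to(np.eye(3)[dosage], joint.shape)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(E[..., None] > 0, joint / E[..., None], 0.0)
    return E, W


def _fb_chunk(obs, pair_T, pi, A, params) -> np.ndarray:
    S, M = obs.shape[:2]
    haploid = pi.ndim == 1
    state_shape = pi.shape
    sum_axes = (1,) if haploid else (1, 2)

    def step(X, m):
        # one transition application: A x (A x) along each copied haplotype
        if haploid:
            return np.matmul(X, A[m])
        return np.matmul(np.matmul(A[m], X), A[m])

    def em(m):
        return _genotype_weights(
            obs[:, m], pair_T[:, m] if haploid else pair_T[:, :, m],
            params.projection,
        )

    fwd = np.empty((M, S) + state_shape)
    E, _ = em(0)
    F = _rescale(pi[None] * E, 0, sum_axes)
    fwd[0] = F
    for m in range(1, M):
        E, _ = em(m)
        F = _rescale(step(F, m - 1) * E, m, sum_axes)
        fwd[m] = F

    post = np.empty((S, M, 3))
    B = np.ones((S,) + state_shape)
    for m in range(M - 1, -1, -1):
        E, W = em(m)
        G = fwd[m] * B
        G /= G.sum(axis=sum_axes, keepdims=True)
        post[:, m] = (G[..., None] * W).sum(axis=sum_axes)
        if m > 0:
            B = step(B * E, m - 1)
            B /= B.sum(axis=sum_axes, keepdims=True)
    return post


def _rescale(F: np.ndarray, m: int, sum_axes) -> np.ndarray:
    c = F.sum(axis=sum_axes, keepdims=True)
    if (c <= 0).any():
        raise ImputationError(
            f"zero likelihood at marker index {m}; observations contradict "
            "every template pair — use lam > 0"
        )
    return F / c


def panel_from_matrix(dosages: np.ndarray, labels: list[str]) -> ReferencePanel:
    """Build a haploid panel from fully homozygous diploid dosages.

    Each homozygous founder contributes one template haplotype
    (allele = dosage / 2). Unphased homozygous records are accepted since
    phasing them is trivial.
    """
    d = np.asarray(dosages)
    if (d == 1).any() or (d < 0).any():
        raise ImputationError(
            "reference panel must be fully homozygous with no missing calls"
        )
    return ReferencePanel(haplotypes=(d // 2).astype(np.int8), labels=list(labels))
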