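"""Locus-level ancestry inference from unphased genotypes.

A three-state hidden Markov model over the unordered ancestry diplotype
{AFR/AFR, AFR/EAS, EAS/EAS} of an admixed individual along one chromosome.
Each haplotype follows an independent two-state chain: at stationarity a
locus copy is African with probability alpha, and between adjacent markers
separated by genetic distance d (morgans) the copy's ancestry survives
un-recombined with probability exp(-g d) for g generations since admixture,
otherwise it is redrawn from the admixture prior. The diplotype chain is the
product of the two haplotype chains collapsed to unordered states.

Emissions assume within-source Hardy–Weinberg proportions and independence
of the two locus copies: given the diplotype state, the observed genotype
(alternate-allele dosage 0/1/2) is a sum of two Bernoulli draws with the
source-specific allele frequencies. Decoding is scaled forward–backward
(posterior marginals), numerically safe for long panels.

This is a deliberately simplified single-layer model: production local
ancestry tools additionally model haplotype structure within each source
(two-layer HMMs); externally produced calls can be supplied instead of this
decoder anywhere downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .panel import MarkerPanel

__all__ = [
    "STATES",
    "AncestryHmm",
    "DiplotypeCall",
    "build_hmm",
    "posterior_decode",
    "posterior_decode_matrix",
    "call_locus",
    "ancestry_dosage",
]

#: Unordered ancestry diplotype states, in fixed index order.
STATES = ("AFR/AFR", "AFR/EAS", "EAS/EAS")
UNASSIGNED = "UNASSIGNED"

#: African copy count of each state (used for dosages and genotype draws).
AFR_COPIES = np.array([2, 1, 0])


@dataclass(frozen=True)
class AncestryHmm:
    """Diplotype HMM: stationary prior, per-interval transition matrices, and
    per-marker emission tables P(genotype | state)."""

    panel: MarkerPanel
    alpha: float
    generations: float
    prior: np.ndarray         # (3,)
    transitions: np.ndarray   # (m-1, 3, 3)
    emissions: np.ndarray     # (m, 3, 3): marker x state x genotype dosage

    def __post_init__(self) -> None:
        if not math.isclose(float(self.prior.sum()), 1.0, abs_tol=1e-12):
            raise ValueError("prior must sum to 1")
        if self.transitions.size and np.abs(self.transitions.sum(axis=2) - 1).max() > 1e-12:
            raise ValueError("transition rows must sum to 1")
        if np.abs(self.emissions.sum(axis=2) - 1).max() > 1e-9:
            raise ValueError("emission rows must sum to 1 over genotypes")


@dataclass(frozen=True)
class DiplotypeCall:
    state: str  # one of STATES or UNASSIGNED
    posterior: float
    locus_index: int


def _haplotype_transition(alpha: float, s: float) -> np.ndarray:
    """2x2 single-copy chain: recombine with probability s, then redraw the
    source from the admixture prior."""
    stay = np.eye(2)
    redraw = np.array([[alpha, 1 - alpha], [alpha, 1 - alpha]])
    return (1 - s) * stay + s * redraw


def _diplotype_from_haplotype(P: np.ndarray) -> np.ndarray:
    """Collapse the ordered product chain of two i.i.d. copies to the
    unordered 3-state chain (2, 1, 0 African copies)."""
    pAA, pAE = P[0, 0], P[0, 1]
    pEA, pEE = P[1, 0], P[1, 1]
    T = np.empty((3, 3))
    # from 2 African copies
    T[0] = [pAA * pAA, 2 * pAA * pAE, pAE * pAE]
    # from 1 African + 1 East Asian copy
    T[1] = [pAA * pEA, pAA * pEE + pAE * pEA, pAE * pEE]
    # from 2 East Asian copies
    T[2] = [pEA * pEA, 2 * pEA * pEE, pEE * pEE]
    return T


def _emission_table(panel: MarkerPanel) -> np.ndarray:
    """P(dosage 0/1/2 | state) per marker from two independent copies."""
    fa, fe = panel.f_alt_afr, panel.f_alt_eas
    pairs = [(fa, fa), (fa, fe), (fe, fe)]  # state order AFR/AFR, AFR/EAS, EAS/EAS
    E = np.empty((len(panel), 3, 3))
    for s, (f1, f2) in enumerate(pairs):
        E[:, s, 0] = (1 - f1) * (1 - f2)
        E[:, s, 1] = f1 * (1 - f2) + f2 * (1 - f1)
        E[:, s, 2] = f1 * f2
    return E


def build_hmm(panel: MarkerPanel, alpha: float, generations: float) -> AncestryHmm:
    """Assemble the diplotype HMM for a panel at admixture proportion
    ``alpha`` and ``generations`` since the admixture pulse.

    The per-haplotype switch probability over an interval of d morgans is
    s = 1 - exp(-g d); the two copies switch independently.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if alpha in (0.0, 1.0):
        warnings.warn("degenerate admixture proportion: prior collapses to one source",
                      stacklevel=2)
    prior = np.array([alpha**2, 2 * alpha * (1 - alpha), (1 - alpha) ** 2])
    d = np.diff(panel.positions_morgans)
    s = 1 - np.exp(-generations * d)
    transitions = np.stack(
        [_diplotype_from_haplotype(_haplotype_transition(alpha, si)) for si in s]
    ) if len(d) else np.empty((0, 3, 3))
    return AncestryHmm(
        panel=panel, alpha=float(alpha), generations=float(generations),
        prior=prior, transitions=transitions, emissions=_emission_table(panel),
    )


def _likelihoods(hmm: AncestryHmm, G: np.ndarray) -> np.ndarray:
    """Per-individual per-marker emission likelihood (n, m, 3); missing
    genotypes (< 0) emit 1 for every state."""
    m = len(hmm.panel)
    G = np.asarray(G)
    if G.ndim == 1:
        G = G[None, :]
    if G.shape[1] != m:
        raise ValueError(f"genotype vectors have {G.shape[1]} markers, panel has {m}")
    n = G.shape[0]
    L = np.ones((n, m, 3))
    obs = G >= 0
    idx_i, idx_m = np.nonzero(obs)
    L[idx_i, idx_m, :] = hmm.emissions[idx_m, :, G[idx_i, idx_m]]
    return L


def posterior_decode_matrix(hmm: AncestryHmm, genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward–backward over a (n_individuals, n_markers) dosage
    matrix. Returns ``(posteriors, loglik)`` with posteriors of shape
    (n, m, 3) and per-individual log marginal likelihoods."""
    L = _likelihoods(hmm, genotypes)
    n, m, _ = L.shape
    T = hmm.transitions
    alpha_f = np.empty((n, m, 3))
    scale = np.empty((n, m))
    a = hmm.prior[None, :] * L[:, 0, :]
    scale[:, 0] = a.sum(axis=1)
    if np.any(scale[:, 0] == 0):
        bad = int(np.argmax(scale[:, 0] == 0))
        raise ValueError(
            f"all-zero emission likelihood at marker 0 for individual {bad}"
        )
    alpha_f[:, 0] = a / scale[:, 0, None]
    for k in range(1, m):
        a = (alpha_f[:, k - 1] @ T[k - 1]) * L[:, k]
        scale[:, k] = a.sum(axis=1)
        if np.any(scale[:, k] == 0):
            bad = int(np.argmax(scale[:, k] == 0))
            raise ValueError(
                f"all-zero emission likelihood at marker {k} for individual {bad}"
            )
        alpha_f[:, k] = a / scale[:, k, None]
    beta = np.empty((n, m, 3))
    beta[:, m - 1] = 1.0
    for k in range(m - 2, -1, -1):
        b = (beta[:, k + 1] * L[:, k + 1]) @ T[k].T
        beta[:, k] = b / scale[:, k + 1, None]
    post = alpha_f * beta
    post /= post.sum(axis=2, keepdims=True)
    loglik = np.log(scale).sum(axis=1)
    return post, loglik


def posterior_decode(hmm: AncestryHmm, genotypes) -> np.ndarray:
    """Posterior state marginals (n_markers, 3) for one individual."""
    post, _ = posterior_decode_matrix(hmm, np.asarray(genotypes))
    return post[0]


def call_locus(posterior: np.ndarray, locus_index: int, threshold: float = 0.9) -> DiplotypeCall:
    """Hard diplotype call at one marker: the argmax state when its posterior
    reaches ``threshold``, otherwise UNASSIGNED."""
    posterior = np.asarray(posterior)
    if not 0 <= locus_index < posterior.shape[0]:
        raise IndexError(f"locus index {locus_index} outside panel")
    row = posterior[locus_index]
    best = int(np.argmax(row))
    if row[best] >= threshold:
        return DiplotypeCall(STATES[best], float(row[best]), locus_index)
    return DiplotypeCall(UNASSIGNED, float(row[best]), locus_index)


def ancestry_dosage(posterior: np.ndarray, locus_index: int) -> float:
    """Expected African copy count in [0, 2] at one marker."""
    posterior = np.asarray(posterior)
    if not 0 <= locus_index < posterior.shape[0]:
        raise IndexError(f"locus index {locus_index} outside panel")
    return float(posterior[locus_index] @ AFR_COPIES)
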