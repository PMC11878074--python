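"""Signed weighted co-occurrence networks from relative-abundance data.

A network is built per cohort by (1) estimating a pairwise correlation
matrix between taxa (Spearman, Pearson, or a compositional SparCC-style
estimator) and (2) thresholding on absolute correlation.  Edge weights
store correlation magnitudes (the weight matrix doubles as the stiffness
matrix downstream, with a unit diagonal so it is typically diagonally
dominant and invertible); edge signs are kept separately for the
positive/negative (P/N) edge-ratio analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sparcc import sparcc_correlations
from .study import AbundanceStudy

logger = logging.getLogger(__name__)

#: sentinel P/N ratio of a subgraph with positive but no negative edges,
#: serialized as an en-dash in result tables.
POSITIVE_ONLY = "POSITIVE_ONLY"
#: sentinel P/N ratio of an empty edge set.
NO_EDGES = "NO_EDGES"

PN_SERIALIZATION = {POSITIVE_ONLY: "–", NO_EDGES: "NA"}


@dataclass
class NetworkConfig:
    """Parameters of cohort network construction.

    Attributes
    ----------
    estimator : {"spearman", "pearson", "sparcc"}
        Pairwise association estimator. Rank correlation is the default
        (robust to compositional skew); SparCC is the compositional
        log-ratio estimator used for first-order-neighbor graphs.
    min_abs_corr : float
        Edges are retained iff ``|corr| >= min_abs_corr``.  Network
        topology is sensitive to this cutoff, so it is always explicit.
    min_prevalence : float
        Fraction of all samples in which a taxon must be nonzero.
    pseudocount : float
        Added to zeros before log-ratio steps (sparcc only).
    sparcc_iterations : int
        Number of strongly-correlated-pair exclusion rounds.
    """

    estimator: str = "spearman"
    min_abs_corr: float = 0.3
    min_prevalence: float = 0.1
    pseudocount: float = 1e-6
    sparcc_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.estimator not in ("spearman", "pearson", "sparcc"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if not 0 <= self.min_abs_corr < 1:
            raise ValueError("min_abs_corr must be in [0, 1)")
        if not 0 < self.min_prevalence <= 1:
            if self.min_prevalence != 0:
                raise ValueError("min_prevalence must be in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class CooccurrenceNetwork:
    """Signed weighted co-occurrence graph over taxa.

    ``W`` stores correlation magnitudes with unit diagonal, ``sign`` the
    edge signs in {-1, 0, +1}, and ``A`` the 0/1 adjacency (zero
    diagonal).  Entries with ``A_ij = 0`` are zero in ``W`` and treated
    as absent in every stiffness computation.
    """

    taxa: list[str]
    W: np.ndarray
    sign: np.ndarray
    A: np.ndarray
    estimator_tag: str = "unspecified"
    zero_variance_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.sign = np.asarray(self.sign, dtype=int)
        self.A = np.asarray(self.A, dtype=int)
        n = len(self.taxa)
        for name, m in (("W", self.W), ("sign", self.sign), ("A", self.A)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {m.shape}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if np.any(np.abs(self.W - np.diag(np.diag(self.W))) > 1 + 1e-12):
            raise ValueError("off-diagonal |W| must be <= 1")
        # correlation-built networks carry a unit diagonal; hollow (zero
        # diagonal) and general nonnegative diagonals are tolerated so the
        # container can hold arbitrary stiffness matrices
        if np.any(np.diag(self.W) < 0):
            raise ValueError("W diagonal must be nonnegative")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("A must have zero diagonal")
        if np.any((self.A == 1) & (self.sign == 0)):
            raise ValueError("retained edges must carry a nonzero sign")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_adjacency(cls, taxa: list[str], A: np.ndarray,
                       unit_diagonal: bool = False) -> "CooccurrenceNetwork":
        """Unweighted network with ``W = A`` (optionally plus identity)."""
        A = np.asarray(A, dtype=int)
        W = A.astype(float)
        if unit_diagonal:
            W = W + np.eye(len(taxa))
        return cls(taxa=list(taxa), W=W, sign=A.copy(), A=A.copy(),
                   estimator_tag="adjacency")

    # -- accessors --------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def effective_weights(self) -> np.ndarray:
        """Weight matrix with non-edges zeroed (diagonal kept)."""
        masked = self.W * self.A
        np.fill_diagonal(masked, np.diag(self.W))
        return masked

    @property
    def signed_weights(self) -> np.ndarray:
        """Signed edge weights (sign * magnitude), zero diagonal."""
        out = self.W * self.A * self.sign
        np.fill_diagonal(out, 0.0)
        return out

    def degree(self) -> np.ndarray:
        return self.A.sum(axis=1)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected retained edges as (i, j) index pairs with i < j."""
        iu, ju = np.triu_indices(self.n_taxa, k=1)
        keep = self.A[iu, ju] == 1
        return list(zip(iu[keep].tolist(), ju[keep].tolist()))


# -- operations ------------------------------------------------------------


def filter_taxa(study: AbundanceStudy, cfg: NetworkConfig) -> AbundanceStudy:
    """Drop taxa present in fewer than ``min_prevalence`` of all samples.

    Presence means abundance strictly positive.  Taxa order is preserved.
    Raises if fewer than 3 taxa survive (a network over <3 nodes carries
    no usable structure).
    """
    if cfg.min_prevalence == 0:
        return study
    frac = (study.abundance > 0).mean(axis=1)
    keep = [t for t, f in zip(study.taxa, frac) if f >= cfg.min_prevalence]
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} taxa pass prevalence >= {cfg.min_prevalence}; "
            "need at least 3 for a network"
        )
    if len(keep) == study.n_taxa:
        return study
    return study.restrict_taxa(keep)


def _rank_transform(matrix: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, matrix)


def estimate_correlations(study: AbundanceStudy, cfg: NetworkConfig,
                          cohort: str | None = None) -> np.ndarray:
    """Pairwise taxon-taxon correlation matrix for one cohort.

    Parameters
    ----------
    study : AbundanceStudy
    cfg : NetworkConfig
    cohort : "A", "B" or None
        Restrict to one cohort's samples; ``None`` uses all samples.

    Returns
    -------
    ndarray (n_taxa x n_taxa)
        Symmetric, unit diagonal, entries in [-1, 1].  Zero-variance
        taxa get zero correlations (flagged via log, not NaN).
    """
    data = study.abundance if cohort is None else study.cohort_matrix(cohort)
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    if cfg.estimator == "sparcc":
        corr = sparcc_correlations(
            data, pseudocount=cfg.pseudocount,
            exclusion_iterations=cfg.sparcc_iterations,
        )
    else:
        obs = _rank_transform(data) if cfg.estimator == "spearman" else data
        sd = obs.std(axis=1)
        flat = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(obs)
        corr = np.nan_to_num(corr, nan=0.0)
        if flat.any():
            names = [t for t, z in zip(study.taxa, flat) if z]
            logger.warning("zero-variance taxa, correlations set to 0: %s",
                           names)
            corr[flat, :] = 0.0
            corr[:, flat] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def build_network(taxa: list[str], corr: np.ndarray,
                  cfg: NetworkConfig) -> CooccurrenceNetwork:
    """Threshold a correlation matrix into a signed co-occurrence network.

    An edge i-j is retained iff ``|corr_ij| >= min_abs_corr`` and i != j;
    its weight is ``|corr_ij|`` and its sign ``sign(corr_ij)``.  The
    weight matrix keeps a unit diagonal.
    """
    corr = np.asarray(corr, dtype=float)
    n = len(taxa)
    if corr.shape != (n, n):
        raise ValueError("correlation matrix does not match taxa")
    A = (np.abs(corr) >= cfg.min_abs_corr).astype(int)
    np.fill_diagonal(A, 0)
    sign = np.sign(corr).astype(int) * A
    W = np.abs(corr) * A
    np.fill_diagonal(W, 1.0)
    return CooccurrenceNetwork(taxa=list(taxa), W=W, sign=sign, A=A,
                               estimator_tag=cfg.estimator)


def build_cohort_network(study: AbundanceStudy, cfg: NetworkConfig,
                         cohort: str) -> CooccurrenceNetwork:
    """Convenience: correlation estimation + thresholding for one cohort."""
    corr = estimate_correlations(study, cfg, cohort=cohort)
    return build_network(study.taxa, corr, cfg)


def pn_ratio(net: CooccurrenceNetwork,
             edge_subset: set[tuple[int, int]] | None = None):
    """Ratio of positive (cooperative) to negative (competitive) edges.

    Returns a float, or ``POSITIVE_ONLY`` when there are positive edges
    but no negative ones (serialized as an en-dash in tables), or
    ``NO_EDGES`` for an empty edge set.
    """
    edges = net.edges()
    if edge_subset is not None:
        subset = {(min(i, j), max(i, j)) for i, j in edge_subset}
        missing = subset - set(edges)
        if missing:
            raise ValueError(f"edge subset not in network: {sorted(missing)}")
        edges = [e for e in edges if e in subset]
    return pn_ratio_from_signs([net.sign[i, j] for i, j in edges])


def pn_ratio_from_signs(signs):
    """P/N ratio from an iterable of edge signs in {-1, +1}."""
    signs = list(signs)
    pos = sum(1 for s in signs if s > 0)
    neg = sum(1 for s in signs if s < 0)
    if pos == 0 and neg == 0:
        return NO_EDGES
    if neg == 0:
        return POSITIVE_ONLY
    return pos / neg


def format_pn(value) -> str:
    """Serialize a P/N ratio for result tables ('–' when positive-only)."""
    if isinstance(value, str):
        return PN_SERIALIZATION.get(value, value)
    return f"{value:.4g}"
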