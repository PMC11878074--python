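"""Two-cohort compositional data with a known correlation backbone.

Samples are drawn from a logistic-normal model: a multivariate normal on
the log scale with a block-structured correlation matrix (the backbone),
exponentiated and renormalized to per-sample proportions.  Cohort B can
carry planted relationship alterations — a chosen taxon subset whose
pairwise correlations are sign-flipped, removed, or strengthened —
while both cohorts share the same log-scale mean vector, so the planted
signal lives purely in the association structure, not in the marginal
abundances.  Zero inflation is applied as a post-hoc Bernoulli mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .study import COHORT_A, COHORT_B, AbundanceStudy, normalize_columns

logger = logging.getLogger(__name__)

REWIRE_MODES = ("sign_flip", "decorrelate", "strengthen")
_STRENGTHEN_TO = 0.9


@dataclass
class SyntheticSpec:
    """Generator settings.

    Attributes
    ----------
    n_taxa, n_samples_a, n_samples_b : int
        Community size and cohort sample counts.
    blocks : list of (size, rho)
        Correlated blocks laid out consecutively from taxon 0; taxa not
        covered by any block are independent.  rho in (-1, 1).
    planted_subset : list of int
        Taxon indices whose mutual cohort-B correlations are rewired.
    rewire_mode : {"sign_flip", "decorrelate", "strengthen"}
    mean_logabund : array or None
        Log-scale means; default is a linear ramp from 0 down to -2,
        giving realistically uneven taxon abundances.
    zero_inflation : float in [0, 1)
        Probability of zeroing an entry before renormalization.
    """

    n_taxa: int = 40
    n_samples_a: int = 30
    n_samples_b: int = 30
    blocks: list[tuple[int, float]] = field(default_factory=list)
    planted_subset: list[int] = field(default_factory=list)
    rewire_mode: str = "sign_flip"
    mean_logabund: np.ndarray | None = None
    log_sd: float = 1.0
    zero_inflation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rewire_mode not in REWIRE_MODES:
            raise ValueError(f"unknown rewire mode {self.rewire_mode!r}")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        if any(not 0 <= i < self.n_taxa for i in self.planted_subset):
            raise ValueError("planted_subset indices out of range")
        for size, rho in self.blocks:
            if not -1 < rho < 1:
                raise ValueError("block correlation must be in (-1, 1)")
        if sum(size for size, _ in self.blocks) > self.n_taxa:
            raise ValueError("blocks exceed number of taxa")
        if self.mean_logabund is None:
            self.mean_logabund = np.linspace(0.0, -2.0, self.n_taxa)
        else:
            self.mean_logabund = np.asarray(self.mean_logabund, dtype=float)
            if self.mean_logabund.shape != (self.n_taxa,):
                raise ValueError("mean_logabund length must equal n_taxa")


@dataclass
class GroundTruth:
    """What the generator planted: taxa and both true correlations."""

    planted: list[int]
    corr_a: np.ndarray
    corr_b: np.ndarray
    taxa: list[str] = field(default_factory=list)

    def planted_taxa(self) -> list[str]:
        return [self.taxa[i] for i in self.planted]


def backbone_correlation(spec: SyntheticSpec) -> np.ndarray:
    """Block-diagonal backbone correlation matrix for cohort A."""
    corr = np.eye(spec.n_taxa)
    start = 0
    for size, rho in spec.blocks:
        block = np.full((size, size), rho)
        np.fill_diagonal(block, 1.0)
        corr[start:start + size, start:start + size] = block
        start += size
    return nearest_psd(corr)


def rewire_correlation(corr: np.ndarray, planted: list[int],
                       mode: str) -> np.ndarray:
    """Alter the mutual correlations of the planted taxa.

    sign_flip negates, decorrelate zeroes, strengthen pushes the
    magnitude up to at least 0.9 (keeping the sign; uncorrelated planted
    pairs are set to +0.9).
    """
    out = corr.copy()
    for a_idx, i in enumerate(planted):
        for j in planted[a_idx + 1:]:
            r = out[i, j]
            if mode == "sign_flip":
                new = -r
            elif mode == "decorrelate":
                new = 0.0
            else:  # strengthen
                s = np.sign(r) if r != 0 else 1.0
                new = s * max(abs(r), _STRENGTHEN_TO)
            out[i, j] = out[j, i] = new
    return nearest_psd(out)


def nearest_psd(corr: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    sym = (corr + corr.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    if eigval.min() >= min_eig:
        return sym
    logger.warning("correlation matrix not PSD (min eig %.3g); repairing",
                   eigval.min())
    repaired = (eigvec * np.maximum(eigval, min_eig)) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _draw_cohort(spec: SyntheticSpec, corr: np.ndarray, n_samples: int,
                 rng: np.random.Generator) -> np.ndarray:
    cov = corr * spec.log_sd ** 2
    logs = rng.multivariate_normal(spec.mean_logabund, cov, size=n_samples,
                                   method="eigh")
    raw = np.exp(logs).T  # taxa x samples
    if spec.zero_inflation > 0:
        mask = rng.random(raw.shape) < spec.zero_inflation
        # never zero a sample's most abundant taxon: keeps columns valid
        mask[raw.argmax(axis=0), np.arange(raw.shape[1])] = False
        raw = raw * ~mask
    return normalize_columns(raw)


def generate_study(spec: SyntheticSpec) -> tuple[AbundanceStudy, GroundTruth]:
    """Draw a two-cohort study plus its ground truth.

    Cohort A follows the backbone correlations; cohort B the rewired
    matrix (identical when no subset is planted).  Both cohorts share
    the log-scale mean vector, so marginal abundances are exchangeable.
    Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    corr_a = backbone_correlation(spec)
    if spec.planted_subset:
        corr_b = rewire_correlation(corr_a, list(spec.planted_subset),
                                    spec.rewire_mode)
    else:
        corr_b = corr_a.copy()
    abund_a = _draw_cohort(spec, corr_a, spec.n_samples_a, rng)
    abund_b = _draw_cohort(spec, corr_b, spec.n_samples_b, rng)
    taxa = [f"taxon_{i:03d}" for i in range(spec.n_taxa)]
    samples = ([f"A{k:03d}" for k in range(spec.n_samples_a)]
               + [f"B{k:03d}" for k in range(spec.n_samples_b)])
    cohort = {s: (COHORT_A if s.startswith("A") else COHORT_B)
              for s in samples}
    study = AbundanceStudy(
        taxa=taxa, samples=samples,
        abundance=np.hstack([abund_a, abund_b]), cohort=cohort,
    )
    truth = GroundTruth(planted=list(spec.planted_subset),
                        corr_a=corr_a, corr_b=corr_b, taxa=taxa)
    return study, truth


PLANTED = "PLANTED"
UNPLANTED = "UNPLANTED"


def truth_labels(truth: GroundTruth) -> dict[str, str]:
    """Per-taxon {PLANTED, UNPLANTED} partition."""
    planted = set(truth.planted)
    return {t: (PLANTED if i in planted else UNPLANTED)
            for i, t in enumerate(truth.taxa)}
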