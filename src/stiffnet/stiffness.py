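"""The five network-stiffness parameters.

The weight matrix W of a co-occurrence network is treated as the
stiffness matrix K of a structural framework, linking force and
displacement vectors on the nodes through f = W d.  The displacement is
the change in a node attribute (per-taxon mean relative abundance)
between the two cohorts.  Five per-taxon parameters follow:

* force        f = W d                       (cause of the observed change)
* displacement d = W^{-1} f                  (effect of a known force)
* stiffness scale s_i = x_i / sum_j w_ij y_j, the diagonal rescaling
  such that diag(s) W maps the reference state y onto the condition
  state x
* impact       I_i = sum_j A_ij G_ji, the mean neighborhood response to
  perturbing node i
* stability    S_i = 1 / sum_j A_ij G_ij, the inverse response of node i
  to perturbations of its neighbors

where G_ij = |(dx_i/x_i) / (dx_j/x_j)| is the perturbation (relative
response) matrix.  Undefined entries (zero denominators, isolated
nodes) are carried as NaN plus an explicit mask — never silently zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import CooccurrenceNetwork
from .study import NodeAttribute

logger = logging.getLogger(__name__)

_ZERO_TOL = 1e-12
_CONDITION_CAP = 1e12


@dataclass
class StiffnessConfig:
    """Numerical settings for stiffness computations."""

    pseudocount: float = 1e-6       # zero-replacement in relative changes
    condition_cap: float = _CONDITION_CAP  # switch to least squares above
    scale_x_state: str = "B"        # stiffness scale maps y=A onto x=B


@dataclass
class PerturbationMatrix:
    """Pairwise relative-response ratios G_ij = |r_i / r_j|.

    ``defined_mask[i, j]`` is False where the denominator's relative
    change r_j vanishes.
    """

    taxa: list[str]
    G: np.ndarray
    defined_mask: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        if self.G.shape != self.defined_mask.shape:
            raise ValueError("G and mask shapes differ")
        defined = self.G[self.defined_mask]
        if defined.size and np.any(defined < 0):
            raise ValueError("G entries must be nonnegative where defined")


@dataclass
class StiffnessProfile:
    """Per-taxon stiffness parameters for one cohort-pair comparison.

    Vectors are aligned to ``taxa``; undefined entries are NaN with the
    matching ``*_defined`` mask False.  ``regularized`` is set when the
    weight matrix was singular/ill-conditioned and the displacement was
    obtained by minimum-norm least squares.
    """

    taxa: list[str]
    force: np.ndarray
    displacement: np.ndarray
    stiffness_scale: np.ndarray
    impact: np.ndarray
    stability: np.ndarray
    scale_defined: np.ndarray
    impact_defined: np.ndarray
    stability_defined: np.ndarray
    regularized: bool = False
    notes: list[str] = field(default_factory=list)

    PARAMETERS = ("stiffness_scale", "impact", "stability")

    def parameter(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def defined(self, name: str) -> np.ndarray:
        masks = {"stiffness_scale": self.scale_defined,
                 "impact": self.impact_defined,
                 "stability": self.stability_defined}
        if name in masks:
            return masks[name]
        return np.isfinite(self.parameter(name))


# -- elementary operations -------------------------------------------------


def compute_force(net: CooccurrenceNetwork, d: np.ndarray) -> np.ndarray:
    """Force vector f = W d (W masked to retained edges, diagonal kept)."""
    d = np.asarray(d, dtype=float)
    if d.shape != (net.n_taxa,):
        raise ValueError(f"displacement length {d.shape} != {net.n_taxa}")
    return net.effective_weights @ d


def compute_displacement(net: CooccurrenceNetwork, f: np.ndarray,
                         cfg: StiffnessConfig | None = None
                         ) -> tuple[np.ndarray, bool]:
    """Solve W d = f for the displacement caused by a known force.

    Returns ``(d, regularized)``.  When W is singular or its condition
    number exceeds the cap, the minimum-norm least-squares solution is
    returned and ``regularized`` is True (flag propagates to profiles).
    """
    cfg = cfg or StiffnessConfig()
    f = np.asarray(f, dtype=float)
    if f.shape != (net.n_taxa,):
        raise ValueError(f"force length {f.shape} != {net.n_taxa}")
    W = net.effective_weights
    try:
        cond = np.linalg.cond(W)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > cfg.condition_cap:
        logger.warning("weight matrix ill-conditioned (cond=%.3g); "
                       "using minimum-norm least squares", cond)
        d, *_ = np.linalg.lstsq(W, f, rcond=None)
        return d, True
    return np.linalg.solve(W, f), False


def compute_stiffness_scale(net: CooccurrenceNetwork, x: np.ndarray,
                            y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node scale s with diag(s) W y = x.

    s_i = x_i / sum_j w_ij y_j.  Entries whose denominator is ~0 are NaN
    with mask False.  Returns ``(s, defined_mask)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = net.n_taxa
    if x.shape != (n,) or y.shape != (n,):
        raise ValueError("attribute vectors must match network size")
    denom = net.effective_weights @ y
    defined = np.abs(denom) > _ZERO_TOL
    s = np.full(n, np.nan)
    s[defined] = x[defined] / denom[defined]
    return s, defined


def compute_perturbation_matrix(attr: NodeAttribute,
                                pseudocount: float = 1e-6
                                ) -> PerturbationMatrix:
    """G_ij = |r_i / r_j| with r_i the baseline-relative abundance change.

    r_i = (x_b[i] - x_a[i]) / max(x_a[i], pseudocount); columns with
    |r_j| ~ 0 are masked undefined.
    """
    dx = attr.x_b - attr.x_a
    base = np.maximum(attr.x_a, pseudocount)
    r = dx / base
    n = len(attr.taxa)
    col_ok = np.abs(r) > _ZERO_TOL
    G = np.full((n, n), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(r[:, None] / r[None, :])
    G[:, col_ok] = ratio[:, col_ok]
    mask = np.broadcast_to(col_ok[None, :], (n, n)).copy()
    return PerturbationMatrix(taxa=list(attr.taxa), G=G, defined_mask=mask)


def compute_impact(net: CooccurrenceNetwork, P: PerturbationMatrix
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Impact I_i = sum_j A_ij G_ji over defined entries.

    Captures the average response of node i's neighborhood when node i
    is perturbed.  Nodes with no defined neighbor term are NaN/masked.
    """
    A = net.A
    GT = P.G.T
    maskT = P.defined_mask.T
    valid = (A == 1) & maskT
    terms = np.where(valid, GT, 0.0)
    I = terms.sum(axis=1)
    defined = valid.any(axis=1)
    I = np.where(defined, I, np.nan)
    return I, defined


def compute_stability(net: CooccurrenceNetwork, P: PerturbationMatrix
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Stability S_i = 1 / sum_j A_ij G_ij over defined entries.

    Inverse response of node i to perturbations of its neighbors;
    close to 0 means susceptible, close to 1 means stable.  Values are
    reported raw (a note is logged when S_i > 1).
    """
    valid = (net.A == 1) & P.defined_mask
    terms = np.where(valid, P.G, 0.0)
    denom = terms.sum(axis=1)
    defined = valid.any(axis=1) & (denom > _ZERO_TOL)
    S = np.full(net.n_taxa, np.nan)
    S[defined] = 1.0 / denom[defined]
    over = defined & (S > 1)
    if over.any():
        logger.info("stability exceeds 1 for %d taxa (reported raw)",
                    int(over.sum()))
    return S, defined


def compute_profile(net: CooccurrenceNetwork, attr: NodeAttribute,
                    cfg: StiffnessConfig | None = None) -> StiffnessProfile:
    """Assemble the five stiffness parameters for one cohort comparison.

    The observed displacement is the attribute change d = x_b - x_a; the
    force is f = W d; the reported displacement re-solves W d = f (an
    internal consistency check that also exposes ill-conditioning); the
    stiffness scale maps the reference state onto the condition state;
    impact and stability derive from the perturbation matrix G.
    """
    cfg = cfg or StiffnessConfig()
    if list(attr.taxa) != list(net.taxa):
        raise ValueError("attribute taxa do not match network taxa")
    d_obs = attr.displacement
    f = compute_force(net, d_obs)
    d, regularized = compute_displacement(net, f, cfg)
    if cfg.scale_x_state == "B":
        x, y = attr.x_b, attr.x_a
    else:
        x, y = attr.x_a, attr.x_b
    s, s_def = compute_stiffness_scale(net, x, y)
    P = compute_perturbation_matrix(attr, pseudocount=cfg.pseudocount)
    impact, i_def = compute_impact(net, P)
    stability, st_def = compute_stability(net, P)
    notes = []
    if regularized:
        notes.append("REGULARIZED")
    return StiffnessProfile(
        taxa=list(net.taxa), force=f, displacement=d, stiffness_scale=s,
        impact=impact, stability=stability, scale_defined=s_def,
        impact_defined=i_def, stability_defined=st_def,
        regularized=regularized, notes=notes,
    )
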