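"""Pooled-permutation null model for the stiffness parameters.

The two cohorts are pooled and the sample→cohort assignment is randomly
permuted (cohort sizes preserved); the cohort networks and the three
permutation-tested stiffness parameters (stiffness scale, impact,
stability) are recomputed for every permutation.  For each taxon the
pseudo-P pair compares the real value R against the null values R_i:

    P1 = #(R_i <  R) / N_valid   (small when R is unusually LOW)
    P2 = #(R_i >= R) / N_valid   (small when R is unusually HIGH)

Benjamini–Hochberg FDR control is applied across taxa separately within
each direction and each parameter; taxa are then labelled significantly
increased (q2 < alpha), significantly decreased (q1 < alpha), or not
significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .network import NetworkConfig, build_cohort_network
from .stiffness import StiffnessConfig, StiffnessProfile, compute_profile
from .study import COHORT_A, COHORT_B, AbundanceStudy

logger = logging.getLogger(__name__)

TESTED_PARAMETERS = ("stiffness_scale", "impact", "stability")

SIG_INCREASED = "SIG_INCREASED"
SIG_DECREASED = "SIG_DECREASED"
NOT_SIG = "NOT_SIG"
UNDEFINED = "UNDEFINED"


@dataclass
class PermutationReport:
    """Null distributions, pseudo-P values and FDR labels per taxon.

    ``real``/``null`` map parameter name → real-value vector / null
    matrix of shape (n_perm, n_taxa) with NaN marking undefined entries.
    ``table`` is the long-format result with one row per taxon x
    parameter and columns R, P1, P2, q1, q2, label.
    """

    taxa: list[str]
    n_perm: int
    real: dict[str, np.ndarray]
    null: dict[str, np.ndarray]
    table: pd.DataFrame | None = None
    alpha: float = 0.05
    undefined_counts: dict[str, int] = field(default_factory=dict)

    def labels(self, parameter: str) -> pd.Series:
        if self.table is None:
            raise ValueError("report not yet classified")
        sub = self.table[self.table["parameter"] == parameter]
        return sub.set_index("taxon")["label"]

    def significant_taxa(self, parameter: str, direction: str) -> list[str]:
        lab = self.labels(parameter)
        return list(lab.index[lab == direction])


def permute_cohorts(study: AbundanceStudy,
                    rng: np.random.Generator) -> AbundanceStudy:
    """Randomly reassign pooled samples to cohorts of the original sizes.

    The pooled m+n samples are permuted; the first m become cohort A and
    the remaining n cohort B.  Abundances are untouched.
    """
    m, _ = study.cohort_sizes()
    order = rng.permutation(study.n_samples)
    cohort = {}
    for rank, idx in enumerate(order):
        cohort[study.samples[idx]] = COHORT_A if rank < m else COHORT_B
    return study.relabel(cohort)


def _permuted_parameters(study: AbundanceStudy, net_cfg: NetworkConfig,
                         stiff_cfg: StiffnessConfig) -> StiffnessProfile:
    """One round of Step-1/Step-2 recomputation under the current labels."""
    net = build_cohort_network(study, net_cfg, COHORT_A)
    return compute_profile(net, study.attributes(), stiff_cfg)


def null_distribution(study: AbundanceStudy, net_cfg: NetworkConfig,
                      stiff_cfg: StiffnessConfig, n_perm: int = 1000,
                      seed: int = 0) -> dict[str, np.ndarray]:
    """Null value matrices (n_perm x n_taxa) for s, I and S.

    Every permutation rebuilds the reference-cohort network and both
    cohort attribute vectors from the permuted labels.  Undefined values
    are stored as NaN, never zero.  Deterministic given the seed, and
    each permutation draws from an independent child generator so the
    result does not depend on execution order.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_perm)
    n = study.n_taxa
    null = {p: np.full((n_perm, n), np.nan) for p in TESTED_PARAMETERS}
    failures = 0
    for k, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        permuted = permute_cohorts(study, rng)
        try:
            profile = _permuted_parameters(permuted, net_cfg, stiff_cfg)
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures += 1
            logger.warning("permutation %d failed: %s", k, exc)
            continue
        for p in TESTED_PARAMETERS:
            values = profile.parameter(p).copy()
            values[~profile.defined(p)] = np.nan
            null[p][k] = values
    if failures:
        logger.warning("%d/%d permutations failed entirely", failures, n_perm)
    return null


def pseudo_p(R: float, null_values: np.ndarray) -> tuple[float, float]:
    """Pseudo-P pair for one real value against its null vector.

    P1 is the fraction of valid null values strictly below R; P2 the
    fraction at or above R (ties count toward P2).  Returns (nan, nan)
    when R is undefined or the null is entirely missing.
    """
    if not np.isfinite(R):
        return (np.nan, np.nan)
    valid = null_values[np.isfinite(null_values)]
    if valid.size == 0:
        return (np.nan, np.nan)
    n1 = int(np.sum(valid < R))
    return n1 / valid.size, (valid.size - n1) / valid.size


def classify_taxa(report: PermutationReport, alpha: float = 0.05,
                  fdr_method: str = "fdr_bh") -> PermutationReport:
    """Compute pseudo-P values, BH-adjust per direction, label taxa.

    BH is applied across taxa separately for the P2 family (increase
    tests) and the P1 family (decrease tests), within each parameter.
    q2 < alpha → significantly increased; else q1 < alpha →
    significantly decreased; a taxon is never both.
    """
    rows = []
    for param in TESTED_PARAMETERS:
        R = report.real[param]
        null = report.null[param]
        p1 = np.full(len(report.taxa), np.nan)
        p2 = np.full(len(report.taxa), np.nan)
        for i in range(len(report.taxa)):
            p1[i], p2[i] = pseudo_p(R[i], null[:, i])
        ok = np.isfinite(p1) & np.isfinite(p2)
        q1 = np.full_like(p1, np.nan)
        q2 = np.full_like(p2, np.nan)
        if ok.any():
            q1[ok] = multipletests(p1[ok], method=fdr_method)[1]
            q2[ok] = multipletests(p2[ok], method=fdr_method)[1]
        for i, taxon in enumerate(report.taxa):
            if not ok[i]:
                label = UNDEFINED
            elif q2[i] < alpha:
                label = SIG_INCREASED
            elif q1[i] < alpha:
                label = SIG_DECREASED
            else:
                label = NOT_SIG
            rows.append({
                "taxon": taxon, "parameter": param, "R": R[i],
                "P1": p1[i], "P2": p2[i], "q1": q1[i], "q2": q2[i],
                "label": label,
            })
        report.undefined_counts[param] = int((~ok).sum())
    report.table = pd.DataFrame(rows)
    report.alpha = alpha
    return report


def run_permutation_test(study: AbundanceStudy, net_cfg: NetworkConfig,
                         stiff_cfg: StiffnessConfig | None = None,
                         n_perm: int = 1000, alpha: float = 0.05,
                         seed: int = 0,
                         fdr_method: str = "fdr_bh") -> PermutationReport:
    """Full Steps 3–5: real profile, permutation null, classification."""
    stiff_cfg = stiff_cfg or StiffnessConfig()
    profile = _permuted_parameters(study, net_cfg, stiff_cfg)
    real = {}
    for p in TESTED_PARAMETERS:
        values = profile.parameter(p).copy()
        values[~profile.defined(p)] = np.nan
        real[p] = values
    null = null_distribution(study, net_cfg, stiff_cfg,
                             n_perm=n_perm, seed=seed)
    report = PermutationReport(taxa=list(study.taxa), n_perm=n_perm,
                               real=real, null=null)
    return classify_taxa(report, alpha=alpha, fdr_method=fdr_method)


def significance_summary(reports: list[PermutationReport] | PermutationReport
                         ) -> pd.DataFrame:
    """Proportion of significant taxa per parameter, across studies.

    For every study and parameter the summary gives the percentage and
    the "k/n" fraction of significantly increased, significantly
    decreased and not-significant taxa; with several studies a footer
    adds the mean percentage and its standard error per column.
    """
    if isinstance(reports, PermutationReport):
        reports = [reports]
    rows = []
    for idx, rep in enumerate(reports, start=1):
        if rep.table is None:
            raise ValueError("classify_taxa must run before summarizing")
        for param in TESTED_PARAMETERS:
            sub = rep.table[rep.table["parameter"] == param]
            defined = sub[sub["label"] != UNDEFINED]
            n = len(defined)
            counts = {
                "sig_increased": int((defined["label"] == SIG_INCREASED).sum()),
                "sig_decreased": int((defined["label"] == SIG_DECREASED).sum()),
                "not_sig": int((defined["label"] == NOT_SIG).sum()),
            }
            row = {"study": f"D{idx}", "parameter": param, "n_taxa": n}
            for key, k in counts.items():
                pct = 0.0 if n == 0 else 100.0 * k / n
                row[f"{key}_pct"] = pct
                row[f"{key}_frac"] = f"{k}/{n}"
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(reports) > 1:
        footer = []
        for param in TESTED_PARAMETERS:
            sub = table[table["parameter"] == param]
            row = {"study": "Mean±SE", "parameter": param,
                   "n_taxa": int(sub["n_taxa"].sum())}
            for key in ("sig_increased", "sig_decreased", "not_sig"):
                vals = sub[f"{key}_pct"].to_numpy(dtype=float)
                mean = vals.mean()
                se = (vals.std(ddof=1) / np.sqrt(len(vals))
                      if len(vals) > 1 else 0.0)
                row[f"{key}_pct"] = mean
                row[f"{key}_frac"] = f"{mean:.1f}%±{se:.1f}"
            footer.append(row)
        table = pd.concat([table, pd.DataFrame(footer)], ignore_index=True)
    return table


def format_percent(k: int, n: int) -> tuple[str, str]:
    """('25.9%', '22/85')-style cell pair for summary tables."""
    pct = 0.0 if n == 0 else 100.0 * k / n
    pct_str = "0%" if k == 0 else f"{pct:.1f}%"
    return pct_str, f"{k}/{n}"
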