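"""Scikit-learn style estimators wrapping the analysis pipeline.

Two estimators cover the workflow:

* :class:`CooccurrenceNetworkEstimator` — fit on a samples x taxa
  abundance matrix; exposes the thresholded signed network as fitted
  attributes (a transformer-shaped building block).
* :class:`StiffnessNetworkAnalysis` — fit on a samples x taxa matrix
  plus binary cohort labels; runs network construction, the stiffness
  parameters and the pooled-permutation significance test, exposing the
  per-taxon report and biomarker sets as fitted attributes.

Both follow sklearn conventions (get_params/set_params, trailing
underscore on fitted attributes, input validation in ``fit``) and
compose with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import neighborhood, network, permutation
from .network import NetworkConfig
from .stiffness import StiffnessConfig, compute_profile
from .study import COHORT_A, COHORT_B, AbundanceStudy, normalize_columns


def _as_study(X, y=None, taxa=None, ref_label=None) -> AbundanceStudy:
    """Coerce (X samples x taxa, y cohort labels) into an AbundanceStudy."""
    if isinstance(X, AbundanceStudy):
        return X
    if isinstance(X, pd.DataFrame):
        taxa = [str(t) for t in X.columns]
        samples = [str(s) for s in X.index]
        values = X.to_numpy(dtype=float).T
    else:
        values = np.asarray(X, dtype=float).T  # -> taxa x samples
        n_taxa, n_samples = values.shape
        taxa = list(taxa) if taxa is not None else [
            f"taxon_{i:03d}" for i in range(n_taxa)]
        samples = [f"sample_{i:03d}" for i in range(n_samples)]
    if y is None:
        y = [COHORT_A] * len(samples)
    y = [str(v) for v in np.asarray(y).ravel()]
    if len(y) != len(samples):
        raise ValueError("y length must equal number of samples (rows)")
    uniq = sorted(set(y))
    if len(uniq) == 1:
        cohort = dict.fromkeys(samples, COHORT_A)
        # degenerate single-cohort studies are allowed internally by
        # duplicating one sample label into cohort B for validation
        cohort[samples[-1]] = COHORT_B
    else:
        if len(uniq) != 2:
            raise ValueError(f"y must contain exactly 2 labels, got {uniq}")
        ref = ref_label if ref_label is not None else uniq[0]
        if str(ref) not in uniq:
            raise ValueError(f"ref_label {ref!r} not among labels {uniq}")
        cohort = {s: (COHORT_A if lab == str(ref) else COHORT_B)
                  for s, lab in zip(samples, y)}
    return AbundanceStudy(taxa=taxa, samples=samples,
                          abundance=normalize_columns(values),
                          cohort=cohort)


class CooccurrenceNetworkEstimator(BaseEstimator):
    """Signed co-occurrence network inference from abundance data.

    Parameters
    ----------
    estimator : {"spearman", "pearson", "sparcc"}, default "spearman"
    min_abs_corr : float, default 0.3
        Absolute-correlation threshold for edge retention.
    min_prevalence : float, default 0.0
        Taxa must be nonzero in at least this fraction of samples.
    pseudocount : float, default 1e-6
    sparcc_iterations : int, default 10

    Attributes
    ----------
    taxa_ : list of str
    correlation_ : ndarray — estimated correlation matrix
    network_ : CooccurrenceNetwork — the thresholded signed network
    """

    def __init__(self, estimator: str = "spearman",
                 min_abs_corr: float = 0.3, min_prevalence: float = 0.0,
                 pseudocount: float = 1e-6, sparcc_iterations: int = 10):
        self.estimator = estimator
        self.min_abs_corr = min_abs_corr
        self.min_prevalence = min_prevalence
        self.pseudocount = pseudocount
        self.sparcc_iterations = sparcc_iterations

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            estimator=self.estimator, min_abs_corr=self.min_abs_corr,
            min_prevalence=self.min_prevalence,
            pseudocount=self.pseudocount,
            sparcc_iterations=self.sparcc_iterations,
        )

    def fit(self, X, y=None, taxa=None):
        """Estimate correlations on all samples of X and threshold them."""
        cfg = self._config()
        study = _as_study(X, taxa=taxa)
        if self.min_prevalence > 0:
            study = network.filter_taxa(study, cfg)
        self.taxa_ = list(study.taxa)
        self.correlation_ = network.estimate_correlations(study, cfg)
        self.network_ = network.build_network(study.taxa,
                                              self.correlation_, cfg)
        return self

    def transform(self, X=None):
        """Return the fitted signed-weight matrix (zero diagonal)."""
        check_is_fitted(self, "network_")
        return self.network_.signed_weights


class StiffnessNetworkAnalysis(BaseEstimator):
    """Two-cohort stiffness network analysis with permutation inference.

    Fit on a samples x taxa abundance matrix ``X`` and binary cohort
    labels ``y``; the reference cohort's co-occurrence network is built,
    the five stiffness parameters are computed from the between-cohort
    change in mean relative abundance, and a pooled-permutation null
    with BH-FDR control classifies each taxon as significantly
    increased/decreased on stiffness scale, impact and stability.

    Parameters
    ----------
    estimator : correlation estimator for network construction
    min_abs_corr, min_prevalence, pseudocount, sparcc_iterations :
        see :class:`CooccurrenceNetworkEstimator`
    n_permutations : int, default 1000
    alpha : float, default 0.05 — FDR level
    fdr_method : str, default "fdr_bh"
    ref_label : label of y treated as the reference cohort (default:
        lexicographically first)
    random_state : int, default 0

    Attributes
    ----------
    study_ : AbundanceStudy (after prevalence filtering)
    network_a_, network_b_ : per-cohort CooccurrenceNetwork
    profile_ : StiffnessProfile of the real cohort comparison
    report_ : PermutationReport with pseudo-P, q values and labels
    increased_, decreased_ : dict parameter -> list of taxa
    """

    def __init__(self, estimator: str = "spearman",
                 min_abs_corr: float = 0.3, min_prevalence: float = 0.0,
                 pseudocount: float = 1e-6, sparcc_iterations: int = 10,
                 n_permutations: int = 1000, alpha: float = 0.05,
                 fdr_method: str = "fdr_bh", ref_label=None,
                 random_state: int = 0):
        self.estimator = estimator
        self.min_abs_corr = min_abs_corr
        self.min_prevalence = min_prevalence
        self.pseudocount = pseudocount
        self.sparcc_iterations = sparcc_iterations
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.fdr_method = fdr_method
        self.ref_label = ref_label
        self.random_state = random_state

    def _configs(self) -> tuple[NetworkConfig, StiffnessConfig]:
        net_cfg = NetworkConfig(
            estimator=self.estimator, min_abs_corr=self.min_abs_corr,
            min_prevalence=self.min_prevalence,
            pseudocount=self.pseudocount,
            sparcc_iterations=self.sparcc_iterations,
            seed=self.random_state,
        )
        return net_cfg, StiffnessConfig(pseudocount=self.pseudocount)

    def fit(self, X, y=None, taxa=None):
        """Run the full analysis; X may also be an AbundanceStudy."""
        net_cfg, stiff_cfg = self._configs()
        study = _as_study(X, y, taxa=taxa, ref_label=self.ref_label)
        if self.min_prevalence > 0:
            study = network.filter_taxa(study, net_cfg)
        self.study_ = study
        self.taxa_ = list(study.taxa)
        self.network_a_ = network.build_cohort_network(study, net_cfg,
                                                       COHORT_A)
        self.network_b_ = network.build_cohort_network(study, net_cfg,
                                                       COHORT_B)
        self.profile_ = compute_profile(self.network_a_,
                                        study.attributes(), stiff_cfg)
        self.report_ = permutation.run_permutation_test(
            study, net_cfg, stiff_cfg, n_perm=self.n_permutations,
            alpha=self.alpha, seed=self.random_state,
            fdr_method=self.fdr_method,
        )
        self.increased_ = {
            p: self.report_.significant_taxa(p, permutation.SIG_INCREASED)
            for p in permutation.TESTED_PARAMETERS}
        self.decreased_ = {
            p: self.report_.significant_taxa(p, permutation.SIG_DECREASED)
            for p in permutation.TESTED_PARAMETERS}
        return self

    # -- post-fit analyses ------------------------------------------------

    def biomarkers(self, parameters=("impact", "stability")
                   ) -> tuple[set[str], set[str]]:
        """Union of significant taxa over the given parameters.

        A taxon flagged increased on one parameter and decreased on
        another is assigned to the direction with more flags (ties go
        to increased).
        """
        check_is_fitted(self, "report_")
        inc_votes: dict[str, int] = {}
        dec_votes: dict[str, int] = {}
        for p in parameters:
            for t in self.increased_[p]:
                inc_votes[t] = inc_votes.get(t, 0) + 1
            for t in self.decreased_[p]:
                dec_votes[t] = dec_votes.get(t, 0) + 1
        inc, dec = set(), set()
        for t in set(inc_votes) | set(dec_votes):
            if inc_votes.get(t, 0) >= dec_votes.get(t, 0):
                inc.add(t)
            else:
                dec.add(t)
        return inc, dec

    def fon_graph(self, cohort: str = "A",
                  parameters=("impact", "stability")) -> "neighborhood.FonGraph":
        """First-order-neighbor graph around the fitted biomarkers."""
        check_is_fitted(self, "report_")
        net = self.network_a_ if cohort == COHORT_A else self.network_b_
        inc, dec = self.biomarkers(parameters)
        return neighborhood.extract_fon(net, inc, dec, cohort_tag=cohort)

    def subgroups(self, cohort: str = "A", min_size: int = 3,
                  parameters=("impact", "stability")):
        """All-positive "allies" biomarker subgroups in one cohort."""
        check_is_fitted(self, "report_")
        net = self.network_a_ if cohort == COHORT_A else self.network_b_
        inc, dec = self.biomarkers(parameters)
        return neighborhood.mine_subgroups(net, inc | dec,
                                           min_size=min_size)

    def summary(self) -> pd.DataFrame:
        check_is_fitted(self, "report_")
        return permutation.significance_summary(self.report_)
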