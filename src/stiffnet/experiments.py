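"""Validation experiments: null calibration and planted-signal recovery.

These protocols quantify how the permutation test behaves on synthetic
data where the truth is known.  They are used both by the test suite
and by the reproduction script, so the study conditions live here in
one place.

* Null calibration: exchangeable cohorts (no planted alteration) —
  pseudo-P2 values should be approximately uniform and the FDR-labeled
  fraction should stay near the nominal level.
* Planted recovery: a 5-taxon block whose mutual correlations are
  sign-flipped in cohort B while marginal means stay equal — measures
  which stiffness parameters detect a pure relationship alteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import StiffnessNetworkAnalysis
from .permutation import SIG_DECREASED, SIG_INCREASED, UNDEFINED
from .simulate import SyntheticSpec, generate_study

#: study conditions for the exchangeable-cohort calibration: a
#: moderately structured 40-taxon community analyzed with the default
#: pipeline settings.
CALIBRATION_CONDITIONS = dict(
    n_taxa=40, n_samples_a=30, n_samples_b=30,
    blocks=[(5, 0.7), (5, 0.4)], zero_inflation=0.1,
)
CALIBRATION_MIN_ABS_CORR = 0.3

#: study conditions for planted-signal recovery: a single cooperative
#: 5-taxon block whose internal correlations are sign-flipped in the
#: condition cohort.  The edge threshold is set near the Spearman
#: critical value for 30 samples (p ~ 0.01) so chance edges do not
#: drown the planted block's four edges per taxon.
RECOVERY_CONDITIONS = dict(
    n_taxa=40, n_samples_a=30, n_samples_b=30,
    blocks=[(5, 0.7)], planted_subset=[0, 1, 2, 3, 4],
    rewire_mode="sign_flip", zero_inflation=0.0,
)
RECOVERY_MIN_ABS_CORR = 0.45


@dataclass
class CalibrationResult:
    ks_distance: float        # KS distance of pooled pseudo-P2 from U(0,1)
    sig_label_rate: float     # fraction of defined taxa given a SIG label
    n_tests: int


@dataclass
class RecoveryResult:
    recovery_impact_stability: float   # planted taxa flagged on I or S
    recovery_stiffness_scale: float    # planted taxa flagged on s
    false_positive_rate: float         # unplanted flagged on I or S
    false_positive_rate_scale: float   # unplanted flagged on s
    n_planted: int
    n_unplanted: int


def _flagged(model: StiffnessNetworkAnalysis, parameters) -> set[str]:
    out: set[str] = set()
    for p in parameters:
        out |= set(model.increased_[p]) | set(model.decreased_[p])
    return out


def null_calibration(n_replicates: int = 20, n_perm: int = 500,
                     seed: int = 0, alpha: float = 0.05
                     ) -> CalibrationResult:
    """Permutation-test behavior on exchangeable synthetic cohorts.

    Each replicate draws a fresh study with no planted alteration and
    runs the full pipeline; pseudo-P2 values are pooled over taxa,
    parameters and replicates.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates)
    p2_all: list[float] = []
    n_sig = 0
    n_tests = 0
    for rep in range(n_replicates):
        spec = SyntheticSpec(seed=int(seeds[2 * rep] % 2**31),
                             **CALIBRATION_CONDITIONS)
        study, _ = generate_study(spec)
        model = StiffnessNetworkAnalysis(
            min_abs_corr=CALIBRATION_MIN_ABS_CORR, n_permutations=n_perm,
            alpha=alpha, random_state=int(seeds[2 * rep + 1] % 2**31),
        ).fit(study)
        table = model.report_.table
        defined = table[table["label"] != UNDEFINED]
        p2_all.extend(defined["P2"].tolist())
        n_sig += int(defined["label"].isin([SIG_INCREASED,
                                            SIG_DECREASED]).sum())
        n_tests += len(defined)
    ks = stats.kstest(np.asarray(p2_all), "uniform").statistic
    return CalibrationResult(ks_distance=float(ks),
                             sig_label_rate=n_sig / n_tests,
                             n_tests=n_tests)


def planted_recovery(n_replicates: int = 5, n_perm: int = 500,
                     seed: int = 0, alpha: float = 0.05) -> RecoveryResult:
    """Recovery of sign-flip relationship alterations, per parameter.

    Marginal mean abundances are identical between cohorts, so any
    detection reflects the altered correlation structure, not abundance
    shifts.
    """
    seeds = np.random.SeedSequence(seed + 1).generate_state(2 * n_replicates)
    rec_is = rec_s = fp_is = fp_s = 0
    n_planted = n_unplanted = 0
    for rep in range(n_replicates):
        spec = SyntheticSpec(seed=int(seeds[2 * rep] % 2**31),
                             **RECOVERY_CONDITIONS)
        study, truth = generate_study(spec)
        model = StiffnessNetworkAnalysis(
            min_abs_corr=RECOVERY_MIN_ABS_CORR, n_permutations=n_perm,
            alpha=alpha, random_state=int(seeds[2 * rep + 1] % 2**31),
        ).fit(study)
        planted = set(truth.planted_taxa())
        flagged_is = _flagged(model, ("impact", "stability"))
        flagged_s = _flagged(model, ("stiffness_scale",))
        rec_is += len(flagged_is & planted)
        rec_s += len(flagged_s & planted)
        fp_is += len(flagged_is - planted)
        fp_s += len(flagged_s - planted)
        n_planted += len(planted)
        n_unplanted += spec.n_taxa - len(planted)
    return RecoveryResult(
        recovery_impact_stability=rec_is / n_planted,
        recovery_stiffness_scale=rec_s / n_planted,
        false_positive_rate=fp_is / n_unplanted,
        false_positive_rate_scale=fp_s / n_unplanted,
        n_planted=n_planted, n_unplanted=n_unplanted,
    )
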