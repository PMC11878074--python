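"""Core domain containers for two-cohort abundance studies.

An :class:`AbundanceStudy` holds a taxa x samples matrix of per-sample
relative abundances together with a binary cohort assignment (cohort ``A``
is the reference, e.g. healthy controls; cohort ``B`` the condition, e.g.
a disease group).  All downstream network and stiffness computations index
matrices by the taxa order stored here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COHORT_A = "A"
COHORT_B = "B"

_NORM_TOL = 1e-6


@dataclass
class AbundanceStudy:
    """Two-cohort relative-abundance table.

    Parameters
    ----------
    taxa : list of str
        Ordered taxon identifiers (opaque strings; no taxonomy parsing).
    samples : list of str
        Ordered sample identifiers.
    abundance : ndarray of shape (n_taxa, n_samples)
        Nonnegative per-sample proportions; each column sums to 1.
    cohort : dict
        Maps each sample id to ``"A"`` (reference) or ``"B"`` (condition).
    """

    taxa: list[str]
    samples: list[str]
    abundance: np.ndarray
    cohort: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        n_taxa, n_samples = self.abundance.shape
        if len(self.taxa) != n_taxa:
            raise ValueError(
                f"taxa list has {len(self.taxa)} entries for {n_taxa} rows"
            )
        if len(self.samples) != n_samples:
            raise ValueError(
                f"sample list has {len(self.samples)} entries for "
                f"{n_samples} columns"
            )
        if np.any(self.abundance < 0):
            raise ValueError("abundance values must be nonnegative")
        missing = [s for s in self.samples if s not in self.cohort]
        if missing:
            raise ValueError(f"samples without a cohort label: {missing}")
        bad = {s: c for s, c in self.cohort.items()
               if s in self.samples and c not in (COHORT_A, COHORT_B)}
        if bad:
            raise ValueError(f"cohort labels must be 'A' or 'B', got {bad}")
        for label in (COHORT_A, COHORT_B):
            if not self.cohort_samples(label):
                raise ValueError(f"cohort {label!r} is empty")
        sums = self.abundance.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > _NORM_TOL):
            raise ValueError(
                "sample columns must sum to 1; call normalize() first"
            )

    # -- accessors --------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def cohort_samples(self, label: str) -> list[str]:
        """Sample ids belonging to one cohort, in study order."""
        return [s for s in self.samples if self.cohort.get(s) == label]

    def cohort_matrix(self, label: str) -> np.ndarray:
        """Taxa x samples abundance sub-matrix of one cohort."""
        idx = [self.samples.index(s) for s in self.cohort_samples(label)]
        return self.abundance[:, idx]

    def cohort_sizes(self) -> tuple[int, int]:
        return (len(self.cohort_samples(COHORT_A)),
                len(self.cohort_samples(COHORT_B)))

    def mean_abundance(self, label: str) -> np.ndarray:
        """Per-taxon mean relative abundance within one cohort."""
        return self.cohort_matrix(label).mean(axis=1)

    def restrict_taxa(self, keep: list[str]) -> "AbundanceStudy":
        """New study keeping only ``keep`` taxa (study order preserved),
        with columns renormalized to proportions."""
        keep_set = set(keep)
        idx = [i for i, t in enumerate(self.taxa) if t in keep_set]
        sub = self.abundance[idx, :]
        sums = sub.sum(axis=0)
        sums[sums == 0] = 1.0
        return AbundanceStudy(
            taxa=[self.taxa[i] for i in idx],
            samples=list(self.samples),
            abundance=sub / sums,
            cohort=dict(self.cohort),
        )

    def relabel(self, cohort: dict[str, str]) -> "AbundanceStudy":
        """Same data under a new sample→cohort assignment."""
        return AbundanceStudy(
            taxa=list(self.taxa),
            samples=list(self.samples),
            abundance=self.abundance,
            cohort=dict(cohort),
        )

    def attributes(self) -> "NodeAttribute":
        """Per-taxon mean abundances in each cohort (the node attribute X
        measured at the two states)."""
        return NodeAttribute(
            taxa=list(self.taxa),
            x_a=self.mean_abundance(COHORT_A),
            x_b=self.mean_abundance(COHORT_B),
        )


@dataclass
class NodeAttribute:
    """A node attribute measured at two states (cohort A and cohort B).

    ``x_a`` and ``x_b`` are per-taxon mean relative abundances; their
    difference ``x_b - x_a`` is the observed displacement vector.
    """

    taxa: list[str]
    x_a: np.ndarray
    x_b: np.ndarray

    def __post_init__(self) -> None:
        self.x_a = np.asarray(self.x_a, dtype=float)
        self.x_b = np.asarray(self.x_b, dtype=float)
        n = len(self.taxa)
        if self.x_a.shape != (n,) or self.x_b.shape != (n,):
            raise ValueError("attribute vectors must match taxa length")
        if np.any(self.x_a < 0) or np.any(self.x_b < 0):
            raise ValueError("attribute values must be nonnegative")

    @property
    def displacement(self) -> np.ndarray:
        """Observed displacement d = x(t_b) - x(t_a)."""
        return self.x_b - self.x_a


def normalize_columns(matrix: np.ndarray) -> np.ndarray:
    """Rescale each column of a nonnegative matrix to sum to 1.

    All-zero columns are left at zero (callers drop or reject them).
    """
    matrix = np.asarray(matrix, dtype=float)
    sums = matrix.sum(axis=0)
    safe = np.where(sums == 0, 1.0, sums)
    return matrix / safe
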