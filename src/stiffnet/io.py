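"""Reading and writing abundance tables, networks and result tables.

Abundance tables are taxa-rows x sample-columns TSV/CSV (orientation is
auto-detected by matching metadata sample ids); metadata is a TSV with a
header mapping samples to cohort labels.  Networks round-trip through a
simple edge TSV or GraphML; stiffness profiles serialize as TSV with a
mean [min, max] summary footer.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import CooccurrenceNetwork
from .stiffness import StiffnessProfile
from .study import COHORT_A, COHORT_B, AbundanceStudy, normalize_columns

logger = logging.getLogger(__name__)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_abundance(table_path, metadata_path, cohort_column: str,
                   ref_label: str) -> AbundanceStudy:
    """Load a two-cohort abundance study from TSV/CSV files.

    Parameters
    ----------
    table_path : path
        Numeric abundance matrix (counts or proportions; columns are
        renormalized to proportions).  Taxa may be rows or columns;
        whichever axis matches the metadata sample ids is taken as the
        sample axis.
    metadata_path : path
        TSV/CSV with sample ids in the first column and a cohort column.
    cohort_column : str
        Metadata column holding the two cohort labels.
    ref_label : str
        The label mapped to cohort A (the reference, e.g. "HC").
    """
    table_path, metadata_path = Path(table_path), Path(metadata_path)
    table = _read_table(table_path)
    meta = _read_table(metadata_path)
    if cohort_column not in meta.columns:
        raise ValueError(f"metadata has no column {cohort_column!r} "
                         f"(columns: {list(meta.columns)})")
    meta_samples = [str(s) for s in meta.index]
    cols = [str(c) for c in table.columns]
    rows = [str(r) for r in table.index]
    overlap_cols = len(set(meta_samples) & set(cols))
    overlap_rows = len(set(meta_samples) & set(rows))
    if overlap_rows > overlap_cols:
        table = table.T  # samples were rows; orient to taxa x samples
        cols = [str(c) for c in table.columns]
    missing = sorted(set(meta_samples) - set(cols))
    if missing:
        raise ValueError(f"metadata samples absent from table: {missing}")
    table = table[meta_samples]
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~np.vectorize(
            lambda v: isinstance(v, (int, float, np.number)))(values))
        r, c = bad[0]
        raise ValueError(
            f"non-numeric cell at taxon {table.index[r]!r}, "
            f"sample {table.columns[c]!r}"
        )
    if np.any(values < 0):
        raise ValueError("abundance table contains negative values")

    labels = meta[cohort_column].astype(str)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 cohort labels, got {uniq}")
    if ref_label not in uniq:
        raise ValueError(f"ref_label {ref_label!r} not among labels {uniq}")
    cohort = {str(s): (COHORT_A if lab == ref_label else COHORT_B)
              for s, lab in labels.items()}
    for label, name in ((COHORT_A, ref_label),
                        (COHORT_B, [u for u in uniq if u != ref_label][0])):
        n = sum(1 for v in cohort.values() if v == label)
        if n < 2:
            raise ValueError(f"cohort {name!r} has {n} sample(s); need >= 2")

    zero_rows = values.sum(axis=1) == 0
    if zero_rows.any():
        dropped = [str(t) for t, z in zip(table.index, zero_rows) if z]
        logger.warning("dropping all-zero taxa: %s", dropped)
        table = table.loc[~zero_rows]
        values = table.to_numpy()
    return AbundanceStudy(
        taxa=[str(t) for t in table.index],
        samples=meta_samples,
        abundance=normalize_columns(values.astype(float)),
        cohort=cohort,
    )


def write_study(study: AbundanceStudy, table_path, metadata_path,
                cohort_labels: tuple[str, str] = ("A", "B")) -> None:
    """Write a study back to abundance + metadata TSVs."""
    df = pd.DataFrame(study.abundance, index=study.taxa,
                      columns=study.samples)
    df.index.name = "taxon"
    df.to_csv(table_path, sep="\t")
    label = {COHORT_A: cohort_labels[0], COHORT_B: cohort_labels[1]}
    meta = pd.DataFrame({"cohort": [label[study.cohort[s]]
                                    for s in study.samples]},
                        index=pd.Index(study.samples, name="sample"))
    meta.to_csv(metadata_path, sep="\t")


def write_network(net: CooccurrenceNetwork, path,
                  format: str = "edge_tsv") -> None:
    """Write a network as an edge TSV or GraphML.

    The edge TSV has columns taxon_i, taxon_j, weight, sign with each
    undirected edge written once (i before j in taxa order).
    """
    path = Path(path)
    if format == "edge_tsv":
        rows = [{"taxon_i": net.taxa[i], "taxon_j": net.taxa[j],
                 "weight": net.W[i, j], "sign": f"{net.sign[i, j]:+d}"}
                for i, j in net.edges()]
        header = ["taxon_i", "taxon_j", "weight", "sign"]
        pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        g = nx.Graph(estimator=net.estimator_tag)
        g.add_nodes_from(net.taxa)
        for i, j in net.edges():
            g.add_edge(net.taxa[i], net.taxa[j],
                       weight=float(net.W[i, j]), sign=int(net.sign[i, j]))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, taxa: list[str] | None = None,
                 estimator_tag: str = "file") -> CooccurrenceNetwork:
    """Read an edge TSV back into a network.

    ``taxa`` fixes the node order (required to recover isolated nodes);
    if omitted, the taxa are those appearing on edges, in first-seen
    order.
    """
    df = pd.read_csv(path, sep="\t",
                     dtype={"taxon_i": str, "taxon_j": str})
    if taxa is None:
        seen: dict[str, None] = {}
        for col in ("taxon_i", "taxon_j"):
            for t in df[col]:
                seen.setdefault(t, None)
        taxa = list(seen)
    index = {t: k for k, t in enumerate(taxa)}
    n = len(taxa)
    W = np.eye(n)
    sign = np.zeros((n, n), dtype=int)
    A = np.zeros((n, n), dtype=int)
    for _, row in df.iterrows():
        i, j = index[row["taxon_i"]], index[row["taxon_j"]]
        W[i, j] = W[j, i] = float(row["weight"])
        sign[i, j] = sign[j, i] = int(row["sign"])
        A[i, j] = A[j, i] = 1
    return CooccurrenceNetwork(taxa=taxa, W=W, sign=sign, A=A,
                               estimator_tag=estimator_tag)


def write_profile(profile: StiffnessProfile, path) -> None:
    """Stiffness profile TSV: one row per taxon plus a summary footer.

    Undefined entries serialize as "NA" and are excluded from the
    footer's "mean [min, max]" cells.
    """
    cols = {"f": profile.force, "d": profile.displacement,
            "s": profile.stiffness_scale, "I": profile.impact,
            "S": profile.stability}

    def fmt(v: float) -> str:
        return "NA" if not np.isfinite(v) else f"{v:.6g}"

    lines = ["\t".join(["taxon", *cols])]
    for k, taxon in enumerate(profile.taxa):
        lines.append("\t".join([taxon, *(fmt(cols[c][k]) for c in cols)]))
    summary = ["summary(mean [min, max])"]
    for c in cols:
        v = cols[c][np.isfinite(cols[c])]
        if v.size == 0:
            summary.append("NA")
        else:
            summary.append(f"{v.mean():.6g} [{v.min():.6g}, {v.max():.6g}]")
    lines.append("\t".join(summary))
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_table(path) -> pd.DataFrame:
    """Data rows of a profile TSV (footer dropped), NA as NaN."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df[~df["taxon"].str.startswith("summary")].reset_index(drop=True)
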