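"""Functional-class profiles and phyletic presence/absence clustering.

Two downstream summaries of the essentiality analysis: (1) the
distribution of essentiality calls across COG functional categories,
where a gene carrying several single-letter labels contributes one
count per letter; and (2) a binary proteome x orthology-group presence
matrix clustered hierarchically (complete linkage, Euclidean distance)
to reveal phyletic blocks of gene-family conservation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io_formats import FunctionalAnnotationRow

__all__ = [
    "UNANNOTATED",
    "cog_distribution",
    "plot_cog_distribution",
    "build_presence_matrix",
    "PresenceClustering",
    "cluster_matrix",
]

log = logging.getLogger(__name__)

#: Pseudo-label for genes with no orthology group or no COG letter.
UNANNOTATED = "unannotated"


def cog_distribution(
    rows: Iterable[FunctionalAnnotationRow], calls: Mapping[str, str]
) -> pd.DataFrame:
    """Count (COG letter, essentiality call) labels over annotated genes.

    Multi-letter labels are split so each letter counts separately; a
    gene with no orthology group or an empty label counts once under the
    ``unannotated`` pseudo-label.  Genes absent from the call table are
    skipped with a warning.
    """
    counter: Counter = Counter()
    for row in rows:
        call = calls.get(row.gene_id)
        if call is None:
            log.warning("no essentiality call for annotated gene %s; skipped",
                        row.gene_id)
            continue
        if not row.og_ids or not row.cog_labels:
            counter[(UNANNOTATED, call)] += 1
        else:
            for letter in row.cog_labels:
                counter[(letter, call)] += 1
    records = [
        {"cog_label": label, "call": call, "count": n}
        for (label, call), n in sorted(counter.items())
    ]
    return pd.DataFrame(records, columns=["cog_label", "call", "count"])


def plot_cog_distribution(
    table: pd.DataFrame, path: str | Path, x_limit: int | None = None
) -> None:
    """Horizontal bar chart of label counts per call, one panel per call.

    Bars exceeding ``x_limit`` are truncated and annotated with their
    true count (a cosmetic option for long-tailed label distributions).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    calls = sorted(table["call"].unique())
    fig, axes = plt.subplots(
        1, len(calls), figsize=(4 * max(len(calls), 1), 6), squeeze=False
    )
    for ax, call in zip(axes[0], calls):
        sub = table[table["call"] == call].sort_values("cog_label")
        values = sub["count"].to_numpy()
        shown = np.minimum(values, x_limit) if x_limit else values
        ax.barh(sub["cog_label"], shown, color="#4c72b0")
        if x_limit:
            for y, (v, s) in enumerate(zip(values, shown)):
                if v > s:
                    ax.text(s, y, f" {v}", va="center", fontsize=7)
            ax.set_xlim(0, x_limit * 1.15)
        ax.set_title(call)
        ax.set_xlabel("labels")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def build_presence_matrix(
    annotations: Mapping[str, Iterable[FunctionalAnnotationRow]],
    group_universe: Sequence[str],
) -> pd.DataFrame:
    """Binary proteome x orthology-group matrix.

    A group present one or more times in a proteome scores 1 (repeated
    occurrences collapse); groups absent everywhere keep their all-zero
    column.  Proteomes with no annotations produce an all-zero row with
    a warning.
    """
    if len(annotations) < 2:
        raise ValueError("need at least two proteomes to build a presence matrix")
    if not group_universe:
        raise ValueError("group universe is empty")
    universe = list(dict.fromkeys(group_universe))
    matrix = pd.DataFrame(
        0, index=list(annotations), columns=universe, dtype=np.int8
    )
    wanted = set(universe)
    for proteome, rows in annotations.items():
        seen = False
        for row in rows:
            seen = True
            for og in row.og_ids & wanted:
                matrix.at[proteome, og] = 1
        if not seen:
            log.warning("proteome %s has no annotations: all-zero row", proteome)
    return matrix


@dataclass
class PresenceClustering:
    """Complete-linkage clustering of a presence/absence matrix."""

    matrix: pd.DataFrame
    linkage: np.ndarray
    cluster_labels: dict[str, int]
    row_order: list[str]
    col_order: list[str]

    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]

    def write_matrix(self, path: str | Path) -> None:
        ordered = self.ordered()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#proteome\tcluster\t" + "\t".join(ordered.columns) + "\n")
            for proteome, row in ordered.iterrows():
                fh.write(
                    f"{proteome}\t{self.cluster_labels[proteome]}\t"
                    + "\t".join(str(int(v)) for v in row)
                    + "\n"
                )

    def write_heatmap(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        ordered = self.ordered()
        fig, ax = plt.subplots(
            figsize=(
                max(4.0, 0.3 * len(ordered.columns)),
                max(3.0, 0.3 * len(ordered.index)),
            )
        )
        # light yellow = absent, red = present
        ax.imshow(
            ordered.to_numpy(),
            cmap=ListedColormap(["#ffffcc", "#d7301f"]),
            aspect="auto",
            vmin=0,
            vmax=1,
        )
        ax.set_xticks(range(len(ordered.columns)))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(ordered.index)))
        ax.set_yticklabels(ordered.index, fontsize=6)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def cluster_matrix(
    matrix: pd.DataFrame, k: int, cluster_columns: bool = False
) -> PresenceClustering:
    """Complete-linkage agglomeration on Euclidean row distances.

    ``k`` cuts the dendrogram into that many flat clusters.  Columns are
    left in input order unless ``cluster_columns`` is set (mirroring the
    both-axes default of pheatmap-style tools).
    """
    n = len(matrix.index)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    values = matrix.to_numpy(dtype=float)
    Z = hierarchy.linkage(values, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(Z)]
    if cluster_columns and len(matrix.columns) > 1:
        Zc = hierarchy.linkage(values.T, method="complete", metric="euclidean")
        col_order = [matrix.columns[i] for i in hierarchy.leaves_list(Zc)]
    else:
        col_order = list(matrix.columns)
    return PresenceClustering(
        matrix=matrix,
        linkage=Z,
        cluster_labels=dict(zip(matrix.index, (int(x) for x in labels))),
        row_order=row_order,
        col_order=col_order,
    )
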