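"""Expression-matrix summaries: z-scores, clustering, tissue-max, UV calls.

Operates on a normalized (TPM-like) genes × samples table with a sample
sheet giving the tissue/stage group of every sample and, for the UV
comparison, treatment and timepoint columns. Rows are z-scored with the
population standard deviation (the convention behind heatmaps drawn on a
−2..2 scale) and ordered by average-linkage hierarchical clustering on a
1 − Pearson metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._util import percentage

__all__ = [
    "ExpressionMatrix",
    "zscore_rows",
    "cluster_rows",
    "tissue_max_calls",
    "TissueMaxResult",
    "uv_response",
]


@dataclass
class ExpressionMatrix:
    """Nonnegative genes × samples abundances plus per-sample metadata.

    ``metadata`` is indexed by sample id and must cover every column of
    ``values``; a ``group`` column is required, ``treatment``/``timepoint``
    only for the UV comparison.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundances")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        if "group" not in self.metadata.columns:
            raise ValueError("metadata must have a 'group' column")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def group_order(self) -> list[str]:
        """Sample groups in metadata (first-appearance) order."""
        return list(dict.fromkeys(self.metadata["group"]))

    def group_means(self) -> pd.DataFrame:
        """Replicate means: genes × sample groups, metadata order."""
        groups = self.metadata.loc[self.values.columns, "group"]
        means = self.values.T.groupby(groups.values).mean().T
        return means[self.group_order()]


def zscore_rows(m: ExpressionMatrix | pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scores (population sd); constant rows map to zeros, flagged."""
    values = m.values if isinstance(m, ExpressionMatrix) else m
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = values.to_numpy(float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (arr - mu) / sd
    z[flat] = 0.0
    flagged = [g for g, f in zip(values.index, flat) if f]
    return pd.DataFrame(z, index=values.index, columns=values.columns), flagged


def cluster_rows(
    m: ExpressionMatrix | pd.DataFrame, method: str = "average"
) -> tuple[list[str], np.ndarray, list[str]]:
    """Hierarchical clustering of rows on a 1 − Pearson metric.

    Returns (leaf order, scipy linkage matrix over the clustered rows,
    constant rows). Constant rows — for which the metric is undefined — are
    placed last in the leaf order and flagged.
    """
    values = m.values if isinstance(m, ExpressionMatrix) else m
    if len(values) < 2:
        raise ValueError("need at least 2 rows")
    arr = values.to_numpy(float)
    flat = arr.std(axis=1) == 0
    flagged = list(values.index[flat])
    ok = values.index[~flat]
    if len(ok) < 2:
        return list(ok) + flagged, np.empty((0, 4)), flagged
    corr = np.corrcoef(arr[~flat])
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = [ok[i] for i in hierarchy.leaves_list(Z)]
    return order + flagged, Z, flagged


@dataclass
class TissueMaxResult:
    """Per-gene argmax sample group with per-group counts and percentages."""

    calls: pd.DataFrame  # gene_id, group, tied
    counts: dict[str, int]
    percentages: dict[str, int]
    no_signal: list[str] = field(default_factory=list)
    ties: list[str] = field(default_factory=list)


def tissue_max_calls(m: ExpressionMatrix) -> TissueMaxResult:
    """Assign each gene to the sample group of its highest replicate mean.

    All-zero genes are flagged "no signal" and excluded from the counts;
    exact ties are broken toward the first tied group in metadata order and
    flagged. Percentages use half-away-from-zero integer rounding over the
    called genes.
    """
    means = m.group_means()
    groups = list(means.columns)
    rows, ties, no_signal = [], [], []
    for gene, row in means.iterrows():
        if (m.values.loc[gene] == 0).all():
            no_signal.append(gene)
            continue
        best = row.max()
        winners = [g for g in groups if row[g] == best]
        if len(winners) > 1:
            ties.append(gene)
        rows.append({"gene_id": gene, "group": winners[0],
                     "tied": len(winners) > 1})
    calls = pd.DataFrame(rows, columns=["gene_id", "group", "tied"])
    counts = {g: int((calls["group"] == g).sum()) for g in groups}
    total = len(calls)
    percentages = {g: percentage(c, total) for g, c in counts.items()} if total \
        else {}
    return TissueMaxResult(calls, counts, percentages, no_signal, ties)


def uv_response(
    m: ExpressionMatrix, lfc_threshold: float = 1.0
) -> pd.DataFrame:
    """Induced/repressed/unchanged calls per gene and treatment timepoint.

    Uses log2((treated mean + 1) / (control mean + 1)) on replicate means
    with a pseudocount of one, compared against ±``lfc_threshold``. Metadata
    needs ``treatment`` in {treated, control} and ``timepoint``; every
    treated timepoint must have matched controls.
    """
    meta = m.metadata
    for col in ("treatment", "timepoint"):
        if col not in meta.columns:
            raise ValueError(f"metadata must have a '{col}' column")
    out = []
    for tp in dict.fromkeys(meta["timepoint"]):
        sub = meta[meta["timepoint"] == tp]
        treated = sub.index[sub["treatment"] == "treated"]
        control = sub.index[sub["treatment"] == "control"]
        if len(treated) == 0:
            continue
        if len(control) == 0:
            raise ValueError(
                f"treated samples {list(treated)} at timepoint {tp} "
                f"have no paired control"
            )
        t_mean = m.values[treated].mean(axis=1)
        c_mean = m.values[control].mean(axis=1)
        lfc = np.log2((t_mean + 1.0) / (c_mean + 1.0))
        call = np.where(
            lfc >= lfc_threshold, "induced",
            np.where(lfc <= -lfc_threshold, "repressed", "unchanged"),
        )
        out.append(pd.DataFrame({
            "gene_id": m.values.index,
            "timepoint": tp,
            "log2fc": lfc.to_numpy(),
            "call": call,
        }))
    return pd.concat(out, ignore_index=True)
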