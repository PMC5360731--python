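"""Transcript–glycoside correlation, candidate ranking and ion masses.

Links gene expression (collapsed to stage means) with glycosylated-volatile
abundances over shared developmental stages by Pearson correlation, with
two-sided t-distribution p-values and Benjamini–Hochberg adjustment across
all gene × compound pairs. "Significant positive" candidates are genes with
r above a floor and q at or below a ceiling, ranked by descending r.

Also computes nominal negative-mode glycoside ion masses: each attached
hexose adds 162 Da (dehydrated glucose), deprotonation subtracts 1, and the
formic-acid adduct adds a further 46 — e.g. a 122-Da aglycone mono-hexoside
gives [M−H]− at m/z 283 and the formate adduct at 329.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationTable",
    "correlate",
    "select_candidates",
    "glycoside_mz",
    "HEXOSE_NOMINAL",
    "FORMIC_ACID_NOMINAL",
]

HEXOSE_NOMINAL = 162  # glucose minus water
FORMIC_ACID_NOMINAL = 46
HEXOSE_MONO = 162.05282
PROTON_MONO = 1.00728
FORMIC_ACID_MONO = 46.00548


@dataclass
class CorrelationTable:
    results: pd.DataFrame  # gene_id, compound_id, r, p, q
    n_stages: int
    skipped: list[tuple[str, str]] = field(default_factory=list)


def correlate(
    stage_means: pd.DataFrame,
    metabolites: pd.DataFrame,
    stage_map: Mapping[str, str] | None = None,
) -> CorrelationTable:
    """Pearson r, p and BH q for every gene × compound pair.

    ``stage_means``: genes × stages; ``metabolites``: compounds × stages.
    ``stage_map`` translates metabolite stage names to expression stage
    names when they differ; only explicitly mapped or identically named
    stages are compared, and at least three shared stages are required.
    Pairs involving a constant profile have no defined r and are skipped
    (reported in ``skipped``).
    """
    mapping = dict(stage_map) if stage_map else {s: s for s in metabolites.columns}
    shared = [s for s in metabolites.columns
              if mapping.get(s) in stage_means.columns]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared stages; need at least 3"
        )
    X = stage_means[[mapping[s] for s in shared]].to_numpy(float)
    Y = metabolites[shared].to_numpy(float)
    n = len(shared)

    x_sd = X.std(axis=1)
    y_sd = Y.std(axis=1)
    skipped = [
        (g, c)
        for gi, g in enumerate(stage_means.index) if x_sd[gi] == 0
        for c in metabolites.index
    ] + [
        (g, c)
        for ci, c in enumerate(metabolites.index) if y_sd[ci] == 0
        for g in stage_means.index
    ]
    gene_ok = x_sd > 0
    comp_ok = y_sd > 0
    Zx = (X[gene_ok] - X[gene_ok].mean(axis=1, keepdims=True)) / x_sd[gene_ok, None]
    Zy = (Y[comp_ok] - Y[comp_ok].mean(axis=1, keepdims=True)) / y_sd[comp_ok, None]
    R = np.clip(Zx @ Zy.T / n, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        t = R * np.sqrt((n - 2) / np.clip(1.0 - R * R, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    genes = stage_means.index[gene_ok]
    comps = metabolites.index[comp_ok]
    results = pd.DataFrame({
        "gene_id": np.repeat(genes, len(comps)),
        "compound_id": np.tile(comps, len(genes)),
        "r": R.ravel(),
        "p": p.ravel(),
    })
    if len(results):
        results["q"] = multipletests(results["p"], method="fdr_bh")[1]
    else:
        results["q"] = []
    return CorrelationTable(results=results, n_stages=n, skipped=skipped)


def select_candidates(
    table: CorrelationTable,
    compound: str,
    r_min: float = 0.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Ranked genes with r > r_min and q <= q_max for one compound."""
    res = table.results
    if compound not in set(res["compound_id"]):
        raise ValueError(f"unknown compound: {compound}")
    sel = res[(res["compound_id"] == compound)
              & (res["r"] > r_min) & (res["q"] <= q_max)]
    return (
        sel.sort_values(["r", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )


def glycoside_mz(
    aglycone_mass: float,
    n_hexose: int = 1,
    adduct: str = "[M-H]-",
    monoisotopic: bool = False,
) -> float:
    """Negative-mode m/z of an aglycone carrying ``n_hexose`` hexose units.

    Nominal arithmetic by default (aglycone + 162·n − 1 for [M−H]−; +46 more
    for the formate adduct); monoisotopic masses on request.
    """
    if aglycone_mass <= 0:
        raise ValueError("aglycone mass must be positive")
    if n_hexose < 0:
        raise ValueError("n_hexose must be >= 0")
    if monoisotopic:
        mz = aglycone_mass + HEXOSE_MONO * n_hexose - PROTON_MONO
        formate = FORMIC_ACID_MONO
    else:
        mz = aglycone_mass + HEXOSE_NOMINAL * n_hexose - 1
        formate = FORMIC_ACID_NOMINAL
    if adduct == "[M-H]-":
        return mz
    if adduct in ("[M+HCOO]-", "formate"):
        return mz + formate
    raise ValueError(f"unknown adduct: {adduct}")
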