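"""Differential-expression weighting of the interactome.

A node's *activity* is the absolute log fold change of its gene, taken
from the probe with maximum |logFC| when several probes map to the same
symbol.  An edge between genes i and j is weighted by the squared mean of
the endpoint activities,

    w(i, j) = ((|FC_i| + |FC_j|) / 2)^2,

floored at a small epsilon so the random walk stays well defined in
regions with no measured differential expression.  Genes failing the
significance filter (or absent from the expression table) keep their
place in the network with activity 0, so topology is identical across
datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionProfile",
    "WeightedNetwork",
    "bh_adjust",
    "read_expression_table",
    "collapse_probes",
    "filter_profile",
    "apply_edge_weights",
]

log = logging.getLogger(__name__)

DEFAULT_WEIGHT_FLOOR = 1e-6


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene differential expression after probe collapse.

    ``table`` is indexed by gene symbol with columns ``fc`` (signed log
    fold change), ``p`` (raw p-value), ``p_adj`` (BH-adjusted) and
    ``activity`` (= |fc|, zeroed for filtered-out genes).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"fc", "p", "p_adj", "activity"} - set(self.table.columns)
        if missing:
            raise ValueError(f"profile table missing columns {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def activity(self, gene: str) -> float:
        """Activity of ``gene``; 0.0 for genes not in the profile."""
        try:
            return float(self.table.at[gene, "activity"])
        except KeyError:
            return 0.0

    def activities(self, genes) -> np.ndarray:
        """Vector of activities for an iterable of genes (0 where unmeasured)."""
        s = self.table["activity"].reindex(list(genes)).fillna(0.0)
        return s.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class WeightedNetwork:
    """An interactome with expression-derived edge weights plus the profile
    that produced them."""

    graph: nx.Graph
    profile: ExpressionProfile
    weight_floor: float


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns adjusted p-values in the original order, clipped to [0, 1],
    with the usual step-up monotonicity enforced.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_COLUMN_ALIASES = {
    "probe_id": {"probe_id", "probe", "id", "probeid"},
    "gene": {"gene", "gene_symbol", "symbol", "gene.symbol"},
    "fc": {"logfc", "fc", "log_fc", "log2fc"},
    "p": {"p.value", "p_value", "pvalue", "p"},
    "p_adj": {"adj.p.val", "adj_p_val", "padj", "p_adj", "adj.p.value", "fdr"},
}


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a limma-style differential-expression TSV.

    Recognizes columns probe_id, gene, logFC, P.Value and (optionally)
    adj.P.Val, case-insensitively.  Returns a frame with canonical column
    names ``probe_id, gene, fc, p[, p_adj]``.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for col in df.columns:
            if col.strip().lower() in aliases:
                rename[col] = canonical
                break
    df = df.rename(columns=rename)
    required = {"probe_id", "gene", "fc", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing expression columns {sorted(missing)}")
    df["gene"] = df["gene"].astype(str).str.strip().str.upper()
    return df


def collapse_probes(table: pd.DataFrame) -> ExpressionProfile:
    """Collapse a probe-level table to one record per gene.

    Per gene the probe with maximum |fc| is kept; ties are broken by the
    smaller p-value, then by lexicographic probe id.  Rows with missing fc
    are skipped (count logged).  The gene-level BH adjustment is computed
    from the retained raw p-values unless the table already carries a
    ``p_adj`` column, in which case the selected probe's value is kept.
    """
    df = table.copy()
    if "probe_id" not in df.columns:
        df["probe_id"] = [f"row{i}" for i in range(len(df))]
    n_bad = int(df["fc"].isna().sum())
    if n_bad:
        log.info("collapse_probes: skipped %d row(s) with missing fold change", n_bad)
        df = df.dropna(subset=["fc"])
    if df.empty:
        raise ValueError("no usable expression rows after dropping missing fold changes")
    if "p" not in df.columns:
        df["p"] = 1.0
    df["p"] = df["p"].fillna(1.0)
    df["_absfc"] = df["fc"].abs()
    df = df.sort_values(
        ["gene", "_absfc", "p", "probe_id"], ascending=[True, False, True, True]
    )
    best = df.groupby("gene", sort=True).first()

    out = pd.DataFrame(index=best.index)
    out["fc"] = best["fc"].astype(float)
    out["p"] = best["p"].astype(float)
    if "p_adj" in best.columns and best["p_adj"].notna().all():
        out["p_adj"] = best["p_adj"].astype(float)
    else:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["activity"] = out["fc"].abs()
    return ExpressionProfile(out)


def filter_profile(
    profile: ExpressionProfile, alpha: float = 0.01, use_adjusted: bool = True
) -> tuple[ExpressionProfile, int]:
    """Zero the activity of genes failing the significance threshold.

    Genes stay in the profile (and the network) with activity 0 so the
    graph topology is unchanged; only the weighting sees the filter.
    Returns the filtered profile and the number of genes retained.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    table = profile.table.copy()
    col = "p_adj" if use_adjusted else "p"
    keep = table[col] <= alpha
    table.loc[~keep, "activity"] = 0.0
    return ExpressionProfile(table), int(keep.sum())


def apply_edge_weights(
    net: nx.Graph,
    profile: ExpressionProfile,
    floor_eps: float = DEFAULT_WEIGHT_FLOOR,
) -> WeightedNetwork:
    """Weight every edge by the squared mean endpoint activity.

    w(i, j) = max( ((|fc_i| + |fc_j|) / 2)^2, floor_eps ).  Genes absent
    from the profile contribute activity 0.
    """
    if floor_eps < 0:
        raise ValueError("floor_eps must be nonnegative")
    graph = net.copy()
    act = profile.table["activity"]
    for u, v, data in graph.edges(data=True):
        a_u = float(act.get(u, 0.0))
        a_v = float(act.get(v, 0.0))
        w = ((a_u + a_v) / 2.0) ** 2
        data["weight"] = max(w, floor_eps)
    return WeightedNetwork(graph=graph, profile=profile, weight_floor=floor_eps)
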