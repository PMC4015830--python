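"""Synthetic interactomes, expression tables and label lists with known
ground truth.

The generator emulates the statistical structure the pipeline assumes in
real data: an interactome with community structure (planted-partition /
stochastic block topology), a differential-expression table in which a
few planted "signal" communities carry elevated |log fold change|, and a
label list enriched inside those communities.  Every generator is fully
seeded and bit-reproducible, and writes the same TSV/SIF/label formats
the pipeline reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "FixtureSpec",
    "planted_partition_graph",
    "planted_expression",
    "planted_labels",
    "write_sif",
    "write_expression_tsv",
    "write_label_file",
]

SOURCE_TAG = "SIM"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults give six communities of 25 genes with within/between edge
    probabilities 0.3/0.02, two signal communities whose genes get a mean
    |log2 fold change| shift of 3 standard deviations of the background
    noise, and labels at 80% inside signal communities versus 10%
    elsewhere.
    """

    community_sizes: tuple[int, ...] = (25, 25, 25, 25, 25, 25)
    p_in: float = 0.3
    p_out: float = 0.02
    signal_modules: tuple[int, ...] = (0, 1)
    noise_sd: float = 0.5
    effect: float = 1.5  # mean |fc| shift in signal modules; 3 * noise_sd
    label_rates: tuple[float, float] = (0.8, 0.1)  # (signal, background)
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.effect < 0:
            raise ValueError("effect must be nonnegative")
        if not all(0 <= r <= 1 for r in self.label_rates):
            raise ValueError("label rates must lie in [0, 1]")
        if any(i < 0 or i >= len(self.community_sizes) for i in self.signal_modules):
            raise ValueError("signal module index out of range")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")

    @property
    def n_genes(self) -> int:
        return sum(self.community_sizes)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("community_sizes", "signal_modules", "label_rates"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _sample_block_graph(spec: FixtureSpec, rng: np.random.Generator) -> nx.Graph:
    n = spec.n_genes
    names = _gene_names(n)
    block = np.repeat(np.arange(len(spec.community_sizes)), spec.community_sizes)
    graph = nx.Graph()
    graph.add_nodes_from(names)
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(block[iu] == block[ju], spec.p_in, spec.p_out)
    hit = rng.random(p.size) < p
    for a, b in zip(iu[hit].tolist(), ju[hit].tolist()):
        graph.add_edge(names[a], names[b], sources={SOURCE_TAG}, weight=1.0)
    return graph


def planted_partition_graph(
    spec: FixtureSpec,
    require_connected: bool = True,
    max_retries: int = 50,
) -> tuple[nx.Graph, dict]:
    """Sample a planted-partition interactome and its ground truth.

    Vertices within a community are connected with probability ``p_in``,
    across communities with ``p_out``.  With ``require_connected`` the
    draw is repeated (bounded) until the graph is connected.  Returns the
    graph and a gene -> community-index map.
    """
    truth = {
        g: int(c)
        for g, c in zip(
            _gene_names(spec.n_genes),
            np.repeat(np.arange(len(spec.community_sizes)), spec.community_sizes),
        )
    }
    for attempt in range(max_retries):
        rng = np.random.default_rng([spec.seed, attempt])
        graph = _sample_block_graph(spec, rng)
        if not require_connected or nx.is_connected(graph):
            return graph, truth
    raise RuntimeError(
        f"no connected draw in {max_retries} tries; raise p_out or p_in"
    )


def planted_expression(
    net: nx.Graph, truth: dict, spec: FixtureSpec
) -> pd.DataFrame:
    """Probe-level differential-expression table with planted signal.

    Background genes draw fc ~ Normal(0, noise_sd); genes of signal
    communities draw fc ~ sign * (effect + Normal(0, noise_sd)) with a
    random sign.  P-values are the two-sided normal tail of
    fc / noise_sd, so significance filtering interacts with the planted
    effect the way it would with a real test statistic.  With
    ``probes_per_gene > 1`` each gene gets that many probes with
    independent noise around the same planted signal.
    """
    missing = set(net.nodes) - set(truth)
    if missing:
        raise ValueError(f"ground truth missing for {len(missing)} gene(s)")
    rng = np.random.default_rng([spec.seed, 10_001])
    signal = set(spec.signal_modules)
    rows = []
    for gene in sorted(net.nodes):
        is_signal = truth[gene] in signal
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for probe_i in range(spec.probes_per_gene):
            noise = rng.normal(0.0, spec.noise_sd)
            fc = sign * (spec.effect + noise) if is_signal else noise
            p = 2.0 * norm.sf(abs(fc) / spec.noise_sd)
            rows.append(
                {
                    "probe_id": f"{gene}_at{probe_i}",
                    "gene": gene,
                    "logFC": fc,
                    "P.Value": min(1.0, float(p)),
                }
            )
    return pd.DataFrame(rows, columns=["probe_id", "gene", "logFC", "P.Value"])


def planted_labels(truth: dict, spec: FixtureSpec) -> set:
    """Bernoulli gene labels, stratified by signal/background community."""
    rng = np.random.default_rng([spec.seed, 20_001])
    signal = set(spec.signal_modules)
    rate_sig, rate_bg = spec.label_rates
    labels = set()
    for gene in sorted(truth):
        rate = rate_sig if truth[gene] in signal else rate_bg
        if rng.random() < rate:
            labels.add(gene)
    return labels


def write_sif(net: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    with Path(path).open("w") as fh:
        for u, v in sorted(map(sorted, net.edges())):
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_expression_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_label_file(labels: Sequence[str] | set, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(labels):
            fh.write(f"{g}\n")
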