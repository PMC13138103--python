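"""Expression matrices, the co-expression distance, and edge weighting.

The filtration driving the persistence computation is built here: per
condition, each gene becomes a point whose coordinates are its (log-scale)
expression values in that condition's samples, and every pathway edge is
weighted by the correlation distance

    d = 1 - |rho|,

rho being the Pearson correlation of the two endpoint profiles.  The
absolute value makes strong negative co-expression (e.g. an inhibitor and
its target) just as "close" as strong positive co-expression; d ranges
from 0 (perfectly co-expressed) to 1 (uncorrelated).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pathway_io import PathwayNetwork

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A gene x sample matrix of finite log-scale expression values."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    condition_map: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match genes x samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.samples if s not in self.condition_map]
        if missing:
            raise ValueError(f"samples missing from condition map: {missing}")
        conds = self.conditions
        if len(conds) != 2:
            raise ValueError(f"expected exactly two conditions, got {conds}")
        for c in conds:
            n = sum(1 for s in self.samples if self.condition_map[s] == c)
            if n < 3:
                logger.warning(
                    "condition %s has only %d samples; correlations degenerate", c, n
                )

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            c = self.condition_map[s]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition_map[s] == condition]

    def profile(self, gene: str, condition: str | None = None) -> np.ndarray:
        i = self.genes.index(gene)
        if condition is None:
            return self.values[i]
        cols = [self.samples.index(s) for s in self.condition_samples(condition)]
        return self.values[i, cols]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class FilteredDigraph:
    """A pathway network with one filtration weight per edge.

    ``dropped_genes`` records pathway nodes removed because they had no
    expression profile.  An empty edge set after dropping is valid (the
    Betti curves are then constant) and flagged via ``degenerate``.
    """

    network: PathwayNetwork
    edge_weights: dict[tuple[str, str], float]
    condition: str
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = set(self.network.edge_pairs())
        if set(self.edge_weights) != pairs:
            raise ValueError("edge_weights must cover exactly the network edges")
        for e, w in self.edge_weights.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"weight {w} for edge {e} outside [0, 1]")

    @property
    def degenerate(self) -> bool:
        return self.network.n_edges == 0


def log_tpm(
    counts: pd.DataFrame,
    lengths: dict[str, float] | pd.Series,
    condition_map: dict[str, str],
) -> ExpressionMatrix:
    """Length- and depth-normalise raw counts to log2(TPM + 1).

    TPM_g = (count_g / length_g) / sum_h (count_h / length_h) * 1e6 per
    sample; the +1 pseudocount keeps zero counts finite after the log.
    """
    lengths = pd.Series(lengths)
    missing = [g for g in counts.index if g not in lengths.index]
    if missing:
        raise ValueError(f"lengths missing for genes: {missing[:5]}")
    lens = lengths.loc[counts.index].astype(float)
    if (lens <= 0).any():
        bad = list(lens.index[lens <= 0])
        raise ValueError(f"non-positive gene lengths: {bad[:5]}")
    rate = counts.astype(float).div(lens, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero samples: {list(zero.index)}")
    tpm = rate.div(totals, axis=1) * 1e6
    values = np.log2(tpm.to_numpy() + 1.0)
    return ExpressionMatrix(
        genes=[str(g) for g in counts.index],
        samples=[str(s) for s in counts.columns],
        values=values,
        condition_map=condition_map,
    )


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Correlation distance d = 1 - |Pearson rho| between two profiles.

    A zero-variance profile leaves rho undefined; such an edge is maximally
    distant (d = 1) so an uninformative gene cannot create early
    connectivity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        logger.warning("zero-variance profile; correlation undefined, d set to 1")
        return 1.0
    rho = stats.pearsonr(x, y).statistic
    d = 1.0 - abs(rho)
    # clamp floating-point excursions just outside [0, 1]
    if -1e-12 <= d < 0.0:
        d = 0.0
    elif 1.0 < d <= 1.0 + 1e-12:
        d = 1.0
    return float(d)


def weight_edges(
    network: PathwayNetwork,
    expr: ExpressionMatrix,
    condition: str,
) -> FilteredDigraph:
    """Attach the condition-specific correlation distance to every edge.

    Pathway genes without an expression profile are dropped (with their
    incident edges) and recorded; both orientations of a mutual edge pair
    get the same weight since d is symmetric.
    """
    if condition not in expr.conditions:
        raise ValueError(f"condition {condition!r} not in expression data")
    measured = set(expr.genes)
    dropped = [n for n in network.nodes if n not in measured]
    if dropped:
        logger.info(
            "pathway %s: dropping %d unmeasured genes: %s",
            network.pathway_id, len(dropped), dropped[:10],
        )
    sub = network.subnetwork(measured)
    cols = [expr.samples.index(s) for s in expr.condition_samples(condition)]
    gene_idx = {g: i for i, g in enumerate(expr.genes)}
    profiles = {n: expr.values[gene_idx[n]][cols] for n in sub.nodes}
    weights: dict[tuple[str, str], float] = {}
    cache: dict[tuple[str, str], float] = {}
    for s, t in sub.edge_pairs():
        key = (s, t) if s <= t else (t, s)
        if key not in cache:
            cache[key] = correlation_distance(profiles[key[0]], profiles[key[1]])
        weights[(s, t)] = cache[key]
    fg = FilteredDigraph(
        network=sub, edge_weights=weights, condition=condition, dropped_genes=dropped
    )
    if fg.degenerate:
        logger.warning(
            "pathway %s has no weighted edges under condition %s",
            network.pathway_id, condition,
        )
    return fg


def read_expression(table: str | io.TextIOBase, condition_map: dict[str, str],
                    sep: str = "\t") -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix (first column gene symbols)."""
    if isinstance(table, str):
        table = io.StringIO(table)
    df = pd.read_csv(table, sep=sep, index_col=0)
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        condition_map=condition_map,
    )


def read_condition_map(table: str | io.TextIOBase) -> dict[str, str]:
    """Read a two-column TSV ``sample<TAB>condition`` into a dict."""
    if isinstance(table, str):
        table = io.StringIO(table)
    df = pd.read_csv(table, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("condition map needs columns sample, condition")
    df.columns = ["sample", "condition"] + list(df.columns[2:])
    return dict(zip(df["sample"], df["condition"]))
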