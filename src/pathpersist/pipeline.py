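"""End-to-end orchestration: expression + pathways -> topology -> statistics.

Stage I integrates the (log-scale) expression matrix with each pathway
network and weights edges by the condition-specific correlation distance.
Stage II computes Betti curves, barcodes and persistence landscapes per
pathway and condition over the 0..1 filtration grid.  Stage III runs the
global averaged-landscape permutation test and the per-pathway KS /
Cohen's d permutation tests with BH correction, flagging pathways
significant on all four tests.

All randomness flows through one seeded generator, so a rerun with the
same configuration and seed is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, read_condition_map, read_expression, weight_edges
from .global_stats import GlobalTestResult, global_tests
from .homology import Barcode, BettiCurve, betti_curve, filtration_grid, persistence_pairs
from .landscapes import Landscape, landscape
from .pathway_io import PathwayNetwork, parse_kgml, read_adjacency, read_edge_list
from .pathway_stats import PathwayTestResult, pathway_significance, score_pathway

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full run (defaults follow the method's standard use)."""

    expression: str = ""
    conditions: str = ""
    pathways: str = ""
    step: float = 0.01
    n_perm_global: int = 1000
    n_perm_pathway: int = 5000
    alpha: float = 0.05
    seed: int | None = None
    norms: tuple[str, ...] = ("sup", "one", "two")
    dimensions: tuple[int, ...] = (0, 1)
    out_dir: str = ""
    backend: str = "fraction"
    estimator: str = "count"
    bh_family: str = "per_dimension"
    drop_essential: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm_global < 1 or self.n_perm_pathway < 1:
            raise ValueError("permutation counts must be >= 1")
        filtration_grid(self.step)  # validates that step divides 1


@dataclass
class PathwayResultBundle:
    """Per-pathway topological summaries for both conditions."""

    pathway_id: str
    curves: dict[str, BettiCurve]
    barcodes: dict[tuple[str, int], Barcode]
    landscapes: dict[tuple[str, int], Landscape]
    dropped_genes: dict[str, list[str]]


@dataclass
class StudyResult:
    config: RunConfig
    conditions: tuple[str, str]
    pathways: list[PathwayResultBundle]
    skipped: list[str]
    global_results: dict[int, GlobalTestResult]
    pathway_results: list[PathwayTestResult]

    @property
    def significant(self) -> list[str]:
        return [r.pathway_id for r in self.pathway_results if r.significant]


def load_pathways(path: str | Path) -> list[PathwayNetwork]:
    """Load every pathway file in a directory (KGML .xml, .tsv edge list, .csv adjacency)."""
    path = Path(path)
    files = sorted(path.iterdir()) if path.is_dir() else [path]
    networks = []
    for f in files:
        if f.suffix == ".xml":
            networks.append(parse_kgml(f.read_text()))
        elif f.suffix == ".tsv":
            networks.append(read_edge_list(f.read_text(), pathway_id=f.stem))
        elif f.suffix == ".csv":
            networks.append(read_adjacency(f.read_text(), pathway_id=f.stem))
        else:
            logger.warning("ignoring unrecognised pathway file %s", f.name)
    if not networks:
        raise ValueError(f"no pathway files found under {path}")
    return networks


def run_study(
    networks: list[PathwayNetwork],
    expr: ExpressionMatrix,
    config: RunConfig | None = None,
) -> StudyResult:
    """Run the full three-stage analysis in memory."""
    config = config or RunConfig()
    grid = filtration_grid(config.step)
    rng = np.random.default_rng(config.seed)
    cond_c, cond_d = expr.conditions  # first label = control/reference

    bundles: list[PathwayResultBundle] = []
    skipped: list[str] = []
    measured = set(expr.genes)
    for net in networks:
        n_measured = sum(1 for n in net.nodes if n in measured)
        if n_measured < 2:
            logger.warning(
                "pathway %s has %d measured genes; skipping", net.pathway_id, n_measured
            )
            skipped.append(net.pathway_id)
            continue
        curves: dict[str, BettiCurve] = {}
        barcodes: dict[tuple[str, int], Barcode] = {}
        landscapes_: dict[tuple[str, int], Landscape] = {}
        dropped: dict[str, list[str]] = {}
        for cond in (cond_c, cond_d):
            fg = weight_edges(net, expr, cond)
            dropped[cond] = fg.dropped_genes
            curves[cond] = betti_curve(fg, grid, config.backend)
            for dim in config.dimensions:
                bc = persistence_pairs(fg, grid, dim, config.backend)
                if config.drop_essential:
                    bc = bc.drop_essential()
                barcodes[(cond, dim)] = bc
                ls = landscape(bc, grid)
                ls.provenance = net.pathway_id
                landscapes_[(cond, dim)] = ls
        bundles.append(
            PathwayResultBundle(net.pathway_id, curves, barcodes, landscapes_, dropped)
        )
    if not bundles:
        raise ValueError("no pathway with >= 2 measured genes")

    landscapes_by_dim = {
        dim: (
            [b.landscapes[(cond_c, dim)] for b in bundles],
            [b.landscapes[(cond_d, dim)] for b in bundles],
        )
        for dim in config.dimensions
    }
    global_results = global_tests(
        landscapes_by_dim,
        n_perm=config.n_perm_global,
        seed=int(rng.integers(2**31 - 1)),
        estimator=config.estimator,
        bh_family=config.bh_family,
    )

    pathway_results = []
    for b in bundles:
        pathway_results.append(
            score_pathway(
                b.pathway_id,
                {d: b.curves[cond_c].series(d) for d in config.dimensions},
                {d: b.curves[cond_d].series(d) for d in config.dimensions},
                n_perm=config.n_perm_pathway,
                rng=rng,
                estimator=config.estimator,
            )
        )
    pathway_significance(pathway_results, config.alpha)

    return StudyResult(
        config=config,
        conditions=(cond_c, cond_d),
        pathways=bundles,
        skipped=skipped,
        global_results=global_results,
        pathway_results=pathway_results,
    )


# ---------------------------------------------------------------------------
# tabular export

def curves_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for b in result.pathways:
        for cond, curve in b.curves.items():
            for dim, series in curve.values.items():
                for f, beta in zip(curve.grid, series):
                    rows.append(
                        {"pathway_id": b.pathway_id, "condition": cond,
                         "dimension": dim, "f": float(f), "betti": int(beta)}
                    )
    return pd.DataFrame(rows)


def barcodes_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for b in result.pathways:
        for (cond, dim), bc in b.barcodes.items():
            for (birth, death), ess in zip(bc.bars, bc.essential):
                rows.append(
                    {"pathway_id": b.pathway_id, "condition": cond,
                     "dimension": dim, "birth": birth, "death": death,
                     "essential": ess}
                )
    return pd.DataFrame(rows)


def landscapes_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for b in result.pathways:
        for (cond, dim), ls in b.landscapes.items():
            for k in range(ls.n_levels):
                for t, v in zip(ls.grid, ls.levels[k]):
                    rows.append(
                        {"pathway_id": b.pathway_id, "condition": cond,
                         "dimension": dim, "level": k + 1, "t": float(t),
                         "value": float(v)}
                    )
    return pd.DataFrame(rows)


def pathway_tests_frame(result: StudyResult) -> pd.DataFrame:
    rows = []
    for r in result.pathway_results:
        for dim, st in r.dims.items():
            rows.append(
                {"pathway_id": r.pathway_id, "dim": dim, "K": st.ks, "d": st.d,
                 "mu_delta": st.mu_delta, "s_pooled": st.s_pooled,
                 "p_ks": st.p_ks, "p_d": st.p_d, "q_ks": st.q_ks, "q_d": st.q_d,
                 "significant": r.significant}
            )
    return pd.DataFrame(rows)


def write_outputs(result: StudyResult, out_dir: str | Path) -> None:
    """Write the CSV/JSON artifact bundle of a run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves_frame(result).to_csv(out / "betti_curves.csv", index=False)
    barcodes_frame(result).to_csv(out / "barcodes.csv", index=False)
    landscapes_frame(result).to_csv(out / "landscapes.csv", index=False)
    pathway_tests_frame(result).to_csv(out / "pathway_tests.csv", index=False)
    summary = {
        "config": asdict(result.config),
        "conditions": list(result.conditions),
        "skipped_pathways": result.skipped,
        "dropped_genes": {
            b.pathway_id: b.dropped_genes for b in result.pathways
        },
        "global_tests": [
            row for res in result.global_results.values() for row in res.summary()
        ],
        "significant_pathways": result.significant,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


def run(config: RunConfig) -> StudyResult:
    """Load inputs per ``config``, run the study, and write outputs."""
    condition_map = read_condition_map(Path(config.conditions).read_text())
    expr = read_expression(Path(config.expression).read_text(), condition_map)
    networks = load_pathways(config.pathways)
    result = run_study(networks, expr, config)
    if config.out_dir:
        write_outputs(result, config.out_dir)
    return result
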