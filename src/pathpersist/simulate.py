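"""Synthetic networks and expression data for offline testing and studies.

Three generators live here:

* :func:`toy_network` — a 10-gene digraph with two planted cycles (a
  canonical 4-cycle g1->g2->g3->g4->g1 and a "directional cross-talk"
  bi-fan g6->g7, g6->g8, g9->g7, g9->g8), a pendant gene g5 attached to
  the first cycle and an isolated gene g10.  Fully connected it has
  beta_0 = 3 weak components and beta_1 = 2 independent cycles.
* :func:`simulate_expression` — two-condition expression matrices whose
  pairwise Pearson correlations converge to prescribed targets, via a
  correlation-matrix (single-draw multivariate normal) construction.
* :func:`two_condition_study` — a multi-pathway benchmark with a known
  subset of "rewired" pathways whose co-expression is strong in the
  disease condition and weak in the control condition.

The toy network's canonical edge distances come from a one-factor model
per component (gene i carries a loading l_i; the distance of edge (i, j)
is 1 - l_i * l_j).  The loadings are chosen so the filtration passes the
qualitative milestones of interest: only g9->g7 (d = 0.184) is present at
threshold 0.2, the bi-fan cycle is complete by 0.4 (nine weak components
left at 0.2, seven at 0.4), and the last edge arrives at 0.946 so the full
network is visible from threshold 0.95 on.  The factor construction also
makes every implied correlation matrix positive semi-definite, so the same
numbers drive the expression simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix
from .homology import FilteredDigraph
from .pathway_io import PathwayNetwork

#: single-factor loadings behind the toy network's canonical distances
_TOY_LOADINGS = {
    "g1": 0.9, "g2": 0.6, "g3": 0.55, "g4": 0.5, "g5": 0.06,
    "g6": 0.83, "g7": 0.96, "g8": 0.75, "g9": 0.85, "g10": 0.0,
}

_TOY_COMPONENTS = (("g1", "g2", "g3", "g4", "g5"), ("g6", "g7", "g8", "g9"))


def toy_network(g5_edge: tuple[str, str] = ("g1", "g5")) -> PathwayNetwork:
    """The 10-gene toy pathway with two cycles, a pendant gene and an isolate.

    ``g5_edge`` configures how the pendant gene g5 attaches to the first
    cycle; the Betti numbers of the full network are invariant to this
    choice (a pendant edge creates no cycle and merges no components
    beyond its own).
    """
    if "g5" not in g5_edge:
        raise ValueError("g5_edge must involve g5")
    edges = [
        ("g1", "g2", "activation"),
        ("g2", "g3", "activation"),
        ("g3", "g4", "activation"),
        ("g4", "g1", "activation"),
        ("g6", "g7", "activation"),
        ("g6", "g8", "activation"),
        ("g9", "g7", "activation"),
        ("g9", "g8", "activation"),
        (g5_edge[0], g5_edge[1], "other"),
    ]
    return PathwayNetwork(
        pathway_id="toy",
        name="two-cycle toy pathway",
        nodes=[f"g{i}" for i in range(1, 11)],
        edges=edges,
    )


def toy_edge_distances(network: PathwayNetwork | None = None) -> dict[tuple[str, str], float]:
    """Canonical correlation distances 1 - |rho| for the toy network's edges."""
    if network is None:
        network = toy_network()
    return {
        (s, t): round(1.0 - _TOY_LOADINGS[s] * _TOY_LOADINGS[t], 6)
        for s, t in network.edge_pairs()
    }


def toy_filtered_digraph(condition: str = "C",
                         network: PathwayNetwork | None = None) -> FilteredDigraph:
    """The toy network wired with its canonical edge distances."""
    if network is None:
        network = toy_network()
    return FilteredDigraph(
        network=network,
        edge_weights=toy_edge_distances(network),
        condition=condition,
    )


def toy_target_correlations() -> dict[tuple[str, str], float]:
    """Target |rho| for every within-component gene pair of the toy network."""
    targets: dict[tuple[str, str], float] = {}
    for comp in _TOY_COMPONENTS:
        for i, a in enumerate(comp):
            for b in comp[i + 1:]:
                targets[(a, b)] = _TOY_LOADINGS[a] * _TOY_LOADINGS[b]
    return targets


@dataclass
class SimulationSpec:
    """Parameters for the two-condition expression simulator.

    ``target_correlations`` prescribes |rho| per gene pair for the first
    condition; ``target_correlations_d`` (default: same map) for the
    second, so "rewired" scenarios can differ between conditions.  Pairs
    not listed are independent.  ``noise_sd`` adds gene-wise independent
    noise whose attenuation is pre-compensated so realised correlations
    still converge to their targets.
    """

    network: PathwayNetwork
    n_samples: int = 17
    target_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    target_correlations_d: dict[tuple[str, str], float] | None = None
    noise_sd: float = 0.0
    seed: int | None = None
    conditions: tuple[str, str] = ("C", "D")

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3 per condition")
        for targets in (self.target_correlations, self.target_correlations_d or {}):
            for pair, t in targets.items():
                if not (0.0 <= t <= 1.0):
                    raise ValueError(f"target |rho| {t} for {pair} outside [0, 1]")


def _correlation_matrix(
    genes: list[str],
    targets: dict[tuple[str, str], float],
    inflate: float,
) -> np.ndarray:
    idx = {g: i for i, g in enumerate(genes)}
    r = np.eye(len(genes))
    for (a, b), t in targets.items():
        if a not in idx or b not in idx:
            raise ValueError(f"target pair ({a}, {b}) not in gene set")
        t_signal = t * inflate
        if t_signal > 1.0 + 1e-12:
            raise ValueError(
                f"target |rho|={t} for ({a}, {b}) infeasible at noise_sd given; "
                "relax the target or reduce noise_sd"
            )
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = min(t_signal, 1.0)
    return r


def _sample_correlated(
    r: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-8:
        raise ValueError(
            "target correlation structure is not positive semi-definite; "
            "relax conflicting targets"
        )
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((r.shape[0], n_samples))
    return factor @ z


def simulate_expression(spec: SimulationSpec) -> ExpressionMatrix:
    """Draw a two-condition expression matrix with prescribed correlations.

    Profiles are multivariate normal with unit variances and the target
    correlation matrix (positive sign convention), plus optional
    independent noise; realised |Pearson rho| of each specified pair
    converges to its target as ``n_samples`` grows.  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.network.nodes
    inflate = 1.0 + spec.noise_sd**2
    cond_targets = [
        spec.target_correlations,
        spec.target_correlations_d
        if spec.target_correlations_d is not None
        else spec.target_correlations,
    ]
    blocks = []
    samples: list[str] = []
    condition_map: dict[str, str] = {}
    for cond, targets in zip(spec.conditions, cond_targets):
        r = _correlation_matrix(genes, targets, inflate)
        x = _sample_correlated(r, spec.n_samples, rng)
        if spec.noise_sd > 0.0:
            x = x + spec.noise_sd * rng.standard_normal(x.shape)
        blocks.append(x)
        for i in range(spec.n_samples):
            sid = f"{cond}{i + 1}"
            samples.append(sid)
            condition_map[sid] = cond
    return ExpressionMatrix(
        genes=list(genes),
        samples=samples,
        values=np.hstack(blocks),
        condition_map=condition_map,
    )


def two_condition_study(
    n_pathways: int = 20,
    n_planted: int = 5,
    n_samples: int = 17,
    strong: float = 0.9,
    weak: float = 0.15,
    base: float = 0.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[list[PathwayNetwork], ExpressionMatrix, list[str]]:
    """A planted-signal benchmark of toy-topology pathways.

    Every pathway is a copy of the 10-gene toy topology on its own genes.
    The first ``n_planted`` pathways are rewired: within-component
    co-expression is ``strong`` in the disease condition but only ``weak``
    in the control condition, so components merge (and cycles form) much
    earlier in disease.  The remaining pathways use ``base`` co-expression
    in both conditions.  Returns (networks, expression, planted ids).
    """
    if not 0 <= n_planted <= n_pathways:
        raise ValueError("need 0 <= n_planted <= n_pathways")
    rng = np.random.default_rng(seed)
    networks: list[PathwayNetwork] = []
    planted: list[str] = []
    all_genes: list[str] = []
    targets_c: dict[tuple[str, str], float] = {}
    targets_d: dict[tuple[str, str], float] = {}
    for k in range(n_pathways):
        pid = f"path{k:02d}"
        prefix = f"p{k:02d}_"
        base_net = toy_network()
        net = PathwayNetwork(
            pathway_id=pid,
            name=f"synthetic pathway {k}",
            nodes=[prefix + n for n in base_net.nodes],
            edges=[(prefix + s, prefix + t, r) for s, t, r in base_net.edges],
        )
        networks.append(net)
        all_genes.extend(net.nodes)
        is_planted = k < n_planted
        if is_planted:
            planted.append(pid)
        rho_c = weak if is_planted else base
        rho_d = strong if is_planted else base
        for comp in _TOY_COMPONENTS:
            named = [prefix + g for g in comp]
            for i, a in enumerate(named):
                for b in named[i + 1:]:
                    targets_c[(a, b)] = rho_c
                    targets_d[(a, b)] = rho_d
    union = PathwayNetwork(pathway_id="study", nodes=all_genes, edges=[])
    spec = SimulationSpec(
        network=union,
        n_samples=n_samples,
        target_correlations=targets_c,
        target_correlations_d=targets_d,
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    return networks, simulate_expression(spec), planted


def write_kgml_fixture(
    network: PathwayNetwork,
    groups: dict[str, list[str]] | None = None,
) -> str:
    """Emit minimal KGML that :func:`pathpersist.pathway_io.parse_kgml` inverts.

    Group nodes listed in ``groups`` become KGML group entries whose
    components are the member genes; relations incident to a group then
    expand onto every member at parse time.
    """
    groups = groups or {}
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name="{network.pathway_id}" title="{network.name}">',
    ]
    entry_id: dict[str, int] = {}
    next_id = 1
    plain = [n for n in network.nodes if n not in groups]
    members = [m for g in groups.values() for m in g]
    for sym in dict.fromkeys(plain + members):
        entry_id[sym] = next_id
        lines.append(f'  <entry id="{next_id}" name="{sym}" type="gene"/>')
        next_id += 1
    for g, mem in groups.items():
        entry_id[g] = next_id
        lines.append(f'  <entry id="{next_id}" type="group">')
        for m in mem:
            lines.append(f'    <component id="{entry_id[m]}"/>')
        lines.append("  </entry>")
        next_id += 1
    subtype = {"activation": "activation", "inhibition": "inhibition",
               "other": "binding/association"}
    for s, t, r in network.edges:
        lines.append(
            f'  <relation entry1="{entry_id[s]}" entry2="{entry_id[t]}" type="PPrel">'
        )
        lines.append(f'    <subtype name="{subtype[r]}" value="--"/>')
        lines.append("  </relation>")
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"
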