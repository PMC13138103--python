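"""Independent brute-force path homology oracle (sympy, exhaustive bases).

Deliberately naive and structurally different from the library: all
regular p-paths are enumerated exhaustively over vertex tuples, chain
spaces and boundary maps are built as dense sympy matrices over the whole
regular-path basis, and Omega spaces come from sympy nullspaces.  Used
only to cross-check the production implementation on small graphs.
"""

from __future__ import annotations

import itertools

import sympy


def regular_paths(nodes: list[str], p: int) -> list[tuple[str, ...]]:
    """All vertex sequences of length p+1 without immediate repeats."""
    out = []
    for tup in itertools.product(nodes, repeat=p + 1):
        if all(tup[i] != tup[i + 1] for i in range(p)):
            out.append(tup)
    return out


def allowed_paths(nodes, edges, p) -> list[tuple[str, ...]]:
    edge_set = set(edges)
    return [
        tup
        for tup in regular_paths(nodes, p)
        if all((tup[i], tup[i + 1]) in edge_set for i in range(p))
    ]


def boundary_on_regular(nodes: list[str], p: int) -> tuple[sympy.Matrix, list, list]:
    """Full boundary map from regular p-paths to regular (p-1)-paths."""
    domain = regular_paths(nodes, p)
    codomain = regular_paths(nodes, p - 1)
    cod_index = {path: i for i, path in enumerate(codomain)}
    mat = sympy.zeros(len(codomain), len(domain))
    for j, path in enumerate(domain):
        for i in range(p + 1):
            face = path[:i] + path[i + 1:]
            if face in cod_index:  # irregular faces vanish
                mat[cod_index[face], j] += (-1) ** i
    return mat, domain, codomain


def _span_columns(vectors: list[sympy.Matrix], length: int) -> sympy.Matrix:
    if not vectors:
        return sympy.zeros(length, 0)
    return sympy.Matrix.hstack(*vectors)


def omega_basis(nodes, edges, p) -> tuple[sympy.Matrix, list]:
    """Columns spanning Omega_p inside the regular p-path basis."""
    reg_p = regular_paths(nodes, p)
    allowed_p = set(allowed_paths(nodes, edges, p))
    if p == 0:
        basis = []
        for i, path in enumerate(reg_p):
            if path in allowed_p:
                v = sympy.zeros(len(reg_p), 1)
                v[i] = 1
                basis.append(v)
        return _span_columns(basis, len(reg_p)), reg_p
    d, domain, codomain = boundary_on_regular(nodes, p)
    allowed_prev = set(allowed_paths(nodes, edges, p - 1))
    # constraints: coordinates on non-allowed p-paths are 0 and the boundary
    # is supported on allowed (p-1)-paths
    constraints = []
    for i, path in enumerate(domain):
        if path not in allowed_p:
            row = sympy.zeros(1, len(domain))
            row[i] = 1
            constraints.append(row)
    for i, face in enumerate(codomain):
        if face not in allowed_prev:
            constraints.append(d[i, :])
    if constraints:
        null = sympy.Matrix.vstack(*constraints).nullspace()
    else:
        null = sympy.eye(len(domain)).columnspace()
    return _span_columns(list(null), len(domain)), domain


def betti_numbers(nodes: list[str], edges: list[tuple[str, str]]) -> tuple[int, int]:
    """(beta_0, beta_1) by exhaustive bases and sympy exact rank."""
    omega0, _ = omega_basis(nodes, edges, 0)
    omega1, _ = omega_basis(nodes, edges, 1)
    omega2, _ = omega_basis(nodes, edges, 2)
    d1, _, _ = boundary_on_regular(nodes, 1)
    d2, _, _ = boundary_on_regular(nodes, 2)
    d1_on = d1 * omega1
    d2_on = d2 * omega2
    beta0 = omega0.shape[1] - d1_on.rank()
    dim_z1 = omega1.shape[1] - d1_on.rank()
    beta1 = dim_z1 - d2_on.rank()
    return beta0, beta1


def persistent_beta1(
    nodes: list[str],
    edges_small: list[tuple[str, str]],
    edges_big: list[tuple[str, str]],
) -> int:
    """dim Z_1(G_i) - dim(Z_1(G_i) ∩ B_1(G_j)) for nested edge sets."""
    assert set(edges_small) <= set(edges_big)
    omega1_small, domain1 = omega_basis(nodes, edges_small, 1)
    omega2_big, _ = omega_basis(nodes, edges_big, 2)
    d1, _, _ = boundary_on_regular(nodes, 1)
    d2, _, _ = boundary_on_regular(nodes, 2)
    z_small = (d1 * omega1_small).nullspace()
    z_cols = _span_columns([omega1_small * v for v in z_small], len(domain1))
    b_cols = d2 * omega2_big
    dim_z = z_cols.rank()
    dim_b = b_cols.rank()
    joint = sympy.Matrix.hstack(z_cols, b_cols).rank()
    return dim_z - (dim_z + dim_b - joint)


def random_digraph(rng, n_nodes: int, p_edge: float = 0.3):
    """A random simple digraph (no self-loops) as (nodes, edges)."""
    nodes = [f"v{i}" for i in range(n_nodes)]
    edges = [
        (a, b)
        for a in nodes
        for b in nodes
        if a != b and rng.random() < p_edge
    ]
    return nodes, edges
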