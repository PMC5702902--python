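"""Independent brute-force LP oracle for small networks.

Enumerates every basic feasible solution (vertex) of
{S v = 0, l <= v <= u}: for each choice of a basic index set B of size
rank(S) and each assignment of the non-basic variables to their lower or
upper bounds, solve the square system for the basic variables and keep the
point if it is feasible. The optimum of a bounded LP is attained at a
vertex, so the maximal objective over the vertex list equals the LP
optimum. Exponential, usable only for networks with <= ~10 reactions; it
deliberately shares no code with the package's linprog-based solver.
"""

from itertools import combinations, product

import numpy as np

from hepaflux.network import build_stoichiometric_matrix


def enumerate_vertices(S, lb, ub, tol=1e-9):
    """All vertices of {S v = 0, lb <= v <= ub}, deduplicated."""
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = S.shape[1]
    m = np.linalg.matrix_rank(S) if S.size else 0
    vertices = []
    for basic in combinations(range(n), m):
        B = S[:, basic]
        if np.linalg.matrix_rank(B) < m:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for choice in product((0, 1), repeat=len(nonbasic)):
            v = np.zeros(n)
            for j, c in zip(nonbasic, choice):
                v[j] = lb[j] if c == 0 else ub[j]
            rhs = -S[:, nonbasic] @ v[nonbasic] if nonbasic else np.zeros(S.shape[0])
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v[list(basic)] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if not any(np.allclose(v, w, atol=1e-7) for w in vertices):
                vertices.append(v)
    return vertices


def oracle_fba(network, objective, tol=1e-9):
    """(z_max, optimal_vertices) by exhaustive vertex enumeration."""
    S = build_stoichiometric_matrix(network)
    lb = np.array([r.lower_bound for r in network.reactions])
    ub = np.array([r.upper_bound for r in network.reactions])
    a = np.array([objective.coefficients.get(rid, 0.0)
                  for rid in network.reaction_ids])
    vertices = enumerate_vertices(S, lb, ub, tol=tol)
    if not vertices:
        return None, []
    values = [float(a @ v) for v in vertices]
    z_max = max(values)
    optima = [v for v, z in zip(vertices, values)
              if abs(z - z_max) <= 1e-7 * max(1.0, abs(z_max))]
    return z_max, optima
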