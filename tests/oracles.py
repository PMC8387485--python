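"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package internals: the skeleton
census oracle works on an explicit pixel-adjacency graph with set
operations (no path tracing), the Welch oracle integrates the t density
numerically from its closed form, and the area oracle is a literal
flood fill.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy.integrate import quad


def pixel_graph(sk: np.ndarray) -> nx.Graph:
    coords = [tuple(c) for c in np.argwhere(sk)]
    present = set(coords)
    G = nx.Graph()
    G.add_nodes_from(coords)
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=sk.ndim) if any(o)]
    for p in coords:
        for o in offsets:
            q = tuple(pi + oi for pi, oi in zip(p, o))
            if q in present:
                G.add_edge(p, q)
    return G


def brute_force_census(sk: np.ndarray) -> dict:
    """Junction/branch census from the raw pixel-adjacency graph.

    Nodes are junction-pixel clusters (pixel degree >= 3, merged when
    touching) plus individual endpoint/isolated pixels; branches are slab
    components with their node attachments, direct node-node adjacencies,
    and pure cycles.  Node degree is the number of incident branch ends.
    """
    G = pixel_graph(np.asarray(sk, dtype=bool))
    deg = dict(G.degree())
    junction_px = {p for p, d in deg.items() if d >= 3}
    slab_px = {p for p, d in deg.items() if d == 2}
    loose_px = {p for p, d in deg.items() if d <= 1}

    node_of = {}
    node_ids = []
    for i, comp in enumerate(nx.connected_components(G.subgraph(junction_px))):
        node_ids.append(i)
        for p in comp:
            node_of[p] = i
    nid = len(node_ids)
    for p in sorted(loose_px):
        node_of[p] = nid
        node_ids.append(nid)
        nid += 1

    incidences: dict[int, int] = {i: 0 for i in node_ids}
    n_branches = 0

    for comp in nx.connected_components(G.subgraph(slab_px)):
        attach = []
        for p in comp:
            for q in G.neighbors(p):
                if q not in slab_px:
                    attach.append(node_of[q])
        if attach:
            n_branches += 1
            for a in attach:
                incidences[a] += 1
        else:  # pure cycle
            n_branches += 1

    for p, q in G.edges():
        if p not in slab_px and q not in slab_px and node_of[p] != node_of[q]:
            n_branches += 1
            incidences[node_of[p]] += 1
            incidences[node_of[q]] += 1

    n3 = sum(1 for v in incidences.values() if v == 3)
    n4 = sum(1 for v in incidences.values() if v == 4)
    nh = sum(1 for v in incidences.values() if v >= 5)
    return {
        "n_triple": n3,
        "n_quadruple": n4,
        "n_higher": nh,
        "n_junctions": n3 + n4 + nh,
        "n_branches": n_branches,
    }


def welch_oracle(a, b) -> tuple[float, float, float]:
    """Welch t, df and two-sided p with the p-value obtained by numerical
    integration of the t density (no scipy.stats distribution calls)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))

    def t_pdf(x):
        return (
            math.exp(math.lgamma((df + 1) / 2) - math.lgamma(df / 2))
            / math.sqrt(df * math.pi)
            * (1 + x * x / df) ** (-(df + 1) / 2)
        )

    tail, _ = quad(t_pdf, abs(t), np.inf)
    return t, df, min(2.0 * tail, 1.0)


def flood_fill_areas(mask: np.ndarray, connectivity: int = 1) -> list[int]:
    """Areas of background components by literal stack-based flood fill."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    if connectivity == 1:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offs = [o for o in itertools.product((-1, 0, 1), repeat=2) if any(o)]
    areas = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] or seen[r, c]:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            area = 0
            while stack:
                y, x = stack.pop()
                area += 1
                for dy, dx in offs:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and not mask[yy, xx] and not seen[yy, xx]:
                        seen[yy, xx] = True
                        stack.append((yy, xx))
            areas.append(area)
    return areas


def stripe_pattern(theta_deg: float, shape=(128, 128), period: float = 8.0) -> np.ndarray:
    """Sinusoidal stripes whose structure axis lies at ``theta_deg`` in the
    display convention (x right, y down, angles counter-clockwise)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    th = np.deg2rad(theta_deg)
    u = xx * np.sin(th) + yy * np.cos(th)
    return 0.5 + 0.5 * np.sin(2 * np.pi * u / period)
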