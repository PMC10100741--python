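"""Independent brute-force oracles.

Everything here is deliberately written with plain loops and dictionaries,
sharing no code with the package, so that agreement with the vectorized
implementations is a meaningful check.
"""

from __future__ import annotations

import itertools
import math

GAP = "-"
AA = "ACDEFGHIKLMNPQRSTVWY"


def _pair_observations(rows: list[str], i: int, j: int) -> list[tuple[str, str]]:
    return [
        (r[i], r[j]) for r in rows if r[i] != GAP and r[j] != GAP
    ]


def mi_oracle(rows: list[str], i: int, j: int) -> float | None:
    obs = _pair_observations(rows, i, j)
    if len(obs) < 2:
        return None
    n = len(obs)
    joint: dict[tuple[str, str], int] = {}
    left: dict[str, int] = {}
    right: dict[str, int] = {}
    for a, b in obs:
        joint[(a, b)] = joint.get((a, b), 0) + 1
        left[a] = left.get(a, 0) + 1
        right[b] = right.get(b, 0) + 1
    total = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        total += pab * math.log2(pab / ((left[a] / n) * (right[b] / n)))
    return total


def omes_oracle(rows: list[str], i: int, j: int) -> float | None:
    obs = _pair_observations(rows, i, j)
    if len(obs) < 2:
        return None
    n = len(obs)
    joint: dict[tuple[str, str], int] = {}
    left: dict[str, int] = {}
    right: dict[str, int] = {}
    for a, b in obs:
        joint[(a, b)] = joint.get((a, b), 0) + 1
        left[a] = left.get(a, 0) + 1
        right[b] = right.get(b, 0) + 1
    total = 0.0
    for a in left:
        for b in right:
            n_obs = joint.get((a, b), 0)
            n_exp = left[a] * right[b] / n
            total += (n_obs - n_exp) ** 2
    return total / n


def sca_oracle(rows: list[str], i: int, j: int, lam: float = 0.03) -> float | None:
    obs = _pair_observations(rows, i, j)
    if len(obs) < 2:
        return None
    n = len(obs)
    q = 1.0 / 20.0

    def phi(freq: float) -> float:
        f = (1.0 - lam) * freq + lam * q
        return abs(math.log(f * (1.0 - q) / ((1.0 - f) * q)))

    total = 0.0
    for a in AA:
        fa = sum(1 for x, _ in obs if x == a) / n
        for b in AA:
            fb = sum(1 for _, y in obs if y == b) / n
            fab = sum(1 for x, y in obs if x == a and y == b) / n
            total += (phi(fa) * phi(fb) * (fab - fa * fb)) ** 2
    return math.sqrt(total)


def mip_oracle(rows: list[str], columns: list[int]) -> dict[tuple[int, int], float]:
    """MIp over the given columns via the average-product correction."""
    mi: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(columns, 2):
        v = mi_oracle(rows, i, j)
        if v is not None:
            mi[(i, j)] = v
    row_mean: dict[int, float] = {}
    for c in columns:
        vals = [v for (i, j), v in mi.items() if c in (i, j)]
        if vals:
            row_mean[c] = sum(vals) / len(vals)
    grand = sum(mi.values()) / len(mi)
    out = {}
    for (i, j), v in mi.items():
        if grand == 0:
            out[(i, j)] = v
        else:
            out[(i, j)] = v - row_mean[i] * row_mean[j] / grand
    return out


# ---------------------------------------------------------------------------
# Graph modularity by exhaustive partition enumeration
# ---------------------------------------------------------------------------

def _partitions(items: list):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1 :]
        yield [[first]] + part


def modularity_oracle(edges: list[tuple], nodes: list) -> tuple[float, list[list]]:
    """(max modularity, best partition) by enumerating all partitions."""
    m = len(edges)
    degree: dict = {v: 0 for v in nodes}
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1

    def q(partition: list[list]) -> float:
        total = 0.0
        for comm in partition:
            s = set(comm)
            lc = sum(1 for u, v in edges if u in s and v in s)
            dc = sum(degree[v] for v in s)
            total += lc / m - (dc / (2 * m)) ** 2
        return total

    best_q, best_p = -math.inf, None
    for part in _partitions(list(nodes)):
        value = q(part)
        if value > best_q:
            best_q, best_p = value, part
    return best_q, best_p


# ---------------------------------------------------------------------------
# Structure distances by all-atom double loop
# ---------------------------------------------------------------------------

def min_distance_oracle(atoms_a: list[tuple], atoms_b: list[tuple]) -> float:
    best = math.inf
    for xa, ya, za in atoms_a:
        for xb, yb, zb in atoms_b:
            d = math.sqrt((xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2)
            best = min(best, d)
    return best
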