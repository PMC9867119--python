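"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is written from the definition of the quantity it checks and
shares no code path with the package: exhaustive substring matching for
seed sites, quadratic ECDF sup-distance for KS, all-pairs intersection for
interval overlap, and the textbook pooled-variance t statistic with a
p-value obtained by numeric integration of the t density.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_TYPE_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def oracle_scan(seq: str, mature_seq: str) -> list[tuple[int, int, str]]:
    """Exhaustive seed-site scan: every position, every type, then the same
    precedence / greedy non-overlap rules applied by hand.

    Returns (start, end, match_type) tuples.
    """
    seq = seq.upper().replace("T", "U")
    seed = mature_seq.upper().replace("T", "U")[1:8]
    m8 = "".join(_COMP[c] for c in reversed(seed))
    strings = {
        "8mer": m8 + "A",
        "7mer-m8": m8,
        "7mer-A1": m8[1:] + "A",
        "6mer": m8[1:],
    }
    candidates = []
    for rank, ty in enumerate(_TYPE_ORDER):
        s = strings[ty]
        for i in range(len(seq) - len(s) + 1):
            if seq[i : i + len(s)] == s:
                candidates.append((i, rank, i + len(s), ty))
    candidates.sort(key=lambda c: (c[0], c[1]))
    out: list[tuple[int, int, str]] = []
    cursor = 0
    for i, _rank, end, ty in candidates:
        if i >= cursor:
            out.append((i, end, ty))
            cursor = end
    return out


def oracle_ks_d(a, b) -> float:
    """Quadratic-time KS statistic: sup over all observed thresholds."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for t in np.concatenate([a, b]):
        diff = abs((a <= t).mean() - (b <= t).mean())
        best = max(best, diff)
    return best


def oracle_overlap(site: tuple[int, int], peak: tuple[int, int]) -> bool:
    """All-pairs interval intersection >= 1 nt, half-open semantics."""
    return min(site[1], peak[1]) - max(site[0], peak[0]) >= 1


def oracle_t_statistic(x, y) -> tuple[float, int]:
    """Textbook pooled-variance Student's t and its degrees of freedom."""
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    mx = sum(x) / n1
    my = sum(y) / n2
    s1 = sum((v - mx) ** 2 for v in x) / (n1 - 1)
    s2 = sum((v - my) ** 2 for v in y) / (n2 - 1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    t = (mx - my) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, df


def oracle_t_pvalue(t: float, df: int) -> float:
    """Two-sided p by numeric integration of the t density."""

    def density(u):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _err = quad(density, abs(t), np.inf)
    return 2 * tail


def oracle_fpkm(count: float, length: float, total: float) -> float:
    """Scalar FPKM from the definition."""
    return count * 1e9 / (length * total)


def oracle_targeted_fractions(counts) -> tuple[float, float]:
    """Simple loop over genes."""
    n = len(counts)
    ge1 = sum(1 for c in counts if c >= 1)
    ge2 = sum(1 for c in counts if c >= 2)
    return ge1 / n, ge2 / n


def oracle_enrichment_tally(flags) -> dict:
    """Brute-force tally of validated counts by (ago2, cons) cell.

    ``flags`` is an iterable of (ago2, cons_class, validated) triples.
    """
    out: dict = {}
    for ago2, cons, validated in flags:
        for key in ((ago2, cons), (ago2, "all")):
            n, nv = out.get(key, (0, 0))
            out[key] = (n + 1, nv + bool(validated))
    return out
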