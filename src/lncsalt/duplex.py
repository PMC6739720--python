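"""Minimum free energy of an intermolecular RNA-RNA duplex.

Deliberately reduced hybridization model: Watson-Crick and GU pairs,
nearest-neighbor stacking energies, a single affine penalty for bulges and
interior loops (open + per-nucleotide extension), a duplex initiation
constant, and no intramolecular structure or dangling ends. Watson-Crick
stack values are the standard 37 C nearest-neighbor set; stacks involving a
GU pair are approximated by scaling the corresponding AU-substituted stack
(documented stand-in, validated against the in-repo enumeration oracle).

Sign convention: energies in kcal/mol, more negative = more stable; 0 is
returned when no duplex with negative energy exists.
"""

from __future__ import annotations

INITIATION = 4.09
LOOP_OPEN = 3.2
LOOP_EXT = 0.4
GU_SCALE = 0.6

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}
PAIRS = _WC | _GU

# canonical Watson-Crick nearest-neighbor dG37 values, written 5'XY3'/3'ZW5'
# as ((X, Z), (Y, W)): pair (X,Z) stacked on pair (Y,W)
_CANONICAL_WC = {
    (("A", "T"), ("A", "T")): -0.93,
    (("A", "T"), ("T", "A")): -1.10,
    (("T", "A"), ("A", "T")): -1.33,
    (("C", "G"), ("T", "A")): -2.08,
    (("C", "G"), ("A", "T")): -2.11,
    (("G", "C"), ("T", "A")): -2.24,
    (("G", "C"), ("A", "T")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
}


def _build_stacks() -> dict[tuple[tuple[str, str], tuple[str, str]], float]:
    table: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}

    def put(p1, p2, e):
        table[(p1, p2)] = e
        # reading the helix from the other end is the same physical stack
        table[((p2[1], p2[0]), (p1[1], p1[0]))] = e

    for (p1, p2), e in _CANONICAL_WC.items():
        put(p1, p2, e)
    # GU-containing stacks: substitute G->A or U->C to reach the WC analogue
    sub = {("G", "T"): ("A", "T"), ("T", "G"): ("T", "A")}
    for p1 in PAIRS:
        for p2 in PAIRS:
            if (p1, p2) in table:
                continue
            q1 = sub.get(p1, p1)
            q2 = sub.get(p2, p2)
            base = table.get((q1, q2))
            if base is None:
                continue
            n_gu = (p1 in _GU) + (p2 in _GU)
            put(p1, p2, round(base * (GU_SCALE ** n_gu), 3))
    return table


STACKS = _build_stacks()


def can_pair(x: str, y: str) -> bool:
    return (x, y) in PAIRS


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


def duplex_energy(a: str, b: str) -> float:
    """Minimum duplex free energy between sequences a and b (both 5'->3')."""
    a = _clean(a)
    # reverse b so the antiparallel duplex becomes a co-linear alignment
    rb = _clean(b)[::-1]
    n, m = len(a), len(rb)
    if n < 2 or m < 2:
        return 0.0
    INF = float("inf")
    # H[i][j]: best energy of a duplex whose last pair is (a[i], rb[j])
    # F[i][j]: best energy of a partial duplex with an open loop ending at (i, j)
    H = [[INF] * m for _ in range(n)]
    F = [[INF] * m for _ in range(n)]
    best = INF
    for i in range(n):
        ai = a[i]
        Hi = H[i]
        Fi = F[i]
        Hprev = H[i - 1] if i else None
        Fprev = F[i - 1] if i else None
        for j in range(m):
            pair = (ai, rb[j])
            if pair in PAIRS:
                e = 0.0  # opening pair of the duplex
                if i and j:
                    prev_pair = (a[i - 1], rb[j - 1])
                    if prev_pair in PAIRS and Hprev[j - 1] < INF:
                        e = min(e, Hprev[j - 1] + STACKS.get((prev_pair, pair), 0.0))
                    if Fprev[j - 1] < INF:
                        e = min(e, Fprev[j - 1])
                Hi[j] = e
                if e < best:
                    best = e
            # extend/open a loop consuming a[i] or rb[j]
            f = INF
            if i and Hprev[j] < INF:
                f = min(f, Hprev[j] + LOOP_OPEN + LOOP_EXT)
            if j and Hi[j - 1] < INF:
                f = min(f, Hi[j - 1] + LOOP_OPEN + LOOP_EXT)
            if i and Fprev[j] < INF:
                f = min(f, Fprev[j] + LOOP_EXT)
            if j and Fi[j - 1] < INF:
                f = min(f, Fi[j - 1] + LOOP_EXT)
            Fi[j] = f
    total = best + INITIATION
    return float(total) if total < 0 else 0.0


def duplex_energy_brute(a: str, b: str) -> float:
    """Exhaustive enumeration over all ordered pairings; oracle for tiny inputs."""
    a = _clean(a)
    rb = _clean(b)[::-1]
    n, m = len(a), len(rb)
    if n < 2 or m < 2:
        return 0.0
    best = [float("inf")]

    def loop_cost(g1: int, g2: int) -> float:
        if g1 == 0 and g2 == 0:
            raise AssertionError("stack handled separately")
        return LOOP_OPEN + LOOP_EXT * (g1 + g2)

    def recurse(i: int, j: int, energy: float, last: tuple[int, int] | None):
        if last is not None and energy < best[0]:
            best[0] = energy
        for ii in range(i, n):
            for jj in range(j, m):
                pair = (a[ii], rb[jj])
                if pair not in PAIRS:
                    continue
                if last is None:
                    add = 0.0
                else:
                    g1, g2 = ii - last[0] - 1, jj - last[1] - 1
                    if g1 == 0 and g2 == 0:
                        add = STACKS.get(((a[last[0]], rb[last[1]]), pair), 0.0)
                    else:
                        add = loop_cost(g1, g2)
                recurse(ii + 1, jj + 1, energy + add, (ii, jj))

    recurse(0, 0, 0.0, None)
    total = best[0] + INITIATION
    return float(total) if total < 0 else 0.0
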