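"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def bh_brute(p_values, alpha):
    """Literal step-up definition: q_i = min over j with rank >= rank_i of
    m * p_(j) / j, computed with explicit loops."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos in range(m):
        best = min(m * p[order[j]] / (j + 1) for j in range(pos, m))
        q[order[pos]] = min(best, 1.0)
    return np.array(q), np.array(q) < alpha


_OFFSETS = {
    6: [(dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) == 1],
    18: [(dx, dy, dz)
         for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if 1 <= abs(dx) + abs(dy) + abs(dz) <= 2],
    26: [(dx, dy, dz)
         for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) != (0, 0, 0)],
}


def flood_fill_components(flags, connectivity):
    """Connected components of a boolean 3-D array via breadth-first search.

    Returns a list of frozensets of (i, j, k) tuples.
    """
    flags = np.asarray(flags, dtype=bool)
    seen = np.zeros_like(flags)
    comps = []
    offsets = _OFFSETS[connectivity]
    for start in map(tuple, np.argwhere(flags)):
        if seen[start]:
            continue
        comp = set()
        queue = [start]
        seen[start] = True
        while queue:
            cur = queue.pop()
            comp.add(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(n < 0 or n >= s for n, s in zip(nb, flags.shape)):
                    continue
                if flags[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        comps.append(frozenset(comp))
    return comps
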