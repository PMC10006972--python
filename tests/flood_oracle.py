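"""Brute-force priority-flood oracle, independent of the package.

Implements the same normative flood semantics as the production code
but with naive mechanics: explicit 2-D coordinates and a linear scan
over the pending set for the minimum (gradient, insertion-order) entry
instead of a heap.  Quadratic, so only usable on tiny grids.
"""

UNLABELLED = -1
OUTSIDE = -2
LINE = 0


def oracle_flood(gradient, markers, region_mask=None):
    """Returns a list-of-lists label grid matching watershed_flood."""
    h = len(gradient)
    w = len(gradient[0])
    if region_mask is None:
        region_mask = [[True] * w for _ in range(h)]

    labels = [[OUTSIDE] * w for _ in range(h)]
    for r in range(h):
        for c in range(w):
            if region_mask[r][c]:
                labels[r][c] = markers[r][c] if markers[r][c] > 0 else UNLABELLED

    def neighbours(r, c):
        out = []
        if r > 0:
            out.append((r - 1, c))
        if r < h - 1:
            out.append((r + 1, c))
        if c > 0:
            out.append((r, c - 1))
        if c < w - 1:
            out.append((r, c + 1))
        return out

    pending = []  # entries: [gradient, insertion_order, (r, c), carried_label]
    order = 0
    for r in range(h):
        for c in range(w):
            if labels[r][c] > 0:
                for nr, nc in neighbours(r, c):
                    if labels[nr][nc] == UNLABELLED:
                        pending.append([gradient[nr][nc], order, (nr, nc), labels[r][c]])
                        order += 1

    while pending:
        best = 0
        for i in range(1, len(pending)):
            if (pending[i][0], pending[i][1]) < (pending[best][0], pending[best][1]):
                best = i
        _, _, (r, c), carried = pending.pop(best)
        if labels[r][c] != UNLABELLED:
            continue
        seen = set()
        for nr, nc in neighbours(r, c):
            if labels[nr][nc] > 0:
                seen.add(labels[nr][nc])
        if len(seen) >= 2:
            labels[r][c] = LINE
            onward = carried
        elif len(seen) == 1:
            labels[r][c] = seen.pop()
            onward = labels[r][c]
        else:
            labels[r][c] = carried
            onward = carried
        for nr, nc in neighbours(r, c):
            if labels[nr][nc] == UNLABELLED:
                pending.append([gradient[nr][nc], order, (nr, nc), onward])
                order += 1

    return labels
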