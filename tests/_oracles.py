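"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the dot-plot oracle
works on exact k-mer diagonals (no alignment scoring), the consensus oracle
counts symbols with collections.Counter, and the identity-tract oracle
enumerates runs pair by pair.
"""

from collections import Counter, defaultdict


def dotplot_segments(s1: str, s2: str, k: int = 12):
    """Maximal exact-match diagonal runs as (s1_start, s1_end, s2_start, s2_end)."""
    index = defaultdict(list)
    for i in range(len(s1) - k + 1):
        index[s1[i : i + k]].append(i)
    diag = defaultdict(list)
    for j in range(len(s2) - k + 1):
        for i in index.get(s2[j : j + k], ()):
            diag[j - i].append(j)
    segments = []
    for off, js in diag.items():
        js = sorted(js)
        start = prev = js[0]
        for j in js[1:]:
            if j == prev + 1:
                prev = j
                continue
            segments.append((start - off, prev + k - off, start, prev + k))
            start = prev = j
        segments.append((start - off, prev + k - off, start, prev + k))
    return segments


def dotplot_d(anc: str, der: str, k: int = 12):
    """d from the two longest diagonal runs (second not nested in the first)."""
    segs = sorted(dotplot_segments(anc, der, k), key=lambda s: s[3] - s[2], reverse=True)
    if not segs:
        return None
    longer_is_der = len(der) >= len(anc)
    lo, hi = (2, 3) if longer_is_der else (0, 1)
    m1 = segs[0]
    m2 = next(
        (s for s in segs[1:] if not (m1[lo] <= s[lo] and s[hi] <= m1[hi])), None
    )
    if m2 is None:
        return None
    top, bottom = sorted((m1, m2), key=lambda s: s[lo])
    if longer_is_der:
        return top[1] - bottom[0]  # projections on the ancestral (shorter)
    return top[3] - bottom[2]


def consensus_oracle(aligned):
    """Per-column plurality with tie order A<C<G<T<gap; gap-winner columns drop."""
    order = "ACGT-"
    out = []
    for col in zip(*aligned):
        counts = Counter(col)
        best = max(order, key=lambda sym: (counts.get(sym, 0), -order.index(sym)))
        if best != "-":
            out.append(best)
    return "".join(out)


def tract_length_oracle(matrix, positions, focal):
    """Mean bp length of pairwise identity tracts around one focal site."""
    n = len(matrix)
    sites = list(range(len(positions)))
    lengths = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = matrix[i], matrix[j]
            if a[focal] is None or b[focal] is None or a[focal] != b[focal]:
                continue
            lo = focal
            while lo - 1 in sites and a[lo - 1] is not None and b[lo - 1] is not None \
                    and a[lo - 1] == b[lo - 1]:
                lo -= 1
            hi = focal
            while hi + 1 in sites and a[hi + 1] is not None and b[hi + 1] is not None \
                    and a[hi + 1] == b[hi + 1]:
                hi += 1
            lengths.append(positions[hi] - positions[lo] + 1)
    return sum(lengths) / len(lengths) if lengths else None
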