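"""Naive quadratic / brute-force reference implementations.

These deliberately share no code with the package: plain Python loops over
all positions and all pairs, used to pin down the scanners and counters.
"""

from itertools import product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
        "W": "W", "K": "M", "M": "K", "B": "V", "D": "H", "H": "D", "V": "B", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def naive_scan_ggaa(seq: str) -> list[tuple[int, str]]:
    """All (start, strand) of GGAA / TTCC matches by sliding a 4 bp window."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - 3):
        if seq[i : i + 4] == "GGAA":
            out.append((i, "+"))
        if seq[i : i + 4] == "TTCC":
            out.append((i, "-"))
    return out


def naive_microsatellites(seq: str, min_units: int = 4) -> list[tuple[int, int, int]]:
    """Maximal (GGAA)_k / (TTCC)_k runs as (start, end, k), deduped by interval."""
    seq = seq.upper()
    found = {}
    for unit in ("GGAA", "TTCC"):
        for i in range(len(seq) - 3):
            if i >= 4 and seq[i - 4 : i] == unit:
                continue  # extendable to the left: not maximal
            k = 0
            while seq[i + 4 * k : i + 4 * k + 4] == unit:
                k += 1
            if k >= min_units:
                found[(i, i + 4 * k)] = k
    return sorted((s, e, k) for (s, e), k in found.items())


def naive_isolated(sites: list[tuple[int, int]], min_gap: int) -> list[int]:
    """Indices of sites whose edge gap to every other site is >= min_gap."""
    out = []
    for i, (s1, e1) in enumerate(sites):
        ok = True
        for j, (s2, e2) in enumerate(sites):
            if i == j:
                continue
            gap = max(s2 - e1, s1 - e2)
            if gap < min_gap:
                ok = False
                break
        if ok:
            out.append(i)
    return out


def iupac_match(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        w in IUPAC[p] for w, p in zip(window, pattern)
    )


def naive_iupac_scan(seq: str, pattern: str) -> list[tuple[int, str]]:
    """Both-strand exact IUPAC matches, palindromes reported once on +."""
    seq = seq.upper()
    pattern = pattern.upper()
    rc = revcomp(pattern)
    out = []
    for i in range(len(seq) - len(pattern) + 1):
        window = seq[i : i + len(pattern)]
        if iupac_match(window, pattern):
            out.append((i, "+"))
        elif iupac_match(window, rc):
            out.append((i, "-"))
    return out


def naive_intersect(a, b) -> list[int]:
    """Indices of members of a overlapping >= 1 bp with any member of b."""
    out = []
    for i, (ca, sa, ea) in enumerate(a):
        if any(ca == cb and sa < eb and sb < ea for cb, sb, eb in b):
            out.append(i)
    return out


def naive_tandem(ggaa, cofactors, window):
    """(ggaa_index, cofactor_class, partner_index) triples by all-pairs check."""
    out = []
    for i, (gs, ge) in enumerate(ggaa):
        by_class = {}
        for j, (name, cs, ce) in enumerate(cofactors):
            d = max(cs - ge, gs - ce, 0)
            if d <= window:
                prev = by_class.get(name)
                if prev is None or (d, cs) < (prev[1], prev[2]):
                    by_class[name] = (j, d, cs)
        for name in sorted(by_class):
            out.append((i, name, by_class[name][0]))
    return out


def naive_fragment_counts(fragments, peaks) -> list[int]:
    """Per-peak count of fragments overlapping >= 1 bp (all pairs)."""
    return [
        sum(1 for (fs, fe) in fragments if fs < pe and ps < fe) for (ps, pe) in peaks
    ]


def naive_window_counts(positions, strands, win_start, win_end, win_strand) -> int:
    return sum(
        1
        for p, s in zip(positions, strands)
        if win_start <= p < win_end and s == win_strand
    )


def naive_bh(p: list[float]) -> list[float]:
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = min(val, 1.0)
        prev = adj[i]
    return adj


def naive_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by direct PMF summation."""
    from math import comb

    total = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    ) / total


def naive_spearman(x, y) -> float:
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mid = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = mid
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den
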