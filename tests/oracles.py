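"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written from first principles — a literal
genetic-code string, quadratic dynamic programming, exhaustive enumeration —
and shares no code with the package, so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

# Standard genetic code, codons ordered TTT, TTC, TTA, TTG, TCT, ... (T,C,A,G)
_ORDER = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
       "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
CODE = {}
_i = 0
for _b1 in _ORDER:
    for _b2 in _ORDER:
        for _b3 in _ORDER:
            CODE[_b1 + _b2 + _b3] = _AA[_i]
            _i += 1

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def translate(seq: str) -> str:
    """Per-codon lookup translation; unknown codons give X."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(CODE.get(seq[i:i + 3], "X"))
    return "".join(out)


def six_frames(seq: str) -> list[str]:
    rc = revcomp(seq)
    return [translate(seq[f:]) for f in range(3)] + \
           [translate(rc[f:]) for f in range(3)]


def longest_orf(seq: str) -> str:
    """Exhaustive scan of every ATG..stop/frame-end span in all 6 frames."""
    best = ""
    for prot in six_frames(seq):
        for m, aa in enumerate(prot):
            if aa != "M":
                continue
            stop = prot.find("*", m)
            product = prot[m:] if stop == -1 else prot[m:stop]
            if len(product) > len(best):
                best = product
    return best


# ---------------------------------------------------------------------------
# Alignment DP
# ---------------------------------------------------------------------------

def sw_score(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
             gap_open: float = -5.0, gap_extend: float = -2.0) -> float:
    """Affine-gap Smith-Waterman optimal local score (Gotoh recurrences).

    A gap of length L costs gap_open + (L - 1) * gap_extend.
    """
    n, m = len(a), len(b)
    neg = -math.inf
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (left move)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (up move)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def nw_score(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
             gap_open: float = -5.0, gap_extend: float = -2.0) -> float:
    """Affine-gap Needleman-Wunsch optimal global score (end gaps charged
    like internal ones; gap of length L costs gap_open + (L-1)*gap_extend)."""
    n, m = len(a), len(b)
    neg = -math.inf
    H = [[neg] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = gap_open + (j - 1) * gap_extend
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = gap_open + (i - 1) * gap_extend
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[n][m]


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def ng86_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) fractional sites of one sense codon."""
    syn = 0.0
    for pos in range(3):
        s = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if CODE[mut] != "*" and CODE[mut] == CODE[codon]:
                s += 1
        syn += s / 3
    return 3 - syn, syn


def ng86_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (nonsyn, syn) differences between two sense codons."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    ok_paths, stop_paths = [], []
    for order in permutations(diff):
        cur, nd, sd, hit_stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if CODE[cur] == CODE[nxt]:
                sd += 1
            else:
                nd += 1
            if CODE[nxt] == "*" and nxt != b:
                hit_stop = True
            cur = nxt
        (stop_paths if hit_stop else ok_paths).append((nd, sd))
    paths = ok_paths or stop_paths
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def ng86_estimate(cds_a: str, cds_b: str):
    """Full NG86 (N, S, Nd, Sd, dN, dS) for equal-length gap-free CDSs."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    N = S = Nd = Sd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        na, sa = ng86_sites(ca)
        nb, sb = ng86_sites(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        nd, sd = ng86_differences(ca, cb)
        Nd += nd
        Sd += sd

    def jc(p):
        return math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return N, S, Nd, Sd, jc(Nd / N), jc(Sd / S)


def random_sense_codon(rng) -> str:
    while True:
        codon = "".join(rng.choice(list("ACGT")) for _ in range(3))
        if CODE[codon] != "*":
            return codon


# ---------------------------------------------------------------------------
# Assignment filter and statistics
# ---------------------------------------------------------------------------

# (min_ratio | "min", max mismatches, max gaps, min pident) steps 1..8
FILTER_STEPS = [("min", 0, 0, 99.0), (0.99, 0, 0, 99.0), (0.87, 4, 0, 99.0),
                (0.725, 5, 0, 99.0), (0.69, 4, 1, 99.0), (0.625, 8, 1, 98.0),
                (0.575, 13, 2, 97.0), (0.52, 12, 2, 97.0)]


def brute_force_assign(hits):
    """Enumerate every (query, step, hit) combination and take, per query,
    the lowest step with a qualifying hit, best hit by (bitscore desc,
    evalue asc, subject id asc). ``hits`` are objects with the tabular
    fields; returns {query_id: (step, subject_id)}."""
    queries = sorted({h.query_id for h in hits})
    result = {}
    for q in queries:
        candidates = []
        for step_index, (ratio, mm, gaps, pid) in enumerate(FILTER_STEPS,
                                                            start=1):
            for h in hits:
                if h.query_id != q:
                    continue
                shorter = min(h.query_length, h.subject_length)
                if ratio == "min":
                    ratio_ok = h.match_length == shorter
                else:
                    ratio_ok = h.match_length / shorter >= ratio
                if (ratio_ok and h.mismatches <= mm
                        and h.gap_openings <= gaps
                        and h.percent_identity >= pid):
                    candidates.append((step_index, -h.bitscore, h.evalue,
                                       h.subject_id))
        if candidates:
            step, neg_score, _, subject = min(candidates)
            result[q] = (step, subject)
    return result


def two_pass_sd(values):
    """Two-pass sample standard deviation (n-1 denominator)."""
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return 0.0
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def hypergeom_upper_tail_comb(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail via binomial coefficients."""
    if k <= 0:
        return 1.0
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def hypergeom_upper_tail_enumerate(k: int, K: int, n: int, N: int) -> float:
    """Literal enumeration of all C(N, n) draws (tiny N only)."""
    marked = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n)
               if len(marked.intersection(draw)) >= k)
    return hits / math.comb(N, n)
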