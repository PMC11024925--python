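import math
from fractions import Fraction

import numpy as np
import pytest

from grnrewire import (GenomicInterval, Peak, SimulationParams,
                       generate_landscape)
from grnrewire.peaks import build_peak_union

TINY = dict(n_chromosomes=1, chromosome_length=200_000, n_tf_families=2,
            members_per_family=3, n_genes=20, n_peaks=60, edge_density=0.5,
            hic_link_fraction=0.5, rewired_fraction=0.4,
            sequencing_depth=100.0, nb_dispersion=math.inf,
            planted_fold_change=4.0, expression_noise_sd=0.0)


def tiny_params(seed=0, **over):
    return SimulationParams(seed=seed, **{**TINY, **over})


@pytest.fixture(scope="session")
def tiny_landscape():
    """Zero-noise landscape shared by read-only tests."""
    return generate_landscape(tiny_params(seed=11))


def make_peak(pid, chrom, start, end, summit=None, counts=None):
    return Peak(pid, GenomicInterval(chrom, start, end),
                summit if summit is not None else (start + end) // 2,
                counts or {})


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def naive_union(peaks, extension, mode):
    """O(n^2) all-pairs overlap graph; merged peaks are its connected
    components (chained overlap), independent of the sweep implementation."""
    ivs = []
    for p in peaks:
        if mode == "chip":
            s, e = p.summit - extension, p.summit + extension
        else:
            s, e = p.interval.start - extension, p.interval.end + extension
        ivs.append((p.interval.chrom, max(0, s), e))
    n = len(ivs)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ivs[i], ivs[j]
            if a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    out = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        out.append((ivs[i][0], min(ivs[v][1] for v in comp),
                    max(ivs[v][2] for v in comp)))
    return sorted(out)


def union_intervals(peaks, extension, mode):
    merged = build_peak_union([peaks], extension, mode)
    return sorted((p.interval.chrom, p.interval.start, p.interval.end)
                  for p in merged)


def brute_force_scan(seq, pwm, background=None, threshold_fraction=0.8):
    """Exhaustive per-window scoring of both strands, python loops only."""
    bg = [0.25] * 4 if background is None else list(background)
    L = len(pwm)
    lo = [[math.log2(pwm.matrix[i, b] / bg[b]) for b in range(4)]
          for i in range(L)]
    max_score = float(sum(max(row) for row in lo))
    threshold = threshold_fraction * max_score
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for pos in range(len(seq) - L + 1):
        win = seq[pos:pos + L]
        if any(c not in idx for c in win):
            continue
        fwd = 0.0
        for i, c in enumerate(win):
            fwd += lo[i][idx[c]]
        rc = "".join(comp[c] for c in reversed(win))
        # same accumulation order as the vectorized scanner
        rev = 0.0
        for i in range(L):
            rev += lo[L - 1 - i][idx[comp[win[i]]]]
        assert abs(rev - sum(lo[i][idx[c]] for i, c in enumerate(rc))) < 1e-9
        f_ok, r_ok = fwd >= threshold, rev >= threshold
        if f_ok and (not r_ok or fwd >= rev):
            hits.append((pos, "+", fwd))
        elif r_ok:
            hits.append((pos, "-", rev))
    return hits, max_score


def hypergeom_upper_tail_exact(N, K, n, k):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact draw counting."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return float(min(acc, Fraction(1)))
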