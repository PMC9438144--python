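"""Independently coded brute-force oracles used by the test suite.

Each oracle restates the corresponding algorithm from first principles with
plain loops and explicit arithmetic, sharing no code with the package
implementation it checks.
"""

import math


def avg_ranks(values):
    """Fractional (average) ranks of a list, ascending, by explicit grouping."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_oracle(mat, ref_col, trim_m=0.30, trim_a=0.05):
    """Step-by-step trimmed-mean-of-M-values factors against a fixed reference."""
    n_feat, n_samp = mat.shape
    lib = [float(sum(mat[:, j])) for j in range(n_samp)]
    factors = []
    for j in range(n_samp):
        m_vals, a_vals, var = [], [], []
        for g in range(n_feat):
            o, r = float(mat[g, j]), float(mat[g, ref_col])
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref_col]
                m_vals.append(math.log2(po / pr))
                a_vals.append(0.5 * (math.log2(po) + math.log2(pr)))
                var.append((lib[j] - o) / (lib[j] * o) + (lib[ref_col] - r) / (lib[ref_col] * r))
        n = len(m_vals)
        if n == 0 or max(abs(m) for m in m_vals) < 1e-6:
            factors.append(1.0)
            continue
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = avg_ranks(m_vals)
        rank_a = avg_ranks(a_vals)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += m_vals[i] / var[i]
                den += 1.0 / var[i]
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    log_mean = sum(math.log(f) for f in factors) / n_samp
    return [f / math.exp(log_mean) for f in factors]


def hypergeom_tail_oracle(k, big_k, n, big_n):
    """P(X >= k) by explicit enumeration of the hypergeometric pmf."""
    total = 0
    denom = math.comb(big_n, n)
    for x in range(k, min(n, big_k) + 1):
        total += math.comb(big_k, x) * math.comb(big_n - big_k, n - x)
    return total / denom


def average_rank_oracle(abs_fc, p_values):
    """Mean of the |FC|-descending and p-ascending ranks by double counting."""
    n = len(abs_fc)
    out = []
    for i in range(n):
        better_fc = sum(1 for j in range(n) if abs_fc[j] > abs_fc[i])
        tied_fc = sum(1 for j in range(n) if abs_fc[j] == abs_fc[i])
        rank_fc = better_fc + (tied_fc + 1) / 2.0
        better_p = sum(1 for j in range(n) if p_values[j] < p_values[i])
        tied_p = sum(1 for j in range(n) if p_values[j] == p_values[i])
        rank_p = better_p + (tied_p + 1) / 2.0
        out.append((rank_fc + rank_p) / 2.0)
    return out


def bh_oracle(p_values):
    """Step-up Benjamini-Hochberg by the textbook sorted recursion."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_pos in range(n, 0, -1):
        i = order[rank_pos - 1]
        value = min(p_values[i] * n / rank_pos, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted
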