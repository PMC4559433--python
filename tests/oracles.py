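"""Independent brute-force reference implementations used to verify the
package's metric code.  Deliberately slow and literal: dictionary counting,
explicit loops, two-pass statistics — no shared code with macrobench."""

import math
from collections import Counter


def entropy_bits(counter):
    total = sum(counter.values())
    h = 0.0
    for c in counter.values():
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def mi_matrix_oracle(sequences):
    """Pairwise MI (bits) via joint-count tables; rows gapped at either
    column are dropped for that pair.  Diagonal is 0."""
    length = len(sequences[0])
    mi = [[0.0] * length for _ in range(length)]
    for i in range(length):
        for j in range(i + 1, length):
            pairs = [(s[i], s[j]) for s in sequences
                     if s[i] not in "-.X" and s[j] not in "-.X"]
            if not pairs:
                continue
            joint = Counter(pairs)
            left = Counter(a for a, _ in pairs)
            right = Counter(b for _, b in pairs)
            value = entropy_bits(left) + entropy_bits(right) - entropy_bits(joint)
            mi[i][j] = mi[j][i] = max(0.0, value)
    return mi


def mip_matrix_oracle(mi):
    """Average-product correction, re-derived entry by entry."""
    n = len(mi)
    col_mean = [sum(mi[i][j] for j in range(n) if j != i) / (n - 1)
                for i in range(n)]
    grand = sum(mi[i][j] for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
    mip = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j:
                mip[i][j] = mi[i][j] - (col_mean[i] * col_mean[j] / grand
                                        if grand != 0 else 0.0)
    return mip


def zpx_matrix_oracle(mip):
    """Two-pass column standardization then signed square root of the product."""
    n = len(mip)
    means, sds = [], []
    for k in range(n):
        vals = [mip[k][j] for j in range(n) if j != k]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        means.append(mean)
        sds.append(math.sqrt(var))
    zpx = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if sds[i] == 0 or sds[j] == 0:
                zpx[i][j] = float("nan")
                continue
            z = ((mip[i][j] - means[i]) / sds[i]) * ((mip[i][j] - means[j]) / sds[j])
            zpx[i][j] = math.copysign(math.sqrt(abs(z)), z) if z != 0 else 0.0
    return zpx


def auc_pair_oracle(labels, scores):
    """Wilcoxon AUC by exhaustive positive-negative pair counting (ties 0.5)."""
    positives = [s for lab, s in zip(labels, scores) if lab]
    negatives = [s for lab, s in zip(labels, scores) if not lab]
    total = 0.0
    for p in positives:
        for q in negatives:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(positives) * len(negatives))


def classify_oracle(value, halfwidth=1.0):
    if value < -halfwidth:
        return "stabilizing"
    if value > halfwidth:
        return "destabilizing"
    return "neutral"


def fraction_correct_oracle(exp, pred, exp_hw=1.0, pred_hw=1.0):
    hits = sum(classify_oracle(e, exp_hw) == classify_oracle(p, pred_hw)
               for e, p in zip(exp, pred))
    return hits / len(exp)


def case_metrics_oracle(energies, rmsds):
    """Sort-based per-case summary: (lowest-energy RMSD, best of 5 lowest,
    percent sub-angstrom)."""
    order = sorted(range(len(energies)), key=lambda k: (energies[k], k))
    lowest = rmsds[order[0]]
    best5 = min(rmsds[k] for k in order[:5]) if len(order) >= 5 else None
    pct = 100.0 * sum(1 for r in rmsds if r < 1.0) / len(rmsds)
    return lowest, best5, pct


def median_oracle(values):
    vals = sorted(values)
    n = len(vals)
    mid = n // 2
    return vals[mid] if n % 2 else (vals[mid - 1] + vals[mid]) / 2.0
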