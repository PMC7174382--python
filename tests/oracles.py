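"""Independent brute-force oracles used by the test suite.

These are deliberately naive Python loops, kept free of the package's own
numerics so that agreement is evidence of correctness rather than shared
code paths.
"""

import math


def mean_loop(rr):
    total = 0.0
    for v in rr:
        total += v
    return total / len(rr)


def sdnn_loop(rr):
    m = mean_loop(rr)
    acc = 0.0
    for v in rr:
        acc += (v - m) ** 2
    return math.sqrt(acc / len(rr))


def rmssd_loop(rr):
    acc = 0.0
    for i in range(len(rr) - 1):
        acc += (rr[i + 1] - rr[i]) ** 2
    return math.sqrt(acc / (len(rr) - 1))


def pnn50_loop(rr):
    count = 0
    for i in range(len(rr) - 1):
        if abs(rr[i + 1] - rr[i]) > 50.0:
            count += 1
    return 100.0 * count / len(rr)


def sd1_loop(rr):
    diffs = [rr[i] - rr[i + 1] for i in range(len(rr) - 1)]
    m = mean_loop(diffs)
    var = 0.0
    for d in diffs:
        var += (d - m) ** 2
    var /= len(diffs)
    return math.sqrt(0.5 * var)


def concordance_auc(labels, scores):
    """AUC as the fraction of positive-negative pairs correctly ordered,
    ties counting one half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def conv_pool_trace(input_length, blocks, pool=2):
    """Hand shape arithmetic: valid convolution stride 1 then floor-div
    pooling, per (filters, kernel) block; returns flattened width."""
    length = input_length
    channels = 1
    for filters, kernel in blocks:
        length = length - kernel + 1
        length = length // pool
        channels = filters
    return channels * length
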