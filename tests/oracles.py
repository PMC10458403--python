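"""Independent reference implementations used as test oracles.

These are written directly from the defining formulas as plain Python
double loops, deliberately sharing no code with the package.
"""

import math


def fuzzyen_naive(series, m, r1, r2):
    """Naive FuzzyEn: baseline-removed templates, Chebyshev distance,
    exponential membership exp(-(d^r2)/r1), N-m templates at both
    lengths.  ``r1`` is the absolute tolerance."""
    x = [float(v) for v in series]
    n_templates = len(x) - m

    def templates(length):
        out = []
        for i in range(n_templates):
            seg = x[i:i + length]
            mu = sum(seg) / length
            out.append([v - mu for v in seg])
        return out

    def phi(length):
        vecs = templates(length)
        total = 0.0
        for i in range(n_templates):
            inner = 0.0
            for j in range(n_templates):
                if j == i:
                    continue
                d = max(abs(a - b) for a, b in zip(vecs[i], vecs[j]))
                inner += math.exp(-(d ** r2) / r1)
            total += inner / (n_templates - 1)
        return total / n_templates

    return math.log(phi(m)) - math.log(phi(m + 1))


def perceptron_forward_naive(window, w_in, b_in, w_out, b_out, norm_const):
    """Scalar-loop forward pass of the NL -> NH sigmoid -> 1 linear net."""
    out = b_out
    nh = len(w_in)
    for h in range(nh):
        z = b_in[h]
        for n, x in enumerate(window):
            z += w_in[h][n] * (x - norm_const)
        out += w_out[h] * (1.0 / (1.0 + math.exp(-z)))
    return out
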