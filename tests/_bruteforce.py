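"""Independent brute-force transcription of the five incidence degrees.

Literal loop-based evaluation of the defining formulas on plain Python
lists — no numpy, no sharing of code with the package.  Serves as the
independent oracle for the vectorized implementation.
"""

from __future__ import annotations


def _mean_image(values):
    mean = sum(values) / len(values)
    return [v / mean for v in values]


def _initial_image(values):
    first = values[0]
    return [v / first for v in values]


def _zero_start(values):
    first = values[0]
    return [v - first for v in values]


def grey_coefficients_bf(x0, comparisons, which, epsilon):
    """Coefficients of ``comparisons[which]`` with two-level min/max scope."""
    ref = _mean_image(x0)
    images = [_mean_image(c) for c in comparisons]
    deltas = [[abs(r - v) for r, v in zip(ref, img)] for img in images]
    flat = [d for row in deltas for d in row]
    lo, hi = min(flat), max(flat)
    if hi == 0:
        return [1.0 for _ in ref]
    return [(lo + epsilon * hi) / (d + epsilon * hi) for d in deltas[which]]


def deng_bf(x0, comparisons, which, epsilon=0.5):
    coeffs = grey_coefficients_bf(x0, comparisons, which, epsilon)
    return sum(coeffs) / len(coeffs)


def _area(values):
    zs = _zero_start(values)
    s = 0.0
    for k in range(1, len(zs) - 1):
        s += zs[k]
    return s + 0.5 * zs[-1]


def absolute_bf(x0, xi):
    s0 = _area(x0)
    si = _area(xi)
    return (1 + abs(s0) + abs(si)) / (1 + abs(s0) + abs(si) + abs(si - s0))


def relative_bf(x0, xi):
    return absolute_bf(_initial_image(x0), _initial_image(xi))


def sdgra_bf(absolute, relative, theta=0.5):
    return theta * absolute + (1 - theta) * relative


def ssgra_bf(deng, absolute):
    return (deng + absolute) / 2
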