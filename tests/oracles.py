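"""Independent numeric oracles, deliberately not using the package under test."""

import math


def phi(x: float) -> float:
    """Standard normal CDF via math.erfc."""
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def percentile_linear(sorted_values, q):
    """Linear-interpolation percentile of pre-sorted data, q in [0, 100]."""
    n = len(sorted_values)
    pos = q / 100.0 * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_values[lo] * (1 - frac) + sorted_values[hi] * frac
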