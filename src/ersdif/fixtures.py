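"""Fixed item-parameter sets used throughout the simulation studies.

Two benchmark tests — 10 and 20 four-category items — with slopes drawn from
lognormal(0, 0.3^2), locations from uniform(-2, 2), and step thresholds fixed
at (-0.6, 0, 0.6).  The exact values are frozen here so that every study run
and every false-positive-rate table refers to the same instruments.
"""

from __future__ import annotations

from .ers_gpcm import ItemParams

TAU = (-0.6, 0.0, 0.6)

# (beta, delta) per item, 10-item benchmark test
_TEST_10 = [
    (0.634, -1.112),
    (1.372, 1.483),
    (0.962, -1.173),
    (0.655, 1.674),
    (1.198, -0.046),
    (0.872, 0.447),
    (0.959, 1.064),
    (0.745, 0.074),
    (1.130, -0.813),
    (1.076, -1.249),
]

# (beta, delta) per item, 20-item benchmark test
_TEST_20 = [
    (1.127, -1.112),
    (0.949, 1.483),
    (0.909, -1.173),
    (0.719, 1.674),
    (0.792, -0.046),
    (0.589, 0.447),
    (0.560, 1.064),
    (1.581, 0.074),
    (1.226, -0.813),
    (0.505, -1.249),
    (0.651, -1.677),
    (0.716, 0.954),
    (1.315, -0.235),
    (1.340, -1.367),
    (0.623, 1.520),
    (1.063, -0.904),
    (0.568, -0.343),
    (1.247, -0.816),
    (1.398, 0.515),
    (1.250, 0.319),
]


def benchmark_items(n_items: int) -> list[ItemParams]:
    """Return the frozen 10- or 20-item benchmark parameter set."""
    if n_items == 10:
        table = _TEST_10
    elif n_items == 20:
        table = _TEST_20
    else:
        raise ValueError("benchmark tests exist for 10 or 20 items only")
    return [ItemParams(beta=b, delta=d, tau=TAU) for b, d in table]
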