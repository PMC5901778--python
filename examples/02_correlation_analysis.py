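"""Correlation analysis of reference patterns with known structure.

Stripes of width w have their first zero of the radially averaged
correlation at pi*w/4 (the angular average mixes the along-stripe
direction, which never decorrelates, with the cross-stripe square wave).
A random 1:1 pattern decorrelates within about one site; a Voronoi
tessellation of n founders has territories of scale ~ L/sqrt(n).
"""

import numpy as np

from biofilmca import (
    ReferencePatternSpec,
    autocorrelation,
    correlation_length,
    generate_reference_pattern,
)

for kind, kwargs, expected in [
    ("stripes", dict(width=4), f"pi*w/4 = {np.pi:.3f}"),
    ("stripes", dict(width=10), f"pi*w/4 = {np.pi * 10 / 4:.2f}"),
    ("random", dict(seed=1), "~1 (uncorrelated)"),
    ("voronoi", dict(n_seeds=36, seed=0), ">= territory scale L/sqrt(n) = 10"),
]:
    pattern = generate_reference_pattern(ReferencePatternSpec(kind=kind, L=60, **kwargs))
    xi = correlation_length(autocorrelation(pattern))
    label = ", ".join(f"{k}={v}" for k, v in kwargs.items())
    print(f"{kind}({label}): xi = {xi.xi:.2f}  (expected scale: {expected})")
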