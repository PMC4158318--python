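"""Shared helpers for the test suite: random parameter draws and admissible fields."""

from __future__ import annotations

import numpy as np
import sympy as sp

from mtshell import DimensionlessGroups, DisplacementField
from mtshell.symbolic import x, theta


def random_groups(rng: np.random.Generator, eta: float | None = None) -> DimensionlessGroups:
    """A random valid set of dimensionless groups (K = 1 so N/K = N)."""
    return DimensionlessGroups(
        k1=float(rng.uniform(0.05, 2.0)),
        k2=float(rng.uniform(0.01, 0.5)),
        c2=float(rng.uniform(1e-4, 0.05)),
        K=1.0,
        eta=float(rng.uniform(0.0, 0.3)) if eta is None else eta,
        l=float(rng.uniform(5.0, 40.0)),
        mu1=float(rng.uniform(0.0, 0.45)),
        foundation=float(rng.uniform(0.0, 0.5)),
    )


def ss_field(
    rng: np.random.Generator, l: float, m_max: int = 3, n_max: int = 2
) -> DisplacementField:
    """Random field triple in the simply supported admissible family.

    Superposition of harmonics u ~ cos(mπx/l)cos(nθ), v ~ sin·sin, w ~ sin·cos;
    satisfies v = w = 0 and u_x = 0 at both ends and 2π-periodicity in θ.
    """
    u = v = w = sp.S.Zero
    L = sp.Float(l)
    for m in range(1, m_max + 1):
        lam = m * sp.pi / L
        for n in range(0, n_max + 1):
            u += float(rng.uniform(-1, 1)) * sp.cos(lam * x) * sp.cos(n * theta)
            v += float(rng.uniform(-1, 1)) * sp.sin(lam * x) * sp.sin(n * theta)
            w += float(rng.uniform(-1, 1)) * sp.sin(lam * x) * sp.cos(n * theta)
    return DisplacementField(u, v, w)


def rel_dev(a: np.ndarray, b: np.ndarray) -> float:
    """Entrywise deviation of two matrices relative to the larger magnitude."""
    scale = max(np.max(np.abs(a)), np.max(np.abs(b)), 1e-300)
    return float(np.max(np.abs(np.asarray(a) - np.asarray(b))) / scale)
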