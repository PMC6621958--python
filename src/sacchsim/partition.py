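"""Enzyme partitioning between the solid cake and the liquid phase.

At every centrifugation the cellulase distributes between the solids and the
supernatant.  The absorbed fraction is described by an empirical linear
model in total enzyme and glucose concentration,

    y = d1*[E] + d2*[G1] + d3,

clamped to [0, 1] since the raw plane goes negative at high enzyme dose.
Both coefficients are negative for CTec2 on alpha-cellulose: extra glucose
competes with the substrate for the enzyme, and high dosage saturates the
cellulose surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PartitionParameters",
    "fraction_absorbed",
    "fraction_absorbed_from_assay",
    "fit_partition",
]


@dataclass(frozen=True)
class PartitionParameters:
    """Coefficients of the linear enzyme-distribution model.

    ``d1`` (L/g) weighs total enzyme concentration, ``d2`` (L/g) glucose
    concentration, ``d3`` is the dilute-limit absorbed fraction.
    """

    d1: float = -0.550
    d2: float = -8.04e-4
    d3: float = 0.795

    def scaled(self, **factors: float) -> "PartitionParameters":
        from dataclasses import replace
        return replace(self, **{k: getattr(self, k) * v
                                for k, v in factors.items()})


def fraction_absorbed(E, G1,
                      pp: PartitionParameters = PartitionParameters()):
    """Fraction of enzyme absorbed on the solids, clamp(d1*E + d2*G1 + d3).

    ``E`` is the total active enzyme in the vessel (liquid + solid phases,
    per liquid volume, g/L) at centrifugation time; ``G1`` in g/L.
    """
    E = np.asarray(E, dtype=float)
    G1 = np.asarray(G1, dtype=float)
    if np.any(E < 0) or np.any(G1 < 0):
        raise ValueError("E and G1 must be >= 0")
    out = np.clip(pp.d1 * E + pp.d2 * G1 + pp.d3, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def fraction_absorbed_from_assay(test_conc: float, control_conc: float) -> float:
    """Absorbed fraction from supernatant protein assays.

    1 minus the ratio of supernatant protein in the test (with substrate)
    to the substrate-free control at the same loadings.
    """
    if control_conc <= 0:
        raise ValueError("control protein concentration must be > 0")
    if test_conc < 0:
        raise ValueError("test protein concentration must be >= 0")
    return 1.0 - test_conc / control_conc


def fit_partition(points) -> tuple[PartitionParameters, float]:
    """Ordinary-least-squares plane fit of the partition model.

    ``points`` is an iterable of (E, G1, observed fraction) triples; at
    least three non-collinear points are required.  Returns the fitted
    coefficients and the coefficient of determination R^2.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need >= 3 points of (E, G1, fraction)")
    X = np.column_stack([pts[:, 0], pts[:, 1], np.ones(pts.shape[0])])
    y = pts[:, 2]
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: points are collinear")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PartitionParameters(d1=float(coef[0]), d2=float(coef[1]),
                               d3=float(coef[2])), r2
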