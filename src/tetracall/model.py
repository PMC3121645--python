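"""Signal transforms, dosage->mean models and Hardy-Weinberg mixing proportions.

A bi-allelic marker assayed on a tetraploid yields two channel intensities
``s_a`` and ``s_b``.  The allele signal ratio ``s_a / (s_a + s_b)`` is
variance-stabilized with the arcsine-square-root (asr) transform, and the
expected transformed ratio for each allele-a dosage ``x`` in 0..4 is modelled
as a parametric curve with background (``c1``, ``c2`` or a common ``c``),
channel sensitivity ratio (``r``) and optional quadratic curvature (``d``).
Four nested mean models are supported:

=======  =======================  ======================================
model    free mean parameters     expected a-channel / b-channel signal
=======  =======================  ======================================
1        c1, c2, r                c1 + x          /  c2 + r(4-x)
2        c (=c1=c2), r            c + x           /  c + r(4-x)
3        c1, c2, r, d             c1 + x + d x^2  /  c2 + r(4-x) + r d (4-x)^2
4        c (=c1=c2), r, d         c + x + d x^2   /  c + r(4-x) + r d (4-x)^2
=======  =======================  ======================================

The curvature term uses the same relative coefficient ``d`` in both channels
(equal curvature, scaled by the channel sensitivity ``r``).  Everything in
this module is a pure function of its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Tetraploid dosage classes for allele a (nulliplex .. quadruplex).
DOSAGES = np.arange(5)

PLOIDY = 4

#: Free mean-model parameter names per model id.
MODEL_PARAM_NAMES: dict[int, tuple[str, ...]] = {
    1: ("c1", "c2", "r"),
    2: ("c", "r"),
    3: ("c1", "c2", "r", "d"),
    4: ("c", "r", "d"),
}

#: Lower bounds for fitting; parameters are ratios of physical signal
#: coefficients, so backgrounds and curvature are non-negative and the
#: sensitivity ratio is strictly positive.
PARAM_LOWER_BOUNDS: dict[str, float] = {
    "c1": 0.0,
    "c2": 0.0,
    "c": 0.0,
    "r": 1e-6,
    "d": 0.0,
}


class DomainError(ValueError):
    """Input outside the mathematically valid domain."""


def asr_transform(ratio):
    """Arcsine-square-root transform ``y = arcsin(sqrt(ratio))``.

    Maps a signal fraction in [0, 1] onto [0, pi/2], stabilizing the
    variance of fractions near the boundaries.  Accepts scalars or arrays.

    Raises
    ------
    DomainError
        If any value lies outside [0, 1].
    """
    arr = np.asarray(ratio, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0) or np.any(np.isnan(arr)):
        raise DomainError("ratio must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(ratio) else out


def asr_inverse(y):
    """Inverse transform ``sin(y)**2``, mapping [0, pi/2] back to [0, 1]."""
    arr = np.asarray(y, dtype=float)
    out = np.sin(arr) ** 2
    return float(out) if np.isscalar(y) else out


def compute_ratio_and_intensity(s_a, s_b):
    """Per-observation allele signal ratio and total intensity.

    Parameters
    ----------
    s_a, s_b
        Non-negative raw channel intensities (scalars or arrays).

    Returns
    -------
    ratio
        ``s_a / (s_a + s_b)``; NaN where both channels are zero (such
        records carry no ratio information and should be dropped).
    intensity
        Euclidean total intensity ``sqrt(s_a**2 + s_b**2)``.
    """
    a = np.asarray(s_a, dtype=float)
    b = np.asarray(s_b, dtype=float)
    if np.any(a < 0.0) or np.any(b < 0.0):
        raise DomainError("raw intensities must be non-negative")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0.0, a / np.where(total > 0.0, total, 1.0), np.nan)
    intensity = np.hypot(a, b)
    if np.isscalar(s_a) and np.isscalar(s_b):
        return float(ratio), float(intensity)
    return ratio, intensity


@dataclass(frozen=True)
class MeanModelParams:
    """Parameters of one dosage->mean model.

    ``c1`` and ``c2`` are the a- and b-channel backgrounds relative to the
    a-channel sensitivity, ``r`` the ratio of b- to a-channel sensitivity
    and ``d`` the relative quadratic curvature.  Models 2 and 4 share a
    single background ``c1 == c2``; models 1 and 2 have ``d == 0``.
    """

    model_id: int
    c1: float
    c2: float
    r: float
    d: float = 0.0

    def __post_init__(self):
        if self.model_id not in MODEL_PARAM_NAMES:
            raise DomainError(f"unknown model_id {self.model_id!r}")
        if self.c1 < 0.0 or self.c2 < 0.0:
            raise DomainError("background parameters must be non-negative")
        if self.r <= 0.0:
            raise DomainError("sensitivity ratio r must be positive")
        if self.d < 0.0:
            raise DomainError("curvature d must be non-negative")
        if self.model_id in (2, 4) and self.c1 != self.c2:
            raise DomainError("models 2 and 4 require a common background c1 == c2")
        if self.model_id in (1, 2) and self.d != 0.0:
            raise DomainError("models 1 and 2 are linear (d must be 0)")

    @property
    def c(self) -> float:
        """Common background for models 2/4."""
        return self.c1

    def free_names(self) -> tuple[str, ...]:
        return MODEL_PARAM_NAMES[self.model_id]

    def to_vector(self, fixed: dict[str, float] | None = None) -> np.ndarray:
        """Free-parameter vector in the canonical order, omitting fixed names."""
        fixed = fixed or {}
        vals = {"c1": self.c1, "c2": self.c2, "c": self.c1, "r": self.r, "d": self.d}
        return np.array([vals[n] for n in self.free_names() if n not in fixed])

    @classmethod
    def from_vector(
        cls,
        model_id: int,
        vector,
        fixed: dict[str, float] | None = None,
    ) -> "MeanModelParams":
        """Build params from a free-parameter vector (canonical order)."""
        fixed = dict(fixed or {})
        names = [n for n in MODEL_PARAM_NAMES[model_id] if n not in fixed]
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (len(names),):
            raise DomainError(
                f"model {model_id} expects {len(names)} free parameters, "
                f"got shape {vector.shape}"
            )
        vals = dict(zip(names, vector))
        vals.update(fixed)
        if model_id in (2, 4):
            c = vals["c"]
            return cls(model_id, c, c, vals["r"], vals.get("d", 0.0))
        return cls(model_id, vals["c1"], vals["c2"], vals["r"], vals.get("d", 0.0))


def mean_model_eval(params: MeanModelParams, dosage) -> np.ndarray:
    """Expected transformed ratio for allele-a dosage(s) under one mean model.

    The expected signal fraction for dosage ``x`` is

        (c1 + x + d x^2) / (c1 + x + d x^2 + c2 + r (4 - x) + r d (4 - x)^2)

    with ``d = 0`` for models 1/2 and ``c1 = c2`` for models 2/4; the result
    is returned on the asr-transformed scale.  Strictly increasing in ``x``
    for any admissible parameters.
    """
    x = np.asarray(dosage, dtype=float)
    if np.any(x < 0) or np.any(x > PLOIDY):
        raise DomainError("dosage must lie in 0..4")
    xb = PLOIDY - x
    num = params.c1 + x + params.d * x**2
    den = num + params.c2 + params.r * xb + params.r * params.d * xb**2
    if np.any(den <= 0.0):
        raise DomainError("mean-model denominator must be positive")
    frac = num / den
    out = np.arcsin(np.sqrt(frac))
    return float(out) if np.isscalar(dosage) else out


def hwe_proportions(p) -> np.ndarray:
    """Mixing proportions over a-dosage classes 0..4 under Hardy-Weinberg.

    ``p`` is the population frequency of the b allele (the allele whose
    dosage is ``4 - x`` in component ``x``), so the vector reads
    ``(p^4, 4 p^3 q, 6 p^2 q^2, 4 p q^3, q^4)`` with ``q = 1 - p``: the
    nulliplex-a class has probability ``p**4``.  The a-allele frequency is
    ``1 - p``.
    """
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise DomainError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    return np.array(
        [p**4, 4 * p**3 * q, 6 * p**2 * q**2, 4 * p * q**3, q**4]
    )


def parameter_count(model_id: int, hwe_constrained: bool) -> int:
    """Number of free parameters of one mixture variant.

    Mean-model parameters (3/2/4/3 for models 1..4) plus one common
    standard deviation, plus either one allele frequency (HWE-constrained
    mixing proportions) or four free mixing proportions.
    """
    if model_id not in MODEL_PARAM_NAMES:
        raise DomainError(f"unknown model_id {model_id!r}")
    return len(MODEL_PARAM_NAMES[model_id]) + 1 + (1 if hwe_constrained else 4)
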