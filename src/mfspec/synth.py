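"""Synthetic inputs with known multifractal structure.

Two families:

* **Multiplicative cascades** — deterministic (or shuffled) recursive mass
  splittings on dyadic grids.  Their multifractal spectra have exact closed
  forms (``theory_tau``, ``theory_dimension``, ``theory_alpha_f``), which is
  what makes them the standard verification oracle for box-counting
  estimators.  For weights w_1..w_b and per-level scale ratio 1/2,

      tau(q)   = -log2( sum_i w_i^q )
      D(1)     = -sum_i w_i log2 w_i
      alpha(q) = -sum_i w_i^q ln w_i / (ln 2 * sum_j w_j^q)
      f(q)     = q alpha(q) - tau(q)
      alpha_min = -log2 max w_i,   alpha_max = -log2 min w_i.

* **Synthetic cell-like FTIR spectra** — a sum of Gaussian absorption bands
  over 4000-650 cm^-1 plus a cascade-derived fine-structure texture whose
  skew parameter ``roughness_p`` tunes how strongly multifractal the trace
  is.  Lower ``roughness_p`` (more skewed cascade) stands in for the
  rougher, more strongly multifractal phenotype; population mixing at a
  cancer-cell fraction ``phi`` is a pointwise affine blend of two such
  spectra.  These are fixtures emulating the shape of mid-IR cell spectra,
  not a physical ATR model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mfa import MassField
from .spectra_io import Spectrum

__all__ = [
    "CascadeSpec",
    "SyntheticCellSpec",
    "binomial_measure_1d",
    "multinomial_measure_2d",
    "theory_tau",
    "theory_dimension",
    "theory_alpha_f",
    "synth_ftir_spectrum",
    "mix_spectra",
    "DEFAULT_BANDS",
]


@dataclass(frozen=True)
class CascadeSpec:
    """A multiplicative cascade: weights, depth, optional shuffled splits."""

    weights: tuple
    depth: int
    shuffle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.ndim != 1 or np.any(w <= 0):
            raise ValueError("weights must be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 (within 1e-12)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))


def binomial_measure_1d(spec: CascadeSpec) -> MassField:
    """1-D cascade over 2^depth cells from a weight pair {p, 1-p}.

    Each level splits every cell's mass between its two children by the
    weights (order fixed, or independently permuted per cell when
    ``shuffle``).  Total mass is conserved at 1.
    """
    w = np.asarray(spec.weights)
    if w.size != 2:
        raise ValueError("1-D cascade needs exactly 2 weights")
    rng = np.random.default_rng(spec.seed)
    m = np.array([1.0])
    for _ in range(spec.depth):
        W = np.tile(w, (m.size, 1))
        if spec.shuffle:
            W = rng.permuted(W, axis=1)
        m = (m[:, None] * W).ravel()
    return MassField(m)


def multinomial_measure_2d(spec: CascadeSpec) -> MassField:
    """2-D cascade on a 2^depth x 2^depth grid from a weight quadruple."""
    w = np.asarray(spec.weights)
    if w.size != 4:
        raise ValueError("2-D cascade needs exactly 4 weights")
    rng = np.random.default_rng(spec.seed)
    m = np.array([[1.0]])
    for _ in range(spec.depth):
        n = m.shape[0]
        W = np.tile(w, (n * n, 1))
        if spec.shuffle:
            W = rng.permuted(W, axis=1)
        blocks = m.reshape(n * n, 1) * W  # (n*n, 4)
        blocks = blocks.reshape(n, n, 2, 2)
        m = blocks.transpose(0, 2, 1, 3).reshape(2 * n, 2 * n)
    return MassField(m)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def theory_tau(weights, q):
    """Exact tau(q) = -log2 sum w_i^q for a scale-ratio-1/2 cascade."""
    w = np.asarray(weights, float)
    qa = np.atleast_1d(np.asarray(q, float))
    tau = -np.log2(np.power(w[None, :], qa[:, None]).sum(axis=1))
    return float(tau[0]) if np.asarray(q).ndim == 0 else tau


def theory_dimension(weights, q):
    """Exact D(q); the q = 1 entry is the entropy -sum w log2 w."""
    w = np.asarray(weights, float)
    q = np.atleast_1d(np.asarray(q, float))
    tau = theory_tau(w, q)
    d = np.empty_like(q)
    at_one = np.isclose(q, 1.0)
    d[~at_one] = tau[~at_one] / (q[~at_one] - 1.0)
    d[at_one] = -(w * np.log2(w)).sum()
    return d if d.size > 1 else float(d[0])


def theory_alpha_f(weights, q):
    """Exact (alpha, f) for the cascade; tangent to f = alpha at q = 1."""
    w = np.asarray(weights, float)
    q = np.atleast_1d(np.asarray(q, float))
    wq = np.power(w[None, :], q[:, None])
    Z = wq.sum(axis=1)
    alpha = -(wq * np.log(w)[None, :]).sum(axis=1) / (np.log(2.0) * Z)
    f = q * alpha - theory_tau(w, q)
    if alpha.size == 1:
        return float(alpha[0]), float(f[0])
    return alpha, f


# ---------------------------------------------------------------------------
# FTIR-like fixtures
# ---------------------------------------------------------------------------

#: Gaussian band placements (center cm^-1, width cm^-1, amplitude AU)
#: loosely following O-H/amide/CH-stretch/phosphate zones of cell spectra.
DEFAULT_BANDS = (
    (3300.0, 200.0, 0.6),
    (2925.0, 60.0, 0.3),
    (1650.0, 40.0, 0.9),
    (1545.0, 40.0, 0.6),
    (1080.0, 60.0, 0.4),
)


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Recipe for a synthetic cell-like absorbance spectrum.

    ``roughness_p`` in (0, 0.5] is the cascade split parameter of the
    fine-structure texture: 0.5 gives a flat (monofractal) texture, smaller
    values a more strongly multifractal one.  ``roughness_amp`` is the
    texture amplitude in AU relative to band amplitudes of order 1.
    """

    bands: tuple = DEFAULT_BANDS
    roughness_p: float = 0.3
    roughness_amp: float = 0.08
    n_points: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.roughness_p <= 0.5:
            raise ValueError("roughness_p must be in (0, 0.5]")
        if self.roughness_amp < 0:
            raise ValueError("roughness_amp must be >= 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        for c, wdt, amp in self.bands:
            if not 650.0 <= c <= 4000.0:
                raise ValueError(f"band center {c} outside 650-4000 cm^-1")
            if amp < 0 or wdt <= 0:
                raise ValueError("band widths must be positive, amplitudes >= 0")


def synth_ftir_spectrum(spec: SyntheticCellSpec = SyntheticCellSpec()) -> Spectrum:
    """Gaussian band mixture plus zero-mean cascade texture, clipped at 0."""
    w = np.linspace(4000.0, 650.0, spec.n_points)  # descending, canonical
    a = np.zeros_like(w)
    for center, width, amp in spec.bands:
        a += amp * np.exp(-0.5 * ((w - center) / width) ** 2)
    if spec.roughness_amp > 0:
        depth = int(np.ceil(np.log2(spec.n_points)))
        cascade = binomial_measure_1d(
            CascadeSpec((spec.roughness_p, 1.0 - spec.roughness_p), depth,
                        shuffle=True, seed=spec.seed)
        ).mass[: spec.n_points]
        texture = cascade / cascade.mean() - 1.0  # zero-mean, >= -1
        a = np.clip(a + spec.roughness_amp * texture, 0.0, None)
    meta = {
        "roughness_p": f"{spec.roughness_p:g}",
        "roughness_amp": f"{spec.roughness_amp:g}",
        "seed": str(spec.seed),
    }
    return Spectrum(w, a, meta)


def mix_spectra(healthy: Spectrum, cancer: Spectrum, phi: float) -> Spectrum:
    """Pointwise blend (1-phi)*healthy + phi*cancer on a shared grid."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must be in [0, 1]")
    if healthy.wavenumbers.shape != cancer.wavenumbers.shape or not np.allclose(
        healthy.wavenumbers, cancer.wavenumbers
    ):
        raise ValueError("wavenumber grids differ; resample to a common grid first")
    vals = (1.0 - phi) * healthy.absorbance + phi * cancer.absorbance
    meta = dict(healthy.meta)
    meta.update({"phi": f"{phi:g}"})
    return Spectrum(healthy.wavenumbers.copy(), vals, meta)
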