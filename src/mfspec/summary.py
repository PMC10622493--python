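"""Scalar multifractal numbers and the three experiment templates.

The multifractal number is the scalar used to rank samples.  The default
realization is the singularity-spectrum width Delta-alpha = alpha_max -
alpha_min, extracted over the moment orders whose fits clear the R^2
quality gate; alternative reductions (alpha(0), D(1), f at a chosen Q, the
"aperture" |f(alpha(1)) - f(alpha(-1))|) are selectable because the
literature's scalar is not uniquely pinned down.

Experiment templates mirror how such numbers are used in practice:
group separation (Welch t / one-way ANOVA on replicate numbers),
concentration invariance (spread of the number under amplitude scalings of
the same spectrum), and dose response (Spearman rank correlation between a
cancer-cell mixing fraction and the number).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .mfa import MfaConfig, MfaError, MultifractalSpectrum, analyze, config_hash
from .rasterize import RasterConfig, spectrum_to_binary
from .spectra_io import Spectrum

__all__ = [
    "MultifractalNumber",
    "GroupComparison",
    "DoseResponse",
    "multifractal_number",
    "mf_number_of_spectrum",
    "compare_groups",
    "invariance_report",
    "dose_response",
]

_METHODS = ("delta_alpha", "alpha0", "d1", "f_at_q", "aperture")


@dataclass(frozen=True)
class MultifractalNumber:
    """A scalar reduction of a multifractal spectrum, with its provenance."""

    value: float
    method: str
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("multifractal number must be finite")


def multifractal_number(
    ms: MultifractalSpectrum,
    method: str = "delta_alpha",
    q_star: float = 2.0,
    source: str = "",
) -> MultifractalNumber:
    """Reduce a spectrum to one scalar by the chosen method.

    ``aperture`` (|f(alpha(1)) - f(alpha(-1))|) is one defensible reading
    of intersecting the hump between Q = +-1 and is labeled experimental.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if not ms.q_ok.any():
        raise MfaError("no moment order passed the fit-quality gate")
    at = ms._at
    if method == "delta_alpha":
        value = ms.delta_alpha
    elif method == "alpha0":
        value = ms.alpha0
    elif method == "d1":
        value = ms.d1
    elif method == "f_at_q":
        value = at(ms.f, q_star)
    else:  # aperture
        value = abs(at(ms.f, 1.0) - at(ms.f, -1.0))
    label = f"f_at_q({q_star:g})" if method == "f_at_q" else method
    return MultifractalNumber(float(value), label, source)


def mf_number_of_spectrum(
    s: Spectrum,
    raster_cfg: RasterConfig = RasterConfig(),
    mfa_cfg: MfaConfig = MfaConfig(),
    method: str = "delta_alpha",
) -> MultifractalNumber:
    """Spectrum -> binary trace -> MFA -> scalar, in one call."""
    img = spectrum_to_binary(s, raster_cfg)
    ms = analyze(img, mfa_cfg)
    src = s.meta.get("sample", "") or s.meta.get("seed", "")
    return multifractal_number(ms, method, source=f"{src}|{config_hash(mfa_cfg)}")


# ---------------------------------------------------------------------------
# experiment templates
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    means: list
    sds: list
    ns: list
    test: str
    statistic: float
    p_value: float


def _values(group: Sequence) -> np.ndarray:
    vals = [g.value if isinstance(g, MultifractalNumber) else float(g) for g in group]
    return np.asarray(vals, float)


def compare_groups(groups: Sequence[Sequence], test: str = "auto") -> GroupComparison:
    """Welch t (2 groups) or one-way ANOVA (>2) on replicate MF numbers."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    methods = {
        g.method for grp in groups for g in grp if isinstance(g, MultifractalNumber)
    }
    if len(methods) > 1:
        raise ValueError(f"groups mix multifractal-number methods: {sorted(methods)}")
    arrs = [_values(g) for g in groups]
    for a in arrs:
        if a.size < 2:
            raise ValueError("each group needs n >= 2 for an SD")
    if test == "auto":
        test = "welch_t" if len(arrs) == 2 else "anova"
    if test == "welch_t":
        if len(arrs) != 2:
            raise ValueError("welch_t applies to exactly 2 groups")
        res = stats.ttest_ind(arrs[0], arrs[1], equal_var=False)
    elif test == "anova":
        res = stats.f_oneway(*arrs)
    else:
        raise ValueError("test must be 'welch_t', 'anova' or 'auto'")
    return GroupComparison(
        means=[float(a.mean()) for a in arrs],
        sds=[float(a.std(ddof=1)) for a in arrs],
        ns=[int(a.size) for a in arrs],
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def invariance_report(numbers: Sequence) -> float:
    """Max absolute pairwise spread of MF numbers across amplitude scalings.

    With min-max normalization in the raster stage the scaled spectra
    produce identical images, so the spread is exactly 0; a positive spread
    flags a pipeline run without normalization (or with clipping).
    """
    vals = _values(numbers)
    if vals.size < 2:
        return 0.0
    return float(vals.max() - vals.min())


@dataclass
class DoseResponse:
    rho: float
    p_value: float
    direction: str  # "increasing" | "decreasing" | "flat" | "undefined"


def dose_response(phis: Sequence[float], numbers: Sequence) -> DoseResponse:
    """Spearman rank correlation of MF number against mixing fraction."""
    phis = np.asarray(phis, float)
    vals = _values(numbers)
    if phis.size != vals.size or phis.size < 3:
        raise ValueError("need equal-length phi/number lists with >= 3 entries")
    if np.ptp(vals) == 0:
        return DoseResponse(float("nan"), float("nan"), "undefined")
    rho, p = stats.spearmanr(phis, vals)
    if np.isnan(rho):
        return DoseResponse(float("nan"), float("nan"), "undefined")
    direction = "increasing" if rho > 0 else ("decreasing" if rho < 0 else "flat")
    return DoseResponse(float(rho), float(p), direction)
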