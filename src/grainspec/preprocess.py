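"""Spectral pre-processing operators.

Eight per-spectrum transforms common in chemometrics, applied row-wise to a
:class:`~grainspec.imaging.SpectraTable`:

``smoothing``
    centered moving average (window w, reflected edges)
``mean_norm`` / ``max_norm`` / ``range_norm``
    divide by the spectrum mean / max, or map [min, max] -> [0, 1]
``snv``
    standard normal variate: per-spectrum z-score with sample (n-1) sd
``msc``
    multiplicative scatter correction: regress each spectrum on a reference
    (default: column mean of the table), return (x - intercept) / slope
``sg1`` / ``sg2``
    Savitzky-Golay first/second derivative (scipy), polynomial edge handling

Operators compose left-to-right via :func:`apply_chain`. The pipeline default
is no preprocessing: under controlled acquisition the transforms leave
downstream regressions essentially unchanged, but all eight remain available
and tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateSpectrumError, ScatterCorrectionError
from .imaging import SpectraTable

METHODS = (
    "smoothing",
    "mean_norm",
    "max_norm",
    "range_norm",
    "msc",
    "snv",
    "sg1",
    "sg2",
)


@dataclass
class PreprocessSpec:
    """One transform with its parameters.

    window/polyorder only matter for smoothing and the SG derivatives;
    reference only for MSC (a fitted model stores its training-mean reference
    here so test spectra are corrected consistently).
    """

    method: str
    window: int = 7
    polyorder: int = 2
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS and self.method != "none":
            raise ValueError(f"unknown method {self.method!r}; one of {METHODS}")
        if self.method in ("sg1", "sg2"):
            if self.window % 2 == 0 or self.window <= self.polyorder:
                raise ValueError("SG window must be odd and > polyorder")
            deriv = 1 if self.method == "sg1" else 2
            if self.polyorder < deriv:
                raise ValueError("polyorder must be >= derivative order")
        if self.method == "smoothing" and (self.window < 3 or self.window % 2 == 0):
            raise ValueError("smoothing window must be odd and >= 3")


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    pad = window // 2
    padded = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, padded)


def apply_preprocess(spectra: SpectraTable, spec: PreprocessSpec) -> SpectraTable:
    """Apply one transform row-wise; shape and sample order are preserved."""
    x = spectra.spectra.copy()
    m = spec.method
    if m == "none":
        out = x
    elif m == "smoothing":
        out = _moving_average(x, spec.window)
    elif m == "mean_norm":
        means = x.mean(axis=1, keepdims=True)
        if np.any(means == 0):
            raise DegenerateSpectrumError("zero-mean spectrum under mean_norm")
        out = x / means
    elif m == "max_norm":
        maxes = x.max(axis=1, keepdims=True)
        if np.any(maxes == 0):
            raise DegenerateSpectrumError("zero-max spectrum under max_norm")
        out = x / maxes
    elif m == "range_norm":
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        if np.any(hi - lo == 0):
            raise DegenerateSpectrumError("constant spectrum under range_norm")
        out = (x - lo) / (hi - lo)
    elif m == "snv":
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise DegenerateSpectrumError("constant spectrum under snv")
        out = (x - mu) / sd
    elif m == "msc":
        ref = spec.reference if spec.reference is not None else x.mean(axis=0)
        ref = np.asarray(ref, dtype=float)
        ref_c = ref - ref.mean()
        denom = float(ref_c @ ref_c)
        if denom == 0:
            raise ScatterCorrectionError("constant MSC reference")
        slopes = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
        if np.any(np.abs(slopes) < 1e-12):
            raise ScatterCorrectionError("MSC slope numerically zero")
        intercepts = x.mean(axis=1) - slopes * ref.mean()
        out = (x - intercepts[:, None]) / slopes[:, None]
    elif m in ("sg1", "sg2"):
        deriv = 1 if m == "sg1" else 2
        out = savgol_filter(
            x, spec.window, spec.polyorder, deriv=deriv, axis=1, mode="interp"
        )
    else:  # pragma: no cover - guarded in PreprocessSpec
        raise ValueError(m)
    return SpectraTable(spectra.sample_ids, out, spectra.wavelengths)


def apply_chain(spectra: SpectraTable, specs: list[PreprocessSpec]) -> SpectraTable:
    """Apply a sequence of transforms left-to-right."""
    for spec in specs:
        spectra = apply_preprocess(spectra, spec)
    return spectra


def parse_chain(chain: str) -> list[PreprocessSpec]:
    """Parse a comma-separated chain like ``"snv,sg1"`` (CLI helper)."""
    specs = []
    for name in chain.split(","):
        name = name.strip()
        if name and name != "none":
            specs.append(PreprocessSpec(method=name))
    return specs
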