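"""Ten spectral preprocessing methods with a leak-free fit/transform contract.

Row-wise methods (msc, snv, norm, ma, detrend, sg, sg-fd, sg-sd) operate on
each spectrum independently; column-wise methods (mc, auto) and msc carry
training-set state (column means/sds, the MSC reference spectrum) so that
test spectra never contribute statistics to their own transformation.

Method identifiers (matching the accuracy tables' row labels):
``msc`` multiplicative scatter correction, ``snv`` standard normal variate,
``norm`` per-row min-max, ``auto`` autoscaling, ``mc`` mean centering,
``ma`` moving average, ``detrend`` per-row polynomial baseline removal
(order 2), ``sg``/``sg-fd``/``sg-sd`` Savitzky–Golay smoothing and first and
second derivatives (derivatives scaled by the band spacing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

METHODS = ("msc", "snv", "norm", "auto", "mc", "ma", "detrend",
           "sg", "sg-fd", "sg-sd")
_ROW_WISE = ("msc", "snv", "norm", "ma", "detrend", "sg", "sg-fd", "sg-sd")
_SG_DERIV = {"sg": 0, "sg-fd": 1, "sg-sd": 2}


@dataclass
class SpectraMatrix:
    """n_samples × n_bands real reflectances with a shared wavelength axis."""

    X: np.ndarray
    wavelengths_nm: np.ndarray
    sample_ids: Optional[Sequence] = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.X.shape[1] != self.wavelengths_nm.size:
            raise ValueError(
                f"matrix has {self.X.shape[1]} columns but "
                f"{self.wavelengths_nm.size} wavelengths")
        if np.isnan(self.X).any():
            raise ValueError("spectra matrix contains NaN")
        if self.sample_ids is None:
            self.sample_ids = [str(i) for i in range(self.X.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def with_values(self, X: np.ndarray) -> "SpectraMatrix":
        return SpectraMatrix(X, self.wavelengths_nm, list(self.sample_ids))


@dataclass
class Preprocessor:
    """One preprocessing method with its parameters and fitted state.

    ``window`` (odd) and ``polyorder`` apply to the SG family and ``ma``
    (window only) and ``detrend`` (polyorder, default 2).
    """

    method: str
    window: int = 11
    polyorder: int = 2
    ma_window: int = 5
    reference_: Optional[np.ndarray] = None       # msc
    column_means_: Optional[np.ndarray] = None    # mc / auto
    column_sds_: Optional[np.ndarray] = None      # auto

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"choose from {METHODS}")
        if self.method in _SG_DERIV:
            if self.window % 2 == 0 or self.window <= self.polyorder:
                raise ValueError(
                    "SG window must be odd and greater than polyorder")
        if self.method == "ma" and self.ma_window % 2 == 0:
            raise ValueError("moving-average window must be odd")

    # -- fitting ------------------------------------------------------------

    @property
    def is_fitted(self) -> bool:
        if self.method == "msc":
            return self.reference_ is not None
        if self.method in ("mc", "auto"):
            return self.column_means_ is not None
        return True

    def fit(self, train: SpectraMatrix) -> "Preprocessor":
        """Store training statistics; row-wise methods store nothing."""
        if self.method in ("msc", "mc", "auto") and train.n_samples < 2:
            raise ValueError(f"{self.method} requires at least 2 training rows")
        if self.method == "msc":
            self.reference_ = train.X.mean(axis=0)
        elif self.method in ("mc", "auto"):
            self.column_means_ = train.X.mean(axis=0)
            if self.method == "auto":
                sds = train.X.std(axis=0, ddof=1)
                zero = np.nonzero(sds == 0.0)[0]
                if zero.size:
                    wl = train.wavelengths_nm[zero[0]]
                    raise ValueError(
                        f"autoscale: zero variance at band {zero[0]} "
                        f"({wl:.1f} nm)")
                self.column_sds_ = sds
        return self

    def fit_transform(self, train: SpectraMatrix) -> SpectraMatrix:
        return self.fit(train).transform(train)

    # -- transforms ---------------------------------------------------------

    def transform(self, data: SpectraMatrix) -> SpectraMatrix:
        if not self.is_fitted:
            raise ValueError(f"{self.method} preprocessor is not fitted")
        X = data.X
        m = self.method
        if m == "snv":
            mean = X.mean(axis=1, keepdims=True)
            sd = X.std(axis=1, ddof=1, keepdims=True)
            if np.any(sd == 0.0):
                raise ValueError("SNV undefined on a zero-variance spectrum")
            out = (X - mean) / sd
        elif m == "msc":
            out = self._msc(X)
        elif m == "norm":
            lo = X.min(axis=1, keepdims=True)
            hi = X.max(axis=1, keepdims=True)
            if np.any(hi == lo):
                raise ValueError("min-max normalization undefined on a "
                                 "constant spectrum")
            out = (X - lo) / (hi - lo)
        elif m == "auto":
            out = (X - self.column_means_) / self.column_sds_
        elif m == "mc":
            out = X - self.column_means_
        elif m == "ma":
            out = _moving_average(X, self.ma_window)
        elif m == "detrend":
            out = _detrend(X, data.wavelengths_nm, self.polyorder)
        else:  # sg family
            delta = float(np.mean(np.diff(data.wavelengths_nm)))
            out = savgol_filter(X, self.window, self.polyorder,
                                deriv=_SG_DERIV[m], delta=delta,
                                axis=1, mode="interp")
        return data.with_values(out)

    def _msc(self, X: np.ndarray) -> np.ndarray:
        ref = self.reference_
        ref_c = ref - ref.mean()
        denom = float(ref_c @ ref_c)
        if denom == 0.0:
            raise ValueError("MSC reference spectrum is constant")
        b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
        if np.any(b == 0.0):
            raise ValueError("MSC slope b = 0 for some spectrum")
        a = X.mean(axis=1) - b * ref.mean()
        return (X - a[:, None]) / b[:, None]


def _moving_average(X: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window truncates at the edges."""
    kernel = np.ones(window)
    counts = np.convolve(np.ones(X.shape[1]), kernel, mode="same")
    sums = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), 1, X)
    return sums / counts


def _detrend(X: np.ndarray, wl: np.ndarray, order: int) -> np.ndarray:
    """Subtract each row's least-squares polynomial baseline in wavelength."""
    t = (wl - wl.mean()) / (wl.max() - wl.min())   # conditioning
    V = np.vander(t, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, X.T, rcond=None)
    return X - (V @ coef).T


def make_preprocessor(method: str, **kwargs) -> Preprocessor:
    return Preprocessor(method=method, **kwargs)
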