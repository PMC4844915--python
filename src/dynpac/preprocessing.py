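"""Signal conditioning: notch, PCA reduction, artifact flagging,
band-pass filter bank and pairwise orthogonalization.

All filters are zero-phase (forward-backward application of third-order
Butterworth sections), matching the analysis chain the PAC stage assumes.
The independent-component decomposition itself is not performed here; the
flagging rule consumes externally computed component time courses.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from sklearn.decomposition import PCA

from .bands import DEFAULT_BANDS, Band, validate_scheme
from .recording import Recording

__all__ = [
    "butter_bandpass_sos", "bandpass", "notch_filter", "pca_whiten",
    "PCAModel", "flag_artifact_components", "ComponentFlagReport",
    "bandpass_bank", "orthogonalize_pair",
]


def butter_bandpass_sos(low_hz: float, high_hz: float, rate_hz: float,
                        order: int = 3) -> np.ndarray:
    if high_hz >= rate_hz / 2:
        raise ValueError(f"band edge {high_hz} Hz at or above Nyquist")
    if low_hz <= 0:
        raise ValueError("low edge must be positive")
    return sps.butter(order, [low_hz, high_hz], btype="bandpass",
                      fs=rate_hz, output="sos")


def bandpass(x: np.ndarray, low_hz: float, high_hz: float, rate_hz: float,
             order: int = 3, axis: int = 0) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    sos = butter_bandpass_sos(low_hz, high_hz, rate_hz, order)
    return sps.sosfiltfilt(sos, x, axis=axis)


def notch_filter(rec: Recording, line_hz: float = 60.0,
                 quality: float = 30.0) -> Recording:
    """Remove line noise with a zero-phase IIR notch."""
    if line_hz >= rec.rate_hz / 2:
        raise ValueError("line frequency at or above Nyquist")
    b, a = sps.iirnotch(line_hz, quality, fs=rec.rate_hz)
    out = sps.filtfilt(b, a, rec.data, axis=0)
    return rec.copy_with(out)


@dataclass
class PCAModel:
    """Back-projection description returned by :func:`pca_whiten`."""

    mean: np.ndarray
    components: np.ndarray        # (n_kept, n_channels)
    singular_scale: np.ndarray    # per-component std restored on inverse
    explained_ratio: np.ndarray

    def inverse_transform(self, comps: np.ndarray) -> np.ndarray:
        return (comps * self.singular_scale) @ self.components + self.mean


def pca_whiten(rec: Recording, var_kept: float = 0.95
               ) -> tuple[Recording, PCAModel]:
    """Reduce to the leading principal components explaining ``var_kept``.

    Returns the whitened component time courses (unit variance each) and a
    model sufficient to back-project to channel space.
    """
    if rec.n_samples <= rec.n_channels:
        raise ValueError("need more samples than channels")
    total = rec.data.var(axis=0).sum()
    if total == 0:
        raise ValueError("all-zero recording cannot be whitened")
    if 0 < var_kept < 1:
        pca = PCA(n_components=var_kept, svd_solver="full", whiten=True)
    else:
        pca = PCA(svd_solver="full", whiten=True)
    comps = pca.fit_transform(rec.data)
    if var_kept >= 1:
        keep = pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]
        comps = comps[:, keep]
        model = PCAModel(pca.mean_, pca.components_[keep],
                         np.sqrt(pca.explained_variance_[keep]),
                         pca.explained_variance_ratio_[keep])
    else:
        model = PCAModel(pca.mean_, pca.components_,
                         np.sqrt(pca.explained_variance_),
                         pca.explained_variance_ratio_)
    out = Recording(comps, rec.rate_hz,
                    [f"pc{i:02d}" for i in range(comps.shape[1])], rec.units)
    return out, model


@dataclass
class ComponentFlagReport:
    """Per-component artifact summary from the moment-based rule."""

    kurtosis_frac: np.ndarray
    skewness_frac: np.ndarray
    flagged: np.ndarray

    def __iter__(self):
        return iter(self.flagged)


def flag_artifact_components(components: np.ndarray | Recording,
                             rate_hz: float | None = None,
                             segment_s: float = 1.0,
                             z_bound: float = 2.0,
                             frac: float = 0.30) -> ComponentFlagReport:
    """Flag components whose segment-wise kurtosis or skewness is extreme.

    Kurtosis and skewness are computed per consecutive ``segment_s``
    segment and z-scored over the pooled (component, segment) values; a
    component is flagged when more than ``frac`` of its kurtosis values or
    skewness values fall outside ``+/- z_bound``.  Pooling across
    components keeps the rule sensitive when a large fraction of one
    component's segments is contaminated (a within-component z-score is
    bounded at (1-f)/sqrt(f(1-f)) and can never exceed 2 once more than a
    fifth of the segments are artifactual).  Because the moments are
    scale-free the rule is invariant to channel scaling.
    """
    if isinstance(components, Recording):
        rate_hz = components.rate_hz
        data = components.data
    else:
        data = np.asarray(components, float)
        if data.ndim == 1:
            data = data[:, None]
        if rate_hz is None:
            raise ValueError("rate_hz required for plain-array input")
    seg = int(round(segment_s * rate_hz))
    n_seg = data.shape[0] // seg
    if n_seg < 10:
        raise ValueError("need at least 10 segments per component")
    chunks = data[:n_seg * seg].reshape(n_seg, seg, data.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        kurt = spstats.kurtosis(chunks, axis=1, fisher=True, bias=False)
        skew = spstats.skew(chunks, axis=1, bias=False)
    kurt = np.nan_to_num(kurt)
    skew = np.nan_to_num(skew)

    def zfrac(vals):
        mu, sd = vals.mean(), vals.std()
        z = (vals - mu) / sd if sd > 0 else np.zeros_like(vals)
        return (np.abs(z) > z_bound).mean(axis=0)

    kf = zfrac(kurt)
    sf = zfrac(skew)
    return ComponentFlagReport(kf, sf, (kf > frac) | (sf > frac))


def bandpass_bank(rec: Recording,
                  scheme: tuple[Band, ...] = DEFAULT_BANDS
                  ) -> dict[str, Recording]:
    """Zero-phase third-order Butterworth filter bank over the band scheme."""
    validate_scheme(scheme)
    out = {}
    for b in scheme:
        if b.high >= rec.rate_hz / 2:
            raise ValueError(f"band {b.name} exceeds Nyquist")
        out[b.name] = rec.copy_with(bandpass(rec.data, b.low, b.high, rec.rate_hz))
    return out


def orthogonalize_pair(analytic_x: np.ndarray, analytic_y: np.ndarray,
                       eps: float = 1e-12) -> np.ndarray:
    """Remove from y, per sample, the component in phase with x.

    Both inputs are complex analytic signals of equal length.  The output
    has zero projection onto x's instantaneous phase direction at every
    sample; the operation is asymmetric (y relative to x) and idempotent.
    Zero-amplitude samples in x are floored at ``eps``.
    """
    zx = np.asarray(analytic_x, complex)
    zy = np.asarray(analytic_y, complex)
    if zx.shape != zy.shape:
        raise ValueError("analytic signals must have equal length")
    xhat = zx / np.maximum(np.abs(zx), eps)
    return zy - np.real(zy * np.conj(xhat)) * xhat
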