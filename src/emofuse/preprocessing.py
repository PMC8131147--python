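"""Raw EEG to frame-aligned alpha/beta/theta topographic image sequences.

The EEG branch of the pipeline: wavelet soft-threshold denoising, tiling
into segments of duration T (1/T matches the expression frame rate),
Welch band-energy estimation per channel, and interpolation of the 32
band powers onto a 2-D scalp image per band per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.interpolate import CloughTocher2DInterpolator, LinearNDInterpolator
from scipy.signal import welch

from . import montage

#: conventional band edges, Hz
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}
#: canonical band order used throughout the pipeline (image channel axis)
BAND_ORDER: tuple[str, str, str] = ("alpha", "beta", "theta")


@dataclass
class RawEEG:
    """32-channel scalp potential time series in microvolts."""

    samples: np.ndarray  # (n_channels, n_samples), uV
    sampling_rate: float  # Hz
    electrode_names: tuple[str, ...] = montage.CHANNEL_NAMES
    electrode_positions: np.ndarray = field(
        default_factory=lambda: montage.electrode_positions()
    )

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.electrode_names):
            raise ValueError(
                f"expected ({len(self.electrode_names)}, n) samples, got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG samples must be finite")
        if self.sampling_rate < 64:
            raise ValueError("sampling_rate must be at least 64 Hz")
        if len(set(self.electrode_names)) != len(self.electrode_names):
            raise ValueError("electrode names must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class EEGSegment:
    samples: np.ndarray  # (n_channels, window)
    duration: float  # s
    index: int
    sampling_rate: float


def read_raw_edf(path) -> RawEEG:
    """Load a 32-channel EDF/BDF recording as :class:`RawEEG` (µV).

    Channel names must come from the supported 32-electrode montage so
    that scalp positions are available.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = tuple(raw.ch_names)
    unknown = [n for n in names if n not in montage.CHANNEL_NAMES]
    if unknown:
        raise ValueError(f"unsupported electrode names in EDF: {unknown[:5]}")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return RawEEG(
        data_uv,
        float(raw.info["sfreq"]),
        electrode_names=names,
        electrode_positions=montage.electrode_positions(names),
    )


def denoise_wavelet_soft(
    raw: RawEEG,
    wavelet_name: str = "db4",
    level: int = 4,
    threshold_rule: str = "universal",
) -> RawEEG:
    """Per-channel discrete-wavelet soft-threshold denoising.

    Detail coefficients at every level are shrunk toward zero by the
    universal threshold lambda = sigma * sqrt(2 ln L), with the noise
    scale sigma estimated from the median absolute deviation of the
    finest-level details (sigma = MAD / 0.6745).  ``threshold_rule`` may
    be ``"universal"`` or ``"none"`` (lambda = 0, identity up to
    reconstruction round-off).
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    n = raw.samples.shape[1]
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet_name).dec_len)
    if level > max_level:
        raise ValueError(
            f"decomposition level {level} too deep for signal length {n} "
            f"(max {max_level})"
        )
    if threshold_rule not in ("universal", "none"):
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")

    coeffs = pywt.wavedec(raw.samples, wavelet_name, level=level, axis=-1)
    if threshold_rule == "universal":
        # per-channel sigma from the finest detail band
        mad = np.median(np.abs(coeffs[-1]), axis=-1, keepdims=True)
        sigma = mad / 0.6745
        lam = sigma * np.sqrt(2.0 * np.log(n))
    else:
        lam = np.zeros((raw.samples.shape[0], 1))
    # soft shrinkage: sign(c) * max(|c| - lambda, 0)
    out = [coeffs[0]] + [
        np.sign(c) * np.maximum(np.abs(c) - lam, 0.0) for c in coeffs[1:]
    ]
    rec = pywt.waverec(out, wavelet_name, axis=-1)[:, :n]
    return RawEEG(rec, raw.sampling_rate, raw.electrode_names, raw.electrode_positions)


def segment(raw: RawEEG, T: float) -> list[EEGSegment]:
    """Tile the trial into floor(duration/T) non-overlapping segments."""
    if T <= 0:
        raise ValueError("segment duration T must be positive")
    win = int(round(T * raw.sampling_rate))
    if win < 32:
        raise ValueError(
            f"T * sampling_rate = {T * raw.sampling_rate:.1f} samples; need >= 32"
        )
    n_seg = raw.samples.shape[1] // win
    return [
        EEGSegment(raw.samples[:, i * win : (i + 1) * win], T, i, raw.sampling_rate)
        for i in range(n_seg)
    ]


def band_power(seg: EEGSegment, band: str | tuple[float, float]) -> np.ndarray:
    """Per-channel spectral energy in the band, via Welch's method (uV^2)."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    nyq = seg.sampling_rate / 2.0
    if not (0 <= lo < hi <= nyq):
        raise ValueError(f"band ({lo}, {hi}) Hz outside (0, Nyquist={nyq}) Hz")
    powers = _welch_band_powers(seg.samples, seg.sampling_rate, [(lo, hi)])
    return powers[:, 0]


def _welch_band_powers(
    x: np.ndarray, fs: float, bands: list[tuple[float, float]]
) -> np.ndarray:
    """Integrated Welch PSD over each band; x (..., L) -> (..., n_bands)."""
    L = x.shape[-1]
    nperseg = min(L, 256)
    f, psd = welch(x, fs=fs, nperseg=nperseg, axis=-1)
    df = f[1] - f[0]
    out = np.empty(x.shape[:-1] + (len(bands),))
    for k, (lo, hi) in enumerate(bands):
        sel = (f >= lo) & (f < hi)
        out[..., k] = psd[..., sel].sum(axis=-1) * df
    return out


def trial_band_powers(raw: RawEEG, T: float) -> np.ndarray:
    """(n_segments, 3, 32) band powers in BAND_ORDER, vectorised over segments."""
    win = int(round(T * raw.sampling_rate))
    if T <= 0 or win < 32:
        raise ValueError("invalid segment duration")
    n_seg = raw.samples.shape[1] // win
    segs = raw.samples[:, : n_seg * win].reshape(raw.n_channels, n_seg, win)
    segs = np.moveaxis(segs, 0, 1)  # (n_seg, ch, win)
    bands = [BANDS[b] for b in BAND_ORDER]
    bp = _welch_band_powers(segs, raw.sampling_rate, bands)  # (n_seg, ch, 3)
    return np.moveaxis(bp, -1, 1)


class TopoMapper:
    """Interpolates 32 electrode values onto an H x W scalp image.

    Both supported interpolants (Clough-Tocher cubic, piecewise linear)
    are linear *in the electrode values*, so the map is precomputed once
    as a (32, H*W) weight matrix by interpolating the 32 canonical basis
    vectors.  Pixels outside the electrode convex hull form the scalp
    mask and are zero.  The pixel nearest each electrode is assigned that
    electrode's measured value, and cubic images are clipped to the
    electrode [min, max] range so interpolation never overshoots the
    measurements.
    """

    def __init__(
        self,
        positions: np.ndarray | None = None,
        resolution: int = 32,
        method: str = "cubic",
    ):
        pos = montage.electrode_positions() if positions is None else np.asarray(positions)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if np.any(np.hypot(pos[:, 0], pos[:, 1]) > 1.0 + 1e-9):
            raise ValueError("electrode positions must lie inside the unit disc")
        if len(np.unique(pos.round(12), axis=0)) != len(pos):
            raise ValueError("duplicate electrode positions")
        if method not in ("cubic", "linear"):
            raise ValueError(f"unknown interpolation method {method!r}")
        self.positions = pos
        self.resolution = int(resolution)
        self.method = method

        grid = np.linspace(-1.0, 1.0, self.resolution)
        gx, gy = np.meshgrid(grid, grid, indexing="xy")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        cls = CloughTocher2DInterpolator if method == "cubic" else LinearNDInterpolator
        n = len(pos)
        basis = np.empty((n, pts.shape[0]))
        for i in range(n):
            e = np.zeros(n)
            e[i] = 1.0
            basis[i] = cls(pos, e)(pts)
        mask_flat = np.isfinite(basis).all(axis=0)
        basis[~np.isfinite(basis)] = 0.0
        # snap each electrode to its nearest pixel: that pixel carries the
        # measured value exactly and belongs to the scalp mask even when
        # the electrode sits on the hull boundary
        d2 = ((pts[None, :, :] - pos[:, None, :]) ** 2).sum(-1)
        nearest = np.argmin(d2, axis=1)
        for i, px in enumerate(nearest):
            basis[:, px] = 0.0
            basis[i, px] = 1.0
            mask_flat[px] = True
        self.mask = mask_flat.reshape(self.resolution, self.resolution)
        self.weights = basis  # (n_electrodes, H*W)

    def __call__(self, values: np.ndarray) -> np.ndarray:
        """values (..., 32) -> images (..., H, W), clipped to [min, max]."""
        values = np.asarray(values, dtype=float)
        img = values @ self.weights
        lo = values.min(axis=-1, keepdims=True)
        hi = values.max(axis=-1, keepdims=True)
        img = np.clip(img, lo, hi)
        img = img.reshape(values.shape[:-1] + (self.resolution, self.resolution))
        return img * self.mask


def topo_image(
    band_powers: np.ndarray,
    positions: np.ndarray | None = None,
    resolution: int = 32,
    method: str = "cubic",
) -> tuple[np.ndarray, np.ndarray]:
    """Single scalp image from one 32-vector; returns (pixels, scalp_mask)."""
    bp = np.asarray(band_powers, dtype=float)
    if bp.ndim != 1:
        raise ValueError("band_powers must be a vector")
    if np.any(bp < 0):
        raise ValueError("band powers must be nonnegative")
    mapper = TopoMapper(positions, resolution, method)
    return mapper(bp), mapper.mask.copy()


def trial_to_band_images(
    raw: RawEEG,
    T: float = 0.2,
    mapper: TopoMapper | None = None,
    denoise: bool = True,
) -> np.ndarray:
    """Full EEG branch for one trial: (n_segments, 3, H, W) in BAND_ORDER."""
    if denoise:
        raw = denoise_wavelet_soft(raw)
    bp = trial_band_powers(raw, T)  # (S, 3, 32)
    if mapper is None:
        mapper = TopoMapper(raw.electrode_positions)
    return mapper(bp)
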