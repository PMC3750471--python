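"""Four-stage size/shape adjustment of cumulated-phase signals.

The pipeline order is fixed:

1. **median filtration** (default window 4) — suppresses single-sample
   excursions so individual nucleotides do not dominate the comparison;
2. **downsampling** (default factor 10, or spectrum-guided) — keeps the
   significant trend while discarding redundant samples; the factor can be
   estimated so that the retained band holds >= 99.5 % of the mean-removed
   spectral energy;
3. **normalization to [0, 1]** — removes amplitude/scale differences between
   signals;
4. **polynomial detrendization** (default order 4) — removes the slow
   nonlinear drift inherent to a cumulative phase so that local segment
   structure, not the global trend, drives the distance.

Even-window medians are the mean of the two central order statistics; window
truncation at the edges keeps the output length equal to the input length.
Downsampling is anti-alias low-pass filtering (zero-phase polyphase FIR, cut
at half the new Nyquist) followed by keeping every ``factor``-th sample.
The detrend polynomial is fit on the sample index rescaled to [0, 1] for
numerical conditioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np
from scipy.signal import resample_poly

from .errors import ParameterError
from .signal_transform import GenomicSignal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the four-stage preprocessing chain.

    ``downsample_factor`` may be an integer or the string ``"auto"``, in
    which case the factor is estimated from the power spectrum so that the
    retained band holds at least ``energy_fraction`` of the signal's
    mean-removed spectral energy (capped at ``max_auto_factor``).
    """

    median_window: int = 4
    downsample_factor: Union[int, str] = 10
    energy_fraction: float = 0.995
    poly_order: int = 4
    max_auto_factor: int = 70

    def __post_init__(self) -> None:
        if self.median_window < 1:
            raise ParameterError("median_window must be >= 1")
        if isinstance(self.downsample_factor, str):
            if self.downsample_factor != "auto":
                raise ParameterError(
                    "downsample_factor must be an integer or 'auto'"
                )
        elif self.downsample_factor < 1:
            raise ParameterError("downsample_factor must be >= 1")
        if not 0 < self.energy_fraction <= 1:
            raise ParameterError("energy_fraction must be in (0, 1]")
        if self.poly_order < 0:
            raise ParameterError("poly_order must be >= 0")
        if self.max_auto_factor < 1:
            raise ParameterError("max_auto_factor must be >= 1")


def load_config(path: Union[str, Path]) -> PreprocessConfig:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    fields = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key == "downsample_factor":
            fields[key] = value if value == "auto" else int(value)
        elif key == "energy_fraction":
            fields[key] = float(value)
        elif key in ("median_window", "poly_order", "max_auto_factor"):
            fields[key] = int(value)
        else:
            raise ParameterError(f"{path}: unknown config key {key!r}")
    return PreprocessConfig(**fields)


def _values(signal) -> np.ndarray:
    return signal.values if isinstance(signal, GenomicSignal) else np.asarray(
        signal, dtype=np.float64
    )


def median_filter(signal: GenomicSignal, window: int) -> GenomicSignal:
    """Centered running median; output length equals input length.

    Even windows average the two middle order statistics; at the edges the
    window is truncated to the available samples.
    """
    x = _values(signal)
    n = x.size
    if window < 1:
        raise ParameterError(f"median window must be >= 1 (got {window})")
    if window > n:
        raise ParameterError(
            f"median window ({window}) exceeds signal length ({n})"
        )
    if window == 1:
        out = x.copy()
    else:
        left = (window - 1) // 2
        right = window // 2
        # Stack shifted copies with NaN padding; nanmedian handles both the
        # truncated edges and the even-window mean-of-middle-two convention.
        stacked = np.full((window, n), np.nan)
        for k, offset in enumerate(range(-left, right + 1)):
            src_lo = max(0, -offset)
            src_hi = min(n, n - offset)
            stacked[k, src_lo:src_hi] = x[src_lo + offset : src_hi + offset]
        out = np.nanmedian(stacked, axis=0)
    if isinstance(signal, GenomicSignal):
        return signal.derive(out, "filtered", median_window=window)
    return GenomicSignal(out, stage="filtered")


def spectral_energy_below(x: np.ndarray, cutoff: float) -> float:
    """Fraction of mean-removed spectral power at frequencies < ``cutoff``.

    ``cutoff`` is a normalized frequency (0.5 = Nyquist).  Returns NaN for a
    constant signal (zero total power).
    """
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size)
    total = power[1:].sum()
    if total == 0:
        return float("nan")
    return float(power[(freqs > 0) & (freqs < cutoff)].sum() / total)


def estimate_downsample_factor(
    signal: GenomicSignal, energy_fraction: float = 0.995, max_factor: int = 70
) -> int:
    """Largest factor k <= max_factor whose retained band (< 1/(2k)) still
    holds at least ``energy_fraction`` of the mean-removed spectral power.

    Returns 1 when no k >= 2 qualifies.  A constant signal (all power at DC)
    returns ``max_factor`` with a logged note.
    """
    x = _values(signal)
    if x.size < 8:
        raise ParameterError("signal too short for spectral factor estimation")
    if np.ptp(x) == 0:
        logger.info(
            "estimate_downsample_factor: constant signal (all energy at DC); "
            "returning max_factor=%d", max_factor,
        )
        return max_factor
    for k in range(max_factor, 1, -1):
        if spectral_energy_below(x, 1.0 / (2 * k)) >= energy_fraction:
            return k
    return 1


def downsample(signal: GenomicSignal, factor: int) -> GenomicSignal:
    """Anti-alias low-pass then keep every ``factor``-th sample.

    Zero-phase polyphase FIR with cutoff at 1/(2*factor) normalized; output
    length is ``ceil(len/factor)``; ``sample_step`` is multiplied by the
    factor.  Edge samples are handled by edge-value padding so a constant
    (DC) signal passes through exactly.
    """
    x = _values(signal)
    if factor < 1:
        raise ParameterError(f"downsample factor must be >= 1 (got {factor})")
    if factor >= x.size and factor != 1:
        raise ParameterError(
            f"downsample factor ({factor}) must be smaller than the signal "
            f"length ({x.size})"
        )
    out = x.copy() if factor == 1 else resample_poly(x, 1, factor, padtype="edge")
    if isinstance(signal, GenomicSignal):
        return signal.derive(
            out,
            "downsampled",
            sample_step=signal.sample_step * factor,
            downsample_factor=factor,
        )
    return GenomicSignal(out, stage="downsampled", sample_step=factor)


def normalize01(signal: GenomicSignal) -> GenomicSignal:
    """Linear rescale to [0, 1]; a constant signal maps to all zeros."""
    x = _values(signal)
    span = x.max() - x.min()
    out = np.zeros_like(x) if span == 0 else (x - x.min()) / span
    if isinstance(signal, GenomicSignal):
        return signal.derive(out, "normalized")
    return GenomicSignal(out, stage="normalized")


def detrend_poly(signal: GenomicSignal, order: int) -> GenomicSignal:
    """Subtract the least-squares polynomial trend of the given order.

    The fit uses the sample index rescaled to [0, 1].  Order 0 is mean
    centering.  Requires ``len(signal) > order``.
    """
    x = _values(signal)
    if order < 0:
        raise ParameterError(f"poly order must be >= 0 (got {order})")
    if x.size <= order:
        raise ParameterError(
            f"signal length ({x.size}) must exceed poly order ({order})"
        )
    t = np.linspace(0.0, 1.0, x.size)
    coeffs = np.polynomial.polynomial.polyfit(t, x, order)
    trend = np.polynomial.polynomial.polyval(t, coeffs)
    out = x - trend
    if isinstance(signal, GenomicSignal):
        return signal.derive(out, "detrended", poly_order=order)
    return GenomicSignal(out, stage="detrended")


def preprocess(
    signal: GenomicSignal, config: PreprocessConfig = PreprocessConfig()
) -> GenomicSignal:
    """Full chain: median filter -> downsample -> normalize -> detrend.

    With ``downsample_factor="auto"`` the factor is estimated from the
    signal's power spectrum (see :func:`estimate_downsample_factor`).  All
    applied parameters are recorded in the output signal's metadata.
    """
    factor = config.downsample_factor
    if factor == "auto":
        factor = estimate_downsample_factor(
            signal, config.energy_fraction, config.max_auto_factor
        )
        logger.info(
            "preprocess(%s): auto downsample factor -> %d",
            getattr(signal, "source_id", "?"), factor,
        )
    out = median_filter(signal, config.median_window)
    out = downsample(out, factor)
    out = normalize01(out)
    out = detrend_poly(out, config.poly_order)
    out.metadata["preprocess_config"] = replace(config, downsample_factor=factor)
    return out
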