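"""Disparity-energy-style unit responses and tuning analysis.

A binocular simple unit applies linear spatial filtering per eye, sums the
two drives with a bias, and passes the result through a static output
nonlinearity.  Its disparity tuning to broadband stimuli is well
approximated (for a squaring nonlinearity) by an affine function of the
interocular receptive-field cross-correlogram:

    f(delta) ~= 2 * (W_L x W_R)[delta] * E(S^2) + C

where the cross-correlogram at lag delta is sum_x W_L(x) W_R(x + delta)
under this package's convention that positive disparity shifts right-eye
features rightward.  The monocular energy terms contribute the
disparity-independent constant C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.signal import fftconvolve

from .gabor import BinocularRF
from .stimgen import RDSConfig, StereoPair, make_rds

__all__ = [
    "NonlinearitySpec",
    "TuningCurve",
    "simple_response",
    "response_map",
    "disparity_tuning",
    "rf_cross_correlogram",
    "predict_tuning_from_crosscorr",
]


@dataclass(frozen=True)
class NonlinearitySpec:
    """Static output nonlinearity of a simple unit.

    kinds: 'relu' (linear rectification), 'squaring' (unrectified square),
    'rectified-squaring', and 'power' (rectified power with the given
    exponent).
    """

    kind: Literal["relu", "squaring", "rectified-squaring", "power"] = "squaring"
    exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.kind == "power" and self.exponent <= 0:
            raise ValueError("power nonlinearity requires exponent > 0")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "relu":
            return np.maximum(x, 0.0)
        if self.kind == "squaring":
            return x * x
        if self.kind == "rectified-squaring":
            return np.maximum(x, 0.0) ** 2
        if self.kind == "power":
            return np.maximum(x, 0.0) ** self.exponent
        raise ValueError(f"unknown nonlinearity: {self.kind}")


@dataclass
class TuningCurve:
    """Mean response versus stimulus disparity with per-trial samples."""

    disparities: np.ndarray  # (n_disp,), strictly increasing
    trials: np.ndarray  # (n_trials, n_disp)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.disparities = np.asarray(self.disparities, dtype=float)
        self.trials = np.asarray(self.trials, dtype=float)
        if np.any(np.diff(self.disparities) <= 0):
            raise ValueError("disparity grid must be strictly increasing")
        if self.trials.shape[1] != len(self.disparities):
            raise ValueError("trials must be (n_trials, n_disparities)")

    @property
    def mean(self) -> np.ndarray:
        return self.trials.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.trials.std(axis=0, ddof=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "disparity": self.disparities,
                "mean": self.mean,
                "sd": self.sd,
                "n": np.full(len(self.disparities), self.trials.shape[0]),
            }
        )


def _linear_drive_maps(rf: BinocularRF, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Valid-mode correlation of each eye's image stack with its RF, summed
    across eyes plus the bias.  Stacks are (n, H, W)."""
    kl = rf.w_left[::-1, ::-1]
    kr = rf.w_right[::-1, ::-1]
    out = fftconvolve(left, kl[None], mode="valid", axes=(1, 2))
    out += fftconvolve(right, kr[None], mode="valid", axes=(1, 2))
    return out + rf.bias


def simple_response(
    rf: BinocularRF, pair: StereoPair, nl: NonlinearitySpec
) -> float | np.ndarray:
    """Response of a simple unit to a stereo pair.

    If the pair matches the RF size exactly, returns the scalar response at
    that single position; otherwise the RF is applied convolutionally (no
    padding) and a response map is returned.
    """
    if pair.shape == rf.shape:
        drive = (
            float(np.sum(rf.w_left * pair.left))
            + float(np.sum(rf.w_right * pair.right))
            + rf.bias
        )
        return float(nl.apply(np.asarray(drive)))
    if pair.shape[0] < rf.shape[0] or pair.shape[1] < rf.shape[1]:
        raise ValueError(
            f"stimulus {pair.shape} smaller than receptive field {rf.shape}"
        )
    return response_map(rf, pair, nl)


def response_map(rf: BinocularRF, pair: StereoPair, nl: NonlinearitySpec) -> np.ndarray:
    """Convolutional (valid, stride 1) response map of a simple unit."""
    drive = _linear_drive_maps(rf, pair.left[None], pair.right[None])[0]
    return nl.apply(drive)


def disparity_tuning(
    rf: BinocularRF,
    nl: NonlinearitySpec,
    disparities: np.ndarray,
    trials: int = 100,
    density: float = 0.5,
    dot_size: int = 1,
    correlated: bool = True,
    polarity: str = "mixed",
    stimulus_size: Optional[tuple[int, int]] = None,
    mode: Literal["single", "sum"] = "single",
    seed: Optional[int] = None,
) -> TuningCurve:
    """Empirical disparity tuning curve from random-dot stereograms.

    For each disparity, ``trials`` fresh RDS are generated (dots drawn in
    the left eye, right eye a shifted -- and for anticorrelated ensembles
    contrast-inverted -- copy).  ``mode='single'`` evaluates the unit at one
    position (stimulus size = RF size); ``mode='sum'`` applies the RF
    convolutionally and sums the rectified map over space, i.e. the drive a
    downstream unit pooling over a map of identical simple units receives.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    disparities = np.asarray(disparities)
    size = stimulus_size or rf.shape
    h, w = size
    out = np.empty((trials, len(disparities)))

    wl = rf.w_left.ravel()
    wr = rf.w_right.ravel()
    for j, d in enumerate(disparities):
        cfg = RDSConfig(
            size=(h, w),
            dot_size=dot_size,
            density=density,
            polarity=polarity,  # type: ignore[arg-type]
            disparity=int(d),
            correlated=correlated,
        )
        if dot_size == 1:
            # vectorized path for 1-px dots
            left = np.zeros((trials, h, w))
            mask = rng.random((trials, h, w)) < density
            if polarity == "mixed":
                vals = rng.choice([-1.0, 1.0], size=mask.shape)
            elif polarity == "bright":
                vals = np.ones(mask.shape)
            else:
                vals = -np.ones(mask.shape)
            left[mask] = vals[mask]
            right = np.roll(left, int(d), axis=2)
            if not correlated:
                right = -right
            if mode == "single" and size == rf.shape:
                out[:, j] = nl.apply(
                    left.reshape(trials, -1) @ wl
                    + right.reshape(trials, -1) @ wr
                    + rf.bias
                )
            else:
                maps = nl.apply(_linear_drive_maps(rf, left, right))
                out[:, j] = maps.sum(axis=(1, 2)) if mode == "sum" else maps[
                    :, maps.shape[1] // 2, maps.shape[2] // 2
                ]
        else:
            for t in range(trials):
                pair = make_rds(cfg, rng=rng)
                resp = simple_response(rf, pair, nl)
                out[t, j] = resp if np.isscalar(resp) else (
                    resp.sum() if mode == "sum" else resp[resp.shape[0] // 2, resp.shape[1] // 2]
                )
    return TuningCurve(
        disparities=disparities,
        trials=out,
        meta={
            "density": density,
            "dot_size": dot_size,
            "correlated": correlated,
            "polarity": polarity,
            "mode": mode,
            "stimulus_size": tuple(size),
        },
    )


def rf_cross_correlogram(
    rf: BinocularRF,
    lags: np.ndarray,
    circular: bool = False,
) -> np.ndarray:
    """Interocular receptive-field cross-correlogram.

    value at lag d = sum_{x,y} W_L(y, x) * W_R(y, x + d), so a unit whose
    right RF is the left RF translated rightward by k pixels peaks at lag
    k -- the unit's preferred disparity under the package sign convention.
    Out-of-range samples are treated as zero unless ``circular``.
    """
    lags = np.asarray(lags, dtype=int)
    w = rf.shape[1]
    out = np.empty(len(lags))
    for i, d in enumerate(lags):
        if circular:
            out[i] = float(np.sum(rf.w_left * np.roll(rf.w_right, -d, axis=1)))
            continue
        if abs(d) >= w:
            out[i] = 0.0
        elif d >= 0:
            out[i] = float(np.sum(rf.w_left[:, : w - d] * rf.w_right[:, d:]))
        else:
            out[i] = float(np.sum(rf.w_left[:, -d:] * rf.w_right[:, : w + d]))
    return out


def predict_tuning_from_crosscorr(
    rf: BinocularRF,
    lags: np.ndarray,
    stimulus_energy: float,
    baseline: float = 0.0,
) -> np.ndarray:
    """Cross-correlogram prediction of the squaring-nonlinearity tuning
    curve: 2 * (W_L x W_R)[delta] * E(S^2) + C.

    ``stimulus_energy`` is the per-pixel second moment E(S^2) of the
    stimulus ensemble (0.5 for 50%-density mixed +-1 dots on a mid-gray
    background); ``baseline`` is the disparity-independent monocular
    term C.  Both are normally estimated empirically from the ensemble.
    """
    return 2.0 * rf_cross_correlogram(rf, lags) * stimulus_energy + baseline
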