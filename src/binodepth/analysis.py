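"""Analysis pipelines: tuning-curve Gabor fits with bootstrap amplitude
ratios, readout-weight versus cross-correlogram correlation, the
mixed/single-polarity step-edge task, and the synthetic-scene training
pipeline that feeds the binocular network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bnn import BNNModel, depth_sign_map
from .gabor import BinocularRF, GaborFitter
from .stimgen import (
    PatchSet,
    SceneSpec,
    StepEdgeConfig,
    make_step_edge,
    polarity_controls,
    render_stereo_from_depth,
    extract_patches,
    synth_scene,
)
from .units import TuningCurve, rf_cross_correlogram

__all__ = [
    "AmplitudeRatioResult",
    "PolarityTaskResult",
    "amplitude_ratio",
    "encoding_table",
    "readout_vs_crosscorr",
    "polarity_task",
    "make_training_data",
    "bnn_unit_rfs",
    "make_rds_test_set",
]


@dataclass
class AmplitudeRatioResult:
    """Bootstrap distribution of aRDS/cRDS fitted-Gabor amplitude ratios."""

    ratios: np.ndarray  # (n_boot,)
    r2_correlated: np.ndarray
    r2_anticorrelated: np.ndarray
    n_excluded: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.ratios.mean())


def amplitude_ratio(
    tuning_correlated: TuningCurve,
    tuning_anticorrelated: TuningCurve,
    n_boot: int = 5000,
    seed: Optional[int] = None,
    min_r2: float = 0.0,
) -> AmplitudeRatioResult:
    """Bootstrap the aRDS/cRDS amplitude ratio of a complex unit.

    Trials are resampled with replacement per disparity; a Gabor is fit to
    each resampled mean tuning curve (after removing the curve's mean,
    since the Gabor model carries no baseline term) and the ratio of the
    fitted anticorrelated to correlated amplitudes is recorded.  With
    ``n_boot=1`` and no resampling variability this reduces to the point
    estimate from the mean curves.
    """
    if not np.array_equal(
        tuning_correlated.disparities, tuning_anticorrelated.disparities
    ):
        raise ValueError("tuning curves must share a disparity grid")
    rng = np.random.default_rng(seed)
    fitter = GaborFitter(tuning_correlated.disparities)

    def _resample(tc: TuningCurve) -> np.ndarray:
        t = tc.trials
        idx = rng.integers(0, t.shape[0], size=t.shape[0])
        return t[idx].mean(axis=0)

    ratios, r2c_all, r2a_all = [], [], []
    excluded = 0
    for b in range(n_boot):
        if n_boot == 1:
            mc = tuning_correlated.mean
            ma = tuning_anticorrelated.mean
        else:
            mc = _resample(tuning_correlated)
            ma = _resample(tuning_anticorrelated)
        try:
            pc, r2c = fitter.fit(mc - mc.mean())
            pa, r2a = fitter.fit(ma - ma.mean())
        except ValueError:
            excluded += 1
            continue
        if r2c < min_r2 or r2a < min_r2:
            excluded += 1
            continue
        ratios.append(pa.amplitude / pc.amplitude)
        r2c_all.append(r2c)
        r2a_all.append(r2a)
    if excluded > 0.2 * n_boot:
        import warnings

        warnings.warn(
            f"{excluded}/{n_boot} bootstrap fits failed or fell below the "
            f"R^2 floor and were excluded",
            stacklevel=2,
        )
    return AmplitudeRatioResult(
        ratios=np.asarray(ratios),
        r2_correlated=np.asarray(r2c_all),
        r2_anticorrelated=np.asarray(r2a_all),
        n_excluded=excluded,
        meta={"n_boot": n_boot},
    )


def bnn_unit_rfs(model: BNNModel) -> list[BinocularRF]:
    """The network's convolutional kernels as binocular receptive fields."""
    return [
        BinocularRF(
            w_left=model.kernels[k, :, :, 0].astype(float),
            w_right=model.kernels[k, :, :, 1].astype(float),
            bias=float(model.conv_bias[k]),
        )
        for k in range(model.n_kernels)
    ]


def encoding_table(rfs: Sequence[BinocularRF], min_r2: float = 0.5):
    """Per-eye Gabor fit parameters for a bank of binocular RFs.

    Returns a DataFrame with one row per unit per eye (amplitude, center,
    sigma, frequency, phase, R^2) plus the unit's interocular position and
    phase disparities; suitable for CSV export.  Units whose fit fails in
    either eye are kept with NaN entries and ``valid=False``.
    """
    import pandas as pd

    from .gabor import GaborFitter, classify_encoding, pixel_grid

    rows = []
    fitter = GaborFitter(pixel_grid(rfs[0].shape[1])) if rfs else None
    for u, rf in enumerate(rfs):
        enc = classify_encoding(rf, min_r2=min_r2, fitter=fitter)
        row_idx = int(np.argmax(np.sum(rf.w_left**2 + rf.w_right**2, axis=1)))
        for eye, weights, r2 in (
            ("left", rf.w_left, enc.r2_left),
            ("right", rf.w_right, enc.r2_right),
        ):
            try:
                params, _ = fitter.fit(weights[row_idx])
                vals = dict(
                    amplitude=params.amplitude,
                    center=params.center,
                    sigma=params.sigma,
                    frequency=params.frequency,
                    phase=params.phase,
                )
            except ValueError:
                vals = dict(
                    amplitude=np.nan, center=np.nan, sigma=np.nan,
                    frequency=np.nan, phase=np.nan,
                )
            rows.append(
                {
                    "unit": u,
                    "eye": eye,
                    **vals,
                    "r2": r2,
                    "position_disparity": enc.position_disparity,
                    "phase_disparity": enc.phase_disparity,
                    "valid": enc.valid,
                }
            )
    return pd.DataFrame(rows)


def readout_vs_crosscorr(
    model: BNNModel, lag_range: int = 9
) -> dict[str, dict[str, float]]:
    """Correlate each output unit's mean readout weights with the units'
    cross-correlograms averaged over that output's preferred lags.

    For the near (far) output unit, each simple unit's cross-correlogram is
    averaged over the negative (positive) half of the lag grid and
    correlated, across the 28 units, with the mean readout weight onto that
    output.  Returns Pearson R and p per output.
    """
    from scipy.stats import pearsonr

    w_eff = model.readout_matrix()
    if np.allclose(w_eff, 0):
        raise ValueError("readout weights are all zero (untrained model)")
    k = model.n_kernels
    mean_w = w_eff.reshape(k, -1, w_eff.shape[-1]).mean(axis=1)  # (K, n_out)

    lags = np.arange(-lag_range, lag_range + 1)
    ccs = np.stack([rf_cross_correlogram(rf, lags) for rf in bnn_unit_rfs(model)])
    near_cc = ccs[:, lags < 0].mean(axis=1)
    far_cc = ccs[:, lags > 0].mean(axis=1)

    out = {}
    for j, (name, cc) in enumerate((("near", near_cc), ("far", far_cc))):
        r, p = pearsonr(mean_w[:, j], cc)
        out[name] = {"R": float(r), "p": float(p)}
    return out


@dataclass
class PolarityTaskResult:
    """Proportion correct per dot-polarity condition and control."""

    proportion_correct: dict  # {(polarity, control): float}
    n_trials: int


def _decide_step(model: BNNModel, pair, bank=None) -> str:
    """Step-arrangement decision: the half whose mean depth-sign (far minus
    near) activity is lower is called near."""
    m = depth_sign_map(model, pair, bank=bank).values
    w = m.shape[1]
    left_mean = m[:, : w // 2].mean()
    right_mean = m[:, w // 2 :].mean()
    return "left" if left_mean < right_mean else "right"


def polarity_task(
    model: BNNModel,
    n_trials: int = 1000,
    controls: Sequence[Optional[str]] = (None, "dc-removed", "range-matched", "range-matched-after-dc"),
    config: StepEdgeConfig = StepEdgeConfig(),
    seed: Optional[int] = None,
) -> PolarityTaskResult:
    """Step-edge depth discrimination across polarity conditions.

    Per trial one step-edge dot layout is generated (near side
    counterbalanced) and rendered in all three polarity conditions --
    mixed dots as drawn, bright-only and dark-only as the same layout with
    every dot set to +1 or -1 -- so the conditions are compared on
    identical geometry and disparity noise.  Each rendering is optionally
    passed through a covariate control before the model's depth-sign map
    decides the step arrangement.  Returns the proportion of correct
    choices per (polarity, control) cell.
    """
    from dataclasses import replace

    from .bnn import ConvBank
    from .stimgen import StereoPair

    bank = ConvBank(model, config.size)
    rng = np.random.default_rng(seed)
    polarities = ("mixed", "bright", "dark")
    correct = {(p, c): 0 for p in polarities for c in controls}
    for t in range(n_trials):
        near_side = "left" if rng.random() < 0.5 else "right"
        cfg = replace(config, polarity="mixed", near_side=near_side, seed=None)
        mixed = make_step_edge(cfg, rng=rng)
        variants = {
            "mixed": mixed,
            "bright": StereoPair(np.abs(mixed.left), np.abs(mixed.right)),
            "dark": StereoPair(-np.abs(mixed.left), -np.abs(mixed.right)),
        }
        for polarity, pair in variants.items():
            for control in controls:
                shown = pair if control is None else polarity_controls(pair, control)
                if _decide_step(model, shown, bank=bank) == near_side:
                    correct[(polarity, control)] += 1
    results = {
        (p, c or "none"): correct[(p, c)] / n_trials
        for p in polarities
        for c in controls
    }
    return PolarityTaskResult(proportion_correct=results, n_trials=n_trials)


def oracle_step_decision(pair) -> str:
    """Ground-truth decision rule applied to the imposed disparity map
    (separates decision-rule error from model error)."""
    d = pair.meta["signal_disparity"]
    w = d.shape[1]
    return "left" if d[:, : w // 2].mean() < d[:, w // 2 :].mean() else "right"


def make_training_data(
    n_scenes: int = 200,
    spec: SceneSpec = SceneSpec(),
    patch: int = 30,
    split: tuple[float, float, float] = (70.0, 15.0, 15.0),
    seed: Optional[int] = None,
) -> tuple[PatchSet, PatchSet, PatchSet]:
    """Render synthetic naturalistic scenes into stereo pairs and cut
    labelled near/far patches (see :func:`stimgen.extract_patches`)."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_scenes):
        texture, depth = synth_scene(spec, rng=rng)
        # depth is in [-1, 1] units; full scale maps to max_shift pixels
        pairs.append(
            render_stereo_from_depth(
                texture,
                depth * spec.max_shift,
                max_shift=spec.max_shift,
                normalize_depth=False,
            )
        )
    return extract_patches(
        pairs, patch=patch, split=split, seed=int(rng.integers(2**31))
    )


def make_rds_test_set(
    n: int = 6000,
    patch: int = 30,
    disparities: Sequence[int] = (2,),
    density: float = 0.5,
    dot_size: int = 1,
    correlated: bool = True,
    seed: Optional[int] = None,
) -> PatchSet:
    """Random-dot stereogram test set at the trained near/far disparity
    magnitudes (labels: 0 = near/negative, 1 = far/positive)."""
    from .stimgen import RDSConfig, make_rds

    rng = np.random.default_rng(seed)
    lefts = np.empty((n, patch, patch))
    rights = np.empty((n, patch, patch))
    labels = rng.integers(0, 2, n)
    mags = rng.choice(list(disparities), n)
    for i in range(n):
        d = int(mags[i]) * (1 if labels[i] == 1 else -1)
        pair = make_rds(
            RDSConfig(
                size=(patch, patch),
                dot_size=dot_size,
                density=density,
                disparity=d,
                correlated=correlated,
            ),
            rng=rng,
        )
        lefts[i] = pair.left
        rights[i] = pair.right
    return PatchSet(lefts, rights, labels)
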