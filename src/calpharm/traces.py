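"""Fluorescence normalization primitives.

Two normalizations are used throughout.  Stimulation experiments use the
classical dF/Fo with an imaging-background term,

    dF/Fo(t) = (F(t) - Fo) / (Fo - FB),

where Fo and FB are the means of the ROI trace and of the background trace
over the pre-stimulus window.  Awake locomotion sessions instead subtract
scaled neuropil fluorescence, F = F_MLI - r*F_Neuropil with r = 0.7, and
normalize every recording of a block to the per-ROI resting fluorescence
F_rest measured on the block's least-active recording:

    dF/F_rest(t) = (F(t) - F_rest) / F_rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import DffMatrix, Recording, SessionBlock, window_to_frames

DEFAULT_NEUROPIL_SCALE = 0.7
DEFAULT_BASELINE_WINDOW = (0.0, 5.0)


class DegenerateBaselineError(ValueError):
    """Raised when Fo <= FB or F_rest <= 0 makes a normalization undefined."""


@dataclass
class BackgroundEstimate:
    trace: np.ndarray           # Fb(t), one value per frame
    pixel_index: np.ndarray     # flat indices of the selected darkest pixels


def estimate_background(frame_stack: np.ndarray, n_low: int = 25) -> BackgroundEstimate:
    """Background trace Fb(t) from the ``n_low`` darkest pixels.

    Pixels are ranked on the time-averaged image (the stable reading of
    "lowest F value throughout all the frames"); Fb(t) is the mean of that
    fixed pixel set at each frame.  ``n_low`` conventionally lies in [20, 30].
    """
    stack = np.asarray(frame_stack, dtype=float)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("frame_stack must be a non-empty (frames, y, x) array")
    n_pix = stack.shape[1] * stack.shape[2]
    if not 1 <= n_low <= n_pix:
        raise ValueError(f"n_low={n_low} outside [1, {n_pix}]")
    mean_img = stack.mean(axis=0).ravel()
    # argpartition gives the n_low smallest; ties at the cut resolved by index order
    order = np.argsort(mean_img, kind="stable")[:n_low]
    flat = stack.reshape(stack.shape[0], n_pix)
    return BackgroundEstimate(trace=flat[:, order].mean(axis=1), pixel_index=np.sort(order))


def compute_dff(
    trace: np.ndarray,
    prestim_window: tuple[float, float],
    background: np.ndarray | float,
    frame_rate: float = 30.0,
) -> np.ndarray:
    """dF/Fo(t) = (F(t) - Fo)/(Fo - FB) with Fo, FB averaged over the
    pre-stimulus window.  Raises DegenerateBaselineError when Fo <= FB."""
    f = np.asarray(trace, dtype=float)
    fb = np.broadcast_to(np.asarray(background, dtype=float), f.shape)
    sl = window_to_frames(prestim_window, frame_rate, len(f))
    fo = f[sl].mean()
    fb_mean = fb[sl].mean()
    if fo <= fb_mean:
        raise DegenerateBaselineError(
            f"Fo={fo:.4g} <= FB={fb_mean:.4g}: dF/Fo undefined"
        )
    return (f - fo) / (fo - fb_mean)


def neuropil_correct(
    soma: np.ndarray | pd.DataFrame,
    neuropil: np.ndarray | pd.DataFrame,
    r: float = DEFAULT_NEUROPIL_SCALE,
) -> np.ndarray | pd.DataFrame:
    """F = F_MLI - r * F_Neuropil, elementwise (r = 0.7 by default)."""
    if np.shape(soma) != np.shape(neuropil):
        raise ValueError("soma and neuropil traces must have equal shape")
    if not 0.0 <= r < 1.0:
        raise ValueError("neuropil scale r must be in [0, 1)")
    return soma - r * neuropil


def select_least_active(
    recordings: list[Recording],
    window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
) -> int:
    """Global index of the recording with the least locomotor activity.

    Activity is the total absolute distance traveled by the treadmill within
    the baseline window; ties go to the lowest recording index.
    """
    if not recordings:
        raise ValueError("no recordings given")
    best_idx, best_dist = np.inf, np.inf
    for rec in recordings:
        enc = rec.encoder
        if enc is None or "position_cm" not in enc:
            raise ValueError(f"recording {rec.index} has no encoder trace")
        t = enc["time_s"].to_numpy()
        pos = enc["position_cm"].to_numpy()
        in_win = (t >= window[0]) & (t < window[1])
        dist = float(np.abs(np.diff(pos[in_win])).sum()) if in_win.sum() > 1 else 0.0
        if dist < best_dist or (dist == best_dist and rec.index < best_idx):
            best_idx, best_dist = rec.index, dist
    return best_idx


def normalize_to_rest(
    block: SessionBlock,
    condition: str,
    k: int | None = None,
    window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    r: float = DEFAULT_NEUROPIL_SCALE,
) -> DffMatrix:
    """Rest-normalize all recordings of one condition block.

    F_rest per ROI is the mean of the neuropil-corrected soma trace of the
    least-active recording ``k`` over the baseline window (correction is
    applied before normalization).  Every recording of the block, using the
    single per-ROI F_rest, becomes (F(t) - F_rest)/F_rest.
    """
    recs = block.by_condition(condition)
    if not recs:
        raise ValueError(f"block has no {condition!r} recordings")
    if k is None:
        k = select_least_active(recs, window)
    by_index = {rec.index: rec for rec in recs}
    if k not in by_index:
        raise ValueError(f"recording {k} not in {condition!r} block")
    ref = by_index[k]
    corrected_ref = neuropil_correct(ref.soma, ref.neuropil, r)
    sl = window_to_frames(window, ref.frame_rate, ref.n_frames)
    f_rest = corrected_ref.iloc[sl].mean(axis=0)
    bad = f_rest[f_rest <= 0]
    if len(bad):
        raise DegenerateBaselineError(
            f"F_rest <= 0 for ROIs {bad.index.tolist()}: rest normalization undefined"
        )
    traces = {}
    for rec in recs:
        corrected = neuropil_correct(rec.soma, rec.neuropil, r)
        traces[rec.index] = (corrected - f_rest) / f_rest
    return DffMatrix(
        traces=traces,
        f_rest=f_rest,
        least_active=k,
        condition=condition,
        frame_rate=recs[0].frame_rate,
    )


def qc_table(dff: DffMatrix) -> pd.DataFrame:
    """Per-ROI QC summary (F_rest and flags) for export."""
    out = pd.DataFrame({"roi": dff.f_rest.index, "f_rest": dff.f_rest.to_numpy()})
    out["condition"] = dff.condition
    out["least_active_recording"] = dff.least_active
    out["flag"] = np.where(out["f_rest"] > 0, "", "nonpositive_f_rest")
    return out
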