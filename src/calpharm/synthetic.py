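"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure the analyses assume rather than the
underlying biophysics: a motorized-treadmill speed protocol, locomotion-locked
somatic fluorescence riding on a resting baseline with neuropil
contamination and a session-wide exponential decay, a drug effect whose
magnitude is linearly coupled to the pre-drug locomotion fluorescence, rigid
translations between the pre- and post-drug fields of view, and radially
declining immunogold particle density around a postsynaptic-density outline.
All randomness flows from the explicit ``seed`` of each parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .blocks import POST, PRE, GroundTruth, Recording, SessionBlock

# ---------------------------------------------------------------------------
# treadmill protocol


@dataclass
class ProtocolParams:
    """Motorized forced-locomotion protocol.

    The wheel is free until ``t_free_end``, starts a linear acceleration of
    ``accel`` cm/s^2 at ``t_accel_start``, holds ``v_max`` until
    ``t_const_end``, decelerates to rest by ``t_stop`` and stays still until
    ``t_total``.  The acceleration is stored exactly as v_max / 3 cm/s^2
    (printed as 3.33) so the kinematic identities below are exact.
    """

    t_free_end: float = 6.0
    t_accel_start: float = 7.0
    accel: float = 10.0 / 3.0
    v_max: float = 10.0
    t_const_end: float = 23.0
    t_stop: float = 26.0
    t_total: float = 40.0
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if not (self.t_free_end < self.t_accel_start < self.t_const_end < self.t_stop <= self.t_total):
            raise ValueError("protocol times must satisfy free < accel < const_end < stop <= total")
        if self.accel <= 0 or self.v_max <= 0 or self.frame_rate <= 0:
            raise ValueError("accel, v_max and frame_rate must be positive")
        if self.t_accel_start + self.v_max / self.accel > self.t_const_end:
            raise ValueError("v_max not reached before the constant-speed phase ends")

    @property
    def t_vmax(self) -> float:
        """Time at which the wheel reaches maximal speed (10 s at defaults)."""
        return self.t_accel_start + self.v_max / self.accel


@dataclass
class SpeedTrace:
    time_s: np.ndarray
    speed_cm_s: np.ndarray
    position_cm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "speed_cm_s": self.speed_cm_s, "position_cm": self.position_cm}
        )


def _protocol_speed(t: np.ndarray, p: ProtocolParams) -> np.ndarray:
    decel = p.v_max / (p.t_stop - p.t_const_end)
    return np.select(
        [
            t < p.t_accel_start,
            t < p.t_vmax,
            t < p.t_const_end,
            t < p.t_stop,
        ],
        [
            0.0,
            p.accel * (t - p.t_accel_start),
            p.v_max,
            p.v_max - decel * (t - p.t_const_end),
        ],
        default=0.0,
    )


def protocol_position(t: np.ndarray | float, p: ProtocolParams) -> np.ndarray | float:
    """Closed-form wheel position (cm): the running integral of the speed."""
    t = np.asarray(t, dtype=float)
    decel = p.v_max / (p.t_stop - p.t_const_end)
    d_accel = 0.5 * p.accel * (p.t_vmax - p.t_accel_start) ** 2
    d_const = d_accel + p.v_max * (p.t_const_end - p.t_vmax)
    d_total = d_const + p.v_max * (p.t_stop - p.t_const_end) - 0.5 * decel * (p.t_stop - p.t_const_end) ** 2
    pos = np.select(
        [
            t < p.t_accel_start,
            t < p.t_vmax,
            t < p.t_const_end,
            t < p.t_stop,
        ],
        [
            0.0,
            0.5 * p.accel * (t - p.t_accel_start) ** 2,
            d_accel + p.v_max * (t - p.t_vmax),
            d_const + p.v_max * (t - p.t_const_end) - 0.5 * decel * (t - p.t_const_end) ** 2,
        ],
        default=d_total,
    )
    return pos if pos.shape else float(pos)


def gen_speed_trace(protocol: ProtocolParams | None = None) -> SpeedTrace:
    """Deterministic piecewise-linear treadmill speed sampled at the frame rate."""
    p = protocol or ProtocolParams()
    n = int(round(p.t_total * p.frame_rate))
    t = np.arange(n) / p.frame_rate
    return SpeedTrace(time_s=t, speed_cm_s=_protocol_speed(t, p), position_cm=protocol_position(t, p))


# ---------------------------------------------------------------------------
# ROI mask scenes


@dataclass
class ROISceneParams:
    n_rois: int = 313
    field_px: tuple[int, int] = (512, 512)
    roi_radius_px: float = 5.0
    radius_jitter_px: float = 1.0
    shift_px: tuple[int, int] = (3, -2)
    perturb_radius_frac: float = 0.0   # per-ROI radius change in image B
    overlap_threshold: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.roi_radius_px <= self.radius_jitter_px:
            raise ValueError("roi_radius_px must exceed radius_jitter_px")


def _disc_mask(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def gen_roi_scene(
    params: ROISceneParams | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int], pd.DataFrame]:
    """Two label images related by a rigid translation, with truth pairs.

    Image A holds ``n_rois`` disjoint disc ROIs on a jittered grid; image B is
    the same set translated by ``shift_px`` (and optionally radius-perturbed)
    with freshly permuted labels.  The truth table lists, for every ROI, its
    labels in both images and the aligned-frame overlap ratio, and whether the
    pair should match at the overlap threshold.
    """
    p = params or ROISceneParams()
    rng = np.random.default_rng(p.seed)
    h, w = p.field_px
    dx, dy = p.shift_px
    margin = int(np.ceil(p.roi_radius_px * (1 + abs(p.perturb_radius_frac)) + p.radius_jitter_px)) + max(
        abs(dx), abs(dy)
    ) + 2
    n_side = int(np.ceil(np.sqrt(p.n_rois)))
    cell_h = (h - 2 * margin) / n_side
    cell_w = (w - 2 * margin) / n_side
    if min(cell_h, cell_w) < 2 * (p.roi_radius_px + p.radius_jitter_px) + 2:
        raise ValueError("ROIs do not fit in the field without overlap; reduce n_rois or radius")
    centers = []
    for idx in range(p.n_rois):
        gy, gx = divmod(idx, n_side)
        jit = rng.uniform(-1, 1, size=2) * (
            np.array([cell_h, cell_w]) / 2 - p.roi_radius_px - p.radius_jitter_px - 1
        )
        centers.append(
            (margin + (gy + 0.5) * cell_h + jit[0], margin + (gx + 0.5) * cell_w + jit[1])
        )
    radii = p.roi_radius_px + rng.uniform(-1, 1, size=p.n_rois) * p.radius_jitter_px

    image_a = np.zeros((h, w), dtype=np.uint16)
    image_b = np.zeros((h, w), dtype=np.uint16)
    perm = rng.permutation(p.n_rois) + 1
    masks_a, masks_b = [], []
    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        ma = _disc_mask((h, w), cy, cx, r)
        rb = r * (1 + p.perturb_radius_frac * rng.uniform(-1, 1))
        mb = _disc_mask((h, w), cy + dy, cx + dx, rb)
        if not mb.any() or mb[0, :].any() or mb[-1, :].any() or mb[:, 0].any() or mb[:, -1].any():
            raise ValueError(f"ROI {i + 1} leaves the field after the planted shift")
        image_a[ma] = i + 1
        image_b[mb] = perm[i]
        masks_a.append(ma)
        masks_b.append(mb)

    rows = []
    for i, (ma, mb) in enumerate(zip(masks_a, masks_b)):
        mb_aligned = np.zeros_like(mb)
        # undo the planted shift so both masks sit in frame A
        src = np.argwhere(mb)
        dst = src - np.array([dy, dx])
        mb_aligned[dst[:, 0], dst[:, 1]] = True
        inter = np.logical_and(ma, mb_aligned).sum()
        union = np.logical_or(ma, mb_aligned).sum()
        ratio = inter / union
        rows.append(
            {
                "label_a": i + 1,
                "label_b": int(perm[i]),
                "ratio": float(ratio),
                "should_match": bool(ratio >= p.overlap_threshold),
            }
        )
    truth = pd.DataFrame(rows)
    return image_a, image_b, (dx, dy), truth


# ---------------------------------------------------------------------------
# locomotion session blocks


@dataclass
class LocoGenParams:
    """Generator settings for one synthetic forced-locomotion session.

    The defaults are the study conditions of the drug-effect analysis: 313
    matched ROIs with per-ROI pre-drug locomotion fluorescence
    b ~ Normal(1.28, 0.60) dF/F_rest, a planted linear drug effect
    d = effect_slope*(b - baseline_mean) + Normal(0, effect_noise_sd), a
    shared decay A + B*exp(-j/C) over the 1-based recording index j, six
    pre-drug and eleven post-drug recordings, and a rigid translation of the
    post-drug field of view.
    """

    n_rois: int = 313
    n_pre: int = 6
    n_post: int = 11
    baseline_mean: float = 1.28
    baseline_sd: float = 0.60
    effect_slope: float = -0.65
    effect_noise_sd: float = 0.597
    decay_A: float = 0.1
    decay_B: float = 0.5
    decay_C: float = 4.0
    neuropil_scale: float = 0.7
    jitter_sd: float = 0.05
    shift_px: tuple[int, int] = (3, -2)
    seed: int = 0
    truncate_baseline: bool = False  # optionally truncate b at 0
    loco_window: tuple[float, float] = (10.0, 25.0)
    percentile: float = 75.0
    protocol: ProtocolParams = field(default_factory=ProtocolParams)

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be > 0")
        if self.n_pre < 2:
            raise ValueError("need >= 2 pre-drug recordings")
        if self.n_post < 4:
            raise ValueError("need >= 4 post-drug recordings (first three are excluded)")
        if not 0 <= self.neuropil_scale < 1:
            raise ValueError("neuropil_scale must be in [0, 1)")

    @property
    def population_r(self) -> float:
        """Analytic correlation between b and the planted change d."""
        num = self.effect_slope * self.baseline_sd
        denom = np.hypot(num, self.effect_noise_sd)
        return num / denom if denom > 0 else 0.0


def _decay(j: np.ndarray | float, a: float, b: float, c: float) -> np.ndarray | float:
    return a + b * np.exp(-np.asarray(j, dtype=float) / c)


def gen_locomotion_block(params: LocoGenParams | None = None) -> tuple[SessionBlock, GroundTruth]:
    """Synthesize one forced-locomotion session with planted ground truth.

    Per ROI i the designed locomotion fluorescence of recording j is
    ``b_i`` (+ ``d_i`` post drug) + decay(j); each recording's trace is built
    so that the 75th percentile of dF/F_rest over the motorized window equals
    that designed value exactly (jitter is re-centred on its own 75th
    percentile), resting segments sit at the resting fluorescence, and the
    observed soma trace is contaminated as
    soma_obs = soma_true + neuropil_scale * neuropil_obs, so the standard
    0.7-scaled subtraction inverts the generative model when
    neuropil_scale = 0.7.
    """
    p = params or LocoGenParams()
    rng = np.random.default_rng(p.seed)

    b = rng.normal(p.baseline_mean, p.baseline_sd, size=p.n_rois)
    if p.truncate_baseline:
        while (b <= 0).any():
            b[b <= 0] = rng.normal(p.baseline_mean, p.baseline_sd, size=int((b <= 0).sum()))
    eps = rng.normal(0.0, p.effect_noise_sd, size=p.n_rois) if p.effect_noise_sd > 0 else np.zeros(p.n_rois)
    d = p.effect_slope * (b - p.baseline_mean) + eps

    n_rec = p.n_pre + p.n_post
    j_index = np.arange(1, n_rec + 1)
    decay = _decay(j_index, p.decay_A, p.decay_B, p.decay_C)
    designed = np.where(j_index[:, None] <= p.n_pre, b[None, :], (b + d)[None, :]) + decay[:, None]

    scene = ROISceneParams(n_rois=p.n_rois, shift_px=p.shift_px, seed=int(rng.integers(2**31)))
    image_a, image_b, shift, pairs = gen_roi_scene(scene)
    labels_a = pairs["label_a"].to_numpy()
    labels_b = pairs["label_b"].to_numpy()

    speed = gen_speed_trace(p.protocol)
    n_frames = len(speed.time_s)
    rate = p.protocol.frame_rate
    win = slice(int(np.floor(p.loco_window[0] * rate)), int(np.floor(p.loco_window[1] * rate)))
    ramp_up = slice(int(np.floor(p.protocol.t_accel_start * rate)), win.start)
    ramp_down = slice(win.stop, int(np.floor(p.protocol.t_stop * rate)))
    up = np.linspace(0, 1, ramp_up.stop - ramp_up.start, endpoint=False)
    down = np.linspace(1, 0, ramp_down.stop - ramp_down.start, endpoint=False)

    f_rest = rng.uniform(80.0, 120.0, size=p.n_rois)
    np_offset = rng.uniform(40.0, 60.0, size=p.n_rois)
    np_amp = rng.uniform(5.0, 15.0, size=p.n_rois)
    profile = speed.speed_cm_s / p.protocol.v_max
    encoder = speed.to_frame()[["time_s", "position_cm"]]

    recordings = []
    for j in j_index:
        dff = np.zeros((n_frames, p.n_rois))
        level = designed[j - 1]
        window_vals = level[None, :] + rng.normal(0.0, p.jitter_sd, size=(win.stop - win.start, p.n_rois))
        if p.jitter_sd > 0:
            q = np.percentile(window_vals, p.percentile, axis=0)
            window_vals += level - q
        dff[win] = window_vals
        dff[ramp_up] = up[:, None] * level[None, :]
        dff[ramp_down] = down[:, None] * level[None, :]
        soma_true = f_rest[None, :] * (1.0 + dff)
        neuropil = np_offset[None, :] + np_amp[None, :] * profile[:, None]
        soma_obs = soma_true + p.neuropil_scale * neuropil
        condition = PRE if j <= p.n_pre else POST
        cols = labels_a if condition == PRE else labels_b
        recordings.append(
            Recording(
                index=int(j),
                condition=condition,
                soma=pd.DataFrame(soma_obs, columns=cols),
                neuropil=pd.DataFrame(neuropil, columns=cols),
                encoder=encoder.copy(),
                frame_rate=rate,
            )
        )

    block = SessionBlock(
        recordings=recordings,
        masks={PRE: image_a, POST: image_b},
        frame_rate=rate,
    )
    truth = GroundTruth(
        baseline=pd.Series(b, index=labels_a),
        change=pd.Series(d, index=labels_a),
        designed_L=pd.DataFrame(designed, index=j_index, columns=labels_a),
        decay=(p.decay_A, p.decay_B, p.decay_C),
        shift_px=shift,
        label_map=pd.Series(labels_b, index=labels_a),
        f_rest=pd.Series(f_rest, index=labels_a),
        population_r=float(p.population_r),
    )
    return block, truth


# ---------------------------------------------------------------------------
# beam-stimulation datasets


@dataclass
class StimGenParams:
    """Per-cell peak dF/Fo responses under control and a drug condition.

    The control response of cell i is a_i * (1 + m): a drug-insensitive
    component a_i (Gamma with the given mean/CV) plus a drug-sensitive
    component m * a_i that the drug removes, so the designed mean
    drug/control ratio is 1 / (1 + m).
    """

    n_cells: int = 21
    control_peak_mean: float = 1.39   # dF/Fo, i.e. 139%
    control_peak_cv: float = 0.5
    drug_component_multiplier: float = 1.1277
    peak_noise_sd: float = 0.0
    drug_label: str = "drug"
    frequency_hz: float = 100.0
    duration_s: float = 1.0
    compartment: str = "soma"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drug_component_multiplier < 0:
            raise ValueError("drug_component_multiplier must be >= 0")
        if self.control_peak_mean <= 0:
            raise ValueError("control_peak_mean must be > 0")


def gen_stim_dataset(params: StimGenParams | None = None) -> tuple[pd.DataFrame, dict]:
    """Long-format stimulation table (cell, condition, ..., peak_dff) + truth."""
    p = params or StimGenParams()
    rng = np.random.default_rng(p.seed)
    m = p.drug_component_multiplier
    mean_a = p.control_peak_mean / (1.0 + m)
    if p.control_peak_cv > 0:
        shape = 1.0 / p.control_peak_cv**2
        a = rng.gamma(shape, mean_a / shape, size=p.n_cells)
    else:
        a = np.full(p.n_cells, mean_a)
    drug = a.copy()
    if p.peak_noise_sd > 0:
        drug = np.clip(drug + rng.normal(0.0, p.peak_noise_sd, size=p.n_cells), 0.0, None)
    rows = []
    for cell in range(p.n_cells):
        for cond, peak in (("control", a[cell] * (1.0 + m)), (p.drug_label, drug[cell])):
            rows.append(
                {
                    "cell": cell + 1,
                    "condition": cond,
                    "frequency_hz": p.frequency_hz,
                    "duration_s": p.duration_s,
                    "compartment": p.compartment,
                    "peak_dff": peak,
                }
            )
    truth = {"mean_ratio": 1.0 / (1.0 + m), "insensitive_component": a}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# immunogold particle fields


@dataclass
class EMGenParams:
    """Gold-particle field around a postsynaptic-density outline.

    ``radial_profile`` is either "uniform" (homogeneous points over the
    square field) or a sequence of per-band densities (particles/um^2) for
    the 50 nm annuli [0,50), ..., [200,250) outside the PSD edge.
    """

    psd_vertices: np.ndarray | None = None     # (n, 2) nm; default: 100 nm-radius circle
    particle_count: int = 200
    radial_profile: str | tuple[float, ...] = "uniform"
    band_width_nm: float = 50.0
    n_bands: int = 5
    field_extent_nm: float = 800.0             # square half-width around the centroid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particle_count < 0:
            raise ValueError("particle_count must be >= 0")
        if not isinstance(self.radial_profile, str) and len(self.radial_profile) != self.n_bands:
            raise ValueError(f"radial_profile must give one density per band ({self.n_bands})")

    def polygon(self) -> Polygon:
        if self.psd_vertices is None:
            theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
            verts = np.c_[100.0 * np.cos(theta), 100.0 * np.sin(theta)]
        else:
            verts = np.asarray(self.psd_vertices, dtype=float)
        poly = Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            raise ValueError("psd polygon must be simple and non-degenerate")
        return poly


def gen_em_sample(params: EMGenParams | None = None) -> tuple[dict, pd.DataFrame]:
    """Particle coordinates around a PSD polygon, plus the designed profile.

    Returns (sample, truth) where sample = {"psd_polygon": Polygon,
    "particles": (n, 2) nm array} and truth tabulates the per-band expected
    density the particles were drawn from.
    """
    p = params or EMGenParams()
    rng = np.random.default_rng(p.seed)
    poly = p.polygon()
    cx, cy = poly.centroid.x, poly.centroid.y
    lo_x, hi_x = cx - p.field_extent_nm, cx + p.field_extent_nm
    lo_y, hi_y = cy - p.field_extent_nm, cy + p.field_extent_nm

    edges = np.arange(p.n_bands + 1) * p.band_width_nm
    if isinstance(p.radial_profile, str):
        if p.radial_profile != "uniform":
            raise ValueError(f"unknown radial_profile {p.radial_profile!r}")
        pts = np.c_[
            rng.uniform(lo_x, hi_x, size=p.particle_count),
            rng.uniform(lo_y, hi_y, size=p.particle_count),
        ]
        field_area_um2 = (2 * p.field_extent_nm / 1000.0) ** 2
        truth = pd.DataFrame(
            {
                "band_nm": [f"[{int(a)},{int(b)})" for a, b in zip(edges[:-1], edges[1:])],
                "expected_density_per_um2": p.particle_count / field_area_um2,
            }
        )
        return {"psd_polygon": poly, "particles": pts}, truth

    densities = np.asarray(p.radial_profile, dtype=float)
    rings = [poly.buffer(e, quad_segs=64) for e in edges]
    band_areas_um2 = np.array(
        [(rings[i + 1].area - rings[i].area) / 1e6 for i in range(p.n_bands)]
    )
    weights = densities * band_areas_um2
    if weights.sum() <= 0:
        counts = np.zeros(p.n_bands, dtype=int)
    else:
        counts = rng.multinomial(p.particle_count, weights / weights.sum())
    boundary = poly.exterior
    pts = []
    for i, n_band in enumerate(counts):
        lo_d, hi_d = edges[i], edges[i + 1]
        outer = rings[i + 1]
        bx_lo, by_lo, bx_hi, by_hi = outer.bounds
        placed = 0
        while placed < n_band:
            cand = np.c_[
                rng.uniform(bx_lo, bx_hi, size=4 * (n_band - placed) + 8),
                rng.uniform(by_lo, by_hi, size=4 * (n_band - placed) + 8),
            ]
            for x, y in cand:
                pt = Point(x, y)
                if poly.covers(pt):
                    continue
                dist = boundary.distance(pt)
                if lo_d <= dist < hi_d:
                    pts.append((x, y))
                    placed += 1
                    if placed == n_band:
                        break
    pts = np.array(pts, dtype=float).reshape(-1, 2)
    truth = pd.DataFrame(
        {
            "band_nm": [f"[{int(a)},{int(b)})" for a, b in zip(edges[:-1], edges[1:])],
            "expected_density_per_um2": densities,
        }
    )
    return {"psd_polygon": poly, "particles": pts}, truth
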