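"""Awake forced-locomotion drug-effect pipeline.

The quantity of interest per ROI and recording is the *locomotion
fluorescence* L: the 75th percentile of dF/F_rest during the maximal-speed
motorized window [10, 25) s.  Locomotion fluorescence decays with the
recording number j (shared across ROIs, attributed to the repetition count
rather than wall-clock time), so a single exponential f_j = A + B*exp(-j/C)
is fitted per ROI to the pre-drug points and subtracted from *all*
recordings, which re-centres the pre-drug values on zero and exposes any
drug-induced change beyond the general decay.  Each ROI is then classified
(increase / decrease / none at alpha = 0.01) and the per-ROI change is
regressed on the pre-drug baseline.

``LocomotionPharmacology`` orchestrates the full pipeline from a
``SessionBlock``: field-of-view alignment, ROI matching, rest normalization,
detrending, classification and regression; ``fit()`` returns a results
object carrying every intermediate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .blocks import POST, PRE, SessionBlock, window_to_frames
from .matching import MatchParams, estimate_translation, match_rois
from .traces import DEFAULT_NEUROPIL_SCALE, normalize_to_rest

DEFAULT_LOCO_WINDOW = (10.0, 25.0)
DEFAULT_PERCENTILE = 75.0


# ---------------------------------------------------------------------------
# primitives


def locomotion_fluorescence(
    trace: np.ndarray | pd.Series | pd.DataFrame,
    window: tuple[float, float] = DEFAULT_LOCO_WINDOW,
    q: float = DEFAULT_PERCENTILE,
    frame_rate: float = 30.0,
):
    """q-th percentile (linear interpolation between order statistics, index
    (n-1)*q/100) of the trace within the half-open window."""
    if not 0 < q < 100:
        raise ValueError("percentile q must be in (0, 100)")
    values = np.asarray(trace, dtype=float)
    sl = window_to_frames(window, frame_rate, values.shape[0])
    if sl.stop - sl.start < 2:
        raise ValueError("window maps to fewer than 2 frames")
    result = np.percentile(values[sl], q, axis=0)
    if isinstance(trace, pd.DataFrame):
        return pd.Series(result, index=trace.columns)
    return float(result) if np.ndim(result) == 0 else result


@dataclass
class DecayFit:
    """Single-exponential decay f_j = A + B*exp(-j/C) over recording index j."""

    A: float
    B: float
    C: float
    method: str = "exponential"     # or "linear" (fallback), "constant"
    flags: tuple[str, ...] = ()

    def predict(self, j: np.ndarray | float) -> np.ndarray | float:
        j = np.asarray(j, dtype=float)
        if self.method == "linear":
            out = self.A + self.B * j
        else:
            out = self.A + self.B * np.exp(-j / self.C)
        return out if out.shape else float(out)


def fit_decay(values: np.ndarray, j: np.ndarray | None = None) -> DecayFit:
    """Least-squares fit of A + B*exp(-j/C) to pre-drug locomotion values.

    ``j`` defaults to 1, 2, ... in recording order.  With fewer than 3 points
    or on non-convergence the fit falls back to a straight line in j and the
    result is flagged; exactly constant data is returned directly (B = 0, C
    unidentifiable).
    """
    y = np.asarray(values, dtype=float)
    if j is None:
        j = np.arange(1, len(y) + 1, dtype=float)
    j = np.asarray(j, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 points to fit a decay")
    if np.ptp(y) == 0:
        return DecayFit(A=float(y[0]), B=0.0, C=1.0, method="constant", flags=("degenerate_constant",))
    if len(y) < 3:
        slope, intercept = np.polyfit(j, y, 1)
        return DecayFit(A=float(intercept), B=float(slope), C=np.nan, method="linear", flags=("too_few_points",))
    try:
        span = max(np.ptp(y), 1e-12)
        p0 = (float(y[-1]), float(y[0] - y[-1]) or span, max(float(j[-1]) / 2.0, 1.0))
        popt, _ = optimize.curve_fit(
            lambda jj, a, b, c: a + b * np.exp(-jj / c),
            j,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e6]),
            maxfev=10000,
        )
        return DecayFit(A=float(popt[0]), B=float(popt[1]), C=float(popt[2]))
    except (RuntimeError, optimize.OptimizeWarning):
        slope, intercept = np.polyfit(j, y, 1)
        return DecayFit(A=float(intercept), B=float(slope), C=np.nan, method="linear", flags=("nonconvergent",))


def detrend_block(values: np.ndarray, j: np.ndarray, fit: DecayFit) -> np.ndarray:
    """L' = L - f_j for every recording (pre and post drug alike)."""
    return np.asarray(values, dtype=float) - fit.predict(np.asarray(j, dtype=float))


@dataclass
class DrugTestParams:
    exclude_first: int = 3      # wash-in: drop the first post-drug recordings
    alpha: float = 0.01
    test_kind: str = "welch"    # "welch" | "pooled" | "paired"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.test_kind not in ("welch", "pooled", "paired"):
            raise ValueError(f"unknown test_kind {self.test_kind!r}")


def classify_drug_effect(
    pre_values: np.ndarray,
    post_values: np.ndarray,
    params: DrugTestParams | None = None,
) -> tuple[float, str, tuple[str, ...]]:
    """Two-sided test of a drug-induced mean change in locomotion fluorescence.

    The first ``exclude_first`` post-drug values are dropped (drug wash-in).
    Default is a Welch two-sample t-test (pre/post recording counts differ, so
    observation-level pairing is undefined); a pooled-variance and a
    truncated paired variant are available.  Returns (p, label, flags) with
    label in {"increase", "decrease", "none"}.
    """
    params = params or DrugTestParams()
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)[params.exclude_first :]
    if len(pre) < 2 or len(post) < 2:
        return float("nan"), "none", ("too_few_recordings",)
    flags: tuple[str, ...] = ()
    if np.ptp(pre) == 0 and np.ptp(post) == 0:
        p = 1.0 if pre[0] == post[0] else 0.0
        flags = ("zero_variance",)
    elif params.test_kind == "paired":
        n = min(len(pre), len(post))
        diffs = post[:n] - pre[:n]
        if np.ptp(diffs) == 0 and diffs[0] == 0:
            p, flags = 1.0, ("zero_variance",)
        else:
            p = float(stats.ttest_rel(post[:n], pre[:n]).pvalue)
        flags = flags + ("paired_truncated",) if len(pre) != len(post) else flags
    else:
        import warnings

        with warnings.catch_warnings():
            # near-identical samples (e.g. exactly detrended values) trip a
            # harmless precision-loss warning inside the moment calculation
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(post, pre, equal_var=params.test_kind == "pooled").pvalue)
    if np.isnan(p):
        p, flags = 1.0, flags + ("undefined_statistic",)
    if p < params.alpha:
        label = "increase" if post.mean() > pre.mean() else "decrease"
    else:
        label = "none"
    return p, label, flags


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n: int
    stderr: float

    def summary(self) -> str:
        return (
            f"change = {self.slope:+.3f} * baseline {self.intercept:+.3f}; "
            f"r = {self.r:.3f}, R^2 = {self.r2:.3f}, p = {self.p:.3g}, n = {self.n}"
        )


def regress_change_vs_baseline(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of per-ROI drug-induced change on pre-drug locomotion fluorescence.

    x is the raw (pre-detrend) pre-drug mean per ROI, y the mean detrended
    post-drug value; r is the Pearson correlation with its two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in baseline: regression undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=len(x),
        stderr=float(res.stderr),
    )


def artifact_ratio(metric_820: pd.Series, metric_910: pd.Series) -> pd.DataFrame:
    """Per-ROI 820 nm / 910 nm ratio of a locomotion-window statistic.

    At 820 nm GCaMP fluorescence is calcium-insensitive, so the ratio bounds
    the movement-artifact share of the locomotion signal.  Input series must
    share matched ROI labels (>= 30% overlap rule applied upstream).
    """
    joined = pd.DataFrame({"m820": metric_820, "m910": metric_910}).dropna()
    ratio = np.where(joined["m910"] != 0, joined["m820"] / joined["m910"], np.nan)
    out = joined.assign(ratio=ratio, flag=np.where(joined["m910"] == 0, "zero_910_metric", ""))
    return out


# ---------------------------------------------------------------------------
# model / results


@dataclass
class LocomotionPharmacologyResults:
    """Fitted tables of the locomotion drug-effect pipeline."""

    shift_px: tuple[int, int]
    match_table: pd.DataFrame
    locomotion_table: pd.DataFrame   # roi, recording j, condition, L, L_detrended
    decay_table: pd.DataFrame        # per ROI: A, B, C, method
    effect_table: pd.DataFrame       # per ROI: baseline, change, p, label (+ raw-value test)
    regression: RegressionResult
    f_rest: dict[str, pd.Series]
    params: "LocomotionPharmacology"

    @property
    def class_counts(self) -> pd.Series:
        return self.effect_table["label"].value_counts().reindex(
            ["increase", "decrease", "none"], fill_value=0
        )

    def summary(self) -> str:
        c = self.class_counts
        lines = [
            "Locomotion drug-effect analysis",
            "================================",
            f"matched ROIs: {len(self.effect_table)}   "
            f"field shift: dx={self.shift_px[0]} px, dy={self.shift_px[1]} px",
            f"classification (alpha={self.params.test_params.alpha}): "
            f"{c['increase']} increase / {c['decrease']} decrease / {c['none']} none",
            "change vs baseline: " + self.regression.summary(),
        ]
        return "\n".join(lines)

    def plot_change_vs_baseline(self, ax=None):
        """Scatter of drug-induced change vs pre-drug baseline, colored by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        colors = {"increase": "tab:red", "decrease": "tab:blue", "none": "0.6"}
        for label, sub in self.effect_table.groupby("label"):
            ax.scatter(sub["baseline"], sub["change"], s=12, c=colors.get(label, "k"), label=label)
        xs = np.linspace(self.effect_table["baseline"].min(), self.effect_table["baseline"].max(), 50)
        ax.plot(xs, self.regression.intercept + self.regression.slope * xs, "k--", lw=1)
        ax.set_xlabel("pre-drug locomotion fluorescence (dF/F_rest)")
        ax.set_ylabel("drug-induced change (dF/F_rest)")
        ax.legend(frameon=False, fontsize=8)
        ax.set_title(f"r = {self.regression.r:.3f}, R$^2$ = {self.regression.r2:.2f}")
        return ax


@dataclass
class LocomotionPharmacology:
    """Drug-effect model over one forced-locomotion session block."""

    block: SessionBlock
    match_params: MatchParams = field(default_factory=MatchParams)
    test_params: DrugTestParams = field(default_factory=DrugTestParams)
    loco_window: tuple[float, float] = DEFAULT_LOCO_WINDOW
    percentile: float = DEFAULT_PERCENTILE
    baseline_window: tuple[float, float] = (0.0, 5.0)
    neuropil_r: float = DEFAULT_NEUROPIL_SCALE

    @classmethod
    def from_block(cls, block: SessionBlock, **kwargs) -> "LocomotionPharmacology":
        return cls(block=block, **kwargs)

    def fit(self) -> LocomotionPharmacologyResults:
        block = self.block
        mask_pre, mask_post = block.masks[PRE], block.masks[POST]
        shift = estimate_translation(
            (mask_pre > 0).astype(float), (mask_post > 0).astype(float), self.match_params.max_shift
        )
        matches = match_rois(mask_pre, mask_post, shift, self.match_params)
        pairs = matches[matches["matched"]]

        dff = {
            cond: normalize_to_rest(block, cond, window=self.baseline_window, r=self.neuropil_r)
            for cond in (PRE, POST)
        }
        l_by_rec = {}
        for cond in (PRE, POST):
            for j, tr in dff[cond].traces.items():
                l_by_rec[j] = locomotion_fluorescence(
                    tr, self.loco_window, self.percentile, dff[cond].frame_rate
                )
        pre_j = sorted(r.index for r in block.pre)
        post_j = sorted(r.index for r in block.post)

        loco_rows, decay_rows, effect_rows = [], [], []
        for _, pair in pairs.iterrows():
            la, lb = int(pair["label_a"]), int(pair["label_b"])
            pre_l = np.array([l_by_rec[j][la] for j in pre_j])
            post_l = np.array([l_by_rec[j][lb] for j in post_j])
            fit = fit_decay(pre_l, np.asarray(pre_j, dtype=float))
            pre_det = detrend_block(pre_l, np.asarray(pre_j, float), fit)
            post_det = detrend_block(post_l, np.asarray(post_j, float), fit)
            for j, L, Ld in zip(pre_j, pre_l, pre_det):
                loco_rows.append(dict(roi=la, roi_post=lb, recording=j, condition=PRE, L=L, L_detrended=Ld))
            for j, L, Ld in zip(post_j, post_l, post_det):
                loco_rows.append(dict(roi=la, roi_post=lb, recording=j, condition=POST, L=L, L_detrended=Ld))
            decay_rows.append(dict(roi=la, A=fit.A, B=fit.B, C=fit.C, method=fit.method, flags=";".join(fit.flags)))
            p, label, flags = classify_drug_effect(pre_det, post_det, self.test_params)
            p_raw, label_raw, _ = classify_drug_effect(pre_l, post_l, self.test_params)
            excl = self.test_params.exclude_first
            effect_rows.append(
                dict(
                    roi=la,
                    roi_post=lb,
                    baseline=float(pre_l.mean()),
                    change=float(post_det[excl:].mean()),
                    p=p,
                    label=label,
                    p_raw=p_raw,
                    label_raw=label_raw,
                    flags=";".join(flags),
                )
            )

        effect_table = pd.DataFrame(effect_rows)
        regression = regress_change_vs_baseline(
            effect_table["baseline"].to_numpy(), effect_table["change"].to_numpy()
        )
        return LocomotionPharmacologyResults(
            shift_px=shift,
            match_table=matches,
            locomotion_table=pd.DataFrame(loco_rows),
            decay_table=pd.DataFrame(decay_rows),
            effect_table=effect_table,
            regression=regression,
            f_rest={cond: dff[cond].f_rest for cond in dff},
            params=self,
        )
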