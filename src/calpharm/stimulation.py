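"""Beam-stimulation pharmacology: peak dF/Fo ratios and Wilcoxon statistics.

Parallel-fiber train stimulation evokes somatic calcium transients whose peak
dF/Fo is the response measure.  Drug effects are summarized per protocol bin
(train duration x frequency x compartment) as the per-cell ratio of the drug
peak to the control peak, mean +/- sem, with a two-tailed Wilcoxon
signed-rank test of the paired peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import window_to_frames

DEFAULT_GROUP_BY = ("duration_s", "frequency_hz", "compartment")


def peak_response(
    trace: np.ndarray,
    response_window: tuple[float, float],
    frame_rate: float = 30.0,
    smooth: int = 0,
) -> float:
    """Maximum dF/Fo within the response window (stimulus onset at its start).

    The peak is taken on the raw trace; ``smooth`` > 1 applies an optional
    centred moving average of that many frames first (off by default).
    """
    f = np.asarray(trace, dtype=float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        f = np.convolve(f, kernel, mode="same")
    sl = window_to_frames(response_window, frame_rate, len(f))
    return float(f[sl].max())


def wilcoxon_signed_p(differences: np.ndarray, exact_max_n: int = 25) -> tuple[float, tuple[str, ...]]:
    """Two-tailed Wilcoxon signed-rank p for paired differences.

    Zero differences are dropped before ranking (standard signed-rank
    convention; logged in the flags).  For n <= ``exact_max_n`` the exact
    null distribution of the positive-rank sum is computed by dynamic
    programming over midranks (valid under ties); larger samples use the
    normal approximation with tie correction and continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    flags: tuple[str, ...] = ()
    n_zero = int((d == 0).sum())
    if n_zero:
        flags += (f"dropped_{n_zero}_zero_differences",)
        d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0, flags + ("all_differences_zero",)
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # doubled midranks are integers; enumerate the sign-flip distribution
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: total + 1 - r]
        counts /= counts.sum()
        w2 = int(round(2 * w_pos))
        p_le = counts[: w2 + 1].sum()
        p_ge = counts[w2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        if var <= 0:
            return 1.0, flags + ("zero_variance",)
        z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        flags += ("normal_approximation",)
    return p, flags


@dataclass
class RatioSummaryRow:
    group: tuple
    mean_ratio: float
    sem: float
    n: int
    p_wilcoxon: float
    flags: tuple[str, ...] = ()


def drug_ratio_summary(
    table: pd.DataFrame,
    pairing: tuple[str, str],
    group_by: tuple[str, ...] = DEFAULT_GROUP_BY,
) -> pd.DataFrame:
    """Per-protocol-bin drug/control peak ratios.

    ``pairing`` is (drug_condition, control_condition).  Within each group the
    per-cell ratio peak_drug/peak_control is averaged (mean +/- sem) and the
    paired peaks are compared with the two-tailed Wilcoxon signed-rank test.
    Cells missing either condition are dropped with a warning; zero control
    peaks are flagged and excluded from the ratio mean.
    """
    drug_cond, control_cond = pairing
    required = {"cell", "condition", "peak_dff", *group_by}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"stimulation table missing columns {sorted(missing)}")
    rows = []
    for key, sub in table.groupby(list(group_by)):
        wide = sub.pivot_table(index="cell", columns="condition", values="peak_dff", aggfunc="first")
        if drug_cond not in wide or control_cond not in wide:
            continue
        both = wide[[drug_cond, control_cond]]
        n_dropped = int(both.isna().any(axis=1).sum())
        if n_dropped:
            warnings.warn(
                f"group {key}: dropped {n_dropped} cells missing a condition", stacklevel=2
            )
        both = both.dropna()
        flags: tuple[str, ...] = ()
        zero_ctrl = both[control_cond] == 0
        if zero_ctrl.any():
            flags += (f"{int(zero_ctrl.sum())}_zero_control_peaks",)
        valid = both[~zero_ctrl]
        ratios = valid[drug_cond] / valid[control_cond]
        diffs = (both[drug_cond] - both[control_cond]).to_numpy()
        p, wflags = wilcoxon_signed_p(diffs)
        n = len(ratios)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            {
                **dict(zip(group_by, key)),
                "mean_ratio": float(ratios.mean()) if n else np.nan,
                "sem": float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
                "p_wilcoxon": p,
                "flags": ";".join(flags + wflags),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StimulationPharmacologyResults:
    ratio_table: pd.DataFrame
    cell_table: pd.DataFrame
    pairing: tuple[str, str]

    def summary(self) -> str:
        lines = [
            f"Stimulation pharmacology: {self.pairing[0]} / {self.pairing[1]} peak dF/Fo ratios",
            "=" * 60,
        ]
        for _, row in self.ratio_table.iterrows():
            group = ", ".join(
                f"{k}={row[k]}" for k in self.ratio_table.columns
                if k not in ("mean_ratio", "sem", "n", "p_wilcoxon", "flags")
            )
            lines.append(
                f"{group}: ratio = {row['mean_ratio']:.3f} +/- {row['sem']:.3f} "
                f"(n={row['n']}, Wilcoxon p={row['p_wilcoxon']:.3g})"
            )
        return "\n".join(lines)


@dataclass
class StimulationPharmacology:
    """Drug/control ratio model over a per-cell peak-response table."""

    table: pd.DataFrame
    drug_condition: str
    control_condition: str = "control"
    group_by: tuple[str, ...] = field(default=DEFAULT_GROUP_BY)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, drug_condition: str, **kwargs) -> "StimulationPharmacology":
        return cls(table=table, drug_condition=drug_condition, **kwargs)

    def fit(self) -> StimulationPharmacologyResults:
        pairing = (self.drug_condition, self.control_condition)
        ratio_table = drug_ratio_summary(self.table, pairing, self.group_by)
        wide = self.table.pivot_table(
            index=["cell", *self.group_by], columns="condition", values="peak_dff", aggfunc="first"
        ).reset_index()
        if self.drug_condition in wide and self.control_condition in wide:
            with np.errstate(divide="ignore", invalid="ignore"):
                wide["ratio"] = wide[self.drug_condition] / wide[self.control_condition]
        return StimulationPharmacologyResults(
            ratio_table=ratio_table, cell_table=wide, pairing=pairing
        )
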