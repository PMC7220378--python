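"""Cross-session ROI registration and matching.

Pre- and post-drug fields of view are related by a small rigid translation
(the animal's headpost returns the brain to nearly the same position).  The
translation is estimated by integer-pixel zero-mean cross-correlation, and
ROIs are declared the same soma when their masks, after shifting, overlap by
at least 30% of the combined area: 0.3 <= A_overlap / A_union.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

DEFAULT_OVERLAP_THRESHOLD = 0.3


@dataclass
class MatchParams:
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD
    max_shift: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must be in (0, 1]")


def shift_image(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate by (dx, dy) = (columns right, rows down), zero-filling."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys, yd = (0, h - dy) if dy >= 0 else (-dy, h)
    xs, xd = (0, w - dx) if dx >= 0 else (-dx, w)
    out[ys + dy : yd + dy, xs + dx : xd + dx] = img[ys:yd, xs:xd]
    return out


def estimate_translation(
    image_a: np.ndarray, image_b: np.ndarray, max_shift: int = 20
) -> tuple[int, int]:
    """Integer (dx, dy) aligning image_b onto image_a.

    Maximizes the zero-mean cross-correlation over the (2*max_shift+1)^2
    search window; ties broken by smallest |dx|+|dy|, then lexicographically.
    The returned shift is the translation to apply to image_b.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have equal dimensions")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("flat image: translation cannot be estimated")
    a0 = a - a.mean()
    b0 = b - b.mean()
    # full linear cross-correlation: entry (dy+h-1, dx+w-1) is the zero-filled
    # correlation score of shift (dx, dy)
    from scipy.signal import correlate

    h, w = a.shape
    full = correlate(a0, b0, mode="full", method="fft")
    dys = np.arange(-max_shift, max_shift + 1)
    dxs = np.arange(-max_shift, max_shift + 1)
    window = full[np.ix_(dys + h - 1, dxs + w - 1)]
    top = window.max()
    tol = 1e-9 * max(abs(top), 1.0)
    iy, ix = np.nonzero(window >= top - tol)
    cands = sorted(
        (abs(int(dxs[j])) + abs(int(dys[i])), int(dxs[j]), int(dys[i]))
        for i, j in zip(iy, ix)
    )
    _, dx, dy = cands[0]
    return dx, dy


def overlap_ratio(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """A_overlap / A_union for two boolean masks in a common frame."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both masks empty: overlap ratio defined as 0", stacklevel=2)
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def match_rois(
    set_a: np.ndarray,
    set_b: np.ndarray,
    shift: tuple[int, int] = (0, 0),
    params: MatchParams | None = None,
) -> pd.DataFrame:
    """One-to-one ROI pairing between two label images.

    ``set_b`` is shifted by ``shift`` before comparison.  Candidate pairs with
    overlap ratio >= threshold (inclusive: "at least 30%") are accepted
    greedily in descending ratio, ratio ties broken by the smaller label pair,
    so the pairing is deterministic and order-independent.  Returns a table
    with one row per candidate label on either side: columns label_a, label_b,
    ratio, matched (unmatched labels appear with NaN partner).
    """
    params = params or MatchParams()
    a = np.asarray(set_a)
    b = shift_image(np.asarray(set_b), *shift)
    labels_a = np.unique(a[a > 0])
    labels_b = np.unique(b[b > 0])
    # contingency counts between the two label images give every pairwise
    # intersection in one pass; ratio = |a∩b| / (|a| + |b| - |a∩b|)
    area_a = np.bincount(a.ravel())
    area_b = np.bincount(b.ravel())
    both = (a > 0) & (b > 0)
    pair_ids = a[both].astype(np.int64) * (len(area_b)) + b[both].astype(np.int64)
    candidates = []
    for pid, inter in zip(*np.unique(pair_ids, return_counts=True)):
        la, lb = int(pid // len(area_b)), int(pid % len(area_b))
        union = area_a[la] + area_b[lb] - inter
        ratio = float(inter / union)
        if ratio >= params.overlap_threshold:
            candidates.append((ratio, la, lb))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for ratio, la, lb in candidates:
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        rows.append({"label_a": la, "label_b": lb, "ratio": ratio, "matched": True})
    for la in labels_a:
        if int(la) not in used_a:
            rows.append({"label_a": int(la), "label_b": np.nan, "ratio": np.nan, "matched": False})
    for lb in labels_b:
        if int(lb) not in used_b:
            rows.append({"label_a": np.nan, "label_b": int(lb), "ratio": np.nan, "matched": False})
    df = pd.DataFrame(rows, columns=["label_a", "label_b", "ratio", "matched"])
    return df.sort_values(
        ["matched", "label_a", "label_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
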