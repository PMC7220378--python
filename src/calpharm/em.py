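"""Perisynaptic immunogold annulus-density profiling.

On SDS-digested freeze-fracture replicas the postsynaptic density (PSD) is
demarcated as a polygon and each immunogold particle is a point (nm).  The
analysis measures, for every particle, its Euclidean distance from the PSD
edge, then bins particles into concentric 50 nm-wide annuli (distance lines
at 50, 100, 150, 200, 250 nm) and divides by the annulus area to obtain a
radial density profile in particles/um^2.  Particles inside the PSD are
excluded from the bands and reported separately, as are particles beyond the
last line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

BAND_WIDTH_NM = 50.0
N_BANDS = 5
_QUAD_SEGS = 64  # buffer circle-approximation tolerance well below 1 nm


@dataclass
class PSDSample:
    """One PSD outline with its surrounding gold-particle coordinates (nm)."""

    psd_polygon: Polygon
    particles: np.ndarray                      # (n, 2)
    analysis_region: Polygon | None = None     # optional membrane-face clip

    def __post_init__(self) -> None:
        if isinstance(self.psd_polygon, (list, tuple, np.ndarray)):
            self.psd_polygon = Polygon(np.asarray(self.psd_polygon, dtype=float))
        if not self.psd_polygon.is_valid or len(self.psd_polygon.exterior.coords) < 4:
            raise ValueError("PSD polygon must be simple with >= 3 vertices")
        self.particles = np.asarray(self.particles, dtype=float).reshape(-1, 2)


def edge_distance(point: tuple[float, float], psd_polygon: Polygon) -> tuple[float, bool]:
    """(distance from the PSD edge in nm, inside flag).

    Exterior points get their Euclidean distance to the polygon boundary;
    points inside or on the boundary get distance 0 and are flagged interior.
    """
    poly = psd_polygon if isinstance(psd_polygon, Polygon) else Polygon(psd_polygon)
    if poly.area == 0 or not poly.is_valid:
        raise ValueError("degenerate PSD polygon")
    pt = Point(point)
    if poly.covers(pt):
        return 0.0, True
    return float(poly.exterior.distance(pt)), False


def particle_distances(sample: PSDSample) -> pd.DataFrame:
    """Per-particle edge distance and interior flag."""
    rows = []
    for x, y in sample.particles:
        dist, inside = edge_distance((x, y), sample.psd_polygon)
        rows.append({"x_nm": x, "y_nm": y, "distance_nm": dist, "inside_psd": inside})
    out = pd.DataFrame(rows, columns=["x_nm", "y_nm", "distance_nm", "inside_psd"])
    return out.astype({"distance_nm": float, "inside_psd": bool})


@dataclass
class AnnulusProfile:
    """Per-band particle counts, areas and densities around one or more PSDs."""

    table: pd.DataFrame           # band_lo_nm, band_hi_nm, count, area_nm2, density_per_um2
    inside_count: int
    beyond_count: int
    total: int
    flags: tuple[str, ...] = ()

    @property
    def densities(self) -> np.ndarray:
        return self.table["density_per_um2"].to_numpy()

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        centers = (self.table["band_lo_nm"] + self.table["band_hi_nm"]) / 2
        ax.bar(centers, self.table["density_per_um2"], width=0.9 * BAND_WIDTH_NM, color="0.3")
        ax.set_xlabel("distance from PSD edge (nm)")
        ax.set_ylabel("particle density (1/µm²)")
        return ax


def annulus_density_profile(
    sample: PSDSample,
    band_width: float = BAND_WIDTH_NM,
    n_bands: int = N_BANDS,
) -> AnnulusProfile:
    """Radial density profile in half-open bands [b*w, (b+1)*w) from the edge.

    Band areas are ring areas of the buffered PSD polygon (round joins),
    clipped to ``analysis_region`` when the sample provides one; densities
    are count/area.  Counts always conserve:
    inside + sum(bands) + beyond == total.
    """
    dist = particle_distances(sample)
    poly = sample.psd_polygon
    region = sample.analysis_region
    edges = np.arange(n_bands + 1) * band_width
    rings = [poly.buffer(e, quad_segs=_QUAD_SEGS) if e > 0 else poly for e in edges]
    if region is not None:
        rings = [r.intersection(region) for r in rings]
    outside = dist.loc[~dist["inside_psd"]]
    flags: tuple[str, ...] = ()
    rows = []
    for b in range(n_bands):
        lo, hi = edges[b], edges[b + 1]
        in_band = (outside["distance_nm"] >= lo) & (outside["distance_nm"] < hi)
        if region is not None:
            pts_in_region = np.array(
                [region.covers(Point(x, y)) for x, y in outside.loc[in_band, ["x_nm", "y_nm"]].to_numpy()],
                dtype=bool,
            ) if in_band.any() else np.array([], dtype=bool)
            count = int(pts_in_region.sum())
        else:
            count = int(in_band.sum())
        area = rings[b + 1].area - rings[b].area
        if area <= 0:
            flags += (f"zero_area_band_{int(lo)}_{int(hi)}",)
            density = np.nan
        else:
            density = count / (area / 1e6)
        rows.append(
            {
                "band_lo_nm": lo,
                "band_hi_nm": hi,
                "count": count,
                "area_nm2": area,
                "density_per_um2": density,
            }
        )
    table = pd.DataFrame(rows)
    inside_count = int(dist["inside_psd"].sum())
    counted = inside_count + int(table["count"].sum())
    beyond = len(dist) - counted
    return AnnulusProfile(
        table=table,
        inside_count=inside_count,
        beyond_count=int(beyond),
        total=len(dist),
        flags=flags,
    )


@dataclass
class AnnulusDensityResults:
    profiles: list[AnnulusProfile]
    pooled: AnnulusProfile

    def summary(self) -> str:
        t = self.pooled.table
        lines = [
            "Perisynaptic immunogold density profile",
            "=======================================",
            f"samples: {len(self.profiles)}   particles: {self.pooled.total} "
            f"(inside PSD: {self.pooled.inside_count}, beyond last band: {self.pooled.beyond_count})",
        ]
        for _, row in t.iterrows():
            lines.append(
                f"[{row['band_lo_nm']:.0f}, {row['band_hi_nm']:.0f}) nm: "
                f"{row['count']:.0f} particles, {row['density_per_um2']:.1f} /µm²"
            )
        return "\n".join(lines)


@dataclass
class AnnulusDensity:
    """Radial-density model over one or more PSD samples."""

    samples: list[PSDSample]
    band_width: float = BAND_WIDTH_NM
    n_bands: int = N_BANDS

    @classmethod
    def from_sample(cls, sample: PSDSample, **kwargs) -> "AnnulusDensity":
        return cls(samples=[sample], **kwargs)

    def fit(self) -> AnnulusDensityResults:
        profiles = [
            annulus_density_profile(s, self.band_width, self.n_bands) for s in self.samples
        ]
        counts = np.sum([p.table["count"].to_numpy() for p in profiles], axis=0)
        areas = np.sum([p.table["area_nm2"].to_numpy() for p in profiles], axis=0)
        pooled_table = profiles[0].table.copy()
        pooled_table["count"] = counts.astype(int)
        pooled_table["area_nm2"] = areas
        pooled_table["density_per_um2"] = np.where(areas > 0, counts / (areas / 1e6), np.nan)
        pooled = AnnulusProfile(
            table=pooled_table,
            inside_count=sum(p.inside_count for p in profiles),
            beyond_count=sum(p.beyond_count for p in profiles),
            total=sum(p.total for p in profiles),
            flags=tuple(f for p in profiles for f in p.flags),
        )
        return AnnulusDensityResults(profiles=profiles, pooled=pooled)
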