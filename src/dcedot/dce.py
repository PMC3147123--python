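"""Contrast-enhancement difference images, ROIs, linearity and kinetics.

Enhancement maps are node-wise differences between post- and pre-contrast
reconstructions.  Regions of interest come either from the full-width-half-
maximum of the resolved inclusion (methods without a structural prior) or
from the anatomical region labels.  Linearity of the mean ROI enhancement
across the contrast series, and the time-resolved enhancement kinetics, are
the quantitative outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from dcedot.forward import OpticalMap
from dcedot.meshgen import Mesh2D


@dataclass
class EnhancementMap:
    """Per-node absorption enhancement Delta mu_a (mm^-1) on a mesh."""

    delta_mua: np.ndarray
    mesh: Mesh2D
    label: str = ""

    def __post_init__(self):
        self.delta_mua = np.asarray(self.delta_mua, dtype=float)
        if len(self.delta_mua) != self.mesh.n_nodes:
            raise ValueError("enhancement field does not match mesh")


@dataclass
class KineticsCurve:
    """Time-resolved mean ROI enhancement and its max-normalised form."""

    times: np.ndarray
    values: np.ndarray
    normalized: np.ndarray = None
    normalization_ok: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.normalized is None:
            peak = self.values.max()
            if peak > 0:
                self.normalized = self.values / peak
            else:
                warnings.warn("kinetics curve has no positive peak; "
                              "normalization skipped", stacklevel=2)
                self.normalized = self.values.copy()
                self.normalization_ok = False


def difference_map(post: OpticalMap, pre: OpticalMap, mesh: Mesh2D,
                   label: str = "") -> EnhancementMap:
    """Node-wise mu_a(post) - mu_a(pre)."""
    if post.mua.shape != pre.mua.shape or len(post.mua) != mesh.n_nodes:
        raise ValueError("post/pre maps are not on the same mesh")
    return EnhancementMap(post.mua - pre.mua, mesh, label=label)


def roi_fwhm(emap: EnhancementMap) -> np.ndarray:
    """FWHM region of interest around the strongest enhancement.

    Threshold at background-median + half the peak-above-background, then
    keep only the element-adjacency connected component containing the peak
    node.  Returns sorted node indices.
    """
    v = emap.delta_mua
    bg = float(np.median(v))
    peak = float(v.max())
    if peak <= bg:
        raise ValueError("no inclusion resolved: map maximum does not exceed background")
    thresh = bg + 0.5 * (peak - bg)
    candidate = v >= thresh
    peak_node = int(np.argmax(v))

    adj = {}
    for tri in emap.mesh.elements:
        for a in range(3):
            u, w = tri[a], tri[(a + 1) % 3]
            if candidate[u] and candidate[w]:
                adj.setdefault(u, set()).add(w)
                adj.setdefault(w, set()).add(u)
    seen = {peak_node}
    stack = [peak_node]
    while stack:
        u = stack.pop()
        for w in adj.get(u, ()):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return np.array(sorted(seen), dtype=np.int64)


def roi_from_prior(mesh: Mesh2D, region_id: int) -> np.ndarray:
    """All nodes carrying an anatomical region label."""
    nodes = np.flatnonzero(mesh.region_labels == region_id)
    if len(nodes) == 0:
        raise ValueError(f"region id {region_id} not present on the mesh")
    return nodes


def mean_enhancement(emap: EnhancementMap, roi: np.ndarray) -> float:
    """Area-weighted mean Delta mu_a over the ROI (mesh-refinement stable)."""
    roi = np.asarray(roi, dtype=np.int64)
    if len(roi) == 0:
        raise ValueError("empty ROI")
    w = emap.mesh.node_areas()[roi]
    return float(np.sum(w * emap.delta_mua[roi]) / np.sum(w))


def linearity_analysis(contrast_levels, mean_enhancements):
    """OLS line through (contrast, enhancement) and normalised deviations.

    Returns (slope, intercept, deviations) with
    deviations = |data - fit| / max(data).
    """
    x = np.asarray(contrast_levels, dtype=float)
    y = np.asarray(mean_enhancements, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 matching (contrast, enhancement) points")
    slope, intercept = np.polyfit(x, y, 1)
    fit = slope * x + intercept
    deviations = np.abs(y - fit) / np.max(y)
    return float(slope), float(intercept), deviations


def kinetics_curve(frame_maps, roi, times) -> KineticsCurve:
    """Mean ROI enhancement per frame, plus the max-normalised curve."""
    if len(frame_maps) != len(times):
        raise ValueError("frame_maps and times must have equal length")
    values = np.array([mean_enhancement(m, roi) for m in frame_maps])
    return KineticsCurve(times=np.asarray(times, dtype=float), values=values)


def render_map(mesh: Mesh2D, values: np.ndarray, path, title: str = "",
               vmin: float = None, vmax: float = None) -> None:
    """Render a nodal field on the mesh to a PNG (shared scale via vmin/vmax)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    tpc = ax.tripcolor(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.elements,
                       values, shading="gouraud", vmin=vmin, vmax=vmax)
    fig.colorbar(tpc, ax=ax, shrink=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
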