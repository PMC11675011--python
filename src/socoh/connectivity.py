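"""Band-coherence matrices, connectogram edges, and RSS region strength.

For each animal and chamber condition, pairwise gamma-band coherences form
a symmetric region x region matrix.  Pairs of wires sharing a cannula are
never analysed (proximity makes their coherence spuriously high), so for
the standard montage of 8 bundles x 4 wires the validity mask excludes
8 * C(4,2) = 48 of the C(32,2) = 496 distinct pairs.

The per-region connectivity strength is the root square summation

    RSS(r) = sqrt( sum_i sigma_i^2 )

over the region's valid pairwise coherences sigma_i — a single number
combining the number of connections and their strengths.  Regions are
ranked by the group-mean RSS of a *reference condition* (sham animals in
the social chamber) and the top k become the regions of interest; using
only the reference condition keeps the selection blind to any injury
effect, mirroring the bias-avoidance rule of the original analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoherenceMatrix",
    "same_bundle_pairs",
    "build_matrix",
    "rss",
    "rss_by_region",
    "select_top_regions",
    "pairwise_table",
    "connectogram_edges",
    "plot_connectogram",
]


def same_bundle_pairs(bundle_id: np.ndarray) -> np.ndarray:
    """Boolean (C, C) matrix flagging within-bundle pairs (and the diagonal)."""
    b = np.asarray(bundle_id)
    return b[:, None] == b[None, :]


@dataclass
class CoherenceMatrix:
    """Symmetric band-coherence matrix with a validity mask.

    ``values[i, j]`` is the band coherence of regions i and j; ``valid``
    is False on the diagonal, on within-bundle pairs, and on any pair
    involving a dropped channel.
    """

    values: np.ndarray
    valid: np.ndarray
    region_names: list = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("coherence matrix must be square")
        self.values = v
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def masked(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out


def build_matrix(band_coherence: np.ndarray, bundle_id: np.ndarray,
                 channel_mask: np.ndarray | None = None,
                 region_names: list | None = None) -> CoherenceMatrix:
    """Assemble a validity-masked, symmetrised coherence matrix.

    ``band_coherence`` is a (C, C) array of band-mean coherences (from
    :meth:`CrossSpectralAccumulator.band_coherence`); ``channel_mask``
    flags channels kept by the rejection step.
    """
    c = np.asarray(band_coherence, dtype=float)
    c = 0.5 * (c + c.T)
    valid = ~same_bundle_pairs(bundle_id)
    if channel_mask is not None:
        keep = np.asarray(channel_mask, dtype=bool)
        valid &= keep[:, None] & keep[None, :]
    np.fill_diagonal(valid, False)
    return CoherenceMatrix(c, valid, list(region_names or []))


def rss(matrix: CoherenceMatrix, region: int) -> float:
    """Root square summation of one region's valid pairwise coherences.

    NaN when the region has no valid pair (fully masked / dropped).
    """
    row_valid = matrix.valid[region]
    if not row_valid.any():
        return float("nan")
    sig = matrix.values[region, row_valid]
    return float(np.sqrt(np.sum(sig ** 2)))


def rss_by_region(matrix: CoherenceMatrix) -> np.ndarray:
    """RSS for every region of a matrix."""
    return np.array([rss(matrix, i) for i in range(matrix.n)])


def select_top_regions(rss_values, region_names, k: int = 6) -> list:
    """Top-k regions by descending RSS, ties broken by region label.

    ``rss_values`` must come from the reference condition only (group-mean
    sham/social RSS); NaN entries sort last.
    """
    names = list(region_names)
    vals = np.asarray(rss_values, dtype=float)
    if len(names) != vals.size:
        raise ValueError("rss_values and region_names must align")
    if k > vals.size:
        raise ValueError(f"k={k} exceeds the {vals.size} available regions")
    order = sorted(
        range(vals.size),
        key=lambda i: (-(vals[i] if np.isfinite(vals[i]) else -np.inf), names[i]),
    )
    return [names[i] for i in order[:k]]


def pairwise_table(selected: list, matrices: dict) -> pd.DataFrame:
    """Long-format per-pair coherence table for the stats layer.

    ``matrices`` maps ``(animal_id, group, chamber)`` to a
    :class:`CoherenceMatrix`.  The output has one row per selected region
    pair and condition with columns
    ``animal_id, group, chamber, region_i, region_j, pair, value``; pairs
    invalid in a matrix (same bundle or dropped channel) yield NaN.
    """
    rows = []
    for (animal, group, chamber), mat in matrices.items():
        name_to_idx = {n: i for i, n in enumerate(mat.region_names)}
        for a in range(len(selected)):
            for b in range(a + 1, len(selected)):
                ri, rj = selected[a], selected[b]
                i, j = name_to_idx[ri], name_to_idx[rj]
                val = mat.values[i, j] if mat.valid[i, j] else np.nan
                rows.append({
                    "animal_id": animal, "group": group, "chamber": chamber,
                    "region_i": ri, "region_j": rj, "pair": f"{ri}-{rj}",
                    "value": val,
                })
    return pd.DataFrame(rows)


def connectogram_edges(matrix: CoherenceMatrix, bundle_id=None,
                       threshold: float = 0.0) -> list:
    """Valid edges as ``{region_i, region_j, weight, bundle_i, bundle_j}`` dicts."""
    edges = []
    names = matrix.region_names or [str(i) for i in range(matrix.n)]
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            if matrix.valid[i, j] and matrix.values[i, j] >= threshold:
                e = {"region_i": names[i], "region_j": names[j],
                     "weight": float(matrix.values[i, j])}
                if bundle_id is not None:
                    e["bundle_i"] = int(bundle_id[i])
                    e["bundle_j"] = int(bundle_id[j])
                edges.append(e)
    return edges


def plot_connectogram(matrix: CoherenceMatrix, bundle_id, path=None,
                      threshold: float = 0.0, cmap: str = "viridis"):
    """Circular connectivity diagram; edge width encodes coherence.

    Nodes are placed on a circle grouped by bundle.  Returns the figure
    (saved to ``path`` when given).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = matrix.region_names or [str(i) for i in range(matrix.n)]
    order = np.argsort(np.asarray(bundle_id), kind="stable")
    pos = {}
    for rank, idx in enumerate(order):
        th = 2 * np.pi * rank / matrix.n
        pos[idx] = (np.cos(th), np.sin(th))
    fig, ax = plt.subplots(figsize=(7, 7))
    vmax = np.nanmax(matrix.values[matrix.valid]) if matrix.valid.any() else 1.0
    for e in connectogram_edges(matrix, bundle_id, threshold):
        i, j = names.index(e["region_i"]), names.index(e["region_j"])
        (x0, y0), (x1, y1) = pos[i], pos[j]
        ax.plot([x0, x1], [y0, y1], lw=3.0 * e["weight"] / max(vmax, 1e-12),
                color="steelblue", alpha=0.6, zorder=1)
    for idx, (x, y) in pos.items():
        ax.scatter([x], [y], s=40, c=[plt.get_cmap(cmap)(bundle_id[idx] / 8)],
                   zorder=2)
        ax.annotate(names[idx], (1.08 * x, 1.08 * y), ha="center", va="center",
                    fontsize=7)
    ax.set_aspect("equal")
    ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
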