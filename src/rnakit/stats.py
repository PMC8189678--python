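"""Descriptive analyses over the merged dataset.

Three machines reproduce the standard exploratory views of such a dataset:

* chain-length distributions by family, with small families pooled into an
  ``Other`` group;
* per-family sequence-identity matrices rendered after Ward clustering;
* Ramachandran-like joint densities of the pseudotorsion pairs (eta, theta)
  or (eta', theta'), stratified by sugar pucker -- the C3'-endo stratum
  excludes nucleotides annotated as part of an A/B/Z helix (they swamp the
  central peak), the C2'-endo stratum filters on pucker only.  Densities
  are Gaussian kernel estimates on the torus [0, 360)^2 (both axes wrap),
  with line contours at rho + {1, 2, 4} sigma, where rho and sigma are the
  mean and standard deviation of the evaluated density grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

PERIOD = 360.0


@dataclass
class DensityField:
    """A KDE evaluated on a regular grid over the torus [0, 360)^2."""

    grid: np.ndarray  # (n, n) density values, per squared degree
    xs: np.ndarray  # grid coordinates along eta (degrees)
    ys: np.ndarray  # grid coordinates along theta (degrees)
    bandwidth: float  # isotropic Gaussian sigma, degrees
    rho: float  # mean grid height
    sigma: float  # std of grid heights

    @property
    def contour_levels(self) -> list[float]:
        return [self.rho + self.sigma, self.rho + 2 * self.sigma, self.rho + 4 * self.sigma]


def select_nucleotides(
    records: pd.DataFrame,
    stratum: str,
    resolution_max: float | None = 4.0,
    angles: tuple[str, str] = ("eta", "theta"),
    exclude_helical_in_c2: bool = False,
    unique_chains: bool = True,
) -> np.ndarray:
    """Angle pairs for one pucker stratum of the nucleotide table.

    ``stratum`` is ``"c3-nonhelical"`` (C3'-endo pucker, helix-form labels
    A/B/Z excluded) or ``"c2"`` (C2'-endo pucker; pass
    ``exclude_helical_in_c2=True`` to apply the helix exclusion there too).
    Rows with an undefined member of the angle pair are dropped.  With
    ``unique_chains`` the copies created by multi-family mapping are
    reduced to one chain per (structure_id, chain_id) before selection.
    """
    df = records
    if unique_chains and {"structure_id", "chain_id"} <= set(df.columns):
        first_fam = (
            df.groupby(["structure_id", "chain_id"], sort=True)["family"]
            .transform("first")
        )
        df = df[df["family"].fillna("") == first_fam.fillna("")]
    if resolution_max is not None and "resolution" in df.columns:
        df = df[df["resolution"].notna() & (df["resolution"] <= resolution_max)]
    if stratum == "c3-nonhelical":
        df = df[df["pucker_label"] == "C3'-endo"]
        df = df[~df["form_label"].isin(["A", "B", "Z"])]
    elif stratum == "c2":
        df = df[df["pucker_label"] == "C2'-endo"]
        if exclude_helical_in_c2:
            df = df[~df["form_label"].isin(["A", "B", "Z"])]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    x, y = angles
    df = df[df[x].notna() & df[y].notna()]
    return df[[x, y]].to_numpy(dtype=float)


def scott_bandwidth(points: np.ndarray) -> float:
    """Scott's rule bandwidth (degrees) from the circular std of the sample."""
    n = len(points)
    sds = []
    for k in range(points.shape[1]):
        rad = np.radians(points[:, k])
        r = math.hypot(float(np.mean(np.cos(rad))), float(np.mean(np.sin(rad))))
        r = min(max(r, 1e-12), 1.0 - 1e-15)
        sds.append(math.degrees(math.sqrt(-2.0 * math.log(r))))
    sd = float(np.mean(sds))
    if sd == 0.0:
        sd = 1.0  # degenerate all-identical sample; any positive width works
    return sd * n ** (-1.0 / 6.0)  # Scott's factor for d = 2


def kde_torus(
    points: np.ndarray,
    grid_size: int = 256,
    bandwidth: float | None = None,
) -> DensityField:
    """Gaussian KDE on the torus [0, 360)^2.

    Each kernel is a product of wrapped normals: periodic images at
    +- k*360 degrees are summed over enough k for the truncation error to
    be far below the 1e-8 oracle tolerance.  The returned grid integrates
    to ~1 over the torus (density per squared degree).  Deterministic.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 2:
        raise ValueError("need at least 2 angle pairs")
    points = points % PERIOD
    if bandwidth is None:
        bandwidth = scott_bandwidth(points)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    xs = np.arange(grid_size) * (PERIOD / grid_size)
    ys = xs.copy()
    n_images = max(2, int(math.ceil(4.0 * bandwidth / PERIOD)) + 1)
    shifts = np.arange(-n_images, n_images + 1) * PERIOD

    def axis_kernels(grid_coords: np.ndarray, centers: np.ndarray) -> np.ndarray:
        # (n_points, grid_size) wrapped-normal evaluations
        delta = grid_coords[None, :] - centers[:, None]  # (n, g)
        acc = np.zeros_like(delta)
        for s in shifts:
            acc += np.exp(-0.5 * ((delta + s) / bandwidth) ** 2)
        return acc / (bandwidth * math.sqrt(2.0 * math.pi))

    kx = axis_kernels(xs, points[:, 0])
    ky = axis_kernels(ys, points[:, 1])
    # density[i, j] over (x=xs[i], y=ys[j]); product kernel summed over points
    grid = (kx.T @ ky) / len(points)
    rho = float(grid.mean())
    sigma = float(grid.std())
    return DensityField(grid=grid, xs=xs, ys=ys, bandwidth=bandwidth, rho=rho, sigma=sigma)


def torus_integral(fieldlike: DensityField) -> float:
    cell = (PERIOD / len(fieldlike.xs)) ** 2
    return float(fieldlike.grid.sum() * cell)


def length_histogram(
    chain_lengths: pd.DataFrame,
    pool_threshold: int = 3,
    bins: int | np.ndarray = 30,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Binned chain-length counts per family, small families pooled.

    ``chain_lengths`` needs columns ``family`` and ``length``.  Families
    with fewer than ``pool_threshold`` chains are pooled under ``Other``.
    Returns a tidy frame (family, bin_left, bin_right, count); total counts
    are conserved.  Bin edges are logarithmic when ``log_scale``.
    """
    if chain_lengths.empty:
        return pd.DataFrame(columns=["family", "bin_left", "bin_right", "count"])
    df = chain_lengths.copy()
    df["family"] = df["family"].fillna("unmapped")
    sizes = df["family"].value_counts()
    small = set(sizes[sizes < pool_threshold].index)
    df.loc[df["family"].isin(small), "family"] = "Other"
    lengths = df["length"].to_numpy(dtype=float)
    if isinstance(bins, int):
        lo, hi = lengths.min(), lengths.max()
        if log_scale:
            edges = np.geomspace(max(lo, 1.0), max(hi, lo + 1.0, 2.0), bins + 1)
        else:
            edges = np.linspace(lo, max(hi, lo + 1.0), bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    rows = []
    for fam, grp in df.groupby("family", sort=True):
        counts, _ = np.histogram(grp["length"].to_numpy(dtype=float), bins=edges)
        # histogram excludes values above the last edge; clamp them in
        overflow = int((grp["length"] > edges[-1]).sum())
        counts[-1] += overflow
        underflow = int((grp["length"] < edges[0]).sum())
        counts[0] += underflow
        for left, right, count in zip(edges[:-1], edges[1:], counts):
            rows.append({"family": fam, "bin_left": left, "bin_right": right, "count": int(count)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plotting (thin matplotlib wrappers; figures returned, never shown)

def plot_density(field: DensityField, points: np.ndarray | None = None, title: str = ""):
    """Scatter + filled density + rho + {1,2,4} sigma line contours."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    extent = (0, PERIOD, 0, PERIOD)
    ax.imshow(field.grid.T, origin="lower", extent=extent, cmap="Blues", aspect="equal")
    if points is not None and len(points):
        ax.scatter(points[:, 0] % PERIOD, points[:, 1] % PERIOD, s=2, c="k", alpha=0.3)
    levels = [lv for lv in field.contour_levels if lv < field.grid.max()]
    if levels:
        ax.contour(field.xs, field.ys, field.grid.T, levels=levels, colors="r", linewidths=0.8)
    ax.set_xlabel("eta (degrees)")
    ax.set_ylabel("theta (degrees)")
    ax.set_title(title)
    return fig


def plot_length_histogram(hist: pd.DataFrame, log_scale: bool = True):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = None
    for fam, grp in hist.groupby("family", sort=True):
        widths = grp["bin_right"] - grp["bin_left"]
        vals = grp["count"].to_numpy()
        ax.bar(grp["bin_left"], vals, width=widths, align="edge",
               bottom=bottom, label=fam, edgecolor="none")
        bottom = vals if bottom is None else bottom + vals
    if log_scale:
        ax.set_xscale("log")
    ax.set_xlabel("chain length (nt)")
    ax.set_ylabel("chains")
    ax.legend(fontsize=6)
    return fig


def plot_identity_matrix(matrix, order=None, title: str = ""):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    values = matrix.values
    if order is not None:
        values = values[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(values, cmap="viridis", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="sequence identity")
    ax.set_title(title)
    return fig
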