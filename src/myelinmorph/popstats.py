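"""Population-level aggregation of fiber morphometrics.

Implements the diameter-bin stratification, overall and per-bin mean±SD,
the pairwise correlation structure among diameter / myelin thickness /
g-ratio, ordinary-least-squares R² for thickness~diameter and g~diameter,
and myelinated-fiber density.  Sample SD (n−1) throughout; bins are
half-open ``[lo, hi)`` with a final open-ended bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from myelinmorph.morphometry import FiberRecord

#: Metric columns used in correlations and per-bin summaries.
METRICS = ("axon_diameter_um", "myelin_thickness_um", "g_ratio")

DEFAULT_EDGES = (0.335, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75)


@dataclass(frozen=True)
class BinScheme:
    """Diameter stratification: half-open bins plus a final open-ended bin.

    Default edges are 0.335, then 0.25 µm steps from 0.5 to 1.75, with a
    last bin of 1.75 µm and above.
    """

    edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("edges must be strictly increasing, length >= 2")

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    @property
    def labels(self) -> list[str]:
        out = [f"{a:g}-{b:g}" for a, b in zip(self.edges, self.edges[1:])]
        out.append(f"{self.edges[-1]:g}+")
        return out

    def assign(self, diameter: float) -> int:
        """Bin index for one diameter; below the first edge is an error."""
        if diameter < self.edges[0]:
            raise ValueError(
                f"diameter {diameter} below first edge {self.edges[0]} "
                "(should have been removed by QC)")
        # half-open [lo, hi); searchsorted(side='right') gives 1-based bin
        return min(int(np.searchsorted(self.edges, diameter, side="right")) - 1,
                   self.n_bins - 1)


def bin_records(records: list[FiberRecord],
                scheme: BinScheme | None = None) -> list[list[FiberRecord]]:
    """Group records by diameter bin; every bin present (possibly empty)."""
    scheme = scheme or BinScheme()
    groups: list[list[FiberRecord]] = [[] for _ in range(scheme.n_bins)]
    for r in records:
        groups[scheme.assign(r.axon_diameter_um)].append(r)
    return groups


@dataclass
class PopulationSummary:
    """Overall and per-bin statistics of one screened population."""

    n: int
    mean_diameter: float
    sd_diameter: float
    mean_thickness: float
    sd_thickness: float
    mean_g: float
    sd_g: float
    density_per_mm2: float
    per_bin: pd.DataFrame            # count, mean/sd per metric, per bin
    correlations: pd.DataFrame       # Pearson r, metrics × metrics
    correlation_p: pd.DataFrame      # two-sided p-values
    r2_thickness_vs_diameter: float
    r2_g_vs_diameter: float
    scheme: BinScheme = field(default_factory=BinScheme)


def records_frame(records: list[FiberRecord]) -> pd.DataFrame:
    from myelinmorph.morphometry import RECORD_FIELDS
    return pd.DataFrame(
        [{f: getattr(r, f) for f in RECORD_FIELDS} for r in records])


def _per_bin_table(groups: list[list[FiberRecord]],
                   scheme: BinScheme) -> pd.DataFrame:
    rows = []
    for label, grp in zip(scheme.labels, groups):
        row: dict[str, object] = {"bin": label, "count": len(grp)}
        for m in METRICS:
            vals = np.array([getattr(r, m) for r in grp])
            row[f"mean_{m}"] = vals.mean() if len(vals) else math.nan
            row[f"sd_{m}"] = vals.std(ddof=1) if len(vals) > 1 else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(records: list[FiberRecord], total_area_mm2: float,
              scheme: BinScheme | None = None) -> PopulationSummary:
    """Aggregate screened records over a total imaged area (mm²).

    With fewer than two records, SDs, correlations and R² are reported as
    NaN markers rather than raised.
    """
    scheme = scheme or BinScheme()
    if total_area_mm2 <= 0:
        raise ValueError("total_area_mm2 must be positive")
    n = len(records)
    d = np.array([r.axon_diameter_um for r in records])
    t = np.array([r.myelin_thickness_um for r in records])
    g = np.array([r.g_ratio for r in records])

    def sd(x):
        return float(x.std(ddof=1)) if n > 1 else math.nan

    cols = {m: x for m, x in zip(METRICS, (d, t, g))}
    rmat = pd.DataFrame(np.nan, index=METRICS, columns=METRICS)
    pmat = pd.DataFrame(np.nan, index=METRICS, columns=METRICS)
    r2_td = r2_gd = math.nan
    if n >= 2:
        for a in METRICS:
            for b in METRICS:
                if a == b:
                    rmat.loc[a, b], pmat.loc[a, b] = 1.0, 0.0
                elif np.ptp(cols[a]) > 0 and np.ptp(cols[b]) > 0:
                    res = sps.pearsonr(cols[a], cols[b])
                    rmat.loc[a, b] = res.statistic
                    pmat.loc[a, b] = res.pvalue
        if np.ptp(d) > 0:
            r2_td = float(sps.linregress(d, t).rvalue ** 2)
            r2_gd = float(sps.linregress(d, g).rvalue ** 2)

    groups = bin_records(records, scheme)
    return PopulationSummary(
        n=n,
        mean_diameter=float(d.mean()) if n else math.nan,
        sd_diameter=sd(d),
        mean_thickness=float(t.mean()) if n else math.nan,
        sd_thickness=sd(t),
        mean_g=float(g.mean()) if n else math.nan,
        sd_g=sd(g),
        density_per_mm2=n / total_area_mm2,
        per_bin=_per_bin_table(groups, scheme),
        correlations=rmat,
        correlation_p=pmat,
        r2_thickness_vs_diameter=r2_td,
        r2_g_vs_diameter=r2_gd,
        scheme=scheme,
    )


def compare_regions(summary_a: PopulationSummary, summary_b: PopulationSummary,
                    names: tuple[str, str] = ("a", "b")) -> pd.DataFrame:
    """Side-by-side per-bin mean±SD table for two regions.

    Purely descriptive (no hypothesis test); empty bins stay NaN, never 0.
    Both summaries must share a bin scheme.
    """
    if summary_a.scheme.edges != summary_b.scheme.edges:
        raise ValueError("summaries use different bin schemes")
    na, nb = names
    a = summary_a.per_bin.set_index("bin")
    b = summary_b.per_bin.set_index("bin")
    out = a.join(b, lsuffix=f"_{na}", rsuffix=f"_{nb}")
    return out.reset_index()


def plot_summary(summary: PopulationSummary, records: list[FiberRecord],
                 out_prefix: str) -> list[str]:
    """Write diagnostic figures (diameter histogram, binned means,
    correlation heatmap) as PNGs; returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    d = [r.axon_diameter_um for r in records]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(d, bins=40)
    ax.set_xlabel("axon diameter (µm)")
    ax.set_ylabel("count")
    p = f"{out_prefix}_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(7, 4))
    tbl = summary.per_bin
    x = np.arange(len(tbl))
    ax.bar(x, tbl["count"])
    ax.set_xticks(x, tbl["bin"], rotation=45)
    ax.set_ylabel("fibers per bin")
    fig.tight_layout()
    p = f"{out_prefix}_bins.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(summary.correlations.to_numpy(), vmin=-1, vmax=1,
                   cmap="RdBu_r")
    ax.set_xticks(range(len(METRICS)), METRICS, rotation=45)
    ax.set_yticks(range(len(METRICS)), METRICS)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    p = f"{out_prefix}_corr.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
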