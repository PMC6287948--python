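"""Repeatability statistics: Bland–Altman, Wilcoxon signed-rank, regional MAD.

The Wilcoxon implementation enumerates the exact null distribution for
small samples (n <= 12 non-zero differences), with zero differences
dropped and ties mid-ranked; larger samples use the normal approximation
with tie correction.  Note that scipy's exact mode refuses ties, which is
why the exact path is implemented here.

"MAD" here is the study's definition — the median over lung regions of the
absolute difference between each region's median and the whole-lung median
— an intra-patient heterogeneity measure, *not* the conventional median
absolute deviation from the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ValidationError

__all__ = [
    "BlandAltmanResult", "MadResult", "PairedStudy",
    "bland_altman", "wilcoxon_signed_rank", "regional_mad", "gradient_contrast",
    "bland_altman_plot",
]

PARAMETERS = ("MTT", "PBF", "PBV")


@dataclass
class BlandAltmanResult:
    """Agreement between paired measurements: bias and 95% limits."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass
class MadResult:
    """Regional heterogeneity (study MAD) per parameter for one measurement."""

    values: dict[str, float]


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def bland_altman(a, b) -> BlandAltmanResult:
    """Mean difference (b - a), SD of differences, 95% limits of agreement."""
    a, b = _paired(a, b)
    if a.size < 2:
        raise ValidationError("Bland-Altman needs at least 2 complete pairs")
    d = b - a
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(n=int(d.size), mean_diff=mean, sd_diff=sd,
                             loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd)


def _exact_sf_cdf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) for doubled integer ranks, by convolution."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    return float(counts[: w2 + 1].sum()), float(counts[w2:].sum())


def wilcoxon_signed_rank(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns ``(W_plus, p)``.  Zero differences are dropped; absolute
    differences are mid-ranked.  ``mode``: "exact" (enumeration of the
    sign-flip null; default for n <= 12), "approx" (normal with tie
    correction) or "auto".
    """
    a, b = _paired(a, b)
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValidationError("degenerate pairing: all differences are zero")
    if n < 5:
        raise ValidationError("need at least 5 non-zero differences")
    ranks = rankdata(np.abs(d))  # midranks; multiples of 0.5
    w_plus = float(ranks[d > 0].sum())
    if mode == "auto":
        mode = "exact" if n <= 12 else "approx"

    if mode == "exact":
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        cdf, sf = _exact_sf_cdf(ranks2, w2)
        p = min(1.0, 2.0 * min(cdf, sf))
    elif mode == "approx":
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return w_plus, p


def regional_mad(region_medians, whole_lung_median: float) -> float:
    """Median over regions of |region median - whole-lung median|."""
    r = np.asarray(region_medians, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 2:
        raise ValidationError("need at least 2 regions for MAD")
    return float(np.median(np.abs(r - whole_lung_median)))


def gradient_contrast(region_table: pd.DataFrame, axis: str, value_col: str) -> float:
    """Perfusion gradient along an anatomical axis for one measurement.

    ``dorsoventral``: mean over back (dorsal) regions minus mean over front
    (ventral) regions.  ``apicobasal``: mean over upper minus mean over
    lower regions, the middle slabs excluded.
    """
    t = region_table
    if axis == "dorsoventral":
        hi = t.loc[t.depth == "back", value_col]
        lo = t.loc[t.depth == "front", value_col]
    elif axis == "apicobasal":
        hi = t.loc[t.vertical == "upper", value_col]
        lo = t.loc[t.vertical == "lower", value_col]
    else:
        raise ValidationError("axis must be 'dorsoventral' or 'apicobasal'")
    if hi.empty or lo.empty:
        raise ValidationError(f"missing regions for {axis} contrast")
    return float(hi.mean() - lo.mean())


class PairedStudy:
    """Tidy table of the 2-day x 2-injection measurement grid.

    One row per (subject, day, injection, region, parameter) observation;
    region 0 denotes the whole lung.  Pairing for a contrast is done by
    aligning on the remaining keys, dropping incomplete cells pairwise.
    """

    COLUMNS = ["subject", "day", "injection", "region_id", "parameter", "value"]

    def __init__(self, frame: pd.DataFrame | None = None):
        self.frame = (frame[self.COLUMNS].copy() if frame is not None
                      else pd.DataFrame(columns=self.COLUMNS))

    def add(self, subject, day, injection, region_id, parameter, value) -> None:
        self.frame.loc[len(self.frame)] = [subject, day, injection,
                                           region_id, parameter, value]

    def append_rows(self, rows: list[dict]) -> None:
        new = pd.DataFrame(rows)[self.COLUMNS]
        self.frame = (new.copy() if self.frame.empty
                      else pd.concat([self.frame, new], ignore_index=True))

    def pairs(
        self,
        contrast: str,
        parameter: str,
        regions: str = "regional",
    ) -> tuple[np.ndarray, np.ndarray]:
        """Aligned (first, second) arrays for a contrast.

        ``contrast``: "injection" (1 vs 2) or "day" (1 vs 2).  ``regions``:
        "regional" pools the 12 regions (the study's per-region data
        points), "whole" uses whole-lung values only.
        """
        df = self.frame[self.frame.parameter == parameter]
        df = df[df.region_id > 0] if regions == "regional" else df[df.region_id == 0]
        if contrast == "injection":
            keys, split = ["subject", "day", "region_id"], "injection"
        elif contrast == "day":
            keys, split = ["subject", "injection", "region_id"], "day"
        else:
            raise ValidationError("contrast must be 'injection' or 'day'")
        wide = df.pivot_table(index=keys, columns=split, values="value")
        if not {1, 2}.issubset(wide.columns):
            raise ValidationError(f"incomplete grid for contrast {contrast!r}")
        wide = wide.dropna(subset=[1, 2])
        return wide[1].to_numpy(), wide[2].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PairedStudy":
        return cls(pd.read_csv(path))


def bland_altman_plot(a, b, path, title: str = "", unit: str = "") -> None:
    """Write a Bland–Altman scatter (mean vs difference) with LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = _paired(a, b)
    res = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, b - a, s=12, alpha=0.6)
    for y, style in ((res.mean_diff, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel(f"mean {unit}".strip())
    ax.set_ylabel(f"difference {unit}".strip())
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
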