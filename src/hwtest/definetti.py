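"""Isosceles de Finetti (ternary) diagram for two-allele genotype data.

A genotype frequency triple (d, h, r) maps to x = r + h/2, y = h on an
isosceles triangle with unit base and unit height (vertices AA at (0,0),
aa at (1,0), Aa at (0.5, 1)).  Under this mapping the x-coordinate IS the
allele frequency q of the a allele and the y-coordinate IS the heterozygote
frequency, so neither is distorted — the reason this convention is used
instead of the equilateral one.  Hardy-Weinberg populations trace the
parabola y = 2x(1-x); the 95% chi-squared confidence band is the pair of
curves obtained by offsetting the fixation index to F = +/- sqrt(3.841/N),
i.e. y = 2x(1-x)(1 -+ F).  A point lies between the bands exactly when the
uncorrected chi-squared of its sample would not reject HW at the 5% level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .core import allele_frequencies
from .counts import CountsLike, as_multi
from .simulate import hw_probs, observed_probs, sample_class_counts, task_rng

__all__ = [
    "CHI2_95_1DF",
    "DeFinettiFigure",
    "ternary_coords",
    "hw_parabola",
    "confidence_band",
    "build_figure",
    "render",
]

#: chi-squared 95% critical value for 1 df, kept at the conventional rounded
#: figure so the band curves match published diagrams exactly.
CHI2_95_1DF = 3.841

_CURVE_POINTS = 401


@dataclass(frozen=True)
class DeFinettiFigure:
    """Geometry bundle for one diagram (all coordinates in the unit square)."""

    triangle: np.ndarray  # (3, 2) vertices AA, aa, Aa
    parabola: np.ndarray  # (m, 2) polyline
    band_lower: np.ndarray
    band_upper: np.ndarray
    cloud_hw: np.ndarray  # (t, 2) HW-simulated populations
    cloud_obs: np.ndarray  # (t, 2) observed-frequency-simulated populations
    observed_point: tuple[float, float]
    N: int


def ternary_coords(d: float, h: float, r: float) -> tuple[float, float]:
    """Map a genotype frequency triple to (x, y) = (r + h/2, h).

    x equals the allele frequency q of a; y equals the heterozygote
    frequency.
    """
    if d < 0 or h < 0 or r < 0 or abs(d + h + r - 1.0) > 1e-9:
        raise ValueError(f"(d, h, r) = {(d, h, r)} is not a frequency triple")
    return (r + h / 2.0, h)


def hw_parabola(m: int = _CURVE_POINTS) -> np.ndarray:
    """Polyline of the HW parabola: images of (p^2, 2pq, q^2) over a uniform
    q grid; reduces to y = 2x(1-x)."""
    if m < 2:
        raise ValueError("need at least 2 points")
    q = np.linspace(0.0, 1.0, m)
    p = 1.0 - q
    pts = [ternary_coords(pp**2, 2 * pp * qq, qq**2) for pp, qq in zip(p, q)]
    return np.array(pts)


def confidence_band(
    N: int, m: int = _CURVE_POINTS, exact_quantile: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """95% chi-squared band curves (lower, upper) for sample size N.

    Each curve is the ternary image of {p^2 + pqF, 2pq(1-F), q^2 + pqF} with
    F = +sqrt(3.841/N) (lower, heterozygote deficit) and -sqrt(3.841/N)
    (upper, excess); grid points where any genotype coordinate leaves [0, 1]
    are dropped.  ``exact_quantile`` substitutes the unrounded chi-squared
    95% quantile for the conventional 3.841.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    crit = float(chi2_dist.ppf(0.95, 1)) if exact_quantile else CHI2_95_1DF
    f = float(np.sqrt(crit / N))

    def curve(F: float) -> np.ndarray:
        q = np.linspace(0.0, 1.0, m)
        p = 1.0 - q
        d = p**2 + p * q * F
        h = 2 * p * q * (1.0 - F)
        r = q**2 + p * q * F
        ok = (d >= 0) & (h >= 0) & (r >= 0) & (d <= 1) & (h <= 1) & (r <= 1)
        return np.column_stack([r[ok] + h[ok] / 2.0, h[ok]])

    return curve(f), curve(-f)


def _cloud(counts: np.ndarray, N: int) -> np.ndarray:
    # class order (AA, Aa, aa): x = r + h/2, y = h
    freq = counts / N
    return np.column_stack([freq[:, 2] + freq[:, 1] / 2.0, freq[:, 1]])


def build_figure(
    c: CountsLike,
    t: int = 1000,
    rng_hw: np.random.Generator | None = None,
    rng_obs: np.random.Generator | None = None,
    seed: int = 0,
) -> DeFinettiFigure:
    """Assemble the full diagram geometry for a two-allele sample.

    Two clouds of t simulated populations of size N each: one at HW
    proportions from the observed allele frequencies, one at the observed
    genotype frequencies; plus the observed point and the bands for N.
    """
    m = as_multi(c)
    if m.k != 2:
        raise ValueError("the de Finetti diagram is defined for two alleles only")
    if t < 1:
        raise ValueError("cloud size must be >= 1")
    if rng_hw is None:
        rng_hw = task_rng(seed, "cloud_hw")
    if rng_obs is None:
        rng_obs = task_rng(seed, "cloud_observed")
    N = m.N
    cloud_hw = _cloud(sample_class_counts(hw_probs(allele_frequencies(m)), N, t, rng_hw), N)
    cloud_obs = _cloud(sample_class_counts(observed_probs(m), N, t, rng_obs), N)
    d, h, r = (m.class_counts / N).tolist()
    lower, upper = confidence_band(N)
    return DeFinettiFigure(
        triangle=np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]]),
        parabola=hw_parabola(),
        band_lower=lower,
        band_upper=upper,
        cloud_hw=cloud_hw,
        cloud_obs=cloud_obs,
        observed_point=ternary_coords(d, h, r),
        N=N,
    )


def render(fig: DeFinettiFigure, path: str, format: str | None = None) -> None:
    """Render the diagram to SVG or PNG (800 x 700 px by default).

    SVG output is byte-stable for identical inputs: the embedded creation
    date is suppressed and the hash salt fixed.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt not in ("svg", "png"):
        raise ValueError(f"unsupported format {fmt!r}; use svg or png")

    with plt.rc_context({"svg.hashsalt": "hwtest"}):
        f, ax = plt.subplots(figsize=(8.0, 7.0), dpi=100)
        tri = np.vstack([fig.triangle, fig.triangle[:1]])
        ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1.2)
        ax.plot(fig.parabola[:, 0], fig.parabola[:, 1], color="black", lw=1.5,
                label="HW parabola")
        ax.plot(fig.band_lower[:, 0], fig.band_lower[:, 1], "--", color="gray",
                lw=1.0, label="95% band")
        ax.plot(fig.band_upper[:, 0], fig.band_upper[:, 1], "--", color="gray",
                lw=1.0)
        ax.scatter(fig.cloud_hw[:, 0], fig.cloud_hw[:, 1], s=6, color="tab:blue",
                   alpha=0.35, linewidths=0, label="HW-simulated populations")
        ax.scatter(fig.cloud_obs[:, 0], fig.cloud_obs[:, 1], s=6,
                   color="tab:orange", alpha=0.35, linewidths=0,
                   label="observed-frequency simulations")
        ax.scatter(*fig.observed_point, marker="*", s=180, color="tab:red",
                   zorder=5, label="observed sample")
        ax.annotate("AA", (0, 0), xytext=(-6, -14), textcoords="offset points")
        ax.annotate("aa", (1, 0), xytext=(-6, -14), textcoords="offset points")
        ax.annotate("Aa", (0.5, 1), xytext=(-6, 6), textcoords="offset points")
        ax.set_xlabel("allele frequency q = freq(a)")
        ax.set_ylabel("heterozygote frequency h")
        ax.set_title(f"de Finetti diagram (N = {fig.N})")
        ax.set_xlim(-0.05, 1.05)
        ax.set_ylim(-0.08, 1.1)
        ax.legend(loc="upper right", fontsize=8)
        metadata = {"Date": None} if fmt == "svg" else None
        f.savefig(path, format=fmt, metadata=metadata)
        plt.close(f)
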