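"""Agreement analysis between TEF estimators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BlandAltmanResult",
    "bland_altman",
    "summary_table",
    "format_mean_sd_range",
    "plot_bland_altman",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and 1.96-SD limits of agreement for paired estimates."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pairs: int


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement of paired estimates ``a`` and ``b``.

    Differences are ``a - b``; SD uses the n-1 denominator; limits of
    agreement are mean +/- 1.96 SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D paired estimates")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        pairs=int(a.size),
    )


def format_mean_sd_range(values, decimals: int = 1) -> str:
    """Format a group as ``mean ± SD [min–max]`` at the given precision."""
    v = np.asarray(values, dtype=float)
    sd = 0.0 if v.size < 2 else float(v.std(ddof=1))
    f = f"{{:.{decimals}f}}"
    return (
        f"{f.format(v.mean())} ± {f.format(sd)} "
        f"[{f.format(v.min())}–{f.format(v.max())}]"
    )


def summary_table(
    results,
    value: str = "tef_percent",
    by=("method", "period", "condition"),
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-group mean ± SD [range] over a collection of TEF results.

    ``results`` is a list of :class:`~teftool.estimators.TefResult` or a
    DataFrame of their rows.  Groups of size 1 report SD 0 and are flagged.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([r.as_row() for r in results])
    by = [c for c in by if c in results.columns]
    rows = []
    for key, grp in results.groupby(by, dropna=False, sort=True):
        v = grp[value].to_numpy(dtype=float)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            {
                **dict(zip(by, key)),
                "n": v.size,
                "mean": round(float(v.mean()), decimals),
                "sd": round(0.0 if v.size < 2 else float(v.std(ddof=1)),
                            decimals),
                "min": round(float(v.min()), decimals),
                "max": round(float(v.max()), decimals),
                "formatted": format_mean_sd_range(v, decimals),
                "single_observation": v.size == 1,
            }
        )
    return pd.DataFrame(rows)


def plot_bland_altman(a, b, ax=None, labels=("a", "b")):
    """Scatter of pair means vs differences with mean line and dashed LoA."""
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, color="black", s=25)
    ax.axhline(res.mean_diff, color="black")
    ax.axhline(res.loa_low, color="black", linestyle="--")
    ax.axhline(res.loa_high, color="black", linestyle="--")
    ax.set_xlabel(f"mean of {labels[0]} and {labels[1]}")
    ax.set_ylabel(f"{labels[0]} − {labels[1]}")
    return ax, res
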