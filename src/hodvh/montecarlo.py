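"""Monte Carlo resampling of cohort index summaries.

Each evaluated index, in each arm, is resampled as 10,000 independent
normal draws parameterized by the cohort (mean, SD) — the mean locates the
distribution, the SD sets its spread.  The resulting frequency
distributions expose the robustness of each index and, via
:func:`fraction_below`, the probability mass falling short of a clinically
relevant threshold such as the 7 Gy prophylactic dose.

Indices are sampled independently (no covariance structure is imposed), and
the normal family is used without truncation: with the baseline SDs of this
study, negative draws are negligible.  Every (index, arm) pair owns a
deterministic substream derived from the master seed and a stable hash of
its name, so adding indices never perturbs existing streams.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dvh import Arm
from .baseline import reference_baseline
from .stats import SummaryStat, summarize

__all__ = [
    "MCConfig",
    "MCDistribution",
    "draw_index_samples",
    "run_mc_study",
    "fraction_below",
    "export_histograms",
    "export_summary",
    "plot_distributions",
]

DEFAULT_N_SAMPLES = 10_000
DEFAULT_N_BINS = 60


def _stream_seed(master_seed: int, index_name: str, arm: Arm) -> np.random.SeedSequence:
    offset = zlib.crc32(f"{index_name}|{arm.value}".encode()) & 0x7FFFFFFF
    return np.random.SeedSequence([int(master_seed), offset])


@dataclass(frozen=True)
class MCConfig:
    """Configuration of the resampling study.

    ``baseline`` maps index name -> arm -> (mean, sd); it defaults to the
    reference cohort summary.  ``bin_width`` (index units) overrides the
    default equal-width binning into ``n_bins`` bins.
    """

    seed: int
    n_samples: int = DEFAULT_N_SAMPLES
    baseline: Mapping[str, Mapping[Arm, tuple[float, float]]] = field(
        default_factory=reference_baseline
    )
    n_bins: int = DEFAULT_N_BINS
    bin_width: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.bin_width is not None and self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for index_name, arms in self.baseline.items():
            for arm, (mean, sd) in arms.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {index_name}/{arm}")


@dataclass(frozen=True)
class MCDistribution:
    index_name: str
    arm: Arm
    samples: np.ndarray
    summary: SummaryStat
    hist_edges: np.ndarray
    hist_counts: np.ndarray


def draw_index_samples(mean: float, sd: float, n: int, seed) -> np.ndarray:
    """``n`` independent N(mean, sd²) draws; identical seed, identical draws."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.normal(mean, sd, size=n)


def _histogram(samples: np.ndarray, n_bins: int, bin_width: float | None):
    lo, hi = float(samples.min()), float(samples.max())
    if bin_width is None:
        if hi == lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        start = np.floor(lo / bin_width) * bin_width
        k = max(int(np.ceil((hi - start) / bin_width)), 1)
        while start + k * bin_width < hi:
            k += 1
        edges = start + bin_width * np.arange(k + 1)
    counts, edges = np.histogram(samples, bins=edges)
    return edges, counts


def run_mc_study(config: MCConfig) -> list[MCDistribution]:
    """One resampled distribution per (index, arm) in the baseline."""
    out: list[MCDistribution] = []
    for index_name, arms in config.baseline.items():
        if not arms:
            raise ValueError(f"baseline entry for {index_name!r} is empty")
        for arm in (Arm.IC_OFF, Arm.IC_ON):
            if arm not in arms:
                continue
            mean, sd = arms[arm]
            samples = draw_index_samples(
                mean, sd, config.n_samples, _stream_seed(config.seed, index_name, arm)
            )
            edges, counts = _histogram(samples, config.n_bins, config.bin_width)
            summary = (
                summarize(samples)
                if samples.size >= 2
                else SummaryStat(1, float(samples[0]), 0.0, float(samples[0]), float(samples[0]))
            )
            out.append(
                MCDistribution(
                    index_name=index_name,
                    arm=arm,
                    samples=samples,
                    summary=summary,
                    hist_edges=edges,
                    hist_counts=counts,
                )
            )
    return out


def fraction_below(dist: MCDistribution | Sequence[float], threshold: float) -> float:
    """Proportion of resampled values strictly below ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    samples = np.asarray(getattr(dist, "samples", dist), dtype=float)
    return float(np.count_nonzero(samples < threshold)) / samples.size


# ---------------------------------------------------------------------------
# exports


def export_summary(dists: Sequence[MCDistribution], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "arm", "n", "mean", "sd", "ci_low", "ci_high"])
        for d in dists:
            s = d.summary
            writer.writerow(
                [d.index_name, d.arm.value, s.n, f"{s.mean:.6g}", f"{s.sd:.6g}",
                 f"{s.ci_low:.6g}", f"{s.ci_high:.6g}"]
            )
    return path


def export_histograms(dists: Sequence[MCDistribution], path: str | Path) -> Path:
    """Long-format CSV of every histogram (one row per bin)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "arm", "bin_low", "bin_high", "count"])
        for d in dists:
            for lo, hi, c in zip(d.hist_edges[:-1], d.hist_edges[1:], d.hist_counts):
                writer.writerow([d.index_name, d.arm.value, f"{lo:.6g}", f"{hi:.6g}", int(c)])
    return path


def plot_distributions(
    dists: Sequence[MCDistribution], path: str | Path, *, indices: Sequence[str] | None = None
) -> Path:
    """Overlayed IC-off / IC-on frequency curves, one panel per index.

    Requires matplotlib (``pip install hodvh[plot]``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_index: dict[str, list[MCDistribution]] = {}
    for d in dists:
        if indices is None or d.index_name in indices:
            by_index.setdefault(d.index_name, []).append(d)
    n = len(by_index)
    ncols = min(4, max(n, 1))
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for ax, (name, group) in zip(axes.ravel(), sorted(by_index.items())):
        for d in group:
            centers = 0.5 * (d.hist_edges[:-1] + d.hist_edges[1:])
            style = ":" if d.arm is Arm.IC_OFF else "-"
            ax.plot(centers, d.hist_counts, style, label=d.arm.value)
        ax.set_title(name)
        ax.legend(fontsize="x-small")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
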