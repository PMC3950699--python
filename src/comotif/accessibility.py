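"""DNaseI accessibility scoring and stage-dynamics statistics.

A signal track holds dense per-base scores for one condition/stage. A
site's accessibility score is the mean signal over the site extended by a
flank (default 50 nt) on each side; a site is accessible in a stage when
that score strictly exceeds the genome-wide top-5% (nearest-rank) signal
threshold of the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SignalTrack:
    """Per-base signal for one stage: ``data[chrom]`` is a dense float array."""

    stage: str
    data: dict[str, np.ndarray]

    _cum: dict[str, np.ndarray] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        self.data = {c: np.asarray(v, dtype=np.float64) for c, v in self.data.items()}
        for c, v in self.data.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite signal on {c}")

    def _cumsum(self, chrom: str) -> np.ndarray:
        cum = self._cum.get(chrom)
        if cum is None:
            cum = np.concatenate(([0.0], np.cumsum(self.data[chrom])))
            self._cum[chrom] = cum
        return cum


def site_accessibility_score(site, track: SignalTrack, flank: int = 50) -> float:
    """Mean signal over [start - flank, end + flank), clipped at chromosome bounds."""
    chrom = site["chrom"] if isinstance(site, dict) else site.chrom
    start = int(site["start"] if isinstance(site, dict) else site.start)
    end = int(site["end"] if isinstance(site, dict) else site.end)
    if chrom not in track.data:
        raise KeyError(f"chromosome {chrom!r} absent from track {track.stage!r}")
    n = len(track.data[chrom])
    lo, hi = max(0, start - flank), min(n, end + flank)
    cum = track._cumsum(chrom)
    return float((cum[hi] - cum[lo]) / (hi - lo))


def site_scores(sites: pd.DataFrame, track: SignalTrack, flank: int = 50) -> np.ndarray:
    """Vectorized :func:`site_accessibility_score` over a site table."""
    out = np.empty(len(sites), dtype=float)
    chroms = sites["chrom"].to_numpy()
    starts = sites["start"].to_numpy()
    ends = sites["end"].to_numpy()
    for chrom in np.unique(chroms):
        if chrom not in track.data:
            raise KeyError(f"chromosome {chrom!r} absent from track {track.stage!r}")
        m = chroms == chrom
        n = len(track.data[chrom])
        lo = np.clip(starts[m] - flank, 0, n)
        hi = np.clip(ends[m] + flank, 0, n)
        cum = track._cumsum(chrom)
        out[m] = (cum[hi] - cum[lo]) / (hi - lo)
    return out


def genome_threshold(track: SignalTrack, top_fraction: float = 0.05) -> float:
    """Nearest-rank (1 - top_fraction) quantile of the pooled per-base scores."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    pooled = np.sort(np.concatenate([v for v in track.data.values()]))
    if len(pooled) == 0:
        raise ValueError("empty track")
    k = max(1, int(np.ceil((1.0 - top_fraction) * len(pooled))))
    return float(pooled[k - 1])


def annotate_accessibility(
    sites: pd.DataFrame,
    tracks: list[SignalTrack],
    flank: int = 50,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Add one boolean ``acc_<stage>`` column per track (score > threshold)."""
    sites = sites.copy()
    for track in tracks:
        thr = genome_threshold(track, top_fraction)
        sites[f"acc_{track.stage}"] = site_scores(sites, track, flank) > thr
    return sites


@dataclass
class StageUsage:
    """Per-motif accessible-site usage across stages."""

    stages: list[str]
    counts: pd.DataFrame  # motifs x stages, accessible-site counts
    degrees: pd.DataFrame  # counts / per-stage totals; columns sum to 1
    centered: pd.DataFrame  # degrees / per-motif mean over stages
    variation_ratio: pd.Series  # max/min degree; +inf when min degree is 0


def stage_usage(sites: pd.DataFrame, stages: list[str]) -> StageUsage:
    """Normalized degrees and variation ratios from per-stage accessibility flags.

    Normalized degree of a motif in a stage = its accessible-site count
    divided by the total accessible-site count over all motifs in that
    stage. Variation ratio = max/min of a motif's per-stage degrees
    (reported as +inf when the minimum is 0 and excluded from histograms).
    """
    cols = [f"acc_{s}" for s in stages]
    missing = [c for c in cols if c not in sites.columns]
    if missing:
        raise ValueError(f"missing accessibility flags: {missing}")
    counts = sites.groupby("motif_id")[cols].sum()
    counts.columns = stages
    totals = counts.sum(axis=0)
    degrees = counts / totals.replace(0, np.nan)
    degrees = degrees.fillna(0.0)
    mean = degrees.mean(axis=1)
    centered = degrees.div(mean.replace(0, np.nan), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = degrees.max(axis=1) / degrees.min(axis=1)
    ratio = ratio.replace(np.nan, np.inf)
    return StageUsage(list(stages), counts, degrees, centered, ratio)


@dataclass
class PermutationNull:
    real_ratios: pd.Series
    null_ratios: np.ndarray  # (n_rand, n_motifs), +inf where undefined
    bins: np.ndarray
    real_hist: np.ndarray
    null_hist_mean: np.ndarray
    null_hist_sd: np.ndarray


def stage_permutation_null(
    sites: pd.DataFrame,
    stages: list[str],
    n_rand: int,
    seed,
    bins: np.ndarray | None = None,
) -> PermutationNull:
    """Null distribution of variation ratios under per-site stage permutation.

    Each site's binary per-stage accessibility vector is independently and
    uniformly permuted across stages, stage usage is recomputed, and
    histograms of real vs randomized variation ratios are accumulated
    (+inf ratios are excluded from histograms).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)
    cols = [f"acc_{s}" for s in stages]
    flags = sites[cols].to_numpy(dtype=bool)
    motifs, codes = np.unique(sites["motif_id"].to_numpy(), return_inverse=True)
    n_m, n_s = len(motifs), len(stages)

    real = stage_usage(sites, stages).variation_ratio.reindex(motifs)
    if bins is None:
        finite = real[np.isfinite(real)]
        top = float(finite.max()) if len(finite) else 1.0
        bins = np.linspace(1.0, max(top, 2.0) * 1.5, 30)

    null = np.empty((n_rand, n_m))
    for r in range(n_rand):
        perm = np.argsort(rng.random(flags.shape), axis=1)
        shuffled = np.take_along_axis(flags, perm, axis=1)
        counts = np.zeros((n_m, n_s))
        np.add.at(counts, codes, shuffled.astype(float))
        totals = counts.sum(axis=0)
        deg = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = deg.max(axis=1) / deg.min(axis=1)
        ratio[~np.isfinite(ratio)] = np.inf
        null[r] = ratio

    real_hist = np.histogram(real[np.isfinite(real)], bins=bins)[0]
    per_rand = np.stack([np.histogram(row[np.isfinite(row)], bins=bins)[0] for row in null])
    return PermutationNull(
        real_ratios=real,
        null_ratios=null,
        bins=bins,
        real_hist=real_hist,
        null_hist_mean=per_rand.mean(axis=0),
        null_hist_sd=per_rand.std(axis=0),
    )
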