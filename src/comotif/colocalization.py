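"""Motif-pair co-localization against a composition-matched shuffling null.

For each "pivot" motif, pairs between its sites and the sites of every
other motif are enumerated (nearest other-motif site on each side of each
pivot site, within 1000 nt), weighted by the smaller of the two
conservation percentiles, and accumulated into 100-nt distance histograms.
The null preserves every site's position, strand and percentile but
shuffles motif identity labels within (chromosome x composition-cluster)
strata; pivot-motif sites are never relabeled. Empirical p-values per bin
are the fraction of randomized weighted counts >= the real count,
Benjamini-Hochberg adjusted per (pivot, stage) family. A pair is called
when the first bin is significant with either motif as pivot (reciprocity)
and its first-bin weighted count reaches a floor (default 10).
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

N_BINS = 10
BIN_WIDTH = 100
MAX_DIST = 1000


def _gap(p_start, p_end, o_start, o_end):
    """Distance in nt between nearest edges of two intervals; 0 if overlapping."""
    return np.maximum(0, np.maximum(o_start - p_end, p_start - o_end))


class PairEngine:
    """Precomputed pivot-site/other-site candidate geometry for one stage.

    Positions never move under identity shuffling, so every (pivot site,
    candidate other site) pair with its side, distance, bin and weight is
    computed once; a histogram for any label assignment then reduces to a
    nearest-per-(pivot site, side, label) selection on the precomputed,
    distance-sorted candidate list.
    """

    def __init__(self, sites: pd.DataFrame, pivot_motif: str,
                 max_dist: int = MAX_DIST, n_bins: int = N_BINS, bin_width: int = BIN_WIDTH):
        self.pivot = pivot_motif
        self.n_bins = n_bins
        self.motifs = sorted(sites["motif_id"].unique())
        self.motif_index = {m: i for i, m in enumerate(self.motifs)}
        is_pivot = (sites["motif_id"] == pivot_motif).to_numpy()
        piv = sites.loc[is_pivot]
        oth = sites.loc[~is_pivot].reset_index(drop=True)
        self.other_sites = oth
        self.labels0 = np.array([self.motif_index[m] for m in oth["motif_id"]], dtype=np.int64)

        groups, dists, opos, weights = [], [], [], []
        o_chrom = oth["chrom"].to_numpy()
        o_start = oth["start"].to_numpy()
        o_end = oth["end"].to_numpy()
        o_perc = oth["percentile"].to_numpy()
        o_mid = (o_start + o_end) / 2.0
        gid = 0
        for row in piv.itertuples(index=False):
            on_chrom = np.nonzero(o_chrom == row.chrom)[0]
            g = _gap(row.start, row.end, o_start[on_chrom], o_end[on_chrom])
            near = on_chrom[g <= max_dist]
            if len(near):
                gnear = g[g <= max_dist]
                side = (o_mid[near] >= (row.start + row.end) / 2.0).astype(np.int64)
                groups.append(gid * 2 + side)
                dists.append(gnear)
                opos.append(near)
                weights.append(np.minimum(row.percentile, o_perc[near]))
            gid += 1
        if groups:
            group = np.concatenate(groups)
            dist = np.concatenate(dists)
            pos = np.concatenate(opos)
            weight = np.concatenate(weights)
            order = np.lexsort((pos, o_start[pos], dist, group))
            self.c_group = group[order]
            self.c_dist = dist[order]
            self.c_pos = pos[order]
            self.c_weight = weight[order]
        else:
            self.c_group = np.empty(0, dtype=np.int64)
            self.c_dist = np.empty(0, dtype=np.int64)
            self.c_pos = np.empty(0, dtype=np.int64)
            self.c_weight = np.empty(0, dtype=float)
        self.c_bin = self.c_dist // bin_width

    def histogram(self, labels: np.ndarray | None = None) -> np.ndarray:
        """(n_motifs, n_bins) weighted counts for a label assignment."""
        if labels is None:
            labels = self.labels0
        M = len(self.motifs)
        hist = np.zeros((M, self.n_bins))
        if len(self.c_group) == 0:
            return hist
        lab = labels[self.c_pos]
        key = self.c_group * M + lab
        _, first = np.unique(key, return_index=True)
        sel = first[self.c_bin[first] < self.n_bins]
        np.add.at(hist, (lab[sel], self.c_bin[sel]), self.c_weight[sel])
        return hist

    def strata(self, comp_of_motif: dict) -> list[np.ndarray]:
        """Shuffling strata: other-site positions grouped by (chrom, composition)."""
        oth = self.other_sites
        keys = [
            (c, comp_of_motif[m]) for c, m in zip(oth["chrom"], oth["motif_id"])
        ]
        frame = pd.DataFrame({"k": pd.Series(keys).astype(str)})
        return [idx for _, idx in sorted(frame.groupby("k").indices.items())]

    def null_histograms(self, strata: list[np.ndarray], rng, n_rand: int) -> np.ndarray:
        """(n_rand, n_motifs, n_bins) histograms under within-stratum shuffling."""
        out = np.empty((n_rand, len(self.motifs), self.n_bins))
        labels = self.labels0.copy()
        for r in range(n_rand):
            for idx in strata:
                if len(idx) > 1:
                    labels[idx] = self.labels0[idx][rng.permutation(len(idx))]
            out[r] = self.histogram(labels)
        return out


def enumerate_pairs(sites: pd.DataFrame, pivot_motif: str, max_dist: int = MAX_DIST) -> pd.DataFrame:
    """Nearest-per-side pair enumeration for one pivot motif.

    For each pivot site and each other motif, only the nearest other-motif
    site on each side (by edge-to-edge gap; overlap counts as 0) within
    ``max_dist`` is paired. Homotypic pairs are excluded. The weight of a
    pair is the smaller of the two conservation percentiles.
    """
    eng = PairEngine(sites, pivot_motif, max_dist=max_dist, n_bins=10**9, bin_width=BIN_WIDTH)
    lab = eng.labels0[eng.c_pos]
    key = eng.c_group * len(eng.motifs) + lab
    _, first = np.unique(key, return_index=True)
    first = np.sort(first)
    oth = eng.other_sites
    piv_idx = eng.c_group[first] // 2
    piv = sites.loc[sites["motif_id"] == pivot_motif].reset_index(drop=True)
    return pd.DataFrame(
        {
            "pivot_motif": pivot_motif,
            "chrom": piv["chrom"].to_numpy()[piv_idx],
            "pivot_start": piv["start"].to_numpy()[piv_idx],
            "pivot_end": piv["end"].to_numpy()[piv_idx],
            "other_motif": oth["motif_id"].to_numpy()[eng.c_pos[first]],
            "other_start": oth["start"].to_numpy()[eng.c_pos[first]],
            "other_end": oth["end"].to_numpy()[eng.c_pos[first]],
            "side": np.where(eng.c_group[first] % 2 == 0, "left", "right"),
            "distance": eng.c_dist[first],
            "weight": eng.c_weight[first],
        }
    )


def weighted_histogram(distances, weights, n_bins: int = N_BINS, bin_width: int = BIN_WIDTH) -> np.ndarray:
    """Per-bin sum of pair weights; distances >= n_bins*bin_width are dropped."""
    distances = np.asarray(distances, dtype=np.int64)
    weights = np.asarray(weights, dtype=float)
    hist = np.zeros(n_bins)
    b = distances // bin_width
    ok = b < n_bins
    np.add.at(hist, b[ok], weights[ok])
    return hist


def shuffle_identities(
    sites: pd.DataFrame, comp_of_motif: dict, rng, pivot_motif: str | None = None
) -> pd.DataFrame:
    """Permute motif identities within (chromosome x composition cluster) strata.

    Positions, strands and percentile scores stay attached to the genomic
    records; only the identity labels move. Sites of ``pivot_motif`` are
    frozen entirely (neither relabeled nor used as shuffle targets).
    """
    out = sites.copy().reset_index(drop=True)
    movable = np.nonzero((out["motif_id"] != pivot_motif).to_numpy())[0]
    labels = out["motif_id"].to_numpy().copy()
    strata: dict[str, list[int]] = {}
    for i in movable:
        key = f"{out['chrom'].iat[i]}\x00{comp_of_motif[labels[i]]}"
        strata.setdefault(key, []).append(i)
    for key in sorted(strata):
        idx = np.asarray(strata[key])
        if len(idx) > 1:
            labels[idx] = labels[idx][rng.permutation(len(idx))]
    out["motif_id"] = labels
    return out


def empirical_pvalues(real: np.ndarray, nulls: np.ndarray) -> np.ndarray:
    """p = fraction of randomized counts >= the real count, per cell."""
    nulls = np.asarray(nulls)
    if nulls.shape[0] < 1:
        raise ValueError("need at least one randomization")
    return (nulls >= np.asarray(real)[None]).mean(axis=0)


def candidate_filter(real: np.ndarray, masses: np.ndarray, pivot_mass: float,
                     min_fraction: float = 0.01) -> np.ndarray:
    """Bins eligible for testing: weighted count >= min_fraction of the total
    percentile mass of each involved motif (pivot and other)."""
    real = np.atleast_2d(real)
    masses = np.asarray(masses, dtype=float)
    return (real >= min_fraction * pivot_mass) & (real >= min_fraction * masses[:, None])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def enumerate_stratum_assignments(labels: np.ndarray, strata: list[np.ndarray]):
    """Yield every distinct label array reachable by independently permuting
    the labels within each stratum (for exact-null enumeration on tiny inputs)."""
    labels = np.asarray(labels)
    per_stratum = []
    for idx in strata:
        opts = sorted(set(itertools.permutations(labels[idx])))
        per_stratum.append(opts)
    for combo in itertools.product(*per_stratum):
        out = labels.copy()
        for idx, perm in zip(strata, combo):
            out[idx] = perm
        yield out


@dataclass
class PivotResult:
    """Per-(stage, pivot) co-localization statistics."""

    pivot: str
    motifs: list[str]
    real: np.ndarray  # (n_motifs, n_bins) weighted counts
    null_mean: np.ndarray
    null_sd: np.ndarray
    pvalues: np.ndarray
    eligible: np.ndarray  # candidate_filter outcome; pivot row always False
    mass: dict  # motif -> total percentile mass of analyzed sites
    fdr: np.ndarray | None = None  # filled by call_pairs (per pivot family)


def analyze_pivot(
    sites: pd.DataFrame,
    pivot_motif: str,
    comp_of_motif: dict,
    n_rand: int,
    rng,
    max_dist: int = MAX_DIST,
    n_bins: int = N_BINS,
    bin_width: int = BIN_WIDTH,
    min_fraction: float = 0.01,
) -> PivotResult:
    """Real and null pair histograms plus empirical p-values for one pivot."""
    eng = PairEngine(sites, pivot_motif, max_dist, n_bins, bin_width)
    real = eng.histogram()
    nulls = eng.null_histograms(eng.strata(comp_of_motif), rng, n_rand)
    pv = empirical_pvalues(real, nulls)
    mass = sites.groupby("motif_id")["percentile"].sum().to_dict()
    masses = np.array([mass.get(m, 0.0) for m in eng.motifs])
    elig = candidate_filter(real, masses, mass.get(pivot_motif, 0.0), min_fraction)
    elig[eng.motif_index[pivot_motif], :] = False
    return PivotResult(
        pivot=pivot_motif,
        motifs=eng.motifs,
        real=real,
        null_mean=nulls.mean(axis=0),
        null_sd=nulls.std(axis=0),
        pvalues=pv,
        eligible=elig,
        mass=mass,
    )


def _apply_fdr(res: PivotResult) -> None:
    """BH over the (other motif, bin) tests passing the candidate filter."""
    fdr = np.full_like(res.pvalues, np.nan)
    sel = res.eligible
    if sel.any():
        fdr[sel] = bh_fdr(res.pvalues[sel])
    res.fdr = fdr


def call_pairs(
    results: dict,
    fdr_cut: float = 0.05,
    min_weighted: float = 10.0,
) -> pd.DataFrame:
    """Final reciprocal pair calls from per-(stage, pivot) results.

    ``results[stage][pivot]`` must be a :class:`PivotResult`. A pair (A, B)
    is called in a stage iff the first distance bin has BH FDR <= fdr_cut
    with A as pivot and with B as pivot, and the smaller of the two
    first-bin weighted counts is >= min_weighted. The output is symmetric
    in (A, B); motif_a < motif_b lexicographically.
    """
    rows = []
    for stage, by_pivot in results.items():
        for res in by_pivot.values():
            if res.fdr is None:
                _apply_fdr(res)
        for a, b in itertools.combinations(sorted(by_pivot), 2):
            ra, rb = by_pivot[a], by_pivot[b]
            ia, ib = ra.motifs.index(b), rb.motifs.index(a)
            real_ab, real_ba = ra.real[ia, 0], rb.real[ib, 0]
            fdr_ab, fdr_ba = ra.fdr[ia, 0], rb.fdr[ib, 0]
            null_mean = 0.5 * (ra.null_mean[ia, 0] + rb.null_mean[ib, 0])
            real_mean = 0.5 * (real_ab + real_ba)
            reciprocal = (
                np.isfinite(fdr_ab) and np.isfinite(fdr_ba)
                and fdr_ab <= fdr_cut and fdr_ba <= fdr_cut
            )
            rows.append(
                {
                    "motif_a": a,
                    "motif_b": b,
                    "stage": stage,
                    "bin": 0,
                    "real_count": min(real_ab, real_ba),
                    "real_count_mean": real_mean,
                    "null_mean": null_mean,
                    "null_sd": 0.5 * (ra.null_sd[ia, 0] + rb.null_sd[ib, 0]),
                    "empirical_p": max(ra.pvalues[ia, 0], rb.pvalues[ib, 0]),
                    "fdr": max(fdr_ab, fdr_ba) if reciprocal else np.nan,
                    "reciprocal": bool(reciprocal),
                    "enrichment_ratio": real_mean / null_mean if null_mean > 0 else np.nan,
                    "called": bool(reciprocal and min(real_ab, real_ba) >= min_weighted),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["stage", "motif_a", "motif_b"], kind="stable").reset_index(drop=True)
    return table


def stage_enrichment_ratio(real_first_bin: dict, null_mean_first_bin: dict):
    """Per-stage enrichment ratios (real/null first-bin weighted counts) and
    the ratios centered by their mean over stages.

    Stages with a zero null mean are excluded with a warning.
    """
    ratios = {}
    for stage, real in real_first_bin.items():
        nm = null_mean_first_bin[stage]
        if nm <= 0:
            warnings.warn(f"stage {stage}: null mean 0, enrichment ratio undefined")
            continue
        ratios[stage] = real / nm
    if not ratios:
        return {}, {}
    mean = float(np.mean(list(ratios.values())))
    centered = {s: (r / mean if mean > 0 else np.nan) for s, r in ratios.items()}
    return ratios, centered


def edge_swap_randomize(edges, n_swaps: int, rng, directed: bool = False,
                        max_tries: int | None = None) -> list:
    """Degree-preserving edge-swap randomization of a simple network.

    Two edges (a, b), (c, d) are rewired to (a, d), (c, b); swaps creating
    self-loops or duplicate edges are rejected. ``n_swaps`` accepted swaps
    are performed (or until ``max_tries`` proposals, whichever first, so
    rigid networks such as stars terminate). Undirected edges are treated
    as unordered pairs; directed swaps preserve in- and out-degrees.
    """
    edges = [tuple(e) for e in edges]
    if len(edges) < 2:
        return list(edges)

    def norm(e):
        return e if directed else tuple(sorted(e))

    present = {norm(e) for e in edges}
    if len(present) != len(edges):
        raise ValueError("duplicate edges in input network")
    if any(a == b for a, b in edges):
        raise ValueError("self-loops in input network")
    if max_tries is None:
        max_tries = 100 * n_swaps + 100
    accepted = tries = 0
    while accepted < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.choice(len(edges), size=2, replace=False)
        (a, b), (c, d) = edges[i], edges[j]
        if directed or rng.random() < 0.5:
            e1, e2 = (a, d), (c, b)
        else:
            # undirected graphs admit a second valid pairing
            e1, e2 = (a, c), (b, d)
        if e1[0] == e1[1] or e2[0] == e2[1]:
            continue
        if norm(e1) in present or norm(e2) in present or norm(e1) == norm(e2):
            continue
        present.discard(norm(edges[i]))
        present.discard(norm(edges[j]))
        present.add(norm(e1))
        present.add(norm(e2))
        edges[i], edges[j] = e1, e2
        accepted += 1
    return edges


def pivot_rng(master_seed: int, stage: str, pivot: str):
    """Deterministic per-(stage, pivot) RNG stream derived from the master seed
    by stable hashing, so per-pivot work units are order-independent."""
    key = zlib.crc32(f"{stage}:{pivot}".encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(key,)))


@dataclass
class ColocResult:
    """Output of a full multi-stage co-localization run."""

    table: pd.DataFrame  # one row per (pair, stage)
    calls: pd.DataFrame  # called subset
    results: dict  # stage -> pivot -> PivotResult

    def pair_stage_ratios(self, motif_a: str, motif_b: str):
        """Per-stage enrichment ratios and centered ratios for one pair."""
        sub = self.table[(self.table["motif_a"] == motif_a) & (self.table["motif_b"] == motif_b)]
        real = dict(zip(sub["stage"], sub["real_count_mean"]))
        null = dict(zip(sub["stage"], sub["null_mean"]))
        return stage_enrichment_ratio(real, null)


def run_colocalization(
    sites: pd.DataFrame,
    comp_of_motif: dict,
    stages: list[str],
    n_rand: int = 10000,
    master_seed: int = 0,
    floor_percentile: float = 0.6,
    fdr_cut: float = 0.05,
    min_weighted: float = 10.0,
    max_dist: int = MAX_DIST,
    min_fraction: float = 0.01,
) -> ColocResult:
    """Run the pair analysis for every stage and pivot motif.

    ``sites`` must carry percentile and per-stage ``acc_<stage>`` columns;
    the analyzed set per stage is percentile >= floor and accessible in the
    stage. Each (stage, pivot) unit gets its own seeded RNG stream.
    """
    results: dict = {}
    for stage in stages:
        sub = sites.loc[
            (sites["percentile"] >= floor_percentile) & sites[f"acc_{stage}"]
        ].reset_index(drop=True)
        results[stage] = {}
        for pivot in sorted(sub["motif_id"].unique()):
            rng = pivot_rng(master_seed, stage, pivot)
            results[stage][pivot] = analyze_pivot(
                sub, pivot, comp_of_motif, n_rand, rng,
                max_dist=max_dist, min_fraction=min_fraction,
            )
    table = call_pairs(results, fdr_cut=fdr_cut, min_weighted=min_weighted)
    calls = table.loc[table["called"]].reset_index(drop=True) if len(table) else table
    return ColocResult(table=table, calls=calls, results=results)
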