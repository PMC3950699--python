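"""Assessment machinery for predicted sites and called motif pairs.

Covers TF -> target-gene network construction around transcription start
sites, GO-term enrichment ratios, ChIP bound-region overlap percentages,
ChIP- and conservation-based category comparisons for called pairs, and
curated-network overlap enrichment against edge-swapped nulls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from comotif.colocalization import edge_swap_randomize
from comotif.intervals import IntervalSet, overlaps_any


def build_network(sites: pd.DataFrame, tss_table: pd.DataFrame, window: int = 2000) -> pd.DataFrame:
    """Regulator -> gene edges: a motif regulates a gene iff one of its sites
    lies within +/-``window`` nt of the gene's TSS (symmetric, strand-ignorant).

    ``tss_table`` columns: gene, chrom, position (0-based), strand.
    Returns a simple edge table (regulator, gene) without duplicates.
    """
    edges = set()
    tss_sorted = tss_table.sort_values(["chrom", "position"], kind="stable")
    for chrom, sub in sites.groupby("chrom"):
        genes = tss_sorted.loc[tss_sorted["chrom"] == chrom]
        if len(genes) == 0:
            continue
        pos = genes["position"].to_numpy()
        names = genes["gene"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        motifs = sub["motif_id"].to_numpy()
        # TSS within [start - window, end - 1 + window]
        lo = np.searchsorted(pos, starts - window, side="left")
        hi = np.searchsorted(pos, ends - 1 + window, side="right")
        for m, a, b in zip(motifs, lo, hi):
            for g in names[a:b]:
                edges.add((m, g))
    return pd.DataFrame(sorted(edges), columns=["regulator", "gene"])


def filter_annotations(gene_terms: pd.DataFrame, min_genes: int = 5, max_genes: int = 1000) -> pd.DataFrame:
    """Keep terms annotating more than ``min_genes`` and fewer than ``max_genes`` genes."""
    counts = gene_terms.groupby("term")["gene"].nunique()
    keep = counts[(counts > min_genes) & (counts < max_genes)].index
    return gene_terms.loc[gene_terms["term"].isin(keep)].reset_index(drop=True)


def go_enrichment(
    network: pd.DataFrame,
    annotations: pd.DataFrame,
    tf_terms: dict,
) -> tuple[pd.DataFrame, float]:
    """Functional-coherence enrichment ratios between TFs and their targets.

    For each regulator and each term annotating it (``tf_terms[regulator]``),
    ratio = (fraction of the regulator's target genes annotated with the
    term) / (fraction of non-target genes, restricted to genes with at
    least one annotation, annotated with the term). Ratios with a zero
    denominator are +inf and excluded from the summary median (count of
    exclusions is warned about).
    """
    ann_genes = annotations.groupby("gene")["term"].apply(set)
    rows = []
    n_inf = 0
    for tf, targets in network.groupby("regulator")["gene"]:
        terms = tf_terms.get(tf, set())
        if not terms:
            continue
        tset = set(targets)
        target_ann = [ann_genes.get(g, set()) for g in sorted(tset)]
        bg_genes = [g for g in ann_genes.index if g not in tset]
        if not target_ann or not bg_genes:
            continue
        for term in sorted(terms):
            f_t = np.mean([term in s for s in target_ann])
            f_b = np.mean([term in ann_genes[g] for g in bg_genes])
            ratio = f_t / f_b if f_b > 0 else np.inf
            if not np.isfinite(ratio):
                n_inf += 1
            rows.append({"regulator": tf, "term": term, "ratio": ratio})
    df = pd.DataFrame(rows, columns=["regulator", "term", "ratio"])
    finite = df.loc[np.isfinite(df["ratio"]), "ratio"]
    if n_inf:
        warnings.warn(f"{n_inf} enrichment ratios were infinite and excluded from the median")
    median = float(finite.median()) if len(finite) else np.nan
    return df, median


def chip_percent(sites: pd.DataFrame, bound_regions: IntervalSet) -> float:
    """Percent of sites overlapping any bound region by >= 1 nt; NaN when empty."""
    if len(sites) == 0:
        warnings.warn("chip_percent of zero sites is undefined")
        return np.nan
    hit = np.zeros(len(sites), dtype=bool)
    chroms = sites["chrom"].to_numpy()
    for c, merged in bound_regions.items():
        m = chroms == c
        if m.any():
            hit[m] = overlaps_any(sites["start"].to_numpy()[m], sites["end"].to_numpy()[m], merged)
    return 100.0 * float(hit.mean())


def _has_neighbor(tf_sites: pd.DataFrame, other: pd.DataFrame, window: int) -> np.ndarray:
    """Per TF site: any ``other`` site within ``window`` nt (edge gap)."""
    out = np.zeros(len(tf_sites), dtype=bool)
    for i, row in enumerate(tf_sites.itertuples(index=False)):
        o = other.loc[other["chrom"] == row.chrom]
        if len(o) == 0:
            continue
        gap = np.maximum(
            0, np.maximum(o["start"].to_numpy() - row.end, row.start - o["end"].to_numpy())
        )
        out[i] = bool((gap <= window).any())
    return out


def pair_categories(
    tf: str, sites: pd.DataFrame, partners: set, window: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a TF's sites into partner-adjacent and other-adjacent categories.

    Category 1: sites with a site of a called partner motif within
    ``window`` nt. Category 2: sites with some other-motif site within the
    window but no called partner.
    """
    tf_sites = sites.loc[sites["motif_id"] == tf].reset_index(drop=True)
    partner_sites = sites.loc[sites["motif_id"].isin(partners)]
    other_sites = sites.loc[~sites["motif_id"].isin(partners | {tf})]
    near_partner = _has_neighbor(tf_sites, partner_sites, window)
    near_other = _has_neighbor(tf_sites, other_sites, window)
    cat1 = tf_sites.loc[near_partner]
    cat2 = tf_sites.loc[near_other & ~near_partner]
    return cat1, cat2


def pair_category_assessment(
    sites: pd.DataFrame,
    calls: pd.DataFrame,
    bound_regions_by_tf: dict,
    window: int = 100,
    n_rand: int = 1000,
    rng=None,
) -> pd.DataFrame:
    """ChIP-support difference between partner-adjacent and other-adjacent sites.

    For each TF with bound regions, difference = chip_percent(category 1) -
    chip_percent(category 2); the significance of the median difference is
    assessed against call networks randomized by degree-preserving edge
    swapping (empirical p over ``n_rand`` randomizations).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    edges = list(zip(calls["motif_a"], calls["motif_b"]))

    def differences(edge_list):
        partner_map: dict = {}
        for a, b in edge_list:
            partner_map.setdefault(a, set()).add(b)
            partner_map.setdefault(b, set()).add(a)
        diffs = {}
        for tf, regions in bound_regions_by_tf.items():
            cat1, cat2 = pair_categories(tf, sites, partner_map.get(tf, set()), window)
            if len(cat1) == 0 or len(cat2) == 0:
                continue
            diffs[tf] = chip_percent(cat1, regions) - chip_percent(cat2, regions)
        return diffs

    real = differences(edges)
    rows = [{"tf": tf, "difference": d} for tf, d in sorted(real.items())]
    out = pd.DataFrame(rows, columns=["tf", "difference"])
    if len(out) and len(edges) >= 2 and n_rand > 0:
        real_median = float(np.median(out["difference"]))
        null_medians = []
        for _ in range(n_rand):
            swapped = edge_swap_randomize(edges, n_swaps=max(1, len(edges)), rng=rng)
            nd = differences(swapped)
            if nd:
                null_medians.append(float(np.median(list(nd.values()))))
        if null_medians:
            p = float(np.mean([m >= real_median for m in null_medians]))
            out.attrs["median_difference"] = real_median
            out.attrs["null_median_mean"] = float(np.mean(null_medians))
            out.attrs["empirical_p"] = p
    return out


def conservation_pair_assessment(
    sites: pd.DataFrame,
    motif_a: str,
    motif_b: str,
    window: int = 100,
    threshold: float = 0.8,
) -> dict:
    """Conservation support for one called pair, on unfiltered site predictions.

    Categories: (i) A sites with a B site within the window; (ii) A sites
    with a non-B site within the window; (iii) B sites with a non-A site
    within the window. For each, the fraction of site pairs where both
    percentiles >= threshold, plus differences (i)-(ii) and (i)-(iii).
    Empty categories yield NaN fractions.
    """

    def _fraction(pivot_motif: str, target_motifs: set, exclude: set) -> float:
        piv = sites.loc[sites["motif_id"] == pivot_motif]
        if target_motifs:
            oth = sites.loc[sites["motif_id"].isin(target_motifs)]
        else:
            oth = sites.loc[~sites["motif_id"].isin(exclude)]
        vals = []
        for row in piv.itertuples(index=False):
            o = oth.loc[oth["chrom"] == row.chrom]
            if len(o) == 0:
                continue
            gap = np.maximum(
                0, np.maximum(o["start"].to_numpy() - row.end, row.start - o["end"].to_numpy())
            )
            near = o.loc[gap <= window]
            for orow in near.itertuples(index=False):
                vals.append(row.percentile >= threshold and orow.percentile >= threshold)
        return float(np.mean(vals)) if vals else np.nan

    f1 = _fraction(motif_a, {motif_b}, set())
    f2 = _fraction(motif_a, set(), {motif_a, motif_b})
    f3 = _fraction(motif_b, set(), {motif_a, motif_b})
    return {
        "frac_ab": f1,
        "frac_a_other": f2,
        "frac_b_other": f3,
        "diff_ab_vs_a_other": f1 - f2 if np.isfinite(f1) and np.isfinite(f2) else np.nan,
        "diff_ab_vs_b_other": f1 - f3 if np.isfinite(f1) and np.isfinite(f3) else np.nan,
    }


def overlap_enrichment(
    network: pd.DataFrame,
    curated: pd.DataFrame,
    n_rand: int = 1000,
    rng=None,
) -> dict:
    """Overlap of a predicted network with a curated one, against edge-swapped nulls.

    enrichment = |edges intersect curated| / mean over ``n_rand``
    edge-swapped curated networks of the analogous overlap; the empirical p
    is the fraction of swapped overlaps >= the real overlap. A zero
    expected overlap leaves the enrichment undefined (NaN).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pred = set(map(tuple, network[["regulator", "gene"]].itertuples(index=False)))
    cur_edges = list(map(tuple, curated[["regulator", "gene"]].itertuples(index=False)))
    real = len(pred & set(cur_edges))
    null = []
    for _ in range(n_rand):
        swapped = edge_swap_randomize(cur_edges, n_swaps=max(1, len(cur_edges)), rng=rng, directed=True)
        null.append(len(pred & set(swapped)))
    expected = float(np.mean(null))
    if expected == 0:
        warnings.warn("expected overlap is 0; enrichment undefined")
        enrichment = np.nan
    else:
        enrichment = real / expected
    p = float(np.mean([x >= real for x in null]))
    return {"overlap": real, "expected": expected, "enrichment": enrichment, "empirical_p": p}
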