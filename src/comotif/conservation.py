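"""Cross-species conservation of predicted binding sites.

A site on the reference genome is considered conserved in another species
when that species' alignment row contains a PWM match (either strand, same
p-value threshold) starting within a small offset (default +/-10 alignment
columns) of the site. The matched species define a minimal spanning subtree
of the phylogeny; the branch length score (BLS) is that subtree's total
branch length as a fraction of the whole tree. Per motif, BLS values are
converted to conservation percentiles (fraction of that motif's sites with
strictly smaller BLS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from comotif.motifs import PWM
from comotif.scan import ScoreModel, encode_sequence, match_starts


class ReferencePhylogeny:
    """Rooted tree with branch lengths and a designated reference leaf.

    Precomputes per-edge leaf bitmasks so BLS evaluation is O(#edges), plus
    the patristic distance of every leaf from the reference and the derived
    distance ranks (ties broken by species name) used by distant-match
    pruning.
    """

    def __init__(self, tree: "dendropy.Tree | str", reference: str):
        if isinstance(tree, str):
            tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
        self.tree = tree
        self.species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        if reference not in self.species:
            raise ValueError(f"reference {reference!r} is not a leaf of the tree")
        self.reference = reference
        self._bit = {s: 1 << i for i, s in enumerate(self.species)}
        # postorder bitmask of leaves below each node; edges = (below_mask, length)
        below = {}
        edges = []
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = self._bit[node.taxon.label]
            else:
                below[node] = 0
                for ch in node.child_nodes():
                    below[node] |= below[ch]
            if node.parent_node is not None:
                length = node.edge.length or 0.0
                if length < 0:
                    raise ValueError("negative branch length")
                edges.append((below[node], float(length)))
        self.edges = edges
        self.total_length = float(sum(l for _, l in edges))
        if self.total_length <= 0:
            raise ValueError("total branch length must be > 0")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        self.distance = {
            s: float(pdm.patristic_distance(taxa[reference], taxa[s])) for s in self.species
        }
        ranked = sorted(self.species, key=lambda s: (self.distance[s], s))
        if ranked[0] != reference:  # reference has distance 0; keep it first
            ranked.remove(reference)
            ranked.insert(0, reference)
        self.rank = {s: i for i, s in enumerate(ranked)}
        self.by_rank = ranked
        self._bls_cache: dict[int, float] = {}

    def mask(self, species) -> int:
        m = 0
        for s in species:
            m |= self._bit[s]
        return m

    def bls_mask(self, mask: int) -> float:
        """BLS of the leaf set encoded as a bitmask."""
        cached = self._bls_cache.get(mask)
        if cached is not None:
            return cached
        n = bin(mask).count("1")
        if n <= 1:
            self._bls_cache[mask] = 0.0
            return 0.0
        total = 0.0
        for below, length in self.edges:
            k = bin(below & mask).count("1")
            if 0 < k < n:
                total += length
        val = total / self.total_length
        self._bls_cache[mask] = val
        return val


def branch_length_score(matched, tree: ReferencePhylogeny) -> float:
    """Total branch length of the minimal subtree spanning ``matched`` leaves,
    as a fraction of the whole tree. 0.0 when only the reference matched."""
    matched = set(matched)
    if tree.reference not in matched:
        raise ValueError("matched set must contain the reference species")
    unknown = matched - set(tree.species)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}")
    return tree.bls_mask(tree.mask(matched))


def prune_distant_match(
    matched, tree: ReferencePhylogeny, max_gap: int = 4, distance_ratio: float = 2.0
) -> set[str]:
    """Drop an isolated most-distant match that is likely spurious.

    Species are ranked by patristic distance from the reference. With m1 and
    m2 the most and second-most distant matched species, m1 is removed iff
    more than ``max_gap`` unmatched species lie strictly between their ranks
    and the reference distance of m1 exceeds ``distance_ratio`` times that
    of m2. At most one species is ever removed.
    """
    matched = set(matched)
    if tree.reference not in matched:
        raise ValueError("matched set must contain the reference species")
    others = sorted(matched - {tree.reference}, key=lambda s: tree.rank[s])
    if len(others) < 2:
        return matched
    m1, m2 = others[-1], others[-2]
    # every species ranked strictly between m2 and m1 is unmatched by
    # construction (m1, m2 are the two most distant matches)
    gap = tree.rank[m1] - tree.rank[m2] - 1
    if gap > max_gap and tree.distance[m1] > distance_ratio * tree.distance[m2]:
        matched.discard(m1)
    return matched


@dataclass
class AlignmentBlock:
    """One aligned region: equal-length per-species rows in reference coordinates.

    ``rows[species]`` is the gapped row ('-' for gaps); the reference row's
    ungapped positions map bijectively onto [ref_start, ref_start + n).
    """

    chrom: str
    ref_start: int
    rows: dict[str, str]
    reference: str

    _col_of_ref: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        lens = {len(r) for r in self.rows.values()}
        if len(lens) != 1:
            raise ValueError("alignment rows must have equal length")
        ref_row = self.rows[self.reference]
        self._col_of_ref = np.nonzero(np.frombuffer(ref_row.encode(), dtype=np.uint8) != ord("-"))[0]

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self._col_of_ref)

    def column_of(self, ref_pos: int) -> int:
        """Alignment column of a reference coordinate."""
        i = ref_pos - self.ref_start
        if not 0 <= i < len(self._col_of_ref):
            raise ValueError(f"position {ref_pos} outside block")
        return int(self._col_of_ref[i])

    def species_match_columns(self, species: str, model: ScoreModel, p_threshold: float) -> np.ndarray:
        """Sorted alignment columns where the species row has a PWM match (either strand)."""
        row = self.rows.get(species)
        if row is None:
            return np.empty(0, dtype=np.int64)
        codes_gapped = np.frombuffer(row.encode(), dtype=np.uint8)
        keep = np.nonzero(codes_gapped != ord("-"))[0]
        if len(keep) < model.width:
            return np.empty(0, dtype=np.int64)
        ungapped = encode_sequence(row.replace("-", ""))
        starts = match_starts(model, ungapped, p_threshold)
        return keep[starts]


def find_conserved_instances(
    site,
    block: AlignmentBlock,
    pwm: PWM,
    tree: ReferencePhylogeny,
    offset: int = 10,
    p_threshold: float = 1e-4,
    model: ScoreModel | None = None,
) -> set[str]:
    """Species whose rows carry a match within +/- ``offset`` alignment columns
    of the site start. The reference is always included.

    ``site`` needs attributes/keys ``start`` (and ``chrom`` matching the block).
    """
    start = site["start"] if isinstance(site, dict) else site.start
    col = block.column_of(int(start))
    model = model or ScoreModel(pwm, background=np.full(4, 0.25))
    matched = {tree.reference}
    for sp in tree.species:
        if sp == tree.reference:
            continue
        cols = block.species_match_columns(sp, model, p_threshold)
        lo = np.searchsorted(cols, col - offset, side="left")
        hi = np.searchsorted(cols, col + offset, side="right")
        if hi > lo:
            matched.add(sp)
    return matched


def annotate_conservation(
    sites: pd.DataFrame,
    blocks: dict[str, AlignmentBlock],
    pwm: PWM,
    tree: ReferencePhylogeny,
    model: ScoreModel,
    offset: int = 10,
    p_threshold: float = 1e-4,
    prune: bool = True,
) -> pd.DataFrame:
    """Add matched species sets and BLS for every site of one motif.

    Distant-match pruning (see :func:`prune_distant_match`) is applied
    before BLS by default.
    """
    sites = sites.copy()
    if len(sites) == 0:
        sites["n_species"] = pd.Series(dtype=int)
        sites["bls"] = pd.Series(dtype=float)
        return sites
    species = [s for s in tree.species if s != tree.reference]
    ref_bit = tree._bit[tree.reference]
    masks = np.full(len(sites), ref_bit, dtype=np.int64)
    for chrom, idx in sites.groupby("chrom").indices.items():
        block = blocks[chrom]
        cols = np.array([block.column_of(p) for p in sites["start"].to_numpy()[idx]])
        for sp in species:
            mcols = block.species_match_columns(sp, model, p_threshold)
            lo = np.searchsorted(mcols, cols - offset, side="left")
            hi = np.searchsorted(mcols, cols + offset, side="right")
            masks[idx[hi > lo]] |= tree._bit[sp]
    if prune:
        masks = _prune_masks(masks, tree)
    bls = np.array([tree.bls_mask(int(m)) for m in masks])
    sites["n_species"] = [bin(int(m)).count("1") for m in masks]
    sites["bls"] = bls
    return sites


def _prune_masks(masks: np.ndarray, tree: ReferencePhylogeny) -> np.ndarray:
    """Vectorized-ish distant-match pruning on bitmask rows (cached per mask)."""
    cache: dict[int, int] = {}
    out = np.empty_like(masks)
    for i, m in enumerate(masks):
        m = int(m)
        r = cache.get(m)
        if r is None:
            matched = {s for s in tree.species if m & tree._bit[s]}
            matched.add(tree.reference)
            r = tree.mask(prune_distant_match(matched, tree))
            cache[m] = r
        out[i] = r
    return out


def conservation_percentiles(sites: pd.DataFrame, by: str = "motif_id") -> pd.DataFrame:
    """Per motif, percentile = fraction of that motif's sites with strictly
    smaller BLS; values lie in [0, 1)."""
    sites = sites.copy()
    def _pct(x):
        return (rankdata(x, method="min") - 1) / len(x)
    sites["percentile"] = sites.groupby(by)["bls"].transform(_pct)
    return sites


def top_conserved(sites: pd.DataFrame, fraction: float = 0.2) -> pd.DataFrame:
    """Keep, per motif, sites with conservation percentile >= 1 - fraction."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return sites.loc[sites["percentile"] >= 1.0 - fraction].reset_index(drop=True)
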