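"""PWM representation, information content, similarity and clustering.

A PWM is a per-column base-frequency model of a TF's binding preference.
This module covers: column information content (IC), IC-based edge trimming,
an IC-weighted Pearson-correlation similarity between PWMs with
end-gap penalties, average-linkage clustering of similar PWMs, clustering of
motif clusters by base-pair composition (the strata used by the
co-localization null), and ChIP/accessibility-driven selection of one PWM
per TF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch

from comotif.intervals import IntervalSet, overlap_fraction

BASES = "ACGT"
#: index permutation implementing A<->T, C<->G
RC = np.array([3, 2, 1, 0])

#: genome-wide mononucleotide background of the D. melanogaster genome
FLY_BACKGROUND = np.array([0.2887, 0.2115, 0.2111, 0.2886])
UNIFORM_BACKGROUND = np.full(4, 0.25)


class EmptyMotifError(ValueError):
    """Raised when trimming removes every column of a PWM."""


def _validate_freqs(freqs: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape[-1] != 4:
        raise ValueError(f"expected 4 base frequencies, got shape {freqs.shape}")
    if np.any(freqs < -tol) or np.any(freqs > 1 + tol):
        raise ValueError("frequencies must lie in [0, 1]")
    sums = freqs.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-4):
        raise ValueError(f"columns must sum to 1 (got {sums})")
    return np.clip(freqs, 0.0, 1.0)


def column_ic(freqs) -> float:
    """Information content of one PWM column: ``2 + sum_i p_i log2 p_i`` bits.

    ``0 * log2(0)`` is taken as 0; the result lies in [0, 2].
    """
    p = _validate_freqs(np.asarray(freqs, dtype=float))
    nz = p[p > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def _column_ics(matrix: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(matrix > 0, matrix * np.log2(np.where(matrix > 0, matrix, 1.0)), 0.0)
    return 2.0 + t.sum(axis=1)


@dataclass
class PWM:
    """Position weight matrix: ordered base-frequency columns (A, C, G, T)."""

    motif_id: str
    tf_name: str
    matrix: np.ndarray  # shape (width, 4)

    def __post_init__(self):
        m = _validate_freqs(np.atleast_2d(np.asarray(self.matrix, dtype=float)))
        if m.shape[0] < 1:
            raise EmptyMotifError(f"{self.motif_id}: PWM must have at least one column")
        self.matrix = m

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def column_ics(self) -> np.ndarray:
        return _column_ics(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.tf_name, self.matrix[::-1, RC])

    def composition(self) -> np.ndarray:
        """Mean base frequency over columns."""
        return self.matrix.mean(axis=0)


def trim_pwm(pwm: PWM, ic_threshold: float = 0.2) -> PWM:
    """Strip leading/trailing low-information columns (IC < threshold).

    Interior columns are never removed; idempotent. Raises
    :class:`EmptyMotifError` if no column reaches the threshold.
    """
    ics = pwm.column_ics()
    keep = np.nonzero(ics >= ic_threshold)[0]
    if len(keep) == 0:
        raise EmptyMotifError(f"{pwm.motif_id}: all columns below IC {ic_threshold}")
    return PWM(pwm.motif_id, pwm.tf_name, pwm.matrix[keep[0] : keep[-1] + 1])


def _pcc(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two 4-vectors; 0 if either has zero variance."""
    du = u - u.mean()
    dv = v - v.mean()
    nu = np.sqrt((du * du).sum())
    nv = np.sqrt((dv * dv).sum())
    if nu < 1e-12 or nv < 1e-12:
        return 0.0
    return float((du * dv).sum() / (nu * nv))


def _weighted_pcc_one(mx, my, icx, icy, offset, min_overlap):
    """IC-weighted PCC for one end-gapped alignment of y against x.

    Column j of y is aligned with column offset + j of x. Matched columns
    weigh sqrt(icx * icy) and contribute their PCC; overhanging end columns
    weigh ic/2 and contribute 0 (a pure penalty).
    """
    wx, wy = len(mx), len(my)
    lo = max(0, offset)
    hi = min(wx, offset + wy)
    if hi - lo < min_overlap:
        return None
    num = 0.0
    den = 0.0
    for i in range(lo, hi):
        w = np.sqrt(icx[i] * icy[i - offset])
        num += w * _pcc(mx[i], my[i - offset])
        den += w
    for i in range(0, lo):
        den += icx[i] / 2.0
    for i in range(hi, wx):
        den += icx[i] / 2.0
    for j in range(0, lo - offset):
        den += icy[j] / 2.0
    for j in range(hi - offset, wy):
        den += icy[j] / 2.0
    if den < 1e-12:
        return None
    return num / den


def pwm_similarity(x: PWM, y: PWM, min_overlap: int = 2) -> float:
    """Maximum IC-weighted column PCC over all end-gapped offsets and both orientations.

    Columns with higher IC dominate the score; unmatched end columns are
    penalized with weight IC/2 in the denominator. Offsets with fewer than
    ``min_overlap`` matched columns are skipped (PCC of a single column pair
    is already defined on 4 frequencies, but a 2-column minimum avoids
    spuriously perfect one-column matches). Returns 0 with a warning when
    every alignment has zero total weight (fully uniform PWMs).
    """
    mx, icx = x.matrix, x.column_ics()
    best = None
    for y_or in (y, y.reverse_complement()):
        my, icy = y_or.matrix, y_or.column_ics()
        for offset in range(-(y_or.width - 1), x.width):
            s = _weighted_pcc_one(mx, my, icx, icy, offset, min_overlap)
            if s is not None and (best is None or s > best):
                best = s
    if best is None:
        warnings.warn(
            f"pwm_similarity({x.motif_id}, {y.motif_id}): zero total IC weight, returning 0"
        )
        return 0.0
    return float(best)


@dataclass
class MotifCluster:
    """A flat cluster of PWMs with similar binding specificity."""

    cluster_id: int
    members: tuple[str, ...]  # motif_ids
    representative: str  # motif_id of representative member
    centroid: PWM

    @property
    def name(self) -> str:
        return f"{self.centroid.tf_name}_{self.cluster_id}"


def centroid_pwm(pwms: list[PWM], anchor: PWM | None = None) -> PWM:
    """Average member PWMs over their shared columns.

    Each member is aligned to the anchor (default: first member) at its
    best-scoring offset/orientation; columns of the anchor covered by every
    member are averaged. If no column is shared by all members the anchor's
    own matrix is returned.
    """
    if anchor is None:
        anchor = pwms[0]
    if len(pwms) == 1:
        return PWM(anchor.motif_id, anchor.tf_name, anchor.matrix)
    wx = anchor.width
    cover = np.zeros(wx, dtype=int)
    acc = np.zeros((wx, 4))
    mx, icx = anchor.matrix, anchor.column_ics()
    for p in pwms:
        best, best_align = -np.inf, None
        for orient in (p, p.reverse_complement()):
            my, icy = orient.matrix, orient.column_ics()
            for offset in range(-(orient.width - 1), wx):
                s = _weighted_pcc_one(mx, my, icx, icy, offset, 2)
                if s is not None and s > best:
                    best, best_align = s, (orient, offset)
        if best_align is None:
            continue
        orient, offset = best_align
        lo, hi = max(0, offset), min(wx, offset + orient.width)
        acc[lo:hi] += orient.matrix[lo - offset : hi - offset]
        cover[lo:hi] += 1
    shared = cover == len(pwms)
    if not shared.any():
        return PWM(anchor.motif_id, anchor.tf_name, anchor.matrix)
    idx = np.nonzero(shared)[0]
    mat = acc[idx[0] : idx[-1] + 1] / cover[idx[0] : idx[-1] + 1, None]
    mat = mat / mat.sum(axis=1, keepdims=True)
    return PWM(anchor.motif_id, anchor.tf_name, mat)


def similarity_matrix(pwms: list[PWM]) -> np.ndarray:
    n = len(pwms)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = pwm_similarity(pwms[i], pwms[j])
    return sim


def cluster_pwms(pwms: list[PWM], cut: float = 0.8, sim: np.ndarray | None = None) -> list[MotifCluster]:
    """Average-linkage hierarchical clustering of PWMs, cut at similarity >= ``cut``.

    Flat clusters are the maximal subtrees whose merge similarities are all
    >= ``cut`` (equivalently: fcluster at cophenetic distance 1 - cut on
    1 - similarity). Singletons are allowed.
    """
    if len(pwms) == 0:
        raise ValueError("need at least one PWM")
    order = np.argsort([p.motif_id for p in pwms])
    pwms = [pwms[i] for i in order]
    if sim is not None:
        sim = np.asarray(sim)[np.ix_(order, order)]
    else:
        sim = similarity_matrix(pwms)
    n = len(pwms)
    if n == 1:
        labels = np.array([1])
    else:
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        condensed = dist[np.triu_indices(n, 1)]
        Z = sch.linkage(np.maximum(condensed, 0.0), method="average")
        labels = sch.fcluster(Z, t=1.0 - cut, criterion="distance")
    clusters = []
    for cid in sorted(set(labels), key=lambda c: min(pwms[i].motif_id for i in np.nonzero(labels == c)[0])):
        idx = np.nonzero(labels == cid)[0]
        members = [pwms[i] for i in idx]
        rep = min(members, key=lambda p: (p.tf_name, p.motif_id))
        clusters.append(
            MotifCluster(
                cluster_id=len(clusters),
                members=tuple(p.motif_id for p in members),
                representative=rep.motif_id,
                centroid=centroid_pwm(members, anchor=rep),
            )
        )
    return clusters


@dataclass
class CompositionCluster:
    """Motif clusters grouped by background-subtracted base composition."""

    comp_id: int | str  # integer label or "others"
    members: tuple[int, ...]  # cluster_ids
    composition: dict[int, np.ndarray] = field(default_factory=dict)


def composition_clusters(
    clusters: list[MotifCluster],
    background: np.ndarray = FLY_BACKGROUND,
    cut: float = 0.8,
    min_members: int = 5,
    exclude_fraction: float = 0.10,
) -> list[CompositionCluster]:
    """Group motif clusters by similarity of their base-pair composition.

    The composition of a cluster is the column-mean of its centroid PWM with
    the genomic background subtracted. Clusters whose composition standard
    deviation falls in the bottom ``exclude_fraction`` (weak base
    preference; strict rank, ties broken by cluster id) go to "others".
    The remainder are average-linkage clustered on
    ``max(PCC(u, v), PCC(u, revcomp(v)))`` cut at ``cut``; resulting groups
    with fewer than ``min_members`` members are merged into "others".
    """
    background = np.asarray(background, dtype=float)
    if abs(background.sum() - 1.0) > 1e-3:
        raise ValueError("background must sum to 1")
    comp = {c.cluster_id: c.centroid.composition() - background for c in clusters}
    ids = sorted(comp)
    stds = {i: float(np.std(comp[i])) for i in ids}
    n_excl = int(np.floor(exclude_fraction * len(ids)))
    by_std = sorted(ids, key=lambda i: (stds[i], i))
    others = set(by_std[:n_excl])
    rest = [i for i in ids if i not in others]

    groups: list[list[int]] = []
    if len(rest) < 2:
        if rest:
            warnings.warn("fewer than 2 clusters with base-pair preference; all assigned 'others'")
        others.update(rest)
    else:
        n = len(rest)
        sim = np.ones((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                u, v = comp[rest[a]], comp[rest[b]]
                sim[a, b] = sim[b, a] = max(_pcc(u, v), _pcc(u, v[RC]))
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        Z = sch.linkage(np.maximum(dist[np.triu_indices(n, 1)], 0.0), method="average")
        labels = sch.fcluster(Z, t=1.0 - cut, criterion="distance")
        for lab in sorted(set(labels), key=lambda c: min(rest[i] for i in np.nonzero(labels == c)[0])):
            g = [rest[i] for i in np.nonzero(labels == lab)[0]]
            if len(g) < min_members:
                others.update(g)
            else:
                groups.append(sorted(g))

    out = []
    for k, g in enumerate(groups):
        out.append(CompositionCluster(k, tuple(g), {i: comp[i] for i in g}))
    if others:
        out.append(CompositionCluster("others", tuple(sorted(others)), {i: comp[i] for i in others}))
    return out


def composition_assignment(comp_clusters: list[CompositionCluster]) -> dict[int, int | str]:
    """Map cluster_id -> composition-cluster label."""
    return {cid: cc.comp_id for cc in comp_clusters for cid in cc.members}


def select_pwm_per_tf(
    candidates: list[PWM],
    site_caller,
    reference_region_sets: list[IntervalSet],
) -> PWM:
    """Pick the candidate PWM whose predicted sites best overlap reference regions.

    ``site_caller(pwm)`` must return site coordinates as an iterable of
    (chrom, start, end). Each candidate is scored by the percentage of its
    sites overlapping each region set (ChIP bound regions, or top-accessible
    regions as a fallback); with several region sets the median percentage is
    used. Deterministic tie-break: lexicographically smallest motif_id.
    """
    if not candidates:
        raise ValueError("need at least one candidate PWM")
    if not reference_region_sets:
        raise ValueError("need at least one reference region set")
    tfs = {p.tf_name for p in candidates}
    if len(tfs) > 1:
        raise ValueError(f"candidates must share tf_name, got {sorted(tfs)}")
    scores = {}
    for p in candidates:
        sites = list(site_caller(p))
        if not sites:
            warnings.warn(f"{p.motif_id}: no predicted sites, score 0")
            scores[p.motif_id] = 0.0
            continue
        chroms, starts, ends = zip(*sites)
        pcts = [
            100.0 * overlap_fraction(starts, ends, rs, chroms) for rs in reference_region_sets
        ]
        scores[p.motif_id] = float(np.median(pcts))
    best = max(candidates, key=lambda p: (scores[p.motif_id], _neg_id(p.motif_id)))
    return best


def _neg_id(s: str):
    # max() helper: prefer lexicographically smaller id on score ties
    return tuple(-ord(c) for c in s)
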