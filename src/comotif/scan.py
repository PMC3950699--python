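"""PWM scanning with exact background p-value calibration.

Scores are log-odds (bits) of the window under the PWM versus an i.i.d.
mononucleotide background. The null score distribution is computed exactly
by per-column convolution of a discretized score matrix, giving a monotone
map from score to p-value; a window is reported when its p-value is at or
below the scan threshold (default 1e-4), on either strand, excluding
windows containing N.

Site tables are pandas DataFrames with 0-based half-open coordinates on the
forward strand regardless of match strand (columns: motif_id, chrom, start,
end, strand, score, pvalue).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from comotif.intervals import IntervalSet, overlaps_any
from comotif.motifs import PWM, RC, UNIFORM_BACKGROUND, MotifCluster

SITE_COLUMNS = ["motif_id", "chrom", "start", "end", "strand", "score", "pvalue"]

_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to codes A,C,G,T -> 0..3; anything else -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class ScoreModel:
    """Discretized log-odds scoring of one PWM under an i.i.d. background.

    Frequencies get a fixed pseudocount (default 1e-3, renormalized) so the
    log-odds are finite; per-column scores are discretized onto a common
    integer grid of ``granularity`` bins per column and convolved column by
    column under the background to obtain the exact null distribution of
    the discretized score.
    """

    def __init__(
        self,
        pwm: PWM,
        background: np.ndarray = UNIFORM_BACKGROUND,
        pseudocount: float = 1e-3,
        granularity: int = 1000,
    ):
        if granularity < 100:
            raise ValueError("granularity < 100 bins per column is too coarse")
        self.pwm = pwm
        self.background = np.asarray(background, dtype=float)
        freqs = pwm.matrix + pseudocount
        freqs /= freqs.sum(axis=1, keepdims=True)
        self.lod = np.log2(freqs / self.background)  # (w, 4) bits
        w = pwm.width
        self._mins = self.lod.min(axis=1)
        ranges = self.lod.max(axis=1) - self._mins
        max_range = max(ranges.max(), 1e-9)
        self.scale = (granularity - 1) / max_range
        self.int_matrix = np.rint((self.lod - self._mins[:, None]) * self.scale).astype(np.int64)
        # exact pmf of the integer score under the background
        pmf = np.array([1.0])
        for j in range(w):
            new = np.zeros(len(pmf) + self.int_matrix[j].max(), dtype=float)
            for b in range(4):
                new[self.int_matrix[j, b] : self.int_matrix[j, b] + len(pmf)] += (
                    self.background[b] * pmf
                )
            pmf = new
        self.pmf = pmf
        # survival: P(score >= s), monotone non-increasing in s
        self.sf = np.cumsum(pmf[::-1])[::-1]

    @property
    def width(self) -> int:
        return self.pwm.width

    def int_score(self, codes: np.ndarray) -> int:
        """Integer score of one width-length window of base codes."""
        return int(self.int_matrix[np.arange(self.width), codes].sum())

    def float_score(self, int_score: int) -> float:
        """Map an integer score back to (discretized) log-odds bits."""
        return float(int_score / self.scale + self._mins.sum())

    def pvalue(self, int_score) -> np.ndarray:
        s = np.clip(np.asarray(int_score, dtype=np.int64), 0, len(self.sf) - 1)
        return self.sf[s]

    def threshold_int_score(self, p_threshold: float) -> int:
        """Smallest integer score whose p-value is <= p_threshold."""
        idx = np.nonzero(self.sf <= p_threshold)[0]
        return int(idx[0]) if len(idx) else len(self.sf)

    def pvalue_table(self):
        """(float score grid, p-value) arrays for every attainable integer score."""
        grid = np.arange(len(self.sf)) / self.scale + self._mins.sum()
        return grid, self.sf.copy()


def score_pvalue_table(pwm: PWM, background=UNIFORM_BACKGROUND, granularity: int = 1000,
                       pseudocount: float = 1e-3):
    """Exact score -> p-value map for a PWM under an i.i.d. background."""
    return ScoreModel(pwm, background, pseudocount, granularity).pvalue_table()


def _window_scores(int_matrix: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer score of every window plus a validity mask (no N in window)."""
    w = int_matrix.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    safe = np.minimum(codes, 3)
    scores = np.zeros(n, dtype=np.int64)
    for j in range(w):
        scores += int_matrix[j][safe[j : j + n]]
    bad = np.cumsum(np.concatenate(([0], (codes >= 4).astype(np.int64))))
    valid = (bad[w:] - bad[:-w]) == 0
    return scores, valid


def scan_sequence(
    model: ScoreModel, seq: str | np.ndarray, chrom: str, p_threshold: float = 1e-4
) -> pd.DataFrame:
    """Scan one sequence on both strands; windows with N are skipped."""
    codes = encode_sequence(seq) if isinstance(seq, str) else seq
    thr = model.threshold_int_score(p_threshold)
    w = model.width
    rc_int = model.int_matrix[::-1][:, RC]  # scores revcomp(window) under the same model
    rows = []
    for strand, mat in (("+", model.int_matrix), ("-", rc_int)):
        scores, valid = _window_scores(mat, codes)
        hit = np.nonzero(valid & (scores >= thr))[0]
        for i in hit:
            rows.append((chrom, int(i), int(i) + w, strand, int(scores[i])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "_int"])
    df.insert(0, "motif_id", model.pwm.motif_id)
    df["score"] = [model.float_score(s) for s in df["_int"]]
    df["pvalue"] = model.pvalue(df["_int"].to_numpy()) if len(df) else []
    df = df.drop(columns="_int").sort_values(["chrom", "start", "strand"], kind="stable")
    return df.reset_index(drop=True)


def scan_genome(
    pwm: PWM,
    genome: dict[str, str],
    background=UNIFORM_BACKGROUND,
    p_threshold: float = 1e-4,
    pseudocount: float = 1e-3,
    granularity: int = 1000,
) -> pd.DataFrame:
    """Scan every chromosome of ``genome`` (mapping chrom -> sequence)."""
    model = ScoreModel(pwm, background, pseudocount, granularity)
    parts = [
        scan_sequence(model, seq, chrom, p_threshold)
        for chrom, seq in sorted(genome.items())
    ]
    if not parts:
        return pd.DataFrame(columns=SITE_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def match_starts(
    model: ScoreModel, codes: np.ndarray, p_threshold: float = 1e-4
) -> np.ndarray:
    """Sorted start positions of matches on either strand (no site records)."""
    thr = model.threshold_int_score(p_threshold)
    rc_int = model.int_matrix[::-1][:, RC]
    s_f, v_f = _window_scores(model.int_matrix, codes)
    s_r, v_r = _window_scores(rc_int, codes)
    hit = (v_f & (s_f >= thr)) | (v_r & (s_r >= thr))
    return np.nonzero(hit)[0]


def mask_exons(sites: pd.DataFrame, mask: IntervalSet) -> pd.DataFrame:
    """Drop sites overlapping a masked (coding-exon) interval by >= 1 nt."""
    if len(sites) == 0:
        return sites.copy()
    drop = np.zeros(len(sites), dtype=bool)
    chroms = sites["chrom"].to_numpy()
    starts = sites["start"].to_numpy()
    ends = sites["end"].to_numpy()
    for c, merged in mask.items():
        m = chroms == c
        if m.any():
            drop[m] = overlaps_any(starts[m], ends[m], merged)
    return sites.loc[~drop].reset_index(drop=True)


def merge_cluster_sites(sites: pd.DataFrame, clusters: list[MotifCluster]) -> pd.DataFrame:
    """Relabel sites by motif cluster and merge overlapping same-cluster sites.

    A site is predicted for a cluster if it is predicted for at least one
    member; overlapping same-cluster sites become one site spanning their
    union, carrying the best member score (max score / min p-value) and,
    once set, the maximum member bls/percentile. Merging is within-cluster
    only; sites of different clusters are never combined.
    """
    member_to_cluster = {}
    for c in clusters:
        for mid in c.members:
            if mid in member_to_cluster:
                raise ValueError(f"motif {mid} belongs to more than one cluster")
            member_to_cluster[mid] = c
    unknown = set(sites["motif_id"]) - set(member_to_cluster)
    if unknown:
        raise ValueError(f"sites reference motifs outside the clustering: {sorted(unknown)}")
    df = sites.copy()
    df["motif_id"] = [member_to_cluster[m].name for m in df["motif_id"]]
    extra = [c for c in ("bls", "percentile") if c in df.columns]
    out = []
    for (name, chrom), g in df.groupby(["motif_id", "chrom"], sort=True):
        g = g.sort_values(["start", "end"], kind="stable")
        cur = None
        for row in g.itertuples(index=False):
            if cur is None or row.start >= cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = row._asdict()
            else:
                cur["end"] = max(cur["end"], row.end)
                if row.score > cur["score"]:
                    cur["score"], cur["pvalue"], cur["strand"] = row.score, row.pvalue, row.strand
                for c in extra:
                    a, b = cur[c], getattr(row, c)
                    cur[c] = np.nanmax([a, b])
        if cur is not None:
            out.append(cur)
    res = pd.DataFrame(out, columns=list(df.columns))
    return res.sort_values(["motif_id", "chrom", "start"], kind="stable").reset_index(drop=True)
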