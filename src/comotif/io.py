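"""Readers/writers for the standard formats the pipeline consumes and emits.

PWMs: MEME minimal format and JASPAR PFM (counts normalized with a
pseudocount). Genomes: FASTA via Bio.SeqIO. Alignments: MAF via
Bio.AlignIO, plus a simplified gapless aligned-FASTA dialect (one
equal-length record per species per chromosome, reference ungapped).
Signal tracks: bedGraph and fixed-step wig. Sites: BED6+ with -log10
p-value in the score column and extra columns for bls/percentile/
accessibility flags. Exons: GFF3 (type CDS) or BED. Trees: Newick.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from comotif.conservation import AlignmentBlock
from comotif.accessibility import SignalTrack
from comotif.intervals import IntervalSet, make_interval_set
from comotif.motifs import PWM


# ---------------------------------------------------------------- PWMs

def read_meme(path) -> list[PWM]:
    """Parse PWMs from MEME minimal motif format."""
    text = Path(path).read_text()
    pwms = []
    for m in re.finditer(
        r"MOTIF\s+(\S+)(?:\s+(\S+))?\s*\n.*?letter-probability matrix[^\n]*\n((?:\s*[\d.eE+-]+[^\n]*\n)+)",
        text,
    ):
        motif_id, alt = m.group(1), m.group(2)
        rows = [
            [float(x) for x in line.split()]
            for line in m.group(3).strip().splitlines()
        ]
        pwms.append(PWM(motif_id=motif_id, tf_name=alt or motif_id, matrix=np.array(rows)))
    if not pwms:
        raise ValueError(f"no MEME motifs found in {path}")
    return pwms


def write_meme(pwms: list[PWM], path, background=None) -> None:
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    if background is not None:
        bg = " ".join(f"{b} {f:.4f}" for b, f in zip("ACGT", background))
        lines += ["Background letter frequencies", bg, ""]
    for p in pwms:
        lines.append(f"MOTIF {p.motif_id} {p.tf_name}")
        lines.append(f"letter-probability matrix: alength= 4 w= {p.width}")
        for row in p.matrix:
            lines.append(" " + " ".join(f"{x:.6f}" for x in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_jaspar(path, pseudocount: float = 0.5) -> list[PWM]:
    """Parse JASPAR PFM files (counts); normalized to frequencies with a pseudocount."""
    text = Path(path).read_text()
    pwms = []
    blocks = re.split(r"(?=^>)", text, flags=re.M)
    for block in blocks:
        if not block.startswith(">"):
            continue
        header, *rows = block.strip().splitlines()
        parts = header[1:].split()
        motif_id = parts[0]
        tf_name = parts[1] if len(parts) > 1 else motif_id
        counts = {}
        for row in rows:
            m = re.match(r"\s*([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?\s*$", row)
            if m:
                counts[m.group(1)] = [float(x) for x in m.group(2).split()]
        if set(counts) != set("ACGT"):
            continue
        mat = np.array([counts[b] for b in "ACGT"]).T + pseudocount
        mat /= mat.sum(axis=1, keepdims=True)
        pwms.append(PWM(motif_id=motif_id, tf_name=tf_name, matrix=mat))
    if not pwms:
        raise ValueError(f"no JASPAR motifs found in {path}")
    return pwms


# ---------------------------------------------------------------- genomes

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------- alignments

def read_aligned_fasta(path, chrom: str, reference: str) -> AlignmentBlock:
    """Read the simplified per-chromosome aligned-FASTA dialect: one record
    per species, all rows equal length, reference row ungapped."""
    rows = read_fasta(path)
    if reference not in rows:
        raise ValueError(f"reference {reference!r} missing from {path}")
    return AlignmentBlock(chrom=chrom, ref_start=0, rows=rows, reference=reference)


def write_aligned_fasta(block: AlignmentBlock, path) -> None:
    write_fasta(block.rows, path)


def read_maf(path, reference: str) -> list[AlignmentBlock]:
    """Read MAF alignment blocks; species taken as the text before the first
    '.' in each sequence source name, coordinates from the reference row."""
    blocks = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = {}
        chrom = None
        ref_start = None
        for rec in aln:
            src = rec.id
            species, _, rest = src.partition(".")
            rows[species] = str(rec.seq).upper()
            if species == reference:
                chrom = rest or src
                ref_start = int(rec.annotations.get("start", 0))
        if chrom is None:
            continue
        blocks.append(AlignmentBlock(chrom=chrom, ref_start=ref_start, rows=rows, reference=reference))
    return blocks


# ---------------------------------------------------------------- tracks

def read_bedgraph(path, stage: str, chrom_lengths: dict[str, int]) -> SignalTrack:
    data = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            if chrom in data:
                data[chrom][int(start) : int(end)] = float(value)
    return SignalTrack(stage=stage, data=data)


def write_bedgraph(track: SignalTrack, path, decimals: int = 4) -> None:
    """Run-length-encoded bedGraph; zero runs are omitted (missing == 0)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            v = np.round(track.data[chrom], decimals)
            if len(v) == 0:
                continue
            change = np.nonzero(np.diff(v))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


def read_wig_fixedstep(path, stage: str, chrom_lengths: dict[str, int]) -> SignalTrack:
    data = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    chrom, pos, step = None, 0, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # wig is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
            else:
                if chrom in data and pos < len(data[chrom]):
                    data[chrom][pos : pos + span] = float(line)
                pos += step
    return SignalTrack(stage=stage, data=data)


# ---------------------------------------------------------------- sites & features

def write_sites_bed(sites: pd.DataFrame, path) -> None:
    """BED6+ site table: name = motif id, score = -log10 p-value, then any of
    bls / percentile / acc_* columns present."""
    extra = [c for c in sites.columns if c in ("bls", "percentile") or c.startswith("acc_")]
    with open(path, "w") as fh:
        for row in sites.itertuples(index=False):
            score = -np.log10(max(row.pvalue, 1e-300))
            cols = [row.chrom, row.start, row.end, row.motif_id, f"{score:.4f}", row.strand]
            for c in extra:
                v = getattr(row, c)
                cols.append(int(v) if isinstance(v, (bool, np.bool_)) else f"{v:.6g}")
            fh.write("\t".join(map(str, cols)) + "\n")


def read_sites_bed(path, extra: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end", "motif_id", "neglog10p", "strand"] + list(extra or [])
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    df["pvalue"] = 10.0 ** (-df.pop("neglog10p"))
    df["score"] = np.nan
    for c in extra or []:
        if c.startswith("acc_"):
            df[c] = df[c].astype(bool)
    return df


def read_bed_intervals(path) -> IntervalSet:
    recs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            recs.append((f[0], int(f[1]), int(f[2])))
    return make_interval_set(recs)


def read_gff3_cds(path) -> IntervalSet:
    """Coding-exon intervals (type CDS) from GFF3; converts to 0-based half-open."""
    recs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 5 and f[2] == "CDS":
                recs.append((f[0], int(f[3]) - 1, int(f[4])))
    return make_interval_set(recs)


def read_tss_table(path) -> pd.DataFrame:
    """TSV with columns gene, chrom, position, strand (0-based position)."""
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})


def write_clusters_tsv(clusters, pwms: list[PWM], path) -> None:
    by_id = {p.motif_id: p for p in pwms}
    with open(path, "w") as fh:
        fh.write("cluster_id\tmotif_id\ttf_name\trepresentative\n")
        for c in clusters:
            for mid in c.members:
                rep = 1 if mid == c.representative else 0
                fh.write(f"{c.cluster_id}\t{mid}\t{by_id[mid].tf_name}\t{rep}\n")
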