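"""Synthetic study generator: phylogeny-aware genomes with planted motifs.

Generates everything the pipeline consumes, with known ground truth: a
reference genome drawn i.i.d. from a genomic background composition;
gapless per-species alignment rows evolved along a 12-leaf phylogeny by
per-branch Jukes-Cantor-style substitution; planted motif instances copied
intact into a chosen set of species (so their branch length score is
controlled) and scrambled elsewhere; per-stage DNaseI-like signal tracks
with noise plus plateaus covering just under the accessibility quantile;
and planted co-localized motif pairs inside the plateaus of designated
stages.

The defaults define the study conditions used throughout the test suite
and the reproduction script: 2 chromosomes x 100 kb, 20 motifs of width 8
drawn from three base-composition archetypes, five developmental stages,
per-motif conserved/non-conserved decoy sites, and one planted pair with
40 co-occurrences at gaps <= 80 nt in the accessible regions of stage S5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from comotif.accessibility import SignalTrack
from comotif.conservation import AlignmentBlock, ReferencePhylogeny
from comotif.motifs import FLY_BACKGROUND, PWM, pwm_similarity
from comotif.scan import ScoreModel

#: 12-leaf tree loosely shaped like the sequenced Drosophila phylogeny
DEFAULT_NEWICK = (
    "((((((dmel:0.06,(dsim:0.03,dsec:0.03):0.04):0.05,"
    "(dyak:0.09,dere:0.08):0.05):0.1,dana:0.3):0.1,"
    "(dpse:0.03,dper:0.03):0.35):0.1,dwil:0.55):0.08,"
    "((dmoj:0.3,dvir:0.28):0.12,dgri:0.45):0.2);"
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: base-composition archetypes from which motif consensi are drawn
ARCHETYPES = (
    np.array([0.40, 0.10, 0.10, 0.40]),  # A/T rich
    np.array([0.10, 0.40, 0.40, 0.10]),  # C/G rich
    np.array([0.35, 0.15, 0.35, 0.15]),  # purine rich
)


@dataclass
class PlantedPair:
    motif_a: str
    motif_b: str
    n_occurrences: int = 40
    max_gap: int = 80
    stages: tuple = ("S5",)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset; the seed fully determines
    every output."""

    seed: int = 0
    newick: str = DEFAULT_NEWICK
    reference: str = "dmel"
    n_chromosomes: int = 2
    genome_length: int = 100_000
    n_motifs: int = 20
    motif_width: int = 8
    stages: tuple = ("S5", "S9", "S10", "S11", "S14")
    background: tuple = tuple(FLY_BACKGROUND)
    planted_pairs: tuple = (PlantedPair("M00", "M01"),)
    # per motif, per chromosome: non-conserved and mid-conservation decoys
    n_low_singletons: int = 150
    n_mid_singletons: int = 20
    low_bls_target: float = 0.0
    mid_bls_target: float = 0.45
    # per motif, per stage, per chromosome: conserved decoys inside plateaus.
    # Motifs involved in a planted pair get fewer decoys (their analyzed
    # sites are dominated by the planted occurrences) and are never
    # co-assigned to a decoy plateau with their partner, so the only
    # co-localization of a planted pair is the planted one.
    n_accessible_singletons: int = 5
    n_accessible_singletons_paired: int = 2
    accessible_bls_targets: tuple = (0.8, 0.9, 1.0)
    pair_bls_target: float = 1.0
    # accessibility tracks: decoy sites share a few wide plateaus; each
    # planted pair occurrence gets its own narrow plateau, so pair
    # adjacency is never confounded with decoy-plateau crowding
    n_plateaus: int = 8
    plateau_width: int = 350
    plateau_height: float = 8.0
    plateau_margin: int = 10  # keep planted sites this far from plateau edges
    plateau_buffer: int = 200  # plateau-to-plateau / plateau-to-site separation
    pair_pad: int = 12  # pair-plateau padding around the planted pair span
    noise_mean: float = 0.5
    noise_sd: float = 0.2
    substitution_scale: float = 1.0
    max_similarity: float = 0.75  # motif-set rejection threshold

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SimData:
    """One simulated study: inputs for every pipeline stage plus ground truth."""

    config: SimulationConfig
    tree: ReferencePhylogeny
    pwms: list[PWM]
    genome: dict[str, str]
    blocks: dict[str, AlignmentBlock]
    tracks: list[SignalTrack]
    plateaus: dict[str, dict[str, np.ndarray]]  # stage -> chrom -> (n, 2)
    truth_sites: pd.DataFrame
    truth_pairs: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    @property
    def background(self) -> np.ndarray:
        return np.asarray(self.config.background)


def _jc_prob(branch_length: float) -> float:
    """Probability a base differs after evolving a branch (Jukes-Cantor)."""
    return 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))


def achievable_clade_bls(tree: ReferencePhylogeny) -> list[tuple[float, tuple]]:
    """BLS of every reference-anchored distance-rank prefix of the leaves.

    Planting into prefix sets keeps the matched species contiguous in the
    distance ranking, so distant-match pruning never fires on planted sites.
    """
    out = []
    for k in range(1, len(tree.by_rank) + 1):
        clade = tuple(tree.by_rank[:k])
        out.append((tree.bls_mask(tree.mask(clade)), clade))
    return out


def _clade_for_target(tree: ReferencePhylogeny, target: float, tol: float = 0.35):
    options = achievable_clade_bls(tree)
    bls, clade = min(options, key=lambda t: abs(t[0] - target))
    if abs(bls - target) > tol:
        raise ValueError(
            f"BLS target {target} unreachable; achievable clade BLS values: "
            f"{[round(b, 3) for b, _ in options]}"
        )
    return bls, clade


def _sharp_matrix(consensus: np.ndarray, dominant: float = 0.94) -> np.ndarray:
    w = len(consensus)
    mat = np.full((w, 4), (1.0 - dominant) / 3.0)
    mat[np.arange(w), consensus] = dominant
    return mat


def _cross_matchable(c1: np.ndarray, c2: np.ndarray,
                     min_overlap: int = 6, max_mismatch: int = 1) -> bool:
    """Can one sharp motif's scanner fire inside the other's planted sites?

    True when the two consensi share an aligned overlap of at least
    ``min_overlap`` columns with at most ``max_mismatch`` mismatches, in
    either orientation: such near-subwords let one motif match on top of
    (or flush against) the other's planted instances once a couple of
    random flanking bases cooperate.
    """
    for other in (c2, 3 - c2[::-1]):
        for off in range(-(len(other) - min_overlap), len(c1) - min_overlap + 1):
            lo, hi = max(0, off), min(len(c1), off + len(other))
            if hi - lo >= min_overlap:
                mm = int((c1[lo:hi] != other[lo - off : hi - off]).sum())
                if mm <= max_mismatch:
                    return True
    return False


def make_motif_set(config: SimulationConfig, rng) -> list[PWM]:
    """Draw sharp-consensus PWMs from composition archetypes.

    Candidates are resampled until the set is mutually distinct for any
    seed: a candidate is rejected when its consensus is not scannable at
    the default p-value threshold under the genomic background, when it
    shares a near-identical >= 6-column subword with an accepted motif
    (see :func:`_cross_matchable`), or when its PWM similarity to an
    accepted motif reaches ``max_similarity`` (so motif clustering at the
    default cut yields one cluster per motif).
    """
    bg = np.asarray(config.background)
    pwms: list[PWM] = []
    consensi: list[np.ndarray] = []
    for i in range(config.n_motifs):
        arch = ARCHETYPES[i % len(ARCHETYPES)]
        for _ in range(1000):
            consensus = rng.choice(4, size=config.motif_width, p=arch)
            if any(_cross_matchable(consensus, c) for c in consensi):
                continue
            pwm = PWM(f"M{i:02d}", f"tf{i:02d}", _sharp_matrix(consensus))
            model = ScoreModel(pwm, background=bg)
            if model.pvalue(model.int_score(consensus)) > 1e-4:
                continue
            if all(pwm_similarity(pwm, q) < config.max_similarity for q in pwms):
                pwms.append(pwm)
                consensi.append(consensus)
                break
        else:
            raise RuntimeError("could not draw a sufficiently distinct motif set")
    return pwms


def _place_in_interval(rng, lo: int, hi: int, lengths: list[int]) -> list[int]:
    """Uniform non-overlapping placement of items in [lo, hi); returns starts."""
    free = (hi - lo) - sum(lengths)
    if free < 0:
        raise ValueError("interval too small for requested occurrences")
    cuts = np.sort(rng.random(len(lengths))) * free
    starts = []
    used = 0
    for c, ln in zip(cuts, lengths):
        starts.append(int(lo + c + used))
        used += ln
    return starts


def _assign_and_place(rng, intervals: list[tuple[int, int]], items: list[dict],
                      conflicts: dict | None = None) -> None:
    """Distribute items over intervals (capacity-aware) and place each group.

    Mutates each item dict, adding 'start'. ``conflicts`` maps a motif id to
    the motif ids it must never share an interval with. Raises when total
    capacity is insufficient (genome too small for the requested occurrences).
    """
    items = list(items)
    rng.shuffle(items)
    capacity = [hi - lo for lo, hi in intervals]
    occupants: list[set] = [set() for _ in intervals]
    assigned: list[list[dict]] = [[] for _ in intervals]
    order = np.arange(len(intervals))
    for it in items:
        banned = (conflicts or {}).get(it.get("motif_id"), set())
        rng.shuffle(order)
        for k in order:
            if capacity[k] >= it["length"] and not (occupants[k] & banned):
                capacity[k] -= it["length"]
                occupants[k].add(it.get("motif_id"))
                assigned[k].append(it)
                break
        else:
            raise ValueError("not enough room to place planted sites; genome too small")
    for (lo, hi), group in zip(intervals, assigned):
        if not group:
            continue
        starts = _place_in_interval(rng, lo, hi, [g["length"] for g in group])
        for g, s in zip(group, starts):
            g["start"] = s


def _complement(intervals: np.ndarray, lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    cur = lo
    for s, e in intervals:
        if s > cur:
            out.append((cur, min(s, hi)))
        cur = max(cur, e)
    if cur < hi:
        out.append((cur, hi))
    return [(a, b) for a, b in out if b - a > 0]


def simulate_study(config: SimulationConfig | None = None, **overrides) -> SimData:
    """Generate one complete synthetic study from the configuration."""
    config = replace(config or SimulationConfig(), **overrides)
    rng = np.random.default_rng(config.seed)
    tree = ReferencePhylogeny(config.newick, config.reference)
    bg = np.asarray(config.background, dtype=float)
    bg = bg / bg.sum()
    pwms = make_motif_set(config, rng)
    by_id = {p.motif_id: p for p in pwms}
    L = config.genome_length
    chroms = config.chromosomes

    # --- plateau layout ---------------------------------------------------
    # Per (stage, chrom): `n_plateaus` wide decoy plateaus, plus one narrow
    # dedicated plateau per planted pair occurrence. Dedicated plateaus keep
    # the planted adjacency free of decoy crowding, so the shuffling null
    # reflects identity exchange rather than local density. Total per-stage
    # coverage stays below the accessibility quantile.
    sep = config.plateau_buffer
    w = config.motif_width
    clades = {}
    for target in (
        [config.low_bls_target, config.mid_bls_target, config.pair_bls_target]
        + list(config.accessible_bls_targets)
    ):
        clades[target] = _clade_for_target(tree, target)
    plan: list[dict] = []
    plateaus: dict[str, dict[str, list]] = {s: {c: [] for c in chroms} for s in config.stages}
    decoy_plateaus: dict[str, dict[str, list]] = {
        s: {c: [] for c in chroms} for s in config.stages
    }

    for chrom in chroms:
        # pair occurrences for this chromosome, with their gaps drawn now so
        # every dedicated plateau is sized to its pair span
        pair_items = []
        for pair in config.planted_pairs:
            per_chrom = pair.n_occurrences // len(chroms)
            if chrom == chroms[-1]:
                per_chrom = pair.n_occurrences - per_chrom * (len(chroms) - 1)
            wa, wb = by_id[pair.motif_a].width, by_id[pair.motif_b].width
            for _ in range(per_chrom):
                gap = int(rng.integers(0, pair.max_gap + 1))
                pair_items.append(
                    {
                        "chrom": chrom,
                        "motif_id": (pair.motif_a, pair.motif_b),
                        "kind": "pair",
                        "stage": pair.stages[0],
                        "length": wa + gap + wb,
                        "gap": gap,
                        "bls_target": config.pair_bls_target,
                    }
                )
        blocks = [
            {"stage": s, "kind": "decoy", "width": config.plateau_width}
            for s in config.stages
            for _ in range(config.n_plateaus)
        ] + [
            {"stage": it["stage"], "kind": "pair", "width": it["length"] + 2 * config.pair_pad,
             "item": it}
            for it in pair_items
        ]
        rng.shuffle(blocks)
        starts = _place_in_interval(rng, 1000, L - 1000, [b["width"] + 2 * sep for b in blocks])
        for b, s0 in zip(blocks, starts):
            lo, hi = s0 + sep, s0 + sep + b["width"]
            plateaus[b["stage"]][chrom].append((lo, hi))
            if b["kind"] == "decoy":
                decoy_plateaus[b["stage"]][chrom].append((lo, hi))
            else:
                b["item"]["start"] = lo + config.pair_pad
        # accessible conserved decoys inside the decoy plateaus
        margin = config.plateau_margin
        paired_motifs = {m for p in config.planted_pairs for m in (p.motif_a, p.motif_b)}
        conflicts = {}
        for p in config.planted_pairs:
            conflicts.setdefault(p.motif_a, set()).add(p.motif_b)
            conflicts.setdefault(p.motif_b, set()).add(p.motif_a)
        for stage in config.stages:
            items = []
            k = 0
            for p in pwms:
                n_acc = (
                    config.n_accessible_singletons_paired
                    if p.motif_id in paired_motifs
                    else config.n_accessible_singletons
                )
                for _ in range(n_acc):
                    target = config.accessible_bls_targets[k % len(config.accessible_bls_targets)]
                    k += 1
                    items.append(
                        {
                            "chrom": chrom,
                            "motif_id": p.motif_id,
                            "kind": "accessible",
                            "stage": stage,
                            "length": w,
                            "bls_target": target,
                        }
                    )
            inner = [(s + margin, e - margin) for s, e in decoy_plateaus[stage][chrom]]
            _assign_and_place(rng, inner, items, conflicts)
            plan.extend(items)
        plan.extend(pair_items)
        # non-accessible singletons in the complement of all plateaus
        all_pl = np.array(
            sorted(
                (s - sep, e + sep)
                for stage in config.stages
                for s, e in plateaus[stage][chrom]
            ),
            dtype=np.int64,
        )
        comp = _complement(all_pl, 100, L - 100)
        items = []
        for p in pwms:
            for kind, n, target in (
                ("low", config.n_low_singletons, config.low_bls_target),
                ("mid", config.n_mid_singletons, config.mid_bls_target),
            ):
                for _ in range(n):
                    items.append(
                        {
                            "chrom": chrom,
                            "motif_id": p.motif_id,
                            "kind": kind,
                            "stage": None,
                            "length": w,
                            "bls_target": target,
                        }
                    )
        _assign_and_place(rng, comp, items)
        plan.extend(items)

    # --- reference genome and planted sequences ---------------------------
    genome_codes = {c: rng.choice(4, size=L, p=bg).astype(np.int8) for c in chroms}
    site_rows = []
    pair_rows = []
    for it in plan:
        chrom, start = it["chrom"], it["start"]
        bls, clade = clades[it["bls_target"]]
        mask = tree.mask(clade)
        if it["kind"] == "pair":
            ma, mb = it["motif_id"]
            wa, wb = by_id[ma].width, by_id[mb].width
            subs = [(ma, start, start + wa), (mb, start + wa + it["gap"], start + it["length"])]
            pair_rows.append(
                {
                    "chrom": chrom,
                    "motif_a": ma,
                    "motif_b": mb,
                    "a_start": subs[0][1],
                    "b_start": subs[1][1],
                    "gap": it["gap"],
                    "stage": it["stage"],
                }
            )
        else:
            m = it["motif_id"]
            subs = [(m, start, start + w)]
        for m, s0, e0 in subs:
            strand = "+" if rng.random() < 0.5 else "-"
            cons = by_id[m].matrix.argmax(axis=1)
            if strand == "-":
                cons = 3 - cons[::-1]
            genome_codes[chrom][s0:e0] = cons
            site_rows.append(
                {
                    "chrom": chrom,
                    "start": s0,
                    "end": e0,
                    "motif_id": m,
                    "kind": it["kind"],
                    "stage": it["stage"],
                    "strand": strand,
                    "clade_bls": bls,
                    "clade_mask": mask,
                }
            )
    truth_sites = pd.DataFrame(site_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    truth_pairs = pd.DataFrame(
        pair_rows, columns=["chrom", "motif_a", "motif_b", "a_start", "b_start", "gap", "stage"]
    )

    # --- evolve species rows along the tree (rerooted at the reference) ---
    adjacency: dict = {}
    for node in tree.tree.preorder_node_iter():
        for ch in node.child_nodes():
            ln = (ch.edge.length or 0.0) * config.substitution_scale
            adjacency.setdefault(node, []).append((ch, ln))
            adjacency.setdefault(ch, []).append((node, ln))
    ref_node = next(
        lf for lf in tree.tree.leaf_node_iter() if lf.taxon.label == config.reference
    )
    rows_codes = {c: {} for c in chroms}
    for chrom in chroms:
        seqs = {ref_node: genome_codes[chrom]}
        stack = [ref_node]
        seen = {ref_node}
        while stack:
            node = stack.pop()
            for nb, ln in adjacency.get(node, []):
                if nb in seen:
                    continue
                seen.add(nb)
                parent = seqs[node]
                p = _jc_prob(ln)
                child = parent.copy()
                hit = np.nonzero(rng.random(L) < p)[0]
                child[hit] = (child[hit] + rng.integers(1, 4, size=len(hit))) % 4
                seqs[nb] = child
                stack.append(nb)
        for lf in tree.tree.leaf_node_iter():
            rows_codes[chrom][lf.taxon.label] = seqs[lf]
        # planted intervals: intact inside the clade, scrambled outside
        for row in truth_sites.loc[truth_sites["chrom"] == chrom].itertuples(index=False):
            seg = genome_codes[chrom][row.start : row.end]
            for sp in tree.species:
                if sp == config.reference:
                    continue
                if tree._bit[sp] & row.clade_mask:
                    rows_codes[chrom][sp][row.start : row.end] = seg
                else:
                    rows_codes[chrom][sp][row.start : row.end] = rng.choice(
                        4, size=len(seg), p=bg
                    )

    def _to_str(codes: np.ndarray) -> str:
        return _BASE_BYTES[codes.astype(np.uint8)].tobytes().decode()

    genome = {c: _to_str(genome_codes[c]) for c in chroms}
    blocks = {
        c: AlignmentBlock(
            chrom=c,
            ref_start=0,
            rows={sp: _to_str(arr) for sp, arr in rows_codes[c].items()},
            reference=config.reference,
        )
        for c in chroms
    }

    # --- per-stage signal tracks ------------------------------------------
    tracks = []
    for stage in config.stages:
        data = {}
        for chrom in chroms:
            v = np.clip(rng.normal(config.noise_mean, config.noise_sd, L), 0.0, None)
            for s, e in plateaus[stage][chrom]:
                v[s:e] += config.plateau_height * (1.0 + 0.1 * (rng.random() - 0.5))
            data[chrom] = v
        tracks.append(SignalTrack(stage=stage, data=data))

    return SimData(
        config=config,
        tree=tree,
        pwms=pwms,
        genome=genome,
        blocks=blocks,
        tracks=tracks,
        plateaus={
            s: {c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2) for c, v in per.items()}
            for s, per in plateaus.items()
        },
        truth_sites=truth_sites,
        truth_pairs=truth_pairs,
    )


def simulate_alignment(config: SimulationConfig | None = None, **overrides):
    """Aligned per-species rows plus the Newick tree for the configuration."""
    sim = simulate_study(config, **overrides)
    return sim.blocks, sim.config.newick


def plant_pairs(config: SimulationConfig | None = None, **overrides) -> pd.DataFrame:
    """Ground-truth table of planted co-localized pair occurrences."""
    return simulate_study(config, **overrides).truth_pairs


def simulate_tracks(config: SimulationConfig | None = None, **overrides) -> list[SignalTrack]:
    """Per-stage signal tracks for the configuration."""
    return simulate_study(config, **overrides).tracks
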