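"""Gene-order synteny: anchor chaining into collinear blocks, Kendall-tau
conservation statistics, host-vs-parasite rank-sum comparison, and
rearrangement-spectrum normalization.

Blocks are built from single-copy shared orthogroups ("anchors") by greedy
chaining along genome A: consecutive anchors extend the current block while
they sit on the same scaffold pair and are at most ``gap`` genes apart in
both genomes (direction-agnostic in B, so inverted runs stay in one block
and simply depress tau). Blocks spanning fewer than ``min_span`` genes in
either genome are discarded, mirroring the >= 25-gene region filter used
when comparing host and parasite genomes. A perfectly collinear block has
tau = 1; a fully reversed block has tau = -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneOrder",
    "GeneEntry",
    "SyntenicBlock",
    "MutationCountTable",
    "chain_anchor_blocks",
    "block_order_correlation",
    "compare_tau_sets",
    "mutation_spectrum",
]


@dataclass
class GeneEntry:
    scaffold: str
    rank: int
    gene_id: str
    strand: str  # '+' or '-'
    orthogroup: str


@dataclass
class GeneOrder:
    """Ordered, stranded gene list of one genome."""

    genome: str
    entries: list[GeneEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self) -> list[str]:
        report = []
        seen: set[str] = set()
        last_rank: dict[str, int] = {}
        for e in self.entries:
            if e.gene_id in seen:
                report.append(f"duplicate gene id {e.gene_id}")
            seen.add(e.gene_id)
            if e.scaffold in last_rank and e.rank <= last_rank[e.scaffold]:
                report.append(
                    f"ranks not strictly increasing on scaffold "
                    f"{e.scaffold} at gene {e.gene_id}"
                )
            last_rank[e.scaffold] = e.rank
            if e.strand not in "+-":
                report.append(f"bad strand {e.strand!r} for {e.gene_id}")
        return report

    def orthogroup_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.orthogroup] = counts.get(e.orthogroup, 0) + 1
        return counts

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "dict[str, GeneOrder]":
        """Gene orders from a tidy table with columns genome, scaffold,
        rank, gene_id, strand, orthogroup."""
        orders = {}
        for genome, sub in df.groupby("genome", sort=False):
            sub = sub.sort_values(["scaffold", "rank"])
            orders[genome] = cls(
                genome=str(genome),
                entries=[
                    GeneEntry(str(r.scaffold), int(r.rank), str(r.gene_id),
                              str(r.strand), str(r.orthogroup))
                    for r in sub.itertuples()
                ],
            )
        return orders

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genome": self.genome,
                    "scaffold": e.scaffold,
                    "rank": e.rank,
                    "gene_id": e.gene_id,
                    "strand": e.strand,
                    "orthogroup": e.orthogroup,
                }
                for e in self.entries
            ]
        )

    @classmethod
    def from_tsv(cls, path) -> "dict[str, GeneOrder]":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str).astype(
            {"rank": int}))


def write_orders_tsv(orders, path) -> None:
    pd.concat([o.to_frame() for o in orders.values()]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class SyntenicBlock:
    """A chained run of ortholog anchors between two genomes."""

    genome_a: str
    genome_b: str
    #: (index in A's order, index in B's order), strictly increasing in A
    anchors: list[tuple[int, int]]
    span_a: int
    span_b: int

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def tau(self) -> float | None:
        return block_order_correlation(self)


@dataclass
class BlockSet:
    blocks: list[SyntenicBlock]
    n_discarded: int


def _anchor_pairs(a: GeneOrder, b: GeneOrder) -> list[tuple[int, int, str, str]]:
    """Single-copy shared orthogroups as (index_a, index_b, scaf_a, scaf_b)."""
    count_a = a.orthogroup_counts()
    count_b = b.orthogroup_counts()
    pos_b = {
        e.orthogroup: (i, e.scaffold)
        for i, e in enumerate(b.entries)
        if count_b[e.orthogroup] == 1
    }
    pairs = []
    for i, e in enumerate(a.entries):
        if count_a[e.orthogroup] != 1:
            continue
        hit = pos_b.get(e.orthogroup)
        if hit is not None:
            pairs.append((i, hit[0], e.scaffold, hit[1]))
    return pairs


def chain_anchor_blocks(a: GeneOrder, b: GeneOrder, gap: int = 5,
                        min_span: int = 25) -> BlockSet:
    """Greedily chain single-copy ortholog anchors into syntenic blocks.

    Anchors are scanned in A order; an anchor joins the current chain when
    it lies on the same scaffold pair and within ``gap`` intervening genes
    of the previous anchor in both genomes (|delta index| <= gap + 1 on
    each side, sign-free in B). Chains whose gene span is below
    ``min_span`` in either genome are discarded and counted.
    """
    pairs = _anchor_pairs(a, b)
    chains: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    cur_scafs: tuple[str, str] | None = None
    for ia, ib, sa, sb in pairs:
        if cur and cur_scafs == (sa, sb) \
                and (ia - cur[-1][0]) <= gap + 1 \
                and abs(ib - cur[-1][1]) <= gap + 1:
            cur.append((ia, ib))
        else:
            if cur:
                chains.append(cur)
            cur = [(ia, ib)]
            cur_scafs = (sa, sb)
    if cur:
        chains.append(cur)

    blocks, discarded = [], 0
    for chain in chains:
        ia = [x[0] for x in chain]
        ib = [x[1] for x in chain]
        span_a = max(ia) - min(ia) + 1
        span_b = max(ib) - min(ib) + 1
        if span_a < min_span or span_b < min_span:
            discarded += 1
            continue
        blocks.append(
            SyntenicBlock(a.genome, b.genome, chain, span_a, span_b)
        )
    return BlockSet(blocks=blocks, n_discarded=discarded)


def block_order_correlation(block: SyntenicBlock) -> float | None:
    """Kendall tau-b between the A and B positions of a block's anchors.

    Returns None (undefined) for blocks with fewer than 2 anchors. tau = 1
    iff B's order is perfectly concordant with A's; a fully reversed block
    gives tau = -1.
    """
    if block.n_anchors < 2:
        return None
    xa = [p[0] for p in block.anchors]
    xb = [p[1] for p in block.anchors]
    tau = stats.kendalltau(xa, xb, variant="b").statistic
    return float(tau)


@dataclass
class RankSumComparison:
    p: float
    z: float
    n: int
    n_first: int
    n_second: int
    statistic: float  # rank-sum of the first (e.g. host) sample


def compare_tau_sets(tau_hosts, tau_parasites, permutations: int = 9999,
                     seed: int = 0) -> RankSumComparison:
    """One-sided Monte-Carlo Wilcoxon-Mann-Whitney comparison of tau sets.

    Alternative: the parasite taus are stochastically smaller than the host
    taus. The p-value is the permutation tail probability with the
    (b + 1) / (R + 1) correction; z is the tie-corrected normal
    approximation, negative when parasites rank below hosts.
    """
    x = np.asarray(list(tau_hosts), dtype=float)
    y = np.asarray(list(tau_parasites), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both tau sets must be non-empty")
    if permutations < 99:
        raise ValueError("need at least 99 permutations")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(pooled)
    w_obs = ranks[n1:].sum()  # parasite rank sum; small => parasites lower

    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(pooled.size)
        if ranks[perm[n1:]].sum() <= w_obs:
            exceed += 1
    p = (exceed + 1.0) / (permutations + 1.0)

    # tie-corrected normal approximation
    n = n1 + n2
    mean_w = n2 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / ((n * (n - 1.0)) or 1.0)
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (w_obs - mean_w) / np.sqrt(var_w) if var_w > 0 else 0.0
    return RankSumComparison(
        p=float(p), z=float(z), n=n, n_first=n1, n_second=n2,
        statistic=float(ranks[:n1].sum()),
    )


EVENT_TYPES = ("P", "I", "D", "V", "U")  # transposition, insertion,
# deletion, inversion, duplication


@dataclass
class MutationCountTable:
    """Per-branch rearrangement event counts by type and size bin."""

    counts: pd.DataFrame  # columns: branch, type, size_bin, count
    durations: dict[str, float]  # branch -> Ma

    def validate(self) -> list[str]:
        report = []
        if (self.counts["count"] < 0).any():
            report.append("negative event counts")
        for b, d in self.durations.items():
            if d <= 0:
                report.append(f"non-positive duration for branch {b}")
        bad = set(self.counts["type"]) - set(EVENT_TYPES)
        if bad:
            report.append(f"unknown event types: {sorted(bad)}")
        return report

    @classmethod
    def from_tsv(cls, path, durations: dict[str, float]) -> "MutationCountTable":
        return cls(pd.read_csv(path, sep="\t"), durations)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def mutation_spectrum(table: MutationCountTable) -> pd.DataFrame:
    """Events per Ma and percent deviation from the across-branch mean.

    For every (type, size bin), rate = count / branch duration and
    deviation = 100 * (rate - mean) / mean with the mean taken over all
    branches (no exclusions). Branches absent from a (type, bin) cell count
    as rate 0. Deviations are absent (NaN) for all-zero cells.
    """
    branches = sorted(table.durations)
    rows = []
    cells = table.counts.groupby(["type", "size_bin"])
    for (etype, size_bin), sub in cells:
        per_branch = sub.groupby("branch")["count"].sum()
        rates = {
            b: per_branch.get(b, 0) / table.durations[b] for b in branches
        }
        mean = float(np.mean(list(rates.values())))
        for b in branches:
            dev = (100.0 * (rates[b] - mean) / mean) if mean > 0 else float("nan")
            rows.append(
                {
                    "branch": b,
                    "type": etype,
                    "size_bin": size_bin,
                    "events_per_ma": rates[b],
                    "pct_deviation": dev,
                }
            )
    return pd.DataFrame(rows)
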