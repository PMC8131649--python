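"""Synthetic genome-evolution generator.

Produces every input the analysis stages consume, with fixed seeds and a
ground-truth log for parameter-recovery tests:

* codon alignments evolved along the species tree under the MG94xHKY
  mixture with a selection-intensity exponent k applied on the "test"
  (parasite) branch set, via per-site Gillespie simulation so that true
  synonymous/nonsynonymous substitution counts are logged;
* gene-family count tables under a linear birth-death process with
  branch-class gain/loss rates, plus the +/-1 observation-error channel;
* gene orders mutated by inversions, transpositions, deletions,
  duplications and insertions with per-branch Poisson event counts and a
  replayable per-event log.

The default study phylogeny is a six-taxon leafcutter tree (one Atta
outgroup, two host/parasite species pairs plus a second parasite) with the
divergence ages 12, 2.50, 1.63 and 0.96 Ma and the four parasite branches
(the A. insinuator terminal, the stem of (A. charruanus, P. argentina) and
both its terminals) forming the "test" set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._codons import get_code
from .alignments import CodonAlignment
from .gene_families import FamilyCountTable
from .phylo import BranchPartition, Node, Phylogeny
from .selection import Mg94Params, mg94_rate_matrix
from .synteny import GeneEntry, GeneOrder, MutationCountTable

__all__ = [
    "SimulationConfig",
    "GroundTruthLog",
    "default_study_phylogeny",
    "simulate_codon_alignment",
    "simulate_family_counts",
    "simulate_gene_orders",
    "replay_gene_orders",
    "mutation_counts_from_log",
]

TAXA = (
    "At_colombica",
    "A_echinatior",
    "A_insinuator",
    "A_heyeri",
    "A_charruanus",
    "P_argentina",
)

#: crown age (Ma) of the Acromyrmex radiation; the published tree prints
#: 12 / 2.50 / 1.63 / 0.96 Ma for the other nodes but not this one
CROWN_ACROMYRMEX_MA = 8.0


def default_study_phylogeny() -> tuple[Phylogeny, BranchPartition]:
    """Six-taxon leafcutter study tree with parasite branch classes.

    Node ages (Ma): root 12 (Atta/Acromyrmex), crown Acromyrmex 8.0,
    host/parasite splits 0.96 (A. echinatior / A. insinuator) and 2.50
    (A. heyeri vs the parasite stem), parasite-pair split 1.63
    (A. charruanus / P. argentina). Branch lengths are in Ma. The "test"
    set holds the four parasite branches; everything else is "reference".
    """
    ages = {
        "attine_root": 12.0,
        "acromyrmex": CROWN_ACROMYRMEX_MA,
        "echinatior_insinuator": 0.96,
        "heyeri_clade": 2.50,
        "charruanus_argentina": 1.63,
    }
    spec = [
        # label, parent index
        ("attine_root", None),
        ("At_colombica", 0),
        ("acromyrmex", 0),
        ("echinatior_insinuator", 2),
        ("A_echinatior", 3),
        ("A_insinuator", 3),
        ("heyeri_clade", 2),
        ("A_heyeri", 6),
        ("charruanus_argentina", 6),
        ("A_charruanus", 8),
        ("P_argentina", 8),
    ]
    nodes = []
    for idx, (label, parent) in enumerate(spec):
        age = ages.get(label, 0.0)
        length = None
        if parent is not None:
            length = ages[spec[parent][0]] - age
        nodes.append(Node(idx, label, parent, [], length, age))
    for idx, (_, parent) in enumerate(spec):
        if parent is not None:
            nodes[parent].children.append(idx)
    tree = Phylogeny(nodes, unit="Ma")

    test = {"A_insinuator", "charruanus_argentina", "A_charruanus",
            "P_argentina"}
    partition = BranchPartition(
        {
            b: (BranchPartition.TEST if b in test
                else BranchPartition.REFERENCE)
            for b in tree.branch_labels()
        }
    )
    return tree, partition


@dataclass
class SimulationConfig:
    """All generator knobs, with the study conditions as defaults."""

    seed: int = 0
    # --- codon model ------------------------------------------------------
    kappa: float = 2.0
    pi_nuc: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    omegas: tuple[float, float, float] = (0.1, 0.5, 2.0)
    props: tuple[float, float, float] = (0.6, 0.3, 0.1)
    k: float = 1.0
    n_sites: int = 300
    #: molecular clock converting Ma branch lengths into expected
    #: substitutions per codon site
    clock_subs_per_codon_per_ma: float = 0.02
    table_id: int = 1
    # --- gene families ----------------------------------------------------
    family_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"test": (0.002, 0.002),
                                 "reference": (0.002, 0.002)}
    )
    n_families: int = 1000
    root_size_max: int = 5  # root sizes uniform on {1..root_size_max}
    eps: dict[str, float] | float = 0.0
    # --- gene orders ------------------------------------------------------
    n_genes: int = 200
    #: per-genome events per Ma by type; a value may also be a
    #: {branch label: rate} mapping (with optional "default") for
    #: branch-specific rates
    rearrangement_rates: dict = field(
        default_factory=lambda: {"V": 0.5, "P": 0.5, "D": 0.3, "U": 0.3,
                                 "I": 0.3}
    )
    segment_mean: float = 5.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("selection intensity k must be > 0")
        if abs(sum(self.props) - 1.0) > 1e-8:
            raise ValueError("site-category proportions must sum to 1")
        for cls, (lam, mu) in self.family_rates.items():
            if lam < 0 or mu < 0:
                raise ValueError(f"negative family rate in class {cls!r}")
        for rate in self.rearrangement_rates.values():
            values = rate.values() if isinstance(rate, dict) else [rate]
            if any(v < 0 for v in values):
                raise ValueError("rearrangement rates must be >= 0")

    def rearrangement_rate(self, etype: str, branch: str) -> float:
        rate = self.rearrangement_rates.get(etype, 0.0)
        if isinstance(rate, dict):
            return float(rate.get(branch, rate.get("default", 0.0)))
        return float(rate)

    def study_tree(self) -> tuple[Phylogeny, BranchPartition]:
        return default_study_phylogeny()

    def eps_for(self, species: str) -> float:
        if isinstance(self.eps, dict):
            return self.eps.get(species, 0.0)
        return float(self.eps)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("pi_nuc", "omegas", "props"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "family_rates" in raw:
            raw["family_rates"] = {
                k: tuple(v) for k, v in raw["family_rates"].items()
            }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruthLog:
    """Seed, true parameters and per-branch event records of one run."""

    seed: int
    kind: str
    locus_params: dict[str, Any] = field(default_factory=dict)
    branch_events: dict[str, Any] = field(default_factory=dict)
    family_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    extras: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


# --------------------------------------------------------------------------
# codon alignments
# --------------------------------------------------------------------------


class _GillespieKernel:
    """Jump-chain tables for one (category, branch-class) rate matrix."""

    def __init__(self, params: Mg94Params):
        Q, pi = mg94_rate_matrix(params)
        self.pi = pi
        self.exit_rate = -np.diag(Q).copy()
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            jump = off / self.exit_rate[:, None]
        jump[self.exit_rate <= 0] = 0.0
        self.jump_cdf = np.cumsum(jump, axis=1)


def _evolve_branch(states: np.ndarray, t: float, kern: _GillespieKernel,
                   syn_pair: np.ndarray, rng: np.random.Generator):
    """Gillespie evolution of many independent sites over one branch.

    Returns (new_states, n_syn, n_nonsyn)."""
    s = states.copy()
    rem = np.full(s.shape, float(t))
    active = np.arange(s.size)
    n_syn = n_nonsyn = 0
    while active.size:
        rate = kern.exit_rate[s[active]]
        with np.errstate(divide="ignore"):
            dt = np.where(rate > 0,
                          rng.exponential(1.0, size=active.size) / rate,
                          np.inf)
        fires = dt < rem[active]
        idx = active[fires]
        if idx.size:
            u = rng.random(idx.size)
            rows = kern.jump_cdf[s[idx]]
            new = (rows < u[:, None]).sum(axis=1)
            syn = syn_pair[s[idx], new]
            n_syn += int(syn.sum())
            n_nonsyn += int((~syn).sum())
            rem[idx] -= dt[fires]
            s[idx] = new
        active = idx
    return s, n_syn, n_nonsyn


def simulate_codon_alignment(
    cfg: SimulationConfig, locus: int = 0,
    tree: Phylogeny | None = None,
    partition: BranchPartition | None = None,
) -> tuple[CodonAlignment, GroundTruthLog]:
    """Evolve one codon alignment along the study tree.

    Each site draws a fixed omega category; substitutions follow the
    MG94xHKY jump chain with category omegas on reference branches and
    omega^k on test branches. Root codons come from the model's stationary
    distribution, so the output contains no gaps and no stop codons. The
    log records the site categories and true per-branch syn/nonsyn
    substitution counts.
    """
    if cfg.k <= 0:
        raise ValueError("selection intensity k must be > 0")
    if tree is None or partition is None:
        tree, partition = cfg.study_tree()
    rng = np.random.default_rng([cfg.seed, 11, locus])
    code = get_code(cfg.table_id)
    aa = np.array(code.aa)
    syn_pair = aa[:, None] == aa[None, :]

    kernels: dict[tuple[int, bool], _GillespieKernel] = {}
    for ci, omega in enumerate(cfg.omegas):
        for is_test in (False, True):
            w = omega ** cfg.k if is_test else omega
            kernels[(ci, is_test)] = _GillespieKernel(
                Mg94Params(cfg.kappa, w, np.asarray(cfg.pi_nuc),
                           cfg.table_id)
            )

    cats = rng.choice(len(cfg.props), size=cfg.n_sites, p=cfg.props)
    pi = kernels[(0, False)].pi
    root_states = rng.choice(code.n, size=cfg.n_sites, p=pi)

    clock = (cfg.clock_subs_per_codon_per_ma if tree.unit == "Ma" else 1.0)
    states_at: dict[int, np.ndarray] = {tree.root.index: root_states}
    branch_events: dict[str, Any] = {}
    for node in reversed(tree.postorder()):  # preorder
        if node.parent is None:
            continue
        parent_states = states_at[node.parent]
        t = (node.length or 0.0) * clock
        is_test = partition.is_test(node.label)
        out = parent_states.copy()
        tot_syn = tot_nonsyn = 0
        for ci in range(len(cfg.omegas)):
            mask = cats == ci
            if not mask.any():
                continue
            new, ns, nn = _evolve_branch(
                parent_states[mask], t, kernels[(ci, is_test)], syn_pair,
                rng,
            )
            out[mask] = new
            tot_syn += ns
            tot_nonsyn += nn
        states_at[node.index] = out
        branch_events[node.label] = {"syn": tot_syn, "nonsyn": tot_nonsyn}

    codon_strings = np.array(code.codons)
    seqs = {
        leaf.label: "".join(codon_strings[states_at[leaf.index]])
        for leaf in tree.leaves()
    }
    aln = CodonAlignment(seqs, table_id=cfg.table_id)
    log = GroundTruthLog(
        seed=cfg.seed,
        kind="codon_alignment",
        locus_params={
            "locus": locus,
            "kappa": cfg.kappa,
            "omegas": list(cfg.omegas),
            "props": list(cfg.props),
            "k": cfg.k,
            "site_categories": cats.tolist(),
        },
        branch_events=branch_events,
    )
    return aln, log


# --------------------------------------------------------------------------
# gene-family counts
# --------------------------------------------------------------------------


def _bd_gillespie(n: int, lam: float, mu: float, t: float,
                  rng: np.random.Generator) -> int:
    remaining = t
    total_rate = lam + mu
    while n > 0 and total_rate > 0:
        dt = rng.exponential(1.0 / (n * total_rate))
        if dt > remaining:
            break
        remaining -= dt
        if rng.random() < lam / total_rate:
            n += 1
        else:
            n -= 1
    return n


def simulate_family_counts(
    cfg: SimulationConfig,
    tree: Phylogeny | None = None,
    partition: BranchPartition | None = None,
) -> tuple[FamilyCountTable, GroundTruthLog]:
    """Evolve gene-family counts by linear birth-death on the tree.

    Root sizes are uniform on {1..root_size_max}; each branch uses its
    class (lambda, mu) per gene per Ma; leaf counts pass through the
    epsilon error channel. Families extinct in every leaf (and the rare
    families whose observed counts are all zero) are dropped and counted.
    """
    if tree is None or partition is None:
        tree, partition = cfg.study_tree()
    for cls in set(partition.classes.values()):
        if cls not in cfg.family_rates:
            raise ValueError(f"no family rates for branch class {cls!r}")
    rng = np.random.default_rng([cfg.seed, 23])
    preorder = [n for n in reversed(tree.postorder())]
    leaves = tree.leaf_labels()

    kept_rows = []
    kept_truth = []
    dropped_extinct = 0
    dropped_unobserved = 0
    for _ in range(cfg.n_families):
        counts: dict[str, int] = {}
        counts[tree.root.label] = int(rng.integers(1, cfg.root_size_max + 1))
        for node in preorder:
            if node.parent is None:
                continue
            lam, mu = cfg.family_rates[partition.classes[node.label]]
            parent_count = counts[tree.nodes[node.parent].label]
            counts[node.label] = _bd_gillespie(
                parent_count, lam, mu, node.length or 0.0, rng
            )
        true_leaf = {sp: counts[sp] for sp in leaves}
        if all(v == 0 for v in true_leaf.values()):
            dropped_extinct += 1
            continue
        observed = {}
        for sp in leaves:
            n = true_leaf[sp]
            e = cfg.eps_for(sp)
            if e > 0 and rng.random() < e:
                n = max(n + (1 if rng.random() < 0.5 else -1), 0)
            observed[sp] = n
        if all(v == 0 for v in observed.values()):
            dropped_unobserved += 1
            continue
        kept_rows.append(observed)
        kept_truth.append(counts)

    fam_ids = [f"fam{i}" for i in range(len(kept_rows))]
    table = FamilyCountTable(
        pd.DataFrame(kept_rows, index=fam_ids, columns=leaves)
    )
    log = GroundTruthLog(
        seed=cfg.seed,
        kind="family_counts",
        locus_params={
            "family_rates": {k: list(v) for k, v in cfg.family_rates.items()},
            "eps": cfg.eps,
            "root_size_max": cfg.root_size_max,
        },
        family_counts={fid: truth for fid, truth in zip(fam_ids, kept_truth)},
        extras={
            "dropped_extinct": dropped_extinct,
            "dropped_unobserved": dropped_unobserved,
        },
    )
    return table, log


# --------------------------------------------------------------------------
# gene orders
# --------------------------------------------------------------------------


def _truncated_geometric(mean: float, upper: int,
                         rng: np.random.Generator) -> int:
    p = min(max(1.0 / max(mean, 1.0), 1e-6), 1.0)
    for _ in range(1000):
        length = int(rng.geometric(p))
        if 1 <= length <= upper:
            return length
    return 1


def _apply_event(genome: list, ev: dict) -> list:
    etype = ev["type"]
    if etype == "V":  # inversion: reverse segment, flip strands
        s, L = ev["start"], ev["length"]
        seg = [(g, "-" if st == "+" else "+", og)
               for g, st, og in reversed(genome[s: s + L])]
        return genome[:s] + seg + genome[s + L:]
    if etype == "P":  # transposition: excise, reinsert
        s, L, at = ev["start"], ev["length"], ev["insert_at"]
        seg = genome[s: s + L]
        rest = genome[:s] + genome[s + L:]
        return rest[:at] + seg + rest[at:]
    if etype == "D":  # deletion
        s, L = ev["start"], ev["length"]
        return genome[:s] + genome[s + L:]
    if etype == "U":  # tandem duplication with fresh gene ids
        s, L = ev["start"], ev["length"]
        seg = genome[s: s + L]
        copy = [
            (gid, st, og)
            for gid, (_, st, og) in zip(ev["new_gene_ids"], seg)
        ]
        return genome[: s + L] + copy + genome[s + L:]
    if etype == "I":  # insertion of novel singleton orthogroups
        at = ev["insert_at"]
        seg = list(zip(ev["new_gene_ids"], ev["strands"],
                       ev["new_orthogroups"]))
        return genome[:at] + seg + genome[at:]
    raise ValueError(f"unknown event type {etype!r}")


def simulate_gene_orders(
    cfg: SimulationConfig,
    tree: Phylogeny | None = None,
    partition: BranchPartition | None = None,
) -> tuple[dict[str, GeneOrder], GroundTruthLog]:
    """Mutate gene orders along the tree by P/I/D/V/U rearrangements.

    The root order is genes 0..n-1 on one forward-strand chromosome; on
    each branch, per-type event counts are Poisson(rate x branch Ma) and
    segment lengths are truncated-geometric (mean ``segment_mean``). A
    deletion that would empty the genome is resampled (and the resample
    recorded). Every applied event is appended to the replayable log.
    """
    if cfg.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if tree is None or partition is None:
        tree, partition = cfg.study_tree()
    rng = np.random.default_rng([cfg.seed, 37])
    root = [(f"g{i}", "+", f"og{i}") for i in range(cfg.n_genes)]
    gene_counter = cfg.n_genes
    og_counter = cfg.n_genes

    genomes: dict[int, list] = {tree.root.index: root}
    events_by_branch: dict[str, list[dict]] = {}
    resamples = 0
    for node in reversed(tree.postorder()):  # preorder
        if node.parent is None:
            continue
        genome = list(genomes[node.parent])
        t = node.length or 0.0
        schedule: list[str] = []
        for etype in sorted(cfg.rearrangement_rates):
            rate = cfg.rearrangement_rate(etype, node.label)
            count = rng.poisson(rate * t)
            schedule.extend([etype] * count)
        schedule = [schedule[i] for i in rng.permutation(len(schedule))]

        records = []
        for etype in schedule:
            n = len(genome)
            ev: dict[str, Any] = {"type": etype}
            if etype in ("V", "P", "D", "U"):
                if etype == "D":
                    if n <= 1:  # deletion may never empty the genome
                        resamples += 1
                        continue
                    L = _truncated_geometric(cfg.segment_mean, n - 1, rng)
                else:
                    L = _truncated_geometric(cfg.segment_mean, n, rng)
                ev["start"] = int(rng.integers(0, n - L + 1))
                ev["length"] = L
                if etype == "P":
                    ev["insert_at"] = int(rng.integers(0, n - L + 1))
                if etype == "U":
                    ev["new_gene_ids"] = [
                        f"g{gene_counter + i}" for i in range(L)
                    ]
                    gene_counter += L
            else:  # insertion
                L = _truncated_geometric(cfg.segment_mean, cfg.n_genes, rng)
                ev["insert_at"] = int(rng.integers(0, n + 1))
                ev["new_gene_ids"] = [
                    f"g{gene_counter + i}" for i in range(L)
                ]
                gene_counter += L
                ev["new_orthogroups"] = [
                    f"og{og_counter + i}" for i in range(L)
                ]
                og_counter += L
                ev["strands"] = [
                    "+" if rng.random() < 0.5 else "-" for _ in range(L)
                ]
            genome = _apply_event(genome, ev)
            records.append(ev)
        genomes[node.index] = genome
        events_by_branch[node.label] = records

    orders = {
        leaf.label: GeneOrder(
            genome=leaf.label,
            entries=[
                GeneEntry("chr1", i, gid, strand, og)
                for i, (gid, strand, og) in enumerate(genomes[leaf.index])
            ],
        )
        for leaf in tree.leaves()
    }
    log = GroundTruthLog(
        seed=cfg.seed,
        kind="gene_orders",
        branch_events=events_by_branch,
        extras={
            "root_order": root,
            "resampled_deletions": resamples,
        },
    )
    return orders, log


def replay_gene_orders(log: GroundTruthLog,
                       tree: Phylogeny) -> dict[str, list]:
    """Re-derive every leaf gene order from the event log alone.

    Written independently of the simulator's event application so it can
    serve as a self-consistency oracle: replaying the log from the logged
    root order must reproduce each leaf order exactly.
    """
    root = [tuple(e) for e in log.extras["root_order"]]

    def replay_event(genome: list, ev: dict) -> list:
        g = list(genome)
        if ev["type"] == "V":
            s, L = ev["start"], ev["length"]
            flipped = []
            for gid, st, og in g[s: s + L]:
                flipped.append((gid, "+" if st == "-" else "-", og))
            flipped.reverse()
            g[s: s + L] = flipped
        elif ev["type"] == "P":
            s, L = ev["start"], ev["length"]
            seg = g[s: s + L]
            del g[s: s + L]
            for offset, item in enumerate(seg):
                g.insert(ev["insert_at"] + offset, item)
        elif ev["type"] == "D":
            del g[ev["start"]: ev["start"] + ev["length"]]
        elif ev["type"] == "U":
            s, L = ev["start"], ev["length"]
            copy = [
                (nid, g[s + i][1], g[s + i][2])
                for i, nid in enumerate(ev["new_gene_ids"])
            ]
            g[s + L: s + L] = copy
        elif ev["type"] == "I":
            seg = [
                (nid, st, og)
                for nid, st, og in zip(ev["new_gene_ids"], ev["strands"],
                                       ev["new_orthogroups"])
            ]
            g[ev["insert_at"]: ev["insert_at"]] = seg
        else:
            raise ValueError(f"unknown event type {ev['type']!r}")
        return g

    result: dict[int, list] = {tree.root.index: root}
    for node in reversed(tree.postorder()):
        if node.parent is None:
            continue
        genome = result[node.parent]
        for ev in log.branch_events.get(node.label, []):
            genome = replay_event(genome, ev)
        result[node.index] = genome
    return {
        leaf.label: result[leaf.index] for leaf in tree.leaves()
    }


_SIZE_BINS = ((1, 5, "1-5"), (6, 20, "6-20"), (21, 10 ** 9, "21+"))


def _size_bin(length: int) -> str:
    for lo, hi, name in _SIZE_BINS:
        if lo <= length <= hi:
            return name
    return _SIZE_BINS[-1][2]


def mutation_counts_from_log(log: GroundTruthLog,
                             tree: Phylogeny) -> MutationCountTable:
    """Tabulate the simulator's true event counts per branch/type/size bin
    in the layout the mutation-spectrum analysis consumes."""
    rows = []
    durations = {}
    for node in tree.branches():
        if not node.length:
            continue
        durations[node.label] = float(node.length)
        tallies: dict[tuple[str, str], int] = {}
        for ev in log.branch_events.get(node.label, []):
            length = ev.get("length", len(ev.get("new_gene_ids", [])) or 1)
            key = (ev["type"], _size_bin(length))
            tallies[key] = tallies.get(key, 0) + 1
        for (etype, sbin), count in tallies.items():
            rows.append(
                {"branch": node.label, "type": etype, "size_bin": sbin,
                 "count": count}
            )
    df = pd.DataFrame(rows, columns=["branch", "type", "size_bin", "count"])
    return MutationCountTable(df, durations)
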