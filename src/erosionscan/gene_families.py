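"""Gene-family size evolution on a species tree.

Family counts evolve by a linear birth-death process: a family of size n
gains a gene at rate n*lambda and loses one at rate n*mu, with rates shared
within named branch classes. Observed leaf counts pass through a simple
per-species error channel (with probability epsilon the observed count is
the true count plus or minus one, floored at zero) that absorbs annotation
and assembly noise. The family likelihood is computed by pruning over
truncated count states, conditioned on the family not being extinct in all
leaves, which mirrors how families are constructed from clustering (an
everywhere-absent family is unobservable).

On top of the likelihood sit the analyses of branch-specific dynamics:
per-branch two-class model scans, k-means clustering of the per-branch
(lambda, mu) estimates with AIC model choice, max-posterior ancestral count
reconstruction with per-branch expansion/contraction tallies and empirical
loss rates, and profile-likelihood estimation of the per-species error
rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import expm
from sklearn.cluster import KMeans

from .phylo import Phylogeny

__all__ = [
    "FamilyCountTable",
    "BirthDeathModel",
    "bd_transition_matrix",
    "family_set_loglik",
    "fit_birth_death",
    "scan_two_class_models",
    "cluster_branch_rates",
    "infer_branch_changes",
    "estimate_observation_error",
]

RATE_BOUNDS = (math.log(1e-7), math.log(2.0))


@dataclass
class FamilyCountTable:
    """Family x species table of observed gene counts."""

    counts: pd.DataFrame  # index: family id, columns: species, int values

    def __post_init__(self):
        self.counts = self.counts.astype(int)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def max_count(self) -> int:
        return int(self.counts.values.max())

    def validate(self) -> list[str]:
        report = []
        if (self.counts.values < 0).any():
            report.append("negative counts present")
        empty = self.counts.index[(self.counts == 0).all(axis=1)]
        for fam in empty:
            report.append(f"family {fam} has zero count in every species")
        return report

    @classmethod
    def from_tsv(cls, path, exclude: set[str] | None = None) -> "FamilyCountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if exclude:
            df = df.drop(index=[f for f in exclude if f in df.index])
        return cls(df)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="family_id")


@dataclass
class BirthDeathModel:
    """Branch-class birth-death rates plus the observation-error model.

    ``rates`` maps class name -> (lambda, mu) per gene per unit time (the
    tree's time unit); ``classes`` maps branch label -> class name;
    ``eps`` maps species -> error rate in [0, 0.5] (missing species: 0).
    """

    rates: dict[str, tuple[float, float]]
    classes: dict[str, str]
    n_max: int
    eps: dict[str, float] = field(default_factory=dict)
    #: root-size prior over 0..n_max; default uniform on {1..n_max}
    root_prior: np.ndarray | None = None

    def __post_init__(self):
        for cls, (lam, mu) in self.rates.items():
            if lam < 0 or mu < 0:
                raise ValueError(f"negative rate in class {cls!r}")
        for sp, e in self.eps.items():
            if not 0.0 <= e <= 0.5:
                raise ValueError(f"eps for {sp} outside [0, 0.5]")
        if self.root_prior is None:
            prior = np.zeros(self.n_max + 1)
            prior[1:] = 1.0 / self.n_max
            self.root_prior = prior

    def branch_rates(self, branch_label: str) -> tuple[float, float]:
        return self.rates[self.classes[branch_label]]


def bd_transition_matrix(lam: float, mu: float, t: float,
                         n_max: int) -> np.ndarray:
    """Transition probabilities of the truncated linear birth-death chain.

    Entry [n, m] is P(count m at time t | count n at time 0) for the chain
    with birth rate n*lam and death rate n*mu, truncated at ``n_max``
    (births out of the cap are suppressed, so mass that would escape the
    cap accumulates in state n_max). State 0 is absorbing. Rows sum to 1.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if t < 0 or lam < 0 or mu < 0:
        raise ValueError("t, lam and mu must be non-negative")
    n = np.arange(n_max + 1, dtype=float)
    G = np.zeros((n_max + 1, n_max + 1))
    G[np.arange(n_max), np.arange(1, n_max + 1)] = lam * n[:-1]
    G[np.arange(1, n_max + 1), np.arange(n_max)] = mu * n[1:]
    np.fill_diagonal(G, -G.sum(axis=1))
    P = expm(G * t)
    return np.clip(P, 0.0, None)


def _emission_matrix(eps: float, n_max: int) -> np.ndarray:
    """P(observed | true) for the +/-1 error channel, floored at zero."""
    E = np.eye(n_max + 1) * (1.0 - eps)
    for true in range(n_max + 1):
        down = max(true - 1, 0)
        up = min(true + 1, n_max)
        E[true, down] += eps / 2.0
        E[true, up] += eps / 2.0
    return E


class _FamilyPruner:
    """Vectorized count-state pruning over all families at once."""

    def __init__(self, table: FamilyCountTable, tree: Phylogeny,
                 n_max: int):
        missing = [sp for sp in tree.leaf_labels() if sp not in table.species]
        if missing:
            raise ValueError(f"species missing from count table: {missing}")
        if table.max_count > n_max:
            raise ValueError(
                f"observed count {table.max_count} exceeds n_max={n_max}; "
                "increase the cap"
            )
        self.table = table
        self.tree = tree
        self.n_max = n_max
        self.post = tree.postorder()
        self.obs = {
            sp: table.counts[sp].to_numpy() for sp in tree.leaf_labels()
        }
        self.n_fam = len(table.families)

    def _transition(self, model: BirthDeathModel, node) -> np.ndarray:
        lam, mu = model.branch_rates(node.label)
        return bd_transition_matrix(lam, mu, node.length or 0.0, self.n_max)

    def family_likelihoods(self, model: BirthDeathModel) -> np.ndarray:
        """P(observed counts | root prior), one value per family."""
        partial: dict[int, np.ndarray] = {}
        for node in self.post:
            if node.is_leaf:
                E = _emission_matrix(model.eps.get(node.label, 0.0),
                                     self.n_max)
                down = E[:, self.obs[node.label]].T  # (n_fam, n_states)
            else:
                down = np.ones((self.n_fam, self.n_max + 1))
                for c in node.children:
                    down = down * partial.pop(c)
            if node.parent is None:
                return down @ model.root_prior
            P = self._transition(model, node)
            partial[node.index] = down @ P.T
        raise RuntimeError("unreachable")

    def survival_probability(self, model: BirthDeathModel) -> float:
        """P(at least one leaf has true count > 0 | root prior)."""
        partial: dict[int, np.ndarray] = {}
        for node in self.post:
            if node.is_leaf:
                down = np.zeros(self.n_max + 1)
                down[0] = 1.0  # leaf truly extinct
            else:
                down = np.ones(self.n_max + 1)
                for c in node.children:
                    down = down * partial.pop(c)
            if node.parent is None:
                return 1.0 - float(down @ model.root_prior)
            P = self._transition(model, node)
            partial[node.index] = P @ down
        raise RuntimeError("unreachable")

    def loglik(self, model: BirthDeathModel) -> float:
        lik = self.family_likelihoods(model)
        surv = self.survival_probability(model)
        if surv <= 0:
            return -math.inf
        return float(np.sum(np.log(np.maximum(lik, 1e-300)))
                     - self.n_fam * math.log(surv))


def default_n_max(table: FamilyCountTable, slack: int = 10,
                  cap: int = 100) -> int:
    return min(table.max_count + slack, cap)


def family_set_loglik(table: FamilyCountTable, tree: Phylogeny,
                      model: BirthDeathModel) -> float:
    """Log-likelihood of the whole family table under a birth-death model,
    conditioned on non-extinction across all leaves."""
    return _FamilyPruner(table, tree, model.n_max).loglik(model)


def fit_birth_death(table: FamilyCountTable, tree: Phylogeny,
                    classes: dict[str, str], n_max: int | None = None,
                    eps: dict[str, float] | None = None,
                    restarts: int = 4, seed: int = 0,
                    tie_rates: bool = False,
                    root_prior: np.ndarray | None = None):
    """ML fit of per-class (lambda, mu) rates.

    Returns ``(model, lnL, converged)``. With ``tie_rates`` each class has a
    single rate lambda = mu.
    """
    if n_max is None:
        n_max = default_n_max(table)
    eps = eps or {}
    class_names = sorted(set(classes.values()))
    pruner = _FamilyPruner(table, tree, n_max)
    per_class = 1 if tie_rates else 2
    rng = np.random.default_rng(seed)

    def build(x):
        rates = {}
        for i, cls in enumerate(class_names):
            if tie_rates:
                lam = mu = math.exp(x[i])
            else:
                lam, mu = math.exp(x[2 * i]), math.exp(x[2 * i + 1])
            rates[cls] = (lam, mu)
        return BirthDeathModel(rates=rates, classes=classes, n_max=n_max,
                               eps=eps, root_prior=root_prior)

    def nll(x):
        return -pruner.loglik(build(x))

    ndim = per_class * len(class_names)
    starts = [np.full(ndim, math.log(0.002))]
    for _ in range(max(restarts - 1, 0)):
        starts.append(rng.uniform(math.log(1e-5), math.log(0.1), size=ndim))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=[RATE_BOUNDS] * ndim,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    return build(best.x), -float(best.fun), bool(best.success)


@dataclass
class BranchRateEstimates:
    """Per-branch (lambda, mu) from the focal two-class model scan."""

    estimates: dict[str, tuple[float, float]]
    loglik: dict[str, float]
    converged: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "branch": b,
                "lambda": lam,
                "mu": mu,
                "lnL": self.loglik[b],
                "converged": self.converged[b],
            }
            for b, (lam, mu) in self.estimates.items()
        ]
        return pd.DataFrame(rows).set_index("branch")


def _scan_branches(tree: Phylogeny) -> list[str]:
    labels = tree.branch_labels()
    if tree.root.length is not None:
        labels = labels + [tree.root.label]
    return labels


def scan_two_class_models(table: FamilyCountTable, tree: Phylogeny,
                          n_max: int | None = None,
                          eps: dict[str, float] | None = None,
                          restarts: int = 8, seed: int = 0,
                          tie_rates: bool = False,
                          root_prior: np.ndarray | None = None
                          ) -> BranchRateEstimates:
    """Fit, for every branch, the two-class model {focal branch} vs {rest}.

    Each focal model gives the branch its own (lambda, mu) while all other
    branches share a second pair; each fit is restarted ``restarts`` times
    (default 8) from random initial rates. The focal branch's fitted pair is
    recorded together with the model's best log-likelihood. A root-stem
    branch is included only when the root carries an edge length.
    """
    if len(tree.branches()) < 2:
        raise ValueError("need at least 2 branches")
    branch_labels = [b for b in _scan_branches(tree)
                     if b != tree.root.label or tree.root.length]
    estimates, lls, conv = {}, {}, {}
    for i, focal in enumerate(branch_labels):
        classes = {
            b: ("focal" if b == focal else "rest")
            for b in tree.branch_labels()
        }
        model, ll, ok = fit_birth_death(
            table, tree, classes, n_max=n_max, eps=eps,
            restarts=restarts, seed=seed + 7919 * i, tie_rates=tie_rates,
            root_prior=root_prior,
        )
        # the root-stem focal model carries no branch of its own in the
        # pruning, so it degenerates to the homogeneous fit
        estimates[focal] = model.rates.get("focal", model.rates["rest"])
        lls[focal] = ll
        conv[focal] = ok
    return BranchRateEstimates(estimates, lls, conv)


@dataclass
class ClusteredRates:
    chosen_k: int
    assignment: dict[str, int]
    model: BirthDeathModel
    loglik: float
    aic_by_k: dict[int, float]

    def to_dict(self) -> dict:
        """JSON-ready summary of the clustering outcome."""
        return {
            "chosen_k": self.chosen_k,
            "assignment": dict(self.assignment),
            "rates": {c: list(r) for c, r in self.model.rates.items()},
            "loglik": self.loglik,
            "aic_by_k": {str(k): v for k, v in self.aic_by_k.items()},
        }


def cluster_branch_rates(estimates: BranchRateEstimates,
                         table: FamilyCountTable, tree: Phylogeny,
                         k_range=range(2, 9), nstart: int = 1000,
                         n_max: int | None = None,
                         eps: dict[str, float] | None = None,
                         restarts: int = 2, seed: int = 0,
                         root_prior: np.ndarray | None = None
                         ) -> ClusteredRates:
    """Cluster per-branch (lambda, mu) estimates and choose k by AIC.

    k-means with ``nstart`` random initial-center sets groups branches into
    shared rate classes; for each k the clustered model is refit by ML and
    scored with AIC = 2 * (2k) - 2 lnL. The smallest AIC wins; ties go to
    smaller k. Deterministic under a fixed seed.
    """
    branches = list(estimates.estimates)
    X = np.array([estimates.estimates[b] for b in branches])
    results = {}
    best = None
    for k in k_range:
        if k > len(branches):
            raise ValueError(
                f"k={k} exceeds the number of branches ({len(branches)})"
            )
        n_distinct = len({tuple(row) for row in X})
        km = KMeans(n_clusters=min(k, n_distinct), n_init=nstart,
                    random_state=seed, algorithm="lloyd").fit(X)
        labels = {b: int(l) for b, l in zip(branches, km.labels_)}
        # branches absent from the scan fall back to the first cluster
        classes = {
            b: f"c{labels.get(b, labels[branches[0]])}"
            for b in tree.branch_labels()
        }
        model, ll, _ = fit_birth_death(
            table, tree, classes, n_max=n_max, eps=eps,
            restarts=restarts, seed=seed + k, root_prior=root_prior,
        )
        n_params = 2 * len(set(classes.values()))
        aic = 2.0 * n_params - 2.0 * ll
        results[k] = aic
        if best is None or aic < best[1] - 1e-9:
            best = (k, aic, labels, model, ll)
    k, _, labels, model, ll = best
    return ClusteredRates(chosen_k=k, assignment=labels, model=model,
                          loglik=ll, aic_by_k=results)


def reconstruct_ancestral_counts(table: FamilyCountTable, tree: Phylogeny,
                                 model: BirthDeathModel) -> dict[str, np.ndarray]:
    """Joint max-posterior count at every node, per family.

    Dynamic-programming (Viterbi-style) reconstruction over the truncated
    count states; ties break toward the smaller count. Returns
    node label -> integer array over families.
    """
    pruner = _FamilyPruner(table, tree, model.n_max)
    n_states = model.n_max + 1
    n_fam = pruner.n_fam
    logV: dict[int, np.ndarray] = {}
    back: dict[int, np.ndarray] = {}  # child idx -> argmax per parent state

    with np.errstate(divide="ignore"):
        for node in pruner.post:
            if node.is_leaf:
                E = _emission_matrix(model.eps.get(node.label, 0.0),
                                     model.n_max)
                logV[node.index] = np.log(
                    np.maximum(E[:, pruner.obs[node.label]].T, 1e-300)
                )
            else:
                acc = np.zeros((n_fam, n_states))
                for c in node.children:
                    child = pruner.tree.nodes[c]
                    P = pruner._transition(model, child)
                    logP = np.log(np.maximum(P, 1e-300))
                    # (n_fam, parent_state, child_state)
                    M = logP[None, :, :] + logV.pop(c)[:, None, :]
                    back[c] = np.argmax(M, axis=2)
                    acc += np.max(M, axis=2)
                logV[node.index] = acc

        root = pruner.tree.root
        log_prior = np.log(np.maximum(model.root_prior, 1e-300))
        root_score = logV.pop(root.index) + log_prior[None, :]
        states = {root.label: np.argmax(root_score, axis=1)}
        # preorder assignment via stored pointers
        order = [n for n in reversed(pruner.post) if n.parent is not None]
        assigned = {root.index: states[root.label]}
        for node in order:
            parent_states = assigned[node.parent]
            s = back[node.index][np.arange(n_fam), parent_states]
            assigned[node.index] = s
            states[node.label] = s
    return states


def infer_branch_changes(table: FamilyCountTable, tree: Phylogeny,
                         model: BirthDeathModel) -> pd.DataFrame:
    """Per-branch expansions, contractions and empirical loss rate.

    Expansions/contractions count families whose reconstructed child count
    exceeds/falls below the parent count. The loss rate is the summed
    per-family count decrease divided by (summed parent counts x branch
    duration in thousand years); absent (NaN) on zero-duration branches.
    The tree's branch lengths are taken to be in Ma.
    """
    states = reconstruct_ancestral_counts(table, tree, model)
    rows = []
    for node in tree.branches():
        parent = tree.nodes[node.parent]
        child_counts = states[node.label]
        parent_counts = states[parent.label]
        diff = child_counts.astype(int) - parent_counts.astype(int)
        losses = int(np.sum(np.maximum(-diff, 0)))
        t_kyr = (node.length or 0.0) * 1000.0
        denom = float(parent_counts.sum()) * t_kyr
        rows.append(
            {
                "branch": node.label,
                "expansions": int(np.sum(diff > 0)),
                "contractions": int(np.sum(diff < 0)),
                "loss_per_gene_per_kyr": (losses / denom) if denom > 0
                else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("branch")


def estimate_observation_error(table: FamilyCountTable, tree: Phylogeny,
                               model: BirthDeathModel,
                               grid: np.ndarray | None = None,
                               sweeps: int = 2):
    """Profile-likelihood estimate of per-species error rates.

    For each species in turn, the model's epsilon for that species is moved
    along ``grid`` (default 0, 0.01, ..., 0.2) with all other parameters
    fixed, keeping the grid value that maximizes the family-set likelihood;
    the sweep over species is repeated ``sweeps`` times. Returns
    ``(eps_hat, profiles)`` where profiles maps species -> lnL array over
    the grid from the final sweep.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 0.201, 0.01), 10)
    pruner = _FamilyPruner(table, tree, model.n_max)
    eps = {sp: model.eps.get(sp, 0.0) for sp in tree.leaf_labels()}
    profiles: dict[str, np.ndarray] = {}
    for _ in range(sweeps):
        for sp in tree.leaf_labels():
            lls = []
            for e in grid:
                trial = dict(eps)
                trial[sp] = float(e)
                m = BirthDeathModel(rates=model.rates, classes=model.classes,
                                    n_max=model.n_max, eps=trial,
                                    root_prior=model.root_prior)
                lls.append(pruner.loglik(m))
            lls = np.asarray(lls)
            eps[sp] = float(grid[int(np.argmax(lls))])
            profiles[sp] = lls
    return eps, profiles
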