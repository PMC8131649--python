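"""Codon substitution model and the branch-set selection-intensity test.

The substitution process is MG94xHKY: codons substitute one nucleotide at a
time, at rate proportional to the stationary frequency of the target
nucleotide, multiplied by kappa for transitions and by omega (dN/dS) for
nonsynonymous changes. The matrix is scaled so a branch length of 1 equals
one expected substitution per codon site at stationarity.

The relaxation/intensification test fits a three-category omega mixture
(omega_1 <= omega_2 <= 1 <= omega_3 with proportions p_i) shared by all
branches, plus a selection-intensity parameter k that exponentiates every
category on the "test" branch set (omega_i^k). k < 1 compresses rates
toward neutrality (relaxed selection); k > 1 pushes them away
(intensification). The null model fixes k = 1 and the LRT statistic is
referred to a chi-square with one degree of freedom.

Site categories are fixed across the whole tree (no branch-site random
effects); this preserves the k != 1 hypothesis and df = 1 test while
remaining fully tractable and oracle-testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from ._codons import NUC_INDEX, get_code
from .alignments import CodonAlignment, UNAMBIGUOUS
from .phylo import BranchPartition, Phylogeny

__all__ = [
    "Mg94Params",
    "RelaxModel",
    "RelaxResult",
    "mg94_rate_matrix",
    "alignment_loglik",
    "fit_relax",
    "fit_single_omega",
    "background_omega",
    "summarize_selection_intensity",
    "benjamini_hochberg",
]

# optimizer bounds (log scale where noted)
KAPPA_BOUNDS = (math.log(0.05), math.log(50.0))
K_BOUNDS = (math.log(0.01), math.log(50.0))
OMEGA3_MAX = 100.0


@dataclass
class Mg94Params:
    """MG94xHKY parameters.

    ``pi_nuc`` are the stationary nucleotide frequencies (F1x4); the implied
    61-codon stationary distribution is the product over positions,
    renormalized over sense codons, available as :attr:`pi`.
    """

    kappa: float = 2.0
    omega: float = 1.0
    pi_nuc: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    table_id: int = 1

    def __post_init__(self):
        self.pi_nuc = np.asarray(self.pi_nuc, dtype=float)
        if self.kappa < 0 or self.omega < 0:
            raise ValueError("kappa and omega must be non-negative")
        if abs(self.pi_nuc.sum() - 1.0) > 1e-8:
            raise ValueError("nucleotide frequencies must sum to 1")

    @property
    def pi(self) -> np.ndarray:
        """Stationary codon distribution (61-vector summing to 1)."""
        code = get_code(self.table_id)
        p = self.pi_nuc[code.codon_nuc].prod(axis=1)
        return p / p.sum()

    @classmethod
    def f1x4(cls, aln: CodonAlignment, kappa: float = 2.0,
             omega: float = 1.0) -> "Mg94Params":
        """Empirical F1x4 frequencies from an alignment (gaps ignored)."""
        counts = np.zeros(4)
        for seq in aln.sequences.values():
            for ch in seq.upper():
                i = NUC_INDEX.get(ch)
                if i is not None:
                    counts[i] += 1
        if counts.sum() == 0:
            raise ValueError("alignment contains no unambiguous nucleotides")
        return cls(kappa=kappa, omega=omega, pi_nuc=counts / counts.sum(),
                   table_id=aln.table_id)


def mg94_rate_matrix(params: Mg94Params) -> tuple[np.ndarray, np.ndarray]:
    """Build the scaled MG94xHKY rate matrix.

    Returns ``(Q, pi)`` where Q is 61x61 with rows summing to zero, scaled
    so that ``-sum_i pi_i Q_ii = 1`` (one expected substitution per codon
    site per unit branch length at stationarity), and ``pi`` is the
    stationary codon distribution. The chain is reversible:
    ``pi_x Q_xy = pi_y Q_yx``.
    """
    if np.any(params.pi_nuc <= 0):
        zero = [n for n, i in NUC_INDEX.items() if params.pi_nuc[i] <= 0]
        raise ValueError(f"zero stationary frequency for nucleotide(s) {zero}")
    code = get_code(params.table_id)
    n = code.n
    Q = np.zeros((n, n))
    rates = params.pi_nuc[code.pair_target].copy()
    rates[code.pair_ts] *= params.kappa
    rates[~code.pair_syn] *= params.omega
    Q[code.pair_i, code.pair_j] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = params.pi
    scale = -np.dot(pi, np.diag(Q))
    if scale > 0:
        Q = Q / scale
    return Q, pi


def _spectral(Q: np.ndarray, pi: np.ndarray):
    """Symmetrized eigendecomposition of a reversible generator.

    Returns ``(A, w, B)`` with ``expm(Q t) = A @ diag(exp(w t)) @ B``.
    """
    d = np.sqrt(pi)
    S = Q * d[:, None] / d[None, :]
    S = (S + S.T) / 2.0
    w, U = np.linalg.eigh(S)
    A = U / d[:, None]
    B = (U * d[:, None]).T
    return A, w, B


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Qt) via the reversible spectral form (t >= 0)."""
    A, w, B = _spectral(Q, pi)
    P = (A * np.exp(w * t)) @ B
    return np.clip(P, 0.0, None)


@dataclass
class RelaxModel:
    """Three-category omega mixture with branch-set selection intensity."""

    omegas: tuple[float, float, float]
    props: tuple[float, float, float]
    k: float = 1.0
    kappa: float = 2.0
    pi_nuc: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    table_id: int = 1

    def __post_init__(self):
        self.pi_nuc = np.asarray(self.pi_nuc, dtype=float)
        if abs(sum(self.props) - 1.0) > 1e-8:
            raise ValueError("category proportions must sum to 1")
        if self.k <= 0:
            raise ValueError("selection intensity k must be > 0")
        o1, o2, o3 = self.omegas
        if not (o1 <= o2 <= 1.0 <= o3):
            raise ValueError("omega categories must satisfy w1 <= w2 <= 1 <= w3")

    def effective_omegas(self, branch_set: str) -> tuple[float, ...]:
        """Category omegas on a branch set ('test' applies the exponent k)."""
        if branch_set == BranchPartition.TEST:
            return tuple(o ** self.k for o in self.omegas)
        return tuple(self.omegas)


class _CodonPruner:
    """Felsenstein pruning over compressed codon-site patterns."""

    def __init__(self, aln: CodonAlignment, tree: Phylogeny,
                 partition: BranchPartition | None = None,
                 branch_scale: float = 1.0):
        code = get_code(aln.table_id)
        self.code = code
        leaves = tree.leaf_labels()
        missing = [sp for sp in leaves if sp not in aln.sequences]
        if missing:
            raise ValueError(
                f"species in tree but absent from alignment: {missing}"
            )
        if aln.length % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

        # integer-encode codon columns; -1 marks gap/ambiguity (missing data)
        ncod = aln.n_codons
        obs = np.empty((len(leaves), ncod), dtype=np.int64)
        for r, sp in enumerate(leaves):
            seq = aln.sequences[sp].upper()
            for s in range(ncod):
                codon = seq[3 * s: 3 * s + 3]
                if set(codon) - UNAMBIGUOUS:
                    obs[r, s] = -1
                else:
                    idx = code.index.get(codon)
                    if idx is None:
                        raise ValueError(
                            f"in-frame stop codon {codon} in {sp}"
                        )
                    obs[r, s] = idx
        patterns, weights = np.unique(obs, axis=1, return_counts=True)
        self.patterns = patterns
        self.weights = weights.astype(float)
        self.leaf_row = {sp: r for r, sp in enumerate(leaves)}
        self.tree = tree
        self.partition = partition
        self.post = tree.postorder()
        self.n_sites = ncod
        self.branch_scale = float(branch_scale)
        # memoization across optimizer evaluations: finite-difference steps
        # perturb one parameter at a time, so most category matrices and
        # per-pattern likelihood vectors repeat between calls
        self._pi_nuc_key: bytes | None = None
        self._spectral_cache: dict = {}
        self._site_cache: dict = {}

    def _set_frequencies(self, pi_nuc: np.ndarray) -> None:
        key = np.asarray(pi_nuc, dtype=float).tobytes()
        if key != self._pi_nuc_key:
            self._pi_nuc_key = key
            self._spectral_cache.clear()
            self._site_cache.clear()

    def _spectral_for(self, kappa: float, omega: float, pi_nuc, table_id):
        key = (kappa, omega)
        hit = self._spectral_cache.get(key)
        if hit is None:
            Q, pi = mg94_rate_matrix(
                Mg94Params(kappa, omega, pi_nuc, table_id)
            )
            hit = (_spectral(Q, pi), pi)
            if len(self._spectral_cache) > 4096:
                self._spectral_cache.clear()
            self._spectral_cache[key] = hit
        return hit

    def _branch_is_test(self, node) -> bool:
        if self.partition is None:
            return False
        return self.partition.is_test(node.label)

    def site_likelihoods(self, Q_ref: np.ndarray, Q_test: np.ndarray,
                         pi: np.ndarray) -> np.ndarray:
        """Per-pattern likelihood for one rate category."""
        spec_ref = _spectral(Q_ref, pi)
        spec_test = _spectral(Q_test, pi) if Q_test is not Q_ref else spec_ref
        return self._site_likelihoods(spec_ref, spec_test, pi)

    def _site_likelihoods(self, spec_ref, spec_test, pi) -> np.ndarray:
        nstates = pi.shape[0]
        npat = self.patterns.shape[1]
        partial: dict[int, np.ndarray] = {}
        for node in self.post:
            if node.parent is None:
                continue
            A, w, B = spec_test if self._branch_is_test(node) else spec_ref
            t = (node.length or 0.0) * self.branch_scale
            P = np.clip((A * np.exp(w * t)) @ B, 0.0, None)
            if node.is_leaf:
                states = self.patterns[self.leaf_row[node.label]]
                msg = np.ones((nstates, npat))
                seen = states >= 0
                msg[:, seen] = P[:, states[seen]]
            else:
                X = np.ones((nstates, npat))
                for c in node.children:
                    X *= partial.pop(c)
                msg = P @ X
            partial[node.index] = msg
        root = self.tree.root
        X = np.ones((nstates, npat))
        for c in root.children:
            X *= partial.pop(c)
        return pi @ X

    def loglik(self, model: RelaxModel) -> float:
        self._set_frequencies(model.pi_nuc)
        mix = np.zeros(self.patterns.shape[1])
        has_test = (
            self.partition is not None and bool(self.partition.test_branches)
        )
        for omega, omega_t, p in zip(
            model.omegas, model.effective_omegas("test"), model.props
        ):
            if p <= 0:
                continue
            if not has_test:
                omega_t = omega
            key = (model.kappa, omega, omega_t)
            site = self._site_cache.get(key)
            if site is None:
                spec_ref, pi = self._spectral_for(
                    model.kappa, omega, model.pi_nuc, model.table_id
                )
                if omega_t != omega:
                    spec_test, _ = self._spectral_for(
                        model.kappa, omega_t, model.pi_nuc, model.table_id
                    )
                else:
                    spec_test = spec_ref
                site = self._site_likelihoods(spec_ref, spec_test, pi)
                if len(self._site_cache) > 4096:
                    self._site_cache.clear()
                self._site_cache[key] = site
            mix += p * site
        return float(np.dot(self.weights, np.log(np.maximum(mix, 1e-300))))


def alignment_loglik(aln: CodonAlignment, tree: Phylogeny,
                     partition: BranchPartition | None,
                     model: RelaxModel,
                     branch_scale: float = 1.0) -> float:
    """Mixture pruning log-likelihood of a codon alignment.

    Gaps and ambiguous codons are treated as missing data (all-ones partial
    likelihoods); site patterns are compressed before pruning.
    ``branch_scale`` converts the tree's branch-length unit into expected
    substitutions per codon site (e.g. a subs/codon/Ma clock when the tree
    is in Ma; leave at 1.0 for trees already in substitution units).
    """
    return _CodonPruner(aln, tree, partition, branch_scale).loglik(model)


@dataclass
class RelaxResult:
    """Outcome of the branch-set relaxation/intensification test."""

    gene: str | None
    lnL_alt: float
    lnL_null: float
    lrt: float
    p: float
    k: float
    kappa: float
    omegas: tuple[float, float, float]
    props: tuple[float, float, float]
    null_omegas: tuple[float, float, float]
    null_props: tuple[float, float, float]
    null_kappa: float
    pi_nuc: np.ndarray
    q: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def log2_k(self) -> float:
        return math.log2(self.k)

    def effective_omegas(self, branch_set: str) -> tuple[float, ...]:
        if branch_set == BranchPartition.TEST:
            return tuple(o ** self.k for o in self.omegas)
        return tuple(self.omegas)

    def mean_omega(self, branch_set: str) -> float:
        """Proportion-weighted mean omega on a branch set."""
        eff = self.effective_omegas(branch_set)
        return float(sum(p * o for p, o in zip(self.props, eff)))

    @property
    def omega_bg_test(self) -> float | None:
        return background_omega(self, BranchPartition.TEST)

    @property
    def omega_bg_ref(self) -> float | None:
        return background_omega(self, BranchPartition.REFERENCE)


def _unpack(x, with_k: bool):
    log_kappa, q1, q2, u, omega2, omega3 = x[:6]
    k = math.exp(x[6]) if with_k else 1.0
    p1 = q1
    p2 = (1.0 - q1) * q2
    p3 = max(1.0 - p1 - p2, 0.0)
    omegas = (u * omega2, omega2, omega3)
    return math.exp(log_kappa), omegas, (p1, p2, p3), k


_BOUNDS_BASE = [
    KAPPA_BOUNDS,
    (1e-3, 1 - 1e-3),
    (1e-3, 1 - 1e-3),
    (1e-3, 1.0),
    (1e-4, 1.0),
    (1.0, OMEGA3_MAX),
]
_DEFAULT_START = [math.log(2.0), 0.55, 0.7, 0.3, 0.6, 1.5]


def _random_start(rng: np.random.Generator, with_k: bool) -> list[float]:
    x = [
        rng.uniform(math.log(0.5), math.log(8.0)),
        rng.uniform(0.2, 0.8),
        rng.uniform(0.2, 0.8),
        rng.uniform(0.05, 0.95),
        rng.uniform(0.2, 0.95),
        rng.uniform(1.0, 4.0),
    ]
    if with_k:
        x.append(rng.uniform(math.log(0.2), math.log(5.0)))
    return x


def _minimize(fun, starts, bounds):
    best = None
    for x0 in starts:
        res = optimize.minimize(
            fun, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-9
            and len(res.x) == 7
            and abs(res.x[6]) < abs(best.x[6])
        ):
            best = res
    return best


def fit_relax(aln: CodonAlignment, tree: Phylogeny,
              partition: BranchPartition, gene: str | None = None,
              restarts: int = 3, seed: int = 0,
              branch_scale: float = 1.0) -> RelaxResult:
    """Fit the relaxation/intensification model and run the k = 1 LRT.

    The alternative model maximizes the likelihood over
    {kappa, p_i, omega_i, k}; the null fixes k = 1. LRT = 2 (lnL_alt -
    lnL_null), referred to chi-square(df = 1). k-hat < 1 is interpreted as
    relaxed and k-hat > 1 as intensified selection on the test branches.
    Nonconvergence after the restart budget is flagged, never silent.
    """
    if len(aln.sequences) < 3:
        raise ValueError("need at least 3 species")
    if not partition.test_branches or not partition.reference_branches:
        raise ValueError("test and reference branch sets must be non-empty")
    rng = np.random.default_rng(seed)
    pi_nuc = Mg94Params.f1x4(aln).pi_nuc
    pruner = _CodonPruner(aln, tree, partition, branch_scale)

    def make_obj(with_k):
        def obj(x):
            kappa, omegas, props, k = _unpack(x, with_k)
            model = RelaxModel(omegas, props, k, kappa, pi_nuc, aln.table_id)
            return -pruner.loglik(model)
        return obj

    null_starts = [list(_DEFAULT_START)] + [
        _random_start(rng, False) for _ in range(max(restarts - 1, 0))
    ]
    null_res = _minimize(make_obj(False), null_starts, _BOUNDS_BASE)

    alt_starts = [list(null_res.x) + [0.0],
                  list(null_res.x) + [math.log(0.4)],
                  list(null_res.x) + [math.log(2.5)]]
    alt_starts += [_random_start(rng, True) for _ in range(max(restarts - 1, 0))]
    alt_res = _minimize(
        make_obj(True), alt_starts, _BOUNDS_BASE + [list(K_BOUNDS)]
    )

    flags = []
    if not null_res.success or not alt_res.success:
        flags.append("nonconvergence")
    lnL_null = -float(null_res.fun)
    lnL_alt = -float(alt_res.fun)
    lrt = 2.0 * (lnL_alt - lnL_null)
    if lrt < -1e-6:
        flags.append("lrt_negative")
    kappa_a, omegas_a, props_a, k_a = _unpack(alt_res.x, True)
    kappa_0, omegas_0, props_0, _ = _unpack(null_res.x, False)
    return RelaxResult(
        gene=gene,
        lnL_alt=lnL_alt,
        lnL_null=lnL_null,
        lrt=lrt,
        p=float(stats.chi2.sf(max(lrt, 0.0), df=1)),
        k=k_a,
        kappa=kappa_a,
        omegas=omegas_a,
        props=props_a,
        null_omegas=omegas_0,
        null_props=props_0,
        null_kappa=kappa_0,
        pi_nuc=pi_nuc,
        flags=flags,
    )


def fit_single_omega(aln: CodonAlignment, tree: Phylogeny,
                     kappa: float | None = None,
                     branch_scale: float = 1.0) -> tuple[float, float, float]:
    """Single-category ML estimate of a global dN/dS.

    Returns ``(omega_hat, kappa_hat, lnL)``. When ``kappa`` is given it is
    held fixed and only omega is optimized (1-D bounded search); otherwise
    kappa and omega are optimized jointly.
    """
    pi_nuc = Mg94Params.f1x4(aln).pi_nuc
    pruner = _CodonPruner(aln, tree, None, branch_scale)

    def nll(log_omega, log_kappa):
        params = Mg94Params(math.exp(log_kappa), math.exp(log_omega),
                            pi_nuc, aln.table_id)
        Q, pi = mg94_rate_matrix(params)
        site = pruner.site_likelihoods(Q, Q, pi)
        return -float(
            np.dot(pruner.weights, np.log(np.maximum(site, 1e-300)))
        )

    if kappa is not None:
        res = optimize.minimize_scalar(
            lambda lo: nll(lo, math.log(kappa)),
            bounds=(math.log(1e-3), math.log(20.0)), method="bounded",
            options={"xatol": 1e-6},
        )
        return math.exp(res.x), kappa, -float(res.fun)
    res = optimize.minimize(
        lambda x: nll(x[0], x[1]), [0.0, math.log(2.0)],
        method="L-BFGS-B",
        bounds=[(math.log(1e-3), math.log(20.0)), KAPPA_BOUNDS],
        options={"maxiter": 200, "ftol": 1e-10},
    )
    return math.exp(res.x[0]), math.exp(res.x[1]), -float(res.fun)


def background_omega(result: RelaxResult, branch_set: str) -> float | None:
    """Proportion-weighted background omega over the two sub-neutral
    categories, ``(p1 w1 + p2 w2) / (p1 + p2)``, with the test set using
    ``w_i^k``. Returns None when p1 + p2 = 0."""
    eff = result.effective_omegas(branch_set)
    p1, p2 = result.props[0], result.props[1]
    if p1 + p2 <= 0:
        return None
    return (p1 * eff[0] + p2 * eff[1]) / (p1 + p2)


#: log2(k) bin edges of the selection-intensity summary; left-closed
LOG2K_BINS = ((-math.inf, -2.0), (-2.0, 0.0), (0.0, 2.0), (2.0, math.inf))


@dataclass
class SelectionSummary:
    bin_counts: tuple[int, int, int, int]
    retained: list[RelaxResult]
    excluded: list[RelaxResult]
    relaxed_significant: list[RelaxResult]
    intensified_significant: list[RelaxResult]


def summarize_selection_intensity(
    results: list[RelaxResult], rate_cap: float = 10.0,
    fdr: float = 0.1,
) -> SelectionSummary:
    """Filter, bin and FDR-screen a collection of per-gene test results.

    Genes whose proportion-weighted mean omega on either branch set exceeds
    ``rate_cap`` (strictly) are excluded. Remaining log2(k-hat) values are
    counted into left-closed bins (-inf,-2), [-2,0), [0,2), [2,inf)
    (log2(1) = 0 falls in [0,2)). Genes significant at the given FDR are
    split into relaxed (k < 1) and intensified (k > 1) sets; q-values are
    written back onto the retained results.
    """
    retained, excluded = [], []
    for r in results:
        if max(r.mean_omega("test"), r.mean_omega("reference")) > rate_cap:
            excluded.append(r)
        else:
            retained.append(r)
    counts = [0, 0, 0, 0]
    for r in retained:
        v = r.log2_k
        for b, (lo, hi) in enumerate(LOG2K_BINS):
            if lo <= v < hi:
                counts[b] += 1
                break
    relaxed, intensified = [], []
    if retained:
        qvals = benjamini_hochberg([r.p for r in retained])
        for r, q in zip(retained, qvals):
            r.q = float(q)
            if q < fdr:
                (relaxed if r.k < 1 else intensified).append(r)
    return SelectionSummary(
        bin_counts=tuple(counts),
        retained=retained,
        excluded=excluded,
        relaxed_significant=relaxed,
        intensified_significant=intensified,
    )


def relax_results_to_frame(results: list[RelaxResult]):
    """Per-gene results table (one row per gene, TSV-ready)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "lnL_alt": r.lnL_alt,
                "lnL_null": r.lnL_null,
                "LRT": r.lrt,
                "p": r.p,
                "q": r.q,
                "k": r.k,
                "log2k": r.log2_k,
                "omega_bg_test": r.omega_bg_test,
                "omega_bg_ref": r.omega_bg_ref,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
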