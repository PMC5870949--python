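"""Branch codon-model (GY94 + F3X4) likelihoods and the dN/dS LRT.

The Goldman-Yang codon substitution model assigns instantaneous rates over
the 61 sense codons:

    q_cd = 0                      if c,d differ at >1 nucleotide
         = pi_d                   synonymous transversion
         = kappa * pi_d           synonymous transition
         = omega * pi_d           nonsynonymous transversion
         = omega * kappa * pi_d   nonsynonymous transition

with the diagonal set so rows sum to zero and the matrix rescaled so that
branch lengths are expected substitutions per codon. Equilibrium codon
frequencies pi come from F3X4: empirical nucleotide frequencies estimated
separately at the three codon positions, multiplied per codon, with stop
codons removed and the rest renormalized.

Two branch models are supported: one-ratio (a single dN/dS = omega shared
by every branch) and two-ratio (a distinct omega on branches flagged as
foreground, e.g. the stem branch of a duplicate's clade). The models are
nested; 2*(lnL_two - lnL_one) is compared against chi-square with 1 df.
A foreground omega above 1 with a significant LRT is the signature of
episodic positive selection on the foreground branch.

Likelihoods are computed by Felsenstein pruning over codon-site patterns,
with gap codons treated as missing data (partial likelihood 1 over all
states). The matrix exponential uses the eigendecomposition of the model
in the pi^(1/2)-symmetrized basis, exact for this reversible model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .sequence_io import (
    CODON_INDEX,
    SENSE_CODONS,
    CodonAlignment,
    LabeledTree,
    _STANDARD_TABLE,
    check_tree_alignment,
)

N_CODONS = len(SENSE_CODONS)  # 61

_NUC_INDEX = {n: i for i, n in enumerate("ACGT")}
_PURINES = {"A", "G"}


def _codon_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute single-nucleotide-change structure over the 61 codons.

    Returns boolean matrices (single_change, is_transition, is_nonsyn).
    """
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    aas = [_STANDARD_TABLE.forward_table[c] for c in SENSE_CODONS]
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = (a in _PURINES) == (b in _PURINES)
            nonsyn[i, j] = aas[i] != aas[j]
    return single, transition, nonsyn


_SINGLE, _TRANSITION, _NONSYN = _codon_structure()


@dataclass
class CodonFrequencies:
    """F3X4 equilibrium codon frequencies."""

    pi: np.ndarray                 # (61,), sums to 1
    position_nucleotide: np.ndarray  # (3, 4) nucleotide freqs per codon position

    def __post_init__(self) -> None:
        if self.pi.shape != (N_CODONS,) or np.any(self.pi < 0):
            raise ValueError("pi must be 61 non-negative frequencies")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")


def f3x4_frequencies(alignment: CodonAlignment,
                     pseudocount: float = 0.0) -> CodonFrequencies:
    """Empirical F3X4 codon frequencies from a codon alignment.

    Nucleotide frequencies are counted separately at codon positions 1, 2
    and 3 (gaps and ambiguous bases excluded), multiplied per codon, stop
    codons dropped, and the result renormalized over the 61 sense codons.
    """
    counts = np.full((3, 4), pseudocount, dtype=float)
    for _, seq in alignment.records:
        for i, base in enumerate(seq):
            if base in _NUC_INDEX:
                counts[i % 3, _NUC_INDEX[base]] += 1
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("a codon position has no unambiguous nucleotides")
    pos_freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        pos_freqs[0, _NUC_INDEX[c[0]]]
        * pos_freqs[1, _NUC_INDEX[c[1]]]
        * pos_freqs[2, _NUC_INDEX[c[2]]]
        for c in SENSE_CODONS
    ])
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate nucleotide composition: all sense codons "
                         "have zero frequency")
    return CodonFrequencies(pi=pi / total, position_nucleotide=pos_freqs)


def uniform_frequencies() -> CodonFrequencies:
    """pi_c = 1/61 (the F3X4 of uniform nucleotide usage)."""
    return CodonFrequencies(pi=np.full(N_CODONS, 1.0 / N_CODONS),
                            position_nucleotide=np.full((3, 4), 0.25))


def gy94_rate_matrix(kappa: float, omega: float,
                     freqs: CodonFrequencies) -> np.ndarray:
    """GY94 instantaneous rate matrix Q, scaled to one expected
    substitution per codon per unit branch length."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = freqs.pi
    Q = np.where(_SINGLE, pi[np.newaxis, :], 0.0)
    Q = np.where(_TRANSITION & _SINGLE, Q * kappa, Q)
    Q = np.where(_NONSYN & _SINGLE, Q * omega, Q)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / scale


class _EigenQ:
    """Eigendecomposition of a reversible Q for fast exp(Q t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(np.maximum(pi, 1e-300))
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        lam, U = np.linalg.eigh((S + S.T) / 2.0)
        self.lam = lam
        self.left = U / sqrt_pi[:, None]    # D^{-1/2} U
        self.right = (U * sqrt_pi[:, None]).T  # U^T D^{1/2}

    def expm(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.maximum(P, 0.0, out=P)
        return P


# --- tree bookkeeping -----------------------------------------------------

@dataclass
class _TreeIndex:
    """Postorder arrays extracted from a LabeledTree for pruning."""

    postorder: list            # dendropy nodes, seed last
    node_index: dict           # node -> int
    edge_nodes: list           # non-seed nodes in postorder (one per branch)
    foreground: np.ndarray     # (n_edges,) bool
    edge_labels: list[str]
    leaf_row: dict             # node -> row in alignment codon matrix


def _index_tree(tree: LabeledTree, ids: list[str]) -> _TreeIndex:
    post = list(tree.tree.postorder_node_iter())
    node_index = {nd: i for i, nd in enumerate(post)}
    edge_nodes = [nd for nd in post if nd is not tree.tree.seed_node]
    foreground = np.array([bool(getattr(nd.edge, "foreground", False))
                           for nd in edge_nodes])
    labels = []
    for nd in edge_nodes:
        if nd.is_leaf():
            labels.append(nd.taxon.label)
        else:
            leaves = sorted(lf.taxon.label for lf in nd.leaf_iter())
            labels.append("(" + ",".join(leaves) + ")")
    row = {}
    id_pos = {rid: i for i, rid in enumerate(ids)}
    for nd in post:
        if nd.is_leaf():
            row[nd] = id_pos[nd.taxon.label]
    return _TreeIndex(post, node_index, edge_nodes, foreground, labels, row)


def _codon_matrix(alignment: CodonAlignment) -> np.ndarray:
    """(n_seqs, S) matrix of codon indices; -1 marks gap/ambiguous codons."""
    S = alignment.n_codons
    mat = np.full((len(alignment.records), S), -1, dtype=np.int64)
    for r, (_, seq) in enumerate(alignment.records):
        for s in range(S):
            mat[r, s] = CODON_INDEX.get(seq[3 * s: 3 * s + 3], -1)
    return mat


def _patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pats, counts = np.unique(mat, axis=1, return_counts=True)
    return pats, counts.astype(float)


# --- likelihood -----------------------------------------------------------

@dataclass
class CodonModelParams:
    """Parameters of a (possibly branch-heterogeneous) GY94 model."""

    kappa: float
    omega: dict[str, float]        # {"background": w0} or + {"foreground": w1}
    branch_lengths: np.ndarray     # (n_edges,), postorder edge order
    freqs: CodonFrequencies


@dataclass
class CodonModelFit:
    """A maximized codon-model likelihood with its optimizer record."""

    lnl: float
    params: CodonModelParams
    model: str                    # "one_ratio" | "two_ratio"
    converged: bool
    n_starts: int
    n_evaluations: int
    edge_labels: list[str]
    foreground_edges: np.ndarray

    @property
    def omega_foreground(self) -> float | None:
        return self.params.omega.get("foreground")

    @property
    def omega_background(self) -> float:
        return self.params.omega["background"]


@dataclass
class LrtResult:
    """Likelihood-ratio test of nested codon models."""

    statistic: float   # 2*(lnL_alt - lnL_null), clipped at 0
    df: int
    p_value: float
    lnl_null: float
    lnl_alt: float


class CodonLikelihood:
    """Pruning log-likelihood engine bound to one alignment + tree."""

    def __init__(self, alignment: CodonAlignment, tree: LabeledTree,
                 freqs: CodonFrequencies | None = None,
                 drop_gap_columns: bool = False):
        check_tree_alignment(tree, alignment)
        self.tree = tree
        self.freqs = freqs if freqs is not None else f3x4_frequencies(alignment)
        mat = _codon_matrix(alignment)
        if drop_gap_columns:
            mat = mat[:, (mat >= 0).all(axis=0)]
            if mat.shape[1] == 0:
                raise ValueError("no gap-free codon columns remain")
        self.patterns, self.counts = _patterns(mat)
        self.index = _index_tree(tree, alignment.ids)
        self.n_edges = len(self.index.edge_nodes)
        self._edge_pos = {nd: i for i, nd in enumerate(self.index.edge_nodes)}
        self.n_sites = int(self.counts.sum())
        self._eig_cache: dict[tuple[float, float], _EigenQ] = {}

    def _eigen(self, kappa: float, omega: float) -> _EigenQ:
        key = (kappa, omega)
        eig = self._eig_cache.get(key)
        if eig is None:
            eig = _EigenQ(gy94_rate_matrix(kappa, omega, self.freqs),
                          self.freqs.pi)
            if len(self._eig_cache) > 64:
                self._eig_cache.clear()
            self._eig_cache[key] = eig
        return eig

    def edge_omegas(self, omega: dict[str, float]) -> np.ndarray:
        fg = self.index.foreground
        w = np.full(self.n_edges, omega["background"])
        if "foreground" in omega:
            w[fg] = omega["foreground"]
        elif fg.any():
            pass  # one-ratio model ignores flags
        return w

    def log_likelihood(self, params: CodonModelParams) -> float:
        """Felsenstein-pruning log-likelihood over site patterns."""
        t = np.asarray(params.branch_lengths, dtype=float)
        if t.shape != (self.n_edges,):
            raise ValueError(f"expected {self.n_edges} branch lengths")
        omegas = self.edge_omegas(params.omega)
        pats, counts = self.patterns, self.counts
        P = pats.shape[1]
        idx = self.index
        partial: dict = {}
        log_scale = np.zeros(P)
        for nd in idx.postorder:
            if nd.is_leaf():
                continue
            prod = np.ones((N_CODONS, P))
            for child in nd.child_nodes():
                e = self._edge_pos[child]
                Pe = self._eigen(params.kappa, omegas[e]).expm(t[e])
                if child.is_leaf():
                    codons = pats[idx.leaf_row[child]]
                    msg = np.ones((N_CODONS, P))
                    obs = codons >= 0
                    msg[:, obs] = Pe[:, codons[obs]]
                else:
                    msg = Pe @ partial.pop(child)
                prod *= msg
            mx = prod.max(axis=0)
            mx[mx == 0] = 1.0
            prod /= mx
            log_scale += np.log(mx)
            partial[nd] = prod
        root = partial[idx.postorder[-1]]
        site_l = self.freqs.pi @ root
        if np.any(site_l <= 0) or not np.all(np.isfinite(site_l)):
            bad = int(np.argmin(site_l))
            raise FloatingPointError(
                f"non-finite site likelihood at pattern {bad}")
        return float(np.dot(counts, np.log(site_l) + log_scale))


def log_likelihood(alignment: CodonAlignment, tree: LabeledTree,
                   params: CodonModelParams,
                   drop_gap_columns: bool = False) -> float:
    """One-shot pruning log-likelihood (see :class:`CodonLikelihood`)."""
    eng = CodonLikelihood(alignment, tree, freqs=params.freqs,
                          drop_gap_columns=drop_gap_columns)
    return eng.log_likelihood(params)


# --- fitting --------------------------------------------------------------

_BOUNDS = {
    "kappa": (np.log(1e-2), np.log(100.0)),
    "omega": (np.log(1e-4), np.log(99.0)),
    "t": (np.log(1e-6), np.log(20.0)),
}


def _pack(kappa, omegas, t):
    return np.log(np.concatenate([[kappa], omegas, t]))


def fit_branch_model(alignment: CodonAlignment, tree: LabeledTree,
                     model: str = "one_ratio", n_starts: int = 3,
                     seed: int = 0, freqs: CodonFrequencies | None = None,
                     drop_gap_columns: bool = False,
                     fix_branch_lengths: bool = False,
                     fixed_omega_foreground: float | None = None,
                     init: CodonModelParams | None = None,
                     lnl_tol: float = 1e-6) -> CodonModelFit:
    """Maximize the GY94 branch-model likelihood.

    ``model`` is ``"one_ratio"`` (single omega) or ``"two_ratio"``
    (separate foreground omega; the tree must carry '#1' flags). Parameters
    are optimized on the log scale by bounded quasi-Newton (L-BFGS-B) from
    ``n_starts`` jittered starting points; the best optimum is returned.
    Non-convergence is reported through ``converged``, not an exception.

    ``fixed_omega_foreground`` constrains the foreground omega (used for
    profile-likelihood intervals); ``fix_branch_lengths`` keeps the tree's
    branch lengths (then only rate parameters are free).
    """
    if model not in ("one_ratio", "two_ratio"):
        raise ValueError(f"unknown model {model!r}")
    if model == "two_ratio":
        tree.validate_for_two_ratio()
    eng = CodonLikelihood(alignment, tree, freqs=freqs,
                          drop_gap_columns=drop_gap_columns)
    n_edges = eng.n_edges
    omega_names = ["background"] + (
        ["foreground"] if model == "two_ratio" else [])
    n_free_omega = len(omega_names)
    if model == "two_ratio" and fixed_omega_foreground is not None:
        n_free_omega = 1

    tree_t = np.array([nd.edge.length if nd.edge.length else 0.1
                       for nd in eng.index.edge_nodes])

    def unpack(x: np.ndarray) -> CodonModelParams:
        v = np.exp(x)
        kappa = v[0]
        if model == "two_ratio":
            if fixed_omega_foreground is not None:
                omega = {"background": v[1],
                         "foreground": fixed_omega_foreground}
            else:
                omega = {"background": v[1], "foreground": v[2]}
        else:
            omega = {"background": v[1]}
        t = tree_t if fix_branch_lengths else v[1 + n_free_omega:]
        return CodonModelParams(kappa=kappa, omega=omega, branch_lengths=t,
                                freqs=eng.freqs)

    n_eval = 0

    def neg_lnl(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            return -eng.log_likelihood(unpack(x))
        except FloatingPointError:
            return 1e12

    bounds = [_BOUNDS["kappa"]] + [_BOUNDS["omega"]] * n_free_omega
    if not fix_branch_lengths:
        bounds += [_BOUNDS["t"]] * n_edges

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = []
    if init is not None:
        w0 = [init.omega["background"]]
        if model == "two_ratio" and fixed_omega_foreground is None:
            w0.append(init.omega.get("foreground",
                                     init.omega["background"]))
        t0 = np.array([]) if fix_branch_lengths else np.asarray(
            init.branch_lengths)
        starts.append(np.clip(_pack(init.kappa, np.array(w0), t0), lo, hi))
    base = _pack(2.0, np.full(n_free_omega, 0.3),
                 np.array([]) if fix_branch_lengths else tree_t)
    starts.append(base)
    total = n_starts + (1 if init is not None else 0)
    while len(starts) < total:
        jitter = rng.normal(0.0, 0.7, size=base.shape)
        starts.append(np.clip(base + jitter, lo, hi))

    best = None
    converged = False
    for x0 in starts:
        res = minimize(neg_lnl, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-5})
        if best is None or res.fun < best.fun - 0.0:
            best = res
        if res.success:
            converged = True
    params = unpack(best.x)
    return CodonModelFit(
        lnl=-float(best.fun), params=params, model=model,
        converged=converged, n_starts=len(starts), n_evaluations=n_eval,
        edge_labels=eng.index.edge_labels,
        foreground_edges=eng.index.foreground.copy(),
    )


def lrt(null_fit: CodonModelFit, alt_fit: CodonModelFit,
        df: int = 1, tol: float = 1e-4) -> LrtResult:
    """Likelihood-ratio test of nested fits; p from the chi-square upper
    tail. A negative 2dL beyond tolerance signals an optimizer failure and
    raises a refit warning."""
    stat = 2.0 * (alt_fit.lnl - null_fit.lnl)
    if stat < -tol:
        import warnings
        warnings.warn(
            f"alternative lnL {alt_fit.lnl:.4f} below null {null_fit.lnl:.4f}: "
            "refit with more starts", stacklevel=2)
    stat = max(stat, 0.0)
    return LrtResult(statistic=stat, df=df,
                     p_value=float(chi2.sf(stat, df)),
                     lnl_null=null_fit.lnl, lnl_alt=alt_fit.lnl)


def foreground_profile_lrt(alignment: CodonAlignment, tree: LabeledTree,
                           fit: CodonModelFit, omega0: float,
                           seed: int = 0) -> float:
    """2*(lnL_hat - profile lnL at foreground omega = omega0).

    The profile maximizes over all other parameters with the foreground
    omega pinned; the value is compared against chi-square(1) quantiles to
    build profile-likelihood confidence intervals.
    """
    constrained = fit_branch_model(
        alignment, tree, model="two_ratio", n_starts=1, seed=seed,
        freqs=fit.params.freqs, fixed_omega_foreground=omega0,
        init=fit.params)
    return max(0.0, 2.0 * (fit.lnl - constrained.lnl))


def foreground_profile_contains(alignment: CodonAlignment, tree: LabeledTree,
                                fit: CodonModelFit, omega0: float,
                                level: float = 0.95, seed: int = 0) -> bool:
    """Whether omega0 lies in the profile-likelihood CI of the foreground
    omega at the given level."""
    crit = chi2.ppf(level, 1)
    return foreground_profile_lrt(alignment, tree, fit, omega0,
                                  seed=seed) <= crit


def foreground_profile_interval(alignment: CodonAlignment, tree: LabeledTree,
                                fit: CodonModelFit, level: float = 0.95,
                                seed: int = 0, rel_step: float = 1.6,
                                refine: int = 20) -> tuple[float, float]:
    """Profile-likelihood CI for the foreground omega, by bisection on the
    profile deviance against the chi-square(1) critical value."""
    crit = chi2.ppf(level, 1)
    mle = fit.omega_foreground
    if mle is None:
        raise ValueError("fit has no foreground omega")

    def dev(w: float) -> float:
        return foreground_profile_lrt(alignment, tree, fit, w, seed=seed)

    def bracket(direction: int) -> float:
        w = mle
        for _ in range(30):
            w = w * rel_step if direction > 0 else w / rel_step
            if dev(w) > crit or w < 1.1e-4 or w > 98.0:
                break
        lo, hi = (mle, w) if direction > 0 else (w, mle)
        for _ in range(refine):
            mid = np.sqrt(lo * hi)
            inside = dev(mid) <= crit
            if direction > 0:
                lo, hi = (mid, hi) if inside else (lo, mid)
            else:
                lo, hi = (lo, mid) if inside else (mid, hi)
        return hi if direction > 0 else lo

    return bracket(-1), bracket(+1)
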