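"""Branch-model selection analysis: alignment curation, maximum-likelihood
fits of per-clade dN/dS classes, nested likelihood-ratio tests, ladder model
selection, and a simplified RELAX-style selection-intensity test.

The LRT statistic is 2*(lnL_alt - lnL_null) compared to a chi-square with
df equal to the difference in free parameters. The selection-intensity test
fits three shared site categories (omega_i, w_i) on background branches and
raises them to a power K on the test branches: K < 1 means the distribution
is compressed toward 1 (relaxation), K > 1 intensification; the null fixes
K = 1 and the LRT has one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .codonmodel import (
    CodonAlignment,
    CodonModelParams,
    FREQ_MODELS,
    N_CODONS,
    STOPS,
    BranchModelSpec,
    TreeLikelihood,
    spec_from_labels,
)
from .trees import SpeciesTree

OMEGA_BOUNDS = (1e-4, 99.0)
KAPPA_BOUNDS = (0.01, 100.0)
LENGTH_BOUNDS = (1e-7, 20.0)
K_BOUNDS = (1e-3, 50.0)


class ModelError(ValueError):
    pass


# --------------------------------------------------------------------------
# curation
# --------------------------------------------------------------------------

def curate_alignment(raw: Mapping[str, str],
                     disrupted_codons: Mapping[str, Sequence[int]] | None = None,
                     max_gap_fraction: float = 0.9) -> CodonAlignment:
    """Curate a gapped codon-aligned set of sequences for selection analysis.

    Steps, in order: gap out each listed disrupted codon (1-based positions
    in the input columns) in its taxon; drop the terminal stop column when
    present; drop columns whose gap fraction is >= ``max_gap_fraction``.
    A residual stop codon after curation is an error naming taxon and column.
    """
    disrupted_codons = disrupted_codons or {}
    taxa = list(raw)
    lengths = {len(s) for s in raw.values()}
    if len(lengths) != 1:
        raise ModelError("sequences have unequal lengths")
    (length,) = lengths
    if length % 3 != 0:
        raise ModelError("alignment length not a multiple of 3")
    ncol = length // 3
    cols = {t: [raw[t][3 * c: 3 * c + 3].upper() for c in range(ncol)]
            for t in taxa}
    for t, positions in disrupted_codons.items():
        if t not in cols:
            raise ModelError(f"disrupted-codon list names unknown taxon {t!r}")
        for p in positions:
            if not 1 <= p <= ncol:
                raise ModelError(f"disrupted codon {p} outside alignment")
            cols[t][p - 1] = "---"
    keep = list(range(ncol))
    if any(cols[t][ncol - 1] in STOPS for t in taxa):
        keep.remove(ncol - 1)
    kept = []
    for c in keep:
        gap_frac = sum(cols[t][c] == "---" for t in taxa) / len(taxa)
        if gap_frac < max_gap_fraction:
            kept.append(c)
    for t in taxa:
        for c in kept:
            if cols[t][c] in STOPS:
                raise ModelError(
                    f"residual stop codon in taxon {t!r} at codon column {c + 1}"
                )
    seqs = {t: "".join(cols[t][c] for c in kept) for t in taxa}
    return CodonAlignment.from_sequences(seqs)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class FitOptions:
    n_restarts: int = 3
    freq_model: str = "F3x4"
    fixed_branch_lengths: dict[int, float] | None = None
    maxiter: int = 500
    seed: int = 0


@dataclass
class FitResult:
    spec: BranchModelSpec
    lnL: float
    params: CodonModelParams
    n_free_params: int
    converged: bool
    n_restarts_used: int


def _free_edges(tree: SpeciesTree, class_arr: np.ndarray):
    """Edges with their own length parameter; a 2-child root ties one edge.

    With a reversible model the root is arbitrary, so when the root is a
    bifurcation and both root edges share a class, only their sum is
    identifiable: one of the two is pinned to ~0.
    """
    edges = [v for v in range(tree.n_nodes) if v != tree.root]
    pinned: dict[int, float] = {}
    rc = tree.children[tree.root]
    if len(rc) == 2 and class_arr[rc[0]] == class_arr[rc[1]]:
        pinned[rc[1]] = LENGTH_BOUNDS[0]
        edges = [e for e in edges if e != rc[1]]
    return edges, pinned


def fit_branch_model(aln: CodonAlignment, tree: SpeciesTree,
                     spec: BranchModelSpec,
                     opts: FitOptions | None = None) -> FitResult:
    """Maximize the pruning log-likelihood over kappa, per-class omegas and
    branch lengths (multi-start bounded quasi-Newton, F3x4 frequencies fixed
    at their empirical values)."""
    opts = opts or FitOptions()
    pi = FREQ_MODELS[opts.freq_model](aln.codons)
    like = TreeLikelihood(aln, tree)
    class_arr = spec.class_array(tree)
    fixed_bl = opts.fixed_branch_lengths
    if fixed_bl is None:
        free_edges, pinned = _free_edges(tree, class_arr)
    else:
        free_edges, pinned = [], dict(fixed_bl)

    n_classes = spec.n_classes
    lengths = np.zeros(tree.n_nodes)
    for e, t in pinned.items():
        lengths[e] = t

    def unpack(x: np.ndarray):
        kappa = float(np.exp(x[0]))
        omegas = np.exp(x[1: 1 + n_classes])
        bl = lengths.copy()
        for k, e in enumerate(free_edges):
            bl[e] = np.exp(x[1 + n_classes + k])
        return kappa, omegas, bl

    def negloglik(x: np.ndarray) -> float:
        kappa, omegas, bl = unpack(x)
        try:
            return -like.loglik(class_arr, bl, kappa, omegas, pi)
        except FloatingPointError:
            return 1e12

    bounds = ([tuple(np.log(KAPPA_BOUNDS))]
              + [tuple(np.log(OMEGA_BOUNDS))] * n_classes
              + [tuple(np.log(LENGTH_BOUNDS))] * len(free_edges))
    rng = np.random.default_rng(opts.seed)
    best = None
    used = 0
    for r in range(max(1, opts.n_restarts)):
        x0 = np.concatenate([
            [np.log(2.0) + (0.5 * rng.standard_normal() if r else 0.0)],
            np.log(np.full(n_classes, 0.4))
            + (0.7 * rng.standard_normal(n_classes) if r else 0.0),
            np.log(np.full(len(free_edges), 0.1))
            + (0.5 * rng.standard_normal(len(free_edges)) if r else 0.0),
        ])
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": opts.maxiter,
                                         "maxfun": 10 * opts.maxiter})
        used += 1
        if best is None or res.fun < best.fun:
            best = res
    kappa, omegas, bl = unpack(best.x)
    params = CodonModelParams(
        kappa=kappa, pi=pi,
        omega_by_class={c: float(w) for c, w in enumerate(omegas)},
        branch_lengths={e: float(bl[e]) for e in range(tree.n_nodes)
                        if e != tree.root})
    n_free = 1 + n_classes + len(free_edges)
    return FitResult(spec=spec, lnL=-float(best.fun), params=params,
                     n_free_params=n_free, converged=bool(best.success),
                     n_restarts_used=used)


# --------------------------------------------------------------------------
# likelihood-ratio tests
# --------------------------------------------------------------------------

@dataclass
class LRTResult:
    null_id: str
    alt_id: str
    statistic: float
    df: int
    p: float


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("statistic must be >= 0")
    return float(stats.chi2.sf(x, df))


def _is_nested(tree: SpeciesTree, null: BranchModelSpec,
               alt: BranchModelSpec) -> bool:
    """The alternative refines the null partition of edges into classes."""
    null_arr = null.class_array(tree)
    alt_arr = alt.class_array(tree)
    mapping: dict[int, int] = {}
    for v in range(tree.n_nodes - 1):
        a, n = int(alt_arr[v]), int(null_arr[v])
        if a in mapping and mapping[a] != n:
            return False
        mapping[a] = n
    return alt.n_classes >= null.n_classes


def lrt(fit_null: FitResult, fit_alt: FitResult, alpha: float = 0.05,
        tree: SpeciesTree | None = None) -> LRTResult:
    """Likelihood-ratio test between nested branch-model fits."""
    if tree is not None and not _is_nested(tree, fit_null.spec, fit_alt.spec):
        raise ModelError(
            f"model {fit_alt.spec.model_id} does not nest "
            f"{fit_null.spec.model_id}"
        )
    df = fit_alt.n_free_params - fit_null.n_free_params
    if df < 1:
        raise ModelError("alternative must have more free parameters")
    statistic = max(0.0, 2.0 * (fit_alt.lnL - fit_null.lnL))
    return LRTResult(null_id=fit_null.spec.model_id,
                     alt_id=fit_alt.spec.model_id,
                     statistic=statistic, df=df, p=chi2_sf(statistic, df))


def run_ladder(aln: CodonAlignment, tree: SpeciesTree,
               models: Mapping[str, Mapping[str, int]],
               ladder: Sequence[tuple[str, str]],
               alpha: float = 0.05,
               opts: FitOptions | None = None):
    """Fit a ladder of nested branch models and pick the best-supported one.

    ``models`` maps model id to a label->class mapping; ``ladder`` lists
    (null_id, alt_id) comparisons. The best model is the most complex model
    that significantly rejects every simpler model it is tested against and
    is not itself rejected by any more complex model; ties break toward
    fewer parameters.
    """
    ids = {m for pair in ladder for m in pair}
    unknown = ids - set(models)
    if unknown:
        raise ModelError(f"ladder references undefined models: {sorted(unknown)}")
    specs = {mid: spec_from_labels(tree, mid, dict(models[mid])) for mid in ids}
    for null_id, alt_id in ladder:
        if null_id == alt_id or not _is_nested(tree, specs[null_id], specs[alt_id]):
            raise ModelError(f"ladder pair ({null_id}, {alt_id}) is not nested")
    fits = {mid: fit_branch_model(aln, tree, specs[mid], opts) for mid in ids}
    results = [lrt(fits[n], fits[a], alpha) for n, a in ladder]
    by_pair = {(r.null_id, r.alt_id): r for r in results}
    candidates = []
    for mid in ids:
        rejects_simpler = all(
            by_pair[(n, a)].p < alpha for n, a in ladder if a == mid
        )
        unrejected = all(
            by_pair[(n, a)].p >= alpha for n, a in ladder if n == mid
        )
        if rejects_simpler and unrejected:
            candidates.append(mid)
    if not candidates:
        # fall back to the simplest model in the ladder
        best = min(ids, key=lambda m: (fits[m].n_free_params, m))
    else:
        most = max(fits[m].n_free_params for m in candidates)
        top = [m for m in candidates if fits[m].n_free_params == most]
        best = min(top, key=lambda m: (fits[m].n_free_params, m))
    return best, fits, results


# --------------------------------------------------------------------------
# RELAX-style selection-intensity test
# --------------------------------------------------------------------------

@dataclass
class RelaxFit:
    omegas: tuple[float, float, float]
    weights: tuple[float, float, float]
    K: float
    lnL_null: float
    lnL_alt: float
    statistic: float
    p: float
    direction: str                     # relaxed | intensified | none
    converged: bool = True


def _softmax3(a: float, b: float) -> np.ndarray:
    z = np.array([a, b, 0.0])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def relax_test(aln: CodonAlignment, tree: SpeciesTree,
               test_labels: Sequence[str], alpha: float = 0.05,
               opts: FitOptions | None = None) -> RelaxFit:
    """Test for relaxed or intensified selection on a set of branches.

    Background branches draw site omegas from three shared categories; the
    test branches use ``omega_i ** K``. The alternative estimates K freely,
    the null fixes K = 1; the LRT has one degree of freedom. Branch lengths
    and kappa are first estimated under a one-ratio model and then held
    fixed (a standard speed shortcut; see the methods note).
    """
    opts = opts or FitOptions()
    test_edges: set[int] = set()
    for label in test_labels:
        test_edges |= tree.label_edges(label)
    if not test_edges:
        raise ModelError("empty test edge set")
    all_edges = set(range(tree.n_nodes - 1))
    if test_edges >= all_edges:
        raise ModelError("test set must be a proper subset of edges")

    pi = FREQ_MODELS[opts.freq_model](aln.codons)
    base_spec = BranchModelSpec("one-ratio", {v: 0 for v in all_edges}, 1)
    base = fit_branch_model(aln, tree, base_spec,
                            replace(opts, n_restarts=1))
    bl = np.zeros(tree.n_nodes)
    for e, t in base.params.branch_lengths.items():
        bl[e] = t
    kappa0 = base.params.kappa
    like = TreeLikelihood(aln, tree)
    class_arr = np.zeros(tree.n_nodes, dtype=int)
    for e in test_edges:
        class_arr[e] = 1

    def mixture_negloglik(x: np.ndarray, k_fixed: float | None) -> float:
        from scipy.special import logsumexp

        kappa = float(np.exp(x[0]))
        omegas = np.exp(x[1:4])
        w = _softmax3(x[4], x[5])
        K = k_fixed if k_fixed is not None else float(np.exp(x[6]))
        try:
            cat_logs = []
            for om in omegas:
                om_test = float(np.clip(om ** K, *OMEGA_BOUNDS))
                sitelik, logscale = _site_likelihoods(
                    like, class_arr, bl, kappa,
                    np.array([om, om_test]), pi)
                if np.any(sitelik <= 0) or not np.all(np.isfinite(sitelik)):
                    return 1e12
                cat_logs.append(np.log(sitelik) + logscale)
        except FloatingPointError:
            return 1e12
        stack = np.vstack(cat_logs) + np.log(w)[:, None]
        site_log = logsumexp(stack, axis=0)
        return -float(like.counts @ site_log)

    def fit(k_fixed: float | None, x_init: np.ndarray | None = None):
        n = 6 if k_fixed is not None else 7
        bounds = ([tuple(np.log(KAPPA_BOUNDS))]
                  + [tuple(np.log(OMEGA_BOUNDS))] * 3
                  + [(-10, 10)] * 2)
        if k_fixed is None:
            bounds.append(tuple(np.log(K_BOUNDS)))
        rng = np.random.default_rng(opts.seed + 17)
        best = None
        for r in range(max(1, opts.n_restarts)):
            if x_init is not None and r == 0:
                x0 = x_init[:n] if len(x_init) >= n else np.concatenate(
                    [x_init, [0.0] * (n - len(x_init))])
            else:
                x0 = np.concatenate([
                    [np.log(kappa0)],
                    np.log([0.05, 0.4, 1.2])
                    + (0.5 * rng.standard_normal(3) if r else 0.0),
                    [0.0, 0.0],
                    [] if k_fixed is not None else [0.0],
                ])
            res = optimize.minimize(
                mixture_negloglik, x0, args=(k_fixed,), method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": opts.maxiter, "maxfun": 10 * opts.maxiter})
            if best is None or res.fun < best.fun:
                best = res
        return best

    null = fit(1.0)
    alt = fit(None, x_init=np.concatenate([null.x, [0.0]]))
    lnl0, lnl1 = -float(null.fun), -float(alt.fun)
    statistic = max(0.0, 2.0 * (lnl1 - lnl0))
    p = chi2_sf(statistic, 1)
    K = float(np.exp(alt.x[6]))
    w = _softmax3(alt.x[4], alt.x[5])
    direction = "none"
    if p < alpha:
        direction = "relaxed" if K < 1 else "intensified"
    return RelaxFit(
        omegas=tuple(float(v) for v in np.exp(alt.x[1:4])),
        weights=tuple(float(v) for v in w),
        K=K, lnL_null=lnl0, lnL_alt=lnl1, statistic=statistic, p=p,
        direction=direction,
        converged=bool(null.success and alt.success))


def _site_likelihoods(like: TreeLikelihood, class_arr, bl, kappa,
                      omegas, pi) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern likelihoods plus their log rescale factors."""
    from .codonmodel import transition_kernels

    tree = like.tree
    kernels = [transition_kernels(pi, kappa, float(w)) for w in omegas]
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros(like.n_patterns)
    for v in range(tree.n_nodes):
        if tree.node_taxon[v] is not None:
            partials[v] = like._tip_partials[v]
            continue
        acc = np.ones((like.n_patterns, N_CODONS))
        for c in tree.children[v]:
            p = kernels[int(class_arr[c])](float(bl[c]))
            acc *= partials.pop(c) @ p.T
        mx = acc.max(axis=1)
        mx[mx == 0] = 1e-300
        acc /= mx[:, None]
        logscale += np.log(mx)
        partials[v] = acc
    return partials[tree.root] @ pi, logscale
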