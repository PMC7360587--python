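"""Codon substitution machinery: 61-state rate matrices, equilibrium
frequencies and the pruning log-likelihood for branch models.

The model is the standard Goldman–Yang/branch-model parameterization: the
instantaneous rate from codon *i* to *j* is zero unless they differ at a
single nucleotide, and otherwise proportional to the target codon frequency
``pi_j``, multiplied by ``kappa`` for transitions and by the branch's
``omega`` (dN/dS) for nonsynonymous changes. Each class's matrix is scaled
to a mean rate of one substitution per codon at stationarity, so branch
lengths are expected substitutions per codon site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import SpeciesTree

NUCS = "TCAG"
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

STOPS = ("TAA", "TAG", "TGA")

_CODON_TABLE = {}
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_n1, _n2, _n3) in enumerate(
        (a, b, c) for a in NUCS for b in NUCS for c in NUCS):
    _CODON_TABLE[_n1 + _n2 + _n3] = _AA[_i]

#: the 61 sense codons, fixed order
CODONS = tuple(c for c in _CODON_TABLE if _CODON_TABLE[c] != "*")
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)
AMINO = tuple(_CODON_TABLE[c] for c in CODONS)


def _pair_info():
    """Precompute single-nucleotide-difference codon pairs."""
    rows, cols, is_ts, is_nonsyn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diff) != 1:
                continue
            rows.append(i)
            cols.append(j)
            is_ts.append(frozenset(diff[0]) in _TRANSITIONS)
            is_nonsyn.append(AMINO[i] != AMINO[j])
    return (np.array(rows), np.array(cols),
            np.array(is_ts, bool), np.array(is_nonsyn, bool))


_ROWS, _COLS, _IS_TS, _IS_NONSYN = _pair_info()


def rate_matrix(pi: np.ndarray, kappa: float, omega: float,
                normalize: bool = True) -> np.ndarray:
    """Build the 61x61 generator Q for one omega class.

    Rows sum to zero; when ``normalize`` the matrix is scaled so that the
    stationary mean rate -sum_i pi_i Q_ii equals 1.
    """
    q = np.zeros((N_CODONS, N_CODONS))
    rate = pi[_COLS].copy()
    rate[_IS_TS] *= kappa
    rate[_IS_NONSYN] *= omega
    q[_ROWS, _COLS] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        mean_rate = -float(pi @ np.diag(q))
        if mean_rate <= 0:
            raise ValueError("degenerate rate matrix (mean rate <= 0)")
        q /= mean_rate
    return q


def transition_kernels(pi: np.ndarray, kappa: float, omega: float):
    """Eigendecomposition of Q enabling cheap P(t) for many t.

    Q is reversible, so D^{1/2} Q D^{-1/2} is symmetric and has a real
    eigensystem; returns a closure ``P(t)`` computing expm(tQ).
    """
    sqrt_pi = np.sqrt(pi)
    q = rate_matrix(pi, kappa, omega)
    # S = D^{1/2} Q D^{-1/2} is symmetric for a reversible chain
    sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
    left = u / sqrt_pi[:, None]      # D^{-1/2} U
    right = (u * sqrt_pi[:, None]).T  # U^T D^{1/2}

    def kernel(t: float) -> np.ndarray:
        p = (left * np.exp(lam * t)) @ right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    return kernel


# --------------------------------------------------------------------------
# codon frequencies
# --------------------------------------------------------------------------

def f3x4(codon_columns: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    ``codon_columns`` is an integer matrix of codon indices (-1 = gap).
    """
    counts = np.zeros((3, 4))
    flat = codon_columns.ravel()
    flat = flat[flat >= 0]
    for idx in flat:
        codon = CODONS[idx]
        for pos, nt in enumerate(codon):
            counts[pos, NUCS.index(nt)] += 1
    counts += 0.5  # pseudo-count keeps all frequencies positive
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        freqs[0, NUCS.index(c[0])]
        * freqs[1, NUCS.index(c[1])]
        * freqs[2, NUCS.index(c[2])]
        for c in CODONS
    ])
    return pi / pi.sum()


def f1x4(codon_columns: np.ndarray) -> np.ndarray:
    counts = np.zeros(4)
    flat = codon_columns.ravel()
    flat = flat[flat >= 0]
    for idx in flat:
        for nt in CODONS[idx]:
            counts[NUCS.index(nt)] += 1
    counts += 0.5
    freqs = counts / counts.sum()
    pi = np.array([
        freqs[NUCS.index(c[0])] * freqs[NUCS.index(c[1])]
        * freqs[NUCS.index(c[2])] for c in CODONS
    ])
    return pi / pi.sum()


def f61(codon_columns: np.ndarray) -> np.ndarray:
    counts = np.full(N_CODONS, 0.5)
    flat = codon_columns.ravel()
    flat = flat[flat >= 0]
    np.add.at(counts, flat, 1.0)
    return counts / counts.sum()


FREQ_MODELS = {"F3x4": f3x4, "F1x4": f1x4, "F61": f61}


# --------------------------------------------------------------------------
# alignment container
# --------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Codon alignment over the 61 sense codons plus gap (-1)."""

    taxa: list[str]
    codons: np.ndarray                 # (n_taxa, n_codons) int, -1 = gap/ambiguous

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=int)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix shape does not match taxa")
        if self.codons.max(initial=-1) >= N_CODONS:
            raise ValueError("codon index out of range")

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "CodonAlignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("alignment length not a multiple of 3")
        mat = np.full((len(taxa), length // 3), -1, dtype=int)
        for r, t in enumerate(taxa):
            s = seqs[t].upper().replace("U", "T")
            for c in range(length // 3):
                codon = s[3 * c: 3 * c + 3]
                if codon in CODON_INDEX:
                    mat[r, c] = CODON_INDEX[codon]
                elif codon in STOPS:
                    raise ValueError(
                        f"stop codon {codon} at column {c + 1} in {t}"
                    )
        return cls(taxa=taxa, codons=mat)

    def to_sequences(self) -> dict[str, str]:
        out = {}
        for r, t in enumerate(self.taxa):
            out[t] = "".join(
                CODONS[i] if i >= 0 else "---" for i in self.codons[r]
            )
        return out


# --------------------------------------------------------------------------
# pruning likelihood
# --------------------------------------------------------------------------

class TreeLikelihood:
    """Felsenstein pruning for codon branch models on a fixed tree/alignment.

    Site patterns are compressed once; each log-likelihood evaluation
    rebuilds the per-class transition kernels and sweeps the tree in
    postorder with per-pattern rescaling to avoid underflow.
    """

    def __init__(self, aln: CodonAlignment, tree: SpeciesTree):
        missing = set(tree.taxa) - set(aln.taxa)
        if missing:
            raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
        self.tree = tree
        self.aln = aln
        tip_rows = []
        for v in range(tree.n_nodes):
            t = tree.node_taxon[v]
            tip_rows.append(aln.taxa.index(t) if t is not None else -1)
        self.tip_rows = tip_rows
        # pattern compression
        patt, _inverse, counts = np.unique(
            aln.codons[:, :].T[:, [r for r in tip_rows if r >= 0]],
            axis=0, return_inverse=True, return_counts=True)
        # store per tree-tip the pattern column
        self.patterns = patt            # (n_patterns, n_tree_tips)
        self.counts = counts.astype(float)
        self.n_patterns = patt.shape[0]
        self._tip_order = [v for v in range(tree.n_nodes)
                           if tree.node_taxon[v] is not None]
        # tip partial likelihoods
        self._tip_partials = {}
        for k, v in enumerate(self._tip_order):
            part = np.zeros((self.n_patterns, N_CODONS))
            idx = self.patterns[:, k]
            gap = idx < 0
            part[np.arange(self.n_patterns)[~gap], idx[~gap]] = 1.0
            part[gap, :] = 1.0
            self._tip_partials[v] = part

    def loglik(self, edge_class: np.ndarray, branch_lengths: np.ndarray,
               kappa: float, omegas: np.ndarray, pi: np.ndarray) -> float:
        """Log-likelihood for per-edge classes/lengths and per-class omegas.

        ``edge_class[v]`` and ``branch_lengths[v]`` are indexed by child node
        id ``v`` (the root entry is ignored).
        """
        tree = self.tree
        kernels = [transition_kernels(pi, kappa, float(w)) for w in omegas]
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_patterns)
        for v in range(tree.n_nodes):
            if tree.node_taxon[v] is not None:
                partials[v] = self._tip_partials[v]
                continue
            acc = np.ones((self.n_patterns, N_CODONS))
            for c in tree.children[v]:
                p = kernels[int(edge_class[c])](float(branch_lengths[c]))
                acc *= partials.pop(c) @ p.T
            mx = acc.max(axis=1)
            mx[mx == 0] = 1e-300
            acc /= mx[:, None]
            logscale += np.log(mx)
            partials[v] = acc
        root = tree.root
        site_l = partials[root] @ pi
        if np.any(site_l <= 0) or not np.all(np.isfinite(site_l)):
            bad = int(np.argmin(site_l))
            raise FloatingPointError(
                f"non-finite site likelihood at pattern {bad}"
            )
        return float(self.counts @ (np.log(site_l) + logscale))


@dataclass
class BranchModelSpec:
    """Assignment of every tree edge to an omega class (model ids A..N)."""

    model_id: str
    edge_to_class: dict[int, int]      # child-node id -> class index
    n_classes: int

    def __post_init__(self) -> None:
        classes = set(self.edge_to_class.values())
        if classes and (min(classes) < 0 or max(classes) >= self.n_classes):
            raise ValueError("edge classes must be contiguous from 0")

    def class_array(self, tree: SpeciesTree) -> np.ndarray:
        arr = np.zeros(tree.n_nodes, dtype=int)
        for v, cls in self.edge_to_class.items():
            arr[v] = cls
        return arr


def spec_from_labels(tree: SpeciesTree, model_id: str,
                     label_classes: dict[str, int]) -> BranchModelSpec:
    """Build a branch-model spec from clade/branch label -> class mapping.

    Unlisted edges fall in the background class 0. Class indices must be
    contiguous starting at 0 (0 = background omega_0).
    """
    edge_to_class: dict[int, int] = {}
    for label, cls in label_classes.items():
        for e in tree.label_edges(label):
            if e in edge_to_class and edge_to_class[e] != cls:
                raise ValueError(
                    f"edge {e} assigned to two classes in model {model_id}"
                )
            edge_to_class[e] = cls
    n_classes = max(label_classes.values(), default=0) + 1
    used = set(label_classes.values()) | {0}
    if used != set(range(n_classes)):
        raise ValueError(f"model {model_id}: classes not contiguous from 0")
    for v in range(tree.n_nodes - 1):
        edge_to_class.setdefault(v, 0)
    return BranchModelSpec(model_id=model_id, edge_to_class=edge_to_class,
                           n_classes=n_classes)


@dataclass
class CodonModelParams:
    kappa: float
    pi: np.ndarray
    omega_by_class: dict[int, float]
    branch_lengths: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if abs(float(self.pi.sum()) - 1.0) > 1e-8:
            raise ValueError("codon frequencies must sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for w in self.omega_by_class.values():
            if w < 0:
                raise ValueError("omega must be non-negative")
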