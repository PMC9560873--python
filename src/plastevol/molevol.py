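"""Codon-model molecular evolution: MG94-style dS/dN/omega estimation,
branch-model likelihood-ratio tests, gene functional classes and dS ratio
summaries.

The substitution model is Muse-Gaut style: only single-nucleotide codon
changes have nonzero rate; a change's rate is the nucleotide exchangeability
(HKY by default: kappa for transitions) times the equilibrium frequency of
the target nucleotide at the changed position (F3x4), times omega when the
change is nonsynonymous.  Branch lengths are expected substitutions per
codon.  Per-branch dS and dN come from the standard expected-substitutions
decomposition, under which dN/dS equals omega exactly.

Likelihoods are computed by Felsenstein pruning over the 61 sense codons of
the standard genetic code (the plastid code is identical for these genes),
with gapped or ambiguous codons treated as missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .seqstats import SENSE_CODONS, STOP_CODONS

log = logging.getLogger(__name__)

NUC = "ACGT"
_NUC_IDX = {b: i for i, b in enumerate(NUC)}
_CODON_IDX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_STATES = len(SENSE_CODONS)  # 61

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

from .seqstats import CODON_FAMILIES

_AA_OF = {}
for _aa, _fam in CODON_FAMILIES.items():
    for _c in _fam:
        _AA_OF[_c] = _aa


def _pair_structure():
    """Static structure of single-nucleotide codon changes."""
    I, J, POS, TS, TGT, SYN = [], [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            I.append(i)
            J.append(j)
            POS.append(k)
            TS.append((ci[k], cj[k]) in _TRANSITIONS)
            TGT.append(_NUC_IDX[cj[k]])
            SYN.append(_AA_OF[ci] == _AA_OF[cj])
    return (
        np.array(I),
        np.array(J),
        np.array(POS),
        np.array(TS, dtype=bool),
        np.array(TGT),
        np.array(SYN, dtype=bool),
    )


_I, _J, _POS, _TS, _TGT, _SYN = _pair_structure()


def f3x4_frequencies(codon_counts: np.ndarray | None = None, seqs: Sequence[str] = ()) -> np.ndarray:
    """F3x4 codon frequencies: position-specific nucleotide frequencies,
    renormalized over the 61 sense codons.  Stop codons are excluded."""
    pos_freq = np.full((3, 4), 0.25)
    tallies = np.zeros((3, 4))
    for seq in seqs:
        seq = seq.upper()
        for k in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[k : k + 3]
            if "-" in codon or "N" in codon or codon in STOP_CODONS:
                continue
            for p, b in enumerate(codon):
                tallies[p, _NUC_IDX[b]] += 1
    if tallies.sum() > 0:
        pos_freq = (tallies + 0.5) / (tallies + 0.5).sum(axis=1, keepdims=True)
    pi = np.array(
        [pos_freq[0, _NUC_IDX[c[0]]] * pos_freq[1, _NUC_IDX[c[1]]] * pos_freq[2, _NUC_IDX[c[2]]] for c in SENSE_CODONS]
    )
    return pi / pi.sum()


class MG94Matrix:
    """MG94 rate matrix factory for fixed nucleotide parameters.

    ``exchangeability`` may be a scalar kappa (HKY) or a 6-vector of GTR
    exchangeabilities in the order AC, AG, AT, CG, CT, GT.
    """

    def __init__(self, pi_codon: np.ndarray, kappa: float = 2.0, exchangeability: np.ndarray | None = None):
        self.pi = pi_codon
        # position-specific target-nucleotide factor: approximate the F3x4
        # target frequency by the marginal codon frequencies
        tgt_factor = np.empty(len(_I))
        # frequency of target codon divided by frequency of source codon's
        # shared part: for MG94/F3x4 the rate uses the target *codon*
        # frequency contribution at the changed position; using pi_j directly
        # (times symmetric exchangeability on nucleotides) keeps the chain
        # reversible with stationary distribution pi.
        if exchangeability is not None:
            ex = np.asarray(exchangeability, dtype=float)
            order = {("A", "C"): 0, ("A", "G"): 1, ("A", "T"): 2, ("C", "G"): 3, ("C", "T"): 4, ("G", "T"): 5}
            rates = np.empty(len(_I))
            for n, (i, j, k) in enumerate(zip(_I, _J, _POS)):
                a, b = SENSE_CODONS[i][k], SENSE_CODONS[j][k]
                rates[n] = ex[order[tuple(sorted((a, b)))]]
            self._nuc_rate = rates
            self.kappa = None
        else:
            self._nuc_rate = np.where(_TS, kappa, 1.0)
            self.kappa = kappa

    def with_kappa(self, kappa: float) -> "MG94Matrix":
        m = MG94Matrix.__new__(MG94Matrix)
        m.pi = self.pi
        m._nuc_rate = np.where(_TS, kappa, 1.0)
        m.kappa = kappa
        return m

    def q(self, omega: float, normalize: bool = True) -> np.ndarray:
        """Rate matrix; if normalize, scaled to one expected substitution per
        codon per unit branch length."""
        vals = self._nuc_rate * self.pi[_J] * np.where(_SYN, 1.0, omega)
        Q = np.zeros((N_STATES, N_STATES))
        Q[_I, _J] = vals
        np.fill_diagonal(Q, -Q.sum(axis=1))
        if normalize:
            mu = -(self.pi * np.diag(Q)).sum()
            Q /= mu
        return Q

    def flux_fractions(self, omega: float) -> tuple[float, float]:
        """(synonymous, nonsynonymous) fractions of total substitution flux."""
        u_s = float((self._nuc_rate * self.pi[_J] * self.pi[_I])[_SYN].sum())
        u_n = float((self._nuc_rate * self.pi[_J] * self.pi[_I])[~_SYN].sum())
        tot = u_s + omega * u_n
        return u_s / tot, omega * u_n / tot

    def site_fractions(self) -> tuple[float, float]:
        """Neutral (omega=1) synonymous/nonsynonymous site proportions."""
        return self.flux_fractions(1.0)

    def ds_dn(self, t: float, omega: float) -> tuple[float, float]:
        """Expected substitutions per synonymous / nonsynonymous site on a
        branch of length t (per-codon units)."""
        fs, fn = self.flux_fractions(omega)
        ps, pn = self.site_fractions()
        return t * fs / ps, t * fn / pn

    def transition_matrix(self, omega: float, t: float) -> np.ndarray:
        Q = self.q(omega)
        return _expm_reversible(Q, self.pi, t)


def _expm_reversible(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    d = np.sqrt(pi)
    S = Q * d[:, None] / d[None, :]
    S = (S + S.T) / 2
    w, V = np.linalg.eigh(S)
    E = (V * np.exp(w * t)) @ V.T
    P = E / d[:, None] * d[None, :]
    np.clip(P, 1e-300, None, out=P)
    return P


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class BranchTree:
    """Rooted tree in index form: node 0..m-1, postorder, edge above each node."""

    parent: list[int]
    children: list[list[int]]
    postorder: list[int]  # excludes root last? includes all, root last
    labels: list[str | None]  # tip labels; None for internal
    lengths: np.ndarray  # edge length above each node (root entry unused)
    edge_names: list[str]  # stable name per edge (above node)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def edges(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.parent[v] >= 0]

    @property
    def tips(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @classmethod
    def from_newick(cls, newick: str) -> "BranchTree":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree) -> "BranchTree":
        nodes = list(tree.preorder_node_iter())
        idx = {id(n): k for k, n in enumerate(nodes)}
        parent = [-1] * len(nodes)
        children: list[list[int]] = [[] for _ in nodes]
        labels: list[str | None] = [None] * len(nodes)
        lengths = np.zeros(len(nodes))
        edge_names = [""] * len(nodes)
        n_internal = 0
        for k, n in enumerate(nodes):
            if n.parent_node is not None:
                p = idx[id(n.parent_node)]
                parent[k] = p
                children[p].append(k)
                lengths[k] = n.edge.length if n.edge.length is not None else 0.0
            if n.taxon is not None:
                labels[k] = n.taxon.label.replace(" ", "_")
                edge_names[k] = labels[k]
            else:
                name = n.label if n.label else f"node{n_internal}"
                n_internal += 1
                edge_names[k] = name
        post = [idx[id(n)] for n in tree.postorder_node_iter()]
        return cls(parent, children, post, labels, lengths, edge_names)

    def foreground_from_tags(self, tag: str = "#1") -> set[str]:
        """Edges whose name carries a codeml-style tag suffix; tags stripped."""
        fg = set()
        for k in range(self.n_nodes):
            if self.edge_names[k].endswith(tag):
                self.edge_names[k] = self.edge_names[k][: -len(tag)]
                if self.labels[k] is not None:
                    self.labels[k] = self.edge_names[k]
                fg.add(self.edge_names[k])
        return fg


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """In-frame nucleotide alignment keyed by taxon; gene_set is a label."""

    sequences: dict[str, str]
    gene_set: str = ""

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) > 1:
            raise ValueError("alignment rows differ in length")
        L = lens.pop() if lens else 0
        if L % 3:
            raise ValueError(f"alignment length {L} not a codon multiple")
        for taxon, seq in self.sequences.items():
            for k in range(0, L, 3):
                c = seq[k : k + 3].upper()
                if "-" in c or "N" in c:
                    continue
                if c in STOP_CODONS and k < L - 3:
                    raise ValueError(f"internal stop codon in {taxon} at codon {k // 3}")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    def codon_indices(self) -> np.ndarray:
        """(n_taxa, n_codons) int matrix; -1 for missing (gap/N/terminal stop)."""
        out = np.full((len(self.sequences), self.n_codons), -1, dtype=np.int64)
        for r, seq in enumerate(self.sequences.values()):
            seq = seq.upper()
            for k in range(self.n_codons):
                out[r, k] = _CODON_IDX.get(seq[3 * k : 3 * k + 3], -1)
        return out


def back_translate(protein_alignment: Mapping[str, str], cds_map: Mapping[str, str], gene_set: str = "") -> CodonAlignment:
    """Thread unaligned CDS onto a protein alignment (PAL2NAL-style).

    Each amino acid is replaced by its source codon, each gap by ``---``.
    The CDS must translate exactly to the ungapped protein row (a terminal
    stop codon on the CDS is tolerated and dropped).
    """
    from Bio.Seq import Seq

    out: dict[str, str] = {}
    for taxon, prot in protein_alignment.items():
        if taxon not in cds_map:
            raise KeyError(f"no CDS for {taxon!r}")
        cds = cds_map[taxon].upper()
        if len(cds) % 3:
            raise ValueError(f"CDS for {taxon} not a codon multiple")
        codons = [cds[k : k + 3] for k in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        residues = [a for a in prot if a != "-"]
        if len(codons) != len(residues):
            raise ValueError(
                f"{taxon}: CDS encodes {len(codons)} residues, protein row has {len(residues)}"
            )
        for pos, (codon, aa) in enumerate(zip(codons, residues)):
            trans = str(Seq(codon).translate())
            if aa != "X" and trans != aa:
                raise ValueError(
                    f"{taxon}: codon {codon} at residue {pos} translates to {trans}, protein has {aa}"
                )
        it = iter(codons)
        out[taxon] = "".join("---" if a == "-" else next(it) for a in prot)
    return CodonAlignment(out, gene_set=gene_set)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _compress(aln: CodonAlignment, taxa_order: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    M = aln.codon_indices()
    rows = [aln.taxa.index(t) for t in taxa_order]
    M = M[rows]
    cols, weights = np.unique(M, axis=1, return_counts=True)
    return cols, weights.astype(float)


class _Likelihood:
    def __init__(self, aln: CodonAlignment, tree: BranchTree, pi: np.ndarray):
        self.tree = tree
        self.pi = pi
        tip_labels = [tree.labels[v] for v in tree.tips]
        missing = [t for t in tip_labels if t not in aln.sequences]
        if missing:
            raise ValueError(f"tree tips absent from alignment: {missing}")
        cols, self.weights = _compress(aln, tip_labels)
        self.npat = cols.shape[1]
        # tip conditional likelihoods
        self.tipL: dict[int, np.ndarray] = {}
        for r, v in enumerate(tree.tips):
            Lv = np.zeros((self.npat, N_STATES))
            states = cols[r]
            obs = states >= 0
            Lv[obs, states[obs]] = 1.0
            Lv[~obs, :] = 1.0
            self.tipL[v] = Lv

    def lnL(self, mg: MG94Matrix, lengths: np.ndarray, omega_of_edge: np.ndarray) -> float:
        tree = self.tree
        P: dict[int, np.ndarray] = {}
        cache: dict[tuple[float, float], tuple] = {}
        for v in tree.edges:
            om = float(omega_of_edge[v])
            if om not in cache:
                Q = mg.q(om)
                d = np.sqrt(self.pi)
                S = Q * d[:, None] / d[None, :]
                S = (S + S.T) / 2
                w, V = np.linalg.eigh(S)
                cache[om] = (w, V, d)
            w, V, d = cache[om]
            t = float(lengths[v])
            E = (V * np.exp(w * t)) @ V.T
            P[v] = np.clip(E / d[:, None] * d[None, :], 0.0, None)
        # pruning
        partial: dict[int, np.ndarray] = {}
        scale = np.zeros(self.npat)
        for v in tree.postorder:
            if not tree.children[v]:
                partial[v] = self.tipL[v]
                continue
            Lv = np.ones((self.npat, N_STATES))
            for c in tree.children[v]:
                Lv = Lv * (partial[c] @ P[c].T)
                del partial[c]
            m = Lv.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            scale += np.log(m)
            partial[v] = Lv / m[:, None]
        root = tree.root
        site = partial[root] @ self.pi
        site = np.clip(site, 1e-300, None)
        return float(((np.log(site) + scale) * self.weights).sum())


@dataclass
class RateResult:
    """Estimates for one gene set under one branch model."""

    gene_set: str
    model: str  # one_ratio | two_ratio | free_ratio
    lnL: float
    kappa: float
    per_branch: dict[str, tuple[float, float, float]]  # edge -> (dS, dN, omega)
    lengths: dict[str, float]
    n_params: int
    converged: bool = True
    foreground: frozenset[str] = frozenset()

    @property
    def omega(self) -> float:
        """Single omega (one_ratio) or background omega (two_ratio)."""
        return self._omegas[0]

    @property
    def omega_foreground(self) -> float:
        if self.model != "two_ratio":
            raise AttributeError("foreground omega only defined for two_ratio")
        return self._omegas[1]

    _omegas: tuple[float, ...] = (float("nan"),)


@dataclass
class BranchModelTest:
    omega0: float
    omega1: float  # foreground estimate under the two-ratio model
    omega1_background: float
    lnL0: float
    lnL1: float
    p_value: float
    foreground: frozenset[str]


_OMEGA_BOUNDS = (1e-4, 20.0)
_LEN_BOUNDS = (1e-6, 30.0)


def fit_codon_model(
    aln: CodonAlignment,
    tree: BranchTree,
    mode: str = "one_ratio",
    foreground: Iterable[str] | None = None,
    kappa0: float = 2.0,
    omega0: float = 0.3,
    pi: np.ndarray | None = None,
    tol: float = 1e-6,
    init_lengths: Mapping[str, float] | None = None,
) -> RateResult:
    """Maximum-likelihood fit of the MG94 model under a branch-omega scheme.

    mode ``one_ratio``: a single omega; ``two_ratio``: background plus a
    foreground omega on the named edge set; ``free_ratio``: one omega per
    edge.  Branch lengths and kappa are always estimated jointly.
    """
    if mode not in ("one_ratio", "two_ratio", "free_ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "two_ratio":
        if not foreground:
            raise ValueError("two_ratio requires a foreground edge set")
        fg = frozenset(foreground)
        unknown = fg - set(tree.edge_names)
        if unknown:
            raise ValueError(f"foreground edges not in tree: {sorted(unknown)}")
    else:
        fg = frozenset()

    if pi is None:
        pi = f3x4_frequencies(seqs=list(aln.sequences.values()))
    lik = _Likelihood(aln, tree, pi)
    edges = tree.edges
    ne = len(edges)
    edge_name = {v: tree.edge_names[v] for v in edges}

    if mode == "one_ratio":
        n_omega = 1
        omega_class = {v: 0 for v in edges}
    elif mode == "two_ratio":
        n_omega = 2
        omega_class = {v: (1 if edge_name[v] in fg else 0) for v in edges}
    else:
        n_omega = ne
        omega_class = {v: k for k, v in enumerate(edges)}

    base = MG94Matrix(pi, kappa=kappa0)

    omega_of_edge = np.empty(tree.n_nodes)

    def unpack(x):
        kappa = np.exp(x[0])
        omegas = np.exp(x[1 : 1 + n_omega])
        lens = np.exp(x[1 + n_omega :])
        return kappa, omegas, lens

    def nll(x):
        kappa, omegas, lens = unpack(x)
        mg = base.with_kappa(kappa)
        lengths = np.zeros(tree.n_nodes)
        for k, v in enumerate(edges):
            lengths[v] = lens[k]
            omega_of_edge[v] = omegas[omega_class[v]]
        return -lik.lnL(mg, lengths, omega_of_edge)

    if init_lengths:
        l0 = np.array([max(init_lengths.get(edge_name[v], 0.05), 1e-4) for v in edges])
    else:
        l0 = np.array([max(float(tree.lengths[v]), 1e-3) for v in edges])
        if not np.isfinite(l0).all() or l0.max() <= 0:
            l0 = np.full(ne, 0.05)
    x0 = np.concatenate([[np.log(kappa0)], np.full(n_omega, np.log(omega0)), np.log(l0)])
    bounds = (
        [(np.log(0.05), np.log(100.0))]
        + [(np.log(_OMEGA_BOUNDS[0]), np.log(_OMEGA_BOUNDS[1]))] * n_omega
        + [(np.log(_LEN_BOUNDS[0]), np.log(_LEN_BOUNDS[1]))] * ne
    )
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol, "maxiter": 500})
    converged = bool(res.success)
    kappa, omegas, lens = unpack(res.x)
    mg = base.with_kappa(kappa)
    per_branch = {}
    lengths_out = {}
    for k, v in enumerate(edges):
        om = float(omegas[omega_class[v]])
        ds, dn = mg.ds_dn(float(lens[k]), om)
        per_branch[edge_name[v]] = (ds, dn, om)
        lengths_out[edge_name[v]] = float(lens[k])
    result = RateResult(
        gene_set=aln.gene_set,
        model=mode,
        lnL=float(-res.fun),
        kappa=float(kappa),
        per_branch=per_branch,
        lengths=lengths_out,
        n_params=1 + n_omega + ne,
        converged=converged,
        foreground=fg,
    )
    result._omegas = tuple(float(o) for o in omegas)
    if not converged:
        log.warning("codon model fit (%s) did not report convergence: %s", mode, res.message)
    return result


def lrt(lnL0: float, lnL1: float, df: int = 1, tol: float = 1e-6) -> float:
    """Upper chi-square tail probability of the likelihood-ratio statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if lnL1 < lnL0 - max(tol, 1e-6):
        raise ValueError(
            f"alternative lnL {lnL1} below null lnL {lnL0}: optimizer fault"
        )
    stat = max(0.0, 2.0 * (lnL1 - lnL0))
    return float(chi2.sf(stat, df))


def branch_model_test(
    aln: CodonAlignment, tree: BranchTree, foreground: Iterable[str], **kw
) -> BranchModelTest:
    """One-ratio vs two-ratio LRT with the given foreground edge set."""
    null = fit_codon_model(aln, tree, mode="one_ratio", **kw)
    alt = fit_codon_model(
        aln,
        tree,
        mode="two_ratio",
        foreground=foreground,
        kappa0=null.kappa,
        omega0=null.omega,
        init_lengths=null.lengths,
        **{k: v for k, v in kw.items() if k not in ("kappa0", "omega0", "init_lengths")},
    )
    if alt.lnL < null.lnL - 1e-4:
        # restart the alternative from neutral inits; nesting guarantees lnL1 >= lnL0
        alt2 = fit_codon_model(aln, tree, mode="two_ratio", foreground=foreground, **kw)
        if alt2.lnL > alt.lnL:
            alt = alt2
    lnL1 = max(alt.lnL, null.lnL)
    return BranchModelTest(
        omega0=null.omega,
        omega1=alt.omega_foreground,
        omega1_background=alt.omega,
        lnL0=null.lnL,
        lnL1=lnL1,
        p_value=lrt(null.lnL, lnL1, df=1),
        foreground=frozenset(foreground),
    )


# ---------------------------------------------------------------------------
# Gene classes and dS summaries
# ---------------------------------------------------------------------------

OTHER_HK = frozenset({"accD", "clpP", "matK", "ycf1", "ycf2", "ycf12"})
OTHER_PS = frozenset({"ccsA", "cemA", "rbcL", "ycf3", "ycf4"})
IR_GENES_ANGIOSPERM = frozenset({"rps12", "rps7", "ndhB", "ycf2", "ycf1", "rpl23", "rpl2"})
IR_GENES_GYMNOSPERM = frozenset({"ycf2", "ndhB", "rps12", "rps7"})
_SC_PREFIXES = ("atp", "chl", "ndh", "pet", "psa", "psb", "rpl", "rpo", "rps")

SC_CLASSES = _SC_PREFIXES + ("other-HK", "other-PS")


def classify_genes(gene_names: Iterable[str], lineage_kind: str = "angiosperm") -> dict[str, str]:
    """Map each gene to its functional class; IR membership is a separate set.

    Classes: the nine prefix families plus other-HK and other-PS; anything
    else lands in ``unclassified`` with a warning.
    """
    if lineage_kind not in ("angiosperm", "gymnosperm"):
        raise ValueError("lineage_kind must be 'angiosperm' or 'gymnosperm'")
    out = {}
    for g in gene_names:
        if g in OTHER_HK:
            out[g] = "other-HK"
        elif g in OTHER_PS:
            out[g] = "other-PS"
        elif g[:3] in _SC_PREFIXES:
            out[g] = g[:3]
        else:
            log.warning("gene %s not in any functional class; marked unclassified", g)
            out[g] = "unclassified"
    return out


def ir_gene_set(lineage_kind: str) -> frozenset[str]:
    if lineage_kind == "angiosperm":
        return IR_GENES_ANGIOSPERM
    if lineage_kind == "gymnosperm":
        return IR_GENES_GYMNOSPERM
    raise ValueError("lineage_kind must be 'angiosperm' or 'gymnosperm'")


DS_RATIO_LOW = 0.5  # dS_IR/dS_SC below this: still evolving at IR-like rates
DS_RATIO_HIGH = 3.7  # above this: fully SC-like acceleration


def ds_ratio_table(
    ds_numerator: Mapping[str, float],
    ds_denominator: Mapping[str, float],
    low: float = DS_RATIO_LOW,
    high: float = DS_RATIO_HIGH,
):
    """Per-key dS ratios with the survey's flag thresholds as annotations.

    Keys with a zero or missing denominator get ratio NaN and flag
    ``undefined``.  Flags: ``IR-like`` (< low), ``SC-like`` (> high),
    ``intermediate`` otherwise.
    """
    import pandas as pd

    rows = []
    for key in ds_numerator:
        num = ds_numerator[key]
        den = ds_denominator.get(key)
        if den is None or den == 0 or not np.isfinite(den):
            rows.append(dict(key=key, ds_num=num, ds_den=den, ratio=float("nan"), flag="undefined"))
            continue
        r = num / den
        flag = "IR-like" if r < low else ("SC-like" if r > high else "intermediate")
        rows.append(dict(key=key, ds_num=num, ds_den=den, ratio=r, flag=flag))
    return pd.DataFrame(rows)


def terminal_ds(result: RateResult, tree: BranchTree) -> dict[str, float]:
    """Terminal-branch dS per taxon from a free-ratio (or any) fit."""
    tips = {tree.labels[v] for v in tree.tips}
    return {name: ds for name, (ds, _, _) in result.per_branch.items() if name in tips}


def root_to_tip_ds(result: RateResult, tree: BranchTree) -> dict[str, float]:
    """Sum of per-branch dS along the path from the root to each tip."""
    out = {}
    for v in tree.tips:
        total = 0.0
        u = v
        while tree.parent[u] >= 0:
            total += result.per_branch[tree.edge_names[u]][0]
            u = tree.parent[u]
        out[tree.labels[v]] = total
    return out
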