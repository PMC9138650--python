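"""Sequence evolution along a tree with CpG deamination hypermutability.

Methylated cytosines in CpG context deaminate spontaneously to thymine, so the
CpG->TpG transition runs one to two orders of magnitude faster than other
transitions; CpG islands, which stay unmethylated, are exempt from this
erosion. The simulator reproduces exactly that structure on a known rooted
tree, producing gap-free leaf alignments with full ground truth (true tree,
root sequence, per-substitution log) for end-to-end validation of the
SNP-mode and CpG-mode pipelines.

Model
-----
Per site, a K80-style process: every base leaves at total rate ``base_rate``
per unit branch length, split between one transition (weight ``ti_tv_ratio``)
and two transversions (weight 1 each). Whenever the *current* sequence has an
unprotected (i.e. methylated) CpG, the C->T rate at the C and the G->A rate at
the paired G are multiplied by ``cpg_multiplier``. Because a substitution can
create or destroy CpG context at its neighbours, each branch is simulated by
Gillespie event sampling with rates re-evaluated after every event — a
site-independent matrix-exponential scheme cannot express this context
dependence. There are no indels, so the leaves are born aligned.

"Methylated" is operationalised as "CpG outside a protected island": islands
flagged protected in the island spec are immune to the multiplier, everything
else is fair game. Protection of a CpG is read at the position of its C.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cpg_profile import DEFAULT_DINUC_TYPES, dinuc_divergence_stats
from .errors import DistanceError, ParameterError
from .msa_io import AlignedSeqSet
from .phylo import Tree, TreeNode

_BASES = "ACGT"
_A, _C, _G, _T = range(4)
_TRANSITION = {(_A, _G), (_G, _A), (_C, _T), (_T, _C)}


@dataclass(frozen=True)
class SubstitutionModel:
    """Rates of the CpG-aware substitution process.

    base_rate
        Expected substitutions per site per unit branch length (at non-CpG
        sites). Branch lengths are therefore in expected-substitutions units.
    ti_tv_ratio
        Transition/transversion rate ratio (kappa).
    cpg_multiplier
        Factor applied to C->T (and G->A on the paired G) at methylated CpGs.
        The biologically reported range is roughly 10-50; default 25.
    protected_fraction
        Fraction of CpG islands exempt from the multiplier; consumed by
        :func:`make_island_spec` when building island intervals.
    """

    base_rate: float = 1.0
    ti_tv_ratio: float = 2.0
    cpg_multiplier: float = 25.0
    protected_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ParameterError("base_rate must be > 0")
        if self.ti_tv_ratio <= 0:
            raise ParameterError("ti_tv_ratio must be > 0")
        if self.cpg_multiplier < 1:
            raise ParameterError("cpg_multiplier must be >= 1")
        if not 0 <= self.protected_fraction <= 1:
            raise ParameterError("protected_fraction must be in [0, 1]")

    def rate_matrix(self) -> np.ndarray:
        """4x4 off-diagonal rates; rows sum to base_rate."""
        kappa = self.ti_tv_ratio
        scale = self.base_rate / (kappa + 2.0)
        q = np.zeros((4, 4))
        for x in range(4):
            for y in range(4):
                if x == y:
                    continue
                q[x, y] = scale * (kappa if (x, y) in _TRANSITION else 1.0)
        return q


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to reproduce one simulation run.

    ``island_spec`` is a tuple of ``(start, end, protected)`` half-open
    intervals enriched for CpG; non-overlapping, within the sequence. If
    ``root_sequence`` is given it is used verbatim (e.g. an i.i.d. uniform
    root for null experiments); otherwise a root is generated from the island
    spec and CpG densities.
    """

    tree: Tree
    root_sequence_length: int
    seed: int
    model: SubstitutionModel = SubstitutionModel()
    island_spec: "tuple[tuple[int, int, bool], ...]" = ()
    cpg_density_in: float = 0.10
    cpg_density_out: float = 0.01
    root_sequence: "str | None" = None

    def __post_init__(self) -> None:
        if self.root_sequence_length < 2:
            raise ParameterError("root_sequence_length must be >= 2")
        spec = tuple(
            (int(s), int(e), bool(p)) for s, e, p in self.island_spec
        )
        object.__setattr__(self, "island_spec", spec)
        prev_end = 0
        for s, e, _ in spec:
            if not (0 <= s < e <= self.root_sequence_length):
                raise ParameterError(f"island ({s}, {e}) outside sequence")
            if s < prev_end:
                raise ParameterError("island intervals overlap or are unsorted")
            prev_end = e
        for node in _preorder(self.tree.root):
            if node is not self.tree.root and node.length is None:
                raise DistanceError("tree branch without length")
            if node.length is not None and node.length < 0:
                raise DistanceError("negative branch length")
        if self.root_sequence is not None:
            if len(self.root_sequence) != self.root_sequence_length:
                raise ParameterError("root_sequence length mismatch")
            if set(self.root_sequence.upper()) - set(_BASES):
                raise ParameterError("root_sequence must be over ACGT")


@dataclass
class SimTruth:
    """Ground truth of one run: true tree, root, mutation log, protection."""

    tree: Tree
    root_sequence: str
    mutations: pd.DataFrame
    protected: np.ndarray  # bool per position
    config: SimConfig

    @property
    def n_substitutions(self) -> int:
        return len(self.mutations)


def _preorder(node: TreeNode):
    yield node
    for child in node.children:
        yield from _preorder(child)


def make_island_spec(
    length: int,
    n_islands: int = 10,
    island_length: int = 200,
    protected_fraction: float = 0.0,
) -> "tuple[tuple[int, int, bool], ...]":
    """Evenly spaced CpG island intervals; the first ``round(f*n)`` protected."""
    if n_islands <= 0:
        return ()
    if n_islands * island_length > length:
        raise ParameterError("islands do not fit in the sequence")
    gap = (length - n_islands * island_length) // (n_islands + 1)
    n_protected = int(round(protected_fraction * n_islands))
    spec = []
    pos = gap
    for i in range(n_islands):
        spec.append((pos, pos + island_length, i < n_protected))
        pos += island_length + gap
    return tuple(spec)


def generate_root_sequence(
    length: int,
    island_spec: "tuple[tuple[int, int, bool], ...]" = (),
    cpg_density_in: float = 0.10,
    cpg_density_out: float = 0.01,
    seed: "int | None" = None,
    rng: "np.random.Generator | None" = None,
) -> str:
    """Random sequence with controlled CpG dinucleotide density.

    The sequence is built left to right: at each position a CpG is planted
    with probability d/(1-d) (d = local target density), which makes the
    expected frequency of CpG starts equal d; remaining positions are filled
    uniformly, excluding G immediately after a C so no accidental CpGs arise.
    Densities above 0.5 are geometrically infeasible (each CpG occupies two
    columns) and raise :class:`ParameterError`.
    """
    for name, d in (("cpg_density_in", cpg_density_in), ("cpg_density_out", cpg_density_out)):
        if not 0 <= d <= 0.5:
            raise ParameterError(f"{name}={d} outside feasible range [0, 0.5]")
    if island_spec and not cpg_density_in > cpg_density_out:
        raise ParameterError("cpg_density_in must exceed cpg_density_out")
    if length == 0:
        return ""
    if rng is None:
        rng = np.random.default_rng(seed)
    in_island = np.zeros(length, dtype=bool)
    for s, e, _ in island_spec:
        in_island[s:e] = True
    out = []
    i = 0
    while i < length:
        d = cpg_density_in if in_island[i] else cpg_density_out
        p_plant = d / (1.0 - d) if d < 0.5 else 1.0
        if i + 1 < length and rng.random() < p_plant:
            out.append("CG")
            i += 2
        else:
            prev = out[-1][-1] if out else ""
            choices = "ACT" if prev == "C" else "ACGT"
            out.append(choices[int(rng.integers(len(choices)))])
            i += 1
    return "".join(out)[:length]


class _RateIndex:
    """Fenwick (binary indexed) tree over per-site rates.

    Supports O(log L) point update and O(log L) sampling of a site with
    probability proportional to its rate.
    """

    __slots__ = ("n", "values", "tree", "total", "_top")

    def __init__(self, values: np.ndarray) -> None:
        self.n = len(values)
        self.values = [float(v) for v in values]
        tree = [0.0] * (self.n + 1)
        for i, v in enumerate(self.values, start=1):
            tree[i] += v
            j = i + (i & -i)
            if j <= self.n:
                tree[j] += tree[i]
        self.tree = tree
        self.total = float(sum(self.values))
        top = 1
        while top * 2 <= self.n:
            top *= 2
        self._top = top

    def set(self, i: int, v: float) -> None:
        delta = v - self.values[i]
        if delta == 0.0:
            return
        self.values[i] = v
        self.total += delta
        j = i + 1
        tree, n = self.tree, self.n
        while j <= n:
            tree[j] += delta
            j += j & -j

    def sample(self, u: float) -> int:
        """Smallest 0-based i with prefix-sum(i) > u, for u in [0, total)."""
        idx = 0
        bit = self._top
        tree, n = self.tree, self.n
        while bit:
            nxt = idx + bit
            if nxt <= n and tree[nxt] <= u:
                u -= tree[nxt]
                idx = nxt
            bit >>= 1
        return min(idx, self.n - 1)


def _site_totals(arr: np.ndarray, prot: np.ndarray, base: float,
                 extra_c: float, extra_g: float) -> np.ndarray:
    """Vectorised per-site total leaving rates for the current sequence."""
    tot = np.full(arr.size, base)
    cpg = (arr[:-1] == _C) & (arr[1:] == _G) & ~prot[:-1]
    tot[:-1] += np.where(cpg, extra_c, 0.0)
    tot[1:] += np.where(cpg, extra_g, 0.0)
    return tot


def _site_total_at(arr, p, prot, base, extra_c, extra_g) -> float:
    t = base
    if arr[p] == _C and p + 1 < arr.size and arr[p + 1] == _G and not prot[p]:
        t += extra_c
    if arr[p] == _G and p > 0 and arr[p - 1] == _C and not prot[p - 1]:
        t += extra_g
    return t


def _evolve_branch(arr, branch_length, branch_name, prot, model, rng, log) -> None:
    """Gillespie event sampling along one branch; mutates *arr* in place."""
    q = model.rate_matrix()
    m = model.cpg_multiplier
    extra_c = q[_C, _T] * (m - 1.0)
    extra_g = q[_G, _A] * (m - 1.0)
    rates = _RateIndex(_site_totals(arr, prot, model.base_rate, extra_c, extra_g))
    L = arr.size
    t = 0.0
    while True:
        total = rates.total
        t += rng.exponential(1.0 / total)
        if t > branch_length:
            return
        p = rates.sample(rng.random() * total)
        x = int(arr[p])
        targets = []
        cum = 0.0
        cpg_flags = []
        for y in range(4):
            if y == x:
                continue
            r = q[x, y]
            flag = False
            if (
                y == _T and x == _C and p + 1 < L and arr[p + 1] == _G
                and not prot[p]
            ):
                r *= m
                flag = True
            elif (
                y == _A and x == _G and p > 0 and arr[p - 1] == _C
                and not prot[p - 1]
            ):
                r *= m
                flag = True
            cum += r
            targets.append((cum, y))
            cpg_flags.append(flag)
        u = rng.random() * cum
        for k, (c, y) in enumerate(targets):
            if u < c:
                break
        arr[p] = y
        log.append(
            (
                branch_name,
                t,
                p,
                _BASES[x],
                _BASES[y],
                cpg_flags[k] and (m > 1.0),
                (x, y) in _TRANSITION,
            )
        )
        for pp in (p - 1, p, p + 1):
            if 0 <= pp < L:
                rates.set(
                    pp,
                    _site_total_at(arr, pp, prot, model.base_rate, extra_c, extra_g),
                )


_LOG_COLUMNS = (
    "branch", "time", "position", "ref_base", "alt_base", "cpg_context", "transition",
)


def evolve_along_tree(cfg: SimConfig) -> "tuple[AlignedSeqSet, SimTruth]":
    """Evolve a root sequence down every branch of the configured tree.

    Returns the leaf alignment (leaves in tree preorder) and the ground truth
    (true tree, root sequence, substitution log as a DataFrame, protection
    mask). Deterministic: identical configs give byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.root_sequence_length
    if cfg.root_sequence is not None:
        root_seq = cfg.root_sequence.upper()
    else:
        root_seq = generate_root_sequence(
            L, cfg.island_spec, cfg.cpg_density_in, cfg.cpg_density_out, rng=rng
        )
    prot = np.zeros(L, dtype=bool)
    for s, e, protected in cfg.island_spec:
        if protected:
            prot[s:e] = True
    arr0 = np.frombuffer(root_seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.int8)
    for k, b in enumerate(_BASES):
        lut[ord(b)] = k
    arr0 = lut[arr0]

    log: list[tuple] = []
    leaves: list[tuple[str, np.ndarray]] = []
    counter = {"n": 0}

    def branch_name(node: TreeNode) -> str:
        if node.label:
            return str(node.label)
        counter["n"] += 1
        return f"internal_{counter['n']}"

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = seq.copy()
            name = branch_name(child)
            if child.length:
                _evolve_branch(
                    child_seq, child.length, name, prot, cfg.model, rng, log
                )
            if child.is_leaf:
                leaves.append((name, child_seq))
            else:
                descend(child, child_seq)

    descend(cfg.tree.root, arr0)
    inv = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)
    labels = tuple(name for name, _ in leaves)
    rows = tuple(inv[seq].tobytes().decode("ascii") for _, seq in leaves)
    aln = AlignedSeqSet(labels, rows)
    truth = SimTruth(
        tree=cfg.tree,
        root_sequence=root_seq,
        mutations=pd.DataFrame(log, columns=_LOG_COLUMNS),
        protected=prot,
        config=cfg,
    )
    return aln, truth


def summarize_divergence(
    aln: AlignedSeqSet,
    truth: SimTruth,
    dinuc_types: "tuple[str, ...]" = DEFAULT_DINUC_TYPES,
    reference_rule: str = "majority",
) -> pd.DataFrame:
    """Divergence statistics of a simulated alignment next to the ground truth.

    One row per dinucleotide type; the true-substitution columns are run-wide
    (identical in every row) for a flat, TSV-friendly table.
    """
    stats = dinuc_divergence_stats(aln, dinuc_types, reference_rule)
    df = stats.to_frame()
    df["n_true_substitutions"] = truth.n_substitutions
    df["n_true_cpg_deaminations"] = (
        int(truth.mutations["cpg_context"].sum()) if len(truth.mutations) else 0
    )
    return df


def _clock_tree(merges, leaf_heights=None) -> Tree:
    """Build an ultrametric tree from nested (left, right, height) tuples."""

    def build(spec) -> TreeNode:
        if isinstance(spec, str):
            return TreeNode(label=spec, height=0.0)
        left, right, h = spec
        l, r = build(left), build(right)
        l.length = h - l.height
        r.length = h - r.height
        return TreeNode(children=(l, r), height=h)

    return Tree(build(merges))


def five_taxon_primate_tree(scale: float = 1.0) -> Tree:
    """A clock-like five-taxon great-ape tree in p-distance units.

    Heights (before scaling): chimp/bonobo split 0.0015, +human 0.006,
    +gorilla 0.008, +orangutan 0.016 — the human-chimp leaf-to-leaf distance
    of ~1.2% matches whole-genome divergence estimates for that pair.
    """
    s = float(scale)
    return _clock_tree(
        (
            (
                (("chimp", "bonobo", 0.0015 * s), "human", 0.006 * s),
                "gorilla",
                0.008 * s,
            ),
            "orangutan",
            0.016 * s,
        )
    )


def three_taxon_caterpillar(h1: float = 0.01, h2: float = 0.03) -> Tree:
    """((A,B),C) clock tree with merge heights h1 < h2."""
    if not 0 < h1 < h2:
        raise ParameterError("need 0 < h1 < h2")
    return _clock_tree((("A", "B", h1), "C", h2))
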